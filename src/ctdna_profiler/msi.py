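"""Microsatellite instability scoring in the style of mSINGS.

Each microsatellite locus is summarised by its allele-length read-count
histogram.  A locus is *unstable* when the number of prominent alleles
(read fraction >= ``min_allele_frac``) exceeds the stable-panel baseline
mean by more than two baseline standard deviations.  The sample-level
score is the fraction of evaluated loci that are unstable; samples with a
fraction >= 0.2 are classified as microsatellite-instable (MSI).  Loci
with insufficient coverage are not evaluated and never enter the
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence


class MsiError(ValueError):
    pass


@dataclass(frozen=True)
class MsiLocus:
    """Allele-length histogram plus stable-panel baseline statistics."""

    locus_id: str
    histogram: Mapping[int, int]
    baseline_mean: float
    baseline_sd: float

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.histogram.values()):
            raise MsiError(f"negative read count at locus {self.locus_id}")
        if self.baseline_sd < 0:
            raise MsiError(f"negative baseline sd at locus {self.locus_id}")


@dataclass(frozen=True)
class MsiResult:
    n_evaluated: int
    n_unstable: int
    fraction: float
    is_msi: bool


def locus_instability(
    locus: MsiLocus,
    min_allele_frac: float = 0.05,
    min_depth: int = 30,
    n_sd: float = 2.0,
) -> bool | None:
    """Per-locus call: ``None`` when total reads < ``min_depth`` (locus not
    evaluated), otherwise unstable iff the prominent-allele count exceeds
    baseline_mean + ``n_sd`` * baseline_sd."""
    total = sum(locus.histogram.values())
    if total < min_depth:
        return None
    n_alleles = sum(1 for c in locus.histogram.values() if c / total >= min_allele_frac)
    return n_alleles > locus.baseline_mean + n_sd * locus.baseline_sd


def classify_msi(
    loci: Sequence[MsiLocus],
    msi_cutoff: float = 0.2,
    min_allele_frac: float = 0.05,
    min_depth: int = 30,
    n_sd: float = 2.0,
) -> MsiResult:
    """Sample-level MSI classification over the evaluated loci.

    Raises :class:`MsiError` when no locus is evaluable.
    """
    calls = [
        locus_instability(locus, min_allele_frac, min_depth, n_sd) for locus in loci
    ]
    evaluated = [c for c in calls if c is not None]
    if not evaluated:
        raise MsiError("no microsatellite locus with sufficient coverage")
    n_unstable = sum(evaluated)
    fraction = n_unstable / len(evaluated)
    return MsiResult(
        n_evaluated=len(evaluated),
        n_unstable=n_unstable,
        fraction=fraction,
        is_msi=fraction >= msi_cutoff,
    )
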