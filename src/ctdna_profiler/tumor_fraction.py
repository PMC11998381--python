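"""ctDNA fraction (tumor fraction) estimation from driver-mutation VAF.

For a clonal mutation present on ``m`` of ``c`` tumor copies, in plasma at
tumor fraction ``tf`` the expected VAF is

    v = tf * m / (tf * c + 2 * (1 - tf))

(normal cells contribute two reference copies).  Inverting:

    tf = 2v / (m + v * (2 - c))

The driver used is the somatic variant with the highest VAF among those
with moderate/high protein impact, after clonal-hematopoiesis subtraction.
Default copy state is a diploid heterozygous driver (m=1, c=2, tf = 2v);
when the driver locus shows loss of heterozygosity, m=1, c=1 and
tf = 2v / (1 + v).  An externally provided estimate (e.g. ichorCNA from
low-pass WGS) is carried alongside for comparison, never recomputed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .variants import Impact, VariantRecord


class TumorFractionError(ValueError):
    pass


class NoDriverError(LookupError):
    """No somatic moderate/high-impact variant is available."""


class CopyModel(enum.Enum):
    DIPLOID_HET = "DIPLOID_HET"
    LOH = "LOH"
    GENERAL = "GENERAL"


@dataclass(frozen=True)
class TumorFractionEstimate:
    tf: float
    driver: tuple[str, int, str, str]
    model: CopyModel
    driver_vaf: float
    clamped: bool = False
    external_tf: float | None = None


def select_driver(somatic: list[VariantRecord]) -> VariantRecord:
    """Pick the likely driver: highest VAF among moderate/high-impact
    somatic variants; ties broken by higher depth, then lexicographic key."""
    eligible = [v for v in somatic if v.impact in (Impact.HIGH, Impact.MODERATE)]
    if not eligible:
        raise NoDriverError("no somatic moderate/high-impact variant")
    return min(eligible, key=lambda v: (-v.vaf, -v.depth, v.key))


def vaf_to_tf(v: float, m: int = 1, c: int = 2) -> float:
    """Invert the mixture identity; result clamped to [0, 1]."""
    if not 0.0 <= v <= 1.0:
        raise TumorFractionError(f"VAF {v} outside [0, 1]")
    if m < 1 or c < m:
        raise TumorFractionError(f"invalid copy state m={m}, c={c}")
    denom = m + v * (2 - c)
    if denom <= 0:
        raise TumorFractionError(f"inconsistent copy model: m={m}, c={c}, v={v}")
    return min(max(2.0 * v / denom, 0.0), 1.0)


def expected_vaf(tf: float, m: int = 1, c: int = 2) -> float:
    """Forward mixture model: expected VAF of a clonal mutation at ``tf``."""
    return tf * m / (tf * c + 2.0 * (1.0 - tf))


def estimate_ctdna_fraction(
    somatic: list[VariantRecord],
    loh_at_driver: bool = False,
    external_tf: float | None = None,
) -> TumorFractionEstimate:
    """Estimate tumor fraction from the driver VAF.

    ``loh_at_driver`` switches the copy model from diploid-het to LOH
    (typically from ``copynumber.assess_loh`` at the driver locus).
    Raises :class:`NoDriverError` when no eligible variant exists — the
    pipeline then reports the fraction as missing.
    """
    driver = select_driver(somatic)
    if loh_at_driver:
        model, m, c = CopyModel.LOH, 1, 1
    else:
        model, m, c = CopyModel.DIPLOID_HET, 1, 2
    raw = 2.0 * driver.vaf / (m + driver.vaf * (2 - c))
    tf = min(max(raw, 0.0), 1.0)
    return TumorFractionEstimate(
        tf=tf,
        driver=driver.key,
        model=model,
        driver_vaf=driver.vaf,
        clamped=(raw != tf),
        external_tf=external_tf,
    )
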