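"""Somatic/germline variant filtering and clonal-hematopoiesis handling.

Plasma cell-free DNA call sets mix true tumor-derived (somatic) variants
with germline variants and clonal hematopoiesis (CH) — blood-cell clones
whose mutations contaminate plasma at low VAF.  The filter chain here is:

1. per-caller plasma calls -> multi-caller consensus (``consensus_snv_filter``)
2. buffy-coat calls       -> germline gating (``germline_filter``)
3. residual buffy calls   -> CH / CHIP flagging (``flag_ch_variants``)
4. plasma consensus calls -> CH subtraction (``subtract_ch``)

Structural variants have their own consensus rule (``sv_consensus_filter``):
events seen by a single caller are discarded unless that caller is Svcaller,
whose calls are trusted alone.

``select_outcome_alterations`` applies the inclusion rule used for all
clinical-outcome analyses: (likely) pathogenic or high-impact SNVs/indels,
amplifications and homozygous deletions; structural variants and
heterozygous deletions are excluded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence


class Impact(enum.Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


class Pathogenicity(enum.Enum):
    PATHOGENIC = "PATHOGENIC"
    LIKELY_PATHOGENIC = "LIKELY_PATHOGENIC"
    VUS = "VUS"
    BENIGN = "BENIGN"
    UNANNOTATED = "UNANNOTATED"


class Origin(enum.Enum):
    SOMATIC = "SOMATIC"
    GERMLINE = "GERMLINE"
    CH = "CH"
    CHIP = "CHIP"
    UNASSIGNED = "UNASSIGNED"


class VariantClass(enum.Enum):
    SNV = "SNV"
    INDEL = "INDEL"


class SVType(enum.Enum):
    DEL = "DEL"
    DUP = "DUP"
    INV = "INV"
    TRA = "TRA"
    FUSION = "FUSION"


#: alteration classes used in outcome / actionability analyses.
ALTERATION_CLASSES = ("SNV", "INDEL", "SV", "AMP", "HETDEL", "HOMDEL")

PATHOGENIC_SET = frozenset({Pathogenicity.PATHOGENIC, Pathogenicity.LIKELY_PATHOGENIC})


class VariantValidationError(ValueError):
    """Raised when call sets violate a structural precondition."""


@dataclass(frozen=True)
class VariantRecord:
    """One SNV/indel call.  ``pos`` is 1-based (VCF convention)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    depth: int
    callers: frozenset[str]
    impact: Impact = Impact.MODIFIER
    pathogenicity: Pathogenicity = Pathogenicity.UNANNOTATED
    population_af: float | None = None
    origin: Origin = Origin.UNASSIGNED
    variant_class: VariantClass = VariantClass.SNV
    gene: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise VariantValidationError(f"vaf {self.vaf} outside [0, 1] at {self.key}")
        if self.depth < 0:
            raise VariantValidationError(f"negative depth at {self.key}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SVRecord:
    """A structural variant; breakpoints are stored canonically ordered."""

    sv_type: SVType
    breakpoint1: tuple[str, int]
    breakpoint2: tuple[str, int]
    callers: frozenset[str]
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.breakpoint2 < self.breakpoint1:
            object.__setattr__(self, "breakpoint1", self.breakpoint2)
            object.__setattr__(self, "breakpoint2", self.breakpoint1)


@dataclass(frozen=True)
class FilterThresholds:
    """Gates for the variant filter chain.

    ``min_snv_callers``: supporting callers required for a somatic SNV/indel.
    ``germline_min_vaf`` / ``germline_max_pop_af``: buffy-coat germline gates
    (strict ``>`` and ``<`` respectively).
    ``chip_min_vaf``: pathogenic buffy variants at or above this VAF are CHIP.
    ``ch_vaf_band``: half-open buffy VAF band [low, high) treated as CH;
    variants above the band are candidate germline, not CH.
    """

    min_snv_callers: int = 2
    germline_min_vaf: float = 0.4
    germline_max_pop_af: float = 0.005
    chip_min_vaf: float = 0.02
    ch_vaf_band: tuple[float, float] = (0.01, 0.35)
    sv_breakpoint_tol: int = 50

    def __post_init__(self) -> None:
        if self.min_snv_callers < 1:
            raise VariantValidationError("min_snv_callers must be >= 1")
        lo, hi = self.ch_vaf_band
        if not (0.0 <= lo < hi <= 1.0):
            raise VariantValidationError("ch_vaf_band must satisfy 0 <= low < high <= 1")


def consensus_snv_filter(
    per_caller_calls: Iterable[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[VariantRecord]:
    """Merge per-caller SNV/indel calls and keep multi-caller consensus sites.

    Calls sharing (chrom, pos, ref, alt) are merged: the caller set is the
    union of supporters and the VAF the depth-weighted mean over callers.
    Sites supported by fewer than ``min_snv_callers`` callers are dropped.
    Conflicting REF alleles at the same position are a validation error.
    """
    by_key: dict[tuple, list[VariantRecord]] = {}
    ref_at: dict[tuple[str, int], str] = {}
    for rec in per_caller_calls:
        site = (rec.chrom, rec.pos)
        if site in ref_at and ref_at[site] != rec.ref:
            raise VariantValidationError(
                f"inconsistent REF alleles at {rec.chrom}:{rec.pos} "
                f"({ref_at[site]!r} vs {rec.ref!r})"
            )
        ref_at[site] = rec.ref
        by_key.setdefault(rec.key, []).append(rec)

    kept: list[VariantRecord] = []
    for key in sorted(by_key):
        group = by_key[key]
        callers: set[str] = set()
        for rec in group:
            callers |= rec.callers
        if len(callers) < thresholds.min_snv_callers:
            continue
        total_depth = sum(r.depth for r in group)
        if total_depth > 0:
            vaf = sum(r.vaf * r.depth for r in group) / total_depth
        else:
            vaf = sum(r.vaf for r in group) / len(group)
        depth = int(round(total_depth / len(group)))
        proto = group[0]
        kept.append(replace(proto, vaf=vaf, depth=depth, callers=frozenset(callers)))
    return kept


def _same_sv(a: SVRecord, b: SVRecord, tol: int) -> bool:
    if a.sv_type is not b.sv_type:
        return False
    for bp_a, bp_b in ((a.breakpoint1, b.breakpoint1), (a.breakpoint2, b.breakpoint2)):
        if bp_a[0] != bp_b[0] or abs(bp_a[1] - bp_b[1]) > tol:
            return False
    return True


def sv_consensus_filter(
    per_caller_svs: Sequence[SVRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[SVRecord]:
    """Consensus rule for SVs: drop single-caller events unless the sole
    caller is ``svcaller``.  Events from different callers within the
    breakpoint tolerance are merged into one record."""
    merged: list[SVRecord] = []
    for sv in per_caller_svs:
        for i, m in enumerate(merged):
            if _same_sv(sv, m, thresholds.sv_breakpoint_tol):
                merged[i] = replace(
                    m,
                    callers=frozenset(m.callers | sv.callers),
                    genes=tuple(dict.fromkeys(m.genes + sv.genes)),
                )
                break
        else:
            merged.append(sv)
    kept = []
    for sv in merged:
        callers = {c.lower() for c in sv.callers}
        if len(callers) >= 2 or callers == {"svcaller"}:
            kept.append(sv)
    return kept


def germline_filter(
    buffy_calls: Iterable[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[VariantRecord]:
    """Germline gating on buffy-coat calls: VAF > 0.4, moderate/high impact
    and gnomAD-style population AF < 0.005.  Missing population AF is
    treated as 0 (absence from population databases implies rarity)."""
    kept = []
    for rec in buffy_calls:
        pop_af = rec.population_af if rec.population_af is not None else 0.0
        if (
            rec.vaf > thresholds.germline_min_vaf
            and rec.impact in (Impact.HIGH, Impact.MODERATE)
            and pop_af < thresholds.germline_max_pop_af
        ):
            kept.append(replace(rec, origin=Origin.GERMLINE))
    return kept


def flag_ch_variants(
    buffy_calls: Iterable[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[VariantRecord]:
    """Flag likely clonal-hematopoiesis variants among (non-germline) buffy
    calls.  Buffy VAF within ``ch_vaf_band`` marks CH; CH variants that are
    additionally (likely) pathogenic at VAF >= ``chip_min_vaf`` are CHIP."""
    lo, hi = thresholds.ch_vaf_band
    flagged = []
    for rec in buffy_calls:
        if not (lo <= rec.vaf < hi):
            continue
        origin = Origin.CH
        if rec.pathogenicity in PATHOGENIC_SET and rec.vaf >= thresholds.chip_min_vaf:
            origin = Origin.CHIP
        flagged.append(replace(rec, origin=origin))
    return flagged


def subtract_ch(
    plasma_calls: Iterable[VariantRecord],
    ch_set: Iterable[VariantRecord],
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Remove buffy-flagged CH variants from a plasma call set.

    Returns ``(somatic, removed)``; removed records keep their plasma VAF so
    the plasma leakage of each CH clone can be reported.  Applies to both
    baseline and progression samples.
    """
    ch_keys = {rec.key for rec in ch_set}
    somatic: list[VariantRecord] = []
    removed: list[VariantRecord] = []
    for rec in plasma_calls:
        if rec.key in ch_keys:
            removed.append(replace(rec, origin=Origin.CH))
        else:
            out = rec if rec.origin is Origin.SOMATIC else replace(rec, origin=Origin.SOMATIC)
            somatic.append(out)
    return somatic, removed


@dataclass(frozen=True)
class Alteration:
    """A gene-level alteration record used by outcome and actionability
    analyses; ``alteration_class`` is one of ``ALTERATION_CLASSES``."""

    gene: str
    alteration_class: str
    pathogenicity: Pathogenicity = Pathogenicity.UNANNOTATED
    impact: Impact = Impact.MODIFIER
    origin: Origin = Origin.SOMATIC
    vaf: float | None = None

    def __post_init__(self) -> None:
        if self.alteration_class not in ALTERATION_CLASSES:
            raise VariantValidationError(
                f"unknown alteration class {self.alteration_class!r}"
            )


def apply_curation_overrides(
    records: Iterable[VariantRecord], overrides_path
) -> list[VariantRecord]:
    """Deterministic stand-in for manual review: a TSV with columns
    chrom, pos, ref, alt, action (keep/drop) forces individual calls in or
    out of the set.  'drop' removes a matching record; 'keep' is a no-op
    marker recording that the call was reviewed and retained."""
    import csv

    drops: set[tuple[str, int, str, str]] = set()
    with open(overrides_path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
            action = row["action"].strip().lower()
            if action not in ("keep", "drop"):
                raise VariantValidationError(
                    f"curation override row {i}: unknown action {row['action']!r}"
                )
            if action == "drop":
                drops.add((row["chrom"], int(row["pos"]), row["ref"], row["alt"]))
    return [r for r in records if r.key not in drops]


def select_outcome_alterations(alterations: Iterable[Alteration]) -> list[Alteration]:
    """Inclusion rule for clinical-outcome analyses: keep (likely) pathogenic
    or high-impact SNVs/indels, amplifications and homozygous deletions;
    exclude structural variants and heterozygous deletions."""
    kept = []
    for alt in alterations:
        if alt.alteration_class in ("AMP", "HOMDEL"):
            kept.append(alt)
        elif alt.alteration_class in ("SNV", "INDEL"):
            if alt.pathogenicity in PATHOGENIC_SET or alt.impact is Impact.HIGH:
                kept.append(alt)
    return kept
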