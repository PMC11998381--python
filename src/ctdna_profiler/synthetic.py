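"""Synthetic mCRPC liquid-biopsy cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes, so every pipeline stage is testable without patient data:

* tumor-fraction-driven variant allele frequencies — a clonal mutation on
  ``m`` of ``c`` tumor copies has expected plasma VAF
  ``tf*m / (tf*c + 2(1-tf))``; observed VAFs are binomial draws at
  Poisson-distributed depth,
* segment log2 ratios centred on ``log2((tf*c + 2(1-tf)) / 2)`` with
  Gaussian noise shrinking as 1/sqrt(bins),
* multi-caller detection noise (logistic sensitivity in the expected
  alt-read count, uniform panel false positives),
* buffy-coat clonal-hematopoiesis variants leaking into plasma at
  correlated VAFs,
* heterozygous-SNP allele ratios reflecting allelic imbalance,
* microsatellite allele-length histograms with an excess of prominent
  alleles in MSI-positive patients,
* proportional-hazards PFS/OS with per-gene-set hazard multipliers and
  PSA series whose PCWG3-derived progression time matches the survival
  draw.

Every simulated observable traces back to one :class:`TruthRecord`, which
enables parameter-recovery tests.  A single global seed drives per-patient
substreams derived deterministically, so partial re-simulation is
reproducible and a fixed seed yields byte-identical output.

The plasma somatic call sets emulate callers run against the matched
germline sample, so germline variants appear in the buffy-coat call set
(and as heterozygous-SNP allele ratios) but not among plasma somatic
candidate calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .copynumber import Segment, SnpBaf
from .msi import MsiLocus
from .outcomes import OutcomeRecord, psa_progression_time
from .panel import CH_GENES, CHROM_LENGTHS, GENE_SETS, PANEL
from .tumor_fraction import expected_vaf
from .variants import (
    Impact,
    Origin,
    Pathogenicity,
    SVRecord,
    SVType,
    VariantClass,
    VariantRecord,
)

SNV_CALLERS = ("mutect2", "strelka2", "vardict", "varscan2")
SV_CALLERS = ("svcaller", "svict", "lumpy", "svaba")

BIN_SIZE = 100_000
EVENT_COPIES = {"AMP": 8, "HETDEL": 1, "HOMDEL": 0}


class ConfigError(ValueError):
    """A SimulationConfig field failed validation; the message names it."""


@dataclass(frozen=True)
class CallerProfile:
    """Detection model for one SNV caller: logistic sensitivity in the
    expected alt-read count, plus a uniform panel false-positive rate."""

    midpoint_alt_reads: float = 8.0
    slope: float = 0.6
    fp_per_mb: float = 0.05


@dataclass
class PsaParams:
    """PSA-series generator knobs.  ``decline_rate`` / ``relapse_rate`` are
    dimensionless multipliers on the log-scale decline to nadir and the
    post-nadir exponential rise (0 disables the phase entirely)."""

    baseline_range: tuple[float, float] = (10.0, 300.0)
    nadir_frac_range: tuple[float, float] = (0.03, 0.35)
    decline_rate: float = 1.0
    relapse_rate: float = 1.0
    sampling_interval: float = 0.5
    transient_psa50_frac: float = 0.3
    horizon_months: float = 40.0


@dataclass
class SimulationConfig:
    n_patients: int = 50
    seed: int = 0
    tf_range: tuple[float, float] = (0.03, 0.75)
    gene_event_probs: dict[str, dict[str, float]] = field(default_factory=lambda: default_gene_event_probs())
    caller_profiles: dict[str, CallerProfile] = field(default_factory=lambda: {c: CallerProfile() for c in SNV_CALLERS})
    ch_rate: float = 0.13
    germline_rate: float = 0.23
    msi_rate: float = 0.04
    depth_plasma: float = 1000.0
    depth_buffy: float = 300.0
    segment_noise_sd: float = 0.1
    hazard_multipliers: dict[str, tuple[float, float]] = field(default_factory=lambda: default_hazard_multipliers())
    censoring_rate: float = 0.15
    baseline_median_pfs: float = 8.0
    baseline_median_os: float = 22.0
    progression_fraction: float = 0.34
    sv_caller_sens: float = 0.6
    svcaller_sens: float = 0.8
    n_msi_loci: int = 30
    snps_per_gene: int = 6
    psa_params: PsaParams = field(default_factory=PsaParams)

    def validate(self) -> None:
        lo, hi = self.tf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError("tf_range must lie within (0, 1)")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.depth_plasma <= 0 or self.depth_buffy <= 0:
            raise ConfigError("depth_plasma and depth_buffy must be > 0")
        for name in ("ch_rate", "germline_rate", "msi_rate", "censoring_rate",
                     "progression_fraction", "sv_caller_sens", "svcaller_sens"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1]")
        for gene, probs in self.gene_event_probs.items():
            if gene not in PANEL:
                raise ConfigError(f"gene_event_probs: unknown panel gene {gene!r}")
            total = sum(probs.values())
            if any(p < 0 for p in probs.values()) or total > 1.0 + 1e-9:
                raise ConfigError(f"gene_event_probs[{gene!r}] must be probabilities summing to <= 1")
        for gs, (hr_pfs, hr_os) in self.hazard_multipliers.items():
            if hr_pfs <= 0 or hr_os <= 0:
                raise ConfigError(f"hazard_multipliers[{gs!r}] must be > 0")
        if self.segment_noise_sd < 0:
            raise ConfigError("segment_noise_sd must be >= 0")


@dataclass
class TruthRecord:
    patient_id: str
    tf: float
    gene_events: dict[str, str]
    driver_gene: str | None
    driver_key: tuple[str, int, str, str] | None
    driver_vaf: float | None
    altered_gene_sets: tuple[str, ...] = ()
    responder: bool | None = None
    has_ch: bool = False
    is_msi: bool = False


@dataclass
class PatientTimepoint:
    """All molecular observables for one patient at one timepoint."""

    patient_id: str
    timepoint: str  # "baseline" | "progression"
    per_caller_snvs: dict[str, list[VariantRecord]]
    buffy_calls: list[VariantRecord]
    per_caller_svs: list[SVRecord]
    segments: list[Segment]
    snp_bafs: dict[str, list[SnpBaf]]
    msi_loci: list[MsiLocus]
    external_tf: float
    has_ch: bool = False


def default_gene_event_probs() -> dict[str, dict[str, float]]:
    """Per-gene alteration probabilities shaped after the baseline alteration
    landscape of a ctDNA-selected mCRPC cohort (frequent AR-region
    amplification, TP53/PTEN loss, TMPRSS2 fusions, scattered HRR hits)."""
    probs: dict[str, dict[str, float]] = {g: {"SNV": 0.02} for g in PANEL}
    probs.update(
        {
            "AR": {"AMP": 0.45, "SV": 0.15},
            "AR_ENHANCER": {"AMP": 0.47},
            "TP53": {"SNV": 0.25, "HETDEL": 0.10, "SV": 0.05},
            "PTEN": {"SNV": 0.10, "HOMDEL": 0.12, "HETDEL": 0.08, "SV": 0.05},
            "RB1": {"HETDEL": 0.08, "SNV": 0.04},
            "ATM": {"SNV": 0.16, "HETDEL": 0.05},
            "TMPRSS2": {"SV": 0.35},
            "ERG": {"SV": 0.08},
            "BRAF": {"AMP": 0.05},
            "CHD1": {"HOMDEL": 0.05},
            "CCND1": {"AMP": 0.05},
            "CDKN1B": {"HETDEL": 0.05, "SNV": 0.03},
            "CDKN2A": {"HOMDEL": 0.05},
            "ARID1A": {"SNV": 0.06},
            "BRCA1": {"SNV": 0.05},
            "BRCA2": {"SNV": 0.08, "HOMDEL": 0.04},
            "CDK12": {"SNV": 0.06},
            "CHEK2": {"SNV": 0.05},
            "PIK3CA": {"SNV": 0.05},
            "CTNNB1": {"SNV": 0.04},
            "MLH1": {"HOMDEL": 0.02},
        }
    )
    return probs


def default_hazard_multipliers() -> dict[str, tuple[float, float]]:
    """(PFS, OS) hazard ratios per altered gene set; single-gene keys are
    treated as singleton sets.  Values echo effect sizes reported for
    PI3K/PTEN, cell-cycle and chromatin-modulator alterations in mCRPC."""
    return {
        "PI3K": (3.9, 4.9),
        "cell_cycle": (2.7, 4.1),
        "chromatin": (8.8, 4.0),
        "BRAF": (6.0, 3.0),
    }


def _substream(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng([seed, *keys])


def segment_log2_mean(tf: float, copies: float) -> float:
    """Expected segment log2 ratio for tumor copy number ``copies`` in a
    plasma mixture at tumor fraction ``tf``."""
    return math.log2((tf * copies + 2.0 * (1.0 - tf)) / 2.0)


# ---------------------------------------------------------------------------
# per-patient observables


def _draw_gene_events(config: SimulationConfig, rng: np.random.Generator) -> dict[str, str]:
    events: dict[str, str] = {}
    for gene in sorted(PANEL):
        probs = config.gene_event_probs.get(gene, {})
        u = rng.random()
        cum = 0.0
        for ev in ("AMP", "HETDEL", "HOMDEL", "SNV", "SV"):
            cum += probs.get(ev, 0.0)
            if u < cum:
                events[gene] = ev
                break
    return events


def _simulate_segments(
    tf: float,
    gene_events: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[Segment]:
    segments: list[Segment] = []
    cn_events: dict[str, list[tuple[int, int, int]]] = {}
    for gene, ev in gene_events.items():
        if ev not in EVENT_COPIES:
            continue
        chrom, start, end = PANEL[gene]
        pad = int(rng.integers(300_000, 1_200_000))
        cn_events.setdefault(chrom, []).append(
            (max(start - pad, 0), min(end + pad, CHROM_LENGTHS[chrom]), EVENT_COPIES[ev])
        )
    for chrom in sorted(CHROM_LENGTHS):
        length = CHROM_LENGTHS[chrom]
        cuts = {0, length}
        for a, b, _ in cn_events.get(chrom, []):
            cuts.update((a, b))
        cuts.update(range(10_000_000, length, 10_000_000))
        bounds = sorted(cuts)
        for a, b in zip(bounds, bounds[1:]):
            copies = 2
            for ea, eb, c in cn_events.get(chrom, []):
                if a >= ea and b <= eb:
                    copies = c
                    break
            n_bins = max((b - a) // BIN_SIZE, 1)
            mean = segment_log2_mean(tf, copies)
            noise = rng.normal(0.0, config.segment_noise_sd / math.sqrt(n_bins))
            segments.append(Segment(chrom, a, b, mean + noise, n_bins))
    return segments


def _snv_copy_state(event: str | None) -> tuple[int, int]:
    # SNV on a gene with no CN event: diploid heterozygous.
    return (1, 2)


def _make_snv(
    gene: str,
    tf: float,
    rng: np.random.Generator,
    impact: Impact,
    pathogenicity: Pathogenicity,
    offset: int | None = None,
) -> tuple[tuple[str, int, str, str], float]:
    chrom, start, end = PANEL[gene]
    if offset is None:
        offset = int(rng.integers(1, end - start))
    pos = start + offset  # 1-based: offset >= 1 inside the gene
    v = expected_vaf(tf, *_snv_copy_state(None))
    return (chrom, pos, "C", "T"), v


def _per_caller_snv_calls(
    true_snvs: list[tuple[tuple[str, int, str, str], float, Impact, Pathogenicity]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, list[VariantRecord]]:
    calls: dict[str, list[VariantRecord]] = {c: [] for c in config.caller_profiles}
    for key, v_exp, impact, patho in true_snvs:
        for caller, prof in config.caller_profiles.items():
            exp_alt = v_exp * config.depth_plasma
            p_det = 1.0 / (1.0 + math.exp(-prof.slope * (exp_alt - prof.midpoint_alt_reads)))
            if rng.random() >= p_det:
                continue
            depth = max(int(rng.poisson(config.depth_plasma)), 1)
            alt = rng.binomial(depth, min(v_exp, 1.0))
            if alt == 0:
                continue
            calls[caller].append(
                VariantRecord(
                    chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                    vaf=alt / depth, depth=depth, callers=frozenset({caller}),
                    impact=impact, pathogenicity=patho,
                    variant_class=VariantClass.SNV,
                    gene=_gene_at(key[0], key[1]),
                )
            )
    panel_mb = sum(e - s for _, s, e in PANEL.values()) / 1e6
    genes = sorted(PANEL)
    for caller, prof in config.caller_profiles.items():
        n_fp = rng.poisson(prof.fp_per_mb * panel_mb)
        for _ in range(n_fp):
            gene = genes[int(rng.integers(len(genes)))]
            chrom, start, end = PANEL[gene]
            pos = start + int(rng.integers(1, end - start))
            depth = max(int(rng.poisson(config.depth_plasma)), 1)
            vaf = float(rng.uniform(0.004, 0.02))
            calls[caller].append(
                VariantRecord(
                    chrom=chrom, pos=pos, ref="G", alt="A",
                    vaf=vaf, depth=depth, callers=frozenset({caller}),
                    impact=Impact.LOW, pathogenicity=Pathogenicity.UNANNOTATED,
                    gene=gene,
                )
            )
    return calls


def _gene_at(chrom: str, pos: int) -> str | None:
    for gene, (c, s, e) in PANEL.items():
        if c == chrom and s < pos <= e:
            return gene
    return None


def _simulate_svs(
    gene_events: dict[str, str], config: SimulationConfig, rng: np.random.Generator
) -> list[SVRecord]:
    observed: list[SVRecord] = []
    for gene, ev in sorted(gene_events.items()):
        if ev != "SV":
            continue
        chrom, start, end = PANEL[gene]
        bp1 = (chrom, start + int(rng.integers(0, end - start)))
        bp2 = (chrom, bp1[1] + int(rng.integers(10_000, 500_000)))
        sv_type = SVType.FUSION if gene in ("TMPRSS2", "ERG") else SVType.DEL
        for caller in SV_CALLERS:
            sens = config.svcaller_sens if caller == "svcaller" else config.sv_caller_sens
            if rng.random() < sens:
                jitter = int(rng.integers(-20, 21))
                observed.append(
                    SVRecord(
                        sv_type=sv_type,
                        breakpoint1=(bp1[0], bp1[1] + jitter),
                        breakpoint2=(bp2[0], bp2[1] + jitter),
                        callers=frozenset({caller}),
                        genes=(gene,),
                    )
                )
    return observed


def _simulate_buffy(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[VariantRecord], list[VariantRecord], bool]:
    """Returns (buffy calls, plasma-leaked CH calls, has_ch)."""
    buffy: list[VariantRecord] = []
    leaked: list[VariantRecord] = []
    # Common benign germline SNPs: high population AF, fail the rarity gate.
    genes = sorted(PANEL)
    for _ in range(rng.poisson(3)):
        gene = genes[int(rng.integers(len(genes)))]
        chrom, start, end = PANEL[gene]
        depth = max(int(rng.poisson(config.depth_buffy)), 1)
        vaf = rng.binomial(depth, 0.5) / depth
        buffy.append(
            VariantRecord(
                chrom=chrom, pos=start + int(rng.integers(1, end - start)),
                ref="A", alt="G", vaf=vaf, depth=depth,
                callers=frozenset({"haplotypecaller", "strelka2"}),
                impact=Impact.MODERATE, pathogenicity=Pathogenicity.BENIGN,
                population_af=float(rng.uniform(0.01, 0.4)), gene=gene,
            )
        )
    # Rare deleterious germline variant (HRR-weighted).
    if rng.random() < config.germline_rate:
        gene = GENE_SETS["HRR"][int(rng.integers(len(GENE_SETS["HRR"])))]
        chrom, start, end = PANEL[gene]
        depth = max(int(rng.poisson(config.depth_buffy)), 1)
        vaf = rng.binomial(depth, 0.5) / depth
        patho = (
            Pathogenicity.PATHOGENIC if rng.random() < 0.5 else Pathogenicity.VUS
        )
        buffy.append(
            VariantRecord(
                chrom=chrom, pos=start + int(rng.integers(1, end - start)),
                ref="G", alt="T", vaf=vaf, depth=depth,
                callers=frozenset({"haplotypecaller", "strelka2"}),
                impact=Impact.HIGH if rng.random() < 0.6 else Impact.MODERATE,
                pathogenicity=patho,
                population_af=float(rng.uniform(0.0, 0.004)), gene=gene,
            )
        )
    has_ch = bool(rng.random() < config.ch_rate)
    if has_ch:
        for _ in range(int(rng.integers(1, 3))):
            gene = CH_GENES[int(rng.integers(len(CH_GENES)))]
            chrom, start, end = PANEL[gene]
            buffy_vaf_exp = float(rng.uniform(0.02, 0.30))
            depth = max(int(rng.poisson(config.depth_buffy)), 1)
            vaf = rng.binomial(depth, buffy_vaf_exp) / depth
            patho = (
                Pathogenicity.PATHOGENIC
                if gene in ("TP53", "SF3B1") or rng.random() < 0.3
                else Pathogenicity.VUS
            )
            pos = start + int(rng.integers(1, end - start))
            rec = VariantRecord(
                chrom=chrom, pos=pos, ref="C", alt="A",
                vaf=min(vaf, 0.9), depth=depth,
                callers=frozenset({"haplotypecaller", "strelka2"}),
                impact=Impact.MODERATE, pathogenicity=patho,
                population_af=0.0, gene=gene,
            )
            buffy.append(rec)
            # CH clones shed into plasma at correlated VAF.
            plasma_vaf_exp = min(buffy_vaf_exp * math.exp(rng.normal(0.0, 0.15)), 0.9)
            pdepth = max(int(rng.poisson(config.depth_plasma)), 1)
            pvaf = rng.binomial(pdepth, plasma_vaf_exp) / pdepth
            leaked.append(
                VariantRecord(
                    chrom=chrom, pos=pos, ref="C", alt="A",
                    vaf=pvaf, depth=pdepth, callers=frozenset(SNV_CALLERS),
                    impact=Impact.MODERATE, pathogenicity=patho,
                    population_af=0.0, gene=gene,
                )
            )
    return buffy, leaked, has_ch


def _simulate_bafs(
    tf: float,
    gene_events: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, list[SnpBaf]]:
    bafs: dict[str, list[SnpBaf]] = {}
    for gene in sorted(PANEL):
        ev = gene_events.get(gene)
        chrom, start, end = PANEL[gene]
        if ev == "HETDEL":
            major = 1.0 / (2.0 - tf)
        elif ev == "AMP":
            c = EVENT_COPIES["AMP"]
            major = (tf * (c - 1) + (1.0 - tf)) / (tf * c + 2.0 * (1.0 - tf))
        else:  # neutral, HOMDEL (no tumor copies), SNV, SV
            major = 0.5
        snps = []
        for _ in range(config.snps_per_gene):
            depth = max(int(rng.poisson(config.depth_plasma)), 1)
            p_alt = major if rng.random() < 0.5 else 1.0 - major
            ratio = rng.binomial(depth, p_alt) / depth
            snps.append(SnpBaf(position=start + int(rng.integers(1, end - start)), ratio=ratio))
        bafs[gene] = snps
    return bafs


def default_msi_baseline(n_loci: int = 30) -> list[tuple[str, float, float]]:
    """Stable-panel baseline (locus id, mean, sd of prominent-allele counts);
    a deterministic fixture standing in for a stable reference cohort."""
    return [(f"MS{i:02d}", 1.2 + 0.3 * (i % 2), 0.4) for i in range(n_loci)]


def _simulate_msi_loci(
    is_msi: bool, config: SimulationConfig, rng: np.random.Generator
) -> list[MsiLocus]:
    loci = []
    for locus_id, mean, sd in default_msi_baseline(config.n_msi_loci):
        unstable = rng.random() < (0.45 if is_msi else 0.02)
        ref_len = 20
        if unstable:
            lengths = np.arange(ref_len - 4, ref_len + 3)
            weights = rng.dirichlet(np.full(len(lengths), 5.0))
        else:
            lengths = np.array([ref_len - 1, ref_len, ref_len + 1])
            weights = np.array([0.03, 0.94, 0.03])
        depth = max(int(rng.poisson(300)), 1)
        counts = rng.multinomial(depth, weights)
        histogram = {int(l): int(c) for l, c in zip(lengths, counts) if c > 0}
        loci.append(MsiLocus(locus_id, histogram, mean, sd))
    return loci


# ---------------------------------------------------------------------------
# PSA dynamics


def simulate_psa_series(
    responder: bool,
    primary_resistant: bool,
    params: PsaParams | None = None,
    rng: np.random.Generator | None = None,
    target_progression: float | None = None,
    followup_months: float | None = None,
) -> tuple[tuple[float, float], ...]:
    """Generate a PSA series whose PCWG3-derived progression time matches the
    requested class: responders decline >= 50% before a late relapse;
    primary-resistant series progress by month 3 (a configurable fraction
    after a transient PSA50 dip).  ``target_progression=None`` with
    ``followup_months`` set yields a censored (never-progressing) series.
    """
    params = params or PsaParams()
    rng = rng if rng is not None else np.random.default_rng()
    baseline = float(rng.uniform(*params.baseline_range))
    if target_progression is None and followup_months is None:
        target_progression = (
            float(rng.uniform(1.0, 2.5)) if primary_resistant else float(rng.uniform(4.0, 15.0))
        )
    dt = params.sampling_interval
    if primary_resistant and rng.random() < params.transient_psa50_frac and (
        target_progression is not None and target_progression > 1.0
    ):
        nadir_t, nadir_frac = 0.5, 0.45
    elif responder:
        nadir_frac = float(rng.uniform(*params.nadir_frac_range))
        horizon = target_progression if target_progression is not None else followup_months
        nadir_t = max(0.6 * horizon, dt) if horizon and horizon > 0 else dt
    else:
        nadir_t, nadir_frac = 0.0, 1.0
    nadir_frac = nadir_frac ** params.decline_rate
    nadir_val = max(baseline * nadir_frac, 0.05)
    if target_progression is not None:
        t_end = target_progression + 2.0
        rise_target = max(1.3 * nadir_val, nadir_val + 2.5)
        span = max(target_progression - nadir_t, dt)
        rate = math.log(rise_target / nadir_val) / span * params.relapse_rate
    else:
        t_end = followup_months if followup_months is not None else params.horizon_months
        rate = 0.0
    series: list[tuple[float, float]] = []
    t = 0.0
    while t <= t_end + 1e-9:
        if t <= 0.0:
            v = baseline
        elif t < nadir_t:
            v = baseline * (nadir_val / baseline) ** (t / nadir_t)
        else:
            v = nadir_val * math.exp(rate * (t - nadir_t))
        series.append((round(t, 4), round(v, 3)))
        t += dt
    return tuple(series)


# ---------------------------------------------------------------------------
# outcomes


def _carried_sets(gene_events: dict[str, str]) -> tuple[str, ...]:
    """Gene sets 'altered' for hazard purposes, applying the outcome
    inclusion rule at truth level (SNV/AMP/HOMDEL count; SV/HETDEL do not).
    Single-gene hazard keys (e.g. BRAF) are treated as singleton sets."""
    counted = {g for g, ev in gene_events.items() if ev in ("SNV", "AMP", "HOMDEL")}
    carried = []
    for name in sorted(set(GENE_SETS) | {"BRAF", "CHD1"}):
        members = GENE_SETS.get(name, (name,))
        if counted & set(members):
            carried.append(name)
    return tuple(carried)


def simulate_outcomes(
    truth: Sequence[TruthRecord],
    hazard_multipliers: dict[str, tuple[float, float]] | None = None,
    censoring_rate: float = 0.15,
    seed: int = 0,
    baseline_median_pfs: float = 8.0,
    baseline_median_os: float = 22.0,
    psa_params: PsaParams | None = None,
    derive_pfs_from_psa: bool = True,
) -> list[OutcomeRecord]:
    """Draw PFS/OS from exponential baselines scaled by the product of the
    patient's gene-set hazard multipliers, with independent exponential
    censoring, then synthesize a matching PSA series per patient.

    ``derive_pfs_from_psa=False`` keeps the raw (continuous) hazard-model
    event times instead of the PSA-sampling-grid-derived progression times
    — preferable for simulation studies of the survival estimators, where
    grid quantization would introduce heavy ties."""
    multipliers = hazard_multipliers if hazard_multipliers is not None else default_hazard_multipliers()
    for name, (a, b) in multipliers.items():
        if a <= 0 or b <= 0:
            raise ConfigError(f"hazard_multipliers[{name!r}] must be > 0")
    if not 0.0 <= censoring_rate < 1.0:
        raise ConfigError("censoring_rate must be in [0, 1)")
    out: list[OutcomeRecord] = []
    for i, tr in enumerate(truth):
        rng = _substream(seed, 7001, i)
        mult_pfs = mult_os = 1.0
        for name in tr.altered_gene_sets:
            if name in multipliers:
                mult_pfs *= multipliers[name][0]
                mult_os *= multipliers[name][1]
        rate_pfs = math.log(2.0) / baseline_median_pfs * mult_pfs
        rate_os = math.log(2.0) / baseline_median_os * mult_os
        t_pfs = float(rng.exponential(1.0 / rate_pfs))
        t_os = float(rng.exponential(1.0 / rate_os))
        if censoring_rate > 0.0:
            base_rate = math.log(2.0) / baseline_median_pfs
            c_rate = censoring_rate / (1.0 - censoring_rate) * base_rate
            t_cens = float(rng.exponential(1.0 / c_rate))
        else:
            t_cens = math.inf
        pfs_event = t_pfs <= t_cens
        pfs = min(t_pfs, t_cens)
        os_event = t_os <= max(t_cens, t_pfs)  # OS follow-up extends past PFS
        os_months = min(t_os, max(t_cens, t_pfs) + 12.0)
        resistant = pfs_event and pfs <= 3.0
        responder: bool | None
        if pfs_event:
            responder = not resistant
        elif pfs >= 3.0:
            responder = True
        else:
            responder = None  # censored inside the 3-month window: unevaluable
        if derive_pfs_from_psa:
            series = simulate_psa_series(
                responder=bool(responder),
                primary_resistant=resistant,
                params=psa_params,
                rng=rng,
                target_progression=pfs if pfs_event else None,
                followup_months=None if pfs_event else pfs,
            )
            derived_t, derived_event = psa_progression_time(series)
        else:
            series = ()
            derived_t, derived_event = pfs, pfs_event
        tr.responder = responder
        out.append(
            OutcomeRecord(
                patient_id=tr.patient_id,
                pfs_months=derived_t if derived_event else pfs,
                pfs_event=derived_event,
                os_months=os_months,
                os_event=bool(os_event),
                psa_series=series,
                responder=responder,
                primary_resistant=resistant,
                ctdna_fraction=tr.tf,
            )
        )
    return out


# ---------------------------------------------------------------------------
# cohort assembly


def _simulate_timepoint(
    patient_id: str,
    timepoint: str,
    tf: float,
    gene_events: dict[str, str],
    driver: tuple[str, Impact, Pathogenicity, int],
    is_msi: bool,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[PatientTimepoint, tuple[str, int, str, str], float]:
    true_snvs: list[tuple[tuple[str, int, str, str], float, Impact, Pathogenicity]] = []
    driver_gene, impact, patho, offset = driver
    driver_key, driver_vaf = _make_snv(driver_gene, tf, rng, impact, patho, offset)
    true_snvs.append((driver_key, driver_vaf, impact, patho))
    for gene, ev in sorted(gene_events.items()):
        if ev != "SNV" or gene == driver_gene:
            continue
        sub = float(rng.uniform(0.3, 1.0))  # subclonal dilution of passengers
        impact_p = Impact.HIGH if rng.random() < 0.35 else Impact.MODERATE
        patho_p = Pathogenicity.PATHOGENIC if rng.random() < 0.5 else Pathogenicity.VUS
        key, v = _make_snv(gene, tf * sub, rng, impact_p, patho_p)
        true_snvs.append((key, v, impact_p, patho_p))
    per_caller = _per_caller_snv_calls(true_snvs, config, rng)
    buffy, leaked, has_ch = _simulate_buffy(config, rng)
    for rec in leaked:
        for caller in per_caller:
            per_caller[caller].append(
                VariantRecord(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alt,
                    vaf=rec.vaf, depth=rec.depth, callers=frozenset({caller}),
                    impact=rec.impact, pathogenicity=rec.pathogenicity,
                    population_af=rec.population_af, gene=rec.gene,
                )
            )
    svs = _simulate_svs(gene_events, config, rng)
    segments = _simulate_segments(tf, gene_events, config, rng)
    bafs = _simulate_bafs(tf, gene_events, config, rng)
    msi_loci = _simulate_msi_loci(is_msi, config, rng)
    external = float(np.clip(tf * math.exp(rng.normal(0.0, 0.15)), 0.005, 0.95))
    tp = PatientTimepoint(
        patient_id=patient_id,
        timepoint=timepoint,
        per_caller_snvs=per_caller,
        buffy_calls=buffy,
        per_caller_svs=svs,
        segments=segments,
        snp_bafs=bafs,
        msi_loci=msi_loci,
        external_tf=external,
        has_ch=has_ch,
    )
    return tp, driver_key, driver_vaf


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[PatientTimepoint], list[OutcomeRecord], list[TruthRecord]]:
    """Simulate a full cohort: baseline timepoints for every patient, a
    progression timepoint for a configurable subset, matched outcomes and
    the ground-truth records everything traces back to."""
    config.validate()
    timepoints: list[PatientTimepoint] = []
    truth: list[TruthRecord] = []
    for i in range(config.n_patients):
        rng = _substream(config.seed, 1001, i)
        pid = f"P{i + 1:03d}"
        tf = float(rng.uniform(*config.tf_range))
        gene_events = _draw_gene_events(config, rng)
        is_msi = bool(rng.random() < config.msi_rate)
        cn_genes = {g for g, ev in gene_events.items() if ev in EVENT_COPIES}
        candidates = [g for g in sorted(PANEL) if g not in cn_genes]
        driver_gene = candidates[int(rng.integers(len(candidates)))]
        driver = (
            driver_gene,
            Impact.HIGH,
            Pathogenicity.PATHOGENIC if rng.random() < 0.7 else Pathogenicity.VUS,
            int(rng.integers(1, PANEL[driver_gene][2] - PANEL[driver_gene][1])),
        )
        gene_events.setdefault(driver_gene, "SNV")
        tp, driver_key, driver_vaf = _simulate_timepoint(
            pid, "baseline", tf, gene_events, driver, is_msi, config, rng
        )
        timepoints.append(tp)
        truth.append(
            TruthRecord(
                patient_id=pid,
                tf=tf,
                gene_events=dict(gene_events),
                driver_gene=driver_gene,
                driver_key=driver_key,
                driver_vaf=driver_vaf,
                altered_gene_sets=_carried_sets(gene_events),
                has_ch=tp.has_ch,
                is_msi=is_msi,
            )
        )
    outcomes = simulate_outcomes(
        truth,
        config.hazard_multipliers,
        config.censoring_rate,
        seed=config.seed,
        baseline_median_pfs=config.baseline_median_pfs,
        baseline_median_os=config.baseline_median_os,
        psa_params=config.psa_params,
    )
    # Progression timepoints for a subset of progressing patients.
    n_prog = int(round(config.progression_fraction * config.n_patients))
    progressed = [i for i, o in enumerate(outcomes) if o.pfs_event][:n_prog]
    for i in progressed:
        rng = _substream(config.seed, 2001, i)
        tr = truth[i]
        events = dict(tr.gene_events)
        if rng.random() < 0.22:
            events["AR"] = "SNV"  # emergent AR resistance mutation
        elif rng.random() < 0.2 and events.get("AR") != "AMP":
            events["AR"] = "SV"
        tf_prog = float(np.clip(tr.tf * math.exp(rng.normal(0.1, 0.2)), 0.01, 0.9))
        driver = (
            tr.driver_gene,
            Impact.HIGH,
            Pathogenicity.PATHOGENIC,
            tr.driver_key[1] - PANEL[tr.driver_gene][1],
        )
        tp, _, _ = _simulate_timepoint(
            tr.patient_id, "progression", tf_prog, events, driver, tr.is_msi, config, rng
        )
        timepoints.append(tp)
    return timepoints, outcomes, truth
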