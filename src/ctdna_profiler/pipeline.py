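"""End-to-end cohort analysis: simulate/load -> filter -> copy number ->
tumor fraction -> MSI -> endpoints/survival -> enrichment -> actionability.

Baseline and progression timepoints are processed independently and then
diffed, so alterations present at progression but absent at baseline are
reported as *emerging*.  Every stage logs input/retained/removed counts,
and the run manifest records the seed plus a hash of the configuration and
of every output file, making rerun identity checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import actionability as act
from . import copynumber as cn
from . import io as cio
from . import msi as msi_mod
from . import outcomes as oc
from . import tumor_fraction as tfmod
from . import variants as var
from .panel import AR_REGION, GENE_SETS, PANEL
from .synthetic import PatientTimepoint, SimulationConfig, simulate_cohort

log = logging.getLogger("ctdna_profiler")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass
class RunConfig:
    output_dir: str | Path = "ctdna_run"
    simulation: SimulationConfig | None = None
    input_dir: str | Path | None = None
    seed: int = 0
    thresholds: var.FilterThresholds = field(default_factory=var.FilterThresholds)
    cn_thresholds: cn.CNThresholds = field(default_factory=cn.CNThresholds)
    msi_cutoff: float = 0.2
    gene_sets: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(GENE_SETS))
    rules_path: str | Path | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.simulation is None and self.input_dir is None:
            raise PipelineError("RunConfig requires either 'simulation' or 'input_dir'")


@dataclass
class PatientProfile:
    """Per-timepoint analysis product feeding outcomes and actionability."""

    patient_id: str
    timepoint: str
    somatic: list[var.VariantRecord]
    removed_ch: list[var.VariantRecord]
    germline: list[var.VariantRecord]
    svs: list[var.SVRecord]
    cn_calls: dict[str, cn.GeneCNCall]
    tf_estimate: tfmod.TumorFractionEstimate | None
    msi_result: msi_mod.MsiResult | None
    alterations: list[var.Alteration]


CN_TO_CLASS = {
    cn.CNStatus.AMP: "AMP",
    cn.CNStatus.DEL: "HETDEL",
    cn.CNStatus.HOMDEL: "HOMDEL",
}


def analyze_timepoint(
    tp: PatientTimepoint,
    thresholds: var.FilterThresholds,
    cn_thresholds: cn.CNThresholds,
    msi_cutoff: float = 0.2,
) -> PatientProfile:
    """Run the molecular analysis chain for one patient timepoint."""
    all_plasma = [r for calls in tp.per_caller_snvs.values() for r in calls]
    consensus = var.consensus_snv_filter(all_plasma, thresholds)
    germline = var.germline_filter(tp.buffy_calls, thresholds)
    germline_keys = {g.key for g in germline}
    ch_candidates = [b for b in tp.buffy_calls if b.key not in germline_keys]
    ch_set = var.flag_ch_variants(ch_candidates, thresholds)
    somatic, removed = var.subtract_ch(consensus, ch_set)
    svs = var.sv_consensus_filter(tp.per_caller_svs, thresholds)
    log.info(
        "%s/%s: plasma per-caller=%d consensus=%d ch_removed=%d somatic=%d "
        "germline=%d svs=%d",
        tp.patient_id, tp.timepoint, len(all_plasma), len(consensus),
        len(removed), len(somatic), len(germline), len(svs),
    )
    cn_calls = {
        gene: cn.call_focal(
            gene, tp.segments, tp.snp_bafs.get(gene, []), tp.external_tf, cn_thresholds
        )
        for gene in sorted(PANEL)
    }
    tf_est = None
    try:
        driver = tfmod.select_driver(somatic)
        loh = cn.assess_loh(
            driver.gene or "", tp.snp_bafs.get(driver.gene or "", []),
            tp.external_tf, cn_calls.get(driver.gene or ""), cn_thresholds,
        )
        tf_est = tfmod.estimate_ctdna_fraction(somatic, loh, tp.external_tf)
    except tfmod.NoDriverError:
        log.info("%s/%s: no eligible driver; tumor fraction reported missing",
                 tp.patient_id, tp.timepoint)
    msi_result = None
    try:
        msi_result = msi_mod.classify_msi(tp.msi_loci, msi_cutoff)
    except msi_mod.MsiError:
        log.info("%s/%s: MSI not evaluable", tp.patient_id, tp.timepoint)
    alterations: list[var.Alteration] = []
    for rec in somatic:
        if rec.gene:
            alterations.append(
                var.Alteration(rec.gene, rec.variant_class.value, rec.pathogenicity,
                               rec.impact, var.Origin.SOMATIC, rec.vaf)
            )
    for rec in germline:
        if rec.gene:
            alterations.append(
                var.Alteration(rec.gene, rec.variant_class.value, rec.pathogenicity,
                               rec.impact, var.Origin.GERMLINE, rec.vaf)
            )
    for sv in svs:
        for gene in sv.genes:
            alterations.append(var.Alteration(gene, "SV"))
    for gene, call in cn_calls.items():
        if call.status in CN_TO_CLASS:
            alterations.append(var.Alteration(gene, CN_TO_CLASS[call.status]))
    return PatientProfile(
        patient_id=tp.patient_id,
        timepoint=tp.timepoint,
        somatic=somatic,
        removed_ch=removed,
        germline=germline,
        svs=svs,
        cn_calls=cn_calls,
        tf_estimate=tf_est,
        msi_result=msi_result,
        alterations=alterations,
    )


def _included_genes(profile: PatientProfile) -> set[str]:
    """Genes with at least one alteration passing the outcome inclusion rule."""
    return {a.gene for a in var.select_outcome_alterations(profile.alterations)}


def alteration_matrix(profiles: list[PatientProfile]) -> pd.DataFrame:
    """Oncoplot-style patients x genes matrix; cells carry the alteration
    codes (AMP/HETDEL/HOMDEL/SNV/INDEL/SV) joined by '+'."""
    rows = {}
    for p in profiles:
        codes: dict[str, set[str]] = {}
        for a in p.alterations:
            codes.setdefault(a.gene, set()).add(a.alteration_class)
        rows[p.patient_id] = {g: "+".join(sorted(c)) for g, c in codes.items()}
    return pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=sorted(PANEL), fill_value=""
    ).fillna("").sort_index()


def survival_analysis(
    profiles: list[PatientProfile],
    outcomes: list[oc.OutcomeRecord],
    gene_sets: dict[str, tuple[str, ...]],
) -> list[oc.SurvivalTestResult]:
    """Uni- and ctDNA%-adjusted Cox regression per gene set and per headline
    single gene, for PFS and OS, BH-corrected per endpoint x adjustment
    family."""
    by_pid = {p.patient_id: p for p in profiles}
    records = [o for o in outcomes if o.patient_id in by_pid]
    covars: dict[str, list[float]] = {}
    tested = dict(gene_sets)
    tested.update({"PTEN": ("PTEN",), "TP53": ("TP53",), "AR_region": AR_REGION})
    for name, members in tested.items():
        covars[name] = [
            float(bool(_included_genes(by_pid[o.patient_id]) & set(members)))
            for o in records
        ]
    results: list[oc.SurvivalTestResult] = []
    for endpoint in ("PFS", "OS"):
        times = [o.pfs_months if endpoint == "PFS" else o.os_months for o in records]
        events = [o.pfs_event if endpoint == "PFS" else o.os_event for o in records]
        ctdna = [o.ctdna_fraction or 0.0 for o in records]
        for adjust in (False, True):
            family = [
                oc.cox_fit(times, events, covars[name], name, endpoint,
                           ctdna_fraction=ctdna, adjust_ctdna=adjust)
                for name in tested
            ]
            results.extend(oc.adjust_family(family))
    return results


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write all outputs; returns the manifest."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = None
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        timepoints, outcomes, truth = simulate_cohort(sim)
        cio.write_cohort(timepoints, outcomes, outdir / "inputs", truth)
        timepoints, outcomes = cio.load_cohort(outdir / "inputs")
    else:
        timepoints, outcomes = cio.load_cohort(config.input_dir)

    profiles = [
        analyze_timepoint(tp, config.thresholds, config.cn_thresholds, config.msi_cutoff)
        for tp in timepoints
    ]
    baseline = [p for p in profiles if p.timepoint == "baseline"]
    progression = {p.patient_id: p for p in profiles if p.timepoint == "progression"}

    # --- variant audit table -------------------------------------------------
    audit_rows = []
    for p in profiles:
        for rec, decision in (
            [(r, "somatic") for r in p.somatic]
            + [(r, "removed_ch") for r in p.removed_ch]
            + [(r, "germline") for r in p.germline]
        ):
            audit_rows.append(
                {
                    "patient_id": p.patient_id, "timepoint": p.timepoint,
                    "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": rec.alt,
                    "gene": rec.gene, "vaf": rec.vaf, "depth": rec.depth,
                    "callers": ",".join(sorted(rec.callers)), "decision": decision,
                }
            )
    pd.DataFrame(audit_rows).to_csv(outdir / "filtered_variants.tsv", sep="\t", index=False)

    # --- gene copy-number calls ---------------------------------------------
    cn_rows = [
        {
            "patient_id": p.patient_id, "timepoint": p.timepoint, "gene": g,
            "status": c.status.value, "gene_log2": c.gene_log2,
            "control_log2": c.control_log2, "baf_supported": c.baf_supported,
        }
        for p in profiles
        for g, c in p.cn_calls.items()
        if c.status not in (cn.CNStatus.NEUTRAL,)
    ]
    pd.DataFrame(cn_rows).to_csv(outdir / "cn_calls.tsv", sep="\t", index=False)

    # --- tumor fraction -------------------------------------------------------
    tf_rows = []
    for p in profiles:
        est = p.tf_estimate
        tf_rows.append(
            {
                "patient_id": p.patient_id, "timepoint": p.timepoint,
                "driver": ":".join(map(str, est.driver)) if est else "",
                "driver_vaf": est.driver_vaf if est else "",
                "model": est.model.value if est else "",
                "tf_estimate": est.tf if est else "",
                "external_tf": est.external_tf if est else "",
            }
        )
    pd.DataFrame(tf_rows).to_csv(outdir / "tf_estimates.tsv", sep="\t", index=False)

    # --- MSI ------------------------------------------------------------------
    msi_rows = [
        {
            "patient_id": p.patient_id, "timepoint": p.timepoint,
            "n_evaluated": p.msi_result.n_evaluated if p.msi_result else 0,
            "n_unstable": p.msi_result.n_unstable if p.msi_result else 0,
            "fraction": p.msi_result.fraction if p.msi_result else "",
            "is_msi": p.msi_result.is_msi if p.msi_result else "",
        }
        for p in profiles
    ]
    pd.DataFrame(msi_rows).to_csv(outdir / "msi_results.tsv", sep="\t", index=False)

    # --- endpoints ------------------------------------------------------------
    for o in outcomes:
        o.primary_resistant = oc.classify_primary_resistance(o)
        o.responder = None if o.primary_resistant is None else not o.primary_resistant
    cio.write_clinical(outcomes, outdir / "endpoints.csv")

    # --- survival -------------------------------------------------------------
    surv = survival_analysis(baseline, outcomes, config.gene_sets)
    pd.DataFrame([dataclasses.asdict(r) for r in surv]).to_csv(
        outdir / "survival_results.tsv", sep="\t", index=False
    )

    # --- enrichment -----------------------------------------------------------
    altered = {p.patient_id: _included_genes(p) for p in baseline}
    labels = {o.patient_id: o.responder for o in outcomes}
    enrich = oc.enrichment_analysis(altered, labels)
    pd.DataFrame([dataclasses.asdict(r) for r in enrich]).to_csv(
        outdir / "enrichment_results.tsv", sep="\t", index=False
    )

    # --- actionability --------------------------------------------------------
    rules = act.load_rules(config.rules_path)
    annotations = [
        act.annotate_actionability(
            p.patient_id, p.alterations, rules,
            msi_positive=bool(p.msi_result and p.msi_result.is_msi),
        )
        for p in baseline
    ]
    (outdir / "actionability.json").write_text(
        json.dumps(
            [
                {
                    "patient_id": a.patient_id,
                    "highest": a.highest,
                    "germline_actionable": a.germline_actionable,
                    "matches": [
                        {"gene": r.gene, "class": r.alteration_class,
                         "framework": r.framework, "level": r.level, "therapy": r.therapy}
                        for r, _ in a.matches
                    ],
                }
                for a in annotations
            ],
            indent=1,
        )
    )
    act.cohort_actionability_summary(annotations).to_csv(
        outdir / "actionability_summary.tsv", sep="\t", index=False
    )

    # --- cohort matrix and emerging alterations -------------------------------
    matrix = alteration_matrix(baseline)
    matrix.to_csv(outdir / "alteration_matrix.tsv", sep="\t")
    emerging_rows = []
    base_by_pid = {p.patient_id: p for p in baseline}
    for pid, prog in sorted(progression.items()):
        base_genes = {(a.gene, a.alteration_class) for a in base_by_pid[pid].alterations}
        for a in prog.alterations:
            if (a.gene, a.alteration_class) not in base_genes:
                emerging_rows.append(
                    {"patient_id": pid, "gene": a.gene, "class": a.alteration_class}
                )
    pd.DataFrame(emerging_rows, columns=["patient_id", "gene", "class"]).to_csv(
        outdir / "emerging_alterations.tsv", sep="\t", index=False
    )

    # --- manifest -------------------------------------------------------------
    cfg_dump = yaml.safe_dump(_config_dict(config), sort_keys=True)
    hasher = hashlib.sha256(cfg_dump.encode())
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            hasher.update(path.relative_to(outdir).as_posix().encode())
            hasher.update(path.read_bytes())
    manifest = {
        "seed": config.seed,
        "n_timepoints": len(profiles),
        "n_baseline": len(baseline),
        "n_progression": len(progression),
        "outputs": sorted(
            p.relative_to(outdir).as_posix()
            for p in outdir.rglob("*")
            if p.is_file() and p.name != "manifest.json"
        ),
        "hash": hasher.hexdigest(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["output_dir"] = str(d["output_dir"])
    if d.get("input_dir") is not None:
        d["input_dir"] = str(d["input_dir"])
    if d.get("rules_path") is not None:
        d["rules_path"] = str(d["rules_path"])
    return json.loads(json.dumps(d, default=str))
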