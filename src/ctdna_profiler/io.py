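"""File formats for cohort exchange.

Per-caller variant calls travel as VCF 4.2 (written and read with pysam;
INFO keys GENE, VAF, DP_CALLER, IMPACT, PATHOGENICITY, POP_AF, CALLERS),
copy-number segments as SEG-like TSV, heterozygous-SNP allele ratios as
TSV, microsatellite locus histograms as JSON, clinical outcomes as CSV and
ground truth as JSON.  ``write_cohort`` / ``load_cohort`` round-trip a
whole simulated cohort through this schema, which is also the schema an
external cohort must follow.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .copynumber import Segment, SnpBaf
from .msi import MsiLocus
from .outcomes import OutcomeRecord
from .panel import CHROM_LENGTHS
from .synthetic import PatientTimepoint, TruthRecord
from .variants import (
    Impact,
    Origin,
    Pathogenicity,
    SVRecord,
    SVType,
    VariantClass,
    VariantRecord,
)


def _vcf_header() -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    for chrom, length in CHROM_LENGTHS.items():
        header.contigs.add(chrom, length=length)
    header.info.add("GENE", 1, "String", "Panel gene symbol")
    header.info.add("VAF", 1, "Float", "Variant allele frequency")
    header.info.add("DP_CALLER", 1, "Integer", "Read depth at the site")
    header.info.add("IMPACT", 1, "String", "Predicted protein impact")
    header.info.add("PATHOGENICITY", 1, "String", "ClinVar/OncoKB-style classification")
    header.info.add("POP_AF", 1, "Float", "Population allele frequency")
    header.info.add("CALLERS", ".", "String", "Supporting callers")
    return header


def write_vcf(records: Sequence[VariantRecord], path: str | Path) -> None:
    header = _vcf_header()
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for rec in sorted(records, key=lambda r: r.key):
            row = vcf.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                stop=rec.pos - 1 + len(rec.ref),
                alleles=(rec.ref, rec.alt),
            )
            if rec.gene:
                row.info["GENE"] = rec.gene
            row.info["VAF"] = rec.vaf
            row.info["DP_CALLER"] = rec.depth
            row.info["IMPACT"] = rec.impact.value
            row.info["PATHOGENICITY"] = rec.pathogenicity.value
            if rec.population_af is not None:
                row.info["POP_AF"] = rec.population_af
            row.info["CALLERS"] = tuple(sorted(rec.callers))
            vcf.write(row)


def read_vcf(path: str | Path) -> list[VariantRecord]:
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for row in vcf:
            info = row.info
            callers = info.get("CALLERS", ())
            if isinstance(callers, str):
                callers = (callers,)
            pop_af = info.get("POP_AF")
            ref, alt = row.alleles[0], row.alleles[1]
            records.append(
                VariantRecord(
                    chrom=row.chrom,
                    pos=row.pos,
                    ref=ref,
                    alt=alt,
                    vaf=float(info["VAF"]),
                    depth=int(info["DP_CALLER"]),
                    callers=frozenset(callers),
                    impact=Impact(info["IMPACT"]),
                    pathogenicity=Pathogenicity(info["PATHOGENICITY"]),
                    population_af=float(pop_af) if pop_af is not None else None,
                    variant_class=(
                        VariantClass.SNV if len(ref) == len(alt) == 1 else VariantClass.INDEL
                    ),
                    gene=info.get("GENE"),
                )
            )
    return records


def write_segments(segments: Sequence[Segment], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"chrom": s.chrom, "start": s.start, "end": s.end,
             "n_bins": s.n_bins, "log2": s.log2}
            for s in segments
        ]
    ).to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> list[Segment]:
    df = pd.read_csv(path, sep="\t")
    return [
        Segment(r.chrom, int(r.start), int(r.end), float(r.log2), int(r.n_bins))
        for r in df.itertuples(index=False)
    ]


def write_bafs(bafs: dict[str, list[SnpBaf]], path: str | Path) -> None:
    rows = [
        {"gene": gene, "position": s.position, "ratio": s.ratio}
        for gene, snps in sorted(bafs.items())
        for s in snps
    ]
    pd.DataFrame(rows, columns=["gene", "position", "ratio"]).to_csv(
        path, sep="\t", index=False
    )


def read_bafs(path: str | Path) -> dict[str, list[SnpBaf]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[SnpBaf]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.gene, []).append(SnpBaf(int(r.position), float(r.ratio)))
    return out


def write_msi_loci(loci: Sequence[MsiLocus], path: str | Path) -> None:
    payload = [
        {
            "locus_id": l.locus_id,
            "histogram": {str(k): v for k, v in sorted(l.histogram.items())},
            "baseline_mean": l.baseline_mean,
            "baseline_sd": l.baseline_sd,
        }
        for l in loci
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_msi_loci(path: str | Path) -> list[MsiLocus]:
    payload = json.loads(Path(path).read_text())
    return [
        MsiLocus(
            d["locus_id"],
            {int(k): int(v) for k, v in d["histogram"].items()},
            float(d["baseline_mean"]),
            float(d["baseline_sd"]),
        )
        for d in payload
    ]


def write_svs(svs: Sequence[SVRecord], path: str | Path) -> None:
    rows = [
        {
            "sv_type": s.sv_type.value,
            "chrom1": s.breakpoint1[0], "pos1": s.breakpoint1[1],
            "chrom2": s.breakpoint2[0], "pos2": s.breakpoint2[1],
            "callers": ",".join(sorted(s.callers)),
            "genes": ",".join(s.genes),
        }
        for s in svs
    ]
    pd.DataFrame(
        rows, columns=["sv_type", "chrom1", "pos1", "chrom2", "pos2", "callers", "genes"]
    ).to_csv(path, sep="\t", index=False)


def read_svs(path: str | Path) -> list[SVRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        SVRecord(
            sv_type=SVType(r.sv_type),
            breakpoint1=(r.chrom1, int(r.pos1)),
            breakpoint2=(r.chrom2, int(r.pos2)),
            callers=frozenset(str(r.callers).split(",")),
            genes=tuple(g for g in str(r.genes).split(",") if g),
        )
        for r in df.itertuples(index=False)
    ]


def write_clinical(outcomes: Sequence[OutcomeRecord], path: str | Path) -> None:
    rows = []
    for o in outcomes:
        rows.append(
            {
                "patient_id": o.patient_id,
                "pfs_months": o.pfs_months,
                "pfs_event": int(o.pfs_event),
                "os_months": o.os_months,
                "os_event": int(o.os_event),
                "ctdna_fraction": o.ctdna_fraction,
                "responder": "" if o.responder is None else int(o.responder),
                "primary_resistant": "" if o.primary_resistant is None else int(o.primary_resistant),
                "psa_series": json.dumps(list(o.psa_series)),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_clinical(path: str | Path) -> list[OutcomeRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for r in df.itertuples(index=False):
        out.append(
            OutcomeRecord(
                patient_id=r.patient_id,
                pfs_months=float(r.pfs_months),
                pfs_event=bool(int(r.pfs_event)),
                os_months=float(r.os_months),
                os_event=bool(int(r.os_event)),
                ctdna_fraction=float(r.ctdna_fraction),
                responder=None if r.responder == "" else bool(int(r.responder)),
                primary_resistant=None if r.primary_resistant == "" else bool(int(r.primary_resistant)),
                psa_series=tuple((float(t), float(v)) for t, v in json.loads(r.psa_series)),
            )
        )
    return out


def write_truth(truth: Sequence[TruthRecord], path: str | Path) -> None:
    payload = [
        {
            "patient_id": t.patient_id,
            "tf": t.tf,
            "gene_events": t.gene_events,
            "driver_gene": t.driver_gene,
            "driver_key": list(t.driver_key) if t.driver_key else None,
            "driver_vaf": t.driver_vaf,
            "altered_gene_sets": list(t.altered_gene_sets),
            "responder": t.responder,
            "has_ch": t.has_ch,
            "is_msi": t.is_msi,
        }
        for t in truth
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# cohort-level round trip


def _tp_dir(root: Path, tp: PatientTimepoint) -> Path:
    return root / tp.patient_id / tp.timepoint


def write_cohort(
    timepoints: Iterable[PatientTimepoint],
    outcomes: Sequence[OutcomeRecord],
    root: str | Path,
    truth: Sequence[TruthRecord] | None = None,
) -> None:
    root = Path(root)
    for tp in timepoints:
        d = _tp_dir(root, tp)
        d.mkdir(parents=True, exist_ok=True)
        for caller, calls in tp.per_caller_snvs.items():
            write_vcf(calls, d / f"plasma.{caller}.vcf")
        write_vcf(tp.buffy_calls, d / "buffy.vcf")
        write_svs(tp.per_caller_svs, d / "svs.tsv")
        write_segments(tp.segments, d / "segments.seg.tsv")
        write_bafs(tp.snp_bafs, d / "snp_baf.tsv")
        write_msi_loci(tp.msi_loci, d / "msi_loci.json")
        (d / "external_tf.json").write_text(
            json.dumps({"external_tf": tp.external_tf, "has_ch": tp.has_ch})
        )
    write_clinical(outcomes, root / "clinical.csv")
    if truth is not None:
        write_truth(truth, root / "truth.json")


def load_cohort(root: str | Path) -> tuple[list[PatientTimepoint], list[OutcomeRecord]]:
    root = Path(root)
    timepoints = []
    for patient_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for tp_dir in sorted(p for p in patient_dir.iterdir() if p.is_dir()):
            per_caller = {}
            for vcf_path in sorted(tp_dir.glob("plasma.*.vcf")):
                caller = vcf_path.name.split(".")[1]
                per_caller[caller] = read_vcf(vcf_path)
            meta = json.loads((tp_dir / "external_tf.json").read_text())
            timepoints.append(
                PatientTimepoint(
                    patient_id=patient_dir.name,
                    timepoint=tp_dir.name,
                    per_caller_snvs=per_caller,
                    buffy_calls=read_vcf(tp_dir / "buffy.vcf"),
                    per_caller_svs=read_svs(tp_dir / "svs.tsv"),
                    segments=read_segments(tp_dir / "segments.seg.tsv"),
                    snp_bafs=read_bafs(tp_dir / "snp_baf.tsv"),
                    msi_loci=read_msi_loci(tp_dir / "msi_loci.json"),
                    external_tf=float(meta["external_tf"]),
                    has_ch=bool(meta.get("has_ch", False)),
                )
            )
    outcomes = read_clinical(root / "clinical.csv")
    return timepoints, outcomes
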