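"""Prostate-cancer gene panel on a synthetic reference genome.

The panel mirrors the composition of a deep targeted-sequencing assay for
metastatic prostate cancer: AR and its upstream enhancer, tumor suppressors
(TP53, PTEN, RB1), cell-cycle and chromatin regulators, the homologous
recombination repair (HRR) genes used for PARP-inhibitor eligibility,
mismatch-repair genes, and common fusion partners (TMPRSS2, ERG).

Coordinates live on a toy reference (15 autosome-like contigs plus chrX,
60 Mb each) so that every gene has room for 3-8 Mb flanking control windows
without a real genome dependency.  Genes are spaced 18 Mb apart, so control
windows never overlap a neighbouring panel gene.
"""

from __future__ import annotations

CHROM_LENGTH = 60_000_000
GENE_LENGTH = 100_000

# Order determines placement: three genes per contig at 12, 30 and 48 Mb.
_AUTOSOMAL_GENES = (
    "AKT1", "APC", "ARID1A",
    "ARID2", "ATM", "ATR",
    "BARD1", "BRAF", "BRCA1",
    "BRCA2", "BRIP1", "CCND1",
    "CDK12", "CDKN1B", "CDKN2A",
    "CHD1", "CHEK1", "CHEK2",
    "CTNNB1", "DNMT3A", "ERG",
    "FANCA", "FANCL", "FOXA1",
    "KMT2C", "MLH1", "MRE11",
    "MSH2", "MSH3", "NBN",
    "PALB2", "PIK3CA", "PPP2R2A",
    "PTEN", "RAD50", "RAD51B",
    "RAD51C", "RAD51D", "RAD54L",
    "RB1", "SF3B1", "SPOP",
    "TMPRSS2", "TP53",
)


def _build_panel() -> dict[str, tuple[str, int, int]]:
    panel: dict[str, tuple[str, int, int]] = {}
    offsets = (12_000_000, 30_000_000, 48_000_000)
    for i, gene in enumerate(_AUTOSOMAL_GENES):
        chrom = f"chr{i // 3 + 1}"
        start = offsets[i % 3]
        panel[gene] = (chrom, start, start + GENE_LENGTH)
    # AR and its enhancer are separate intervals on chrX so "any alteration
    # in the AR region" is computable as a union over the two.
    panel["AR_ENHANCER"] = ("chrX", 29_250_000, 29_300_000)
    panel["AR"] = ("chrX", 30_000_000, 30_100_000)
    return panel


#: gene -> (chrom, start, end), 0-based half-open.
PANEL: dict[str, tuple[str, int, int]] = _build_panel()

#: contig -> length in bp.
CHROM_LENGTHS: dict[str, int] = {
    f"chr{i}": CHROM_LENGTH
    for i in range(1, -(-len(_AUTOSOMAL_GENES) // 3) + 1)
}
CHROM_LENGTHS["chrX"] = CHROM_LENGTH

#: HRR membership follows the PROfound-trial gene list extended with
#: NBN, RAD50, FANCA, ATR and MRE11.
GENE_SETS: dict[str, tuple[str, ...]] = {
    "cell_cycle": ("CCND1", "CDKN1B", "CDKN2A", "RB1"),
    "chromatin": ("ARID1A", "CHD1"),
    "HRR": (
        "BRCA1", "BRCA2", "ATM", "BRIP1", "BARD1", "CDK12", "CHEK1",
        "CHEK2", "FANCL", "PALB2", "PPP2R2A", "RAD51B", "RAD51C",
        "RAD51D", "RAD54L", "NBN", "RAD50", "FANCA", "ATR", "MRE11",
    ),
    "AR_signaling": ("AR", "AR_ENHANCER", "FOXA1", "SPOP"),
    "WNT": ("CTNNB1", "APC"),
    "PI3K": ("PTEN", "PIK3CA", "AKT1"),
}

#: genes in which clonal-hematopoiesis variants are typically observed.
CH_GENES: tuple[str, ...] = ("DNMT3A", "TP53", "SF3B1", "CHEK2", "BRCA2", "KMT2C")

AR_REGION: tuple[str, ...] = ("AR", "AR_ENHANCER")


def write_bed(path) -> None:
    """Export the panel as BED (0-based half-open), the on-disk form of the
    gene coordinates for interoperability with genome-arithmetic tools."""
    with open(path, "w") as fh:
        for gene, (chrom, start, end) in sorted(
            PANEL.items(), key=lambda kv: (kv[1][0], kv[1][1])
        ):
            fh.write(f"{chrom}\t{start}\t{end}\t{gene}\n")


def gene_interval(gene: str) -> tuple[str, int, int]:
    """Return (chrom, start, end) for a panel gene, raising for unknowns."""
    try:
        return PANEL[gene]
    except KeyError:
        raise KeyError(f"gene {gene!r} is not on the panel") from None
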