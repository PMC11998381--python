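import pytest

from ctdna_profiler.synthetic import SimulationConfig, simulate_cohort
from ctdna_profiler.variants import (
    FilterThresholds,
    Impact,
    Pathogenicity,
    VariantRecord,
)


def make_variant(
    chrom="chr1",
    pos=12_000_500,
    ref="C",
    alt="T",
    vaf=0.1,
    depth=1000,
    callers=("mutect2",),
    impact=Impact.MODERATE,
    pathogenicity=Pathogenicity.UNANNOTATED,
    population_af=None,
    gene=None,
):
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        vaf=vaf,
        depth=depth,
        callers=frozenset(callers),
        impact=impact,
        pathogenicity=pathogenicity,
        population_af=population_af,
        gene=gene,
    )


@pytest.fixture(scope="session")
def thresholds():
    return FilterThresholds()


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-patient simulated cohort shared across tests (read-only)."""
    return simulate_cohort(SimulationConfig(n_patients=12, seed=42))
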