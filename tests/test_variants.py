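"""Consensus, germline, CH and outcome-alteration filtering."""

import numpy as np
import pytest

from ctdna_profiler.variants import (
    Alteration,
    FilterThresholds,
    Impact,
    Origin,
    Pathogenicity,
    SVRecord,
    SVType,
    VariantValidationError,
    consensus_snv_filter,
    flag_ch_variants,
    germline_filter,
    select_outcome_alterations,
    subtract_ch,
    sv_consensus_filter,
)

from conftest import make_variant


class TestConsensusSnvFilter:
    def test_two_of_four_callers_retained_one_dropped(self, thresholds):
        calls = [
            make_variant(pos=100, callers=("mutect2",), vaf=0.10, depth=1000),
            make_variant(pos=100, callers=("strelka2",), vaf=0.12, depth=500),
            make_variant(pos=200, callers=("vardict",), vaf=0.2),
        ]
        out = consensus_snv_filter(calls, thresholds)
        assert [v.pos for v in out] == [100]
        assert out[0].callers == frozenset({"mutect2", "strelka2"})
        # depth-weighted mean VAF
        assert out[0].vaf == pytest.approx((0.10 * 1000 + 0.12 * 500) / 1500)

    def test_inconsistent_ref_raises_naming_site(self):
        calls = [
            make_variant(pos=100, ref="C", alt="T"),
            make_variant(pos=100, ref="G", alt="T", callers=("strelka2",)),
        ]
        with pytest.raises(VariantValidationError, match="chr1:100"):
            consensus_snv_filter(calls)

    def test_matches_brute_force_on_random_sites(self, thresholds):
        rng = np.random.default_rng(7)
        callers = ["mutect2", "strelka2", "vardict", "varscan2"]
        calls = []
        for i in range(100):
            pos = int(rng.integers(1, 10_000))
            support = rng.random(4) < 0.5
            for j, c in enumerate(callers):
                if support[j]:
                    calls.append(
                        make_variant(pos=pos, vaf=float(rng.uniform(0.01, 0.5)),
                                     depth=int(rng.integers(100, 2000)), callers=(c,))
                    )
        out_keys = {v.key for v in consensus_snv_filter(calls, thresholds)}
        # brute force: count distinct callers per key directly
        expected = set()
        for rec in calls:
            supporters = {c for r in calls if r.key == rec.key for c in r.callers}
            if len(supporters) >= thresholds.min_snv_callers:
                expected.add(rec.key)
        assert out_keys == expected

    def test_output_subset_and_idempotent(self, thresholds):
        calls = [
            make_variant(pos=p, callers=(c,))
            for p in (1, 2, 3)
            for c in ("mutect2", "vardict")
        ]
        once = consensus_snv_filter(calls, thresholds)
        assert {v.key for v in once} <= {v.key for v in calls}
        assert consensus_snv_filter(once, thresholds) == once


class TestSvConsensusFilter:
    def _sv(self, callers, pos=1000):
        return SVRecord(
            sv_type=SVType.DEL,
            breakpoint1=("chr1", pos),
            breakpoint2=("chr1", pos + 50_000),
            callers=frozenset(callers),
        )

    def test_single_caller_discarded_unless_svcaller(self):
        assert sv_consensus_filter([self._sv({"lumpy"})]) == []
        kept = sv_consensus_filter([self._sv({"svcaller"})])
        assert len(kept) == 1

    def test_two_callers_kept_with_breakpoint_tolerance(self):
        svs = [self._sv({"lumpy"}, pos=1000), self._sv({"svaba"}, pos=1030)]
        kept = sv_consensus_filter(svs)
        assert len(kept) == 1
        assert kept[0].callers == frozenset({"lumpy", "svaba"})

    def test_beyond_tolerance_not_merged(self):
        svs = [self._sv({"lumpy"}, pos=1000), self._sv({"svaba"}, pos=1200)]
        assert sv_consensus_filter(svs) == []


class TestGermlineFilter:
    @pytest.mark.parametrize(
        "vaf,impact,pop_af,kept",
        [
            (0.45, Impact.HIGH, 0.001, True),
            (0.39, Impact.HIGH, 0.001, False),  # VAF gate is strict >0.4
            (0.50, Impact.MODERATE, 0.01, False),  # pop AF gate <0.005
            (0.50, Impact.LOW, 0.001, False),
            (0.41, Impact.MODERATE, 0.004, True),
        ],
    )
    def test_three_gates(self, thresholds, vaf, impact, pop_af, kept):
        rec = make_variant(vaf=vaf, impact=impact, population_af=pop_af)
        out = germline_filter([rec], thresholds)
        assert (len(out) == 1) is kept
        if kept:
            assert out[0].origin is Origin.GERMLINE

    def test_missing_population_af_treated_as_rare(self, thresholds):
        rec = make_variant(vaf=0.5, impact=Impact.HIGH, population_af=None)
        assert len(germline_filter([rec], thresholds)) == 1


class TestChFlagging:
    def test_pathogenic_above_2pct_is_chip(self, thresholds):
        rec = make_variant(vaf=0.05, pathogenicity=Pathogenicity.PATHOGENIC)
        assert flag_ch_variants([rec], thresholds)[0].origin is Origin.CHIP

    def test_vus_in_band_is_ch_not_chip(self, thresholds):
        rec = make_variant(vaf=0.05, pathogenicity=Pathogenicity.VUS)
        assert flag_ch_variants([rec], thresholds)[0].origin is Origin.CH

    def test_above_band_is_candidate_germline_not_ch(self, thresholds):
        rec = make_variant(vaf=0.45)
        assert flag_ch_variants([rec], thresholds) == []


class TestSubtractCh:
    def test_matching_key_removed_with_plasma_vaf(self):
        plasma = [make_variant(pos=100, vaf=0.08), make_variant(pos=200, vaf=0.3)]
        ch = [make_variant(pos=100, vaf=0.06)]
        somatic, removed = subtract_ch(plasma, ch)
        assert [v.pos for v in somatic] == [200]
        assert [v.pos for v in removed] == [100]
        assert removed[0].vaf == pytest.approx(0.08)  # plasma VAF kept for reporting

    def test_empty_ch_set_identity_and_idempotence(self):
        plasma = [make_variant(pos=100)]
        somatic, removed = subtract_ch(plasma, [])
        assert removed == [] and len(somatic) == 1
        again, removed2 = subtract_ch(somatic, [])
        assert again == somatic and removed2 == []


class TestOutcomeAlterationRule:
    @pytest.mark.parametrize(
        "cls,patho,impact,included",
        [
            ("SNV", Pathogenicity.PATHOGENIC, Impact.MODERATE, True),
            ("SNV", Pathogenicity.VUS, Impact.HIGH, True),
            ("SNV", Pathogenicity.VUS, Impact.MODERATE, False),
            ("AMP", Pathogenicity.UNANNOTATED, Impact.MODIFIER, True),
            ("HOMDEL", Pathogenicity.UNANNOTATED, Impact.MODIFIER, True),
            ("HETDEL", Pathogenicity.UNANNOTATED, Impact.MODIFIER, False),
            ("SV", Pathogenicity.UNANNOTATED, Impact.MODIFIER, False),
        ],
    )
    def test_inclusion_rule(self, cls, patho, impact, included):
        alt = Alteration("PTEN", cls, patho, impact)
        assert (select_outcome_alterations([alt]) == [alt]) is included

    def test_unknown_class_rejected(self):
        with pytest.raises(VariantValidationError):
            Alteration("PTEN", "WEIRD")


def test_curation_override_drops_named_call(tmp_path):
    from ctdna_profiler.variants import apply_curation_overrides

    records = [make_variant(pos=100), make_variant(pos=200)]
    path = tmp_path / "overrides.tsv"
    path.write_text(
        "chrom\tpos\tref\talt\taction\n"
        "chr1\t100\tC\tT\tdrop\n"
        "chr1\t200\tC\tT\tkeep\n"
    )
    kept = apply_curation_overrides(records, path)
    assert [r.pos for r in kept] == [200]
    path.write_text("chrom\tpos\tref\talt\taction\nchr1\t100\tC\tT\tmaybe\n")
    with pytest.raises(VariantValidationError, match="row 2"):
        apply_curation_overrides(records, path)


def test_panel_bed_export_round_trip(tmp_path):
    from ctdna_profiler.panel import PANEL, write_bed

    path = tmp_path / "panel.bed"
    write_bed(path)
    lines = path.read_text().strip().split("\n")
    assert len(lines) == len(PANEL)
    chrom, start, end, gene = lines[0].split("\t")
    assert PANEL[gene] == (chrom, int(start), int(end))


def test_threshold_validation():
    with pytest.raises(VariantValidationError):
        FilterThresholds(min_snv_callers=0)
    with pytest.raises(VariantValidationError):
        FilterThresholds(ch_vaf_band=(0.5, 0.2))
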