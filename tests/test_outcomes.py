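"""Endpoint derivation and survival/enrichment statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from ctdna_profiler.outcomes import (
    OutcomeError,
    OutcomeRecord,
    bh_adjust,
    classify_primary_resistance,
    cox_fit,
    enrichment_analysis,
    fisher_two_sided,
    km_logrank,
    km_median,
    psa_progression_time,
    psa_response_flags,
)


# ---------------------------------------------------------------------------
# independent oracles


def fisher_oracle(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        return 1.0  # a fixed margin is zero: only one table is possible
    rv = hypergeom(n, row1, col1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    probs = rv.pmf(support)
    assert probs.sum() == pytest.approx(1.0, abs=1e-12)
    p_obs = rv.pmf(a)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


def bh_oracle(pvals):
    """Step-up BH recomputed from the definition."""
    n = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(n)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        prev = min(prev, pvals[idx] * n / rank)
        adj[idx] = prev
    return np.minimum(adj, 1.0)


# ---------------------------------------------------------------------------


class TestPsaFlags:
    def test_decline_thresholds(self):
        series = [(0.0, 100.0), (1.0, 50.0)]
        flags = psa_response_flags(series, 100.0)
        assert flags == {"psa30": True, "psa50": True, "psa90": False}

    def test_deep_decline_sets_all(self):
        flags = psa_response_flags([(0.0, 100.0), (2.0, 9.0)], 100.0)
        assert all(flags.values())

    def test_rising_series_sets_none(self):
        flags = psa_response_flags([(0.0, 100.0), (1.0, 120.0), (2.0, 150.0)], 100.0)
        assert not any(flags.values())

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(OutcomeError):
            psa_response_flags([(0.0, 1.0)], 0.0)


class TestPsaProgression:
    def test_confirmed_rise_from_nadir(self):
        series = [(0.0, 100.0), (2.0, 10.0), (6.0, 13.0), (7.0, 15.0)]
        t, event = psa_progression_time(series)
        assert event and t == 6.0  # 13 >= 1.25*10 and rise 3 >= 2, confirmed

    def test_rise_below_25pct_is_no_progression(self):
        series = [(0.0, 100.0), (2.0, 10.0), (6.0, 12.0), (8.0, 12.0)]
        t, event = psa_progression_time(series)
        assert not event and t == 8.0

    def test_rise_below_2ng_absolute_is_no_progression(self):
        series = [(0.0, 5.0), (2.0, 1.0), (6.0, 1.9), (8.0, 1.9)]
        assert psa_progression_time(series)[1] is False

    def test_unconfirmed_rise_censored(self):
        # qualifying rise at month 6 but no later measurement >= 3 weeks after
        series = [(0.0, 100.0), (2.0, 10.0), (6.0, 13.0), (6.3, 14.0)]
        t, event = psa_progression_time(series)
        assert not event

    def test_unsorted_series_rejected(self):
        with pytest.raises(OutcomeError):
            psa_progression_time([(2.0, 1.0), (1.0, 2.0)])


class TestPrimaryResistance:
    def _rec(self, pfs, event):
        return OutcomeRecord("P", pfs, event, 10.0, False)

    def test_failure_by_three_months(self):
        assert classify_primary_resistance(self._rec(2.9, True)) is True
        assert classify_primary_resistance(self._rec(3.0, True)) is True  # inclusive

    def test_later_failure_is_responder(self):
        assert classify_primary_resistance(self._rec(3.1, True)) is False

    def test_early_censoring_unevaluable(self):
        # e.g. treatment switched for side effects at month 2
        assert classify_primary_resistance(self._rec(2.0, False)) is None


class TestKmLogrank:
    def test_median_of_five_events(self):
        assert km_median([1, 2, 3, 4, 5], [True] * 5) == 3.0

    def test_identical_groups_null_p(self):
        group = [(float(t), True) for t in range(1, 101)]
        *_, p = km_logrank(group, list(group))
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(3)
        fast = [(float(t), True) for t in rng.exponential(1.0, 200)]
        slow = [(float(t), True) for t in rng.exponential(4.0, 200)]
        m_fast, m_slow, p = km_logrank(fast, slow)
        assert m_fast < m_slow
        assert p < 1e-6

    def test_empty_group_rejected(self):
        with pytest.raises(OutcomeError):
            km_logrank([], [(1.0, True)])


class TestCoxFit:
    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(8)
        n = 300
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1.0, n)
        res = cox_fit(t, [True] * n, x)
        assert res.estimable
        assert res.ci_low < 1.0 < res.ci_high

    def test_planted_hazard_recovered(self):
        rng = np.random.default_rng(9)
        n = 500
        x = (rng.random(n) < 0.3).astype(float)
        t = rng.exponential(1.0 / np.exp(math.log(4) * x))
        res = cox_fit(t, [True] * n, x)
        assert res.ci_low < 4.0 < res.ci_high
        assert res.p < 1e-6

    def test_constant_covariate_non_estimable(self):
        res = cox_fit([1, 2, 3, 4, 5, 6], [True] * 6, [1.0] * 6)
        assert not res.estimable and res.hazard_ratio is None

    def test_collinear_adjustment_non_estimable(self):
        rng = np.random.default_rng(10)
        n = 50
        x = (rng.random(n) < 0.5).astype(float)
        res = cox_fit(
            rng.exponential(1.0, n), [True] * n, x,
            ctdna_fraction=x, adjust_ctdna=True,
        )
        assert not res.estimable


class TestBhAdjust:
    def test_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            pvals = rng.random(50)
            assert bh_adjust(pvals) == pytest.approx(bh_oracle(pvals))

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(13)
        pvals = rng.random(30)
        assert np.all(np.asarray(bh_adjust(pvals)) >= pvals - 1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(OutcomeError):
            bh_adjust([0.5, 1.2])


class TestFisher:
    def test_ar_region_progression_table(self):
        # 16/18 vs 13/18 with AR-region alteration: printed two-sided p 0.40
        assert fisher_two_sided([[16, 2], [13, 5]]) == pytest.approx(0.40, abs=0.005)

    def test_enrichment_table_vs_enumeration(self):
        assert fisher_two_sided([[2, 8], [0, 42]]) == pytest.approx(
            fisher_oracle([[2, 8], [0, 42]])
        )
        assert fisher_two_sided([[2, 8], [0, 42]]) == pytest.approx(0.0339, abs=5e-4)

    def test_symmetric_table_p_one(self):
        assert fisher_two_sided([[5, 5], [5, 5]]) == 1.0

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        table = [[a, b], [c, d]]
        assert fisher_two_sided(table) == pytest.approx(fisher_oracle(table), abs=1e-9)

    def test_row_and_column_swap_invariance(self):
        table = [[7, 2], [3, 9]]
        swapped = [[9, 3], [2, 7]]
        assert fisher_two_sided(table) == pytest.approx(fisher_two_sided(swapped))

    def test_negative_counts_rejected(self):
        with pytest.raises(OutcomeError):
            fisher_two_sided([[1, -1], [2, 3]])


class TestEnrichment:
    def test_braf_like_enrichment(self):
        altered = {f"N{i}": ({"BRAF"} if i < 2 else set()) for i in range(10)}
        altered.update({f"R{i}": set() for i in range(42)})
        labels = {f"N{i}": False for i in range(10)}
        labels.update({f"R{i}": True for i in range(42)})
        results = enrichment_analysis(altered, labels)
        assert len(results) == 1
        res = results[0]
        assert res.gene == "BRAF" and res.direction == 1
        assert res.p == pytest.approx(0.0339, abs=5e-4)

    def test_single_patient_gene_not_tested(self):
        altered = {"A": {"RB1"}, "B": set(), "C": set(), "D": set()}
        labels = {pid: pid in ("A", "B") for pid in altered}
        assert enrichment_analysis(altered, labels) == []

    def test_equal_frequencies_direction_zero(self):
        altered = {"A": {"TP53"}, "B": set(), "C": {"TP53"}, "D": set()}
        labels = {"A": False, "B": False, "C": True, "D": True}
        res = enrichment_analysis(altered, labels)[0]
        assert res.p == 1.0 and res.direction == 0

    def test_unevaluable_patients_excluded(self):
        altered = {"A": {"TP53"}, "B": {"TP53"}, "C": {"TP53"}}
        labels = {"A": False, "B": None, "C": True}
        res = enrichment_analysis(altered, labels)
        assert res[0].n_nonresponders == 1 and res[0].n_responders == 1
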