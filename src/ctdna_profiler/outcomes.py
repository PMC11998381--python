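"""Clinical endpoints and biomarker statistics.

Endpoints
---------
PSA progression-free survival (PFS) runs from treatment start to confirmed
PSA progression; progression follows the PCWG3 reading: a rise of >= 25%
*and* >= 2 ng/mL above the nadir-so-far, confirmed by a second qualifying
measurement at least 3 weeks later.  Confirmed PSA declines of >= 30/50/90%
from baseline give the PSA30/50/90 response flags.  Primary resistance is
treatment failure (PSA progression) by 3 months, boundary inclusive;
patients censored before 3 months are unevaluable.

Statistics
----------
Kaplan-Meier medians with log-rank tests, uni-/multivariate Cox
proportional-hazards regression (multivariate = adjusted for ctDNA
fraction) with a Schoenfeld-residual proportionality check,
Benjamini-Hochberg correction per endpoint family, and two-sided Fisher
exact tests for responder/non-responder enrichment (genes altered in at
least two patients).  Survival machinery is delegated to lifelines;
Fisher to scipy; BH to statsmodels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, proportional_hazard_test
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

#: one month in days, for the 3-week PCWG3 confirmation interval.
DAYS_PER_MONTH = 30.4375
CONFIRM_MONTHS = 21.0 / DAYS_PER_MONTH

PSA_DECLINE_THRESHOLDS = {"psa30": 0.30, "psa50": 0.50, "psa90": 0.90}


class OutcomeError(ValueError):
    pass


@dataclass
class OutcomeRecord:
    patient_id: str
    pfs_months: float
    pfs_event: bool
    os_months: float
    os_event: bool
    psa_series: tuple[tuple[float, float], ...] = ()
    responder: bool | None = None
    primary_resistant: bool | None = None
    ctdna_fraction: float | None = None


@dataclass(frozen=True)
class SurvivalTestResult:
    covariate: str
    endpoint: str
    hazard_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p: float | None
    p_adjusted: float | None = None
    adjusted_for_ctdna: bool = False
    ph_ok: bool | None = None
    estimable: bool = True


@dataclass(frozen=True)
class EnrichmentResult:
    gene: str
    count_nonresponders: int
    n_nonresponders: int
    count_responders: int
    n_responders: int
    p: float
    direction: int  # +1 enriched in non-responders, -1 in responders, 0 equal


def psa_response_flags(
    psa_series: Sequence[tuple[float, float]], baseline: float
) -> dict[str, bool]:
    """PSA30/50/90 flags: any on-treatment value at or below
    (1 - threshold) x baseline."""
    if baseline <= 0:
        raise OutcomeError("baseline PSA must be positive")
    if not psa_series:
        raise OutcomeError("empty PSA series")
    on_treatment = [v for t, v in psa_series if t > 0]
    low = min(on_treatment) if on_treatment else baseline
    return {
        name: low <= (1.0 - frac) * baseline
        for name, frac in PSA_DECLINE_THRESHOLDS.items()
    }


def psa_progression_time(
    psa_series: Sequence[tuple[float, float]],
) -> tuple[float, bool]:
    """PCWG3 PSA progression: first time the value rises >= 25% and
    >= 2 ng/mL above the nadir-so-far, confirmed by a later measurement
    (>= 3 weeks after) meeting both conditions against the same nadir.
    Returns (event time, True) or (last observation time, False)."""
    times = [t for t, _ in psa_series]
    if times != sorted(times):
        raise OutcomeError("PSA series must be sorted by time")
    if not psa_series:
        raise OutcomeError("empty PSA series")
    nadir = math.inf
    for i, (t, v) in enumerate(psa_series):
        if v < nadir:
            nadir = v
        if v >= 1.25 * nadir and v - nadir >= 2.0:
            for t2, v2 in psa_series[i + 1 :]:
                if t2 >= t + CONFIRM_MONTHS and v2 >= 1.25 * nadir and v2 - nadir >= 2.0:
                    return t, True
    return psa_series[-1][0], False


def classify_primary_resistance(outcome: OutcomeRecord) -> bool | None:
    """Treatment failure by 3 months (inclusive).  Patients censored before
    3 months (e.g. a side-effect treatment switch) are unevaluable (None)."""
    if outcome.pfs_months is None:
        return None
    if outcome.pfs_event:
        return outcome.pfs_months <= 3.0
    if outcome.pfs_months < 3.0:
        return None
    return False


def km_median(times: Sequence[float], events: Sequence[bool]) -> float:
    """Product-limit median: first time the survival estimate drops to 0.5
    or below (inf when never reached)."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=bool))
    return float(kmf.median_survival_time_)


def km_logrank(
    group_a: Sequence[tuple[float, bool]],
    group_b: Sequence[tuple[float, bool]],
) -> tuple[float, float, float]:
    """Kaplan-Meier medians of the two groups plus the log-rank p-value."""
    if not group_a or not group_b:
        raise OutcomeError("both groups must be non-empty")
    ta, ea = zip(*group_a)
    tb, eb = zip(*group_b)
    if not any(ea) and not any(eb):
        raise OutcomeError("log-rank test requires at least one event")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return km_median(ta, ea), km_median(tb, eb), float(res.p_value)


def cox_fit(
    times: Sequence[float],
    events: Sequence[bool],
    covariate: Sequence[float],
    covariate_name: str = "alteration",
    endpoint: str = "PFS",
    ctdna_fraction: Sequence[float] | None = None,
    adjust_ctdna: bool = False,
    ph_alpha: float = 0.05,
) -> SurvivalTestResult:
    """Cox proportional-hazards fit for one (binary or continuous) covariate,
    optionally adjusted for ctDNA fraction.  Degenerate designs (constant
    covariate, separation, collinearity with the adjuster) are flagged
    non-estimable rather than raised.  ``ph_ok`` reports the
    Schoenfeld-residual proportionality check at ``ph_alpha`` (rank time
    transform)."""
    data = {
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events, dtype=float),
        covariate_name: np.asarray(covariate, dtype=float),
    }
    if adjust_ctdna:
        if ctdna_fraction is None:
            raise OutcomeError("adjust_ctdna requires ctdna_fraction values")
        data["ctdna_fraction"] = np.asarray(ctdna_fraction, dtype=float)
    df = pd.DataFrame(data)
    if df["event"].sum() < 5 or df[covariate_name].nunique() < 2:
        return SurvivalTestResult(covariate_name, endpoint, None, None, None, None,
                                  adjusted_for_ctdna=adjust_ctdna, estimable=False)
    if adjust_ctdna and np.isclose(
        abs(np.corrcoef(df[covariate_name], df["ctdna_fraction"])[0, 1]), 1.0
    ):
        return SurvivalTestResult(covariate_name, endpoint, None, None, None, None,
                                  adjusted_for_ctdna=True, estimable=False)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return SurvivalTestResult(covariate_name, endpoint, None, None, None, None,
                                  adjusted_for_ctdna=adjust_ctdna, estimable=False)
    with np.errstate(over="ignore"):
        hr = float(np.exp(cph.params_[covariate_name]))
        ci = cph.confidence_intervals_.loc[covariate_name]
        ci_low, ci_high = float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1]))
        p = float(cph.summary.loc[covariate_name, "p"])
    # separation / monotone likelihood: wildly inflated HR or undefined p
    if not (np.isfinite(hr) and np.isfinite(p) and 0.0 <= p <= 1.0):
        return SurvivalTestResult(covariate_name, endpoint, None, None, None, None,
                                  adjusted_for_ctdna=adjust_ctdna, estimable=False)
    ph_ok: bool | None = None
    try:
        ph = proportional_hazard_test(cph, df, time_transform="rank")
        ph_p = float(ph.summary.loc[covariate_name, "p"].min()) if hasattr(
            ph.summary.loc[covariate_name, "p"], "min"
        ) else float(ph.summary.loc[covariate_name, "p"])
        ph_ok = ph_p >= ph_alpha
    except Exception:
        ph_ok = None
    return SurvivalTestResult(
        covariate=covariate_name,
        endpoint=endpoint,
        hazard_ratio=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        p=p,
        adjusted_for_ctdna=adjust_ctdna,
        ph_ok=ph_ok,
    )


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise OutcomeError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])


def adjust_family(results: Sequence[SurvivalTestResult]) -> list[SurvivalTestResult]:
    """BH-adjust one family of survival tests (typically one endpoint x
    adjustment level); non-estimable entries pass through unadjusted."""
    estimable = [r for r in results if r.estimable and r.p is not None]
    adjusted = bh_adjust([r.p for r in estimable])
    adj_iter = iter(adjusted)
    out = []
    for r in results:
        if r.estimable and r.p is not None:
            out.append(replace(r, p_adjusted=float(next(adj_iter))))
        else:
            out.append(r)
    return out


def fisher_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 count table (sum over outcomes at
    most as probable as the observed one)."""
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise OutcomeError("table must be 2x2 with non-negative integer counts")
    return float(fisher_exact(arr, alternative="two-sided")[1])


def enrichment_analysis(
    altered_genes: Mapping[str, set[str]],
    responder_labels: Mapping[str, bool | None],
    min_patients: int = 2,
) -> list[EnrichmentResult]:
    """Per-gene responder/non-responder enrichment.

    ``altered_genes`` maps patient id -> set of altered genes (after the
    outcome-alteration inclusion rule); ``responder_labels`` maps patient
    id -> True (responder), False (primary resistance) or None
    (unevaluable, excluded).  Genes altered in fewer than ``min_patients``
    labeled patients are not tested.
    """
    labeled = [pid for pid, lab in responder_labels.items() if lab is not None]
    responders = [pid for pid in labeled if responder_labels[pid]]
    nonresponders = [pid for pid in labeled if not responder_labels[pid]]
    genes = sorted({g for pid in labeled for g in altered_genes.get(pid, set())})
    results = []
    for gene in genes:
        alt_nr = sum(1 for pid in nonresponders if gene in altered_genes.get(pid, set()))
        alt_r = sum(1 for pid in responders if gene in altered_genes.get(pid, set()))
        if alt_nr + alt_r < min_patients:
            continue
        p = fisher_two_sided(
            [
                [alt_nr, len(nonresponders) - alt_nr],
                [alt_r, len(responders) - alt_r],
            ]
        )
        freq_nr = alt_nr / len(nonresponders) if nonresponders else 0.0
        freq_r = alt_r / len(responders) if responders else 0.0
        direction = 0 if freq_nr == freq_r else (1 if freq_nr > freq_r else -1)
        results.append(
            EnrichmentResult(
                gene=gene,
                count_nonresponders=alt_nr,
                n_nonresponders=len(nonresponders),
                count_responders=alt_r,
                n_responders=len(responders),
                p=p,
                direction=direction,
            )
        )
    return results
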