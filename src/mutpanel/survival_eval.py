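"""Survival-based model evaluation: Kaplan-Meier curves, log-rank tests,
proportional-hazards regression, ROC/AUC and rank-sum group comparisons.

Conventions used throughout:

* Times are months; the event indicator is 1 for an observed death or
  progression, 0 for right censoring.
* Median survival is the smallest time at which the survival curve reaches
  0.5 or below; when the curve never does, the median is "not reached"
  (represented as ``inf``).
* Hazard ratios for the MT/WT comparison are oriented as the hazard of the
  reference (WT) group relative to MT, so HR > 1 means the MT group does
  better; the orientation is recorded in every result row.
* Tied event times in the hazards model use the Breslow convention.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from sklearn.metrics import roc_curve

from .cohort_io import ClinicalRecord

logger = logging.getLogger(__name__)

NOT_REACHED = float("inf")


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate on the observed event times."""

    times: np.ndarray          # distinct event times, increasing
    survival_prob: np.ndarray  # S(t) just after each event time
    n_at_risk: np.ndarray      # risk-set size just before each event time
    median: float              # months, or inf when not reached
    n: int

    @property
    def median_display(self) -> str:
        return "not reached" if math.isinf(self.median) else f"{self.median:g}"


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    Censored observations shrink the risk set without producing steps.  With
    no censoring the curve equals the empirical survival function.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("cannot estimate a survival curve from no observations")
    if times.shape != events.shape:
        raise ValueError("times and events must be aligned")
    if (times < 0).any():
        raise ValueError("survival times must be nonnegative")

    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_table = kmf.event_table
    steps = event_table[event_table["observed"] > 0]
    t = steps.index.to_numpy(dtype=float)
    s = kmf.survival_function_at_times(t).to_numpy()
    at_risk = steps["at_risk"].to_numpy(dtype=int)

    below = np.nonzero(s <= 0.5)[0]
    median = float(t[below[0]]) if below.size else NOT_REACHED
    return SurvivalCurve(
        times=t, survival_prob=s, n_at_risk=at_risk, median=median, n=int(times.size)
    )


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi_square, p_value)."""
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be non-empty")
    if sum(events_a) + sum(events_b) == 0:
        logger.warning("log-rank on groups with zero events: statistic is 0 by convention")
        return 0.0, 1.0
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class HazardComparison:
    covariate: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    reference_group: str = ""
    mode: str = "univariate"
    penalized: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("hazard ratio must lie within its confidence interval")


def _fit_cox(df: pd.DataFrame, covariates: list[str], mode: str) -> list[HazardComparison]:
    cph = CoxPHFitter(penalizer=0.0)
    penalized = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df[["time_months", "event", *covariates]],
                duration_col="time_months",
                event_col="event",
            )
    except (ConvergenceError, ValueError) as err:
        # Complete separation or a flat likelihood: retry with a small ridge
        # penalty and flag the rows as penalized.
        logger.warning("Cox fit failed for %s (%s); retrying with penalizer=0.1", covariates, err)
        cph = CoxPHFitter(penalizer=0.1)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(
                    df[["time_months", "event", *covariates]],
                    duration_col="time_months",
                    event_col="event",
                )
            penalized = True
        except (ConvergenceError, ValueError) as err2:
            raise RuntimeError(f"Cox model did not converge for {covariates}") from err2
    summary = cph.summary
    out = []
    for cov in covariates:
        row = summary.loc[cov]
        out.append(
            HazardComparison(
                covariate=cov,
                hr=float(row["exp(coef)"]),
                ci_low=float(row["exp(coef) lower 95%"]),
                ci_high=float(row["exp(coef) upper 95%"]),
                p_value=float(row["p"]),
                mode=mode,
                penalized=penalized,
            )
        )
    return out


def cox_fit(
    clinical: Sequence[ClinicalRecord] | pd.DataFrame,
    covariates: list[str],
    mode: str = "univariate",
) -> list[HazardComparison]:
    """Proportional-hazards regression over one or more covariates.

    ``univariate`` fits each covariate alone; ``multivariate`` fits them
    jointly.  Rows with a missing covariate value are dropped with a log
    line.  Covariates must already be numeric (dummy-code upstream).
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError("mode must be 'univariate' or 'multivariate'")
    if isinstance(clinical, pd.DataFrame):
        df = clinical.copy()
    else:
        rows = []
        for rec in clinical:
            row = {"time_months": rec.time_months, "event": rec.event}
            row.update(rec.covariates)
            rows.append(row)
        df = pd.DataFrame(rows)
    for cov in covariates:
        if cov not in df.columns:
            raise ValueError(f"covariate {cov!r} missing from clinical data")
    if df["event"].sum() == 0:
        raise ValueError("no events observed; hazards model undefined")

    results: list[HazardComparison] = []
    if mode == "univariate":
        for cov in covariates:
            sub = df[["time_months", "event", cov]].dropna()
            if len(sub) < len(df):
                logger.info("cox_fit: dropped %d rows missing %s", len(df) - len(sub), cov)
            results.extend(_fit_cox(sub, [cov], mode))
    else:
        sub = df[["time_months", "event", *covariates]].dropna()
        if len(sub) < len(df):
            logger.info("cox_fit: dropped %d rows with missing covariates", len(df) - len(sub))
        results.extend(_fit_cox(sub, covariates, mode))
    return results


def mt_wt_hazard_ratio(
    times: Sequence[float],
    events: Sequence[int],
    is_mt: Sequence[bool],
) -> HazardComparison:
    """HR of WT relative to MT (HR > 1 means the MT group survives longer)."""
    df = pd.DataFrame(
        {
            "time_months": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=int),
            "wt_vs_mt": (~np.asarray(is_mt, dtype=bool)).astype(int),
        }
    )
    res = cox_fit(df, ["wt_vs_mt"], mode="univariate")[0]
    res.reference_group = "MT (HR is hazard of WT relative to MT)"
    return res


@dataclass
class RocResult:
    auc: float
    thresholds: np.ndarray = field(default_factory=lambda: np.array([]))
    sensitivity: np.ndarray = field(default_factory=lambda: np.array([]))
    specificity: np.ndarray = field(default_factory=lambda: np.array([]))


def roc_auc(scores: Sequence[float], outcomes: Sequence[int]) -> RocResult:
    """ROC curve and AUC of a score against a binary outcome.

    AUC is the probability that a random positive outscores a random
    negative, ties counting one half — so a constant score gives exactly 0.5
    and a binary score gives (sensitivity + specificity) / 2.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    pos = scores[outcomes == 1]
    neg = scores[outcomes == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("ROC requires both outcome classes")
    # Mann-Whitney formulation: exact, and well-defined for constant scores.
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * ties) / (pos.size * neg.size)
    fpr, tpr, thresholds = roc_curve(outcomes, scores)
    return RocResult(
        auc=float(auc), thresholds=thresholds, sensitivity=tpr, specificity=1 - fpr
    )


def compare_groups_wilcoxon(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison of two groups."""
    if len(values_a) == 0 or len(values_b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(values_a, values_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Composite evaluation report


def evaluate_mt_wt(
    clinical_df: pd.DataFrame,
    calls: pd.DataFrame,
    auc_scheme: str = "alive_at_horizon(12)",
    auc_outcome: Sequence[int] | None = None,
    auc_sample_ids: Sequence[str] | None = None,
) -> dict:
    """KM medians, log-rank, WT-vs-MT hazard ratio and (optionally) AUC for
    an MT/WT call table joined against clinical follow-up.

    ``clinical_df`` is indexed by sample_id with time_months/event columns;
    ``calls`` is the output of :func:`mutpanel.panel_classifier.classify_cohort`.
    The AUC uses the panel mutant-gene count as score against the supplied
    binarized outcome; the scheme string is recorded alongside the value.
    """
    joined = clinical_df.join(calls, how="inner")
    if joined.empty:
        raise ValueError("no overlap between clinical table and calls")
    mt = joined[joined["group"] == "MT"]
    wt = joined[joined["group"] == "WT"]
    report: dict = {
        "n_samples": int(len(joined)),
        "n_mt": int(len(mt)),
        "n_wt": int(len(wt)),
    }
    for name, sub in (("mt", mt), ("wt", wt)):
        if len(sub):
            curve = km_estimate(sub["time_months"], sub["event"])
            report[f"median_{name}_months"] = (
                None if math.isinf(curve.median) else curve.median
            )
    if len(mt) and len(wt):
        chi2, p = logrank_test(mt["time_months"], mt["event"], wt["time_months"], wt["event"])
        report["logrank_chi_square"] = chi2
        report["logrank_p"] = p
        hr = mt_wt_hazard_ratio(
            joined["time_months"], joined["event"], joined["group"] == "MT"
        )
        report["hr_wt_vs_mt"] = hr.hr
        report["hr_ci"] = [hr.ci_low, hr.ci_high]
        report["hr_p"] = hr.p_value
        report["hr_orientation"] = hr.reference_group
        report["hr_penalized"] = hr.penalized
    if auc_outcome is not None:
        outcome = pd.Series(
            np.asarray(auc_outcome, dtype=int), index=list(auc_sample_ids)
        )
        common = joined.index.intersection(outcome.index)
        # Score orientation: higher mutant-gene count predicts survival
        # (outcome 0), so the score for "death" is the negated count.
        roc = roc_auc(-joined.loc[common, "panel_count"], outcome.loc[common])
        report["auc"] = roc.auc
        report["auc_outcome_scheme"] = auc_scheme
        report["auc_score"] = "negated panel mutant-gene count"
    return report
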