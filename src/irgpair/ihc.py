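"""Immunohistochemistry (IHC) cohort analysis.

Covers the tissue-microarray arm of a marker-prognosis study: H-score
quantification of staining, classification into negative/1+/2+/3+,
marker-positivity, dichotomization of tumor-infiltrating lymphocyte (TIL)
percentages, chi-squared association between marker status and TIL
groups, and disease-free-survival comparison between marker-positive and
marker-negative patients.

The H-score weighs the percentage of tumor cells at each staining
intensity: H = 1*pct1 + 2*pct2 + 3*pct3, ranging 0 (no staining) to 300
(all cells at strong intensity). Classes follow the conventional bins:
0-49 negative, 50-99 -> 1+, 100-199 -> 2+, 200-300 -> 3+; any non-negative
class counts as marker-positive.

An IHC cohort is a DataFrame indexed by patient id with the staining
percentage columns (``pct_intensity_1/2/3``), TIL percentage columns,
``dfs_time``/``dfs_event``, and optional clinical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .survival import CoxFit, KmCurve, cox_multivariate, cox_univariate, km_estimate, logrank_test

__all__ = [
    "StainRecord",
    "h_score",
    "classify_h",
    "marker_status",
    "dichotomize_marker",
    "chisq_association",
    "cohort_summary",
    "dfs_analysis",
    "H_CLASSES",
]

H_CLASSES = ("negative", "1+", "2+", "3+")


@dataclass(frozen=True)
class StainRecord:
    """Percentages of tumor cells at weak/moderate/strong staining."""

    pct_intensity_1: float
    pct_intensity_2: float
    pct_intensity_3: float

    def __post_init__(self) -> None:
        pcts = (self.pct_intensity_1, self.pct_intensity_2, self.pct_intensity_3)
        if any(p < 0 or p > 100 for p in pcts):
            raise ValueError("staining percentages must lie in [0, 100]")
        if sum(pcts) > 100 + 1e-9:
            raise ValueError(f"staining percentages sum to {sum(pcts):g} > 100")


def h_score(record: StainRecord) -> float:
    """H = 1*pct1 + 2*pct2 + 3*pct3, in [0, 300]."""
    return (record.pct_intensity_1
            + 2.0 * record.pct_intensity_2
            + 3.0 * record.pct_intensity_3)


def classify_h(h: float) -> str:
    """Bin an H-score: 0-49 negative, 50-99 1+, 100-199 2+, 200-300 3+.

    Boundaries 50, 100, 200 belong to the upper class.
    """
    if not 0 <= h <= 300:
        raise ValueError(f"H-score {h:g} outside [0, 300]")
    if h < 50:
        return "negative"
    if h < 100:
        return "1+"
    if h < 200:
        return "2+"
    return "3+"


def marker_status(h_class: str) -> str:
    """'positive' for any stained class (1+/2+/3+), else 'negative'."""
    if h_class not in H_CLASSES:
        raise ValueError(f"unknown H-class {h_class!r}")
    return "negative" if h_class == "negative" else "positive"


def dichotomize_marker(values: pd.Series, threshold="median") -> pd.Series:
    """Split per-patient percentages into 'low'/'high' at a threshold.

    ``threshold`` may be a number or ``"median"`` (the cohort median,
    the convention for TIL scoring). Values equal to the threshold go to
    'low'. A constant cohort yields all-'low' (degenerate; warned).
    """
    if len(values) == 0:
        raise ValueError("no values to dichotomize")
    thr = float(values.median()) if threshold == "median" else float(threshold)
    labels = pd.Series(np.where(values > thr, "high", "low"),
                       index=values.index, name=values.name)
    if (labels == "low").all() or (labels == "high").all():
        import warnings

        warnings.warn("dichotomization produced a single group "
                      f"(threshold {thr:g})")
    return labels


def chisq_association(a: pd.Series, b: pd.Series):
    """Pearson chi-squared (no continuity correction) between two binary
    factors.

    Returns (statistic, p-value, 2x2 contingency table). Both factors must
    have both levels represented.
    """
    table = pd.crosstab(a, b)
    if table.shape != (2, 2):
        raise ValueError(
            f"need two levels in each factor; contingency table is {table.shape}"
        )
    stat, p, _, _ = chi2_contingency(table.to_numpy(), correction=False)
    return float(stat), float(p), table


def cohort_summary(h_classes: pd.Series) -> pd.DataFrame:
    """Count and percentage of patients per H-class.

    Percentages are of the whole cohort, rounded to one decimal.
    """
    counts = h_classes.value_counts().reindex(H_CLASSES, fill_value=0)
    n = int(counts.sum())
    pct = (100.0 * counts / n).round(1) if n else counts.astype(float)
    return pd.DataFrame({"count": counts.astype(int), "percent": pct})


def dfs_analysis(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    landmark_months: float = 48.0,
):
    """Disease-free survival comparison between marker-positive and
    marker-negative patients.

    ``cohort`` must carry ``marker_status`` ('positive'/'negative'),
    ``dfs_time`` and ``dfs_event`` columns; ``covariates`` names further
    columns (AJCC stage, LN status, T-stage, Ki-67, grade, menopause, ...)
    for the multivariate model.

    Returns a dict with per-group KM curves, the log-rank (stat, p),
    landmark DFS per group (KM estimate at ``landmark_months``), the
    univariate Cox fit of marker status, and — when covariates are given —
    the multivariate fit.
    """
    surv = pd.DataFrame({"time": cohort["dfs_time"], "event": cohort["dfs_event"]},
                        index=cohort.index)
    pos = surv.loc[cohort["marker_status"] == "positive"]
    neg = surv.loc[cohort["marker_status"] == "negative"]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both marker-positive and marker-negative groups required")
    curves = {"positive": km_estimate(pos), "negative": km_estimate(neg)}
    lr = logrank_test(pos, neg)
    landmark = {g: curves[g].survival_at(landmark_months) for g in curves}
    marker = (cohort["marker_status"] == "positive").astype(float)
    uni = cox_univariate(marker, surv, name="marker_positive")
    multi: CoxFit | None = None
    if covariates:
        X = cohort[covariates].astype(float).copy()
        X.insert(0, "marker_positive", marker)
        multi = cox_multivariate(X, surv)
    return {
        "km": curves,
        "logrank": lr,
        "landmark_dfs": landmark,
        "cox_univariate": uni,
        "cox_multivariate": multi,
    }
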