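"""Risk scoring, cutoff selection, and high/low-risk stratification.

The risk score of a sample is the signature-weighted sum of its pair
indicators, score(s) = sum_i coef_i * indicator_i(s). The cutoff between
low- and high-risk is learned on training data from a fixed-horizon ROC
curve (default 60 months): samples with an event before the horizon are
positives, samples followed event-free beyond it are negatives, samples
censored before the horizon are excluded, and the cutoff maximizing
Youden's J = sensitivity + specificity - 1 is returned. On validation
cohorts the training cutoff is applied unchanged — the published-model
workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pairs import GenePair, encode_pairs
from .signature import Signature
from .survival import CoxFit, KmCurve, cox_univariate, km_estimate, logrank_test

__all__ = [
    "RiskStratification",
    "score_samples",
    "score_expression",
    "optimal_cutoff",
    "stratify_and_compare",
]


@dataclass
class RiskStratification:
    """Per-sample risk scores, the cutoff, and high/low labels."""

    scores: pd.Series
    cutoff: float
    labels: pd.Series      # "high" where score > cutoff, else "low"

    @property
    def n_high(self) -> int:
        return int((self.labels == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == "low").sum())


def score_samples(sig: Signature, indicators: pd.DataFrame) -> pd.Series:
    """Linear risk score per sample from a pair-indicator matrix.

    Every signature pair must be present as a row of ``indicators``
    (missing pairs raise, listing them).
    """
    ids = [p.id for p in sig.pairs]
    missing = [pid for pid in ids if pid not in indicators.index]
    if missing:
        raise KeyError(f"signature pairs missing from indicator matrix: {missing}")
    values = indicators.loc[ids].to_numpy(dtype=float)
    scores = sig.coefficients @ values
    return pd.Series(scores, index=indicators.columns, name="risk_score")


def score_expression(sig: Signature, expression: pd.DataFrame) -> pd.Series:
    """Encode the signature's pairs from expression and score in one step."""
    indicators = encode_pairs(expression, sig.pairs)
    return score_samples(sig, indicators)


def optimal_cutoff(
    scores: pd.Series,
    surv: pd.DataFrame,
    horizon: float = 60.0,
) -> float:
    """Youden-optimal risk cutoff from a fixed-horizon ROC.

    Positives: event before ``horizon``. Negatives: followed event-free to
    at least ``horizon``. Censored before the horizon: excluded. Candidate
    cutoffs are midpoints between consecutive distinct scores; ties in J
    break toward the smaller cutoff.
    """
    common = scores.index.intersection(surv.index)
    s = scores.loc[common].to_numpy(dtype=float)
    t = surv.loc[common, "time"].to_numpy(dtype=float)
    e = surv.loc[common, "event"].to_numpy()
    positive = (e == 1) & (t <= horizon)
    negative = t > horizon
    evaluable = positive | negative
    if positive.sum() == 0 or negative.sum() == 0:
        raise ValueError(
            "need at least one event before the horizon and one event-free "
            "sample beyond it to build a ROC curve"
        )
    s, positive = s[evaluable], positive[evaluable]
    uniq = np.unique(s)
    if len(uniq) < 2:
        raise ValueError("all evaluable samples share one score; ROC is degenerate")
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = positive.sum()
    n_neg = (~positive).sum()
    best_j, best_cut = -np.inf, cuts[0]
    for c in cuts:
        pred = s > c
        sens = (pred & positive).sum() / n_pos
        spec = (~pred & ~positive).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_cut = j, c
    return float(best_cut)


def stratify_and_compare(
    scores: pd.Series,
    cutoff: float,
    surv: pd.DataFrame,
) -> tuple[RiskStratification, dict[str, KmCurve], tuple[float, float], CoxFit]:
    """Label samples high/low at ``cutoff`` and compare their survival.

    Returns the stratification, per-group Kaplan–Meier curves, the
    log-rank (statistic, p), and a univariate Cox fit of the high-vs-low
    indicator (HR > 1 means high risk does worse). Scores exactly at the
    cutoff go to the low group.
    """
    common = scores.index.intersection(surv.index)
    scores = scores.loc[common]
    surv = surv.loc[common]
    labels = pd.Series(np.where(scores > cutoff, "high", "low"),
                       index=scores.index, name="risk_group")
    high = surv.loc[labels == "high"]
    low = surv.loc[labels == "low"]
    if len(high) == 0 or len(low) == 0:
        raise ValueError(
            f"empty {'high' if len(high) == 0 else 'low'}-risk stratum at cutoff "
            f"{cutoff:g}; inspect the score distribution"
        )
    strat = RiskStratification(scores=scores, cutoff=float(cutoff), labels=labels)
    curves = {"high": km_estimate(high), "low": km_estimate(low)}
    lr = logrank_test(high, low)
    fit = cox_univariate((labels == "high").astype(float), surv, name="high_risk")
    return strat, curves, lr, fit
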