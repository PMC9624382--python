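"""Survival estimators and tests: Kaplan–Meier, log-rank, Cox PH.

Thin, validated wrappers around lifelines. Cox models use the Efron
approximation for tied event times (lifelines' default) and report Wald
tests with normal-approximation 95% confidence intervals, the way hazard
ratios are conventionally tabulated in prognostic studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import ConvergenceWarning

__all__ = [
    "KmCurve",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "cox_multivariate",
]


@dataclass
class KmCurve:
    """Product-limit survival curve evaluated at observed event times."""

    times: np.ndarray          # increasing, event times only
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # number at risk just before each event time

    def survival_at(self, t: float) -> float:
        """Step-function value at time ``t`` (last event at or before t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary (one row per covariate)."""

    coefficients: pd.Series
    std_errors: pd.Series
    hazard_ratios: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p_values: pd.Series
    converged: bool = True
    n: int = 0
    n_events: int = 0

    def summary(self) -> pd.DataFrame:
        """Delimited-table-ready summary (term, coef, HR, CI, p)."""
        return pd.DataFrame({
            "coef": self.coefficients,
            "se": self.std_errors,
            "HR": self.hazard_ratios,
            "HR_ci_low": self.ci_lower,
            "HR_ci_high": self.ci_upper,
            "p": self.p_values,
        })


def km_estimate(surv: pd.DataFrame) -> KmCurve:
    """Kaplan–Meier estimate from a survival table (time, event columns).

    Censored times tied with event times are treated as still at risk
    through the event. An all-censored table yields a curve constant at 1
    (with a warning).
    """
    if len(surv) == 0:
        raise ValueError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(surv["time"], surv["event"])
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    if len(ev) == 0:
        warnings.warn("no events observed; survival curve is constant at 1")
        return KmCurve(np.array([]), np.array([]), np.array([]))
    times = ev.index.to_numpy(dtype=float)
    sf = kmf.survival_function_["KM_estimate"]
    survival = sf.loc[ev.index].to_numpy(dtype=float)
    at_risk = ev["at_risk"].to_numpy(dtype=float)
    return KmCurve(times, survival, at_risk)


def logrank_test(surv_a: pd.DataFrame, surv_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-squared statistic, p-value)."""
    if len(surv_a) == 0 or len(surv_b) == 0:
        raise ValueError("both groups must be non-empty")
    if surv_a["event"].sum() + surv_b["event"].sum() == 0:
        raise ValueError("no events in either group; log-rank undefined")
    res = _ll_logrank(surv_a["time"], surv_b["time"],
                      surv_a["event"], surv_b["event"])
    return float(res.test_statistic), float(res.p_value)


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> CoxFit:
    converged = True
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceError as err:
            raise ValueError(f"Cox fit failed to converge: {err}") from err
    s = cph.summary.loc[covariates]
    return CoxFit(
        coefficients=s["coef"],
        std_errors=s["se(coef)"],
        hazard_ratios=s["exp(coef)"],
        ci_lower=s["exp(coef) lower 95%"],
        ci_upper=s["exp(coef) upper 95%"],
        p_values=s["p"],
        converged=converged,
        n=len(df),
        n_events=int(df["event"].sum()),
    )


def cox_univariate(x, surv: pd.DataFrame, name: str = "x") -> CoxFit:
    """Univariate Cox PH fit of survival on a single covariate.

    ``x`` may be a Series aligned to ``surv``'s index or an array in row
    order. Raises on a constant covariate.
    """
    if isinstance(x, pd.Series):
        x = x.reindex(surv.index)
        if x.isna().any():
            raise ValueError("covariate missing for some survival samples")
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: Cox coefficient unidentifiable")
    df = pd.DataFrame({"time": surv["time"].to_numpy(),
                       "event": surv["event"].to_numpy(),
                       name: x})
    return _fit_cox(df, [name])


def cox_multivariate(X: pd.DataFrame, surv: pd.DataFrame) -> CoxFit:
    """Joint Cox PH fit over the named covariates in ``X``.

    Constant columns are dropped (logged through the returned index);
    exactly collinear covariates raise an error naming them.
    """
    X = X.reindex(surv.index)
    if X.isna().any().any():
        raise ValueError("covariates missing for some survival samples")
    keep = [c for c in X.columns if np.ptp(X[c].to_numpy(dtype=float)) > 0]
    if not keep:
        raise ValueError("all covariates constant")
    X = X[keep]
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([arr, np.ones(len(arr))])) < arr.shape[1] + 1:
        corr = np.corrcoef(arr, rowvar=False)
        pairs = [
            (keep[i], keep[j])
            for i in range(len(keep)) for j in range(i + 1, len(keep))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"collinear covariates: {pairs or keep}")
    df = pd.DataFrame({"time": surv["time"].to_numpy(),
                       "event": surv["event"].to_numpy()})
    for c in keep:
        df[c] = X[c].to_numpy(dtype=float)
    return _fit_cox(df, keep)
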