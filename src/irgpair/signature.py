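"""Prognostic signature construction and I/O.

A signature is an ordered list of (gene pair, coefficient) entries. The
published 26-pair breast-cancer signature ships with the package and can
be loaded with :func:`load_table1_signature`.

Candidate pairs are first screened one at a time with univariate Cox
regression; the survivors enter a stability-selection Lasso-Cox: many
rounds of L1-penalized Cox on subsamples, each round choosing its penalty
by cross-validation, with pairs kept when they are selected in a large
enough fraction of rounds. The final coefficients come from a single
penalized fit at the consensus penalty restricted to the consensus pairs,
which yields the small signed coefficients characteristic of such models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

from .io import normalize_gene_id
from .pairs import GenePair, parse_pair_id
from .survival import cox_univariate

logger = logging.getLogger(__name__)

__all__ = [
    "Signature",
    "screen_pairs",
    "lasso_cox_select",
    "load_signature",
    "write_signature",
    "load_table1_signature",
]


@dataclass
class Signature:
    """Ordered (gene pair, coefficient) list with provenance."""

    entries: list[tuple[GenePair, float]]
    provenance: str = "fitted"            # "published_table1" | "fitted"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for pair, coef in self.entries:
            if pair in seen:
                raise ValueError(f"duplicate pair in signature: {pair.id}")
            seen.add(pair)
            if not np.isfinite(coef) or coef == 0:
                raise ValueError(f"coefficient for {pair.id} must be finite and non-zero")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def pairs(self) -> list[GenePair]:
        return [p for p, _ in self.entries]

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([c for _, c in self.entries], dtype=float)

    def genes(self) -> list[str]:
        """Unique genes in the signature, in first-appearance order."""
        out: list[str] = []
        for p, _ in self.entries:
            for g in p:
                if g not in out:
                    out.append(g)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"IRG1": [p.gene_a for p, _ in self.entries],
             "IRG2": [p.gene_b for p, _ in self.entries],
             "Coefficient": [c for _, c in self.entries]}
        )


def _surv_y(surv: pd.DataFrame):
    return Surv.from_arrays(event=surv["event"].astype(bool), time=surv["time"])


def screen_pairs(
    indicators: pd.DataFrame,
    surv: pd.DataFrame,
    alpha: float = 0.05,
) -> list[tuple[GenePair, float]]:
    """Univariate Cox screen of every pair; keep pairs with p < alpha.

    Returns (pair, p-value) tuples sorted by ascending p. Pairs whose
    indicator is constant across the shared samples carry no information
    and are skipped.
    """
    shared = [s for s in indicators.columns if s in surv.index]
    if not shared:
        raise ValueError("no samples shared between indicators and survival table")
    sub = indicators[shared]
    surv = surv.loc[shared]
    results: list[tuple[GenePair, float]] = []
    for pid, row in sub.iterrows():
        x = row.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        fit = cox_univariate(x, surv, name="pair")
        p = float(fit.p_values.iloc[0])
        if p < alpha:
            results.append((parse_pair_id(pid), p))
    results.sort(key=lambda t: t[1])
    return results


def _cv_choose_alpha(X, y, alphas, n_folds, rng) -> float:
    """Pick the penalty maximizing mean cross-validated concordance."""
    n = X.shape[0]
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    scores = np.zeros(len(alphas))
    counts = np.zeros(len(alphas))
    for k in range(n_folds):
        test = folds[k]
        train = np.concatenate([folds[j] for j in range(n_folds) if j != k])
        if y[train]["event"].sum() < 2 or y[test]["event"].sum() < 1:
            continue
        model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas,
                                       fit_baseline_model=False)
        try:
            model.fit(X[train], y[train])
        except (ValueError, ArithmeticError):
            continue
        for i, a in enumerate(model.alphas_):
            idx = int(np.argmin(np.abs(alphas - a)))
            coef = model.coef_[:, i]
            risk = X[test] @ coef
            if np.ptp(risk) == 0:
                continue
            c = concordance_index_censored(y[test]["event"], y[test]["time"], risk)[0]
            scores[idx] += c
            counts[idx] += 1
    valid = counts > 0
    if not valid.any():
        return float(alphas[len(alphas) // 2])
    mean = np.full(len(alphas), -np.inf)
    mean[valid] = scores[valid] / counts[valid]
    # prefer the strongest penalty among near-ties (sparser model)
    best = mean.max()
    candidates = np.flatnonzero(mean >= best - 1e-12)
    return float(alphas[candidates[-1]] if alphas[0] < alphas[-1] else alphas[candidates[0]])


def lasso_cox_select(
    indicators: pd.DataFrame,
    surv: pd.DataFrame,
    n_repeats: int = 1000,
    selection_threshold: float = 0.5,
    seed: int = 0,
    subsample_frac: float = 0.8,
    n_folds: int = 3,
    alphas=None,
) -> Signature:
    """Stability-selection Lasso-Cox over pre-screened pair indicators.

    Each round subsamples ``subsample_frac`` of the cohort without
    replacement, chooses an L1 penalty by ``n_folds``-fold cross-validated
    concordance over a common penalty grid, and records which pairs get a
    non-zero coefficient at that penalty. Pairs selected in at least
    ``selection_threshold`` of rounds form the signature; their
    coefficients come from one penalized fit on the full cohort at the
    median of the per-round penalties. Fully deterministic given ``seed``.

    ``alphas`` overrides the penalty grid (default: a 30-point path from
    the full data); a grid of one huge value shrinks everything away and
    yields an empty signature.

    The returned signature's ``metadata`` records the seed, parameters,
    consensus penalty, and per-pair selection frequencies.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    shared = [s for s in indicators.columns if s in surv.index]
    if not shared:
        raise ValueError("no samples shared between indicators and survival table")
    indicators = indicators[shared]
    surv = surv.loc[shared]
    if int(surv["event"].sum()) < 2:
        raise ValueError("need at least 2 events to fit a Lasso-Cox model")

    X_full = indicators.to_numpy(dtype=float).T  # samples x pairs
    y_full = _surv_y(surv)
    pair_ids = list(indicators.index)
    n, p = X_full.shape

    if alphas is None:
        # common penalty grid from the full-data path
        grid_model = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=30,
                                            alpha_min_ratio=0.01,
                                            fit_baseline_model=False)
        grid_model.fit(X_full, y_full)
        alphas = np.asarray(grid_model.alphas_, dtype=float)
    else:
        alphas = np.asarray(alphas, dtype=float)

    rng = np.random.default_rng(seed)
    n_sub = max(2, int(round(subsample_frac * n)))
    counts = np.zeros(p)
    chosen_alphas = []
    for _ in range(n_repeats):
        idx = rng.choice(n, size=n_sub, replace=False)
        y_sub = y_full[idx]
        if y_sub["event"].sum() < 2:
            continue
        X_sub = X_full[idx]
        a = _cv_choose_alpha(X_sub, y_sub, alphas, n_folds, rng)
        chosen_alphas.append(a)
        model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[a],
                                       fit_baseline_model=False)
        try:
            with warnings.catch_warnings():
                # a fully-shrunk round legitimately selects nothing
                warnings.simplefilter("ignore", UserWarning)
                model.fit(X_sub, y_sub)
        except (ValueError, ArithmeticError):
            continue
        counts += (np.abs(model.coef_[:, 0]) > 0).astype(float)

    freq = counts / n_repeats
    selected = np.flatnonzero(freq >= selection_threshold)
    frequencies = pd.Series(freq, index=pair_ids, name="selection_frequency")
    consensus_alpha = float(np.median(chosen_alphas)) if chosen_alphas else float(alphas[-1])

    metadata = {
        "seed": seed,
        "n_repeats": n_repeats,
        "selection_threshold": selection_threshold,
        "subsample_frac": subsample_frac,
        "n_folds": n_folds,
        "consensus_alpha": consensus_alpha,
        "selection_frequencies": frequencies,
    }
    if len(selected) == 0:
        logger.warning("lasso_cox_select: no pair reached selection threshold %g",
                       selection_threshold)
        return Signature(entries=[], provenance="fitted", metadata=metadata)

    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[consensus_alpha],
                                   fit_baseline_model=False)
    try:
        final.fit(X_full[:, selected], y_full)
        coefs = final.coef_[:, 0]
    except ValueError:
        # consensus penalty shrinks everything on the restricted design;
        # take the nearest penalty on a fresh path instead
        final = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=30,
                                       alpha_min_ratio=0.01,
                                       fit_baseline_model=False)
        final.fit(X_full[:, selected], y_full)
        col = int(np.argmin(np.abs(np.asarray(final.alphas_) - consensus_alpha)))
        coefs = final.coef_[:, col]
    entries = [
        (parse_pair_id(pair_ids[j]), float(c))
        for j, c in zip(selected, coefs)
        if c != 0
    ]
    return Signature(entries=entries, provenance="fitted", metadata=metadata)


def _clean_token(token: str) -> tuple[str, bool]:
    g = normalize_gene_id(token)
    stripped = g.lstrip("|")
    return stripped, stripped != g


def load_signature(path: str, sep: str = "\t") -> Signature:
    """Load a 3-column (IRG1, IRG2, Coefficient) signature file.

    Stray leading '|' characters on gene tokens — present in the published
    table as printed — are stripped and logged. File order is preserved.
    """
    df = pd.read_csv(path, sep=sep)
    required = {"IRG1", "IRG2", "Coefficient"}
    if not required <= set(df.columns):
        raise ValueError(f"signature file must have columns {sorted(required)}")
    entries: list[tuple[GenePair, float]] = []
    for _, row in df.iterrows():
        a, fixed_a = _clean_token(row["IRG1"])
        b, fixed_b = _clean_token(row["IRG2"])
        if fixed_a or fixed_b:
            logger.info("stripped stray '|' from gene token(s) in pair (%s, %s)", a, b)
        try:
            coef = float(row["Coefficient"])
        except (TypeError, ValueError) as err:
            raise ValueError(f"non-numeric coefficient for pair ({a}, {b})") from err
        entries.append((GenePair(a, b), coef))
    return Signature(entries=entries, provenance="published_table1"
                     if "table1" in str(path) else "fitted")


def write_signature(sig: Signature, path: str, sep: str = "\t") -> None:
    """Write a signature so that :func:`load_signature` round-trips."""
    sig.to_frame().to_csv(path, sep=sep, index=False)


def load_table1_signature() -> Signature:
    """The packaged 26-pair published breast-cancer signature."""
    from importlib.resources import files

    path = files("irgpair").joinpath("data", "table1_signature.tsv")
    sig = load_signature(str(path))
    sig.provenance = "published_table1"
    return sig
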