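"""scikit-learn-style estimators over the gene-pair pipeline.

These wrap the functional modules in fit/transform/predict surfaces so
the pipeline composes with sklearn model selection:

* :class:`PairEncoder` — transformer from samples x genes expression to
  samples x pairs binary indicators, learning the informative pair set
  (variation filter) on the training cohort.
* :class:`LassoCoxSignatureSelector` — fits a sparse gene-pair signature
  by univariate Cox screening followed by stability-selection Lasso-Cox.
* :class:`RiskStratifier` — scores samples with a signature, learns the
  Youden-optimal cutoff on training survival, and predicts high/low risk.

Note the orientation: estimators follow the sklearn convention of samples
as rows, the transpose of the genes x samples / pairs x samples matrices
the functional API uses. ``y`` is a survival DataFrame with ``time`` and
``event`` columns indexed like ``X``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import pairs as _pairs
from . import risk as _risk
from . import signature as _signature

__all__ = ["PairEncoder", "LassoCoxSignatureSelector", "RiskStratifier"]


def _as_frame(X) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a DataFrame with sample rows and named columns")
    return X


class PairEncoder(BaseEstimator, TransformerMixin):
    """Encode within-sample gene-pair ordering indicators.

    Parameters
    ----------
    min_frac : float, default 0.2
        Minimum minority-indicator frequency on the training data; pairs
        below it are dropped (set 0 to keep all pairs).
    pairs : list of GenePair, optional
        Explicit pairs to encode (e.g. a signature's); if None, all
        C(n, 2) pairs of the training genes are enumerated.

    Attributes
    ----------
    pairs_ : list of GenePair retained after the variation filter.
    """

    def __init__(self, min_frac: float = 0.2, pairs=None):
        self.min_frac = min_frac
        self.pairs = pairs

    def fit(self, X, y=None):
        X = _as_frame(X)
        candidates = (list(self.pairs) if self.pairs is not None
                      else _pairs.enumerate_candidate_pairs(X.columns))
        indicators = _pairs.encode_pairs(X.T, candidates)
        if self.min_frac > 0:
            indicators = _pairs.variation_filter(indicators, self.min_frac)
        self.pairs_ = [_pairs.parse_pair_id(pid) for pid in indicators.index]
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "pairs_")
        X = _as_frame(X)
        return _pairs.encode_pairs(X.T, self.pairs_).T

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "pairs_")
        return np.array([p.id for p in self.pairs_])


class LassoCoxSignatureSelector(BaseEstimator):
    """Sparse prognostic signature from pair indicators.

    ``fit(X, y)`` takes samples x pairs indicators and a survival frame;
    it runs the univariate Cox screen at ``alpha`` and then
    stability-selection Lasso-Cox with ``n_repeats`` subsample rounds.

    Attributes
    ----------
    signature_ : fitted :class:`~irgpair.signature.Signature`.
    selection_frequencies_ : per-screened-pair selection frequency.
    screened_pairs_ : (pair, p-value) list surviving the screen.
    """

    def __init__(self, alpha: float = 0.05, n_repeats: int = 1000,
                 selection_threshold: float = 0.5, seed: int = 0,
                 subsample_frac: float = 0.8, n_folds: int = 3):
        self.alpha = alpha
        self.n_repeats = n_repeats
        self.selection_threshold = selection_threshold
        self.seed = seed
        self.subsample_frac = subsample_frac
        self.n_folds = n_folds

    def fit(self, X, y):
        X = _as_frame(X)
        indicators = X.T
        self.screened_pairs_ = _signature.screen_pairs(indicators, y, self.alpha)
        if not self.screened_pairs_:
            raise ValueError("no pair passed the univariate screen")
        screened_ids = [p.id for p, _ in self.screened_pairs_]
        self.signature_ = _signature.lasso_cox_select(
            indicators.loc[screened_ids], y,
            n_repeats=self.n_repeats,
            selection_threshold=self.selection_threshold,
            seed=self.seed,
            subsample_frac=self.subsample_frac,
            n_folds=self.n_folds,
        )
        self.selection_frequencies_ = self.signature_.metadata["selection_frequencies"]
        return self

    def decision_function(self, X) -> pd.Series:
        check_is_fitted(self, "signature_")
        return _risk.score_samples(self.signature_, _as_frame(X).T)


class RiskStratifier(BaseEstimator):
    """Score expression with a signature and stratify into high/low risk.

    ``X`` is a samples x genes expression frame; the signature's pairs are
    encoded on the fly, so only the signature genes need to be present.

    Parameters
    ----------
    signature : Signature to score with (e.g. the packaged published one
        or a fitted ``LassoCoxSignatureSelector.signature_``).
    cutoff : float, optional
        Fixed cutoff (validation-cohort mode). If None, ``fit`` learns
        the Youden-optimal cutoff at ``horizon`` months.
    horizon : float, default 60
        Fixed ROC horizon in months for cutoff learning.

    Attributes
    ----------
    cutoff_ : the applied cutoff.
    """

    def __init__(self, signature=None, cutoff: float | None = None,
                 horizon: float = 60.0):
        self.signature = signature
        self.cutoff = cutoff
        self.horizon = horizon

    def _signature(self):
        if self.signature is None:
            raise ValueError("a signature is required")
        return self.signature

    def decision_function(self, X) -> pd.Series:
        return _risk.score_expression(self._signature(), _as_frame(X).T)

    def fit(self, X, y=None):
        scores = self.decision_function(X)
        if self.cutoff is not None:
            self.cutoff_ = float(self.cutoff)
        else:
            if y is None:
                raise ValueError("survival frame y required to learn a cutoff")
            self.cutoff_ = _risk.optimal_cutoff(scores, y, horizon=self.horizon)
        return self

    def predict(self, X) -> pd.Series:
        check_is_fitted(self, "cutoff_")
        scores = self.decision_function(X)
        return pd.Series(np.where(scores > self.cutoff_, "high", "low"),
                         index=scores.index, name="risk_group")

    def stratify(self, X, y):
        """Full comparison on (X, y): stratification, KM curves,
        log-rank, and the high-vs-low Cox fit."""
        check_is_fitted(self, "cutoff_")
        return _risk.stratify_and_compare(self.decision_function(X),
                                          self.cutoff_, y)
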