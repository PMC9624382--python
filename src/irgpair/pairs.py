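"""Within-sample gene-pair ordering indicators.

The gene-pair feature for a pair (A, B) in sample s is 1 when the
expression of A strictly exceeds that of B within that sample, else 0
(ties give 0). Because only the within-sample ordering matters, the
features are invariant to any strictly increasing per-sample transform of
the expression values — the property that lets a signature trained on one
platform be applied on another without normalization.

A pair-indicator matrix is a DataFrame of 0/1 values with pair ids
``"GENEA|GENEB"`` as the index and sample identifiers as columns.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .io import normalize_gene_id

logger = logging.getLogger(__name__)

__all__ = [
    "GenePair",
    "enumerate_candidate_pairs",
    "encode_pairs",
    "variation_filter",
    "pair_id",
    "parse_pair_id",
]


class GenePair(NamedTuple):
    """Ordered gene pair; the indicator reads 'gene_a > gene_b'."""

    gene_a: str
    gene_b: str

    @property
    def id(self) -> str:
        return f"{self.gene_a}|{self.gene_b}"


def pair_id(pair: GenePair) -> str:
    return pair.id


def parse_pair_id(pid: str) -> GenePair:
    a, b = pid.split("|")
    return GenePair(a, b)


def enumerate_candidate_pairs(genes: Iterable[str]) -> list[GenePair]:
    """All C(n, 2) unordered pairs in lexicographic canonical order.

    Each pair is oriented gene_a < gene_b; the learned coefficient sign
    absorbs direction, so the reverse orientation is never enumerated.
    """
    uniq = sorted({normalize_gene_id(g) for g in genes})
    if len(uniq) < 2:
        raise ValueError("need at least 2 genes to form pairs")
    return [GenePair(a, b) for a, b in itertools.combinations(uniq, 2)]


def encode_pairs(matrix: pd.DataFrame, pairs: list[GenePair]) -> pd.DataFrame:
    """Binary pair x sample indicator matrix: 1 iff expr(a) > expr(b).

    Ties yield 0. Raises if any pair gene is absent from the matrix,
    listing the missing genes.
    """
    needed = {g for p in pairs for g in p}
    missing = sorted(needed - set(matrix.index))
    if missing:
        raise KeyError(f"pair genes absent from expression matrix: {missing}")
    x = matrix.to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(matrix.index)}
    ia = np.fromiter((pos[p.gene_a] for p in pairs), dtype=int, count=len(pairs))
    ib = np.fromiter((pos[p.gene_b] for p in pairs), dtype=int, count=len(pairs))
    values = (x[ia] > x[ib]).astype(np.int8)
    return pd.DataFrame(values, index=[p.id for p in pairs],
                        columns=matrix.columns)


def variation_filter(indicators: pd.DataFrame, min_frac: float = 0.2) -> pd.DataFrame:
    """Drop near-constant pairs.

    A pair is kept when its minority-indicator frequency
    ``f = min(mean, 1 - mean)`` is at least ``min_frac``; pairs with
    ``f < min_frac`` carry too little within-cohort variation to be
    informative. May return an empty matrix (logged, not an error).
    """
    if not 0 <= min_frac <= 0.5:
        raise ValueError("min_frac must be in [0, 0.5]")
    mean = indicators.mean(axis=1)
    f = np.minimum(mean, 1.0 - mean)
    kept = indicators.loc[f >= min_frac]
    logger.info("variation_filter: %d of %d pairs retained (min_frac %g)",
                kept.shape[0], indicators.shape[0], min_frac)
    return kept
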