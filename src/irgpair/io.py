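"""Reading, validation and pre-filtering of expression matrices, survival
tables and gene lists.

In-memory containers are plain pandas objects:

* **expression matrix** — ``DataFrame`` with gene identifiers as the index
  and sample identifiers as columns (genes x samples), float values.
* **survival table** — ``DataFrame`` indexed by sample identifier with
  columns ``time`` (months, >= 0) and ``event`` (0/1); any further columns
  are clinical covariates.
* **gene list** — python ``list`` of normalized gene identifiers.

Gene identifiers are normalized by stripping whitespace and uppercasing;
this is the only matching rule applied anywhere in the package.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_gene_id",
    "read_expression",
    "write_expression",
    "read_survival",
    "read_gene_list",
    "intersect_genes",
    "mad_filter",
]


def normalize_gene_id(gene: str) -> str:
    """Strip surrounding whitespace and uppercase a gene identifier."""
    return str(gene).strip().upper()


def _detect_sep(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_expression(
    path: str,
    sep: str | None = None,
    duplicate_rule: str = "highest_median",
) -> pd.DataFrame:
    """Read a delimited gene x sample expression table.

    The first column holds gene identifiers, the header row sample
    identifiers. Rows containing any missing value are dropped (and
    logged). Duplicate gene rows are collapsed according to
    ``duplicate_rule``:

    ``highest_median`` (default)
        keep the row with the highest median expression;
    ``first`` / ``mean``
        keep the first occurrence / average the rows.

    Raises
    ------
    ValueError
        on duplicate sample identifiers or non-numeric cells.
    """
    if sep is None:
        sep = _detect_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dups = sorted({s for s in header if header.count(s) > 1})
    if dups:
        raise ValueError(f"duplicate sample identifiers: {dups}")
    raw = pd.read_csv(path, sep=sep, index_col=0)
    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad.to_numpy().argmax()]
            raise ValueError(f"non-numeric value at gene {row!r}, sample {col!r}")
        raw[col] = coerced
    raw.index = [normalize_gene_id(g) for g in raw.index]

    n_missing = int(raw.isna().any(axis=1).sum())
    if n_missing:
        logger.info("dropping %d gene rows with missing values", n_missing)
        raw = raw.dropna(axis=0)

    if raw.index.duplicated().any():
        dup_genes = raw.index[raw.index.duplicated()].unique().tolist()
        logger.info(
            "collapsing %d duplicated gene identifiers by rule %r",
            len(dup_genes), duplicate_rule,
        )
        if duplicate_rule == "highest_median":
            med = raw.median(axis=1)
            # stable sort by descending median, keep first -> highest-median row
            order = np.argsort(-med.to_numpy(), kind="stable")
            raw = raw.iloc[order]
            raw = raw[~raw.index.duplicated(keep="first")]
        elif duplicate_rule == "first":
            raw = raw[~raw.index.duplicated(keep="first")]
        elif duplicate_rule == "mean":
            raw = raw.groupby(level=0, sort=False).mean()
        else:
            raise ValueError(f"unknown duplicate_rule {duplicate_rule!r}")
    return raw.astype(float)


def write_expression(matrix: pd.DataFrame, path: str, sep: str = "\t") -> None:
    """Write an expression matrix so that :func:`read_expression` round-trips."""
    matrix.to_csv(path, sep=sep, index_label="gene")


def read_survival(path: str, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited survival table with columns sample, time, event.

    Extra columns are kept as covariates. Validates ``time >= 0`` and
    ``event in {0, 1}``.
    """
    if sep is None:
        sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep)
    required = {"sample", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    df = df.set_index("sample")
    if df.index.duplicated().any():
        raise ValueError("duplicate sample identifiers in survival table")
    return validate_survival(df)


def validate_survival(df: pd.DataFrame) -> pd.DataFrame:
    """Check survival-table invariants (time >= 0, event in {0,1})."""
    bad_time = df.index[df["time"] < 0]
    if len(bad_time):
        raise ValueError(f"negative follow-up time for sample(s): {list(bad_time)}")
    if not df["event"].isin([0, 1]).all():
        bad = df.index[~df["event"].isin([0, 1])]
        raise ValueError(f"event indicator not in {{0,1}} for sample(s): {list(bad)}")
    df = df.copy()
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    return df


def read_gene_list(path: str) -> list[str]:
    """Read one gene identifier per line; '#' starts a comment.

    Identifiers are normalized (trimmed, uppercased) and deduplicated,
    keeping first occurrence order.
    """
    genes: list[str] = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if not token:
                continue
            g = normalize_gene_id(token)
            if g not in seen:
                seen.add(g)
                genes.append(g)
    if not genes:
        raise ValueError(f"gene list {path!r} is empty")
    return genes


def intersect_genes(matrix: pd.DataFrame, genes) -> pd.DataFrame:
    """Restrict an expression matrix to genes present in ``genes``.

    Row order of ``matrix`` is preserved. Raises on empty intersection,
    since no downstream step could proceed.
    """
    wanted = {normalize_gene_id(g) for g in genes}
    keep = [g for g in matrix.index if g in wanted]
    if not keep:
        raise ValueError("no genes shared between expression matrix and gene list")
    return matrix.loc[keep]


def mad_filter(matrix: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Keep genes whose median absolute deviation across samples exceeds
    ``threshold`` (strictly).

    MAD is the raw, unscaled ``median(|x - median(x)|)`` on the values as
    provided — no consistency constant, no re-logging.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if matrix.shape[1] < 2:
        raise ValueError("MAD filter needs at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1)
    kept = matrix.loc[mad > threshold]
    logger.info("mad_filter: %d of %d genes retained (threshold %g)",
                kept.shape[0], matrix.shape[0], threshold)
    return kept
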