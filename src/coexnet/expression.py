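"""Reading, validating and preprocessing gene-by-sample expression matrices.

An expression matrix is represented as a :class:`pandas.DataFrame` with
unique gene identifiers as the index, unique sample identifiers as the
columns, and finite float values.  Files are tab-separated: a header row of
sample ids, a first column of gene (or probe) ids, '.'-decimal numbers,
blank cells meaning missing.  Rows containing any missing value are dropped
at read time so that every gene pair is correlated over the same samples.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataFormatError, EmptyResultError

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_probe_map",
    "collapse_probes",
    "filter_uninformative",
    "validate_expression_matrix",
]

logger = logging.getLogger("coexnet")


def validate_expression_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix invariants, returning the matrix.

    Raises :class:`DataFormatError` on duplicate gene or sample ids or
    non-finite values.
    """
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise DataFormatError(f"duplicate gene ids: {dups[:10]}")
    if matrix.columns.has_duplicates:
        dups = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise DataFormatError(f"duplicate sample ids: {dups[:10]}")
    values = matrix.to_numpy(dtype=float, copy=False)
    if not np.isfinite(values).all():
        raise DataFormatError("expression matrix contains non-finite values")
    return matrix


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a TSV expression matrix; drop (and log) rows with missing cells.

    Non-numeric body cells raise :class:`DataFormatError` naming the row and
    column; duplicate gene ids raise before any probe collapsing (use
    :func:`collapse_probes` for probe-level files).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise DataFormatError(f"{path}: duplicate gene ids: {dups[:10]}")
    if raw.columns.has_duplicates:
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise DataFormatError(f"{path}: duplicate sample ids: {dups[:10]}")

    stripped = raw.apply(lambda col: col.str.strip())
    present = stripped != ""

    # Python's float() is correctly rounded, so written values round-trip
    # exactly; pandas' fast C parser is not.
    def parse(cell: str):
        if not cell:
            return np.nan
        try:
            return float(cell)
        except ValueError:
            return None

    parsed = stripped.map(parse)
    bad = parsed.isna() & present
    if bad.to_numpy().any():
        row, col = next(zip(*np.nonzero(bad.to_numpy())))
        raise DataFormatError(
            f"{path}: non-numeric value {stripped.iat[row, col]!r} at gene"
            f" {raw.index[row]!r}, sample {raw.columns[col]!r}"
        )
    numeric = parsed.astype(float)
    inf = present.to_numpy() & ~np.isfinite(numeric.to_numpy())
    if inf.any():
        row, col = next(zip(*np.nonzero(inf)))
        raise DataFormatError(
            f"{path}: non-finite value at gene {raw.index[row]!r},"
            f" sample {raw.columns[col]!r}"
        )

    complete = present.all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("read_expression_matrix: dropped %d row(s) with missing values", dropped)
    matrix = numeric.loc[complete].astype(float)
    if matrix.empty:
        raise EmptyResultError(f"{path}: no complete rows remain after missing-value filtering")
    return matrix


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a matrix in the TSV dialect read back by :func:`read_expression_matrix`."""
    validate_expression_matrix(matrix)
    # %.17g round-trips every double exactly through the text format
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_probe_map(path) -> dict[str, str]:
    """Read a headerless two-column TSV mapping probe id to gene symbol."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise DataFormatError(
                    f"{path}: line {lineno}: expected 'probe_id<TAB>gene_symbol'"
                )
            mapping[parts[0]] = parts[1]
    return mapping


def collapse_probes(matrix: pd.DataFrame, probe_map: Mapping[str, str]) -> pd.DataFrame:
    """Collapse a probe-level matrix to one row per gene symbol.

    Probes absent from ``probe_map`` are dropped.  When several probes map to
    the same symbol, the probe with the highest mean expression across
    samples is kept (ties broken by lexicographically smallest probe id).
    """
    kept = [p for p in matrix.index if p in probe_map]
    if not kept:
        raise EmptyResultError("no probes in the matrix are covered by the probe map")
    sub = matrix.loc[kept]
    means = sub.mean(axis=1)
    best: dict[str, str] = {}
    for probe in sorted(kept):
        symbol = probe_map[probe]
        if symbol not in best or means[probe] > means[best[symbol]]:
            best[symbol] = probe
    symbols = sorted(best)
    out = sub.loc[[best[s] for s in symbols]]
    out.index = pd.Index(symbols, name=matrix.index.name)
    dropped = len(matrix) - len(kept)
    if dropped:
        logger.info("collapse_probes: dropped %d unmapped probe(s)", dropped)
    logger.info("collapse_probes: %d probes -> %d gene symbols", len(kept), len(out))
    return out


def filter_uninformative(matrix: pd.DataFrame) -> pd.DataFrame:
    """Remove constant (zero-variance) genes, which have no defined rank
    correlation; logs the removed count."""
    values = matrix.to_numpy(dtype=float)
    informative = values.max(axis=1) > values.min(axis=1)
    removed = int((~informative).sum())
    if removed == len(matrix):
        raise EmptyResultError("all genes are constant across samples")
    if removed:
        logger.info("filter_uninformative: removed %d constant gene(s)", removed)
    return matrix.loc[informative]
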