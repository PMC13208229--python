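"""Response-matrix I/O, stratified partitioning and report serialisation.

The on-disk currency is a UTF-8 CSV with one header row of item labels and
one row of 0/1 cells per examinee. In memory a response matrix is a pandas
DataFrame with an integer dtype, which keeps item labels attached through
the whole pipeline.
"""

from __future__ import annotations

import json
import logging
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "read_response_matrix",
    "write_response_matrix",
    "stratified_partition",
    "write_report",
    "read_report",
]

logger = logging.getLogger("nncopula")

REPORT_SCHEMA_VERSION = "1.0"


class ResponseMatrixError(ValueError):
    """Raised when a CSV does not parse as a binary response matrix."""


def read_response_matrix(path) -> pd.DataFrame:
    """Read an examinees × items binary response matrix from CSV.

    Raises
    ------
    ResponseMatrixError
        If a cell is not 0/1 (the offending row and item are named) or the
        rows are ragged.
    """
    try:
        df = pd.read_csv(path, header=0)
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise ResponseMatrixError(f"malformed response CSV {path}: {exc}") from exc
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ResponseMatrixError(f"{path}: empty response matrix")
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ResponseMatrixError(
            f"{path}: non-binary cell {values[i, j]!r} at row {i + 1}, "
            f"column {df.columns[j]!r}"
        )
    if df.isna().any().any():
        raise ResponseMatrixError(f"{path}: missing cells are not supported")
    return df.astype(np.int8)


def write_response_matrix(Y, path, item_labels: Sequence[str] | None = None) -> None:
    """Write a binary response matrix to CSV (header row of item labels)."""
    df = _as_frame(Y, item_labels)
    df.to_csv(path, index=False)


def _as_frame(Y, item_labels=None) -> pd.DataFrame:
    if isinstance(Y, pd.DataFrame):
        return Y
    Y = np.asarray(Y)
    if item_labels is None:
        item_labels = [f"item{k + 1:02d}" for k in range(Y.shape[1])]
    return pd.DataFrame(Y, columns=list(item_labels))


def stratified_partition(Y, fractions, seed: int):
    """Split rows into disjoint subsets, stratified by total-score decile.

    Deciles are computed on the pooled sample before splitting; ties at a
    decile boundary fall into the lower stratum. Within each decile, rows
    are shuffled with ``seed`` and allocated to the subsets so that counts
    match ``fractions`` to within one row. Strata with fewer rows than
    subsets degrade to a simple random split (logged).

    Returns a tuple of DataFrames, one per fraction, preserving row order
    within each subset.
    """
    df = _as_frame(Y)
    fractions = np.asarray(fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if (fractions < 0).any():
        raise ValueError("fractions must be nonnegative")
    n = len(df)
    if n < 10:
        raise ValueError("need at least 10 rows to stratify by decile")

    scores = df.to_numpy().sum(axis=1)
    # decile edges on the pooled scores; searchsorted(side='left') sends
    # boundary ties to the lower stratum
    edges = np.quantile(scores, np.linspace(0.1, 0.9, 9), method="linear")
    strata = np.searchsorted(edges, scores, side="left")

    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[] for _ in fractions]
    for s in np.unique(strata):
        rows = np.flatnonzero(strata == s)
        rng.shuffle(rows)
        m = len(rows)
        if m < len(fractions):
            logger.warning(
                "stratum %d has %d rows < %d subsets; simple random split",
                s, m, len(fractions),
            )
        counts = _apportion(m, fractions)
        start = 0
        for j, c in enumerate(counts):
            parts[j].extend(rows[start:start + c].tolist())
            start += c
    return tuple(df.iloc[sorted(p)].reset_index(drop=True) for p in parts)


def _apportion(m: int, fractions: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of m rows across the fractions."""
    raw = fractions * m
    counts = np.floor(raw).astype(int)
    rem = m - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def write_report(report: dict, path) -> None:
    payload = {"schema_version": REPORT_SCHEMA_VERSION, **report}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)


def read_report(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    raise TypeError(f"not JSON serialisable: {type(obj)}")
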