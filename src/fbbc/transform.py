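"""Mix/Norm stage: concatenation, normalization, binarization, arithmetic.

These operations prepare feature series for embedding.  Min–max
normalization keeps columns on comparable scales so no single feature
dominates the embedding distances; binarization and element-wise arithmetic
let users compose derived features.

Conventions (the corresponding degenerate cases are otherwise undefined):

* a constant column min–max normalizes to all zeros (a warning is logged);
* binarize maps values exactly at the threshold to 1;
* division by zero yields missing (count logged);
* concatenation aligns on the intersection of frame indices (rows present
  in only some inputs are dropped, count logged).
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, DegenerateInputError, NamingError, NotFoundError
from .trackio import FeatureSeries

__all__ = ["concat_features", "minmax_normalize", "binarize", "arithmetic"]

log = logging.getLogger(__name__)


def concat_features(series_list: Sequence[FeatureSeries]) -> FeatureSeries:
    """Place the columns of several feature series side by side.

    Rows are aligned on frame index by intersection (inner join): thinning
    and scene filtering legitimately desynchronize series, so rows present
    in only some inputs are dropped (a count is logged) rather than erroring.
    """
    if len(series_list) < 1:
        raise DegenerateInputError("concat_features needs at least one input")
    names = [c for s in series_list for c in s.columns]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise NamingError(f"duplicate column names across inputs: {dupes}")
    fps = series_list[0].fps
    if any(s.fps != fps for s in series_list):
        raise NamingError("cannot concatenate series with different fps")
    joined = pd.concat([s.data for s in series_list], axis=1, join="inner")
    if joined.empty and any(len(s) for s in series_list):
        raise DegenerateInputError("no common frames across inputs")
    dropped = sum(len(s) - len(joined) for s in series_list)
    if dropped:
        log.info("concat_features: dropped %d non-shared rows", dropped)
    prov = tuple(r for s in series_list for r in s.provenance) + (
        {"op": "concat", "inputs": [s.columns for s in series_list]},
    )
    return FeatureSeries(joined, fps=fps, provenance=prov)


def minmax_normalize(
    series: FeatureSeries, columns: Sequence[str] | None = None
) -> FeatureSeries:
    """Map each selected column independently to [0, 1] by (x−min)/(max−min).

    Extremes are taken over non-missing values; missing stays missing.  A
    constant column maps to all zeros rather than NaN so that downstream
    embedding input stays finite.
    """
    cols = list(columns) if columns is not None else series.columns
    unknown = [c for c in cols if c not in series.columns]
    if unknown:
        raise NotFoundError(f"columns {unknown} not in series {series.columns}")
    df = series.data.copy()
    for c in cols:
        vals = df[c]
        lo, hi = vals.min(), vals.max()
        if pd.isna(lo):  # all-missing column
            continue
        if hi == lo:
            log.warning("minmax_normalize: column '%s' is constant; mapped to 0", c)
            df[c] = np.where(vals.notna(), 0.0, np.nan)
        else:
            df[c] = (vals - lo) / (hi - lo)
    return FeatureSeries(
        df, fps=series.fps,
        provenance=series.provenance + ({"op": "minmax", "columns": cols},),
    )


def binarize(series: FeatureSeries, column: str, threshold: float) -> FeatureSeries:
    """Threshold one column: x ≥ threshold → 1, else 0; missing stays missing."""
    if column not in series.columns:
        raise NotFoundError(f"column '{column}' not in series {series.columns}")
    df = series.data.copy()
    vals = df[column]
    df[column] = np.where(vals.isna(), np.nan, (vals >= threshold).astype(float))
    return FeatureSeries(
        df, fps=series.fps,
        provenance=series.provenance
        + ({"op": "binarize", "column": column, "threshold": threshold},),
    )


def arithmetic(
    series: FeatureSeries, column_a: str, column_b: str, op: str, out: str
) -> FeatureSeries:
    """Append ``out = a <op> b`` element-wise; op ∈ {add, subtract, multiply,
    divide}.  Division by zero yields missing (count logged)."""
    for c in (column_a, column_b):
        if c not in series.columns:
            raise NotFoundError(f"column '{c}' not in series {series.columns}")
    if out in series.columns:
        raise NamingError(f"output column '{out}' already exists")
    a = series.data[column_a].to_numpy()
    b = series.data[column_b].to_numpy()
    if op == "add":
        vals = a + b
    elif op == "subtract":
        vals = a - b
    elif op == "multiply":
        vals = a * b
    elif op == "divide":
        zero = b == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(zero, np.nan, a / np.where(zero, np.nan, b))
        if zero.sum():
            log.info("arithmetic: %d divisions by zero -> missing", int(zero.sum()))
    else:
        raise ArgumentError(
            f"unknown op '{op}' (expected add, subtract, multiply or divide)"
        )
    df = series.data.copy()
    df[out] = vals
    return FeatureSeries(
        df, fps=series.fps,
        provenance=series.provenance
        + ({"op": op, "a": column_a, "b": column_b, "out": out},),
    )
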