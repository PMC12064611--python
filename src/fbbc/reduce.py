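"""Thinning and 2-D UMAP embedding of feature series.

Thinning keeps every k-th feature row before embedding.  It suppresses
transitional frames — intermediate postures between one held posture and the
next — which otherwise smear the low-dimensional scatter and blur cluster
boundaries.  The embedding itself is uniform manifold approximation and
projection (UMAP), always to two dimensions, with a fixed random seed so
runs are reproducible.  ``n_neighbors`` around 20–50 and ``min_dist`` = 0.1
are good starting points for posture data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ArgumentError, DegenerateInputError
from .trackio import FeatureSeries

__all__ = ["EmbedParams", "Embedding2D", "thin", "embed",
           "write_embedding", "read_embedding"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmbedParams:
    """UMAP parameters plus the row-selection settings that shape the result.

    Attributes
    ----------
    n_neighbors:
        Neighborhood size controlling the local/global balance (≥ 2).
    min_dist:
        Minimum spacing of embedded points, in [0, 1).
    thin_step:
        Row-thinning step that produced the input (recorded for provenance).
    random_seed:
        Seed for UMAP's stochastic optimization; fixed seed → identical output.
    feature_columns:
        Columns to embed; ``None`` means all columns.
    """

    n_neighbors: int = 20
    min_dist: float = 0.1
    thin_step: int = 1
    random_seed: int = 42
    feature_columns: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise ArgumentError(f"n_neighbors must be >= 2, got {self.n_neighbors}")
        if not (0 <= self.min_dist < 1):
            raise ArgumentError(f"min_dist must be in [0, 1), got {self.min_dist}")
        if self.thin_step < 1:
            raise ArgumentError(f"thin_step must be >= 1, got {self.thin_step}")

    def to_dict(self) -> dict:
        return {
            "n_neighbors": self.n_neighbors,
            "min_dist": self.min_dist,
            "thin_step": self.thin_step,
            "random_seed": self.random_seed,
            "feature_columns": list(self.feature_columns)
            if self.feature_columns else None,
        }


@dataclass
class Embedding2D:
    """2-D embedding with the frame provenance of every point."""

    points: np.ndarray          # (n, 2) float64
    source_frames: np.ndarray   # (n,) int64, frame index of each point
    params: EmbedParams
    fps: float
    provenance: tuple[dict, ...] = field(default=())

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.source_frames = np.asarray(self.source_frames, dtype=np.int64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ArgumentError(
                f"embedding must be 2-D points, got shape {self.points.shape}"
            )
        if len(self.points) != len(self.source_frames):
            raise ArgumentError("points and source_frames length mismatch")

    def __len__(self) -> int:
        return len(self.points)


def thin(series: FeatureSeries, step: int) -> FeatureSeries:
    """Retain rows at positions 0, step, 2·step, … of the row sequence.

    At 29.97 fps a step of 5 keeps one row per ≈ 0.17 s.
    """
    if step < 1:
        raise ArgumentError(f"thin step must be >= 1, got {step}")
    return FeatureSeries(
        series.data.iloc[::step], fps=series.fps,
        provenance=series.provenance + ({"op": "thin", "step": step},),
    )


def embed(series: FeatureSeries, params: EmbedParams) -> Embedding2D:
    """Embed feature rows into 2-D with UMAP.

    Rows with any missing value in the selected columns are dropped first
    (distance computations need complete vectors; the dropped count is
    logged) and are excluded from ``source_frames``.  At least
    ``n_neighbors + 1`` complete rows are required.
    """
    cols = (
        list(params.feature_columns)
        if params.feature_columns is not None
        else series.columns
    )
    unknown = [c for c in cols if c not in series.columns]
    if unknown:
        raise ArgumentError(f"columns {unknown} not in series {series.columns}")
    if not cols:
        raise DegenerateInputError("no feature columns selected for embedding")
    sub = series.data[cols]
    complete = sub.notna().all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        log.info("embed: dropped %d rows with missing values", dropped)
    sub = sub[complete]
    minimum = params.n_neighbors + 1
    if len(sub) < minimum:
        raise DegenerateInputError(
            f"embedding needs at least {minimum} complete rows "
            f"(n_neighbors + 1), got {len(sub)}"
        )
    x = sub.to_numpy(dtype=np.float64)
    if not np.isfinite(x).all():
        raise ArgumentError("feature matrix contains non-finite values")

    import umap  # deferred: numba compilation is slow at import time

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=params.n_neighbors,
        min_dist=params.min_dist,
        random_state=params.random_seed,
        n_jobs=1,
    )
    pts = reducer.fit_transform(x)
    return Embedding2D(
        points=pts,
        source_frames=sub.index.to_numpy(),
        params=params,
        fps=series.fps,
        provenance=series.provenance
        + ({"op": "umap", "params": params.to_dict(), "dropped_rows": dropped},),
    )


def write_embedding(embedding: Embedding2D, path: str | Path) -> None:
    """Write ``frame,u,v`` CSV plus a JSON provenance sidecar (.json)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "frame": embedding.source_frames,
            "u": embedding.points[:, 0],
            "v": embedding.points[:, 1],
        }
    )
    df.to_csv(path, index=False)
    sidecar = {
        "params": embedding.params.to_dict(),
        "fps": embedding.fps,
        "n_points": len(embedding),
        "provenance": list(embedding.provenance),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )


def read_embedding(path: str | Path) -> Embedding2D:
    """Read an embedding written by :func:`write_embedding`."""
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    p = sidecar["params"]
    params = EmbedParams(
        n_neighbors=p["n_neighbors"],
        min_dist=p["min_dist"],
        thin_step=p["thin_step"],
        random_seed=p["random_seed"],
        feature_columns=tuple(p["feature_columns"]) if p["feature_columns"] else None,
    )
    return Embedding2D(
        points=df[["u", "v"]].to_numpy(),
        source_frames=df["frame"].to_numpy(),
        params=params,
        fps=sidecar["fps"],
        provenance=tuple(sidecar["provenance"]),
    )
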