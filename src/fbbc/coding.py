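"""Behavior coding: from embedding-space clusters to a per-frame timeline.

Clusters can be assigned two ways:

* :func:`assign_by_pick` replays the interactive workflow headlessly — every
  embedded point within a given radius of a picked location is labeled,
  later picks overwriting earlier ones.  The radius is measured in embedding
  coordinate units (data units, not screen pixels).
* :func:`auto_cluster` labels every point programmatically, either k-means
  with a known cluster count or density-based grouping (HDBSCAN) when the
  count is unknown; density-based mode leaves sparse points unassigned.

:func:`build_timeline` expands point labels back to the full frame rate.
Because rows are thinned before embedding, each coded point governs the
frames from its own source frame up to (not including) the next retained
frame — a hold-forward rule.  Frames before the first retained frame, and
spans governed by unassigned points, receive the ``NONE`` code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ArgumentError, DegenerateInputError, NamingError, NotFoundError
from .reduce import Embedding2D

__all__ = [
    "UNASSIGNED",
    "NONE_CODE",
    "ClusterAssignment",
    "BehaviorTimeline",
    "assign_by_pick",
    "auto_cluster",
    "build_timeline",
    "export_timeline",
    "read_timeline",
    "timeline_to_intervals",
    "intervals_to_timeline",
    "export_intervals",
    "write_cluster_table",
]

#: Sentinel cluster id for points that no pick or dense group covered.
UNASSIGNED = -1

#: Timeline code for frames with no assigned cluster.
NONE_CODE = "NONE"


@dataclass(frozen=True)
class ClusterAssignment:
    """Cluster table plus per-point labels keyed by source frame.

    ``clusters`` maps cluster id → unique name; ``labels`` maps each labeled
    source frame → cluster id (:data:`UNASSIGNED` marks explicit non-members;
    frames absent from ``labels`` are equally unassigned).
    """

    clusters: dict[int, str]
    labels: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.clusters.values())
        if len(set(names)) != len(names):
            raise NamingError(f"cluster names must be unique: {names}")
        bad = {cid for cid in self.labels.values()
               if cid != UNASSIGNED and cid not in self.clusters}
        if bad:
            raise ArgumentError(f"labels reference unknown cluster ids {sorted(bad)}")

    def name_of(self, cluster_id: int) -> str:
        if cluster_id == UNASSIGNED:
            return NONE_CODE
        return self.clusters[cluster_id]

    @property
    def n_labeled(self) -> int:
        return sum(1 for cid in self.labels.values() if cid != UNASSIGNED)


def assign_by_pick(
    embedding: Embedding2D,
    assignment: ClusterAssignment,
    pick: tuple[float, float],
    picker_range: float,
    cluster_id: int,
) -> ClusterAssignment:
    """Label every point within ``picker_range`` of ``pick`` as ``cluster_id``.

    Distances are Euclidean in embedding coordinates.  Points already
    labeled are overwritten (interactive reassignment semantics); points
    outside the radius keep their labels.
    """
    if cluster_id not in assignment.clusters:
        raise NotFoundError(
            f"cluster id {cluster_id} not in table "
            f"(available: {sorted(assignment.clusters)})"
        )
    if picker_range <= 0:
        raise ArgumentError(f"picker_range must be > 0, got {picker_range}")
    d = np.hypot(
        embedding.points[:, 0] - pick[0], embedding.points[:, 1] - pick[1]
    )
    labels = dict(assignment.labels)
    for frame in embedding.source_frames[d <= picker_range]:
        labels[int(frame)] = cluster_id
    return ClusterAssignment(clusters=dict(assignment.clusters), labels=labels)


def auto_cluster(
    embedding: Embedding2D,
    k: int | None = None,
    random_seed: int = 0,
    min_cluster_size: int | None = None,
) -> ClusterAssignment:
    """Label every embedded point programmatically.

    With ``k`` given, k-means partitions all points into exactly k clusters.
    With ``k=None``, HDBSCAN finds dense groups (cluster count inferred from
    the data); points in sparse regions are marked unassigned.  Cluster ids
    are 0..K−1 with default names ``cluster_0`` .. ``cluster_{K-1}``.
    """
    n = len(embedding)
    if n == 0:
        raise DegenerateInputError("empty embedding")
    if k is not None:
        if k < 1 or k > n:
            raise ArgumentError(f"k must be in [1, {n}], got {k}")
        from sklearn.cluster import KMeans

        raw = KMeans(n_clusters=k, n_init=10, random_state=random_seed).fit_predict(
            embedding.points
        )
    else:
        from sklearn.cluster import HDBSCAN

        if min_cluster_size is None:
            # 2% of the points, floored at 5: small enough to keep rare
            # postures, large enough to ignore stray transitional points
            min_cluster_size = max(5, n // 50)
        raw = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(
            embedding.points
        )
    found = sorted(c for c in np.unique(raw) if c != -1)
    remap = {c: i for i, c in enumerate(found)}
    clusters = {i: f"cluster_{i}" for i in range(len(found))}
    labels = {
        int(f): (remap[c] if c != -1 else UNASSIGNED)
        for f, c in zip(embedding.source_frames, raw)
    }
    return ClusterAssignment(clusters=clusters, labels=labels)


@dataclass
class BehaviorTimeline:
    """Per-frame behavior codes over a contiguous frame range."""

    data: pd.DataFrame  # columns: frame (int64), code (str)
    fps: float

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ArgumentError(f"fps must be > 0, got {self.fps}")
        df = self.data.loc[:, ["frame", "code"]].copy()
        df["frame"] = df["frame"].astype(np.int64)
        df["code"] = df["code"].astype(str)
        frames = df["frame"].to_numpy()
        if len(frames) and np.any(np.diff(frames) != 1):
            raise ArgumentError("timeline frames must be contiguous and increasing")
        self.data = df.reset_index(drop=True)

    @property
    def codes(self) -> np.ndarray:
        return self.data["code"].to_numpy()

    @property
    def frames(self) -> np.ndarray:
        return self.data["frame"].to_numpy()

    def code_set(self) -> set[str]:
        """Distinct behavior codes present, excluding the NONE filler."""
        return set(self.data["code"]) - {NONE_CODE}

    def to_table(self) -> pd.DataFrame:
        out = self.data.copy()
        out.insert(1, "time_ms", out["frame"].to_numpy() / self.fps * 1000.0)
        return out

    def equals(self, other: "BehaviorTimeline") -> bool:
        return (
            isinstance(other, BehaviorTimeline)
            and self.fps == other.fps
            and self.data.equals(other.data)
        )

    def __len__(self) -> int:
        return len(self.data)


def build_timeline(
    assignment: ClusterAssignment,
    embedding: Embedding2D,
    full_frame_range: tuple[int, int],
    fps: float | None = None,
) -> BehaviorTimeline:
    """Expand point labels to a per-frame timeline over ``full_frame_range``
    (inclusive).

    Each coded point governs frames from its source frame up to (not
    including) the next retained source frame; the last point governs through
    the end of the range.  Frames before the first retained frame and spans
    of unassigned points get :data:`NONE_CODE`.
    """
    if not assignment.clusters and not assignment.labels:
        raise DegenerateInputError("empty cluster assignment")
    first, last = full_frame_range
    if first > last:
        raise ArgumentError(f"invalid frame range ({first}, {last})")
    src = np.sort(embedding.source_frames)
    if len(src) and (src[0] < first or src[-1] > last):
        raise ArgumentError(
            "embedding source frames fall outside the requested range"
        )
    frames = np.arange(first, last + 1, dtype=np.int64)
    codes = np.full(len(frames), NONE_CODE, dtype=object)
    boundaries = np.append(src, last + 1)
    for i, f in enumerate(src):
        cid = assignment.labels.get(int(f), UNASSIGNED)
        code = assignment.name_of(cid)
        codes[f - first: boundaries[i + 1] - first] = code
    return BehaviorTimeline(
        pd.DataFrame({"frame": frames, "code": codes}),
        fps=fps if fps is not None else embedding.fps,
    )


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def export_timeline(timeline: BehaviorTimeline, path: str | Path) -> None:
    """Per-frame CSV with columns ``frame,time_ms,code``."""
    timeline.to_table().to_csv(path, index=False)


def read_timeline(path: str | Path, fps: float) -> BehaviorTimeline:
    df = pd.read_csv(path)
    return BehaviorTimeline(df[["frame", "code"]], fps=fps)


def timeline_to_intervals(timeline: BehaviorTimeline) -> pd.DataFrame:
    """Run-length encode a timeline into ``code,start_ms,end_ms`` rows.

    Intervals are half-open; ``end_ms`` is the timestamp of the frame after
    the run, so decoding with :func:`intervals_to_timeline` is lossless.
    """
    codes = timeline.codes
    frames = timeline.frames
    rows = []
    if len(codes):
        starts = np.flatnonzero(np.r_[True, codes[1:] != codes[:-1]])
        ends = np.r_[starts[1:], len(codes)]
        for s, e in zip(starts, ends):
            rows.append(
                (
                    codes[s],
                    frames[s] / timeline.fps * 1000.0,
                    (frames[e - 1] + 1) / timeline.fps * 1000.0,
                )
            )
    return pd.DataFrame(rows, columns=["code", "start_ms", "end_ms"])


def intervals_to_timeline(
    intervals: pd.DataFrame, fps: float
) -> BehaviorTimeline:
    """Decode a run-length interval table back to per-frame codes."""
    if intervals.empty:
        raise DegenerateInputError("empty interval table")
    first = int(round(intervals["start_ms"].min() * fps / 1000.0))
    last = int(round(intervals["end_ms"].max() * fps / 1000.0)) - 1
    frames = np.arange(first, last + 1, dtype=np.int64)
    codes = np.full(len(frames), NONE_CODE, dtype=object)
    for _, row in intervals.iterrows():
        s = int(round(row["start_ms"] * fps / 1000.0))
        e = int(round(row["end_ms"] * fps / 1000.0))
        codes[s - first: e - first] = row["code"]
    return BehaviorTimeline(pd.DataFrame({"frame": frames, "code": codes}), fps=fps)


def export_intervals(timeline: BehaviorTimeline, path: str | Path) -> None:
    timeline_to_intervals(timeline).to_csv(path, index=False)


def write_cluster_table(assignment: ClusterAssignment, path: str | Path) -> None:
    """CSV with columns ``cluster_id,name``."""
    pd.DataFrame(
        sorted(assignment.clusters.items()), columns=["cluster_id", "name"]
    ).to_csv(path, index=False)
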