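"""Keypoint-track data model and I/O.

A *track* is the per-frame, per-person, per-keypoint time series of image
coordinates produced by a pose-estimation backend.  Tracks are held in long
format (one row per ``(frame, person, keypoint)``) with pixel coordinates in
the image convention: origin at the top-left corner, y increasing downward.

Two on-disk representations are supported:

* the native *track container* — a single columnar binary file (Parquet
  payload, ``.track`` extension) carrying the rows plus JSON metadata
  (fps, video name, frame size, keypoint scheme); lossless and bit-exact;
* the DeepLabCut keypoint dialect — an HDF5 table whose columns form the
  three-level ``scorer / bodypart / coord`` hierarchy with coords
  ``x``, ``y`` and optionally ``likelihood``.

Missing coordinates and confidences are represented as NaN and are never
silently zero-filled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.parquet as pq

from .errors import ArgumentError, DialectError, FormatError, NotFoundError
from .schemes import KeypointScheme

__all__ = [
    "TrackSeries",
    "FeatureSeries",
    "ValidationReport",
    "read_dlc_keypoints",
    "write_dlc_keypoints",
    "read_track",
    "write_track",
    "write_track_csv",
    "select_person",
    "filter_confidence",
    "validate_track",
    "read_features",
    "write_features",
    "write_features_csv",
]

_TRACK_COLUMNS = ["frame", "person", "keypoint", "x", "y", "conf"]
_METADATA_KEY = b"fbbc_track_meta"
_FEATURE_METADATA_KEY = b"fbbc_feature_meta"


@dataclass
class TrackSeries:
    """Keypoint detections for one video.

    Attributes
    ----------
    data:
        Long-format table with columns ``frame, person, keypoint`` (int64)
        and ``x, y, conf`` (float64, NaN = missing).
    fps:
        Video frame rate (frames per second), > 0.
    video_name:
        Stem of the source video (informational).
    frame_size:
        Optional ``(width_px, height_px)``.
    scheme:
        Optional :class:`~fbbc.schemes.KeypointScheme` the ids refer to.
    attrs:
        Free-form provenance (e.g. the bodypart→id mapping used at ingest).
    """

    data: pd.DataFrame
    fps: float
    video_name: str = ""
    frame_size: tuple[int, int] | None = None
    scheme: KeypointScheme | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ArgumentError(f"fps must be > 0, got {self.fps}")
        missing = [c for c in _TRACK_COLUMNS if c not in self.data.columns]
        if missing:
            raise ArgumentError(f"track data lacks columns {missing}")
        df = self.data.loc[:, _TRACK_COLUMNS].copy()
        for c in ("frame", "person", "keypoint"):
            df[c] = df[c].astype(np.int64)
        for c in ("x", "y", "conf"):
            df[c] = df[c].astype(np.float64)
        df = df.sort_values(["frame", "person", "keypoint"], kind="mergesort")
        df = df.reset_index(drop=True)
        self.data = df

    # -- accessors ---------------------------------------------------------
    @property
    def frames(self) -> np.ndarray:
        """Sorted unique frame indices present in the track."""
        return np.unique(self.data["frame"].to_numpy())

    @property
    def persons(self) -> np.ndarray:
        return np.unique(self.data["person"].to_numpy())

    @property
    def keypoint_ids(self) -> np.ndarray:
        return np.unique(self.data["keypoint"].to_numpy())

    def timestamps_ms(self, frames: np.ndarray | None = None) -> np.ndarray:
        """Timestamps in milliseconds: ``frame / fps * 1000``."""
        if frames is None:
            frames = self.frames
        return np.asarray(frames, dtype=np.float64) / self.fps * 1000.0

    def coords(self, keypoint_id: int, person_id: int | None = None) -> pd.DataFrame:
        """(x, y, conf) for one keypoint, indexed by frame over the track's
        full frame range (absent frames become NaN rows).

        If the track holds several persons, ``person_id`` is required.
        """
        df = self.data
        if person_id is None:
            persons = self.persons
            if len(persons) > 1:
                raise ArgumentError(
                    f"track has persons {persons.tolist()}; pass person_id or "
                    "use select_person() first"
                )
        else:
            df = df[df["person"] == person_id]
        sub = df[df["keypoint"] == keypoint_id]
        if sub.empty:
            raise NotFoundError(
                f"keypoint {keypoint_id} not in track "
                f"(available: {self.keypoint_ids.tolist()})"
            )
        out = sub.set_index("frame")[["x", "y", "conf"]]
        return out.reindex(self.frames)

    def equals(self, other: "TrackSeries") -> bool:
        """Exact equality including NaN placement and metadata."""
        if not isinstance(other, TrackSeries):
            return False
        meta_eq = (
            self.fps == other.fps
            and self.video_name == other.video_name
            and self.frame_size == other.frame_size
            and self.scheme == other.scheme
        )
        return meta_eq and self.data.equals(other.data)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class FeatureSeries:
    """Named numeric time series derived from a track.

    ``data`` is indexed by frame (unique, strictly increasing) with one
    float64 column per feature.  ``provenance`` records the operations that
    produced each column.
    """

    data: pd.DataFrame
    fps: float
    provenance: tuple[dict, ...] = ()

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ArgumentError(f"fps must be > 0, got {self.fps}")
        df = self.data.copy()
        df.index = df.index.astype(np.int64)
        df.index.name = "frame"
        idx = df.index.to_numpy()
        if len(idx) and (len(np.unique(idx)) != len(idx) or np.any(np.diff(idx) <= 0)):
            raise ArgumentError("frame index must be unique and strictly increasing")
        if df.columns.duplicated().any():
            raise ArgumentError("feature column names must be unique")
        self.data = df.astype(np.float64)
        self.provenance = tuple(self.provenance)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def frames(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def timestamps_ms(self) -> np.ndarray:
        return self.frames.astype(np.float64) / self.fps * 1000.0

    def with_provenance(self, record: dict) -> "FeatureSeries":
        return FeatureSeries(self.data, self.fps, self.provenance + (record,))

    def to_table(self) -> pd.DataFrame:
        """Export view with explicit ``frame`` and ``time_ms`` columns."""
        out = self.data.reset_index()
        out.insert(1, "time_ms", out["frame"].to_numpy() / self.fps * 1000.0)
        return out

    def equals(self, other: "FeatureSeries") -> bool:
        return (
            isinstance(other, FeatureSeries)
            and self.fps == other.fps
            and self.data.equals(other.data)
        )

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# DeepLabCut dialect
# ---------------------------------------------------------------------------

def read_dlc_keypoints(
    path: str | Path,
    fps: float,
    person_id: int = 0,
    name_to_id: dict[str, int] | None = None,
    scheme: KeypointScheme | None = None,
) -> TrackSeries:
    """Read a DeepLabCut keypoint HDF5 file into a :class:`TrackSeries`.

    The dialect stores one pandas table whose columns form a three-level
    hierarchy ``scorer / bodypart / coord`` with coords ``x``, ``y`` and
    optionally ``likelihood``.  The file does not record the frame rate, so
    ``fps`` must be supplied by the caller.

    Bodyparts are mapped to keypoint ids through ``name_to_id`` when given,
    otherwise ids ``0..n-1`` are assigned in column order; the mapping used
    is recorded in ``attrs["bodypart_map"]``.
    """
    if fps <= 0:
        raise ArgumentError(f"fps must be > 0, got {fps}")
    path = Path(path)
    import tables

    try:
        table = pd.read_hdf(path)
    except (OSError, ValueError, KeyError, tables.HDF5ExtError) as exc:
        raise FormatError(f"cannot read DeepLabCut HDF5 file '{path}': {exc}") from exc
    if not isinstance(table, pd.DataFrame) or not isinstance(
        table.columns, pd.MultiIndex
    ):
        raise DialectError(
            f"'{path}': expected a table with hierarchical columns"
        )
    if table.columns.nlevels != 3:
        raise DialectError(
            f"'{path}': expected a 3-level scorer/bodypart/coord column "
            f"hierarchy, found {table.columns.nlevels} levels"
        )

    scorer = table.columns.get_level_values(0)[0]
    bodyparts = list(dict.fromkeys(table.columns.get_level_values(1)))
    if name_to_id is not None:
        unmapped = [bp for bp in bodyparts if bp not in name_to_id]
        if unmapped:
            raise ArgumentError(f"name_to_id lacks entries for bodyparts {unmapped}")
        bp_map = {bp: int(name_to_id[bp]) for bp in bodyparts}
    else:
        bp_map = {bp: i for i, bp in enumerate(bodyparts)}

    frames = np.arange(len(table), dtype=np.int64)
    parts = []
    for bp in bodyparts:
        sub = table[scorer][bp]
        if "x" not in sub.columns or "y" not in sub.columns:
            raise DialectError(f"'{path}': bodypart '{bp}' lacks x/y coordinates")
        conf = (
            sub["likelihood"].to_numpy(dtype=np.float64)
            if "likelihood" in sub.columns
            else np.full(len(table), np.nan)
        )
        parts.append(
            pd.DataFrame(
                {
                    "frame": frames,
                    "person": np.int64(person_id),
                    "keypoint": np.int64(bp_map[bp]),
                    "x": sub["x"].to_numpy(dtype=np.float64),
                    "y": sub["y"].to_numpy(dtype=np.float64),
                    "conf": conf,
                }
            )
        )
    data = pd.concat(parts, ignore_index=True)
    return TrackSeries(
        data=data,
        fps=fps,
        video_name=path.stem,
        scheme=scheme,
        attrs={"dialect": "deeplabcut", "scorer": scorer, "bodypart_map": bp_map},
    )


def write_dlc_keypoints(
    track: TrackSeries,
    path: str | Path,
    scorer: str = "fbbc",
    include_likelihood: bool = True,
) -> None:
    """Write a single-person track in the DeepLabCut HDF5 dialect.

    Bodypart names come from the track's scheme when present, otherwise
    ``kp<id>``.  Used to exercise the reader and to exchange data with
    DeepLabCut-compatible tools.
    """
    persons = track.persons
    if len(persons) > 1:
        raise ArgumentError("DLC dialect stores one person; use select_person() first")
    path = Path(path)
    frames = track.frames
    cols = {}
    for kid in track.keypoint_ids:
        if track.scheme is not None and kid in track.scheme:
            name = track.scheme.label_of(kid)
        else:
            name = f"kp{kid}"
        c = track.coords(int(kid))
        cols[(scorer, name, "x")] = c["x"].to_numpy()
        cols[(scorer, name, "y")] = c["y"].to_numpy()
        if include_likelihood:
            cols[(scorer, name, "likelihood")] = c["conf"].to_numpy()
    table = pd.DataFrame(cols, index=pd.RangeIndex(len(frames)))
    table.columns = pd.MultiIndex.from_tuples(
        table.columns, names=["scorer", "bodyparts", "coords"]
    )
    table.to_hdf(path, key="df_with_missing", mode="w", format="fixed")


# ---------------------------------------------------------------------------
# Native track container
# ---------------------------------------------------------------------------

def write_track(track: TrackSeries, path: str | Path) -> None:
    """Write a track to the native columnar container (Parquet payload).

    The round trip ``read_track(write_track(t)) == t`` is bit-exact for
    coordinates and preserves missingness and all metadata.
    """
    path = Path(path)
    meta = {
        "fps": track.fps,
        "video_name": track.video_name,
        "frame_size": list(track.frame_size) if track.frame_size else None,
        "scheme": track.scheme.to_dict() if track.scheme else None,
        "attrs": track.attrs,
    }
    table = pa.Table.from_pandas(track.data, preserve_index=False)
    table = table.replace_schema_metadata(
        {_METADATA_KEY: json.dumps(meta).encode()}
    )
    pq.write_table(table, path)


def read_track(path: str | Path) -> TrackSeries:
    """Read a track written by :func:`write_track`."""
    path = Path(path)
    try:
        table = pq.read_table(path)
    except (OSError, pa.ArrowInvalid) as exc:
        raise FormatError(f"cannot read track container '{path}': {exc}") from exc
    raw_meta = (table.schema.metadata or {}).get(_METADATA_KEY)
    if raw_meta is None:
        raise FormatError(f"'{path}' is not a track container (metadata missing)")
    meta = json.loads(raw_meta.decode())
    return TrackSeries(
        data=table.to_pandas(),
        fps=meta["fps"],
        video_name=meta["video_name"],
        frame_size=tuple(meta["frame_size"]) if meta["frame_size"] else None,
        scheme=KeypointScheme.from_dict(meta["scheme"]) if meta["scheme"] else None,
        attrs=meta.get("attrs", {}),
    )


def write_track_csv(track: TrackSeries, path: str | Path) -> None:
    """Plain-text mirror of the container for inspection."""
    out = track.data.copy()
    out.insert(1, "time_ms", out["frame"].to_numpy() / track.fps * 1000.0)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Feature container
# ---------------------------------------------------------------------------

def write_features(series: FeatureSeries, path: str | Path) -> None:
    """Write a feature series to the native columnar container."""
    meta = {"fps": series.fps, "provenance": list(series.provenance)}
    table = pa.Table.from_pandas(series.data.reset_index(), preserve_index=False)
    table = table.replace_schema_metadata(
        {_FEATURE_METADATA_KEY: json.dumps(meta).encode()}
    )
    pq.write_table(table, Path(path))


def read_features(path: str | Path) -> FeatureSeries:
    """Read a feature series written by :func:`write_features`."""
    path = Path(path)
    try:
        table = pq.read_table(path)
    except (OSError, pa.ArrowInvalid) as exc:
        raise FormatError(f"cannot read feature container '{path}': {exc}") from exc
    raw_meta = (table.schema.metadata or {}).get(_FEATURE_METADATA_KEY)
    if raw_meta is None:
        raise FormatError(f"'{path}' is not a feature container (metadata missing)")
    meta = json.loads(raw_meta.decode())
    df = table.to_pandas().set_index("frame")
    return FeatureSeries(
        data=df, fps=meta["fps"], provenance=tuple(meta["provenance"])
    )


def write_features_csv(series: FeatureSeries, path: str | Path) -> None:
    """CSV mirror: ``frame, time_ms`` then one column per feature."""
    series.to_table().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Track operations
# ---------------------------------------------------------------------------

def select_person(track: TrackSeries, person_id: int) -> TrackSeries:
    """Restrict a multi-person track to one person; metadata unchanged."""
    persons = track.persons
    if person_id not in persons:
        raise NotFoundError(
            f"person {person_id} not in track (available: {persons.tolist()})"
        )
    return replace(track, data=track.data[track.data["person"] == person_id])


def filter_confidence(track: TrackSeries, threshold: float) -> TrackSeries:
    """Mark coordinates with confidence below ``threshold`` as missing.

    Ingest is lossless; this explicit filter is how low-confidence
    detections are removed from downstream features.
    """
    data = track.data.copy()
    low = data["conf"] < threshold  # NaN conf compares False → kept
    data.loc[low, ["x", "y"]] = np.nan
    return replace(track, data=data)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_track`; empty ``violations`` means valid."""

    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        return "valid track" if self.ok else "\n".join(self.violations)


def validate_track(
    track: TrackSeries, scheme: KeypointScheme | None = None
) -> ValidationReport:
    """Check track invariants and report (never raise).

    Checks: unique ``(frame, person, keypoint)`` keys, non-negative frames,
    finite-or-NaN coordinates, fps > 0, and — when a scheme is given — that
    every keypoint id exists in the scheme.
    """
    v: list[str] = []
    df = track.data
    dup = df.duplicated(subset=["frame", "person", "keypoint"])
    for _, row in df[dup].iterrows():
        v.append(
            "duplicate key (frame={frame}, person={person}, keypoint={keypoint})".format(
                **row[["frame", "person", "keypoint"]].to_dict()
            )
        )
    if (df["frame"] < 0).any():
        v.append("negative frame indices present")
    for c in ("x", "y"):
        vals = df[c].to_numpy()
        if np.isinf(vals).any():
            v.append(f"non-finite (infinite) values in column '{c}'")
    if track.fps <= 0:
        v.append(f"fps must be > 0, got {track.fps}")
    scheme = scheme or track.scheme
    if scheme is not None:
        outside = sorted(set(track.keypoint_ids.tolist()) - set(scheme.ids))
        for kid in outside:
            v.append(f"keypoint id {kid} outside scheme '{scheme.name}'")
    return ValidationReport(v)
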