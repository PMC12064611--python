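"""Scene tables: labeled time intervals restricting analysis to relevant footage.

A scene is a half-open interval ``[start_ms, end_ms)`` with a free-text
description.  Filtering keeps rows whose timestamp falls inside at least one
scene; half-open intervals compose without double-counting boundary frames.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import TypeVar, Union

import pandas as pd

from .errors import ArgumentError, ValidationError
from .trackio import FeatureSeries, TrackSeries

__all__ = ["Scene", "SceneTable", "filter_by_scenes",
           "read_scene_table", "write_scene_table"]


@dataclass(frozen=True)
class Scene:
    start_ms: float
    end_ms: float
    description: str = ""


@dataclass(frozen=True)
class SceneTable:
    """Ordered collection of scenes; every scene must satisfy
    0 ≤ start_ms < end_ms."""

    scenes: tuple[Scene, ...]

    def __post_init__(self) -> None:
        for i, s in enumerate(self.scenes):
            if not (s.start_ms < s.end_ms):
                raise ValidationError(
                    f"scene row {i}: start_ms ({s.start_ms}) must be < "
                    f"end_ms ({s.end_ms})"
                )
            if s.start_ms < 0:
                raise ValidationError(f"scene row {i}: negative start_ms")

    def __len__(self) -> int:
        return len(self.scenes)

    def contains(self, t_ms) -> "pd.Series | bool":
        """Vectorized membership: start ≤ t < end for at least one scene."""
        import numpy as np

        t = np.asarray(t_ms, dtype=float)
        mask = np.zeros(t.shape, dtype=bool)
        for s in self.scenes:
            mask |= (t >= s.start_ms) & (t < s.end_ms)
        return mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.start_ms, s.end_ms, s.description) for s in self.scenes],
            columns=["start_ms", "end_ms", "description"],
        )


_SeriesT = TypeVar("_SeriesT", bound=Union[TrackSeries, FeatureSeries])


def filter_by_scenes(series: _SeriesT, scenes: SceneTable) -> _SeriesT:
    """Keep rows whose timestamp lies in at least one scene interval.

    Works on both tracks and feature series (timestamps derive from frame
    index and fps in both); original row order is preserved and overlapping
    scenes never duplicate rows.
    """
    if len(scenes) == 0:
        raise ArgumentError("scene table is empty")
    if isinstance(series, TrackSeries):
        t_ms = series.data["frame"].to_numpy() / series.fps * 1000.0
        return replace(series, data=series.data[scenes.contains(t_ms)])
    if isinstance(series, FeatureSeries):
        mask = scenes.contains(series.timestamps_ms())
        return FeatureSeries(
            series.data[mask], fps=series.fps,
            provenance=series.provenance
            + ({"op": "scene_filter", "n_scenes": len(scenes)},),
        )
    raise ArgumentError(f"cannot scene-filter object of type {type(series).__name__}")


def read_scene_table(path: str | Path) -> SceneTable:
    """Read a scene CSV with header ``start_ms,end_ms,description``.

    Malformed rows (non-numeric times, start ≥ end, negative start) raise a
    validation error naming the row number.
    """
    df = pd.read_csv(path)
    required = ["start_ms", "end_ms", "description"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"scene table '{path}' lacks columns {missing}")
    scenes = []
    for i, row in df.iterrows():
        try:
            start, end = float(row["start_ms"]), float(row["end_ms"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"scene table '{path}' row {i}: non-numeric start/end"
            ) from None
        desc = "" if pd.isna(row["description"]) else str(row["description"])
        try:
            table = SceneTable((Scene(start, end, desc),))
        except ValidationError as exc:
            raise ValidationError(f"scene table '{path}' row {i}: {exc}") from None
        scenes.append(table.scenes[0])
    return SceneTable(tuple(scenes))


def write_scene_table(table: SceneTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)
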