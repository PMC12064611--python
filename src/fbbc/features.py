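"""Kinematic feature extraction from keypoint tracks.

Features are per-frame scalars derived from one or more keypoints:

* ``position_x`` / ``position_y`` — raw pixel coordinate of one keypoint;
* ``speed`` — instantaneous speed (px/s) by backward difference;
* ``distance`` — Euclidean distance between two keypoints (px);
* ``dot_product`` — (a−o)·(b−o) for three keypoints (px²);
* ``cross_product`` — scalar 2-D cross (a−o)×(b−o) = uₓv_y − u_yvₓ (px²).

Because image coordinates are y-down, the scalar cross product follows a
left-handed sign convention: it is positive when ``b−o`` lies clockwise of
``a−o`` as seen on screen.  Any feature touching a missing coordinate is
missing (NaN); nothing is imputed.

The :data:`RIGHT_ARM_CROSS4` preset encodes a four-cross-product description
of right-arm posture built from the shoulders (5, 6), right elbow (8) and
right hand (10); :data:`DESK_TASK` prepends the neck x-coordinate (18) as an
upper-body sway feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ArgumentError, DegenerateInputError, RecipeError
from .trackio import FeatureSeries, TrackSeries

__all__ = [
    "FeatureSpec",
    "FeatureRecipe",
    "position_series",
    "speed_series",
    "distance_series",
    "dot_product_series",
    "cross_product_series",
    "apply_recipe",
    "kde_dwell",
    "DwellMap",
    "RIGHT_ARM_CROSS4",
    "NECK_X",
    "DESK_TASK",
    "get_preset",
]

_ARITY = {
    "position_x": 1,
    "position_y": 1,
    "speed": 1,
    "distance": 2,
    "dot_product": 3,
    "cross_product": 3,
}


@dataclass(frozen=True)
class FeatureSpec:
    """One feature: an operation, its keypoint ids, and the output name.

    For ``dot_product`` and ``cross_product`` the ids are ordered
    ``(origin, a, b)``: the vectors are ``a − origin`` and ``b − origin``.
    """

    op: str
    ids: tuple[int, ...]
    name: str

    def __post_init__(self) -> None:
        if self.op not in _ARITY:
            raise RecipeError(
                f"spec '{self.name}': unknown op '{self.op}' "
                f"(known: {sorted(_ARITY)})"
            )
        if len(self.ids) != _ARITY[self.op]:
            raise RecipeError(
                f"spec '{self.name}': op '{self.op}' takes {_ARITY[self.op]} "
                f"keypoint ids, got {len(self.ids)}"
            )


@dataclass(frozen=True)
class FeatureRecipe:
    """An ordered list of feature specs with unique output names."""

    specs: tuple[FeatureSpec, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise RecipeError(f"duplicate output names in recipe: {names}")

    def __add__(self, other: "FeatureRecipe") -> "FeatureRecipe":
        return FeatureRecipe(self.specs + other.specs)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def to_list(self) -> list[dict]:
        return [
            {"op": s.op, "ids": list(s.ids), "name": s.name} for s in self.specs
        ]

    @classmethod
    def from_list(cls, items: list[dict]) -> "FeatureRecipe":
        return cls(
            tuple(
                FeatureSpec(op=i["op"], ids=tuple(i["ids"]), name=i["name"])
                for i in items
            )
        )


#: Four scalar cross products describing right-arm posture
#: (origin; a, b per column):  shoulder_left = (5; 10, 6),
#: hand = (10; 8, 5), shoulder_right = (6; 5, 8), elbow = (8; 6, 10).
RIGHT_ARM_CROSS4 = FeatureRecipe(
    (
        FeatureSpec("cross_product", (5, 10, 6), "shoulder_left"),
        FeatureSpec("cross_product", (10, 8, 5), "hand"),
        FeatureSpec("cross_product", (6, 5, 8), "shoulder_right"),
        FeatureSpec("cross_product", (8, 6, 10), "elbow"),
    )
)

#: Horizontal neck position: captures left–right sway of the upper body.
NECK_X = FeatureRecipe((FeatureSpec("position_x", (18,), "neck_x"),))

#: Default desk-task feature set: neck x plus the four arm cross products.
DESK_TASK = NECK_X + RIGHT_ARM_CROSS4

_PRESETS = {
    "right_arm_cross4": RIGHT_ARM_CROSS4,
    "neck_x": NECK_X,
    "desk_task": DESK_TASK,
}


def get_preset(name: str) -> FeatureRecipe:
    """Look up a built-in feature recipe by name."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset '{name}'; built-in presets: {sorted(_PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# elementary feature series
# ---------------------------------------------------------------------------

def _xy(track: TrackSeries, keypoint_id: int) -> tuple[np.ndarray, np.ndarray]:
    c = track.coords(keypoint_id)
    return c["x"].to_numpy(), c["y"].to_numpy()


def _series(track: TrackSeries, values: np.ndarray, name: str, record: dict
            ) -> FeatureSeries:
    df = pd.DataFrame({name: values}, index=pd.Index(track.frames, name="frame"))
    return FeatureSeries(df, fps=track.fps, provenance=(record,))


def position_series(
    track: TrackSeries, keypoint_id: int, axis: str, name: str | None = None
) -> FeatureSeries:
    """Raw pixel coordinate of one keypoint along ``axis`` ('x' or 'y')."""
    if axis not in ("x", "y"):
        raise ArgumentError(f"axis must be 'x' or 'y', got {axis!r}")
    vals = _xy(track, keypoint_id)[0 if axis == "x" else 1]
    name = name or f"{axis}_{keypoint_id}"
    return _series(track, vals, name,
                   {"op": f"position_{axis}", "ids": [keypoint_id], "name": name})


def speed_series(
    track: TrackSeries, keypoint_id: int, name: str | None = None
) -> FeatureSeries:
    """Instantaneous speed in px/s by backward difference.

    At frame t ≥ 1 the value is the Euclidean displacement from the previous
    retained frame divided by the elapsed time; frame 0 is missing.  A
    missing coordinate at either end of the difference yields missing.
    """
    x, y = _xy(track, keypoint_id)
    frames = track.frames
    if len(frames) < 2:
        raise DegenerateInputError("speed needs at least 2 frames")
    dt = np.diff(frames) / track.fps
    disp = np.hypot(np.diff(x), np.diff(y))
    vals = np.concatenate([[np.nan], disp / dt])
    name = name or f"speed_{keypoint_id}"
    return _series(track, vals, name,
                   {"op": "speed", "ids": [keypoint_id], "name": name})


def distance_series(
    track: TrackSeries, id_a: int, id_b: int, name: str | None = None
) -> FeatureSeries:
    """Per-frame Euclidean distance between two keypoints (px)."""
    xa, ya = _xy(track, id_a)
    xb, yb = _xy(track, id_b)
    vals = np.hypot(xb - xa, yb - ya)
    name = name or f"dist_{id_a}_{id_b}"
    return _series(track, vals, name,
                   {"op": "distance", "ids": [id_a, id_b], "name": name})


def _vectors(track: TrackSeries, id_origin: int, id_a: int, id_b: int):
    xo, yo = _xy(track, id_origin)
    xa, ya = _xy(track, id_a)
    xb, yb = _xy(track, id_b)
    return xa - xo, ya - yo, xb - xo, yb - yo


def dot_product_series(
    track: TrackSeries, id_origin: int, id_a: int, id_b: int,
    name: str | None = None,
) -> FeatureSeries:
    """(a−o)·(b−o) per frame, in px²."""
    ux, uy, vx, vy = _vectors(track, id_origin, id_a, id_b)
    vals = ux * vx + uy * vy
    name = name or f"dot_{id_origin}_{id_a}_{id_b}"
    return _series(track, vals, name,
                   {"op": "dot_product", "ids": [id_origin, id_a, id_b],
                    "name": name})


def cross_product_series(
    track: TrackSeries, id_origin: int, id_a: int, id_b: int,
    name: str | None = None,
) -> FeatureSeries:
    """Scalar 2-D cross product (a−o)×(b−o) = uₓv_y − u_yvₓ per frame (px²).

    Evaluated on raw image coordinates (y-down), so the sign follows a
    left-handed convention: positive when ``b−o`` lies clockwise of ``a−o``
    on screen.  Coincident keypoints give 0, not an error.
    """
    ux, uy, vx, vy = _vectors(track, id_origin, id_a, id_b)
    vals = ux * vy - uy * vx
    name = name or f"cross_{id_origin}_{id_a}_{id_b}"
    return _series(track, vals, name,
                   {"op": "cross_product", "ids": [id_origin, id_a, id_b],
                    "name": name})


_OP_FUNCS = {
    "position_x": lambda t, ids, name: position_series(t, ids[0], "x", name),
    "position_y": lambda t, ids, name: position_series(t, ids[0], "y", name),
    "speed": lambda t, ids, name: speed_series(t, ids[0], name),
    "distance": lambda t, ids, name: distance_series(t, ids[0], ids[1], name),
    "dot_product": lambda t, ids, name: dot_product_series(t, *ids, name=name),
    "cross_product": lambda t, ids, name: cross_product_series(t, *ids, name=name),
}


def apply_recipe(track: TrackSeries, recipe: FeatureRecipe) -> FeatureSeries:
    """Evaluate every spec of a recipe; one output column per spec, in order.

    An empty recipe yields a series with the track's frame index and zero
    feature columns.
    """
    frames = pd.Index(track.frames, name="frame")
    out = pd.DataFrame(index=frames)
    prov = []
    for spec in recipe.specs:
        try:
            fs = _OP_FUNCS[spec.op](track, spec.ids, spec.name)
        except RecipeError:
            raise
        except (KeyError, ArgumentError) as exc:
            raise RecipeError(
                f"spec '{spec.name}' ({spec.op} on ids {list(spec.ids)}): {exc}"
            ) from exc
        out[spec.name] = fs.data[spec.name]
        prov.extend(fs.provenance)
    return FeatureSeries(out, fps=track.fps, provenance=tuple(prov))


# ---------------------------------------------------------------------------
# dwell-density map
# ---------------------------------------------------------------------------

@dataclass
class DwellMap:
    """Gaussian-KDE dwell density of one keypoint over the image plane.

    ``density[i, j]`` is the density at ``(x_centers[j], y_centers[i])``;
    the bin-weighted discrete sum approximates 1.
    """

    density: np.ndarray
    x_centers: np.ndarray
    y_centers: np.ndarray
    bandwidth: tuple[float, float]

    @property
    def bin_area(self) -> float:
        dx = self.x_centers[1] - self.x_centers[0] if len(self.x_centers) > 1 else 1.0
        dy = self.y_centers[1] - self.y_centers[0] if len(self.y_centers) > 1 else 1.0
        return float(dx * dy)


def _silverman(values: np.ndarray) -> float:
    n = len(values)
    sd = float(np.std(values))
    if sd == 0.0:
        return 1.0
    return 1.06 * sd * n ** (-1 / 5)


def kde_dwell(
    track: TrackSeries,
    keypoint_id: int,
    grid: tuple[int, int] = (64, 48),
    bandwidth: float | tuple[float, float] | None = None,
    extent: tuple[float, float, float, float] | None = None,
) -> DwellMap:
    """Dwell-density map of one keypoint: where it stayed, and for how long.

    A Gaussian product kernel is placed on every non-missing observation and
    the mixture is evaluated at the centers of a ``grid = (width_bins,
    height_bins)`` raster.  Darker (higher-density) regions correspond to
    locations where the keypoint dwelt longer.

    ``bandwidth`` is in px, one value per axis (a scalar is used for both);
    the default is Silverman's rule computed per axis.  ``extent`` is
    ``(xmin, xmax, ymin, ymax)``; by default the frame size when known, else
    the data bounding box padded by 4 bandwidths.
    """
    c = track.coords(keypoint_id)
    ok = c[["x", "y"]].notna().all(axis=1)
    pts = c.loc[ok, ["x", "y"]].to_numpy()
    if len(pts) < 2:
        raise DegenerateInputError(
            f"kde_dwell needs >= 2 non-missing observations, got {len(pts)}"
        )
    if bandwidth is None:
        hx, hy = _silverman(pts[:, 0]), _silverman(pts[:, 1])
    elif np.isscalar(bandwidth):
        hx = hy = float(bandwidth)
    else:
        hx, hy = map(float, bandwidth)
    if hx <= 0 or hy <= 0:
        raise ArgumentError(f"bandwidth must be > 0, got ({hx}, {hy})")

    if extent is None:
        if track.frame_size is not None:
            extent = (0.0, float(track.frame_size[0]), 0.0, float(track.frame_size[1]))
        else:
            extent = (
                pts[:, 0].min() - 4 * hx, pts[:, 0].max() + 4 * hx,
                pts[:, 1].min() - 4 * hy, pts[:, 1].max() + 4 * hy,
            )
    wbins, hbins = grid
    xe = np.linspace(extent[0], extent[1], wbins + 1)
    ye = np.linspace(extent[2], extent[3], hbins + 1)
    xc = (xe[:-1] + xe[1:]) / 2
    yc = (ye[:-1] + ye[1:]) / 2

    # separable product kernel: density = Gy^T Gx / n
    gx = np.exp(-0.5 * ((xc[None, :] - pts[:, 0, None]) / hx) ** 2)
    gx /= hx * np.sqrt(2 * np.pi)
    gy = np.exp(-0.5 * ((yc[None, :] - pts[:, 1, None]) / hy) ** 2)
    gy /= hy * np.sqrt(2 * np.pi)
    density = gy.T @ gx / len(pts)
    return DwellMap(density=density, x_centers=xc, y_centers=yc, bandwidth=(hx, hy))
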