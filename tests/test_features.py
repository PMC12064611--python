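"""Kinematic feature operations against independent geometric oracles."""

import numpy as np
import pytest
from scipy.stats import norm

from fbbc.errors import ArgumentError, DegenerateInputError, NotFoundError, RecipeError
from fbbc.features import (
    DESK_TASK,
    RIGHT_ARM_CROSS4,
    FeatureRecipe,
    FeatureSpec,
    apply_recipe,
    cross_product_series,
    distance_series,
    dot_product_series,
    get_preset,
    kde_dwell,
    position_series,
    speed_series,
)
from fbbc.synth import desk_task_spec, simulate

from conftest import make_track, random_track


def three_point_track(o, a, b, n_frames=1, fps=10.0):
    return make_track({0: [o] * n_frames, 1: [a] * n_frames, 2: [b] * n_frames},
                      fps=fps)


# ---------------------------------------------------------------------------
# positions and speed
# ---------------------------------------------------------------------------

def test_position_series_extracts_stored_coordinates():
    track = make_track({7: [(3.0, 4.0)] * 10})
    np.testing.assert_array_equal(
        position_series(track, 7, "x").data["x_7"], np.full(10, 3.0))
    np.testing.assert_array_equal(
        position_series(track, 7, "y").data["y_7"], np.full(10, 4.0))


def test_position_series_matches_lookup_on_random_track(rng):
    track = random_track(rng, n_frames=30, keypoints=(0, 1), missing_frac=0.2)
    got = position_series(track, 1, "x").data["x_1"].to_numpy()
    expected = track.coords(1)["x"].to_numpy()
    np.testing.assert_array_equal(got, expected)


def test_position_series_unknown_keypoint_or_axis():
    track = make_track({0: [(1, 1)]})
    with pytest.raises(NotFoundError):
        position_series(track, 9, "x")
    with pytest.raises(ArgumentError):
        position_series(track, 0, "z")


def test_speed_stationary_keypoint_is_zero():
    track = make_track({0: [(5.0, 5.0)] * 6}, fps=10.0)
    vals = speed_series(track, 0).data["speed_0"].to_numpy()
    assert np.isnan(vals[0])
    np.testing.assert_array_equal(vals[1:], 0.0)


def test_speed_constant_velocity_is_displacement_times_fps():
    # +2 px in x per frame at 10 fps -> 20 px/s after frame 0
    track = make_track({0: [(2.0 * f, 0.0) for f in range(8)]}, fps=10.0)
    vals = speed_series(track, 0).data["speed_0"].to_numpy()
    np.testing.assert_allclose(vals[1:], 20.0)


def test_speed_matches_brute_force_on_random_walk(rng):
    track = random_track(rng, n_frames=50, keypoints=(0,), fps=29.97)
    got = speed_series(track, 0).data["speed_0"].to_numpy()
    c = track.coords(0)
    x, y = c["x"].to_numpy(), c["y"].to_numpy()
    for t in range(1, 50):  # independent per-frame oracle
        expected = np.hypot(x[t] - x[t - 1], y[t] - y[t - 1]) * 29.97
        assert got[t] == pytest.approx(expected, rel=1e-12)


def test_speed_propagates_missing_to_both_neighbors():
    track = make_track({0: [(0, 0), (np.nan, np.nan), (2, 2), (3, 3)]})
    vals = speed_series(track, 0).data["speed_0"].to_numpy()
    assert np.isnan(vals[0]) and np.isnan(vals[1]) and np.isnan(vals[2])
    assert np.isfinite(vals[3])


def test_speed_single_frame_is_degenerate():
    with pytest.raises(DegenerateInputError):
        speed_series(make_track({0: [(0, 0)]}), 0)


# ---------------------------------------------------------------------------
# distance / dot / cross
# ---------------------------------------------------------------------------

def test_distance_examples():
    track = make_track({0: [(0.0, 0.0)], 1: [(3.0, 4.0)]})
    assert distance_series(track, 0, 1).data.iloc[0, 0] == 5.0
    assert distance_series(track, 0, 0).data.iloc[0, 0] == 0.0


def test_dot_product_examples():
    t = three_point_track((0, 0), (1, 0), (0, 1))
    assert dot_product_series(t, 0, 1, 2).data.iloc[0, 0] == 0.0
    t = three_point_track((0, 0), (2, 0), (3, 0))
    assert dot_product_series(t, 0, 1, 2).data.iloc[0, 0] == 6.0


def test_cross_product_examples():
    collinear = three_point_track((0, 0), (1, 1), (2, 2))
    assert cross_product_series(collinear, 0, 1, 2).data.iloc[0, 0] == 0.0
    unit = three_point_track((0, 0), (1, 0), (0, 1))
    assert cross_product_series(unit, 0, 1, 2).data.iloc[0, 0] == 1.0


def test_cross_matches_shoelace_oracle_on_1000_random_triples(rng):
    pts = rng.uniform(-500, 500, size=(1000, 3, 2))
    track = make_track({
        0: [tuple(p) for p in pts[:, 0]],
        1: [tuple(p) for p in pts[:, 1]],
        2: [tuple(p) for p in pts[:, 2]],
    })
    got = cross_product_series(track, 0, 1, 2).data.iloc[:, 0].to_numpy()
    # shoelace determinant: twice the signed triangle area
    o, a, b = pts[:, 0], pts[:, 1], pts[:, 2]
    shoelace = (
        o[:, 0] * (a[:, 1] - b[:, 1])
        + a[:, 0] * (b[:, 1] - o[:, 1])
        + b[:, 0] * (o[:, 1] - a[:, 1])
    )
    np.testing.assert_allclose(got, shoelace, rtol=1e-9)


def test_dot_and_distance_match_direct_formula_oracle(rng):
    pts = rng.uniform(-100, 100, size=(200, 3, 2))
    track = make_track({
        0: [tuple(p) for p in pts[:, 0]],
        1: [tuple(p) for p in pts[:, 1]],
        2: [tuple(p) for p in pts[:, 2]],
    })
    u = pts[:, 1] - pts[:, 0]
    v = pts[:, 2] - pts[:, 0]
    np.testing.assert_allclose(
        dot_product_series(track, 0, 1, 2).data.iloc[:, 0],
        u[:, 0] * v[:, 0] + u[:, 1] * v[:, 1], rtol=1e-12)
    np.testing.assert_allclose(
        distance_series(track, 0, 1).data.iloc[:, 0],
        np.sqrt(((pts[:, 1] - pts[:, 0]) ** 2).sum(axis=1)), rtol=1e-12)


def test_cross_antisymmetry_and_translation_invariance(rng):
    pts = rng.uniform(-100, 100, size=(300, 3, 2))
    offset = rng.uniform(-50, 50, size=2)
    base = make_track({i: [tuple(p) for p in pts[:, i]] for i in range(3)})
    shifted = make_track({i: [tuple(p + offset) for p in pts[:, i]] for i in range(3)})
    c_ab = cross_product_series(base, 0, 1, 2).data.iloc[:, 0].to_numpy()
    c_ba = cross_product_series(base, 0, 2, 1).data.iloc[:, 0].to_numpy()
    np.testing.assert_allclose(c_ab, -c_ba, rtol=1e-12)
    for fn, args in [(cross_product_series, (0, 1, 2)),
                     (dot_product_series, (0, 1, 2)),
                     (distance_series, (0, 1))]:
        np.testing.assert_allclose(
            fn(shifted, *args).data.iloc[:, 0],
            fn(base, *args).data.iloc[:, 0], rtol=1e-9)


def test_lagrange_identity_cross_sq_plus_dot_sq(rng):
    pts = rng.uniform(-10, 10, size=(200, 3, 2))
    track = make_track({i: [tuple(p) for p in pts[:, i]] for i in range(3)})
    cross = cross_product_series(track, 0, 1, 2).data.iloc[:, 0].to_numpy()
    dot = dot_product_series(track, 0, 1, 2).data.iloc[:, 0].to_numpy()
    u = pts[:, 1] - pts[:, 0]
    v = pts[:, 2] - pts[:, 0]
    lhs = cross ** 2 + dot ** 2
    rhs = (u ** 2).sum(axis=1) * (v ** 2).sum(axis=1)
    np.testing.assert_allclose(lhs, rhs, rtol=1e-9)


def test_missing_coordinate_propagates_to_every_feature():
    track = make_track({
        0: [(0.0, 0.0), (np.nan, 1.0)],
        1: [(1.0, 0.0), (2.0, 2.0)],
        2: [(0.0, 1.0), (3.0, 3.0)],
    })
    for fs in (distance_series(track, 0, 1),
               dot_product_series(track, 0, 1, 2),
               cross_product_series(track, 0, 1, 2)):
        vals = fs.data.iloc[:, 0].to_numpy()
        assert np.isfinite(vals[0]) and np.isnan(vals[1])


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------

def test_right_arm_preset_yields_exactly_four_cross_columns():
    track, _ = simulate(desk_task_spec(seed=0, duration_s=2.0))
    feats = apply_recipe(track, RIGHT_ARM_CROSS4)
    assert len(feats.columns) == 4
    assert all(p["op"] == "cross_product" for p in feats.provenance)


def test_desk_task_recipe_first_column_equals_standalone_neck_x():
    track, _ = simulate(desk_task_spec(seed=1, duration_s=2.0))
    feats = apply_recipe(track, DESK_TASK)
    assert len(feats.columns) == 5
    standalone = position_series(track, 18, "x", name="neck_x")
    np.testing.assert_array_equal(feats.data["neck_x"], standalone.data["neck_x"])
    # remaining columns equal their standalone evaluation too
    for spec in RIGHT_ARM_CROSS4.specs:
        alone = cross_product_series(track, *spec.ids, name=spec.name)
        np.testing.assert_array_equal(feats.data[spec.name], alone.data[spec.name])


def test_empty_recipe_keeps_frame_index_only():
    track = make_track({0: [(1, 1), (2, 2)]})
    feats = apply_recipe(track, FeatureRecipe(()))
    assert feats.columns == [] and len(feats) == 2


def test_recipe_validation_errors():
    with pytest.raises(RecipeError):  # arity mismatch
        FeatureSpec("distance", (1,), "d")
    with pytest.raises(RecipeError):  # duplicate names
        FeatureRecipe((FeatureSpec("position_x", (0,), "a"),
                       FeatureSpec("position_y", (0,), "a")))
    track = make_track({0: [(1, 1)]})
    with pytest.raises(RecipeError, match="bad_spec"):  # unknown id, spec named
        apply_recipe(track, FeatureRecipe(
            (FeatureSpec("position_x", (99,), "bad_spec"),)))
    with pytest.raises(KeyError):
        get_preset("no_such_preset")


# ---------------------------------------------------------------------------
# dwell-density map
# ---------------------------------------------------------------------------

def test_kde_dwell_peak_at_single_location():
    track = make_track({0: [(50.0, 30.0)] * 20}, frame_size=(100, 60))
    dm = kde_dwell(track, 0, grid=(20, 12), bandwidth=5.0)
    iy, ix = np.unravel_index(np.argmax(dm.density), dm.density.shape)
    assert abs(dm.x_centers[ix] - 50.0) <= 5.0
    assert abs(dm.y_centers[iy] - 30.0) <= 5.0
    assert (dm.density >= 0).all()


def test_kde_dwell_integrates_to_one(rng):
    xy = rng.normal([100, 80], 15, size=(200, 2))
    track = make_track({0: [tuple(p) for p in xy]})
    dm = kde_dwell(track, 0, grid=(120, 120), bandwidth=6.0)  # extent = data +/- 4h
    total = dm.density.sum() * dm.bin_area
    assert total == pytest.approx(1.0, abs=0.02)


def test_kde_dwell_matches_direct_mixture_evaluation(rng):
    # two well-separated point masses, small bandwidth -> two local maxima
    pts = np.array([[20.0, 20.0]] * 10 + [[80.0, 70.0]] * 10)
    track = make_track({0: [tuple(p) for p in pts]})
    dm = kde_dwell(track, 0, grid=(50, 45), bandwidth=3.0,
                   extent=(0, 100, 0, 90))
    # independent oracle: per-point scipy normal pdfs, accumulated in a loop
    expected = np.zeros_like(dm.density)
    for px, py in pts:
        expected += np.outer(norm.pdf(dm.y_centers, py, 3.0),
                             norm.pdf(dm.x_centers, px, 3.0))
    expected /= len(pts)
    np.testing.assert_allclose(dm.density, expected, rtol=1e-9)
    iy1, ix1 = np.unravel_index(np.argmax(dm.density), dm.density.shape)
    masked = dm.density.copy()
    masked[max(0, iy1 - 5): iy1 + 6, max(0, ix1 - 5): ix1 + 6] = 0
    iy2, ix2 = np.unravel_index(np.argmax(masked), masked.shape)
    found = {(round(dm.x_centers[i]), round(dm.y_centers[j]))
             for i, j in [(ix1, iy1), (ix2, iy2)]}
    assert len(found) == 2


def test_kde_dwell_degenerate_inputs():
    track = make_track({0: [(np.nan, np.nan)] * 5})
    with pytest.raises(DegenerateInputError):
        kde_dwell(track, 0)
    ok = make_track({0: [(1.0, 1.0), (2.0, 2.0)]})
    with pytest.raises(ArgumentError):
        kde_dwell(ok, 0, bandwidth=-1.0)
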