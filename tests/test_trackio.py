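"""Track data model, native container round trips, and the DeepLabCut dialect."""

import numpy as np
import pandas as pd
import pytest

from fbbc.errors import ArgumentError, DialectError, FormatError, NotFoundError
from fbbc.schemes import HALPE26_UPPER_BODY, KeypointScheme
from fbbc.trackio import (
    FeatureSeries,
    TrackSeries,
    filter_confidence,
    read_dlc_keypoints,
    read_features,
    read_track,
    select_person,
    validate_track,
    write_dlc_keypoints,
    write_features,
    write_track,
    write_track_csv,
)

from conftest import make_features, make_track, random_track


# ---------------------------------------------------------------------------
# DeepLabCut dialect
# ---------------------------------------------------------------------------

def _write_dlc_fixture(path, scorer="tester", bodyparts=("nose", "tail"),
                       n_frames=3, likelihood=True, seed=0):
    """Independent fixture writer: builds the 3-level hierarchy with plain
    pandas, bypassing the package's own writer."""
    rng = np.random.default_rng(seed)
    coords = ["x", "y"] + (["likelihood"] if likelihood else [])
    cols = pd.MultiIndex.from_product(
        [[scorer], list(bodyparts), coords], names=["scorer", "bodyparts", "coords"]
    )
    values = rng.uniform(0, 100, size=(n_frames, len(cols)))
    df = pd.DataFrame(values, columns=cols)
    df.to_hdf(path, key="df_with_missing", mode="w")
    return df


def test_dlc_reader_recovers_written_values_exactly(tmp_path):
    path = tmp_path / "fixture.h5"
    written = _write_dlc_fixture(path, bodyparts=("nose", "tail"), n_frames=3)
    track = read_dlc_keypoints(path, fps=30.0)
    assert len(track) == 6  # 2 bodyparts x 3 frames
    for i, bp in enumerate(["nose", "tail"]):
        c = track.coords(i)
        np.testing.assert_array_equal(c["x"].to_numpy(),
                                      written[("tester", bp, "x")].to_numpy())
        np.testing.assert_array_equal(c["y"].to_numpy(),
                                      written[("tester", bp, "y")].to_numpy())
        np.testing.assert_array_equal(c["conf"].to_numpy(),
                                      written[("tester", bp, "likelihood")].to_numpy())
    assert track.attrs["bodypart_map"] == {"nose": 0, "tail": 1}


def test_dlc_reader_without_likelihood_marks_confidence_missing(tmp_path):
    path = tmp_path / "nolik.h5"
    _write_dlc_fixture(path, likelihood=False)
    track = read_dlc_keypoints(path, fps=30.0)
    assert track.data["conf"].isna().all()


def test_dlc_reader_rejects_wrong_hierarchy_depth(tmp_path):
    path = tmp_path / "twolevel.h5"
    cols = pd.MultiIndex.from_product([["nose", "tail"], ["x", "y"]])
    pd.DataFrame(np.zeros((3, 4)), columns=cols).to_hdf(path, key="d", mode="w")
    with pytest.raises(DialectError):
        read_dlc_keypoints(path, fps=30.0)


def test_dlc_reader_rejects_bad_fps_and_unreadable_file(tmp_path):
    path = tmp_path / "fixture.h5"
    _write_dlc_fixture(path)
    with pytest.raises(ArgumentError):
        read_dlc_keypoints(path, fps=0)
    garbage = tmp_path / "garbage.h5"
    garbage.write_text("not hdf5")
    with pytest.raises(FormatError):
        read_dlc_keypoints(garbage, fps=30.0)


def test_dlc_reader_uses_supplied_name_to_id_map(tmp_path):
    path = tmp_path / "named.h5"
    _write_dlc_fixture(path, bodyparts=("left_shoulder", "neck"))
    track = read_dlc_keypoints(
        path, fps=30.0, name_to_id={"left_shoulder": 5, "neck": 18}
    )
    assert set(track.keypoint_ids) == {5, 18}


def test_dlc_writer_and_reader_are_mutual_inverses(tmp_path, rng):
    track = random_track(rng, n_frames=10, keypoints=(5, 6, 18),
                         scheme=HALPE26_UPPER_BODY, missing_frac=0.2)
    path = tmp_path / "roundtrip.h5"
    write_dlc_keypoints(track, path)
    back = read_dlc_keypoints(
        path, fps=track.fps,
        name_to_id={HALPE26_UPPER_BODY.label_of(k): int(k)
                    for k in track.keypoint_ids},
        scheme=HALPE26_UPPER_BODY,
    )
    pd.testing.assert_frame_equal(back.data, track.data)


# ---------------------------------------------------------------------------
# native container
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(25))
def test_track_container_round_trip_is_exact(tmp_path, seed):
    rng = np.random.default_rng(seed)
    track = random_track(
        rng,
        n_frames=int(rng.integers(1, 30)),
        keypoints=tuple(rng.choice(20, size=rng.integers(1, 5), replace=False)),
        n_persons=int(rng.integers(1, 3)),
        missing_frac=float(rng.uniform(0, 0.5)),
        scheme=HALPE26_UPPER_BODY if seed % 2 else None,
    )
    path = tmp_path / "t.track"
    write_track(track, path)
    back = read_track(path)
    assert back.equals(track)
    # bit-exact coordinates including NaN placement
    pd.testing.assert_frame_equal(back.data, track.data)


def test_empty_track_round_trips_with_metadata(tmp_path):
    empty = TrackSeries(
        data=pd.DataFrame(columns=["frame", "person", "keypoint", "x", "y", "conf"]),
        fps=25.0, video_name="empty", frame_size=(640, 480),
    )
    path = tmp_path / "empty.track"
    write_track(empty, path)
    back = read_track(path)
    assert len(back) == 0
    assert back.fps == 25.0 and back.video_name == "empty"
    assert back.frame_size == (640, 480)


def test_missing_confidence_survives_round_trip_as_missing(tmp_path):
    track = make_track({0: [(1.0, 2.0), (3.0, 4.0)]}, conf=np.nan)
    path = tmp_path / "conf.track"
    write_track(track, path)
    back = read_track(path)
    assert back.data["conf"].isna().all()
    assert not (back.data["conf"] == 0).any()


def test_non_track_file_raises_format_error(tmp_path):
    path = tmp_path / "bogus.track"
    path.write_bytes(b"\x00" * 32)
    with pytest.raises(FormatError):
        read_track(path)


def test_track_csv_mirror_has_documented_columns(tmp_path):
    track = make_track({0: [(1, 2), (3, 4)]}, fps=10.0)
    path = tmp_path / "t.csv"
    write_track_csv(track, path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["frame", "time_ms", "person", "keypoint",
                                "x", "y", "conf"]
    np.testing.assert_allclose(df["time_ms"], [0.0, 100.0])


def test_feature_container_round_trip(tmp_path):
    fs = make_features({"a": [1.0, np.nan, 3.0], "b": [0.5, 0.6, 0.7]}, fps=29.97)
    fs = fs.with_provenance({"op": "test"})
    path = tmp_path / "f.feat"
    write_features(fs, path)
    back = read_features(path)
    assert back.equals(fs)
    assert back.provenance == fs.provenance


# ---------------------------------------------------------------------------
# person selection / confidence filter / validation
# ---------------------------------------------------------------------------

def test_select_person_identity_on_single_person(rng):
    track = random_track(rng, n_persons=1)
    assert select_person(track, 0).equals(track)


def test_select_person_partitions_rows(rng):
    track = random_track(rng, n_frames=15, n_persons=3)
    parts = [select_person(track, p).data for p in track.persons]
    recombined = TrackSeries(pd.concat(parts), fps=track.fps,
                             video_name=track.video_name)
    pd.testing.assert_frame_equal(recombined.data, track.data)
    assert len(parts[0]) == len(track) // 3


def test_select_person_absent_id_lists_available(rng):
    track = random_track(rng, n_persons=2)
    with pytest.raises(NotFoundError, match=r"\[0, 1\]"):
        select_person(track, 7)


def test_filter_confidence_marks_low_conf_coordinates_missing():
    track = make_track({0: [(1, 1), (2, 2), (3, 3)]})
    track.data.loc[:, "conf"] = [0.9, 0.1, 0.5]
    filtered = filter_confidence(track, 0.5)
    assert filtered.data[["x", "y"]].isna().all(axis=1).tolist() == [
        False, True, False]
    # original unchanged (lossless ingest)
    assert not track.data[["x", "y"]].isna().any().any()


def test_validate_track_reports_each_violation(halpe_scheme):
    good = make_track({5: [(1, 2)], 6: [(3, 4)]}, scheme=halpe_scheme)
    assert validate_track(good).ok

    outside = make_track({99: [(1, 2)]})
    report = validate_track(outside, scheme=halpe_scheme)
    assert len(report.violations) == 1
    assert "99" in report.violations[0] and "scheme" in report.violations[0]

    dup = pd.DataFrame(
        [(0, 0, 5, 1.0, 2.0, 1.0), (0, 0, 5, 9.0, 9.0, 1.0)],
        columns=["frame", "person", "keypoint", "x", "y", "conf"],
    )
    report = validate_track(TrackSeries(dup, fps=10.0))
    assert any("duplicate" in v for v in report.violations)


def test_track_constructor_rejects_bad_fps():
    with pytest.raises(ArgumentError):
        make_track({0: [(1, 2)]}, fps=0)


def test_feature_series_rejects_duplicate_or_unsorted_frames():
    with pytest.raises(ArgumentError):
        make_features({"a": [1.0, 2.0]}, frames=[3, 1])
    with pytest.raises(ArgumentError):
        make_features({"a": [1.0, 2.0]}, frames=[2, 2])


def test_timestamps_follow_frame_over_fps():
    track = make_track({0: [(0, 0)] * 4}, fps=29.97)
    np.testing.assert_allclose(
        track.timestamps_ms(), np.arange(4) / 29.97 * 1000.0
    )
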