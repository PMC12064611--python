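import numpy as np
import pandas as pd
import pytest

from fbbc.schemes import HALPE26_UPPER_BODY, KeypointScheme
from fbbc.trackio import FeatureSeries, TrackSeries


def make_track(points, fps=10.0, scheme=None, person=0, conf=1.0, **meta):
    """Build a single-person track from {keypoint_id: [(x, y), ...]}.

    All keypoints must list the same number of frames; NaN coordinates mark
    missing observations.
    """
    rows = []
    for kid, xy in points.items():
        for f, (x, y) in enumerate(xy):
            rows.append((f, person, kid, x, y, conf))
    df = pd.DataFrame(rows, columns=["frame", "person", "keypoint", "x", "y", "conf"])
    return TrackSeries(data=df, fps=fps, scheme=scheme, **meta)


def random_track(rng, n_frames=20, keypoints=(0, 1, 2), n_persons=1,
                 missing_frac=0.0, fps=30.0, scheme=None):
    """A random-walk track, optionally with NaN-marked missing coordinates."""
    rows = []
    for p in range(n_persons):
        for kid in keypoints:
            xy = np.cumsum(rng.normal(0, 5, size=(n_frames, 2)), axis=0) + 100
            conf = rng.uniform(0, 1, n_frames)
            if missing_frac:
                miss = rng.random(n_frames) < missing_frac
                xy[miss] = np.nan
            for f in range(n_frames):
                rows.append((f, p, kid, xy[f, 0], xy[f, 1], conf[f]))
    df = pd.DataFrame(rows, columns=["frame", "person", "keypoint", "x", "y", "conf"])
    return TrackSeries(data=df, fps=fps, scheme=scheme, video_name="random")


def make_features(columns, fps=10.0, frames=None):
    """Build a FeatureSeries from {name: values}."""
    ncol = {k: np.asarray(v, dtype=float) for k, v in columns.items()}
    n = len(next(iter(ncol.values())))
    idx = pd.Index(frames if frames is not None else range(n), name="frame")
    return FeatureSeries(pd.DataFrame(ncol, index=idx), fps=fps)


@pytest.fixture
def rng():
    return np.random.default_rng(20251002)


@pytest.fixture
def halpe_scheme():
    return HALPE26_UPPER_BODY


@pytest.fixture
def tiny_scheme():
    return KeypointScheme("tiny", ((0, "a"), (1, "b"), (2, "c")))
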