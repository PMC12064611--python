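"""Agreement metrics between a coded timeline and a ground-truth ethogram.

Cluster codes are arbitrary names, so comparison first finds the best
one-to-one mapping between predicted codes and true regimes (maximum-overlap
assignment), then scores per-frame agreement.  Frames just after a regime
change are conventionally excluded: with thinned embeddings the hold-forward
rule cannot resolve a change until the next retained frame, so those frames
carry no information about clustering quality.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .coding import NONE_CODE, BehaviorTimeline

__all__ = ["transition_mask", "best_code_mapping", "timeline_agreement"]


def transition_mask(labels: pd.Series, window: int) -> np.ndarray:
    """True for frames within ``window`` frames after a regime change.

    ``labels`` is the per-frame ground-truth regime series; the first frame
    is treated as a change (the hold-forward timeline starts uninformed).
    """
    vals = labels.to_numpy()
    change = np.r_[True, vals[1:] != vals[:-1]]
    mask = np.zeros(len(vals), dtype=bool)
    idx = np.flatnonzero(change)
    for i in idx:
        mask[i: i + window] = True
    return mask


def best_code_mapping(
    pred: np.ndarray, true: np.ndarray
) -> dict[str, str]:
    """Maximum-overlap one-to-one mapping from predicted codes to true regimes.

    Solved as a linear assignment on the contingency table; predicted codes
    left unmatched (when counts differ) map to nothing and score as
    disagreement.  The NONE filler code is never mapped.
    """
    pred_codes = sorted(set(pred) - {NONE_CODE})
    true_codes = sorted(set(true))
    table = np.zeros((len(pred_codes), len(true_codes)))
    pi = {c: i for i, c in enumerate(pred_codes)}
    ti = {c: i for i, c in enumerate(true_codes)}
    for p, t in zip(pred, true):
        if p != NONE_CODE:
            table[pi[p], ti[t]] += 1
    rows, cols = linear_sum_assignment(-table)
    return {pred_codes[r]: true_codes[c] for r, c in zip(rows, cols)}


def timeline_agreement(
    timeline: BehaviorTimeline,
    truth: pd.Series,
    exclude_window: int = 0,
) -> float:
    """Fraction of (non-excluded) frames where the mapped code matches truth.

    ``truth`` must cover the timeline's frames.  Frames within
    ``exclude_window`` frames after a ground-truth regime change are
    excluded; NONE-coded frames count as disagreement.
    """
    truth = truth.reindex(timeline.frames)
    if truth.isna().any():
        raise ValueError("ground truth does not cover the timeline's frames")
    pred = timeline.codes
    true = truth.to_numpy()
    keep = ~transition_mask(truth, exclude_window) if exclude_window else np.ones(
        len(true), dtype=bool
    )
    mapping = best_code_mapping(pred[keep], true[keep])
    mapped = np.array([mapping.get(p, "__unmatched__") for p in pred])
    return float(np.mean(mapped[keep] == true[keep]))
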