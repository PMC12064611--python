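"""Import DeepLabCut-format keypoints and map where a keypoint dwelt.

Writes a small DeepLabCut-dialect HDF5 file (as a pose-estimation run
would), reads it back with an explicit bodypart -> keypoint-id mapping, and
computes a kernel-density dwell map of the right hand: high density marks
image locations where the keypoint stayed longest.
"""

import tempfile
from pathlib import Path

import numpy as np

from fbbc import (
    HALPE26_UPPER_BODY, desk_task_spec, kde_dwell, read_dlc_keypoints,
    simulate, write_dlc_keypoints,
)

track, _ = simulate(desk_task_spec(seed=5, duration_s=30.0))
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "video_DLC.h5"
    write_dlc_keypoints(track, path)
    name_to_id = {HALPE26_UPPER_BODY.label_of(k): int(k)
                  for k in HALPE26_UPPER_BODY.ids}
    # fps is caller-supplied: the DLC dialect does not store it
    imported = read_dlc_keypoints(path, fps=29.97, name_to_id=name_to_id,
                                  scheme=HALPE26_UPPER_BODY)
print(f"imported {len(imported)} rows, keypoints "
      f"{imported.keypoint_ids.tolist()}")

dm = kde_dwell(imported, keypoint_id=10, grid=(64, 48))  # right hand
total = dm.density.sum() * dm.bin_area
iy, ix = np.unravel_index(np.argmax(dm.density), dm.density.shape)
print(f"dwell map {dm.density.shape[1]}x{dm.density.shape[0]} bins, "
      f"bandwidth ({dm.bandwidth[0]:.1f}, {dm.bandwidth[1]:.1f}) px")
print(f"discrete integral = {total:.3f} (a proper density integrates to ~1)")
print(f"densest location: ({dm.x_centers[ix]:.0f}, {dm.y_centers[iy]:.0f}) px "
      "— where the right hand spent the most time")
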