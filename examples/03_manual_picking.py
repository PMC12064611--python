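"""Replay a manual clustering session headlessly with pick commands.

Instead of clicking on a scatter plot, each pick names a location in
embedding space, a radius (in embedding units, not screen pixels), and the
cluster to assign. Later picks overwrite earlier ones, mirroring interactive
reassignment.
"""

import numpy as np

from fbbc import (
    ClusterAssignment, EmbedParams, apply_recipe, assign_by_pick,
    build_timeline, desk_task_spec, embed, minmax_normalize, simulate, thin,
)
from fbbc.features import DESK_TASK

track, truth = simulate(desk_task_spec(seed=3, duration_s=60.0))
thinned = thin(minmax_normalize(apply_recipe(track, DESK_TASK)), 5)
embedding = embed(thinned, EmbedParams(random_seed=3))

# find where each true regime landed (a user would see this as islands)
assignment = ClusterAssignment(
    clusters={i: name for i, name in enumerate(sorted(truth.unique()))})
for cid, name in assignment.clusters.items():
    member = truth.reindex(embedding.source_frames).to_numpy() == name
    center = embedding.points[member].mean(axis=0)
    assignment = assign_by_pick(embedding, assignment, pick=tuple(center),
                                picker_range=3.0, cluster_id=cid)
    print(f"picked ({center[0]:6.2f}, {center[1]:6.2f}) r=3.0 -> "
          f"{np.sum(member)} points in island, cluster '{name}'")

n_labeled = assignment.n_labeled
print(f"\nlabeled {n_labeled}/{len(embedding)} points with 5 picks "
      "(unpicked points stay unassigned and code as NONE in the timeline)")
timeline = build_timeline(assignment, embedding,
                          (0, int(track.frames.max())), fps=track.fps)
print("behavior codes in the timeline:", sorted(timeline.code_set()))
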