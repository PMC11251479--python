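"""Voxel-wise degree centrality: hub blocks versus the rest of the brain.

Degree centrality counts, for every gray-matter voxel, the connections
whose Pearson correlation with other voxels strictly exceeds r = 0.32;
the map is normalised by its mean. Averaged over subjects, the injected
hub blocks carry the highest degree in the depressed (PSD) group.
"""

import numpy as np

from psdconn import (CohortSpec, DCConfig, compute_dc, generate_cohort,
                     tissue_labels)
from psdconn.core import BoldSeries

spec = CohortSpec(rng_seed=2)
subjects, records, truth = generate_cohort(spec)
gm = tissue_labels(spec.grid_shape) == 1
hub_vox = np.concatenate([truth.blocks[b] for b in truth.hub_blocks])

hub_dc = {"HC": [], "Stroke": [], "PSD": []}
for s in subjects:
    data = s.bold.data if s.lesion_side != "right" else s.bold.data[::-1]
    lesion = None if s.lesion is None else (
        s.lesion if s.lesion_side != "right" else s.lesion[::-1])
    bold = BoldSeries(data=np.ascontiguousarray(data), tr_seconds=spec.tr_seconds)
    mask = gm if lesion is None else gm & ~lesion
    dc = compute_dc(bold, mask, DCConfig(dtype="float32"))
    hub_dc[s.group].append(dc.data.ravel()[hub_vox].mean())

print(f"mean normalised DC inside the hub blocks (n={len(hub_dc['HC'])}/group,"
      " map mean = 1 by construction):")
for group, vals in hub_dc.items():
    print(f"  {group:6s}: {np.mean(vals):5.2f} +- {np.std(vals):.2f}")
print("\n-> the hub elevation is injected only in the PSD group; the "
      "group-mean hub degree separates PSD from both comparison groups, "
      "which is exactly what the specificity conjunction later tests.")
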