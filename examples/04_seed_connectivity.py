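"""Seed-based functional connectivity with Fisher r-to-z maps.

The seed's mean time course is correlated with every gray-matter voxel
and the correlations are variance-stabilised with z = atanh(r). Voxels of
the seed's own network show high z; unrelated background voxels hover
near zero with standard error 1/sqrt(T-3).
"""

import numpy as np

from psdconn import (CohortSpec, SeedSpec, compute_seed_fc, generate_cohort,
                     tissue_labels)

spec = CohortSpec(rng_seed=3)
subjects, _, truth = generate_cohort(spec)
s = next(x for x in subjects if x.group == "PSD" and x.lesion_side != "right")
gm = tissue_labels(spec.grid_shape) == 1
mask = gm & ~s.lesion

hub = truth.hub_blocks[0]
seed = SeedSpec(f"hub{hub}", truth.blocks[hub], provenance="user")
fc = compute_seed_fc(s.bold, seed, mask)

own = fc.data.ravel()[truth.blocks[hub]].mean()
other = fc.data.ravel()[truth.blocks[truth.hub_blocks[1]]].mean()
bg = np.setdiff1d(np.flatnonzero(mask.ravel()),
                  np.concatenate(list(truth.blocks.values())))
print(f"seed = hub block {hub} ({len(seed.voxels)} voxels), "
      f"subject {s.subject_id} (PSD)")
print(f"mean FC-z within the seed's own block:   {own:.2f}")
print(f"mean FC-z in the other hub block:        {other:.2f}")
print(f"mean FC-z over background gray matter:   {fc.data.ravel()[bg].mean():.2f}"
      f"  (null se = {1/np.sqrt(s.bold.n_timepoints-3):.3f})")
print(f"capped voxels (|r| at the 1-1e-7 ceiling): {int(fc.extras['capped'].sum())}")
print("\n-> connectivity is high only where the generator injected shared "
      "signal; distinct networks stay near zero apart from the weak "
      "global component.")
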