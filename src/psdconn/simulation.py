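"""Replicate simulation studies over synthetic cohorts.

Operating-characteristic checks (sensitivity of the PSD-specificity
conjunction under an injected hub effect, its false-flag rate under the
null) need many independent cohorts. This module runs the per-cohort
workflow — generate, restore right-lesion subjects to the canonical
ipsilesional-left orientation, compute degree centrality, average it over
the ground-truth network blocks, and apply the three-group conjunction —
and tabulates verdicts against the injected truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cohort import CohortSpec, generate_cohort, tissue_labels
from .connectivity import DCConfig, compute_dc, extract_roi_mean
from .core import BoldSeries, SeedSpec
from .inference import detect_specific_rois
from .preprocess import flip_to_ipsilesional

__all__ = ["cohort_block_dc_means", "specificity_replicates"]


def cohort_block_dc_means(spec: CohortSpec, dc: DCConfig | None = None):
    """Per-subject mean DC over every ground-truth network block.

    Returns (roi_means, records, truth): ``roi_means`` has one row per
    subject (aligned with ``records``) and one ``block<i>`` column per
    network block. Right-lesion subjects are mirrored back to the
    canonical orientation first; each patient's lesion is removed from
    their gray-matter mask.
    """
    dc = dc or DCConfig(dtype="float32")
    subjects, records, truth = generate_cohort(spec)
    gm = tissue_labels(spec.grid_shape) == 1
    rois = [SeedSpec(f"block{b}", truth.blocks[b]) for b in sorted(truth.blocks)]
    rows = {}
    for s in subjects:
        data = s.bold.data
        lesion = s.lesion
        if s.lesion_side == "right":
            data = flip_to_ipsilesional(data, "right")
            lesion = flip_to_ipsilesional(lesion, "right")
        bold = BoldSeries(data=np.ascontiguousarray(data),
                          tr_seconds=spec.tr_seconds, affine=s.bold.affine)
        mask = gm if lesion is None else gm & ~lesion.astype(bool)
        dc_map = compute_dc(bold, mask, dc)
        rows[s.subject_id] = [extract_roi_mean(dc_map, r) for r in rois]
    roi_means = pd.DataFrame.from_dict(
        rows, orient="index", columns=[r.roi_id for r in rois])
    return roi_means.loc[records.subject_id], records, truth


def specificity_replicates(spec: CohortSpec, n_replicates: int, base_seed: int = 0,
                           alpha: float = 0.05, n_comparisons: int = 3,
                           dc: DCConfig | None = None) -> pd.DataFrame:
    """Specificity-conjunction verdicts over independent replicate cohorts.

    Each replicate regenerates the cohort with seed ``base_seed + rep``.
    Returns one row per (replicate, block) with columns replicate, roi_id,
    is_hub, verdict.
    """
    out = []
    for rep in range(n_replicates):
        rep_spec = dataclasses.replace(spec, rng_seed=base_seed + rep)
        roi_means, records, truth = cohort_block_dc_means(rep_spec, dc=dc)
        res = detect_specific_rois(roi_means, records.group.to_numpy(),
                                   alpha=alpha, n_comparisons=n_comparisons)
        hubs = {f"block{b}" for b in truth.hub_blocks}
        for _, row in res.table.iterrows():
            out.append({"replicate": rep, "roi_id": row.roi_id,
                        "is_hub": row.roi_id in hubs, "verdict": row.verdict})
    return pd.DataFrame(out)
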