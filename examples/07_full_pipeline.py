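"""The full pipeline in one call: simulate -> preprocess -> DC -> group
inference -> data-driven seeds -> seed FC -> specificity -> behavior.

Uses a well-powered demonstration cohort (64-voxel blocks, strong hub
effect, T=240) so every stage has material to work with at desk scale.
Equivalent shell command:
    psdconn run-all --seed 5 --out results/
"""

from psdconn import PipelineConfig, run_pipeline
from psdconn.cohort import CohortSpec, default_network_blocks
from psdconn.connectivity import DCConfig

config = PipelineConfig(
    synthetic=CohortSpec(
        network_blocks=default_network_blocks((16, 16, 12), block_extent=4),
        within_block_r=0.25, effect_delta_r=0.50, n_timepoints=240),
    rng_seed=5,
    dc=DCConfig(dtype="float32"),
)
result = run_pipeline(config)

kept = (result.qc.decision == "keep").sum()
print(f"QC: kept {kept}/{len(result.qc)} subjects")
print(f"DC ANOVA clusters (FDR q<0.05, k>20): "
      f"{result.dc_anova.table.extent.tolist()} voxels")
print(f"PSD-vs-Stroke clusters (p<0.05 within ANOVA mask): "
      f"{result.dc_pairwise.table.extent.tolist()} voxels")
print(f"data-driven seeds (PSD-specific DC): {[s.roi_id for s in result.seeds]}")
for seed_id, spec_res in result.fc_specificity.items():
    print(f"  seed {seed_id}: PSD-specific FC regions -> {spec_res.specific_rois}")
for scale, pred in result.predictions.items():
    print(f"{scale}: LOOCV rho={pred.performance.rho:+.3f} "
          f"p={pred.performance.p:.4f} (lambda={pred.chosen_lambda:g})")
print("\n-> the pipeline rediscovers the injected hub blocks as seeds, "
      "finds their PSD-specific connectivity, and predicts depression "
      "severity from it.")
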