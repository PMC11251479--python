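"""The three-group specificity conjunction on block-wise DC means.

An ROI is "PSD-specific" when the depressed group's mean is higher (or
lower) than both the nondepressed-stroke and control groups, with both
pairwise Welch tests surviving Bonferroni correction over the three
group contrasts. Run on one desk-scale cohort with the default injected
effect (delta r = 0.25), the two hub blocks - and only they - are flagged.
"""

from psdconn import CohortSpec, cohort_block_dc_means, detect_specific_rois
from psdconn import demographic_tests

spec = CohortSpec(effect_delta_r=0.25, rng_seed=4)
roi_means, records, truth = cohort_block_dc_means(spec)
result = detect_specific_rois(roi_means, records.group.to_numpy())

print("per-block verdicts (hub blocks:",
      [f"block{b}" for b in truth.hub_blocks], "):")
cols = ["roi_id", "mean_HC", "mean_Stroke", "mean_PSD",
        "p_psd_stroke", "p_psd_hc", "verdict"]
print(result.table[cols].round(4).to_string(index=False))

print("\ndemographic / clinical group tests on the same cohort:")
print(demographic_tests(records).round(4).to_string(index=False))
print("\n-> PHQ-9/HAMD/CES-D separate the groups strongly (as constructed); "
      "age and gender do not.")
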