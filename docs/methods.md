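# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `psdconn`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The analysis chain

The pipeline reproduces the standard hub-then-seed connectivity analysis
for three-group stroke cohorts, in this fixed order per subject: mirror
right-lesion volumes so the ipsilesional hemisphere is always the left
one → drop the first 10 volumes (scanner equilibration; configurable) →
motion QC → nuisance regression → hemodynamic-lag correction (patients
only) → band-pass filter. Degree centrality is computed on the
*unsmoothed* filtered series and its map smoothed afterwards at 6 mm
FWHM; seed FC uses spatially smoothed series. This asymmetry is
deliberate: smoothing before a thresholded voxel-wise correlation graph
inflates local degree, whereas FC maps benefit from the variance
reduction.

### Preprocessing conventions

- **Motion QC.** Exclusion iff max displacement > 3 mm, max rotation
  > 3°, or mean framewise displacement > 0.5. The thresholds are strict
  inequalities: a subject exactly at a limit is kept. FD follows the
  Power convention, `fd_t = Σ|Δtrans| + 50 mm · Σ|Δrot(rad)|`, `fd_0=0`.
- **Nuisance regression.** One OLS pass per voxel against an intercept,
  the 24-parameter motion expansion `[p, p(t−1), p², p(t−1)²]`, WM and
  CSF mean signals, and a linear ramp. Combining nuisance and detrending
  in a single design avoids the order-dependence of sequential
  residualisation. The global signal is intentionally retained.
  Rank-deficient designs fall back to the pseudoinverse with a warning;
  the residuals are unique regardless of which collinear column is
  dropped.
- **Lag correction.** For each voxel the integer lag in ±`max_lag_tr`
  (default 4 TR) maximising the truncated-overlap Pearson correlation
  between the shifted voxel series and a reference (the gray-matter mean
  by default; configurable because the choice is a genuine degree of
  freedom). Ties prefer the smaller |s|, then the negative shift.
  Correction shifts the series by −lag with edge-sample repetition.
  Zero-variance voxels get lag 0 and are flagged.
- **Band-pass.** An ideal DFT-mask filter retaining bins with frequency
  in [0.01, 0.08] Hz inclusive (the convention of the REST-family
  toolboxes). Bin-aligned components pass exactly; an empty band raises
  an error naming the smallest usable series length.
- **Enantiomorphic filling** mirrors lesioned voxels about the grid's
  central sagittal plane; a lesioned mirror voxel keeps its original
  value and logs a warning. No nonlinear symmetrisation is attempted.
- **Slice timing** exists as a registered no-op hook: synthetic volumes
  have no slice structure.

### Degree centrality

Binary degree with a one-sided threshold on signed r (r > 0.32 strictly;
negative correlations never contribute; the self-connection is
excluded), normalised by the in-mask mean. A weighted variant (sum of
supra-threshold r) is exposed as `DCConfig.binary=False`. Computation
streams over voxel blocks (default 1024) so memory stays O(V·block)
rather than O(V²); the streamed result equals a dense-matrix brute force
to 1e−10 (float64). A float32 mode exists for Monte-Carlo replicate
studies, trading ~1e−6 agreement for roughly double the throughput.
`bonferroni_r_threshold(T, V)` documents how a threshold like 0.32
arises from a Bonferroni-corrected pairwise test, but 0.32 stays the
pipeline constant.

### Group inference

Voxel-wise OLS of the subject maps on group indicators plus covariates
(age, binary-coded gender; NIHSS exactly for the PSD-vs-Stroke pairwise
model — design validation enforces this). The three-group statistic is
the partial F of the group factor with covariates retained in both
models. Voxels fitted to machine precision are assigned F (or t) = 0;
perfect group separation caps the statistic at 1e6 to keep maps finite.

Multiplicity control is Benjamini–Hochberg FDR over in-mask voxels
(q < 0.05) followed by a cluster-extent rule: connected components at
26-connectivity with strictly more than 20 voxels. Signed maps are
clustered separately by sign, so adjacent effects of opposite direction
are reported as distinct clusters — without this, a spatially global
negative difference can swallow a focal positive one. The pairwise
PSD-vs-Stroke map is thresholded inside the ANOVA-significant mask at
p < 0.05 uncorrected by default (the `fdr` mode is also supported and
recorded in the run manifest) — at realistic PSD sample sizes the
pairwise contrast rarely survives voxel-wise FDR, which is precisely why
the conjunction step below re-tests candidate ROIs.

The specificity conjunction runs Welch two-sample t-tests on per-subject
ROI means (unequal group sizes and variances are the norm here);
`psd_specific_up` requires the PSD mean above both other group means
with both PSD-involving p-values satisfying p·3 < 0.05. The Bonferroni
family defaults to the 3 pairwise tests per ROI (configurable), not the
ROI count.

Demographic tests follow the conventional gate: continuous three-group
variables go to one-way ANOVA if every group passes Shapiro–Wilk at
0.05, otherwise Kruskal–Wallis; patient-only continuous variables use
the Mann–Whitney U; categorical variables use the Pearson chi-square
without continuity correction (this convention reproduces the printed
worked-example p-values 0.756 and 0.582 exactly).

### Behavior

Spearman correlations use average ranks for ties, the t approximation
for n ≥ 10 and exact permutation below that; significance is
p < 0.05/3 across the three depression scales. Ridge-LOOCV standardises
features with training-fold statistics, leaves the intercept
unpenalised, and picks λ from a 17-point grid (10⁻³…10³, log-spaced) by
LOOCV MSE with ties to the smaller penalty. The default single-loop
variant (the λ chosen on the same folds that produce the reported
predictions) is optimistically biased; a nested variant exists and the
result records which mode ran. As λ→∞ the predictions collapse to
training-fold means, which rank-anticorrelate with the held-out targets
— a strongly negative reported rho is therefore the signature of
uninformative features, not a bug.

## The synthetic cohort generator

The generator defines the study conditions for every validation in this
repository. Each voxel is

    x_v(t) = √(ρ−ρ_g)·f_b(t−ℓ_v) + √ρ_g·g(t−ℓ_v) + √(1−ρ)·σ·ε_v(t)

with f_b the subject's block factor, g a global gray-matter signal,
ε white noise, all unit variance. Two same-block voxels correlate at
exactly ρ; two background gray-matter voxels at ρ_g; hub blocks in the
PSD group use ρ+Δ. Lags are applied as circular shifts of the shared
components, which preserves factor variance and makes recovery exactly
testable; σ=0 gives the noiseless cohorts used for exact lag-recovery
checks.

Design choices that shape the generator:

- **The global component (ρ_g = 0.08) exists so that time-shift lag
  estimation is well-posed.** With pure white block factors, a
  gray-matter-mean reference carries almost no signal any single voxel
  shares, and the estimated lags degenerate to noise — random per-voxel
  shifts that destroy the injected block structure in exactly the
  patients the correction is meant to help. A weak shared signal (the
  analysis deliberately retains the global signal, so one is present)
  anchors the estimates. It lives only in gray matter, so WM/CSF
  regression does not remove it.
- **Lags are block-constant** (one integer lag per network block per
  patient, uniform on ±2 TR by default): hemodynamic delay after stroke
  is spatially coherent, and a common shift leaves within-block
  correlations untouched — the quantity the downstream stages measure.
- **Lesions** are unilateral cuboids (20–60 voxels, P(left) = 0.55
  matching the cohort's printed L/R split) drawn in the canonical
  ipsilesional-left space, zeroed in the BOLD, and barred from network
  blocks: lesion-mask handling, not lesion physiology, is what the
  pipeline must respect. Right-side subjects are handed out mirrored, so
  the pipeline's flip restores every subject to one common orientation.
- **Behavior coupling.** Depression scores are linear in the subject's
  *realised* mean pairwise correlation within the hub blocks (slope 40
  PHQ-9 points per unit correlation, residual sd 1.5, per-subject
  coupling jitter sd 0.05), then clipped to each scale's range (PHQ-9
  0–27, HAMD 0–52, CES-D 0–60) — yielding a PSD-group PHQ-9 spread of
  about 8.2 ± 2.9, matching the printed cohort. Group baselines, age,
  gender, NIHSS, ADL, onset-day and lesion-size distributions follow the
  printed demographic table.
- **Desk scale.** Defaults are a 16×16×12 grid (3 mm voxels; z-planes 0
  and 1 serve as WM and CSF labels), T = 150 at TR = 2 s, n = 15/group,
  six 27-voxel blocks (three per hemisphere, hubs contralesional),
  within-block ρ = 0.30, Δ = 0.25 — a full pipeline run takes seconds,
  a 100-replicate operating-characteristic study a few minutes, on one
  CPU. Monte-Carlo suites shrink the grid further (10×10×8, T = 100)
  where only null behaviour is measured.
- **Determinism.** One root seed feeds a `SeedSequence` spawn per
  subject; identical spec + seed reproduce byte-identical cohorts, and
  identical pipeline configs reproduce byte-identical output files.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: hemodynamic response shapes and physiological
noise spectra (signals are white before filtering), scanner drift,
spatial autocorrelation of noise, realistic lesion geometry or
pathophysiology, slice structure, and registration error (all subjects
share one grid, so normalisation and segmentation are out of scope).
Operating characteristics measured here (sensitivity ≥ 0.8 at Δ = 0.25,
n = 15/group; false-flag rate at or below the Bonferroni level under the
null) are statements about this generative model, not about any real
cohort.

## Demonstration configuration

End-to-end demonstrations (the pipeline example, the acceptance script's
pipeline and prediction sections) use a deliberately well-powered
cohort: 64-voxel blocks, within-block ρ = 0.25, Δ = 0.50, T = 240. At
the desk-scale defaults the voxel-wise ANOVA+FDR gate is underpowered at
n = 15/group — the band-pass filter leaves roughly 40 effective degrees
of freedom, so a 27-voxel hub excess rarely clears voxel-level FDR —
which mirrors the real-world situation where pairwise PSD contrasts are
reported uncorrected. The conjunction's operating characteristics are
therefore validated directly on ROI means at the study conditions
(where power is ample), while the full voxel-wise chain is demonstrated
on the strong configuration.

## Known limitations

- Single-loop LOOCV reports optimistically biased performance by
  construction; use `nested=True` for honest estimates.
- The ideal DFT band-pass assumes approximate stationarity and has
  non-causal, rectangular frequency response (ringing in time).
- Lag estimation is integer-TR only; sub-TR delays alias to the nearest
  integer.
- The enantiomorphic fill assumes grid-level left–right symmetry.
- Cluster peaks break ties to the lowest flat index, which is
  deterministic but arbitrary.
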