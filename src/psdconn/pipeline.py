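"""End-to-end orchestration: simulate/load -> preprocess -> degree
centrality -> group inference -> seed selection -> seed FC -> specificity
-> brain-behavior correlation and prediction.

One :class:`PipelineConfig` drives every stage; the run writes a manifest
with the config hash and seed, and re-running an identical config on
identical inputs reproduces identical numerical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import connectivity as conn
from . import inference as inf
from . import preprocess as pre
from .cohort import (CohortSpec, SyntheticSubject, generate_cohort,
                     load_cohort, tissue_labels)
from .core import ScalarMap, SeedSpec, save_volume

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "PipelineResult"]

log = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1

_SCALES = ("PHQ9", "HAMD", "CESD")


@dataclass
class PipelineConfig:
    """All pipeline constants in one validated record."""

    schema_version: int = CONFIG_SCHEMA_VERSION
    input_dir: str | None = None          # read a written cohort ...
    synthetic: CohortSpec | None = None   # ... or simulate one
    out_dir: str | None = None            # None -> in-memory only

    drop_initial: int = 10
    max_disp_mm: float = 3.0
    max_rot_deg: float = 3.0
    max_mean_fd: float = 0.5
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    max_lag_tr: int = 4
    fwhm_mm: float = 6.0

    dc: conn.DCConfig = field(default_factory=conn.DCConfig)

    fdr_q: float = 0.05
    min_extent: int = 20
    connectivity: int = 26
    alpha: float = 0.05
    n_comparisons: int = 3
    pairwise_threshold: str = "uncorrected"  # or "fdr" (both are reported modes)

    lambda_grid: tuple = tuple(bhv.default_lambda_grid())
    n_behavior_tests: int = 3

    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "dc" in raw and isinstance(raw["dc"], dict):
            raw["dc"] = conn.DCConfig(**raw["dc"])
        if "synthetic" in raw and isinstance(raw["synthetic"], dict):
            raw["synthetic"] = CohortSpec(**raw["synthetic"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = {k: (list(v) if isinstance(v, tuple) else v)
                              for k, v in dataclasses.asdict(self.synthetic).items()
                              if k != "network_blocks"}
        d["lambda_grid"] = [float(x) for x in self.lambda_grid]
        d.pop("out_dir", None)
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems; an empty list means the config is runnable."""
    p: list[str] = []
    if config.schema_version != CONFIG_SCHEMA_VERSION:
        p.append(f"schema_version: expected {CONFIG_SCHEMA_VERSION}")
    if (config.input_dir is None) == (config.synthetic is None):
        p.append("inputs: exactly one of input_dir or synthetic must be set")
    if config.drop_initial < 0:
        p.append("drop_initial: must be >= 0")
    for name in ("max_disp_mm", "max_rot_deg", "max_mean_fd", "fwhm_mm"):
        if getattr(config, name) <= 0:
            p.append(f"{name}: must be positive")
    if not (0 < config.fdr_q < 1):
        p.append("fdr_q: must be in (0, 1)")
    if not (0 < config.alpha < 1):
        p.append("alpha: must be in (0, 1)")
    if config.min_extent < 0:
        p.append("min_extent: must be >= 0")
    if config.connectivity not in (6, 18, 26):
        p.append("connectivity: must be 6, 18 or 26")
    if config.n_comparisons < 1:
        p.append("n_comparisons: must be >= 1")
    if config.max_lag_tr < 1:
        p.append("max_lag_tr: must be >= 1")
    if not config.band_low_hz < config.band_high_hz:
        p.append("band: band_low_hz must be below band_high_hz")
    if config.pairwise_threshold not in ("uncorrected", "fdr"):
        p.append("pairwise_threshold: must be 'uncorrected' or 'fdr'")
    if any(l <= 0 for l in config.lambda_grid):
        p.append("lambda_grid: all penalties must be positive")
    try:
        config.dc.validate()
    except ValueError as e:
        p.append(f"dc: {e}")
    if config.synthetic is not None:
        try:
            config.synthetic.validate()
        except ValueError as e:
            p.append(f"synthetic: {e}")
        tr = config.synthetic.tr_seconds
        if config.band_high_hz >= 0.5 / tr:
            p.append("band: band_high_hz must be below the Nyquist frequency")
    return p


@dataclass
class PipelineResult:
    """In-memory outputs of one run (files are listed in ``manifest``)."""

    qc: pd.DataFrame
    demographics: pd.DataFrame
    group_mask: np.ndarray
    dc_anova: inf.ClusterTable
    dc_pairwise: inf.ClusterTable
    dc_specificity: inf.SpecificityResult | None
    seeds: list[SeedSpec]
    fc_specificity: dict[str, inf.SpecificityResult]
    behavior_correlations: pd.DataFrame
    predictions: dict[str, bhv.PredictionResult]
    manifest: dict


def _preprocess_subject(s: SyntheticSubject, config: PipelineConfig,
                        masks: dict[str, np.ndarray]) -> dict | None:
    """Flip, trim, QC, regress, lag-correct and filter one subject.

    Returns None when the subject fails motion QC.
    """
    lesion = s.lesion
    bold = s.bold
    if s.lesion_side == "right":
        bold = bold.with_data(pre.flip_to_ipsilesional(bold.data, "right"),
                              flipped=True)
        lesion = pre.flip_to_ipsilesional(lesion, "right")
    bold = pre.slice_timing(bold)
    bold = pre.drop_initial_volumes(bold, config.drop_initial)
    motion_params = s.motion.params[:, config.drop_initial:]
    fd = pre.compute_fd(motion_params)
    decision = pre.qc_exclude(
        type(s.motion)(params=motion_params, fd=fd),
        config.max_disp_mm, config.max_rot_deg, config.max_mean_fd)
    if not decision.keep:
        return {"decision": decision}

    gm = masks["gm"].copy()
    wm = masks["wm"]
    csf = masks["csf"]
    if lesion is not None:
        gm = gm & ~lesion.astype(bool)
    flat = bold.data.reshape(-1, bold.n_timepoints)
    wm_mean = flat[wm.ravel()].mean(axis=0)
    csf_mean = flat[csf.ravel()].mean(axis=0)
    ramp = np.arange(bold.n_timepoints, dtype=float)
    regressors = np.vstack([pre.build_friston24(motion_params),
                            wm_mean, csf_mean, ramp])
    bold = pre.nuisance_regress(bold, regressors)

    lag_map = None
    if s.group != "HC":
        reference = bold.data.reshape(-1, bold.n_timepoints)[gm.ravel()].mean(axis=0)
        lag_map, bold = pre.estimate_and_correct_lag(
            bold, reference, max_lag_tr=config.max_lag_tr, mask=gm)
    bold = pre.bandpass(bold, config.band_low_hz, config.band_high_hz)
    smoothed = bold.with_data(pre.smooth_gaussian(
        bold.data, bold.voxel_size_mm, config.fwhm_mm))
    return {"decision": decision, "bold": bold, "smoothed": smoothed,
            "gm": gm, "lesion": lesion, "lag_map": lag_map}


def _roi_means(maps: dict[str, ScalarMap], rois: list[SeedSpec],
               subject_ids: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {roi.roi_id: [conn.extract_roi_mean(maps[sid], roi) for sid in subject_ids]
         for roi in rois}, index=subject_ids)


def _infer_stage(maps: dict[str, ScalarMap], records: pd.DataFrame,
                 config: PipelineConfig, kind: str
                 ) -> tuple[inf.ClusterTable, inf.ClusterTable, list[SeedSpec],
                            inf.SpecificityResult | None]:
    """ANOVA -> FDR -> clusters -> pairwise PSD-Stroke -> specificity seeds."""
    ids = records["subject_id"].tolist()
    groups = records["group"].tolist()
    gender = (records["gender"] == "M").astype(float).to_numpy()
    design_f = inf.Design(subject_ids=ids, groups=groups,
                          age=records["age"].to_numpy(float), gender=gender,
                          contrast=("three_group_F",))
    stack = [maps[sid] for sid in ids]
    f_map, p_map, _ = inf.fit_voxelwise_glm(stack, design_f)
    sig = inf.fdr_bh(p_map, q=config.fdr_q)
    anova_clusters = inf.extract_clusters(sig, f_map, config.min_extent,
                                          config.connectivity)
    anova_mask = anova_clusters.labels > 0

    pair = records[records["group"].isin(["PSD", "Stroke"])]
    pids = pair["subject_id"].tolist()
    design_t = inf.Design(
        subject_ids=pids, groups=pair["group"].tolist(),
        age=pair["age"].to_numpy(float),
        gender=(pair["gender"] == "M").astype(float).to_numpy(),
        nihss=pair["NIHSS"].to_numpy(float),
        contrast=("pair_t", "PSD", "Stroke"))
    t_map, tp_map, _ = inf.fit_voxelwise_glm([maps[sid] for sid in pids], design_t)
    if config.pairwise_threshold == "fdr":
        pair_sig = inf.fdr_bh(tp_map, q=config.fdr_q, mask=anova_mask) \
            if anova_mask.any() else np.zeros_like(anova_mask)
    else:
        pair_sig = (tp_map.data < config.alpha) & anova_mask
    pair_clusters = inf.extract_clusters(pair_sig, t_map, config.min_extent,
                                         config.connectivity)
    log.info("%s stage: %d ANOVA clusters, %d pairwise clusters "
             "(q=%g, k>%d, pairwise=%s)", kind, len(anova_clusters),
             len(pair_clusters), config.fdr_q, config.min_extent,
             config.pairwise_threshold)
    rois = pair_clusters.to_seeds(provenance="dc_specificity")
    specificity = None
    seeds: list[SeedSpec] = []
    if rois:
        means = _roi_means(maps, rois, ids)
        specificity = inf.detect_specific_rois(
            means, groups, alpha=config.alpha, n_comparisons=config.n_comparisons)
        keep = set(specificity.specific_rois)
        seeds = [r for r in rois if r.roi_id in keep]
    return anova_clusters, pair_clusters, seeds, specificity


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and (optionally) write all outputs + manifest."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))

    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def _write_tsv(df: pd.DataFrame, name: str) -> None:
        if out:
            df.to_csv(out / name, sep="\t", index=False, float_format="%.10g")
            written.append(name)

    def _write_json(obj, name: str) -> None:
        if out:
            with open(out / name, "w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True, default=str)
            written.append(name)

    # ----- stage: inputs -------------------------------------------------
    try:
        if config.synthetic is not None:
            spec = dataclasses.replace(config.synthetic, rng_seed=config.rng_seed)
            subjects, records, _truth = generate_cohort(spec)
            tr = spec.tr_seconds
        else:
            subjects, records = load_cohort(config.input_dir)
            tr = subjects[0].bold.tr_seconds
    except Exception as e:
        raise RuntimeError(f"stage 'inputs' failed: {e}") from e

    grid = subjects[0].bold.grid_shape
    labels = tissue_labels(grid)
    masks = {"gm": labels == 1, "wm": labels == 2, "csf": labels == 3}

    demographics = inf.demographic_tests(records)
    _write_tsv(demographics, "demographics.tsv")

    # ----- stage: preprocess --------------------------------------------
    prepped: dict[str, dict] = {}
    qc_rows = []
    for s in subjects:
        try:
            res = _preprocess_subject(s, config, masks)
        except Exception as e:
            raise RuntimeError(f"stage 'preprocess' failed for {s.subject_id}: {e}") from e
        d = res["decision"]
        qc_rows.append({"subject_id": s.subject_id, "max_disp": d.max_disp_mm,
                        "max_rot_deg": d.max_rot_deg, "mean_fd": d.mean_fd,
                        "decision": "keep" if d.keep else f"exclude:{d.reason}"})
        if d.keep:
            prepped[s.subject_id] = res
    qc = pd.DataFrame(qc_rows)
    _write_tsv(qc, "qc.tsv")
    records = records[records["subject_id"].isin(prepped)].reset_index(drop=True)

    # ----- stage: group mask ---------------------------------------------
    lesions = [p["lesion"] for p in prepped.values() if p["lesion"] is not None]
    group_mask = pre.build_group_mask(
        [np.ones(grid, bool)] * len(prepped), masks["gm"], lesions)
    if out:
        save_volume(out / "group_mask.nii", group_mask.astype(np.uint8),
                    subjects[0].bold.affine, "group gray-matter mask")
        written.append("group_mask.nii")

    # ----- stage: degree centrality --------------------------------------
    ids = records["subject_id"].tolist()
    dc_maps: dict[str, ScalarMap] = {}
    for sid in ids:
        try:
            raw = conn.compute_dc(prepped[sid]["bold"], group_mask, config.dc)
        except Exception as e:
            raise RuntimeError(f"stage 'dc' failed for {sid}: {e}") from e
        smooth = pre.smooth_gaussian(raw.data, prepped[sid]["bold"].voxel_size_mm,
                                     config.fwhm_mm)
        dc_maps[sid] = ScalarMap(data=smooth, mask=group_mask, kind="dc",
                                 affine=raw.affine, extras=raw.extras)
        if out:
            name = f"dc_{sid}.nii"
            save_volume(out / name, dc_maps[sid].data, raw.affine, "dc (smoothed)")
            written.append(name)

    # ----- stage: DC inference / seed selection ---------------------------
    try:
        dc_anova, dc_pairwise, seeds, dc_spec = _infer_stage(
            dc_maps, records, config, "DC")
    except Exception as e:
        raise RuntimeError(f"stage 'dc_inference' failed: {e}") from e
    _write_tsv(dc_anova.table, "dc_anova_clusters.tsv")
    _write_tsv(dc_pairwise.table, "dc_pairwise_clusters.tsv")
    if dc_spec is not None:
        _write_tsv(dc_spec.table, "dc_specificity.tsv")

    # ----- stage: seed FC --------------------------------------------------
    fc_spec: dict[str, inf.SpecificityResult] = {}
    fc_roi_means_psd: dict[str, pd.DataFrame] = {}
    for seed in seeds:
        try:
            fc_maps = {sid: conn.compute_seed_fc(prepped[sid]["smoothed"], seed,
                                                 group_mask) for sid in ids}
            _, fc_pair, fc_seeds, spec_res = _infer_stage(
                fc_maps, records, config, f"FC[{seed.roi_id}]")
        except Exception as e:
            raise RuntimeError(f"stage 'fc' failed for seed {seed.roi_id}: {e}") from e
        if spec_res is not None:
            fc_spec[seed.roi_id] = spec_res
            _write_tsv(spec_res.table, f"fc_specificity_{seed.roi_id}.tsv")
            if fc_seeds:
                psd_ids = records.loc[records["group"] == "PSD",
                                      "subject_id"].tolist()
                fc_roi_means_psd[seed.roi_id] = _roi_means(
                    fc_maps, fc_seeds, psd_ids)

    # ----- stage: behavior -------------------------------------------------
    psd = records[records["group"] == "PSD"]
    psd_ids = psd["subject_id"].tolist()
    corr_rows = []
    if seeds and dc_spec is not None:
        dc_means_psd = _roi_means(dc_maps, seeds, psd_ids)
        for roi in dc_means_psd.columns:
            for scale in _SCALES:
                r = bhv.spearman_bonferroni(
                    dc_means_psd[roi].to_numpy(), psd[scale].to_numpy(),
                    n_tests=config.n_behavior_tests, alpha=config.alpha)
                corr_rows.append({"metric": f"dc:{roi}", "scale": scale,
                                  "rho": r.rho, "p": r.p,
                                  "significant": r.significant})
    behavior_corr = pd.DataFrame(
        corr_rows, columns=["metric", "scale", "rho", "p", "significant"])
    _write_tsv(behavior_corr, "behavior_correlations.tsv")

    predictions: dict[str, bhv.PredictionResult] = {}
    if fc_roi_means_psd:
        features = pd.concat(
            [df.add_prefix(f"{seed_id}:") for seed_id, df in
             sorted(fc_roi_means_psd.items())], axis=1)
        if len(psd_ids) >= 5 and features.shape[1] >= 1:
            for scale in _SCALES:
                predictions[scale] = bhv.ridge_loocv_predict(
                    features.to_numpy(), psd[scale].to_numpy(),
                    lambda_grid=np.asarray(config.lambda_grid),
                    n_tests=config.n_behavior_tests, alpha=config.alpha)
            _write_json({scale: {
                "chosen_lambda": p.chosen_lambda,
                "rho": p.performance.rho, "p": p.performance.p,
                "significant": p.performance.significant,
                "n_features": p.n_features, "mode": p.mode,
                "predicted": [round(float(x), 6) for x in p.predicted],
            } for scale, p in predictions.items()}, "predictions.json")

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "rng_seed": config.rng_seed,
        "tr_seconds": tr,
        "n_subjects": {g: int((records["group"] == g).sum())
                       for g in ("HC", "Stroke", "PSD")},
        "thresholds": {"fdr_q": config.fdr_q, "min_extent": config.min_extent,
                       "alpha": config.alpha,
                       "n_comparisons": config.n_comparisons,
                       "dc_r_threshold": config.dc.r_threshold,
                       "band_hz": [config.band_low_hz, config.band_high_hz],
                       "fwhm_mm": config.fwhm_mm,
                       "pairwise_threshold": config.pairwise_threshold},
        "seeds": [s.roi_id for s in seeds],
        "outputs": sorted(written),
    }
    if out:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        qc=qc, demographics=demographics, group_mask=group_mask,
        dc_anova=dc_anova, dc_pairwise=dc_pairwise, dc_specificity=dc_spec,
        seeds=seeds, fc_specificity=fc_spec,
        behavior_correlations=behavior_corr, predictions=predictions,
        manifest=manifest)
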