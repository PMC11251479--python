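"""Group-level inference: voxel-wise GLMs, FDR + cluster-extent control,
the PSD-specificity conjunction, and demographic/clinical group tests.

The voxel-wise model is ``value ~ group + covariates`` fitted by OLS at
every voxel: a partial F for the three-group factor (covariates retained
in both models) or a t for a pairwise group contrast. Significance maps
are corrected by Benjamini-Hochberg FDR over in-mask voxels and reduced
to clusters of strictly more than ``min_extent`` contiguous voxels
(26-connectivity by default).

An ROI is "PSD-specific" when the depressed group's mean lies above (or
below) both comparison groups and both pairwise Welch tests survive
Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .core import ScalarMap, SeedSpec

__all__ = [
    "Design",
    "ClusterTable",
    "SpecificityResult",
    "fit_voxelwise_glm",
    "fdr_bh",
    "extract_clusters",
    "detect_specific_rois",
    "demographic_tests",
    "chi_square_test",
]

GROUPS = ("HC", "Stroke", "PSD")


@dataclass
class Design:
    """Subject-level design for a voxel-wise group model.

    ``contrast`` is either ``("three_group_F",)`` or
    ``("pair_t", groupA, groupB)`` (positive t means groupA > groupB).
    NIHSS must be supplied exactly for the PSD-vs-Stroke pairwise model,
    mirroring the covariate policy of the analysis.
    """

    subject_ids: list[str]
    groups: list[str]
    age: np.ndarray
    gender: np.ndarray  # binary-coded
    contrast: tuple
    nihss: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        self.groups = list(self.groups)
        self.age = np.asarray(self.age, dtype=float)
        self.gender = np.asarray(self.gender, dtype=float)
        if self.nihss is not None:
            self.nihss = np.asarray(self.nihss, dtype=float)
        for name, arr in (("age", self.age), ("gender", self.gender)):
            if arr.shape != (n,) or not np.all(np.isfinite(arr)):
                raise ValueError(f"covariate {name!r} must be complete, length {n}")
        if set(self.groups) - set(GROUPS):
            raise ValueError(f"unknown group labels: {set(self.groups) - set(GROUPS)}")
        kind = self.contrast[0]
        if kind == "three_group_F":
            if len(set(self.groups)) != 3:
                raise ValueError("three_group_F needs all three groups")
            if self.nihss is not None:
                raise ValueError("NIHSS is not a covariate of the three-group model")
        elif kind == "pair_t":
            a, b = self.contrast[1:]
            if {a, b} - set(self.groups) or a == b:
                raise ValueError(f"bad pairwise contrast {self.contrast}")
            is_psd_stroke = {a, b} == {"PSD", "Stroke"}
            if is_psd_stroke and self.nihss is None:
                raise ValueError("PSD vs Stroke requires NIHSS as a covariate")
            if not is_psd_stroke and self.nihss is not None:
                raise ValueError("NIHSS is only a covariate for PSD vs Stroke")
            if self.nihss is not None and (
                    self.nihss.shape != (len(self.groups),)
                    or not np.all(np.isfinite(self.nihss))):
                raise ValueError("NIHSS covariate must be complete")
        else:
            raise ValueError(f"unknown contrast kind {kind!r}")
        counts = pd.Series(self.groups).value_counts()
        if (counts < 2).any():
            raise ValueError("every included group needs at least 2 subjects")


def _stack_maps(maps: list[ScalarMap]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mask = maps[0].mask
    for m in maps[1:]:
        if m.mask.shape != mask.shape or not np.array_equal(m.mask, mask):
            raise ValueError("subject maps must share one mask")
    Y = np.stack([m.values() for m in maps])  # (n, V)
    return Y, mask, maps[0].affine


def _check_collinear(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"collinear design; columns: {names}")


def fit_voxelwise_glm(maps: list[ScalarMap], design: Design
                      ) -> tuple[ScalarMap, ScalarMap, tuple]:
    """Fit ``value ~ group + covariates`` at every voxel.

    Returns (statistic map, two-sided p map, degrees of freedom). For the
    three-group contrast the statistic is the partial F of the group
    factor; for a pairwise contrast it is the t of the group coefficient.
    """
    if len(maps) != len(design.subject_ids):
        raise ValueError("one map per design row required")
    Y, mask, affine = _stack_maps(maps)
    n = Y.shape[0]
    groups = np.asarray(design.groups)

    covars = [np.ones(n), design.age, design.gender]
    names = ["intercept", "age", "gender"]
    if design.nihss is not None:
        covars.append(design.nihss)
        names.append("nihss")

    if design.contrast[0] == "three_group_F":
        g1 = (groups == "Stroke").astype(float)
        g2 = (groups == "PSD").astype(float)
        X_full = np.column_stack(covars + [g1, g2])
        _check_collinear(X_full, names + ["g_stroke", "g_psd"])
        X_red = np.column_stack(covars)
        rss_full = _rss(Y, X_full)
        rss_red = _rss(Y, X_red)
        df1 = 2
        df2 = n - X_full.shape[1]
        scale = np.maximum((Y ** 2).sum(axis=0), 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ((rss_red - rss_full) / df1) / (rss_full / df2)
        # voxels fitted to machine precision carry no group information;
        # a perfect group fit (zero full-model residual) caps at a large F
        F = np.where(rss_red - rss_full <= 1e-12 * scale, 0.0, F)
        F = np.where(np.isfinite(F), F, 1e6)
        F = np.maximum(F, 0.0)
        p = stats.f.sf(F, df1, df2)
        stat_map = _to_map(F, mask, "F", affine)
        p_map = _to_map(p, mask, "p", affine)
        return stat_map, p_map, (df1, df2)

    _, a, b = design.contrast
    ind = (groups == a).astype(float)  # positive coefficient: a > b
    X = np.column_stack(covars + [ind])
    _check_collinear(X, names + [f"g_{a}"])
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    dof = n - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof
    c = np.zeros(X.shape[1]); c[-1] = 1.0
    var_c = c @ np.linalg.inv(X.T @ X) @ c
    scale = np.maximum((Y ** 2).sum(axis=0), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[-1] / np.sqrt(sigma2 * var_c)
    # degenerate voxels: no residual AND no group coefficient -> t = 0;
    # a perfect group separation caps at a large |t|
    degenerate = (sigma2 * dof <= 1e-12 * scale) & \
                 (beta[-1] ** 2 <= 1e-12 * scale)
    t = np.where(degenerate, 0.0, t)
    t = np.where(np.isfinite(t), t, np.sign(beta[-1]) * 1e6)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return _to_map(t, mask, "t", affine), _to_map(p, mask, "p", affine), (dof,)


def _rss(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return (resid ** 2).sum(axis=0)


def _to_map(values: np.ndarray, mask: np.ndarray, kind: str,
            affine: np.ndarray) -> ScalarMap:
    data = np.zeros(mask.shape, dtype=float)
    if kind == "p":
        data[:] = 1.0
    data[mask] = values
    return ScalarMap(data=data, mask=mask, kind=kind, affine=affine)


def fdr_bh(p_map: ScalarMap | np.ndarray, q: float = 0.05,
           mask: np.ndarray | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up over in-mask voxels; boolean rejection mask."""
    if isinstance(p_map, ScalarMap):
        mask = p_map.mask if mask is None else np.asarray(mask, bool)
        p = p_map.data[mask]
        shape = p_map.data.shape
    else:
        p_arr = np.asarray(p_map, dtype=float)
        mask = np.ones(p_arr.shape, bool) if mask is None else np.asarray(mask, bool)
        p = p_arr[mask]
        shape = p_arr.shape
    if p.size == 0:
        raise ValueError("empty mask: no p-values to correct")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    out = np.zeros(shape, dtype=bool)
    out[mask] = reject
    return out


@dataclass
class ClusterTable:
    """Connected significant clusters with peak statistics.

    ``table`` columns: cluster_id, peak_index (flat C-order), extent,
    peak_stat, sign. ``labels`` is the cluster-id volume (0 = background).
    """

    table: pd.DataFrame
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.table)

    def to_seeds(self, provenance: str = "dc_specificity") -> list[SeedSpec]:
        seeds = []
        for _, row in self.table.iterrows():
            vox = np.flatnonzero(self.labels.ravel() == row["cluster_id"])
            seeds.append(SeedSpec(roi_id=f"cluster{int(row['cluster_id'])}",
                                  voxels=vox, provenance=provenance))
        return seeds


def extract_clusters(sig_mask: np.ndarray, stat_map: ScalarMap,
                     min_extent: int = 20, connectivity: int = 26) -> ClusterTable:
    """Connected components of the significance mask above a size cutoff.

    Components must contain strictly more than ``min_extent`` voxels
    (k > 20 by default). ``connectivity`` is 6 (faces), 18 (+edges) or 26
    (+corners). Signed statistic maps (t) are clustered separately for
    positive and negative voxels, so adjacent effects of opposite
    direction are reported as distinct clusters; nonnegative maps (F, DC)
    are unaffected. The peak is the max-|statistic| voxel, ties resolved
    to the lowest flat index.
    """
    structure = {6: ndimage.generate_binary_structure(3, 1),
                 18: ndimage.generate_binary_structure(3, 2),
                 26: ndimage.generate_binary_structure(3, 3)}[connectivity]
    sig_mask = np.asarray(sig_mask, dtype=bool)
    stat = stat_map.data
    rows = []
    labels_out = np.zeros(sig_mask.shape, dtype=np.int32)
    next_id = 1
    for side_mask in (sig_mask & (stat >= 0), sig_mask & (stat < 0)):
        if not side_mask.any():
            continue
        labelled, n_raw = ndimage.label(side_mask, structure=structure)
        for lab in range(1, n_raw + 1):
            comp = labelled == lab
            extent = int(comp.sum())
            if extent <= min_extent:
                continue
            flat = np.flatnonzero(comp.ravel())
            vals = stat.ravel()[flat]
            peak_local = int(np.argmax(np.abs(vals)))  # argmax -> lowest index on ties
            peak_index = int(flat[peak_local])
            peak_stat = float(vals[peak_local])
            labels_out[comp] = next_id
            rows.append({"cluster_id": next_id, "peak_index": peak_index,
                         "extent": extent, "peak_stat": peak_stat,
                         "sign": int(np.sign(peak_stat)) if peak_stat else 0})
            next_id += 1
    table = pd.DataFrame(rows, columns=["cluster_id", "peak_index", "extent",
                                        "peak_stat", "sign"])
    return ClusterTable(table=table, labels=labels_out)


@dataclass
class SpecificityResult:
    """Per-ROI three-group conjunction verdicts.

    ``table`` columns: roi_id, mean_HC, mean_Stroke, mean_PSD,
    p_psd_stroke, p_psd_hc, p_stroke_hc, verdict in
    {psd_specific_up, psd_specific_down, not_specific}.
    """

    table: pd.DataFrame
    alpha: float
    n_comparisons: int

    @property
    def specific_rois(self) -> list[str]:
        sel = self.table["verdict"].str.startswith("psd_specific")
        return self.table.loc[sel, "roi_id"].tolist()


def detect_specific_rois(roi_means: pd.DataFrame, groups, alpha: float = 0.05,
                         n_comparisons: int = 3) -> SpecificityResult:
    """Three-group specificity conjunction on per-subject ROI means.

    ``roi_means`` has one row per subject and one column per ROI; ``groups``
    aligns with its rows. Pairwise Welch two-sample t-tests (two-sided) are
    Bonferroni-corrected over ``n_comparisons`` tests; an ROI is flagged
    psd_specific_up when the PSD mean exceeds both other groups with both
    PSD-involving tests surviving correction (symmetrically for down).
    """
    groups = np.asarray(groups)
    for g in GROUPS:
        if (groups == g).sum() < 2:
            raise ValueError(f"need at least 2 subjects in group {g}")
    rows = []
    for roi in roi_means.columns:
        v = roi_means[roi].to_numpy(dtype=float)
        by = {g: v[groups == g] for g in GROUPS}
        if np.ptp(v) == 0:
            raise ValueError(f"ROI {roi!r} is degenerate (zero variance everywhere)")
        p_ps = _welch_p(by["PSD"], by["Stroke"])
        p_ph = _welch_p(by["PSD"], by["HC"])
        p_sh = _welch_p(by["Stroke"], by["HC"])
        m = {g: float(x.mean()) for g, x in by.items()}
        up = m["PSD"] > m["Stroke"] and m["PSD"] > m["HC"]
        down = m["PSD"] < m["Stroke"] and m["PSD"] < m["HC"]
        sig = (p_ps * n_comparisons < alpha) and (p_ph * n_comparisons < alpha)
        verdict = ("psd_specific_up" if up and sig else
                   "psd_specific_down" if down and sig else "not_specific")
        rows.append({"roi_id": roi, "mean_HC": m["HC"], "mean_Stroke": m["Stroke"],
                     "mean_PSD": m["PSD"], "p_psd_stroke": p_ps, "p_psd_hc": p_ph,
                     "p_stroke_hc": p_sh, "verdict": verdict})
    return SpecificityResult(table=pd.DataFrame(rows), alpha=alpha,
                             n_comparisons=n_comparisons)


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


# ---------------------------------------------------------------------------
# Demographic / clinical characteristic tests


def chi_square_test(counts) -> dict:
    """Pearson chi-square on a contingency table, no continuity correction."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2D")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        raise ValueError("expected cell count of zero; table is degenerate")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return {"test": "chi_square", "statistic": float(chi2), "df": int(dof),
            "p": float(p)}


def _continuous_three_group(values_by_group: dict[str, np.ndarray],
                            normality_alpha: float = 0.05) -> dict:
    """Shapiro-Wilk gate, then one-way ANOVA (all normal) or Kruskal-Wallis."""
    samples = [values_by_group[g] for g in GROUPS if g in values_by_group]
    normal = all(len(s) >= 3 and np.ptp(s) > 0
                 and stats.shapiro(s).pvalue > normality_alpha for s in samples)
    if normal:
        res = stats.f_oneway(*samples)
        df = (len(samples) - 1, sum(len(s) for s in samples) - len(samples))
        return {"test": "anova", "statistic": float(res.statistic),
                "df": df, "p": float(res.pvalue)}
    res = stats.kruskal(*samples)
    return {"test": "kruskal_wallis", "statistic": float(res.statistic),
            "df": len(samples) - 1, "p": float(res.pvalue)}


def demographic_tests(records: pd.DataFrame) -> pd.DataFrame:
    """Group comparisons of demographic and clinical variables.

    Continuous three-group variables pass a Shapiro-Wilk normality gate
    into one-way ANOVA (all groups normal) or Kruskal-Wallis; two-group
    (patients-only) variables use the Mann-Whitney U; categorical
    variables use the Pearson chi-square without continuity correction.
    """
    req = {"group", "age", "gender", "PHQ9", "ADL"}
    if missing := req - set(records.columns):
        raise ValueError(f"records table missing columns: {sorted(missing)}")
    g = records["group"]
    out = []

    def by3(col):
        return {grp: records.loc[g == grp, col].dropna().to_numpy(float)
                for grp in GROUPS}

    def two(col):
        a = records.loc[g == "Stroke", col].dropna().to_numpy(float)
        b = records.loc[g == "PSD", col].dropna().to_numpy(float)
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return {"test": "mann_whitney_u", "statistic": float(res.statistic),
                "df": None, "p": float(res.pvalue)}

    for col in ("age", "PHQ9", "ADL"):
        out.append({"variable": col, **_continuous_three_group(by3(col))})

    counts = pd.crosstab(g, records["gender"]).reindex(list(GROUPS)).to_numpy()
    out.append({"variable": "gender", **chi_square_test(counts)})

    patients = records[g.isin(["Stroke", "PSD"])]
    if "lesion_side" in records.columns and patients["lesion_side"].ne("").any():
        side = pd.crosstab(patients["group"], patients["lesion_side"])
        out.append({"variable": "lesion_hemisphere",
                    **chi_square_test(side.to_numpy())})
    for col in ("lesion_size_vox", "onset_days", "NIHSS", "HAMD", "CESD"):
        if col in records.columns and patients[col].notna().any():
            out.append({"variable": col, **two(col)})
    return pd.DataFrame(out, columns=["variable", "test", "statistic", "df", "p"])
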