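"""Synthetic multi-group resting-state cohorts with known ground truth.

The generator emulates the statistical structure of a three-group stroke
study (healthy controls, nondepressed stroke, depressed stroke): block-
structured voxel covariance defining "networks", elevated coupling of
designated hub blocks in exactly the depressed group, unilateral lesions,
per-voxel hemodynamic lags in the patient groups, rigid-body motion
traces, and depression scores linearly coupled to each subject's realized
hub coupling. Every downstream stage of the pipeline can therefore be
tested against injected truth without any external data.

Signal model
------------
For a voxel v in network block b of subject i,

    x_v(t) = sqrt(rho - rho_g) * f_b(t - lag_v) + sqrt(rho_g) * g(t - lag_v)
             + sqrt(1 - rho) * sigma * eps_v(t)

where f_b is the subject's block factor (unit-variance white noise), g a
weak global gray-matter signal shared by every gray-matter voxel with
loading rho_g (``global_r``), rho the group/block coupling target, lag_v
the voxel's integer TR lag (circular shift of both shared components;
constant within a block, emulating the spatially coherent hemodynamic
delays of perilesional tissue), sigma the noise scale (``noise_sd``, 1 by
default) and eps white Gaussian noise. The pairwise correlation of two
same-block voxels is exactly rho and of two background gray-matter voxels
rho_g. White matter and CSF voxels carry pure noise, so regressing their
mean signals out does not touch the retained global component — which is
what makes time-shift lag estimation against the gray-matter mean
well-posed. Hub blocks in the depressed group use rho + effect_delta_r.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BoldSeries, MotionTrace, default_affine, load_volume, save_volume

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "SyntheticSubject",
    "default_network_blocks",
    "tissue_labels",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
    "METADATA_COLUMNS",
    "MOTION_COLUMNS",
]

GROUPS = ("HC", "Stroke", "PSD")

METADATA_COLUMNS = [
    "subject_id", "group", "age", "gender", "lesion_side", "lesion_size_vox",
    "onset_days", "NIHSS", "PHQ9", "HAMD", "CESD", "ADL",
]
MOTION_COLUMNS = [
    "trans_x_mm", "trans_y_mm", "trans_z_mm",
    "rot_x_rad", "rot_y_rad", "rot_z_rad",
]

# Group-level demographic / clinical distributions (mean, sd) used to draw
# subject records; depression scales additionally receive the coupling term.
_DEMOGRAPHICS = {
    "age": {"HC": (57.43, 6.83), "Stroke": (59.41, 6.45), "PSD": (60.00, 9.41)},
    "male_prob": {"HC": 43 / 74, "Stroke": 50 / 82, "PSD": 21 / 39},
    "onset_days": {"Stroke": (4.85, 3.26), "PSD": (9.92, 4.92)},
    "nihss": {"Stroke": (2.54, 2.18), "PSD": (5.18, 3.49)},
    "adl": {"HC": (100.0, 0.0), "Stroke": (82.80, 16.76), "PSD": (67.05, 18.05)},
    "phq9_base": {"HC": (0.69, 1.18), "Stroke": (0.23, 0.69), "PSD": (8.23, None)},
    "hamd_base": {"HC": (0.30, 0.60), "Stroke": (0.23, 0.79), "PSD": (19.23, None)},
    "cesd_base": {"HC": (11.50, 1.50), "Stroke": (12.12, 0.57), "PSD": (24.44, None)},
}
# Score-scale slopes (points per unit correlation) and PSD residual noise sd;
# chosen so the PSD-group score spread matches the reference distributions.
_SCALE_SLOPE_FACTOR = {"PHQ9": 1.0, "HAMD": 0.6, "CESD": 1.4}
_SCALE_NOISE = {"PHQ9": 1.5, "HAMD": 1.2, "CESD": 2.5}
_SCALE_CLIP = {"PHQ9": (0, 27), "HAMD": (0, 52), "CESD": (0, 60)}


def tissue_labels(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Synthetic tissue atlas: plane z=0 is WM, z=1 is CSF, the rest GM.

    Labels: 1 = gray matter, 2 = white matter, 3 = CSF.
    """
    labels = np.ones(grid_shape, dtype=np.int16)
    labels[:, :, 0] = 2
    if grid_shape[2] > 1:
        labels[:, :, 1] = 3
    return labels


def default_network_blocks(grid_shape: tuple[int, int, int] = (16, 16, 12),
                           block_extent: int = 3) -> dict[int, np.ndarray]:
    """Six disjoint cuboid network blocks, three per hemisphere.

    Returns flat C-order voxel indices per block id. Blocks 3-5 sit in the
    right hemisphere (contralesional once patients are flipped to the
    ipsilesional-left convention); the default hubs are drawn from them.
    """
    nx, ny, nz = grid_shape
    e = block_extent
    # (x0, y0, z0) corners: left hemisphere x < nx//2, right x >= nx//2
    corners = [
        (max(1, nx // 8), max(1, ny // 8), max(2, nz // 3)),
        (max(1, nx // 8), min(ny - e - 1, 5 * ny // 8), max(2, nz // 2)),
        (max(1, nx // 5), min(ny - e - 1, 3 * ny // 8), min(nz - e - 1, 2 * nz // 3)),
        (min(nx - e - 1, 11 * nx // 16), max(1, ny // 8), max(2, nz // 3)),
        (min(nx - e - 1, 5 * nx // 8), min(ny - e - 1, 5 * ny // 8), max(2, nz // 2)),
        (min(nx - e - 1, 11 * nx // 16), min(ny - e - 1, 3 * ny // 8), min(nz - e - 1, 2 * nz // 3)),
    ]
    blocks: dict[int, np.ndarray] = {}
    taken = np.zeros(grid_shape, dtype=bool)
    for bid, (x0, y0, z0) in enumerate(corners):
        m = np.zeros(grid_shape, dtype=bool)
        m[x0:x0 + e, y0:y0 + e, z0:z0 + e] = True
        m &= ~taken
        taken |= m
        blocks[bid] = np.flatnonzero(m.ravel())
    return blocks


@dataclass
class CohortSpec:
    """Everything the generator needs; same spec + seed => identical output."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 15, "Stroke": 15, "PSD": 15})
    grid_shape: tuple[int, int, int] = (16, 16, 12)
    n_timepoints: int = 150
    tr_seconds: float = 2.0
    network_blocks: dict[int, np.ndarray] | None = None  # None -> defaults
    within_block_r: float = 0.30
    global_r: float = 0.08  # gray-matter global-signal coupling
    hub_blocks: tuple[int, ...] = (3, 4)
    effect_delta_r: float = 0.25
    lesion_size_range: tuple[int, int] = (20, 60)
    lesion_left_prob: float = 0.55
    lag_range_tr: int = 2
    motion_sd_mm: float = 0.05
    behavior_slope: float = 40.0  # PHQ-9 points per unit hub correlation
    behavior_noise_sd: float = 1.5
    subject_coupling_sd: float = 0.05  # per-subject hub-coupling jitter
    noise_sd: float = 1.0  # 0 -> noiseless factors (exact-recovery tests)
    voxel_size_mm: float = 3.0
    dtype: str = "float32"
    rng_seed: int = 0

    def resolved_blocks(self) -> dict[int, np.ndarray]:
        if self.network_blocks is not None:
            return {int(k): np.asarray(v, dtype=np.intp)
                    for k, v in self.network_blocks.items()}
        return default_network_blocks(self.grid_shape)

    def validate(self) -> None:
        if set(self.n_per_group) - set(GROUPS):
            raise ValueError(f"unknown group labels in {self.n_per_group}")
        if any(n < 1 for n in self.n_per_group.values()):
            raise ValueError("each group needs at least one subject")
        if not (0 <= self.within_block_r < 1):
            raise ValueError("within_block_r must be in [0, 1)")
        if not (0 <= self.global_r <= self.within_block_r):
            raise ValueError("global_r must lie in [0, within_block_r]")
        if self.within_block_r + self.effect_delta_r >= 1:
            raise ValueError(
                "infeasible coupling: within_block_r + effect_delta_r must be < 1")
        if self.n_timepoints <= 2 * self.lag_range_tr:
            raise ValueError("n_timepoints must exceed 2 * lag_range_tr")
        nvox = int(np.prod(self.grid_shape))
        blocks = self.resolved_blocks()
        seen: set[int] = set()
        for bid, idx in blocks.items():
            if idx.size == 0 or idx.min() < 0 or idx.max() >= nvox:
                raise ValueError(f"block {bid} outside the grid")
            if seen & set(idx.tolist()):
                raise ValueError("network blocks overlap")
            seen |= set(idx.tolist())
        if not set(self.hub_blocks) <= set(blocks):
            raise ValueError("hub_blocks must be a subset of network block ids")


@dataclass
class SyntheticSubject:
    """Generated per-subject bundle: BOLD, motion, lesion."""

    subject_id: str
    group: str
    bold: BoldSeries
    motion: MotionTrace
    lesion: np.ndarray | None  # 3D bool, patients only
    lesion_side: str | None


@dataclass
class GroundTruth:
    """Injected truth for validating every downstream stage."""

    hub_blocks: tuple[int, ...]
    blocks: dict[int, np.ndarray]
    lag_maps: dict[str, np.ndarray]        # subject_id -> 3D int TR offsets
    factors: dict[str, np.ndarray]         # subject_id -> (n_blocks, T)
    global_signals: dict[str, np.ndarray]  # subject_id -> (T,)
    block_rho: dict[str, dict[int, float]]  # subject_id -> block -> rho used
    hub_coupling: dict[str, float]         # subject_id -> realized mean hub r
    lesions: dict[str, np.ndarray]
    lesion_sides: dict[str, str]
    behavior_slope: float


def _draw_lesion(rng: np.random.Generator, spec: CohortSpec,
                 gm: np.ndarray, block_union: np.ndarray) -> np.ndarray:
    """Random ipsilesional-left cuboid lesion in GM avoiding the blocks.

    Lesions are drawn in the canonical analysis space where the
    ipsilesional hemisphere is the left one (x < nx/2); the subject's
    native hemisphere is decided afterwards by mirroring the whole run.
    """
    nx, ny, nz = spec.grid_shape
    lo, hi = spec.lesion_size_range
    xr = (0, nx // 2)
    for _ in range(50):
        target = int(rng.integers(lo, hi + 1))
        dz = int(rng.integers(2, 5))
        dy = int(rng.integers(2, 6))
        dx = max(1, int(round(target / (dy * dz))))
        x0 = int(rng.integers(xr[0], max(xr[0] + 1, xr[1] - dx)))
        y0 = int(rng.integers(0, max(1, ny - dy)))
        z0 = int(rng.integers(2, max(3, nz - dz)))
        m = np.zeros(spec.grid_shape, dtype=bool)
        m[x0:x0 + dx, y0:y0 + dy, z0:z0 + dz] = True
        m &= gm
        if m.sum() < max(1, lo // 2):
            continue
        if np.any(m & block_union):
            continue
        return m
    raise RuntimeError("could not place a lesion avoiding the network blocks "
                       "after 50 attempts; enlarge the grid or shrink lesions")


def _motion_trace(rng: np.random.Generator, spec: CohortSpec) -> MotionTrace:
    T = spec.n_timepoints
    trans = np.cumsum(rng.normal(0.0, spec.motion_sd_mm, size=(3, T)), axis=1)
    rot = np.cumsum(rng.normal(0.0, spec.motion_sd_mm * 1e-2, size=(3, T)), axis=1)
    trans[:, 0] = 0.0
    rot[:, 0] = 0.0
    return MotionTrace(params=np.vstack([trans, rot]))


def _behavior_scores(rng: np.random.Generator, group: str, coupling_centered: float,
                     slope: float, noise_sd_psd: float) -> dict[str, float]:
    scores = {}
    for scale, base_key in (("PHQ9", "phq9_base"), ("HAMD", "hamd_base"),
                            ("CESD", "cesd_base")):
        base, base_sd = _DEMOGRAPHICS[base_key][group]
        s = slope * _SCALE_SLOPE_FACTOR[scale]
        noise = noise_sd_psd * _SCALE_NOISE[scale] / _SCALE_NOISE["PHQ9"] \
            if base_sd is None else base_sd
        val = base + s * coupling_centered + rng.normal(0.0, noise)
        lo, hi = _SCALE_CLIP[scale]
        scores[scale] = float(np.clip(round(val, 1), lo, hi))
    return scores


def generate_cohort(spec: CohortSpec) -> tuple[list[SyntheticSubject], pd.DataFrame, GroundTruth]:
    """Generate a full cohort; deterministic for a given (spec, seed)."""
    spec.validate()
    blocks = spec.resolved_blocks()
    n_blocks = len(blocks)
    block_ids = sorted(blocks)
    grid = spec.grid_shape
    nvox = int(np.prod(grid))
    T = spec.n_timepoints
    dtype = np.dtype(spec.dtype)

    labels = tissue_labels(grid)
    gm = labels == 1
    block_union = np.zeros(grid, dtype=bool)
    for idx in blocks.values():
        block_union.ravel()[idx] = True

    root = np.random.SeedSequence(spec.rng_seed)
    n_total = sum(spec.n_per_group.get(g, 0) for g in GROUPS)
    child_seeds = root.spawn(n_total)

    subjects: list[SyntheticSubject] = []
    rows: list[dict] = []
    truth = GroundTruth(
        hub_blocks=tuple(spec.hub_blocks), blocks=blocks, lag_maps={},
        factors={}, global_signals={}, block_rho={}, hub_coupling={},
        lesions={}, lesion_sides={}, behavior_slope=spec.behavior_slope,
    )

    affine = default_affine(spec.voxel_size_mm)
    k = 0
    for group in GROUPS:
        for j in range(spec.n_per_group.get(group, 0)):
            rng = np.random.default_rng(child_seeds[k])
            sid = f"sub-{group.lower()}{j + 1:03d}"
            k += 1

            factors = rng.standard_normal((n_blocks, T))
            global_sig = rng.standard_normal(T)
            eta = rng.normal(0.0, spec.subject_coupling_sd)
            rho_g = spec.global_r
            rho_by_block: dict[int, float] = {}
            for bid in block_ids:
                rho = spec.within_block_r
                if bid in spec.hub_blocks:
                    rho += eta
                    if group == "PSD":
                        rho += spec.effect_delta_r
                rho_by_block[bid] = float(np.clip(rho, rho_g, 0.97))

            # block-constant lags (patients only): hemodynamic delay is
            # spatially coherent, so every voxel of a block shares one lag
            lag_map = np.zeros(grid, dtype=np.int16)
            block_lag = {bid: 0 for bid in block_ids}
            if group != "HC" and spec.lag_range_tr > 0:
                for bid in block_ids:
                    block_lag[bid] = int(rng.integers(-spec.lag_range_tr,
                                                      spec.lag_range_tr + 1))
                    lag_map.ravel()[blocks[bid]] = block_lag[bid]

            data = rng.standard_normal((nvox, T)).astype(dtype, copy=False)
            if spec.noise_sd != 1.0:
                data *= dtype.type(spec.noise_sd)
            # background gray matter: weak unlagged global component
            gm_bg = gm.copy()
            gm_bg.ravel()[np.concatenate(list(blocks.values()))] = False
            bg_idx = np.flatnonzero(gm_bg.ravel())
            if rho_g > 0:
                data[bg_idx] *= dtype.type(np.sqrt(1.0 - rho_g))
                data[bg_idx] += (np.sqrt(rho_g) * global_sig).astype(dtype, copy=False)
            for bi, bid in enumerate(block_ids):
                idx = blocks[bid]
                rho = rho_by_block[bid]
                data[idx] *= dtype.type(np.sqrt(1.0 - rho))
                lag = block_lag[bid]
                f = np.roll(factors[bi], lag) if lag else factors[bi]
                shared = np.sqrt(rho - rho_g) * f
                if rho_g > 0:
                    gl = np.roll(global_sig, lag) if lag else global_sig
                    shared = shared + np.sqrt(rho_g) * gl
                data[idx] += shared.astype(dtype, copy=False)

            # realized hub coupling: mean pairwise correlation in hub blocks
            hub_rs = []
            for bid in spec.hub_blocks:
                x = data[blocks[bid]].astype(np.float64)
                x -= x.mean(axis=1, keepdims=True)
                nrm = np.linalg.norm(x, axis=1, keepdims=True)
                nrm[nrm == 0] = 1.0
                r = (x / nrm) @ (x / nrm).T
                iu = np.triu_indices(r.shape[0], k=1)
                hub_rs.append(r[iu].mean())
            c_real = float(np.mean(hub_rs)) if hub_rs else 0.0

            # lesions and network effects live in the canonical space
            # (ipsilesional = left); right-lesion subjects are handed out
            # mirrored, so the pipeline's hemisphere flip restores them.
            lesion = None
            side = None
            vol = data.reshape(*grid, T)
            if group != "HC":
                lesion_canon = _draw_lesion(rng, spec, gm, block_union)
                vol[lesion_canon] = 0.0
                side = "left" if rng.random() < spec.lesion_left_prob else "right"
                truth.lesions[sid] = lesion_canon
                truth.lesion_sides[sid] = side
                if side == "right":
                    vol = vol[::-1].copy()
                    lesion = lesion_canon[::-1].copy()
                else:
                    lesion = lesion_canon

            bold = BoldSeries(data=vol, tr_seconds=spec.tr_seconds,
                              affine=affine)
            motion = _motion_trace(rng, spec)
            subjects.append(SyntheticSubject(sid, group, bold, motion, lesion, side))

            truth.lag_maps[sid] = lag_map
            truth.factors[sid] = factors
            truth.global_signals[sid] = global_sig
            truth.block_rho[sid] = rho_by_block
            truth.hub_coupling[sid] = c_real

            expected = spec.within_block_r + (
                spec.effect_delta_r if group == "PSD" and spec.hub_blocks else 0.0)
            scores = _behavior_scores(rng, group, c_real - expected,
                                      spec.behavior_slope, spec.behavior_noise_sd)
            age = rng.normal(*_DEMOGRAPHICS["age"][group])
            gender = "M" if rng.random() < _DEMOGRAPHICS["male_prob"][group] else "F"
            if group == "HC":
                onset = nihss = np.nan
            else:
                onset = max(1.0, rng.normal(*_DEMOGRAPHICS["onset_days"][group]))
                nihss = max(0.0, round(rng.normal(*_DEMOGRAPHICS["nihss"][group])))
            adl_mu, adl_sd = _DEMOGRAPHICS["adl"][group]
            adl = float(np.clip(rng.normal(adl_mu, adl_sd) if adl_sd else adl_mu, 0, 100))
            rows.append({
                "subject_id": sid, "group": group, "age": round(float(age), 1),
                "gender": gender, "lesion_side": side if side else "",
                "lesion_size_vox": int(lesion.sum()) if lesion is not None else 0,
                "onset_days": round(float(onset), 1) if np.isfinite(onset) else np.nan,
                "NIHSS": nihss, "PHQ9": scores["PHQ9"], "HAMD": scores["HAMD"],
                "CESD": scores["CESD"], "ADL": round(adl, 1),
            })

    records = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    return subjects, records, truth


# ---------------------------------------------------------------------------
# On-disk layout


def write_cohort(subjects: list[SyntheticSubject], records: pd.DataFrame,
                 out_dir: str | Path, spec: CohortSpec | None = None) -> dict:
    """Write BOLD/lesion NIfTIs, motion TSVs, metadata and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid0 = subjects[0].bold.grid_shape
    manifest: dict = {"bold": {}, "lesion": {}, "motion": {}, "tr_seconds":
                      subjects[0].bold.tr_seconds}
    for s in subjects:
        if s.bold.grid_shape != grid0:
            raise ValueError("subjects are not on a common grid")
        bpath = out / f"{s.subject_id}_bold.nii"
        save_volume(bpath, s.bold.data, s.bold.affine, "synthetic BOLD")
        manifest["bold"][s.subject_id] = bpath.name
        mpath = out / f"{s.subject_id}_motion.tsv"
        pd.DataFrame(s.motion.params.T, columns=MOTION_COLUMNS).to_csv(
            mpath, sep="\t", index=False)
        manifest["motion"][s.subject_id] = mpath.name
        if s.lesion is not None:
            lpath = out / f"{s.subject_id}_lesion.nii"
            save_volume(lpath, s.lesion.astype(np.uint8), s.bold.affine, "lesion mask")
            manifest["lesion"][s.subject_id] = lpath.name
    records.to_csv(out / "participants.tsv", sep="\t", index=False)
    manifest["metadata"] = "participants.tsv"
    labels = tissue_labels(grid0)
    save_volume(out / "tissue_labels.nii", labels, subjects[0].bold.affine,
                "1=GM 2=WM 3=CSF")
    manifest["tissue_labels"] = "tissue_labels.nii"
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["manifest"] = "manifest.json"
    return manifest


def load_cohort(in_dir: str | Path) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Round-trip reader for :func:`write_cohort` output."""
    src = Path(in_dir)
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    records = pd.read_csv(src / manifest["metadata"], sep="\t",
                          keep_default_na=True, na_values=[""])
    records["lesion_side"] = records["lesion_side"].fillna("")
    tr = float(manifest["tr_seconds"])
    subjects = []
    for _, row in records.iterrows():
        sid = row["subject_id"]
        data, affine = load_volume(src / manifest["bold"][sid])
        bold = BoldSeries(data=data, tr_seconds=tr, affine=affine)
        mot = pd.read_csv(src / manifest["motion"][sid], sep="\t")
        motion = MotionTrace(params=mot[MOTION_COLUMNS].to_numpy().T)
        lesion = side = None
        if sid in manifest.get("lesion", {}):
            ldata, _ = load_volume(src / manifest["lesion"][sid])
            lesion = ldata.astype(bool)
            side = row["lesion_side"] or None
        subjects.append(SyntheticSubject(sid, row["group"], bold, motion, lesion, side))
    return subjects, records
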