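"""Synthetic multi-subject rest/task cohorts with planted ground truth.

The generator emulates the study structure downstream analyses assume: a
shared toy grid holding an 8-parcel ACC atlas (one dACC per hemisphere),
four "physics" parcels (L/R frontal, L/R parietal) inside a fronto-parietal
search mask, and WM/ventricle nuisance boxes. Each subject carries a rigid
integer-voxel displacement of a physics-responsive voxel core; the SAME
displaced voxels receive the dACC-coupled rest signal and the physics-cue
task activation. That shared displacement is the planted connectivity
fingerprint every recovery experiment targets.

Rest runs: background voxels are AR(1) Gaussian noise (coefficient phi,
innovation SD sigma). All eight ACC parcels share a common component g(t)
-- the signal the common-variance regression step exists to remove -- and
each parcel additionally carries its own unit-variance unique latent; the
dACC latent s(t) is shared by the left and right dACC parcels, and each
displaced physics-core voxel is a*s(t) + noise. WM and ventricle boxes
carry their own shared confound series, weakly mixed (weight 0.2*a) into
all grey voxels so that skipping nuisance regression measurably biases r.
Under perfect nuisance removal (g and the confounds regressed out) the
population correlation of s with a planted voxel is
a / sqrt(a**2 + sigma_eff**2) with sigma_eff = sigma / sqrt(1 - phi**2).

Task runs: displaced core voxels respond to the physics-cue regressor with
amplitude activation_beta; a disjoint fixed voxel set responds to the
colour-cue regressor; noise is AR(1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import BlockDesign, build_block_design, convolve_design
from .volio import (MotionTable, ParcelAtlas, Role, VolumeSeries, write_atlas,
                    write_motion_table, write_volume)

__all__ = [
    "CohortParams",
    "SubjectProfile",
    "SubjectDataset",
    "make_atlas",
    "planted_core_mask",
    "colour_core_mask",
    "simulate_rest_run",
    "simulate_task_run",
    "make_cohort",
    "write_cohort",
]


@dataclass
class CohortParams:
    """Generative settings for one synthetic cohort.

    Defaults mirror the emulated study geometry: TR 2 s, 3 x 3 x 3.5 mm
    voxels, 5-min rest runs (150 volumes), two 207-volume task runs, and a
    20^3 grid large enough for all parcels. seed_coupling is the mixing
    weight a of the dACC latent into planted voxels; displacement_sd_mm sets
    the between-subject spread of the planted voxel positions; ar1_phi = 0.3
    mimics fMRI temporal autocorrelation.
    """

    n_subjects: int = 8
    grid_dims: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.5)
    tr_s: float = 2.0
    n_rest_volumes: int = 150
    rest_runs_per_subject: int = 2
    task_runs_per_subject: int = 2
    seed_coupling: float = 0.5           # a
    activation_beta: float = 1.0
    noise_sd: float = 1.0                # AR(1) innovation SD sigma
    ar1_phi: float = 0.3
    displacement_sd_mm: float = 6.0
    motion_spike_rate: float = 0.02
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.seed_coupling < 0:
            raise ValueError("seed_coupling must be >= 0")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.ar1_phi < 1:
            raise ValueError("ar1_phi must lie in [0, 1)")
        if self.rest_runs_per_subject not in (1, 2):
            raise ValueError("rest_runs_per_subject must be 1 or 2")

    @property
    def noise_sd_stationary(self) -> float:
        """Stationary SD of the AR(1) noise, sigma / sqrt(1 - phi**2)."""
        return self.noise_sd / np.sqrt(1.0 - self.ar1_phi ** 2)

    def planted_r(self) -> float:
        """Population seed-voxel correlation after perfect nuisance removal."""
        a, s = self.seed_coupling, self.noise_sd_stationary
        return a / np.sqrt(a ** 2 + s ** 2)


@dataclass
class SubjectProfile:
    """Per-subject ground truth: the rigid offset of the physics core."""

    subject_id: str
    displacement_vox: np.ndarray          # 3 ints
    displacement_mm: np.ndarray           # displacement_vox * voxel size
    rest_seeds: list[int] = field(default_factory=list)
    task_seeds: list[int] = field(default_factory=list)


@dataclass
class SubjectDataset:
    profile: SubjectProfile
    rest_runs: list[tuple[VolumeSeries, MotionTable]]
    task_runs: list[tuple[VolumeSeries, MotionTable]]
    task_designs: list[BlockDesign]


# ---------------------------------------------------------------------------
# Atlas geometry (all coordinates are inclusive voxel-index ranges)

_PHYSICS_BOXES = {
    "physics_L_parietal": ((1, 8), (1, 8), (13, 18)),
    "physics_L_frontal": ((1, 8), (11, 18), (13, 18)),
    "physics_R_parietal": ((11, 18), (1, 8), (13, 18)),
    "physics_R_frontal": ((11, 18), (11, 18), (13, 18)),
}
_ACC_Y_BANDS = ((2, 4), (5, 7), (8, 10), (11, 13))   # 4 parcels per hemisphere
_ACC_DACC_BAND = 2                                   # index of the dACC band
_ACC_X = {"L": (7, 9), "R": (10, 12)}
_ACC_Z = (7, 10)
_WM_BOX = ((2, 6), (2, 6), (0, 2))
_VENT_BOX = ((13, 17), (2, 6), (3, 5))
_SEARCH_Z = (12, 19)
# planted physics core: central 4x4x4 of each physics parcel; margins of
# (2, 2, 1) voxels keep clipped displacements inside the parcel
_CORE_OFFSET = (2, 2, 1)
_CORE_SIZE = (4, 4, 4)
# colour-responsive control voxels: in the search mask between the parcels
_COLOUR_BOX = ((3, 6), (9, 10), (14, 17))

MIN_GRID = (20, 20, 20)


def _fill(arr: np.ndarray, box, value: int) -> None:
    (x0, x1), (y0, y1), (z0, z1) = box
    arr[x0:x1 + 1, y0:y1 + 1, z0:z1 + 1] = value


def make_atlas(params: CohortParams) -> ParcelAtlas:
    """Deterministic toy atlas: 8 ACC parcels, 4 physics parcels (>= 200
    voxels each), WM and ventricle boxes, and a fronto-parietal search mask
    containing the physics parcels."""
    if any(g < m for g, m in zip(params.grid_dims, MIN_GRID)):
        raise ValueError(f"grid {params.grid_dims} too small; need >= {MIN_GRID}")
    labels = np.zeros(params.grid_dims, dtype=np.int32)
    rows = []
    next_id = 1

    # search mask first so parcels overwrite it (mask() reunites them)
    _fill(labels, ((0, params.grid_dims[0] - 1), (0, params.grid_dims[1] - 1),
                   _SEARCH_Z), next_id)
    rows.append((next_id, "frontoparietal_searchmask", Role.SEARCHMASK.value))
    next_id += 1

    for hemi in ("L", "R"):
        for band_i, yband in enumerate(_ACC_Y_BANDS):
            role = Role.ACC_DACC if band_i == _ACC_DACC_BAND else Role.ACC_OTHER
            name = f"acc_{hemi}_{'dacc' if role is Role.ACC_DACC else f'other{band_i}'}"
            _fill(labels, (_ACC_X[hemi], yband, _ACC_Z), next_id)
            rows.append((next_id, name, role.value))
            next_id += 1

    for name, box in _PHYSICS_BOXES.items():
        _fill(labels, box, next_id)
        rows.append((next_id, name, Role.PHYSICS.value))
        next_id += 1

    _fill(labels, _WM_BOX, next_id)
    rows.append((next_id, "white_matter", Role.WM.value))
    next_id += 1
    _fill(labels, _VENT_BOX, next_id)
    rows.append((next_id, "ventricle", Role.VENTRICLE.value))

    table = pd.DataFrame(rows, columns=["label_id", "name", "role"])
    atlas = ParcelAtlas(labels, table)
    for pid in atlas.ids_for_role(Role.PHYSICS):
        assert int(atlas.mask(pid).sum()) >= 200
    return atlas


def _core_box(parcel_box):
    out = []
    for (lo, _), off, size in zip(parcel_box, _CORE_OFFSET, _CORE_SIZE):
        out.append((lo + off, lo + off + size - 1))
    return tuple(out)


def planted_core_mask(params: CohortParams,
                      displacement_vox=(0, 0, 0)) -> np.ndarray:
    """Union of the four displaced physics cores for one subject."""
    m = np.zeros(params.grid_dims, dtype=bool)
    d = np.asarray(displacement_vox, dtype=int)
    for box in _PHYSICS_BOXES.values():
        (x0, x1), (y0, y1), (z0, z1) = _core_box(box)
        m[x0 + d[0]:x1 + d[0] + 1, y0 + d[1]:y1 + d[1] + 1,
          z0 + d[2]:z1 + d[2] + 1] = True
    return m


def colour_core_mask(params: CohortParams) -> np.ndarray:
    """Fixed colour-responsive control voxels, disjoint from every physics
    parcel (hence from any subject's displaced physics core)."""
    m = np.zeros(params.grid_dims, dtype=bool)
    _fill(m, _COLOUR_BOX, True)
    return m


def clip_displacement_vox(displacement_mm, params: CohortParams) -> np.ndarray:
    """Round a mm displacement to voxels and clip to the core margins so the
    displaced core stays inside its parcel."""
    voxel = np.asarray(params.voxel_size_mm, dtype=float)
    d = np.round(np.asarray(displacement_mm, dtype=float) / voxel).astype(int)
    margins = np.array(_CORE_OFFSET)
    return np.clip(d, -margins, margins)


# ---------------------------------------------------------------------------
# Timeseries machinery


def _ar1(rng: np.random.Generator, phi: float, innovation_sd: float,
         shape: tuple[int, ...]) -> np.ndarray:
    """Stationary AR(1) noise along the last axis."""
    T = shape[-1]
    x = np.empty(shape)
    stat_sd = innovation_sd / np.sqrt(1.0 - phi ** 2) if phi else innovation_sd
    x[..., 0] = rng.standard_normal(shape[:-1]) * stat_sd
    eps = rng.standard_normal(shape) * innovation_sd
    for t in range(1, T):
        x[..., t] = phi * x[..., t - 1] + eps[..., t]
    return x


def _latent(rng: np.random.Generator, phi: float, T: int) -> np.ndarray:
    """Unit-stationary-variance AR(1) latent series."""
    return _ar1(rng, phi, np.sqrt(1.0 - phi ** 2), (T,))


def _motion(rng: np.random.Generator, T: int, spike_rate: float) -> MotionTable:
    """Smooth low-amplitude drift with occasional > 2 mm translation spikes."""
    drift = np.cumsum(rng.standard_normal((T, 6)) * 0.01, axis=0)
    drift[:, :3] *= 0.5                       # rotations drift less (deg)
    spikes = rng.random(T) < spike_rate
    spikes[0] = False
    vals = drift.copy()
    offset = np.zeros(6)
    for t in range(T):
        if spikes[t]:
            offset[3] += rng.choice([-1.0, 1.0]) * (2.5 + rng.random())
        vals[t] += offset
    return MotionTable(vals)


def simulate_rest_run(profile: SubjectProfile, atlas: ParcelAtlas,
                      params: CohortParams, run_seed: int
                      ) -> tuple[VolumeSeries, MotionTable]:
    """One rest run with the subject's planted dACC-physics coupling."""
    rng = np.random.default_rng(run_seed)
    T = params.n_rest_volumes
    dims = params.grid_dims
    a, phi, sigma = params.seed_coupling, params.ar1_phi, params.noise_sd

    data = _ar1(rng, phi, sigma, (*dims, T))
    s = _latent(rng, phi, T)        # dACC unique latent, both hemispheres
    g = _latent(rng, phi, T)        # component common to all 8 ACC parcels
    c_wm = _latent(rng, phi, T)
    c_vent = _latent(rng, phi, T)

    dacc = atlas.mask(Role.ACC_DACC)
    wm = atlas.mask(Role.WM)
    vent = atlas.mask(Role.VENTRICLE)
    planted = planted_core_mask(params, profile.displacement_vox)
    grey = (atlas.labels > 0) & ~wm & ~vent

    data[dacc] += s + g
    for other_id in atlas.ids_for_role(Role.ACC_OTHER):
        data[atlas.mask(other_id)] += _latent(rng, phi, T) + g
    data[planted] += a * s
    data[wm] += c_wm
    data[vent] += c_vent
    data[grey] += 0.2 * a * (c_wm + c_vent)

    vol = VolumeSeries(data, params.voxel_size_mm, params.tr_s)
    motion = _motion(rng, T, params.motion_spike_rate)
    return vol, motion


def simulate_task_run(profile: SubjectProfile, atlas: ParcelAtlas,
                      design: BlockDesign, params: CohortParams, run_seed: int
                      ) -> tuple[VolumeSeries, MotionTable]:
    """One task run: planted cores respond to the physics cue, a disjoint
    control set to the colour cue, on AR(1) noise."""
    if abs(design.total_duration_s / params.tr_s
           - round(design.total_duration_s / params.tr_s)) > 1e-9:
        raise ValueError("design duration is not a multiple of TR")
    rng = np.random.default_rng(run_seed)
    T = design.n_volumes
    dims = params.grid_dims

    X = convolve_design(design)
    physics_reg = X["physics_cue"].to_numpy()
    colour_reg = X["colour_cue"].to_numpy()

    data = _ar1(rng, params.ar1_phi, params.noise_sd, (*dims, T))
    planted = planted_core_mask(params, profile.displacement_vox)
    control = colour_core_mask(params)
    data[planted] += params.activation_beta * physics_reg
    data[control] += params.activation_beta * colour_reg

    vol = VolumeSeries(data, params.voxel_size_mm, params.tr_s)
    motion = _motion(rng, T, params.motion_spike_rate)
    return vol, motion


def make_cohort(params: CohortParams) -> tuple[list[SubjectDataset], ParcelAtlas]:
    """Generate the full cohort; bit-identical for a fixed master_seed.

    Subject displacements are i.i.d. Gaussian in mm (SD displacement_sd_mm
    per axis), rounded to voxels and clipped to the core margins; one
    displacement serves both that subject's rest coupling targets and task
    activation — the planted fingerprint.
    """
    atlas = make_atlas(params)
    root = np.random.SeedSequence(params.master_seed)
    subj_seqs = root.spawn(params.n_subjects)
    datasets = []
    for i, seq in enumerate(subj_seqs):
        rng = np.random.default_rng(seq)
        disp_mm = rng.normal(0.0, params.displacement_sd_mm, size=3)
        disp_vox = clip_displacement_vox(disp_mm, params)
        n_runs = params.rest_runs_per_subject + params.task_runs_per_subject
        run_seeds = [int(s) for s in
                     rng.integers(0, 2 ** 31 - 1, size=n_runs + 1)]
        profile = SubjectProfile(
            subject_id=f"sub-{i + 1:02d}",
            displacement_vox=disp_vox,
            displacement_mm=disp_vox * np.asarray(params.voxel_size_mm),
            rest_seeds=run_seeds[:params.rest_runs_per_subject],
            task_seeds=run_seeds[params.rest_runs_per_subject:n_runs],
        )
        rest = [simulate_rest_run(profile, atlas, params, s)
                for s in profile.rest_seeds]
        designs, task = [], []
        for s in profile.task_seeds:
            d = build_block_design(seed=s)
            designs.append(d)
            task.append(simulate_task_run(profile, atlas, d, params, s))
        datasets.append(SubjectDataset(profile, rest, task, designs))
    return datasets, atlas


def write_cohort(datasets: list[SubjectDataset], atlas: ParcelAtlas,
                 params: CohortParams, out_dir: str | Path) -> Path:
    """Write per-subject NIfTI runs, motion TSVs, the atlas and a YAML
    manifest recording all seeds and true displacements."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_atlas(atlas, out / "atlas.nii.gz", out / "atlas_labels.tsv",
                params.voxel_size_mm)
    manifest = {"params": asdict(params), "subjects": []}
    for ds in datasets:
        p = ds.profile
        sdir = out / p.subject_id
        sdir.mkdir(exist_ok=True)
        for k, (vol, mot) in enumerate(ds.rest_runs, 1):
            write_volume(vol, sdir / f"rest_run-{k}.nii.gz")
            write_motion_table(mot, sdir / f"rest_run-{k}_motion.tsv")
        for k, ((vol, mot), d) in enumerate(zip(ds.task_runs, ds.task_designs), 1):
            write_volume(vol, sdir / f"task_run-{k}.nii.gz")
            write_motion_table(mot, sdir / f"task_run-{k}_motion.tsv")
            d.write_events_tsv(sdir / f"task_run-{k}_events.tsv")
        manifest["subjects"].append({
            "subject_id": p.subject_id,
            "displacement_vox": [int(v) for v in p.displacement_vox],
            "displacement_mm": [float(v) for v in p.displacement_mm],
            "rest_seeds": p.rest_seeds,
            "task_seeds": p.task_seeds,
        })
    path = out / "cohort.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path
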