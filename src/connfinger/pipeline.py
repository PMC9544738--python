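"""End-to-end analysis runs on a cohort (synthetic or loaded from disk).

These functions chain the stage modules: rest preprocessing -> dACC seed
connectivity -> Fisher z per subject; task GLM -> physics - colour contrast
per subject; then the overlap curve, the fingerprint model and the
split-half reliability analysis. They are what the CLI and the acceptance
script call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectivity import fisher_z, group_ttest, seed_connectivity
from .fingerprint import (FingerprintModel, FingerprintResults, OverlapCurve,
                          overlap_curve, rm_anova, spatial_correlation, _zr)
from .glm import subject_contrast
from .preprocess import PreprocConfig, framewise_displacement, preprocess_rest_run
from .synth import CohortParams, SubjectDataset
from .volio import MotionTable, ParcelAtlas, Role, StatMap, VolumeSeries, \
    mask_mean_timeseries

__all__ = [
    "subject_connectivity_zmap",
    "cohort_maps",
    "region_masks_from_parcels",
    "fit_fingerprint",
    "group_overlap_curves",
    "split_half_reliability",
]


def subject_connectivity_zmap(vol: VolumeSeries, motion: MotionTable,
                              atlas: ParcelAtlas, hemisphere: str | None = None,
                              cfg: PreprocConfig | None = None,
                              source: str = "subject") -> StatMap:
    """Preprocess one rest run and return the dACC seed-connectivity z-map.

    ``hemisphere`` selects the left/right dACC parcel by name substring
    ("L"/"R"); None pools both dACC parcels into one seed.
    """
    resid, _ = preprocess_rest_run(vol, motion, atlas, cfg)
    seed_ids = atlas.ids_for_role(Role.ACC_DACC)
    if hemisphere is not None:
        seed_ids = [i for i in seed_ids
                    if f"_{hemisphere.lower()}_" in atlas.name_of(i).lower()]
        if not seed_ids:
            raise ValueError(f"no dACC parcel for hemisphere {hemisphere!r}")
    seed_mask = np.isin(atlas.labels, seed_ids)
    seed = mask_mean_timeseries(resid, seed_mask)
    rmap = seed_connectivity(resid, seed, source=source)
    return fisher_z(rmap)


def _mean_zmap(zmaps: list[StatMap], source: str) -> StatMap:
    return StatMap(np.mean([z.data for z in zmaps], axis=0), kind="z",
                   source=source)


def cohort_maps(datasets: list[SubjectDataset], atlas: ParcelAtlas,
                cfg: PreprocConfig | None = None
                ) -> tuple[dict[str, StatMap], dict[str, StatMap], dict[str, float]]:
    """Per-subject connectivity z-maps, task contrast maps and mean FD.

    Connectivity z-maps average across a subject's rest runs; contrasts
    average across task runs; mean FD pools all runs.
    """
    conn, contrast, fd = {}, {}, {}
    for ds in datasets:
        sid = ds.profile.subject_id
        zmaps = [subject_connectivity_zmap(v, m, atlas, cfg=cfg, source=sid)
                 for v, m in ds.rest_runs]
        conn[sid] = _mean_zmap(zmaps, sid)
        contrast[sid] = subject_contrast(ds.task_runs, ds.task_designs,
                                         source=sid)
        fds = [framewise_displacement(m).mean()
               for _, m in (*ds.rest_runs, *ds.task_runs)]
        fd[sid] = float(np.mean(fds))
    return conn, contrast, fd


def region_masks_from_parcels(atlas: ParcelAtlas,
                              significant: np.ndarray | None = None
                              ) -> dict[str, np.ndarray]:
    """One mask per physics parcel, optionally intersected with a
    group-significance mask (the functionally defined physics ROIs)."""
    out = {}
    for pid in atlas.ids_for_role(Role.PHYSICS):
        m = atlas.mask(pid)
        if significant is not None:
            inter = m & np.asarray(significant, dtype=bool)
            if inter.sum() >= 10:
                m = inter
        out[atlas.name_of(pid)] = m
    return out


def fit_fingerprint(datasets: list[SubjectDataset], atlas: ParcelAtlas,
                    cfg: PreprocConfig | None = None,
                    restrict_to_significant: bool = False
                    ) -> FingerprintResults:
    """Full fingerprint analysis on a cohort.

    With ``restrict_to_significant`` the region masks are intersected with
    the group task-contrast t > 3.3 voxels; otherwise the parcels are used
    whole (robust at small n).
    """
    conn, contrast, fd = cohort_maps(datasets, atlas, cfg)
    significant = None
    if restrict_to_significant:
        tmap = group_ttest(list(contrast.values()))
        significant = tmap.data > 3.3
    masks = region_masks_from_parcels(atlas, significant)
    return FingerprintModel(conn, contrast, masks, fd).fit()


def group_overlap_curves(datasets: list[SubjectDataset], atlas: ParcelAtlas,
                         cfg: PreprocConfig | None = None
                         ) -> dict[str, OverlapCurve]:
    """Per-hemisphere group overlap curves.

    Each hemisphere's subject z-maps are averaged into a group z-map, then
    swept against the physics parcels within the fronto-parietal search
    mask.
    """
    search = atlas.mask(Role.SEARCHMASK)
    physics = atlas.mask(Role.PHYSICS)
    curves = {}
    for hemi in ("L", "R"):
        zmaps = []
        for ds in datasets:
            per_run = [subject_connectivity_zmap(v, m, atlas, hemisphere=hemi,
                                                 cfg=cfg)
                       for v, m in ds.rest_runs]
            zmaps.append(_mean_zmap(per_run, ds.profile.subject_id))
        group = _mean_zmap(zmaps, "group")
        curves[hemi] = overlap_curve(group, physics, search,
                                     seed_label="dACC", hemisphere=hemi)
    return curves


def split_half_reliability(datasets: list[SubjectDataset], atlas: ParcelAtlas,
                           cfg: PreprocConfig | None = None
                           ) -> tuple[pd.DataFrame, "AnovaResult"]:
    """Split-half analogue of the fingerprint: condition x hemisphere ANOVA.

    Each subject's first rest run is split into halves; the L and R dACC
    connectivity maps are computed per half. within = z of the spatial
    correlation of a subject's first and second half; between = mean z of
    the subject's first half against every other subject's first half.
    Spatial correlations are taken over the physics parcels.
    """
    from .fingerprint import AnovaResult  # local: avoid cycle in type refs

    physics = atlas.mask(Role.PHYSICS)
    halves: dict[str, dict[str, list[StatMap]]] = {"L": {}, "R": {}}
    for ds in datasets:
        vol, motion = ds.rest_runs[0]
        T = vol.n_volumes
        if T < 32:
            raise ValueError("run too short to split")
        mid = T // 2
        parts = [(vol.with_data(vol.data[..., :mid]),
                  MotionTable(motion.values[:mid])),
                 (vol.with_data(vol.data[..., mid:]),
                  MotionTable(motion.values[mid:]))]
        for hemi in ("L", "R"):
            halves[hemi][ds.profile.subject_id] = [
                subject_connectivity_zmap(v, m, atlas, hemisphere=hemi, cfg=cfg)
                for v, m in parts]

    rows = []
    for hemi in ("L", "R"):
        maps = halves[hemi]
        subjects = sorted(maps)
        for i in subjects:
            within = _zr(spatial_correlation(maps[i][0], maps[i][1], physics))
            between = np.mean([
                _zr(spatial_correlation(maps[i][0], maps[j][0], physics))
                for j in subjects if j != i])
            rows.extend([
                {"subject": i, "hemisphere": hemi, "condition": "within",
                 "z": within},
                {"subject": i, "hemisphere": hemi, "condition": "between",
                 "z": float(between)},
            ])
    table = pd.DataFrame(rows)
    anova = rm_anova(table, dv="z", subject="subject",
                     within=("condition", "hemisphere"))
    return table, anova
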