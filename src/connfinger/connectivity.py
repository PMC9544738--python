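"""Seed-based voxelwise connectivity and group inference.

Per-voxel Pearson correlation with a seed timeseries, Fisher z-transform,
one-sample group t-test, and familywise-error control by Monte-Carlo
cluster-extent correction: smooth Gaussian null fields are simulated at the
estimated residual smoothness, thresholded at the primary voxel p, and the
(1 - alpha) quantile of the null maximum cluster size becomes the critical
extent for the real map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .preprocess import FWHM_TO_SIGMA
from .volio import StatMap, VolumeSeries

__all__ = [
    "ClusterCorrectionConfig",
    "seed_connectivity",
    "fisher_z",
    "group_ttest",
    "estimate_smoothness",
    "cluster_correct",
]

R_CLIP = 1.0 - 1e-7
T_SENTINEL = 1e6  # stands in for +-inf at zero-variance voxels

# 6-connectivity (face adjacency): AFNI's NN1 rule
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class ClusterCorrectionConfig:
    """Primary threshold, cluster alpha and Monte-Carlo settings.

    voxel_p: primary uncorrected voxel threshold (default 0.001).
    alpha: cluster-level familywise error rate (default 0.05).
    n_sims: number of simulated null fields (>= 100).
    two_sided: apply the primary threshold to |t| (default); the run reports
        both signs and cluster tables flag the sign either way.
    """

    voxel_p: float = 0.001
    alpha: float = 0.05
    n_sims: int = 1000
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.voxel_p < 1:
            raise ValueError("voxel_p must lie in (0, 1)")
        if self.n_sims < 100:
            raise ValueError("n_sims must be >= 100")


def seed_connectivity(vol: VolumeSeries, seed_series: np.ndarray,
                      source: str = "group") -> StatMap:
    """Pearson r between the seed series and every voxel series.

    Constant voxels get r = 0; the number of such voxels is reported via a
    warning. Invariant under affine rescaling of either series.
    """
    seed = np.asarray(seed_series, dtype=float)
    T = vol.n_volumes
    if seed.shape != (T,):
        raise ValueError("seed length must equal the number of volumes")
    if T < 10:
        raise ValueError("need at least 10 volumes for seed connectivity")
    s = seed - seed.mean()
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        raise ValueError("seed series is constant")
    Y = vol.data.reshape(-1, T)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    y_norm = np.linalg.norm(Yc, axis=1)
    flat = y_norm == 0
    n_flat = int(flat.sum())
    if n_flat:
        warnings.warn(f"{n_flat} constant voxel(s) assigned r=0", stacklevel=2)
    r = np.zeros(Y.shape[0])
    ok = ~flat
    r[ok] = (Yc[ok] @ s) / (y_norm[ok] * s_norm)
    r = np.clip(r, -1.0, 1.0)
    return StatMap(r.reshape(vol.shape3d), kind="r", source=source)


def fisher_z(rmap: StatMap) -> StatMap:
    """Variance-stabilising z = atanh(r), with |r| clipped below 1."""
    if rmap.kind != "r":
        raise ValueError("fisher_z expects an r map")
    r = np.clip(rmap.data, -R_CLIP, R_CLIP)
    return rmap.with_data(np.arctanh(r), kind="z")


def group_ttest(maps: list[StatMap]) -> StatMap:
    """Voxelwise one-sample t against zero across subjects; df = n - 1.

    Voxels with zero between-subject variance get a signed large-magnitude
    sentinel (or 0 when the mean is also 0) and are counted in a warning.
    """
    if len(maps) < 2:
        raise ValueError("group t-test needs at least 2 maps")
    shape = maps[0].data.shape
    for m in maps[1:]:
        if m.data.shape != shape:
            raise ValueError("maps are not on a common grid")
    stack = np.stack([m.data for m in maps])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    degenerate = sd == 0
    n_deg = int(degenerate.sum())
    if n_deg:
        warnings.warn(f"{n_deg} zero-variance voxel(s) set to sentinel t",
                      stacklevel=2)
    t = np.zeros(shape)
    ok = ~degenerate
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    t[degenerate] = np.sign(mean[degenerate]) * T_SENTINEL
    return StatMap(t, kind="t", df=n - 1, source="group")


def estimate_smoothness(residual_maps: list[np.ndarray] | list[StatMap],
                        voxel_size_mm) -> np.ndarray:
    """Gaussian-equivalent FWHM (mm, per axis) from spatial first differences.

    For a stationary field with Gaussian autocorrelation, the lag-1
    correlation rho = 1 - var(diff) / (2 var) inverts to
    FWHM = voxel * sqrt(-2 ln 2 / ln rho). On a lattice, smoothness below
    one voxel is not identifiable (white noise gives rho ~ 0), so estimates
    are floored at the voxel size; the floor is continuous at rho = 1/4,
    where the formula itself returns exactly one voxel. Axes are averaged
    across maps.
    """
    if not residual_maps:
        raise ValueError("need at least one residual map")
    voxel = np.asarray(voxel_size_mm, dtype=float).reshape(3)
    per_map = []
    for m in residual_maps:
        x = m.data if isinstance(m, StatMap) else np.asarray(m, dtype=float)
        var = x.var()
        if var == 0:
            raise ValueError("constant map has no estimable smoothness")
        fwhm_vox = np.empty(3)
        for ax in range(3):
            dvar = np.diff(x, axis=ax).var()
            rho = 1.0 - dvar / (2.0 * var)
            if rho <= 0.25:
                fwhm_vox[ax] = 1.0
            else:
                fwhm_vox[ax] = np.sqrt(-2.0 * np.log(2.0) / np.log(rho))
        per_map.append(fwhm_vox)
    return np.mean(per_map, axis=0) * voxel


def _threshold_mask(field: np.ndarray, crit: float, two_sided: bool) -> np.ndarray:
    return (np.abs(field) > crit) if two_sided else (field > crit)


def _max_cluster_size(binary: np.ndarray) -> int:
    labelled, n = ndimage.label(binary, structure=_STRUCT_6)
    if n == 0:
        return 0
    return int(np.max(ndimage.sum_labels(binary, labelled, range(1, n + 1))))


def simulate_null_max_clusters(mask: np.ndarray, fwhm_mm, voxel_size_mm,
                               z_crit: float, n_sims: int, rng,
                               two_sided: bool = True) -> np.ndarray:
    """Max suprathreshold cluster size in each of n_sims smooth null fields.

    Fields are white Gaussian noise smoothed to the requested FWHM and
    re-standardised to unit variance inside the mask before thresholding.
    """
    voxel = np.asarray(voxel_size_mm, dtype=float).reshape(3)
    sigma_vox = np.asarray(fwhm_mm, dtype=float).reshape(3) * FWHM_TO_SIGMA / voxel
    out = np.empty(n_sims, dtype=int)
    for i in range(n_sims):
        field = rng.standard_normal(mask.shape)
        if np.any(sigma_vox > 0):
            field = ndimage.gaussian_filter(field, sigma=sigma_vox)
        inside = field[mask]
        field = (field - inside.mean()) / inside.std()
        supra = _threshold_mask(field, z_crit, two_sided) & mask
        out[i] = _max_cluster_size(supra)
    return out


def critical_cluster_size(null_max_sizes: np.ndarray, alpha: float) -> int:
    """Smallest extent whose null exceedance probability is <= alpha."""
    sizes = np.asarray(null_max_sizes)
    for c in range(1, int(sizes.max()) + 2):
        if np.mean(sizes >= c) <= alpha:
            return c
    return int(sizes.max()) + 1


def cluster_correct(tmap: StatMap, mask: np.ndarray,
                    cfg: ClusterCorrectionConfig, fwhm_mm,
                    voxel_size_mm, rng=None
                    ) -> tuple[StatMap, pd.DataFrame]:
    """Retain suprathreshold clusters larger than the Monte-Carlo critical size.

    Returns a binary survival map plus a table (cluster_id, n_voxels, sign,
    peak_t, x, y, z, critical size). The primary threshold is the t quantile
    of cfg.voxel_p at the map's df (two-sided by default).
    """
    if tmap.kind != "t" or tmap.df is None:
        raise ValueError("cluster correction needs a t map with known df")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tmap.data.shape:
        raise ValueError("mask grid mismatch")
    if not mask.any():
        raise ValueError("mask is empty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    p = cfg.voxel_p / 2 if cfg.two_sided else cfg.voxel_p
    t_crit = stats.t.isf(p, tmap.df)
    z_crit = stats.norm.isf(p)
    null_sizes = simulate_null_max_clusters(
        mask, fwhm_mm, voxel_size_mm, z_crit, cfg.n_sims, rng, cfg.two_sided)
    crit = critical_cluster_size(null_sizes, cfg.alpha)

    supra = _threshold_mask(tmap.data, t_crit, cfg.two_sided) & mask
    labelled, n = ndimage.label(supra, structure=_STRUCT_6)
    keep = np.zeros_like(supra)
    rows = []
    cid = 0
    for lab in range(1, n + 1):
        members = labelled == lab
        size = int(members.sum())
        if size < crit:
            continue
        cid += 1
        keep |= members
        vals = tmap.data[members]
        peak = vals[np.argmax(np.abs(vals))]
        idx = np.argwhere(members)[np.argmax(np.abs(vals))]
        rows.append({"cluster_id": cid, "n_voxels": size,
                     "sign": int(np.sign(peak)), "peak_t": float(peak),
                     "x": int(idx[0]), "y": int(idx[1]), "z": int(idx[2]),
                     "critical_size": crit})
    table = pd.DataFrame(rows, columns=["cluster_id", "n_voxels", "sign",
                                        "peak_t", "x", "y", "z", "critical_size"])
    return StatMap(keep.astype(float), kind="t", df=tmap.df,
                   source=tmap.source), table
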