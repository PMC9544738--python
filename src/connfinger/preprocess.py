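"""Rest/task preprocessing on pre-aligned volumes.

The default rest chain is censor -> smooth -> band-pass -> nuisance
regression (motion + derivatives + WM + ventricle means) -> common-ACC-
variance regression. Every step is a pure function on
:class:`~connfinger.volio.VolumeSeries`; :func:`preprocess_rest_run` wires
them together and reports what it did.

Motion censoring uses framewise displacement (FD): the sum of absolute
backward differences of the three translations plus the three rotations
converted to arc length on a 50 mm sphere. The censor thresholds are 2 mm
for rest runs and 3 mm for task runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .volio import MotionTable, ParcelAtlas, Role, VolumeSeries, roi_mean_timeseries

__all__ = [
    "PreprocConfig",
    "framewise_displacement",
    "censor",
    "bandpass",
    "motion_regressors",
    "nuisance_regress",
    "regress_common_roi_variance",
    "smooth_gaussian",
    "preprocess_rest_run",
]

FD_SPHERE_RADIUS_MM = 50.0
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PreprocConfig:
    """Tunable preprocessing parameters.

    fwhm_mm: Gaussian smoothing kernel FWHM (4 mm default).
    band_low_hz / band_high_hz: band-pass edges (0.009-0.08 Hz default).
    censor_threshold_mm: FD threshold; 2 mm for rest, 3 mm for task.
    include_motion_derivatives: add backward differences of the six motion
        parameters as extra nuisance columns.
    censor_after_filtering: censor volumes after (default) or before the
        temporal filter; recorded in the run report either way.
    common_variance: "mean" removes the mean of the 8 ACC parcel-mean
        series; "pc1" removes their first principal component.
    """

    fwhm_mm: float = 4.0
    band_low_hz: float = 0.009
    band_high_hz: float = 0.08
    censor_threshold_mm: float = 2.0
    include_motion_derivatives: bool = True
    censor_after_filtering: bool = True
    common_variance: str = "mean"

    def validate(self, tr_s: float) -> None:
        nyquist = 1.0 / (2.0 * tr_s)
        if not 0 < self.band_low_hz < self.band_high_hz < nyquist:
            raise ValueError(
                f"band ({self.band_low_hz}, {self.band_high_hz}) Hz must lie inside "
                f"(0, {nyquist}) Hz for TR {tr_s} s"
            )
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")
        if self.common_variance not in ("mean", "pc1"):
            raise ValueError("common_variance must be 'mean' or 'pc1'")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def framewise_displacement(motion: MotionTable) -> np.ndarray:
    """Per-volume FD in mm; FD(0) = 0.

    FD(t) = sum |delta translation_i| + sum |delta rotation_i| * (pi/180) * 50,
    rotations converted to arc length on a 50 mm sphere.
    """
    if len(motion) < 2:
        raise ValueError("framewise displacement needs T >= 2")
    dt = np.abs(np.diff(motion.translations_mm, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(motion.rotations_deg, axis=0)).sum(axis=1)
    dr_mm = dr * np.pi / 180.0 * FD_SPHERE_RADIUS_MM
    return np.concatenate([[0.0], dt + dr_mm])


def censor(vol: VolumeSeries, fd: np.ndarray, threshold_mm: float
           ) -> tuple[VolumeSeries, np.ndarray]:
    """Drop volumes with FD > threshold; return the kept new->old index map.

    The same ``kept`` indices must be applied to any regressor matrix fit
    against the censored series.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.shape[0] != vol.n_volumes:
        raise ValueError("FD length does not match volume count")
    kept = np.flatnonzero(fd <= threshold_mm)
    if kept.size == 0:
        raise ValueError("all volumes censored")
    if kept.size == vol.n_volumes:
        return vol, kept
    return vol.with_data(vol.data[..., kept]), kept


def bandpass(series: np.ndarray, tr_s: float, low_hz: float = 0.009,
             high_hz: float = 0.08) -> np.ndarray:
    """Zero-phase order-2 Butterworth band-pass along the last axis.

    Forward-backward filtering (filtfilt) doubles the effective order and
    removes phase distortion; the DC component is rejected by the high-pass
    edge. Accepts 1D series or any array with time last.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 16:
        raise ValueError("band-pass needs at least 16 samples")
    nyquist = 1.0 / (2.0 * tr_s)
    if not 0 < low_hz < high_hz < nyquist:
        raise ValueError(f"band ({low_hz}, {high_hz}) outside (0, {nyquist}) Hz")
    sos = signal.butter(2, [low_hz / nyquist, high_hz / nyquist],
                        btype="bandpass", output="sos")
    return signal.sosfiltfilt(sos, series, axis=-1)


def motion_regressors(motion: MotionTable, include_derivatives: bool = True
                      ) -> np.ndarray:
    """Six motion parameters, optionally plus their backward differences.

    Derivatives are first backward differences with a zero first row.
    """
    cols = [motion.values]
    if include_derivatives:
        deriv = np.diff(motion.values, axis=0, prepend=motion.values[:1])
        cols.append(deriv)
    return np.hstack(cols)


def _as_matrix(regressors) -> tuple[np.ndarray, list[str]]:
    if isinstance(regressors, pd.DataFrame):
        return regressors.to_numpy(dtype=float), [str(c) for c in regressors.columns]
    X = np.asarray(regressors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the deficiency for the error message
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j])
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")


def nuisance_regress(vol: VolumeSeries, regressors) -> VolumeSeries:
    """OLS residuals of every voxel series on [intercept | regressors].

    Idempotent: residuals are orthogonal to the regressors, so a second
    pass with the same matrix changes nothing.
    """
    X, names = _as_matrix(regressors)
    if X.shape[0] != vol.n_volumes:
        raise ValueError("regressor rows must equal the number of volumes")
    X = np.column_stack([np.ones(X.shape[0]), X])
    _check_rank(X, ["intercept", *names])
    Y = vol.data.reshape(-1, vol.n_volumes).T          # (T, V)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return vol.with_data(resid.T.reshape(vol.data.shape))


def common_acc_series(vol: VolumeSeries, atlas: ParcelAtlas, how: str = "mean"
                      ) -> np.ndarray:
    """Shared component of the 8 ACC parcel-mean series (mean or PC1)."""
    ids = atlas.ids_for_role(Role.ACC_DACC) + atlas.ids_for_role(Role.ACC_OTHER)
    if not ids:
        raise ValueError("atlas has no ACC parcels")
    series = np.stack([roi_mean_timeseries(vol, atlas, i) for i in ids])  # (8, T)
    if how == "mean":
        return series.mean(axis=0)
    if how == "pc1":
        centred = series - series.mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        return vt[0] * np.sign(vt[0] @ centred.mean(axis=0) + 1e-30)
    raise ValueError("how must be 'mean' or 'pc1'")


def regress_common_roi_variance(vol: VolumeSeries, atlas: ParcelAtlas,
                                how: str = "mean") -> VolumeSeries:
    """Remove the ACC parcels' common component from every voxel.

    Leaves each parcel's connectivity reflecting its unique variance; after
    this step every voxel series is orthogonal to the removed component.
    """
    return nuisance_regress(vol, common_acc_series(vol, atlas, how))


def smooth_gaussian(vol: VolumeSeries, fwhm_mm: float) -> VolumeSeries:
    """Per-volume 3D Gaussian smoothing with an isotropic-in-mm kernel.

    sigma per axis in voxels is fwhm_mm / (2*sqrt(2*ln 2)) / voxel_size;
    fwhm 0 is the identity. The kernel is normalised, so the image sum is
    preserved for interior structure.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return vol
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vol.voxel_size_mm
    out = ndimage.gaussian_filter(vol.data, sigma=(*sigma_vox, 0.0), mode="constant")
    return vol.with_data(out)


def preprocess_rest_run(vol: VolumeSeries, motion: MotionTable,
                        atlas: ParcelAtlas, cfg: PreprocConfig | None = None
                        ) -> tuple[VolumeSeries, dict]:
    """Full rest chain; returns residuals and a QC report.

    Nuisance regressors (motion, derivatives, WM and ventricle mean series)
    are band-passed with the data so the regression cannot reintroduce
    filtered frequencies. The report records the step order, config hash,
    kept volume count and FD summary.
    """
    cfg = cfg or PreprocConfig()
    cfg.validate(vol.tr_s)
    fd = framewise_displacement(motion)

    order: list[str] = []

    def build_nuisance(v: VolumeSeries, kept: np.ndarray) -> np.ndarray:
        # motion is filtered at full length, then censored to match the data;
        # tissue series come from v, which has already been filtered/censored
        mot = motion_regressors(motion, cfg.include_motion_derivatives)
        mot = bandpass(mot.T, vol.tr_s, cfg.band_low_hz, cfg.band_high_hz).T[kept]
        wm_ids = atlas.ids_for_role(Role.WM)
        vent_ids = atlas.ids_for_role(Role.VENTRICLE)
        tissue = [roi_mean_timeseries(v, atlas, i) for i in (*wm_ids, *vent_ids)]
        return np.column_stack([mot, *[t[:, None] for t in tissue]]) if tissue else mot

    if cfg.censor_after_filtering:
        v = smooth_gaussian(vol, cfg.fwhm_mm); order.append("smooth")
        v = v.with_data(bandpass(v.data, vol.tr_s, cfg.band_low_hz, cfg.band_high_hz))
        order.append("bandpass")
        v, kept = censor(v, fd, cfg.censor_threshold_mm); order.append("censor")
    else:
        v, kept = censor(vol, fd, cfg.censor_threshold_mm); order.append("censor")
        v = smooth_gaussian(v, cfg.fwhm_mm); order.append("smooth")
        v = v.with_data(bandpass(v.data, vol.tr_s, cfg.band_low_hz, cfg.band_high_hz))
        order.append("bandpass")

    X = build_nuisance(v, kept)
    v = nuisance_regress(v, X); order.append("nuisance_regress")
    v = regress_common_roi_variance(v, atlas, cfg.common_variance)
    order.append("regress_common_roi_variance")

    report = {
        "order": order,
        "config_hash": cfg.config_hash(),
        "n_volumes_in": vol.n_volumes,
        "n_volumes_kept": int(kept.size),
        "fd_mean_mm": float(fd.mean()),
        "fd_max_mm": float(fd.max()),
        "n_nuisance_columns": int(X.shape[1]),
    }
    return v, report
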