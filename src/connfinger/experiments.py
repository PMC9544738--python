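"""Parameter-recovery experiments on synthetic cohorts.

Each function simulates cohorts under the generator's default study
conditions, runs the full pipeline and measures how reliably a planted
quantity is recovered. They back the package's validation suite and the
reproduction script; problem sizes default to desk scale (tens of cohorts
of 8-10 subjects on a 20^3 grid).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .connectivity import critical_cluster_size, simulate_null_max_clusters
from .pipeline import fit_fingerprint, group_overlap_curves, split_half_reliability
from .synth import CohortParams, make_cohort, _ar1, _latent

__all__ = [
    "fingerprint_recovery",
    "fingerprint_null_calibration",
    "split_half_power",
    "overlap_endpoint",
    "cluster_fwe",
    "planted_r_error",
]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n)]


def fingerprint_recovery(n_cohorts: int = 20, n_subjects: int = 8,
                         seed: int = 0) -> dict:
    """Fraction of cohorts whose mean within_z exceeds mean between_z.

    Default conditions: planted displacement SD 6 mm, coupling a = 0.5,
    AR(1) noise. Also reports how often the RM-ANOVA condition effect is
    significant at 0.05.
    """
    wins, sig, gaps = [], [], []
    for s in _spawn_seeds(seed, n_cohorts):
        params = CohortParams(n_subjects=n_subjects, master_seed=s)
        datasets, atlas = make_cohort(params)
        res = fit_fingerprint(datasets, atlas)
        wins.append(res.gap > 0)
        sig.append(res.anova.effect("condition")["p"] < 0.05)
        gaps.append(res.gap)
    return {"n_cohorts": n_cohorts, "within_gt_between_rate": float(np.mean(wins)),
            "condition_significant_rate": float(np.mean(sig)),
            "mean_gap_z": float(np.mean(gaps))}


def fingerprint_null_calibration(n_cohorts: int = 20, n_subjects: int = 8,
                                 seed: int = 0) -> dict:
    """Same pipeline with displacement SD 0: no individual differences.

    The within-minus-between gap is then centred on zero and the condition
    effect should reject at roughly the nominal 5% rate.
    """
    sig, gaps = [], []
    for s in _spawn_seeds(seed + 1, n_cohorts):
        params = CohortParams(n_subjects=n_subjects, master_seed=s,
                              displacement_sd_mm=0.0)
        datasets, atlas = make_cohort(params)
        res = fit_fingerprint(datasets, atlas)
        sig.append(res.anova.effect("condition")["p"] < 0.05)
        gaps.append(res.gap)
    return {"n_cohorts": n_cohorts,
            "condition_significant_rate": float(np.mean(sig)),
            "mean_gap_z": float(np.mean(gaps))}


def split_half_power(n_cohorts: int = 20, n_subjects: int = 10,
                     seed: int = 0) -> dict:
    """Power of the split-half within-vs-between reliability check.

    Mirrors the 10-subject design: one rest run split in two, L/R dACC
    connectivity per half, condition x hemisphere RM-ANOVA; reports the
    fraction of cohorts with a significant condition effect at 0.05.
    """
    sig = []
    for s in _spawn_seeds(seed + 2, n_cohorts):
        params = CohortParams(n_subjects=n_subjects, master_seed=s)
        datasets, atlas = make_cohort(params)
        _, anova = split_half_reliability(datasets, atlas)
        sig.append(anova.effect("condition")["p"] < 0.05)
    return {"n_cohorts": n_cohorts, "significant_rate": float(np.mean(sig))}


def overlap_endpoint(seed: int = 0, n_subjects: int = 8) -> dict:
    """Final-level overlap of the group connectivity map per hemisphere.

    With the planted coupling wholly inside the physics parcels the most
    stringent percentile level should overlap them completely (1.0).
    """
    params = CohortParams(n_subjects=n_subjects, master_seed=seed)
    datasets, atlas = make_cohort(params)
    curves = group_overlap_curves(datasets, atlas)
    return {h: {"final_overlap": float(c.proportions[-1]),
                "first_overlap": float(c.proportions[0]),
                "n_levels": len(c)} for h, c in curves.items()}


def cluster_fwe(seed: int = 0, n_reps: int = 10, n_sims: int = 200,
                n_test_fields: int = 40, grid: int = 16,
                fwhm_mm: float = 9.0, voxel_p: float = 0.001,
                alpha: float = 0.05) -> dict:
    """Familywise false-positive rate of the cluster correction on null fields.

    Each repetition derives a critical extent from ``n_sims`` Monte-Carlo
    fields and applies it to fresh null fields of the same smoothness; the
    aggregate exceedance rate estimates the achieved FWE at nominal alpha.
    """
    rng = np.random.default_rng(seed)
    mask = np.ones((grid,) * 3, bool)
    voxel = (3.0, 3.0, 3.0)
    fwhm = (fwhm_mm,) * 3
    z_crit = stats.norm.isf(voxel_p / 2)
    hits = 0
    for _ in range(n_reps):
        null = simulate_null_max_clusters(mask, fwhm, voxel, z_crit, n_sims, rng)
        crit = critical_cluster_size(null, alpha)
        fresh = simulate_null_max_clusters(mask, fwhm, voxel, z_crit,
                                           n_test_fields, rng)
        hits += int(np.sum(fresh >= crit))
    n_total = n_reps * n_test_fields
    return {"n_fields": n_total, "fwe_rate": hits / n_total,
            "nominal_alpha": alpha}


def planted_r_error(seed: int = 0, T: int = 10_000, n_voxels: int = 100,
                    a: float = 0.5, phi: float = 0.3, sigma: float = 1.0
                    ) -> dict:
    """Mean seed-voxel correlation at planted voxels vs the closed form.

    y = a*s + AR(1) noise correlated against the latent s; the population
    value is a / sqrt(a^2 + sigma_eff^2), sigma_eff the stationary AR SD.
    """
    from .connectivity import seed_connectivity
    from .volio import VolumeSeries
    rng = np.random.default_rng(seed)
    s = _latent(rng, phi, T)
    eps = _ar1(rng, phi, sigma, (n_voxels, T))
    side = int(np.ceil(n_voxels ** (1 / 3)))
    data = np.zeros((side, side, side, T))
    data.reshape(-1, T)[:n_voxels] = a * s + eps
    data.reshape(-1, T)[n_voxels:] = rng.standard_normal(
        (side ** 3 - n_voxels, T))
    vol = VolumeSeries(data, (3, 3, 3), 2.0)
    r = seed_connectivity(vol, s).data.reshape(-1)[:n_voxels]
    expected = a / np.sqrt(a ** 2 + (sigma / np.sqrt(1 - phi ** 2)) ** 2)
    return {"mean_r": float(r.mean()), "expected_r": float(expected),
            "abs_error": float(abs(r.mean() - expected)), "T": T}
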