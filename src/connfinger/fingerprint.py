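"""Percentile-overlap curves and the within/between-subject fingerprint MVPA.

Two bespoke analyses live here.

Overlap curve: a group connectivity z-map is thresholded at increasingly
stringent percentiles (20 levels, 99.00-99.95 in steps of 0.05, computed
within a fronto-parietal search mask) and, per level, the proportion of
surviving voxels that fall inside the task-defined physics parcels is
recorded. Concentrated connectivity drives the proportion to 1 at the most
stringent levels.

Fingerprint MVPA (:class:`FingerprintModel`): for each subject, the spatial
correlation (across voxels, within functionally defined physics ROIs)
between their dACC rest-connectivity map and their own physics - colour
task contrast (within) is compared with the average of the Fisher-z
correlations against every other subject's contrast (between). A two-way
repeated-measures ANOVA (condition: within/between x region) tests whether
connectivity tracks individual differences; a motion-confound check
correlates each subject's mean framewise displacement with their
within-minus-between gap. Correlations are Fisher-z transformed before any
averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import R_CLIP
from .volio import StatMap

__all__ = [
    "OverlapCurve",
    "percentile_sweep",
    "overlap_fraction",
    "overlap_curve",
    "spatial_correlation",
    "within_between_table",
    "AnovaResult",
    "rm_anova",
    "motion_confound_check",
    "FingerprintModel",
    "FingerprintResults",
]

DEFAULT_SWEEP = dict(start_pct=99.0, end_pct=99.95, step_pct=0.05)


# ---------------------------------------------------------------------------
# Percentile-threshold overlap


@dataclass
class OverlapCurve:
    """Overlap proportion as a function of percentile threshold."""

    thresholds: np.ndarray          # percentiles, strictly increasing
    proportions: np.ndarray         # in [0, 1]; NaN where level is empty
    n_voxels: np.ndarray            # suprathreshold voxel count per level
    seed_label: str = ""
    hemisphere: str = ""

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.n_voxels = np.asarray(self.n_voxels, dtype=int)
        if not (len(self.thresholds) == len(self.proportions) == len(self.n_voxels)):
            raise ValueError("curve arrays must have equal length")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")

    def __len__(self) -> int:
        return len(self.thresholds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"percentile": self.thresholds,
                             "n_voxels": self.n_voxels,
                             "proportion": self.proportions})

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        label = " ".join(x for x in (self.seed_label, self.hemisphere) if x)
        ax.plot(self.thresholds, self.proportions, marker="o", label=label or None)
        ax.set_xlabel("connectivity percentile threshold")
        ax.set_ylabel("proportion inside physics parcels")
        ax.set_ylim(-0.02, 1.02)
        if label:
            ax.legend()
        return ax


def percentile_sweep(zmap: StatMap, search_mask: np.ndarray,
                     start_pct: float = 99.0, end_pct: float = 99.95,
                     step_pct: float = 0.05,
                     ) -> list[tuple[float, np.ndarray]]:
    """Masks of voxels at or above each percentile of the in-mask values.

    Percentiles are computed over voxels within ``search_mask``. The default
    sweep (99.00-99.95 by 0.05) yields 20 nested levels; level k+1's mask is
    a subset of level k's.
    """
    search_mask = np.asarray(search_mask, dtype=bool)
    if not search_mask.any():
        raise ValueError("search mask is empty")
    vals = zmap.data[search_mask]
    if np.ptp(vals) == 0:
        raise ValueError("map is constant within the search mask")
    n_levels = int(round((end_pct - start_pct) / step_pct)) + 1
    pcts = start_pct + step_pct * np.arange(n_levels)
    out = []
    for p in pcts:
        cut = np.percentile(vals, p)
        out.append((float(p), (zmap.data >= cut) & search_mask))
    return out


def overlap_fraction(suprathreshold_mask: np.ndarray, physics_mask: np.ndarray,
                     search_mask: np.ndarray) -> float:
    """|supra & physics & search| / |supra & search|; NaN when the
    denominator is empty (flagged missing level)."""
    supra = np.asarray(suprathreshold_mask, dtype=bool) & np.asarray(search_mask, dtype=bool)
    denom = int(supra.sum())
    if denom == 0:
        return float("nan")
    return float((supra & np.asarray(physics_mask, dtype=bool)).sum() / denom)


def overlap_curve(zmap: StatMap, physics_mask: np.ndarray,
                  search_mask: np.ndarray, seed_label: str = "",
                  hemisphere: str = "", **sweep_cfg) -> OverlapCurve:
    """Compose the percentile sweep with the overlap fraction per level."""
    cfg = {**DEFAULT_SWEEP, **sweep_cfg}
    levels = percentile_sweep(zmap, search_mask, **cfg)
    pcts, props, counts = [], [], []
    for p, mask in levels:
        pcts.append(p)
        counts.append(int((mask & np.asarray(search_mask, dtype=bool)).sum()))
        props.append(overlap_fraction(mask, physics_mask, search_mask))
    return OverlapCurve(np.array(pcts), np.array(props), np.array(counts),
                        seed_label, hemisphere)


# ---------------------------------------------------------------------------
# Spatial correlation and the within/between table


def spatial_correlation(map_a: StatMap, map_b: StatMap,
                        roi_mask: np.ndarray) -> float:
    """Pearson r across voxels of ``roi_mask`` between two maps."""
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.sum() < 10:
        raise ValueError("spatial correlation needs >= 10 voxels in the ROI")
    a = map_a.data[roi]
    b = map_b.data[roi]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("map constant within the ROI")
    return float(np.corrcoef(a, b)[0, 1])


def _zr(r: float) -> float:
    return float(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)))


def within_between_table(conn_maps: dict[str, StatMap],
                         contrast_maps: dict[str, StatMap],
                         region_masks: dict[str, np.ndarray],
                         mean_fd_mm: dict[str, float] | None = None
                         ) -> pd.DataFrame:
    """Subject x region fingerprint table.

    within_z(i, roi) = atanh r(conn_i, contrast_i) over the ROI's voxels;
    between_z(i, roi) = mean over j != i of atanh r(conn_i, contrast_j).
    Region masks are typically the group-significant physics voxels
    intersected with each physics parcel. ``mean_fd_mm`` attaches each
    subject's motion summary for the confound check.
    """
    subjects = sorted(conn_maps)
    if sorted(contrast_maps) != subjects:
        missing = set(subjects) ^ set(contrast_maps)
        raise ValueError(f"subjects missing one map type: {sorted(missing)}")
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    rows = []
    for region, mask in region_masks.items():
        z = {(i, j): _zr(spatial_correlation(conn_maps[i], contrast_maps[j], mask))
             for i in subjects for j in subjects}
        for i in subjects:
            between = np.mean([z[i, j] for j in subjects if j != i])
            rows.append({"subject": i, "region": region,
                         "within_z": z[i, i], "between_z": float(between),
                         "mean_fd_mm": (mean_fd_mm or {}).get(i, np.nan)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA (two within factors)


@dataclass
class AnovaResult:
    """Classical repeated-measures ANOVA table (subject as random block)."""

    effects: pd.DataFrame  # columns: effect, F, df_num, df_den, p, note

    def effect(self, name: str) -> pd.Series:
        row = self.effects[self.effects["effect"] == name]
        if row.empty:
            raise KeyError(f"no effect {name!r}")
        return row.iloc[0]

    def to_json_dict(self) -> dict:
        return {r["effect"]: {"F": r["F"], "df_num": int(r["df_num"]),
                              "df_den": int(r["df_den"]), "p": r["p"]}
                for _, r in self.effects.iterrows()}

    def __str__(self) -> str:
        return self.effects.to_string(index=False)


def rm_anova(table: pd.DataFrame, dv: str, subject: str,
             within: tuple[str, str]) -> AnovaResult:
    """Two-way repeated-measures ANOVA by classical sums of squares.

    Each effect is tested against its own subject-interaction error term
    (A vs A x S, B vs B x S, A x B vs A x B x S). Requires a complete
    subject x A x B layout with one observation per cell. Degenerate
    all-equal layouts report F = 0 with a note rather than failing.
    """
    fa, fb = within
    cells = table.groupby([subject, fa, fb], observed=True)[dv].count()
    n_expected = (table[subject].nunique() * table[fa].nunique()
                  * table[fb].nunique())
    if len(cells) != n_expected or (cells != 1).any():
        raise ValueError("incomplete repeated-measures layout "
                         "(need exactly one observation per subject x cell)")
    wide = table.pivot_table(index=subject, columns=[fa, fb], values=dv,
                             observed=True)
    y = wide.to_numpy(dtype=float)                      # (n, a*b)
    n = y.shape[0]
    a = table[fa].nunique()
    b = table[fb].nunique()
    cube = y.reshape(n, a, b)

    grand = cube.mean()
    m_s = cube.mean(axis=(1, 2))
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_sa = cube.mean(axis=2)
    m_sb = cube.mean(axis=1)
    m_ab = cube.mean(axis=0)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_abs = np.sum((cube - m_sa[:, :, None] - m_sb[:, None, :]
                     - m_ab[None, :, :] + m_s[:, None, None]
                     + m_a[None, :, None] + m_b[None, None, :] - grand) ** 2)

    from scipy import stats as sps

    def _row(name, ss_eff, df_eff, ss_err, df_err):
        if ss_err <= 0:
            if ss_eff <= 0:
                return {"effect": name, "F": 0.0, "df_num": df_eff,
                        "df_den": df_err, "p": 1.0,
                        "note": "zero effect and error SS"}
            return {"effect": name, "F": float("inf"), "df_num": df_eff,
                    "df_den": df_err, "p": 0.0, "note": "zero error SS"}
        F = (ss_eff / df_eff) / (ss_err / df_err)
        return {"effect": name, "F": float(F), "df_num": df_eff,
                "df_den": df_err,
                "p": float(sps.f.sf(F, df_eff, df_err)), "note": ""}

    eff = pd.DataFrame([
        _row(fa, ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        _row(fb, ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        _row(f"{fa}:{fb}", ss_ab, (a - 1) * (b - 1), ss_abs,
             (a - 1) * (b - 1) * (n - 1)),
    ])
    return AnovaResult(eff)


def motion_confound_check(table: pd.DataFrame) -> float:
    """Across-subject Pearson r between mean FD and the fingerprint gap.

    The gap is each subject's mean over regions of within_z - between_z.
    """
    per_subj = table.groupby("subject").agg(
        gap=("within_z", "mean"), bet=("between_z", "mean"),
        fd=("mean_fd_mm", "mean"))
    if len(per_subj) < 3:
        raise ValueError("motion check needs >= 3 subjects")
    gap = (per_subj["gap"] - per_subj["bet"]).to_numpy()
    fd = per_subj["fd"].to_numpy()
    if np.ptp(fd) == 0:
        raise ValueError("framewise displacement is constant across subjects")
    if np.ptp(gap) == 0:
        raise ValueError("fingerprint gap is constant across subjects")
    return float(np.corrcoef(fd, gap)[0, 1])


# ---------------------------------------------------------------------------
# Model / Results front end


class FingerprintModel:
    """Within/between-subject connectivity fingerprint model.

    Built from per-subject dACC connectivity z-maps, per-subject
    physics - colour contrast maps, and region masks (the four physics
    ROIs). ``fit`` assembles the fingerprint table, runs the
    condition x region repeated-measures ANOVA and the motion-confound
    correlation, and returns :class:`FingerprintResults`.
    """

    def __init__(self, conn_maps: dict[str, StatMap],
                 contrast_maps: dict[str, StatMap],
                 region_masks: dict[str, np.ndarray],
                 mean_fd_mm: dict[str, float] | None = None):
        self.conn_maps = conn_maps
        self.contrast_maps = contrast_maps
        self.region_masks = region_masks
        self.mean_fd_mm = mean_fd_mm

    def fit(self) -> "FingerprintResults":
        table = within_between_table(self.conn_maps, self.contrast_maps,
                                     self.region_masks, self.mean_fd_mm)
        long = table.melt(id_vars=["subject", "region", "mean_fd_mm"],
                          value_vars=["within_z", "between_z"],
                          var_name="condition", value_name="z")
        long["condition"] = long["condition"].str.replace("_z", "", regex=False)
        anova = rm_anova(long, dv="z", subject="subject",
                         within=("condition", "region"))
        try:
            motion_r = motion_confound_check(table)
        except ValueError:
            motion_r = float("nan")
        return FingerprintResults(self, table, anova, motion_r)


class FingerprintResults:
    """Fingerprint table, ANOVA and diagnostics for a fitted model."""

    def __init__(self, model: FingerprintModel, table: pd.DataFrame,
                 anova: AnovaResult, motion_r: float):
        self.model = model
        self.table = table
        self.anova = anova
        self.motion_r = motion_r

    @property
    def mean_within_z(self) -> float:
        return float(self.table["within_z"].mean())

    @property
    def mean_between_z(self) -> float:
        return float(self.table["between_z"].mean())

    @property
    def gap(self) -> float:
        """Mean within_z - between_z over subjects and regions."""
        return self.mean_within_z - self.mean_between_z

    def identification_rate(self) -> float:
        """Fraction of subjects whose own contrast map is their best match.

        For each subject i, argmax over j of the mean-over-regions z of
        r(conn_i, contrast_j); a hit is argmax == i. A stronger form of the
        within > between claim.
        """
        subjects = sorted(self.model.conn_maps)
        hits = 0
        for i in subjects:
            scores = []
            for j in subjects:
                zs = [_zr(spatial_correlation(self.model.conn_maps[i],
                                              self.model.contrast_maps[j], m))
                      for m in self.model.region_masks.values()]
                scores.append(np.mean(zs))
            hits += subjects[int(np.argmax(scores))] == i
        return hits / len(subjects)

    def summary(self) -> str:
        cond = self.anova.effect("condition")
        lines = [
            "Connectivity fingerprint (within vs between subjects)",
            f"  subjects: {self.table['subject'].nunique()}, "
            f"regions: {self.table['region'].nunique()}",
            f"  mean within_z:  {self.mean_within_z: .4f}",
            f"  mean between_z: {self.mean_between_z: .4f}",
            f"  gap (within - between): {self.gap: .4f}",
            "  RM-ANOVA:",
        ]
        for _, r in self.anova.effects.iterrows():
            lines.append(
                f"    {r['effect']:<18} F({r['df_num']},{r['df_den']}) = "
                f"{r['F']:.3f}, p = {r['p']:.4g}"
            )
        lines.append(f"  condition effect significant at 0.05: "
                     f"{bool(cond['p'] < 0.05)}")
        lines.append(f"  motion confound r(FD, gap): {self.motion_r: .3f}")
        return "\n".join(lines)
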