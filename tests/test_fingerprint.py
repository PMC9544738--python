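import numpy as np
import pandas as pd
import pytest
from scipy import stats

from connfinger.fingerprint import (FingerprintModel, motion_confound_check,
                                    overlap_curve, overlap_fraction,
                                    percentile_sweep, rm_anova,
                                    spatial_correlation, within_between_table)
from connfinger.volio import StatMap


def _zmap(data):
    return StatMap(np.asarray(data, dtype=float), kind="z")


class TestPercentileSweep:
    def test_default_sweep_has_20_nested_levels(self, rng):
        zmap = _zmap(rng.standard_normal((12, 12, 12)))
        mask = np.ones((12, 12, 12), bool)
        levels = percentile_sweep(zmap, mask)
        assert len(levels) == 20
        assert levels[0][0] == pytest.approx(99.0)
        assert levels[-1][0] == pytest.approx(99.95)
        for (_, a), (_, b) in zip(levels, levels[1:]):
            assert np.all(a[b])                      # nested: b subset of a

    def test_99th_percentile_of_1000_distinct_keeps_10(self, rng):
        vals = rng.permutation(1000).astype(float)
        zmap = _zmap(vals.reshape(10, 10, 10))
        mask = np.ones((10, 10, 10), bool)
        _, top = percentile_sweep(zmap, mask, 99.0, 99.0, 0.05)[0]
        assert top.sum() == 10

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            percentile_sweep(_zmap(np.ones((5, 5, 5))),
                             np.ones((5, 5, 5), bool))


class TestOverlapFraction:
    def test_ratio_limits_and_midpoint(self):
        search = np.ones((6, 6, 6), bool)
        physics = np.zeros((6, 6, 6), bool)
        physics[:3] = True
        inside = np.zeros_like(physics)
        inside[0, :3, :3] = True
        outside = np.zeros_like(physics)
        outside[5, :3, :3] = True
        assert overlap_fraction(inside, physics, search) == 1.0
        assert overlap_fraction(outside, physics, search) == 0.0
        both = np.zeros_like(physics)
        both[0, :5, :3] = True      # 15 voxels in, ...
        both[5, :5, :3] = True      # ... 15 out
        assert overlap_fraction(both, physics, search) == 0.5

    def test_empty_denominator_flagged_as_nan(self):
        supra = np.zeros((4, 4, 4), bool)
        assert np.isnan(overlap_fraction(supra, supra, np.ones((4, 4, 4), bool)))


class TestOverlapCurve:
    def test_concentrated_signal_reaches_full_overlap(self, rng):
        shape = (12, 12, 12)
        physics = np.zeros(shape, bool)
        physics[4:8, 4:8, 4:8] = True
        data = rng.standard_normal(shape) * 0.1
        data[physics] += 5.0
        curve = overlap_curve(_zmap(data), physics, np.ones(shape, bool))
        assert curve.proportions[-1] == 1.0
        assert len(curve) == 20

    def test_uniform_signal_tracks_base_rate(self, rng):
        shape = (16, 16, 16)
        physics = np.zeros(shape, bool)
        physics[:8] = True                       # half the mask
        data = rng.standard_normal(shape)        # no concentration anywhere
        curve = overlap_curve(_zmap(data), physics, np.ones(shape, bool))
        base = physics.mean()
        # early levels have >= 21 voxels; later ones are tiny samples
        assert abs(curve.proportions[0] - base) < 0.25

    def test_frame_export(self, rng):
        shape = (10, 10, 10)
        curve = overlap_curve(_zmap(rng.standard_normal(shape)),
                              np.zeros(shape, bool), np.ones(shape, bool))
        df = curve.to_frame()
        assert list(df.columns) == ["percentile", "n_voxels", "proportion"]
        assert (df["n_voxels"].to_numpy() >= 1).all()


class TestSpatialCorrelation:
    def test_identity_and_negation(self, rng):
        m = _zmap(rng.standard_normal((5, 5, 5)))
        roi = np.ones((5, 5, 5), bool)
        assert spatial_correlation(m, m, roi) == pytest.approx(1.0)
        assert spatial_correlation(m, _zmap(-m.data), roi) == pytest.approx(-1.0)

    def test_orthogonal_construction_gives_zero(self):
        n = 64
        a = np.sin(2 * np.pi * 3 * np.arange(n) / n)
        b = np.cos(2 * np.pi * 3 * np.arange(n) / n)
        roi = np.ones((4, 4, 4), bool)
        r = spatial_correlation(_zmap(a.reshape(4, 4, 4)),
                                _zmap(b.reshape(4, 4, 4)), roi)
        assert abs(r) < 1e-10

    def test_small_or_constant_roi_rejected(self, rng):
        m = _zmap(rng.standard_normal((5, 5, 5)))
        small = np.zeros((5, 5, 5), bool)
        small[0, 0, :5] = True
        with pytest.raises(ValueError):
            spatial_correlation(m, m, small)
        with pytest.raises(ValueError):
            spatial_correlation(_zmap(np.ones((5, 5, 5))), m,
                                np.ones((5, 5, 5), bool))


class TestWithinBetweenTable:
    def _maps(self, rng, n, shape=(6, 6, 6)):
        return {f"s{i}": _zmap(rng.standard_normal(shape)) for i in range(n)}

    def test_identical_maps_equalise_within_and_between(self, rng):
        shared = rng.standard_normal((6, 6, 6))
        conn = {f"s{i}": _zmap(shared) for i in range(3)}
        contrast = {f"s{i}": _zmap(shared + 0.0) for i in range(3)}
        masks = {"roi": np.ones((6, 6, 6), bool)}
        table = within_between_table(conn, contrast, masks)
        np.testing.assert_allclose(table["within_z"], table["between_z"])

    def test_two_subjects_between_is_single_correlation(self, rng):
        conn = self._maps(rng, 2)
        contrast = self._maps(rng, 2)
        masks = {"roi": np.ones((6, 6, 6), bool)}
        table = within_between_table(conn, contrast, masks)
        z01 = np.arctanh(spatial_correlation(conn["s0"], contrast["s1"],
                                             masks["roi"]))
        row = table[(table.subject == "s0")].iloc[0]
        assert row["between_z"] == pytest.approx(z01)

    def test_missing_map_raises(self, rng):
        conn = self._maps(rng, 3)
        contrast = self._maps(rng, 2)
        with pytest.raises(ValueError, match="missing"):
            within_between_table(conn, contrast,
                                 {"roi": np.ones((6, 6, 6), bool)})


def _brute_force_rm_anova(cube):
    """Independent SS decomposition by explicit summation loops."""
    n, a, b = cube.shape
    grand = cube.mean()
    ss = {k: 0.0 for k in ("A", "B", "AB", "AS", "BS", "ABS")}
    mA = [cube[:, i, :].mean() for i in range(a)]
    mB = [cube[:, :, j].mean() for j in range(b)]
    mS = [cube[k].mean() for k in range(n)]
    for i in range(a):
        ss["A"] += n * b * (mA[i] - grand) ** 2
    for j in range(b):
        ss["B"] += n * a * (mB[j] - grand) ** 2
    for i in range(a):
        for j in range(b):
            mab = cube[:, i, j].mean()
            ss["AB"] += n * (mab - mA[i] - mB[j] + grand) ** 2
    for k in range(n):
        for i in range(a):
            msa = cube[k, i, :].mean()
            ss["AS"] += b * (msa - mS[k] - mA[i] + grand) ** 2
        for j in range(b):
            msb = cube[k, :, j].mean()
            ss["BS"] += a * (msb - mS[k] - mB[j] + grand) ** 2
    for k in range(n):
        for i in range(a):
            for j in range(b):
                mab = cube[:, i, j].mean()
                msa = cube[k, i, :].mean()
                msb = cube[k, :, j].mean()
                ss["ABS"] += (cube[k, i, j] - msa - msb - mab + mS[k]
                              + mA[i] + mB[j] - grand) ** 2
    FA = (ss["A"] / (a - 1)) / (ss["AS"] / ((a - 1) * (n - 1)))
    FB = (ss["B"] / (b - 1)) / (ss["BS"] / ((b - 1) * (n - 1)))
    FAB = (ss["AB"] / ((a - 1) * (b - 1))) / (ss["ABS"] / ((a - 1) * (b - 1) * (n - 1)))
    return FA, FB, FAB


def _long_table(cube):
    n, a, b = cube.shape
    rows = []
    for k in range(n):
        for i in range(a):
            for j in range(b):
                rows.append({"subject": f"s{k}", "A": f"a{i}", "B": f"b{j}",
                             "y": cube[k, i, j]})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_matches_brute_force_on_12_cell_table(self, rng):
        cube = rng.standard_normal((3, 2, 2)) + np.array([1.0, 0.0])[None, :, None]
        res = rm_anova(_long_table(cube), dv="y", subject="subject",
                       within=("A", "B"))
        FA, FB, FAB = _brute_force_rm_anova(cube)
        assert res.effect("A")["F"] == pytest.approx(FA)
        assert res.effect("B")["F"] == pytest.approx(FB)
        assert res.effect("A:B")["F"] == pytest.approx(FAB)
        assert res.effect("A")["df_num"] == 1
        assert res.effect("A")["df_den"] == 2

    def test_matches_statsmodels_anovarm(self, rng):
        from statsmodels.stats.anova import AnovaRM
        cube = rng.standard_normal((6, 2, 4))
        table = _long_table(cube)
        res = rm_anova(table, dv="y", subject="subject", within=("A", "B"))
        sm = AnovaRM(table, depvar="y", subject="subject",
                     within=["A", "B"]).fit().anova_table
        assert res.effect("A")["F"] == pytest.approx(sm.loc["A", "F Value"])
        assert res.effect("B")["F"] == pytest.approx(sm.loc["B", "F Value"])
        assert res.effect("A:B")["F"] == pytest.approx(sm.loc["A:B", "F Value"])
        assert res.effect("B")["p"] == pytest.approx(sm.loc["B", "Pr > F"])

    def test_all_equal_cells_report_zero_F_with_note(self):
        cube = np.full((3, 2, 2), 5.0)
        res = rm_anova(_long_table(cube), dv="y", subject="subject",
                       within=("A", "B"))
        for eff in ("A", "B", "A:B"):
            assert res.effect(eff)["F"] == 0.0
            assert res.effect(eff)["note"] != ""

    def test_incomplete_layout_rejected(self, rng):
        table = _long_table(rng.standard_normal((3, 2, 2))).iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova(table, dv="y", subject="subject", within=("A", "B"))

    def test_permutation_null_p_values_are_uniform(self):
        rng = np.random.default_rng(12)
        base = rng.standard_normal((6, 2, 3))
        ps = []
        for _ in range(400):
            cube = base.copy()
            # permute condition labels within each subject x region cell pair
            for k in range(cube.shape[0]):
                for j in range(cube.shape[2]):
                    if rng.random() < 0.5:
                        cube[k, :, j] = cube[k, ::-1, j]
            res = rm_anova(_long_table(cube), dv="y", subject="subject",
                           within=("A", "B"))
            ps.append(res.effect("A")["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestMotionConfound:
    def _table(self, gaps, fds):
        rows = []
        for i, (g, f) in enumerate(zip(gaps, fds)):
            rows.append({"subject": f"s{i}", "region": "r1",
                         "within_z": g, "between_z": 0.0, "mean_fd_mm": f})
        return pd.DataFrame(rows)

    def test_independent_motion_gives_small_r(self, rng):
        rs = []
        for _ in range(50):
            n = 10
            rs.append(motion_confound_check(
                self._table(rng.standard_normal(n), rng.random(n))))
        assert abs(np.mean(rs)) < 2 / np.sqrt(10)

    def test_planted_dependence_detected(self, rng):
        gaps = np.linspace(0, 1, 8) + 0.01 * rng.standard_normal(8)
        fds = np.linspace(0.1, 0.9, 8)
        assert motion_confound_check(self._table(gaps, fds)) > 0.9

    def test_constant_fd_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            motion_confound_check(self._table(rng.standard_normal(5),
                                              np.full(5, 0.3)))


class TestFingerprintModel:
    def test_shuffled_pairing_destroys_the_gap(self, small_cohort):
        from connfinger.pipeline import cohort_maps, region_masks_from_parcels
        datasets, atlas = small_cohort
        conn, contrast, fd = cohort_maps(datasets, atlas)
        masks = region_masks_from_parcels(atlas)
        res = FingerprintModel(conn, contrast, masks, fd).fit()
        assert res.gap > 0
        # permute the conn<->contrast subject pairing: the average gap over
        # all n! pairings is exactly zero (exchangeability null)
        from itertools import permutations
        subjects = sorted(conn)
        gaps = []
        for perm in permutations(subjects):
            shuffled = {s: contrast[p] for s, p in zip(subjects, perm)}
            gaps.append(FingerprintModel(conn, shuffled, masks, fd).fit().gap)
        assert abs(np.mean(gaps)) < 1e-10
        assert np.mean(gaps) < res.gap

    def test_summary_mentions_anova_and_motion(self, small_cohort):
        from connfinger.pipeline import fit_fingerprint
        datasets, atlas = small_cohort
        res = fit_fingerprint(datasets, atlas)
        text = res.summary()
        assert "RM-ANOVA" in text and "motion confound" in text
        assert f"subjects: {len(datasets)}" in text
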