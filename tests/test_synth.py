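import numpy as np
import pytest

from connfinger.preprocess import framewise_displacement
from connfinger.synth import (CohortParams, clip_displacement_vox,
                              colour_core_mask, make_atlas, make_cohort,
                              planted_core_mask, simulate_rest_run,
                              simulate_task_run)
from connfinger.volio import Role


class TestAtlas:
    def test_role_counts_match_study_parcellation(self, atlas):
        assert len(atlas.ids_for_role(Role.ACC_DACC)) == 2   # one per hemisphere
        assert len(atlas.ids_for_role(Role.ACC_OTHER)) == 6  # 3 per hemisphere
        assert len(atlas.ids_for_role(Role.PHYSICS)) == 4

    def test_one_dacc_per_hemisphere(self, atlas):
        names = [atlas.name_of(i) for i in atlas.ids_for_role(Role.ACC_DACC)]
        assert any("_l_" in n.lower() for n in names)
        assert any("_r_" in n.lower() for n in names)

    def test_physics_parcels_inside_searchmask_and_large(self, atlas):
        search = atlas.mask(Role.SEARCHMASK)
        for pid in atlas.ids_for_role(Role.PHYSICS):
            m = atlas.mask(pid)
            assert m.sum() >= 200
            assert np.all(search[m])

    def test_tissue_boxes_disjoint_from_parcels(self, atlas):
        wm = atlas.mask(Role.WM)
        vent = atlas.mask(Role.VENTRICLE)
        acc = atlas.mask(Role.ACC_DACC) | atlas.mask(Role.ACC_OTHER)
        phys = atlas.mask(Role.PHYSICS)
        for a, b in [(wm, vent), (wm, acc), (vent, acc), (wm, phys),
                     (vent, phys), (acc, phys)]:
            assert not (a & b).any()

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            make_atlas(CohortParams(grid_dims=(10, 10, 10)))


class TestDisplacement:
    def test_clipped_core_stays_inside_parcels(self, atlas):
        params = CohortParams()
        phys = atlas.mask(Role.PHYSICS)
        for d_mm in ([0, 0, 0], [20, -20, 20], [-7, 4, -9]):
            d = clip_displacement_vox(d_mm, params)
            core = planted_core_mask(params, d)
            assert np.all(phys[core])

    def test_colour_control_disjoint_from_any_displaced_core(self):
        params = CohortParams()
        control = colour_core_mask(params)
        for d_mm in ([0, 0, 0], [9, 9, 9], [-9, -9, -9]):
            core = planted_core_mask(params, clip_displacement_vox(d_mm, params))
            assert not (core & control).any()


class TestRestRun:
    def test_uncoupled_seed_correlation_bounded(self, atlas):
        params = CohortParams(seed_coupling=0.0, n_rest_volumes=200,
                              motion_spike_rate=0.0)
        from connfinger.synth import SubjectProfile
        prof = SubjectProfile("s", np.zeros(3, int), np.zeros(3))
        vol, _ = simulate_rest_run(prof, atlas, params, run_seed=4)
        from connfinger.volio import mask_mean_timeseries
        seed = mask_mean_timeseries(vol, atlas.mask(Role.ACC_DACC))
        core = planted_core_mask(params)
        rs = [np.corrcoef(seed, ts)[0, 1] for ts in vol.data[core][:50]]
        T = params.n_rest_volumes
        assert np.abs(np.mean(rs)) <= 2 / np.sqrt(T)

    def test_planted_correlation_matches_closed_form(self, atlas):
        params = CohortParams(n_rest_volumes=2000, motion_spike_rate=0.0)
        from connfinger.synth import SubjectProfile, _latent
        prof = SubjectProfile("s", np.zeros(3, int), np.zeros(3))
        # reproduce the run's latent stream to get s exactly
        rng = np.random.default_rng(9)
        from connfinger.synth import _ar1
        T = params.n_rest_volumes
        dims = params.grid_dims
        _ = _ar1(rng, params.ar1_phi, params.noise_sd, (*dims, T))
        s = _latent(rng, params.ar1_phi, T)
        vol, _ = simulate_rest_run(prof, atlas, params, run_seed=9)
        core = planted_core_mask(params)
        rs = [np.corrcoef(s, ts)[0, 1] for ts in vol.data[core][:100]]
        assert abs(np.mean(rs) - params.planted_r()) < 0.05

    def test_no_spikes_means_fd_below_two_mm(self, atlas):
        params = CohortParams(motion_spike_rate=0.0, n_rest_volumes=100)
        from connfinger.synth import SubjectProfile
        prof = SubjectProfile("s", np.zeros(3, int), np.zeros(3))
        _, motion = simulate_rest_run(prof, atlas, params, run_seed=2)
        assert framewise_displacement(motion).max() < 2.0

    def test_spikes_exceed_two_mm(self, atlas):
        params = CohortParams(motion_spike_rate=0.2, n_rest_volumes=100)
        from connfinger.synth import SubjectProfile
        prof = SubjectProfile("s", np.zeros(3, int), np.zeros(3))
        _, motion = simulate_rest_run(prof, atlas, params, run_seed=2)
        assert framewise_displacement(motion).max() > 2.0


class TestTaskRun:
    def test_run_length_matches_design(self, atlas):
        from connfinger.design import build_block_design
        from connfinger.synth import SubjectProfile
        params = CohortParams()
        prof = SubjectProfile("s", np.zeros(3, int), np.zeros(3))
        vol, _ = simulate_task_run(prof, atlas, build_block_design(0), params, 3)
        assert vol.n_volumes == 207

    def test_zero_beta_contrast_is_null(self, atlas):
        from connfinger.design import build_block_design
        from connfinger.glm import BlockGlm
        from connfinger.synth import SubjectProfile
        params = CohortParams(activation_beta=0.0, motion_spike_rate=0.0)
        prof = SubjectProfile("s", np.zeros(3, int), np.zeros(3))
        d = build_block_design(0)
        vol, motion = simulate_task_run(prof, atlas, d, params, 3)
        res = BlockGlm.from_run(vol, motion, d).fit()
        core = planted_core_mask(params)
        vals = res.physics_minus_colour().data[core]
        assert abs(vals.mean()) < 2 * vals.std() / np.sqrt(vals.size)

    def test_noiseless_beta_is_exact(self, atlas):
        # sigma cannot be 0 by contract; emulate by fitting the pure signal
        from connfinger.design import build_block_design, convolve_design
        from connfinger.glm import BlockGlm
        params = CohortParams()
        d = build_block_design(0)
        X = convolve_design(d)
        y = 1.0 * X["physics_cue"].to_numpy()
        from connfinger.volio import VolumeSeries
        vol = VolumeSeries(np.tile(y, (2, 2, 2, 1)), params.voxel_size_mm,
                           params.tr_s)
        res = BlockGlm(vol, X).fit()
        np.testing.assert_allclose(res.beta_map("physics_cue").data, 1.0,
                                   atol=1e-6)


class TestCohort:
    def test_fixed_master_seed_is_bit_identical(self):
        params = CohortParams(n_subjects=2, n_rest_volumes=40,
                              rest_runs_per_subject=1,
                              task_runs_per_subject=1, master_seed=8)
        a, _ = make_cohort(params)
        b, _ = make_cohort(params)
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.rest_runs[0][0].data,
                                          db.rest_runs[0][0].data)
            np.testing.assert_array_equal(da.task_runs[0][0].data,
                                          db.task_runs[0][0].data)
            assert np.array_equal(da.profile.displacement_vox,
                                  db.profile.displacement_vox)

    def test_zero_displacement_sd_aligns_all_subjects(self):
        params = CohortParams(n_subjects=3, n_rest_volumes=40,
                              rest_runs_per_subject=1,
                              task_runs_per_subject=1,
                              displacement_sd_mm=0.0, master_seed=8)
        datasets, _ = make_cohort(params)
        for ds in datasets:
            assert np.array_equal(ds.profile.displacement_vox, [0, 0, 0])

    def test_different_master_seeds_differ(self):
        seen = set()
        for seed in range(10):
            params = CohortParams(n_subjects=2, n_rest_volumes=40,
                                  rest_runs_per_subject=1,
                                  task_runs_per_subject=1, master_seed=seed)
            root = np.random.SeedSequence(seed).spawn(2)[0]
            rng = np.random.default_rng(root)
            disp = tuple(np.round(rng.normal(0, params.displacement_sd_mm, 3), 6))
            seen.add(disp)
        assert len(seen) == 10

    def test_writes_readable_cohort(self, tmp_path):
        import yaml
        from connfinger.synth import write_cohort
        from connfinger.volio import read_volume
        params = CohortParams(n_subjects=2, n_rest_volumes=40,
                              rest_runs_per_subject=1,
                              task_runs_per_subject=1, master_seed=8)
        datasets, atlas = make_cohort(params)
        manifest = write_cohort(datasets, atlas, params, tmp_path)
        meta = yaml.safe_load(manifest.read_text())
        assert len(meta["subjects"]) == 2
        vol = read_volume(tmp_path / "sub-01" / "rest_run-1.nii.gz")
        assert vol.n_volumes == 40
        assert vol.tr_s == pytest.approx(2.0)
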