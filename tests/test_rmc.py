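"""Greedy reverse-Monte-Carlo fitting: objective, moves, invariants, stages."""
import numpy as np
import pytest

from condensax.exceptions import (DegenerateWindowError, GridMismatchError,
                                  InvalidParameterError, ResolutionError)
from condensax.geometry import MODEL_GEOMETRIES, clash_check
from condensax.profile import ScatteringProfile
from condensax.rmc import (FitConfig, GaussianBlobRMC, SpherocylinderRMC,
                           chi_squared, fit_blobs, place_copies_from_blobs,
                           refine_copies, resolution_limit, staged_pipeline)
from condensax.scattering import EnsembleModel, OrientationSet, ensemble_intensity
from condensax.synthetic import (generate_droplet_profile,
                                 generate_random_walk_structure)


def _small_target(seed=7, n=120, container=4000.0, window=1000.0, noise=0.0):
    walk = generate_random_walk_structure(n, 200.0, seed, container_diameter=0.9 * container)
    walk = walk - walk.mean(axis=0)
    r = np.linalg.norm(walk, axis=1).max()
    if r > 0.49 * container:
        walk *= 0.49 * container / r
    q = np.geomspace(2 * np.pi / window, 0.03, 20)
    return generate_droplet_profile(walk, q, seed + 1, sigma_blob=40.0,
                                    noise_fraction=noise, window_sigma=window,
                                    container_diameter=container)


class TestChiSquared:
    def test_identical_curves_give_zero_and_unit_scale(self):
        prof = ScatteringProfile(np.array([0.01, 0.02, 0.03, 0.04, 0.05]),
                                 np.array([5.0, 4.0, 3.0, 2.0, 1.0]))
        chi2, c = chi_squared(prof.intensity, prof)
        assert chi2 == pytest.approx(0.0, abs=1e-20)
        assert c == pytest.approx(1.0)

    def test_global_scale_is_absorbed(self):
        prof = ScatteringProfile(np.array([0.01, 0.02, 0.03]), 3.0 * np.array([5.0, 4.0, 3.0]))
        chi2, c = chi_squared(np.array([5.0, 4.0, 3.0]), prof)
        assert chi2 == pytest.approx(0.0, abs=1e-18)
        assert c == pytest.approx(3.0)

    def test_three_point_example_against_brute_force_scan(self):
        i_mod = np.array([1.0, 2.0, 3.0])
        prof = ScatteringProfile(np.array([0.01, 0.02, 0.03]), np.array([2.0, 4.0, 7.0]),
                                 np.ones(3))
        chi2, c = chi_squared(i_mod, prof)
        assert c == pytest.approx(31.0 / 14.0)
        assert chi2 == pytest.approx(5.0 / 14.0)
        # exhaustive scan over the scale confirms the closed-form minimiser
        scan = [np.sum((cc * i_mod - prof.intensity) ** 2)
                for cc in np.linspace(0.5, 4.0, 20001)]
        assert chi2 == pytest.approx(min(scan), abs=1e-6)

    def test_disjoint_grids_are_refused(self):
        prof = ScatteringProfile(np.array([0.01, 0.02, 0.03]), np.ones(3))
        with pytest.raises(GridMismatchError):
            chi_squared(np.ones(5), prof)


class TestGuards:
    def test_window_resolution_guard_refuses_unresolvable_q(self):
        prof = ScatteringProfile(np.geomspace(0.001, 0.03, 30), np.ones(30))
        config = FitConfig(n_copies=10, window_sigma=1500.0, q_min=0.001,
                           max_moves=0, model_geometry="blobs")
        with pytest.raises(ResolutionError, match="2 pi / sigma_w"):
            fit_blobs(prof, config)

    def test_printed_blob_window_is_admitted(self):
        # the canonical droplet window 0.002 < q with sigma_w = 3000 A sits
        # marginally below the exact 2 pi / sigma_w and must not be refused
        prof = ScatteringProfile(np.geomspace(0.002, 0.03, 25), np.ones(25))
        config = FitConfig(n_copies=5, window_sigma=3000.0, q_min=0.002,
                           n_orientations=4, max_moves=0, model_geometry="blobs")
        fit_blobs(prof, config)  # does not raise

    def test_sparse_window_is_refused(self):
        prof = ScatteringProfile(np.array([0.005, 0.01, 0.02, 0.05]), np.ones(4))
        config = FitConfig(n_copies=5, window_sigma=1000.0, q_max=0.03,
                           max_moves=0, model_geometry="blobs")
        with pytest.raises(DegenerateWindowError):
            fit_blobs(prof, config)


class TestBlobFit:
    CFG = dict(n_copies=60, sigma_blob=40.0, container_diameter=4000.0,
               window_sigma=1000.0, q_max=0.03, n_orientations=32,
               translation_step=150.0, model_geometry="blobs")

    def test_zero_moves_returns_seeded_start_with_one_trace_entry(self):
        prof = _small_target()
        result = fit_blobs(prof, FitConfig(max_moves=0, seed=3, **self.CFG))
        assert result.chi2_trace.size == 1
        assert result.n_accepted == 0 and result.n_rejected == 0
        assert result.final_model.n_blobs == 60

    def test_trace_monotone_and_centers_stay_inside(self):
        prof = _small_target()
        result = fit_blobs(prof, FitConfig(max_moves=800, seed=5, **self.CFG))
        assert np.all(np.diff(result.chi2_trace) < 0)
        radii = np.linalg.norm(result.final_model.centers, axis=1)
        assert np.all(radii <= 2000.0 + 1e-9)
        assert result.n_accepted + result.n_rejected == 800

    def test_identical_seed_reproduces_the_fit_bit_for_bit(self):
        prof = _small_target()
        config = FitConfig(max_moves=400, seed=11, **self.CFG)
        a = fit_blobs(prof, config)
        b = fit_blobs(prof, config)
        np.testing.assert_array_equal(a.chi2_trace, b.chi2_trace)
        np.testing.assert_array_equal(a.final_model.centers, b.final_model.centers)

    def test_self_recovery_reaches_a_tenth_of_the_starting_chi2(self):
        # profile generated from a known 200-blob structure, fitted with
        # 200 blobs at a reduced move budget
        prof = _small_target(seed=42, n=200)
        config = FitConfig(n_copies=200, sigma_blob=40.0, container_diameter=4000.0,
                           window_sigma=1000.0, q_max=0.03, n_orientations=64,
                           translation_step=150.0, max_moves=6000, seed=6,
                           model_geometry="blobs")
        result = fit_blobs(prof, config)
        assert result.chi2 <= 0.1 * result.chi2_trace[0]

    def test_estimator_facade_exposes_fitted_attributes(self):
        prof = _small_target()
        est = GaussianBlobRMC(n_blobs=40, container_diameter=4000.0,
                              window_sigma=1000.0, n_orientations=16,
                              translation_step=150.0, max_moves=50, seed=1)
        fitted = est.fit(prof)
        assert fitted is est
        assert est.ensemble_.n_blobs == 40
        assert est.chi2_trace_[0] >= est.chi2_trace_[-1]
        assert "n_blobs" in est.get_params()


class TestPlacement:
    def _blob_result(self, n=200, seed=42):
        prof = _small_target(seed=seed, n=n)
        config = FitConfig(n_copies=n, sigma_blob=40.0, container_diameter=4000.0,
                           window_sigma=1000.0, q_max=0.03, n_orientations=48,
                           translation_step=150.0, max_moves=3000, seed=8,
                           model_geometry="blobs")
        return fit_blobs(prof, config)

    def test_copies_inside_container_and_clash_free(self):
        blob_result = self._blob_result()
        config = FitConfig(n_copies=300, container_diameter=4000.0, window_sigma=1000.0,
                           q_max=0.03, model_geometry="model1", clash_checking=True, seed=9)
        model = place_copies_from_blobs(blob_result, MODEL_GEOMETRIES["model1"], config)
        refs = np.array([c.reference_point for c in model.copies])
        assert np.all(np.linalg.norm(refs, axis=1) <= 2000.0 + 1e-9)
        for i in range(len(model.copies)):
            near = np.where(np.linalg.norm(refs - refs[i], axis=1) < 400.0)[0]
            for j in near[near > i]:
                assert not clash_check(model.copies[i], model.copies[int(j)])

    def test_single_copy_has_valid_geometry(self):
        blob_result = self._blob_result(n=50)
        config = FitConfig(n_copies=1, container_diameter=4000.0, window_sigma=1000.0,
                           q_max=0.03, model_geometry="model3", clash_checking=True, seed=2)
        model = place_copies_from_blobs(blob_result, MODEL_GEOMETRIES["model3"], config)
        assert len(model.copies) == 1
        assert model.copies[0].n_segments == 3

    def test_occupancy_follows_the_blob_mass_distribution(self):
        # sampling fidelity: coarse-grid occupancy of 5000 placed copies
        # rank-correlates with the blob mixture density
        from scipy.stats import spearmanr
        from condensax.scattering import window_weight

        blob_result = self._blob_result()
        config = FitConfig(n_copies=5000, container_diameter=4000.0, window_sigma=1000.0,
                           q_max=0.03, model_geometry="model1", clash_checking=False, seed=4)
        model = place_copies_from_blobs(blob_result, MODEL_GEOMETRIES["model1"], config)
        refs = np.array([c.reference_point for c in model.copies])
        cell = 800.0  # coarse: blob tail mass must stay inside its cell
        blobs = blob_result.final_model
        mass = window_weight(blobs.centers, blob_result.window_center, 1000.0)
        keys_b = np.floor(blobs.centers / cell).astype(int)
        keys_c = np.floor(refs / cell).astype(int)
        all_keys = np.unique(np.vstack([keys_b, keys_c]), axis=0)
        density, occupancy = [], []
        for key in all_keys:
            density.append(mass[(keys_b == key).all(axis=1)].sum())
            occupancy.append(np.count_nonzero((keys_c == key).all(axis=1)))
        rho = spearmanr(density, occupancy).statistic
        assert rho > 0.9


class TestRefine:
    def _initial(self, blob_seed=42, n_copies=250, clash=True):
        prof = _small_target(seed=blob_seed, n=200)
        blob_config = FitConfig(n_copies=200, sigma_blob=40.0, container_diameter=4000.0,
                                window_sigma=1000.0, q_max=0.03, n_orientations=48,
                                translation_step=150.0, max_moves=2500, seed=8,
                                model_geometry="blobs")
        blob_result = fit_blobs(prof, blob_config)
        config = FitConfig(n_copies=n_copies, container_diameter=4000.0,
                           window_sigma=1000.0, q_max=0.03, n_orientations=32,
                           translation_step=80.0, rotation_step=0.4, max_moves=400,
                           model_geometry="model1", clash_checking=clash, seed=14,
                           validate_moves=True)
        initial = place_copies_from_blobs(blob_result, MODEL_GEOMETRIES["model1"], config)
        return prof, initial, config

    def test_zero_moves_returns_the_initial_model(self):
        prof, initial, config = self._initial()
        from dataclasses import replace
        result = refine_copies(prof, initial, replace(config, max_moves=0))
        assert result.chi2_trace.size == 1
        assert result.final_model.copies is not initial.copies  # fresh list
        a = initial.copies[0].segments[0].start
        b = result.final_model.copies[0].segments[0].start
        np.testing.assert_array_equal(a, b)

    def test_trace_monotone_accepted_moves_clash_free_and_deterministic(self):
        prof, initial, config = self._initial()
        result = refine_copies(prof, initial, config)  # validate_moves asserts clashes
        assert np.all(np.diff(result.chi2_trace) < 0)
        again = refine_copies(prof, initial, config)
        np.testing.assert_array_equal(result.chi2_trace, again.chi2_trace)
        refs = np.array([c.reference_point for c in result.final_model.copies])
        chains = result.final_model.copies
        for i in range(len(chains)):
            near = np.where(np.linalg.norm(refs - refs[i], axis=1) < 400.0)[0]
            for j in near[near > i]:
                assert not clash_check(chains[i], chains[int(j)])

    def test_initial_clashes_are_refused(self):
        prof, initial, config = self._initial()
        # duplicate one chain on top of another to force an overlap
        bad = list(initial.copies)
        bad[1] = bad[0].translated(np.array([5.0, 0.0, 0.0]))
        bad_model = EnsembleModel(bad, initial.container_diameter, initial.window_sigma)
        with pytest.raises(InvalidParameterError, match="clash"):
            refine_copies(prof, bad_model, config)

    def test_self_recovery_from_randomized_start(self):
        # target intensity from a known clustered model-1 ensemble; greedy
        # refinement from a uniform random start recovers >= 80% of chi2
        rng = np.random.default_rng(77)
        container, n = 4000.0, 400
        from condensax.rmc import _centered_chain
        target_chains = []
        while len(target_chains) < n:
            pos = rng.normal(0.0, 600.0, size=3)
            if np.linalg.norm(pos) > 1900.0:
                continue
            target_chains.append(_centered_chain(MODEL_GEOMETRIES["model1"], pos, rng))
        q = np.geomspace(2 * np.pi / 1000.0, 0.03, 18)
        target_model = EnsembleModel(target_chains, container, 1000.0)
        intensity = ensemble_intensity(target_model, q, OrientationSet.random(200, 5))
        prof = ScatteringProfile(q, intensity)

        start_chains = []
        while len(start_chains) < n:
            pos = rng.uniform(-1900.0, 1900.0, size=3)
            if np.linalg.norm(pos) > 1900.0:
                continue
            start_chains.append(_centered_chain(MODEL_GEOMETRIES["model1"], pos, rng))
        start = EnsembleModel(start_chains, container, 1000.0)
        config = FitConfig(n_copies=n, container_diameter=container, window_sigma=1000.0,
                           q_max=0.03, n_orientations=48, translation_step=250.0,
                           rotation_step=0.5, max_moves=4000, model_geometry="model1",
                           clash_checking=False, seed=21)
        result = refine_copies(prof, start, config)
        assert result.chi2 <= 0.2 * result.chi2_trace[0]


class TestStagedPipeline:
    def test_end_to_end_stages_and_model2_initialisation(self):
        prof = _small_target(seed=19, n=150, noise=0.02)
        blobs = FitConfig(n_copies=150, sigma_blob=40.0, container_diameter=4000.0,
                          window_sigma=1000.0, q_max=0.03, n_orientations=48,
                          translation_step=150.0, max_moves=2500, seed=1,
                          model_geometry="blobs")
        stage = dict(n_copies=200, container_diameter=4000.0, window_sigma=1000.0,
                     q_max=0.03, n_orientations=32, translation_step=80.0,
                     rotation_step=0.4, clash_checking=True)
        configs = {
            "blobs": blobs,
            "model1": FitConfig(max_moves=3000, seed=2, model_geometry="model1", **stage),
            "model2": FitConfig(max_moves=3000, seed=3, model_geometry="model2", **stage),
            "model3": FitConfig(max_moves=3000, seed=4, model_geometry="model3", **stage),
        }
        results = staged_pipeline(prof, configs)
        assert list(results) == ["blobs", "model1", "model2", "model3"]
        for result in results.values():
            assert np.all(np.diff(result.chi2_trace) < 0)
        # every stage ends within 2x of the blob-stage chi2 on the shared window
        for stage_name in ("model1", "model2", "model3"):
            assert results[stage_name].chi2 <= 2.0 * results["blobs"].chi2
        # model-2 chains carry 155 A first segments; model 3 splits further
        assert all(c.segments[0].length == 155.0 for c in results["model2"].final_model.copies)
        assert all(c.n_segments == 3 for c in results["model3"].final_model.copies)

    def test_model2_first_segment_is_collinear_with_its_parent(self):
        prof = _small_target(seed=23, n=100)
        blobs = FitConfig(n_copies=100, sigma_blob=40.0, container_diameter=4000.0,
                          window_sigma=1000.0, q_max=0.03, n_orientations=32,
                          translation_step=150.0, max_moves=1000, seed=1,
                          model_geometry="blobs")
        stage = dict(n_copies=120, container_diameter=4000.0, window_sigma=1000.0,
                     q_max=0.03, n_orientations=24, translation_step=80.0,
                     rotation_step=0.4, clash_checking=True)
        model1_cfg = FitConfig(max_moves=0, seed=2, model_geometry="model1", **stage)
        results = staged_pipeline(prof, {"blobs": blobs, "model1": model1_cfg})
        parents = results["model1"].final_model

        from condensax.rmc import _grow_stage
        model2_cfg = FitConfig(max_moves=0, seed=3, model_geometry="model2", **stage)
        grown = _grow_stage(parents, MODEL_GEOMETRIES["model2"], model2_cfg)
        for parent, child in zip(parents.copies, grown.copies):
            p_seg = parent.segments[0]
            c_seg = child.segments[0]
            ends = [p_seg.start, p_seg.end]
            assert any(np.linalg.norm(c_seg.start - e) < 1e-9 for e in ends)
            assert abs(abs(np.dot(c_seg.axis, p_seg.axis)) - 1.0) < 1e-9

    def test_pipeline_must_start_from_blobs(self):
        prof = _small_target()
        with pytest.raises(InvalidParameterError):
            staged_pipeline(prof, {"model1": FitConfig(model_geometry="model1")})


def test_resolution_limit_arithmetic():
    assert resolution_limit(3000.0) == pytest.approx(2 * np.pi / 3000.0)
    with pytest.raises(InvalidParameterError):
        resolution_limit(-1.0)


def test_spherocylinder_estimator_facade():
    prof = _small_target(seed=31, n=100)
    blob_est = GaussianBlobRMC(n_blobs=100, container_diameter=4000.0,
                               window_sigma=1000.0, n_orientations=32,
                               translation_step=150.0, max_moves=1000, seed=1)
    blob_est.fit(prof)
    est = SpherocylinderRMC(model_geometry="model1", n_copies=100,
                            container_diameter=4000.0, window_sigma=1000.0,
                            n_orientations=24, max_moves=100, seed=2)
    est.fit(prof, blob_result=blob_est.result_)
    assert est.chi2_trace_[-1] <= est.chi2_trace_[0]
    assert est.model_.n_copies == 100
    params = est.get_params()
    assert params["model_geometry"] == "model1"
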