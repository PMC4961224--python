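import numpy as np
import pytest

from contextgain.drc import DRCParams, generate_drc
from contextgain.fitting import (
    FitConfig,
    ModelDims,
    cross_validate,
    fit_cgf_als,
    fit_dual_cgf,
    fit_lowrank_quadratic,
    fit_separable_cgf,
    fit_shared_cgf,
    fit_strf,
)
from contextgain.models import (
    CGFField,
    CGFModel,
    PRFField,
    predict_cgf,
    predict_strf,
    STRFModel,
)
from contextgain.synth import make_ground_truth, simulate_trials

DIMS = ModelDims(4, 4, 2)


def drc(n_bins=4000, seed=0, cpo=2):
    return generate_drc(
        DRCParams(
            n_time_bins=n_bins,
            presence_prob=0.3,
            level_set=(0.4, 0.6, 0.8, 1.0),
            channels_per_octave=cpo,
            seed=seed,
        )
    )


def truth(seed=0, **kwargs):
    return make_ground_truth(
        seed=seed, n_lags=4, n_channels=9, n_delays=4, n_offsets=2,
        channels_per_octave=2.0, **kwargs,
    )


TIGHT = FitConfig(
    ridge_lambda_prf=(1e-8,), ridge_lambda_cgf=(1e-8,),
    convergence_tol=1e-11, max_als_iterations=80,
)


class TestSTRF:
    def test_noiseless_recovery_at_vanishing_ridge(self):
        spec = drc()
        neuron = truth(suppression_amp=0.0, enhancement_amp=0.0)
        rate = predict_strf(STRFModel(neuron.c, neuron.prf.weights), spec)
        model, trace = fit_strf(spec, rate, DIMS, TIGHT)
        assert np.linalg.norm(model.weights - neuron.prf.weights) < 1e-6 * np.linalg.norm(
            neuron.prf.weights
        )
        assert model.c == pytest.approx(neuron.c, abs=1e-6)

    def test_weights_shrink_monotonically_with_ridge(self, rng):
        spec = drc(n_bins=500)
        y = rng.standard_normal(500)  # response unrelated to the stimulus
        norms = []
        for lam in (1e-2, 1.0, 1e2, 1e4):
            model, _ = fit_strf(spec, y, DIMS, FitConfig(ridge_lambda_prf=(lam,)))
            norms.append(np.linalg.norm(model.weights))
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_constant_response_with_large_ridge(self):
        spec = drc(n_bins=800)
        model, _ = fit_strf(spec, np.full(800, 3.0), DIMS, FitConfig(ridge_lambda_prf=(1e8,)))
        assert model.c == pytest.approx(3.0, abs=1e-3)
        assert np.max(np.abs(model.weights)) < 1e-3

    def test_all_silent_stimulus_warns(self):
        from contextgain.drc import Spectrogram

        silent = Spectrogram(np.zeros((100, 9)), channels_per_octave=2)
        with pytest.warns(UserWarning):
            fit_strf(silent, np.ones(100), DIMS, FitConfig(ridge_lambda_prf=(1.0,)))


class TestCGFALS:
    def test_collapsed_cgf_window_equals_strf_exactly(self):
        spec = drc(n_bins=1000)
        neuron = truth(seed=3)
        psth = simulate_trials(neuron, spec, 5, seed=4).psth
        cfg = FitConfig(ridge_lambda_prf=(1.0,), ridge_lambda_cgf=(1.0,))
        strf, _ = fit_strf(spec, psth, ModelDims(4), cfg)
        collapsed, _ = fit_cgf_als(spec, psth, ModelDims(4, 1, 0), cfg)
        np.testing.assert_array_equal(collapsed.prf.weights, strf.weights)
        assert collapsed.c == strf.c

    def test_noiseless_recovery(self):
        spec = drc(n_bins=6000)
        neuron = truth(seed=5)
        rate = predict_cgf(neuron.model, spec)
        model, trace = fit_cgf_als(spec, rate, DIMS, TIGHT)
        r_prf = np.corrcoef(model.prf.weights.ravel(), neuron.prf.weights.ravel())[0, 1]
        r_cgf = np.corrcoef(model.cgf.weights.ravel(), neuron.cgf.weights.ravel())[0, 1]
        assert r_prf > 0.999
        assert r_cgf > 0.999

    def test_training_objective_never_increases(self):
        spec = drc(n_bins=1500, seed=6)
        neuron = truth(seed=6)
        psth = simulate_trials(neuron, spec, 3, seed=7).psth
        _, trace = fit_cgf_als(
            spec, psth, DIMS, FitConfig(convergence_tol=1e-9, max_als_iterations=25)
        )
        objective = np.array(trace.objective)
        assert np.all(np.diff(objective) <= 1e-9 * objective[0])
        mse = np.array(trace.mse)
        assert np.all(np.diff(mse) <= 1e-7 * mse[0])

    def test_masked_entries_are_exactly_zero(self):
        spec = drc(n_bins=1500, seed=8)
        neuron = truth(seed=8)
        psth = simulate_trials(neuron, spec, 3, seed=9).psth
        mask = np.zeros((4, 5), dtype=bool)
        mask[2, :] = True
        cfg = FitConfig(cgf_mask=mask, max_als_iterations=5, convergence_tol=1e-4)
        model, _ = fit_cgf_als(spec, psth, DIMS, cfg)
        assert np.all(model.cgf.weights[2, :] == 0.0)
        assert model.cgf.weights[0, 2] == 0.0
        assert np.any(model.cgf.weights != 0.0)


class TestDualCGF:
    def test_all_true_partition_reduces_to_single_cgf(self):
        spec = drc(n_bins=1200, seed=10)
        neuron = truth(seed=10)
        psth = simulate_trials(neuron, spec, 3, seed=11).psth
        cfg = FitConfig(
            ridge_lambda_prf=(1.0,), ridge_lambda_cgf=(1.0,),
            max_als_iterations=4, convergence_tol=1e-9,
        )
        single, _ = fit_cgf_als(spec, psth, DIMS, cfg)
        dual, _ = fit_dual_cgf(
            spec, psth, DIMS, cfg, partition=np.ones((4, 9), dtype=bool)
        )
        np.testing.assert_allclose(dual.cgf_a.weights, single.cgf.weights, atol=1e-8)
        np.testing.assert_allclose(dual.prf.weights, single.prf.weights, atol=1e-8)

    def test_shared_truth_gives_similar_fields(self):
        """With one true CGF driving all PRF tiles, the two fitted context
        fields should agree."""
        spec = drc(n_bins=8000, seed=12)
        neuron = truth(seed=12)
        rate = predict_cgf(neuron.model, spec)
        model, _ = fit_dual_cgf(
            spec, rate, DIMS,
            FitConfig(ridge_lambda_prf=(1e-6,), ridge_lambda_cgf=(1e-6,),
                      convergence_tol=1e-10, max_als_iterations=40),
        )
        r = np.corrcoef(model.cgf_a.weights.ravel(), model.cgf_b.weights.ravel())[0, 1]
        assert r > 0.95


class TestSeparableCGF:
    def test_rank1_truth_recovered_up_to_scale(self):
        spec = drc(n_bins=8000, seed=13)
        u_true = np.array([0.0, -0.5, -0.3, -0.1])
        v_true = np.array([0.2, 0.6, 1.0, 0.6, 0.2])
        w = np.outer(u_true, v_true)
        w[0, 2] = 0.0
        neuron = truth(seed=13, suppression_amp=0.0, enhancement_amp=0.0)
        true_model = CGFModel(neuron.c, neuron.prf, CGFField(w))
        rate = predict_cgf(true_model, spec)
        model, trace = fit_separable_cgf(
            spec, rate, DIMS,
            FitConfig(ridge_lambda_prf=(1e-7,), ridge_lambda_cgf=(1e-7,),
                      convergence_tol=1e-11, max_als_iterations=60),
        )
        assert np.linalg.norm(model.u_tau) == pytest.approx(1.0)
        r = np.corrcoef(model.cgf.weights.ravel(), w.ravel())[0, 1]
        assert r > 0.999
        mse = np.array(trace.mse)
        assert np.all(np.diff(mse) <= 1e-7 * mse[0])


class TestLowRankQuadratic:
    def test_rank0_equals_strf(self):
        spec = drc(n_bins=1000, seed=14)
        neuron = truth(seed=14)
        psth = simulate_trials(neuron, spec, 3, seed=15).psth
        cfg = FitConfig(ridge_lambda_prf=(1.0,))
        strf, _ = fit_strf(spec, psth, DIMS, cfg)
        lr, _ = fit_lowrank_quadratic(spec, psth, 0, DIMS, cfg)
        np.testing.assert_array_equal(lr.linear, strf.weights.ravel())

    def test_rank1_truth_subspace_alignment(self, rng):
        spec = drc(n_bins=5000, seed=16)
        d = 4 * 9
        b_true = rng.standard_normal(d)
        b_true /= np.linalg.norm(b_true)
        w_true = 0.5 * rng.standard_normal(d)
        from contextgain.models import LowRankQuadraticModel, predict_lowrank_quadratic

        true = LowRankQuadraticModel(0.5, w_true, [(b_true, 0.8)])
        rate = predict_lowrank_quadratic(true, spec)
        fitted, _ = fit_lowrank_quadratic(
            spec, rate, 1, DIMS,
            FitConfig(ridge_lambda_prf=(1e-7,), n_restarts=3, seed=2),
        )
        b_hat = fitted.components[0][0]
        cos = abs(b_hat @ b_true) / np.linalg.norm(b_hat)
        assert cos > 0.99

    def test_contextual_truth_fits_training_data_worse_than_cgf(self):
        """At a comparable parameter budget, the outer-product quadratic
        cannot match the contextual model's own structure even on training
        data."""
        spec = drc(n_bins=4000, seed=17)
        neuron = truth(seed=17)
        rate = predict_cgf(neuron.model, spec)
        cfg = FitConfig(ridge_lambda_prf=(1e-6,), ridge_lambda_cgf=(1e-6,),
                        convergence_tol=1e-9, max_als_iterations=30, seed=3)
        _, trace_cgf = fit_cgf_als(spec, rate, DIMS, cfg)
        _, trace_lr = fit_lowrank_quadratic(spec, rate, 1, DIMS, cfg)
        assert trace_lr.mse[-1] >= trace_cgf.mse[-1]


class TestSharedCGF:
    def test_single_neuron_population_matches_individual_fit(self):
        spec = drc(n_bins=1200, seed=18)
        neuron = truth(seed=18)
        psth = simulate_trials(neuron, spec, 4, seed=19).psth
        cfg = FitConfig(ridge_lambda_prf=(1.0,), ridge_lambda_cgf=(1.0,),
                        max_als_iterations=4, convergence_tol=1e-10)
        single, _ = fit_cgf_als(spec, psth, DIMS, cfg)
        shared_cgf, per_neuron, trace = fit_shared_cgf([(spec, psth)], DIMS, cfg)
        np.testing.assert_allclose(shared_cgf.weights, single.cgf.weights, atol=1e-8)
        mse = np.array(trace.mse)
        assert np.all(np.diff(mse) <= 1e-7 * mse[0])

    def test_pooling_beats_short_individual_fits(self):
        """With one true CGF shared by all neurons and short noisy
        recordings, the pooled estimate is closer to the truth than the
        median individual fit."""
        cfg = FitConfig(ridge_lambda_prf=(1.0,), ridge_lambda_cgf=(1.0,),
                        max_als_iterations=6, convergence_tol=1e-6)
        true_cgf = truth(seed=20).cgf.weights
        population = []
        for i in range(5):
            spec_i = drc(n_bins=1200, seed=30 + i)
            neuron_i = truth(seed=20)  # same CGF, same PRF family
            psth = simulate_trials(neuron_i, spec_i, 3, seed=50 + i).psth
            population.append((spec_i, psth))
        shared_cgf, _, _ = fit_shared_cgf(population, DIMS, cfg)
        shared_err = np.linalg.norm(shared_cgf.weights - true_cgf)
        individual_errs = []
        for spec_i, psth in population:
            m, _ = fit_cgf_als(spec_i, psth, DIMS, cfg)
            individual_errs.append(np.linalg.norm(m.cgf.weights - true_cgf))
        assert shared_err < np.median(individual_errs)


class TestCrossValidation:
    def test_deterministic_and_fold_structure(self, small_recording):
        neuron, spec, trials = small_recording
        dims = ModelDims(8, 8, 3)
        cfg = FitConfig(max_als_iterations=3, convergence_tol=1e-4)
        cv1 = cross_validate("cgf", spec, trials, 2, dims, cfg)
        cv2 = cross_validate("cgf", spec, trials, 2, dims, cfg)
        assert cv1.mean_test_pp == cv2.mean_test_pp
        assert len(cv1.folds) == 2

    def test_fold_shorter_than_window_rejected(self, small_recording):
        _, spec, trials = small_recording
        with pytest.raises(ValueError):
            cross_validate("strf", spec, trials, 2000, ModelDims(8), FitConfig())

    def test_needs_two_folds(self, small_recording):
        _, spec, trials = small_recording
        with pytest.raises(ValueError):
            cross_validate("strf", spec, trials, 1, ModelDims(8), FitConfig())
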