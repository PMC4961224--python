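"""Self-contained simulation studies validating the framework end to end.

Each study builds its own synthetic data from a seed, runs the package's
estimators and analyses, and returns plain-number summaries. They back
both the heavyweight integration tests and the results-reproduction
script, so the measured quantities come from exactly one code path.

``eq1_reference`` is an intentionally naive nested-loop evaluation of the
contextual-gain rate equation, kept free of any shared code with the
vectorized predictors so it can serve as an independent oracle.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .analysis import (
    REGION_PRESETS,
    context_sorted_slopes,
    elide_and_compare,
    region_mask,
    shifted_control_mask,
)
from .drc import DRCParams, generate_drc
from .evaluation import (
    TrialResponses,
    estimate_signal_noise_power,
    population_extrapolation,
)
from .fitting import FitConfig, ModelDims, cross_validate, fit_cgf_als
from .models import (
    CGFField,
    CGFModel,
    PRFField,
    evaluate_volterra,
    predict_cgf,
    to_volterra,
)
from .synth import make_ground_truth, make_population, simulate_trials

# Study-scale fitting settings: on noisy data the ALS objective plateaus
# within a handful of iterations and the weight fields stop moving, so a
# 1e-4 relative-MSE tolerance trades nothing measurable for a severalfold
# iteration saving.
STUDY_CFG = FitConfig(convergence_tol=1e-4, max_als_iterations=25)


def _seeds(seed: int, n: int) -> list:
    return [int(s % 2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


# ---------------------------------------------------------------------------
# independent oracle


def eq1_reference(c: float, prf: np.ndarray, cgf: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Nested-loop evaluation of the contextual-gain rate equation.

    Every sum is written out explicitly with explicit bounds checks for
    the zero-padding convention; quadratic in the window sizes and slow,
    by design.
    """
    n_lags, n_chan = prf.shape
    n_delays, width = cgf.shape
    n_half = (width - 1) // 2
    t_bins = levels.shape[0]
    rate = np.full(t_bins, float(c))
    for i in range(t_bins):
        for j in range(n_lags):
            if i - j < 0:
                continue
            for k in range(n_chan):
                s1 = levels[i - j, k]
                if s1 == 0.0:
                    continue
                ctx = 0.0
                for m in range(n_delays):
                    if i - j - m < 0:
                        continue
                    for n in range(-n_half, n_half + 1):
                        if 0 <= k + n < n_chan:
                            ctx += cgf[m, n + n_half] * levels[i - j - m, k + n]
                rate[i] += prf[j, k] * s1 * (1.0 + ctx)
    return rate


def oracle_equivalence(n_instances: int = 100, seed: int = 0) -> dict:
    """Vectorized predictor and Volterra expansion vs. the nested-loop oracle.

    Random small model/stimulus instances; reports the largest relative
    deviation (normalized by the dynamic range of the oracle rate).
    """
    rng = np.random.default_rng(seed)
    worst_predict = 0.0
    worst_volterra = 0.0
    for _ in range(n_instances):
        t_bins = int(rng.integers(30, 60))
        n_chan = int(rng.integers(4, 10))
        n_lags = int(rng.integers(1, 4))
        n_delays = int(rng.integers(1, 4))
        n_half = int(rng.integers(0, 3))
        levels = rng.random((t_bins, n_chan)) * (rng.random((t_bins, n_chan)) < 0.4)
        prf = rng.standard_normal((n_lags, n_chan))
        cgf = 0.3 * rng.standard_normal((n_delays, 2 * n_half + 1))
        cgf[0, n_half] = 0.0
        c = float(rng.standard_normal())
        reference = eq1_reference(c, prf, cgf, levels)
        scale = max(np.ptp(reference), 1e-12)
        model = CGFModel(c, PRFField(prf), CGFField(cgf))
        worst_predict = max(
            worst_predict, float(np.max(np.abs(predict_cgf(model, levels) - reference)) / scale)
        )
        vc, vl, vq = to_volterra(model)
        worst_volterra = max(
            worst_volterra,
            float(np.max(np.abs(evaluate_volterra(vc, vl, vq, levels) - reference)) / scale),
        )
    return {
        "max_rel_error_predict": worst_predict,
        "max_rel_error_volterra": worst_volterra,
        "n_instances": n_instances,
    }


# ---------------------------------------------------------------------------
# parameter recovery


def parameter_recovery(
    n_neurons: int = 20,
    duration_s: float = 500.0,
    n_trials: int = 20,
    seed: int = 0,
) -> dict:
    """Fit the contextual model to Poisson populations with known truth.

    Returns per-neuron Pearson correlations between fitted and true weight
    fields, their medians, the rank correlation between fitted and true
    suppression-motif amplitudes, and pooled effective-gain statistics of
    the fitted fields over their own stimuli.
    """
    recs = make_population(n_neurons, duration_s=duration_s, n_trials=n_trials, seed=seed)
    dims = ModelDims(8, 8, 3)
    prf_r, cgf_r = [], []
    fitted_amp, true_amp = [], []
    gain_pairs = []
    for rec in recs:
        model, _ = fit_cgf_als(rec.spectrogram, rec.trials.psth, dims, STUDY_CFG)
        prf_r.append(
            float(np.corrcoef(model.prf.weights.ravel(), rec.neuron.prf.weights.ravel())[0, 1])
        )
        cgf_r.append(
            float(np.corrcoef(model.cgf.weights.ravel(), rec.neuron.cgf.weights.ravel())[0, 1])
        )
        # projection of the fitted field onto the unit suppression motif
        from .synth import suppression_motif

        motif = suppression_motif(dims.n_delays, dims.n_offsets)
        fitted_amp.append(-float(np.sum(model.cgf.weights * motif) / np.sum(motif**2)))
        true_amp.append(rec.neuron.suppression_amp)
        gain_pairs.append((model.cgf, rec.spectrogram))
    rho_amp = float(stats.spearmanr(fitted_amp, true_amp).statistic)
    from .analysis import pooled_gain_stats

    pooled, per_rec, sign_p = pooled_gain_stats(gain_pairs)
    return {
        "prf_correlations": prf_r,
        "cgf_correlations": cgf_r,
        "median_prf_r": float(np.median(prf_r)),
        "median_cgf_r": float(np.median(cgf_r)),
        "suppression_amp_rank_r": rho_amp,
        "pooled_gain_median": pooled.median,
        "pooled_gain_iqr": pooled.iqr,
        "pooled_gain_sign_p": sign_p,
        "n_neurons": n_neurons,
    }


def noiseless_recovery(seed: int = 0, duration_s: float = 500.0) -> dict:
    """Exact recovery from the model's own (unrectified) rate at vanishing ridge."""
    neuron = make_ground_truth(seed=seed)
    n_bins = int(duration_s * 1000 / 20)
    spec = generate_drc(
        DRCParams(
            n_time_bins=n_bins,
            presence_prob=0.25,
            level_set=(0.4, 0.6, 0.8, 1.0),
            channels_per_octave=3,
            seed=seed + 1,
        )
    )
    rate = predict_cgf(neuron.model, spec)
    cfg = FitConfig(
        ridge_lambda_prf=(1e-9,),
        ridge_lambda_cgf=(1e-9,),
        convergence_tol=1e-13,
        max_als_iterations=200,
    )
    model, trace = fit_cgf_als(spec, rate, ModelDims(8, 8, 3), cfg)
    rel = lambda a, b: float(np.linalg.norm(a - b) / np.linalg.norm(b))
    return {
        "prf_rel_error": rel(model.prf.weights, neuron.prf.weights),
        "cgf_rel_error": rel(model.cgf.weights, neuron.cgf.weights),
        "c_abs_error": abs(model.c - neuron.c),
        "iterations": trace.iterations,
    }


# ---------------------------------------------------------------------------
# model comparison


def model_comparison(
    n_neurons: int = 20,
    duration_s: float = 200.0,
    n_trials: int = 10,
    k_folds: int = 2,
    seed: int = 0,
    pure_strf: bool = False,
) -> dict:
    """Cross-validated contextual model vs. linear STRF, per neuron.

    With contextual ground truth the CGF model should win in nearly every
    neuron; with pure-STRF ground truth (``pure_strf=True``) the paired
    advantage should be indistinguishable from zero (two-sided sign test).
    """
    amp_kwargs = (
        dict(suppression_amp_range=(0.0, 0.0), enhancement_amp_range=(0.0, 0.0))
        if pure_strf
        else {}
    )
    recs = make_population(
        n_neurons, duration_s=duration_s, n_trials=n_trials, seed=seed, **amp_kwargs
    )
    dims = ModelDims(8, 8, 3)
    advantage = []
    pairs = []
    for rec in recs:
        cv_strf = cross_validate("strf", rec.spectrogram, rec.trials, k_folds, dims, STUDY_CFG)
        cv_cgf = cross_validate("cgf", rec.spectrogram, rec.trials, k_folds, dims, STUDY_CFG)
        pairs.append((cv_strf.mean_test_pp, cv_cgf.mean_test_pp))
        advantage.append(cv_cgf.mean_test_pp - cv_strf.mean_test_pp)
    advantage = np.asarray(advantage)
    nonzero = advantage[advantage != 0]
    if nonzero.size:
        sign_p = float(
            stats.binomtest(int(np.sum(nonzero > 0)), nonzero.size, 0.5).pvalue
        )
    else:
        sign_p = 1.0
    return {
        "win_fraction": float(np.mean(advantage > 0)),
        "mean_advantage": float(advantage.mean()),
        "advantage_sign_p": sign_p,
        "pairs": pairs,
        "n_neurons": n_neurons,
    }


def population_brackets(
    n_neurons: int = 12,
    duration_s: float = 150.0,
    k_folds: int = 2,
    seed: int = 0,
) -> dict:
    """Zero-noise extrapolation over a population with graded trial counts.

    Neurons get different numbers of trials (hence different normalized
    noise powers); training and test predictive powers are regressed on
    normalized noise and extrapolated to the zero-noise intercepts for the
    contextual and linear model families.
    """
    trial_counts = np.linspace(4, 20, n_neurons).round().astype(int)
    recs = make_population(n_neurons, duration_s=duration_s, n_trials=int(trial_counts.max()), seed=seed)
    dims = ModelDims(8, 8, 3)
    out = {}
    for family in ("cgf", "strf"):
        pts = {"training": [], "test": []}
        for rec, n_tr in zip(recs, trial_counts):
            trials = TrialResponses(rec.trials.counts[:n_tr], rec.trials.bin_duration)
            cv = cross_validate(family, rec.spectrogram, trials, k_folds, dims, STUDY_CFG)
            powers = estimate_signal_noise_power(trials)
            pts["test"].append((powers.normalized_noise, cv.mean_test_pp))
            pts["training"].append((powers.normalized_noise, cv.mean_train_pp))
        fit = population_extrapolation(pts)
        out[family] = {
            "test_intercept": fit["test"]["intercept"],
            "training_intercept": fit["training"]["intercept"],
        }
    for family in out:
        lo, hi = sorted(
            (out[family]["test_intercept"], out[family]["training_intercept"])
        )
        out[family]["midpoint"] = 0.5 * (lo + hi)
    return out


# ---------------------------------------------------------------------------
# estimator calibration


def estimator_calibration(seed: int = 0, n_sims: int = 300) -> dict:
    """Signal-power identity, unbiasedness, and exact-line extrapolation."""
    rng = np.random.default_rng(seed)
    # identity on an arbitrary simulated recording
    neuron = make_ground_truth(seed=seed)
    spec = generate_drc(
        DRCParams(n_time_bins=600, presence_prob=0.25, channels_per_octave=3, seed=seed)
    )
    trials = simulate_trials(neuron, spec, 10, seed=seed + 1)
    powers = estimate_signal_noise_power(trials)
    identity_residual = abs(
        powers.mean_trial_power - (powers.signal_power + powers.noise_power)
    ) / powers.mean_trial_power

    # unbiasedness: Poisson trials around a known rate
    rate = np.clip(predict_cgf(neuron.model, spec), 0.0, None)
    true_signal = float(np.var(rate))
    estimates = np.empty(n_sims)
    for i in range(n_sims):
        counts = rng.poisson(rate, size=(10, rate.size)).astype(float)
        estimates[i] = estimate_signal_noise_power(TrialResponses(counts)).signal_power
    bias = estimates.mean() - true_signal
    bias_z = float(bias / (estimates.std(ddof=1) / np.sqrt(n_sims)))

    # exact line recovered exactly
    x = np.array([0.2, 0.5, 1.1, 2.0, 3.5])
    pts = {"test": list(zip(x, 0.8 - 0.1 * x))}
    intercept = population_extrapolation(pts)["test"]["intercept"]
    return {
        "identity_rel_residual": float(identity_residual),
        "signal_power_bias_z": bias_z,
        "signal_power_rel_bias": float(bias / true_signal),
        "extrapolation_intercept_error": float(abs(intercept - 0.8)),
        "n_sims": n_sims,
    }


# ---------------------------------------------------------------------------
# elision


def elision_study(
    n_neurons: int = 30,
    duration_s: float = 150.0,
    n_trials: int = 10,
    seed: int = 0,
) -> dict:
    """Does eliding the region that truly carries contextual mass hurt?

    Ground-truth context fields hold delayed narrowband suppression
    confined to the canonical suppression region (20-120 ms, within 1/3
    octave); the control elision is the same-size region shifted to the
    longest delays, where the truth is exactly zero.
    """
    dims = ModelDims(6, 13, 3)
    bin_ms = 20.0
    cpo = 3.0
    feature = region_mask(
        dims.n_delays, dims.n_offsets, bin_ms, cpo, **REGION_PRESETS["suppression"]
    )
    control = shifted_control_mask(feature)
    recs = make_population(
        n_neurons,
        duration_s=duration_s,
        n_trials=n_trials,
        seed=seed,
        suppression_amp_range=(0.3, 0.55),
        enhancement_amp_range=(0.0, 0.0),
        dims=(dims.n_lags, dims.n_delays, dims.n_offsets),
        cgf_mask=feature,
    )
    result = elide_and_compare(
        [(r.spectrogram, r.trials) for r in recs], dims, STUDY_CFG, feature, control
    )
    return {
        "p_feature": result.p_feature,
        "p_control": result.p_control,
        "p_paired": result.p_paired,
        "mean_delta_feature": float(result.delta_feature.mean()),
        "mean_delta_control": float(result.delta_control.mean()),
        "n_neurons": n_neurons,
    }


# ---------------------------------------------------------------------------
# context-sorted slopes


def _uniform_window_cgf(n_delays: int = 4, n_offsets: int = 3) -> CGFField:
    w = np.ones((n_delays, 2 * n_offsets + 1))
    w[0, n_offsets] = 0.0
    return CGFField(w / w.sum())


def slope_null_calibration(
    n_runs: int = 200,
    duration_s: float = 60.0,
    n_trials: int = 10,
    n_perm: int = 199,
    seed: int = 0,
) -> dict:
    """Distribution of permutation p-values under a pure-STRF truth.

    Context cannot modulate the anchor's gain in a linear neuron, so the
    low-vs-high slope-difference p-value should be uniform; summarized by
    a Kolmogorov-Smirnov test against the uniform distribution.
    """
    n_bins = int(duration_s * 1000 / 20)
    window = _uniform_window_cgf()
    p_values = []
    for run_seed in _seeds(seed, n_runs):
        rng = np.random.default_rng(run_seed)
        neuron = make_ground_truth(
            seed=run_seed, suppression_amp=0.0, enhancement_amp=0.0
        )
        spec = generate_drc(
            DRCParams(
                n_time_bins=n_bins,
                presence_prob=0.25,
                level_set=(0.4, 0.6, 0.8, 1.0),
                channels_per_octave=3,
                seed=int(rng.integers(2**31)),
            )
        )
        trials = simulate_trials(neuron, spec, n_trials, seed=int(rng.integers(2**31)))
        j_a, k_a = np.unravel_index(np.argmax(neuron.prf.weights), neuron.prf.weights.shape)
        res = context_sorted_slopes(
            spec, trials, (int(j_a), int(k_a)), window, n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        p_values.append(res.p_values["low_high"])
    ks = stats.kstest(p_values, "uniform")
    return {
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "n_runs": n_runs,
        "p_values": p_values,
    }


def slope_detection(
    duration_s: float = 400.0,
    n_trials: int = 20,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Power check: facilitatory local context raises the high-context slope.

    Sorting by context at the anchor itself should order the slopes
    (high > low, significant); sorting by context around a distant channel
    should not. The control channel sits two octaves away: the context
    window extends one octave to each side, so that is the smallest
    separation at which the local and distant neighbourhoods do not
    overlap.
    """
    n_bins = int(duration_s * 1000 / 20)
    neuron = make_ground_truth(seed=seed, suppression_amp=0.0, enhancement_amp=0.6)
    spec = generate_drc(
        DRCParams(
            n_time_bins=n_bins,
            presence_prob=0.25,
            level_set=(0.4, 0.6, 0.8, 1.0),
            channels_per_octave=3,
            seed=seed + 1,
        )
    )
    trials = simulate_trials(neuron, spec, n_trials, seed=seed + 2)
    j_a, k_a = np.unravel_index(np.argmax(neuron.prf.weights), neuron.prf.weights.shape)
    j_a, k_a = int(j_a), int(k_a)
    local = context_sorted_slopes(
        spec, trials, (j_a, k_a), neuron.cgf, n_perm=n_perm, seed=seed + 3
    )
    n_chan = spec.n_channels
    distant = k_a + 6 if k_a + 6 < n_chan else k_a - 6  # two octaves at 3 ch/oct
    distant_res = context_sorted_slopes(
        spec, trials, (j_a, k_a), neuron.cgf, distant_channel=distant,
        n_perm=n_perm, seed=seed + 4,
    )
    return {
        "local_slopes": local.slopes.tolist(),
        "local_low_high_p": local.p_values["low_high"],
        "local_ordered": bool(local.slopes[2] > local.slopes[0]),
        "distant_low_high_p": distant_res.p_values["low_high"],
        "n_bins": n_bins,
    }
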