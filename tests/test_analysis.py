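import numpy as np
import pytest

from contextgain.analysis import (
    REGION_PRESETS,
    cgf_pca,
    cgf_profiles,
    context_sorted_slopes,
    gain_distribution_stats,
    gain_vs_advantage,
    pooled_gain_stats,
    population_mean_cgf,
    region_mask,
    shifted_control_mask,
)
from contextgain.drc import DRCParams, Spectrogram, generate_drc
from contextgain.models import CGFField, effective_gain_field
from contextgain.synth import make_ground_truth, simulate_trials


def random_cgf(rng, n_delays=4, n_half=2, scale=0.2):
    w = scale * rng.standard_normal((n_delays, 2 * n_half + 1))
    w[0, n_half] = 0.0
    return CGFField(w)


class TestGainStats:
    def test_zero_cgf_gives_unit_median_zero_iqr(self, small_spec):
        stats = gain_distribution_stats(CGFField.zeros(3, 2), small_spec)
        assert stats.median == 1.0
        assert stats.iqr == 0.0
        assert not stats.iqr_excludes_unity

    def test_uniform_weights_fully_occupied_interior(self):
        """With every usable weight -0.1 and a fully occupied level-1
        stimulus, every interior gain is 1 - 0.1 * (window size - 1)."""
        n_delays, n_half = 3, 2
        w = -0.1 * np.ones((n_delays, 2 * n_half + 1))
        w[0, n_half] = 0.0
        levels = np.ones((30, 20))
        gains = effective_gain_field(CGFField(w), levels)
        expected = 1.0 - 0.1 * (n_delays * (2 * n_half + 1) - 1)
        interior = gains[n_delays - 1 :, n_half:-n_half]
        np.testing.assert_allclose(interior, expected, atol=1e-12)

    def test_quartiles_match_bruteforce_enumeration(self, rng, small_spec):
        cgf = random_cgf(rng)
        stats = gain_distribution_stats(cgf, small_spec)
        gains = effective_gain_field(cgf, small_spec)[small_spec.levels > 0]
        lo, med, hi = np.percentile(gains, [25, 50, 75])
        assert stats.median == pytest.approx(med)
        assert stats.lower_quartile == pytest.approx(lo)
        assert stats.upper_quartile == pytest.approx(hi)
        assert stats.n_tiles == gains.size

    def test_all_tiles_rule(self, rng, small_spec):
        cgf = random_cgf(rng)
        stats = gain_distribution_stats(cgf, small_spec, tile_rule="all")
        assert stats.n_tiles == small_spec.levels.size


class TestPooledGains:
    def test_zero_cgfs_pool_to_unit_median(self, small_spec):
        pooled, per_rec, p = pooled_gain_stats(
            [(CGFField.zeros(3, 2), small_spec)] * 3
        )
        assert pooled.median == 1.0
        assert p == 1.0

    def test_suppressive_population_median_below_one(self, rng, small_spec):
        pairs = []
        for _ in range(5):
            w = -np.abs(0.1 * rng.standard_normal((4, 5))) - 0.02
            w[0, 2] = 0.0
            pairs.append((CGFField(w), small_spec))
        pooled, per_rec, p = pooled_gain_stats(pairs)
        assert pooled.median < 1.0
        assert p < 0.05
        assert all(g.median <= 1.0 for g in per_rec)

    def test_per_recording_flags_match_bruteforce(self, rng, small_spec):
        pairs = [(random_cgf(rng), small_spec) for _ in range(4)]
        _, per_rec, _ = pooled_gain_stats(pairs)
        for (cgf, spec), stats in zip(pairs, per_rec):
            gains = effective_gain_field(cgf, spec)[spec.levels > 0]
            lo, hi = np.percentile(gains, [25, 75])
            assert stats.iqr_excludes_unity == (not lo <= 1.0 <= hi)


class TestGainVsAdvantage:
    def test_perfectly_monotone_relation(self):
        from contextgain.analysis import GainStats

        stats = [GainStats(1.0 - 0.05 * i, 0.9, 1.1 + 0.1 * i, 100) for i in range(8)]
        adv = [0.01 * i for i in range(8)]
        res = gain_vs_advantage(stats, adv)
        assert res["iqr"][0] == pytest.approx(1.0)
        assert res["median"][0] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self, rng):
        from contextgain.analysis import GainStats

        n = 200
        stats = [GainStats(rng.random(), 0.0, rng.random(), 10) for _ in range(n)]
        adv = rng.random(n)
        res = gain_vs_advantage(stats, adv)
        # within 3 SDs of the permutation null (SD ~ 1/sqrt(n-1))
        assert abs(res["iqr"][0]) < 3.0 / np.sqrt(n - 1)
        assert res["iqr"][1] > 0.01

    def test_ties_use_average_ranks(self):
        from contextgain.analysis import GainStats
        from scipy import stats as sps

        med = [1.0, 1.0, 0.8, 0.7]
        iqr = [0.3, 0.2, 0.2, 0.5]
        adv = [0.0, 0.1, 0.1, 0.4]
        stats_list = [GainStats(m, 0.0, q, 10) for m, q in zip(med, iqr)]
        res = gain_vs_advantage(stats_list, adv)
        assert res["median"][0] == pytest.approx(sps.spearmanr(med, adv).statistic)
        assert res["iqr"][0] == pytest.approx(sps.spearmanr(iqr, adv).statistic)


class TestContextSortedSlopes:
    def test_constant_context_energy_rejected(self):
        levels = np.zeros((200, 9))
        spec = Spectrogram(levels, channels_per_octave=2)
        cgf = CGFField.zeros(3, 2)
        with pytest.raises(ValueError):
            context_sorted_slopes(spec, np.ones(200), (1, 4), cgf, n_perm=10)

    def test_facilitatory_context_orders_slopes(self):
        neuron = make_ground_truth(seed=21, suppression_amp=0.0, enhancement_amp=0.6)
        spec = generate_drc(
            DRCParams(n_time_bins=12000, presence_prob=0.25,
                      level_set=(0.4, 0.6, 0.8, 1.0), channels_per_octave=3, seed=22)
        )
        trials = simulate_trials(neuron, spec, 20, seed=23)
        j, k = np.unravel_index(np.argmax(neuron.prf.weights), neuron.prf.weights.shape)
        res = context_sorted_slopes(
            spec, trials, (int(j), int(k)), neuron.cgf, n_perm=399, seed=3
        )
        assert res.slopes[2] > res.slopes[0]
        assert res.p_values["low_high"] < 0.05
        assert res.tercile_counts.sum() == spec.n_time_bins

    def test_terciles_partition_near_equally(self, small_recording):
        neuron, spec, trials = small_recording
        j, k = np.unravel_index(np.argmax(neuron.prf.weights), neuron.prf.weights.shape)
        res = context_sorted_slopes(spec, trials, (int(j), int(k)), neuron.cgf, n_perm=20)
        assert np.ptp(res.tercile_counts) <= 1


class TestProfiles:
    def test_single_weight_profiles(self):
        w = np.zeros((4, 5))
        w[2, 0] = 0.6
        prof = cgf_profiles(w)
        expected_t = np.zeros(4)
        expected_t[2] = 0.6 / 5
        np.testing.assert_allclose(prof["temporal"], expected_t)
        expected_s = np.zeros(5)
        expected_s[0] = 0.6 / 4
        np.testing.assert_allclose(prof["spectral"], expected_s)
        np.testing.assert_allclose(prof["zero_lag_spectral"], np.zeros(5))

    def test_symmetric_field_gives_symmetric_spectral_profile(self, rng):
        half = rng.standard_normal((3, 2))
        w = np.hstack([half, rng.standard_normal((3, 1)), half[:, ::-1]])
        w[0, 2] = 0.0
        prof = cgf_profiles(w)
        np.testing.assert_allclose(prof["spectral"], prof["spectral"][::-1])

    def test_profiles_match_bruteforce_means(self, rng):
        w = rng.standard_normal((5, 7))
        prof = cgf_profiles(w)
        np.testing.assert_allclose(prof["temporal"], [row.mean() for row in w])
        np.testing.assert_allclose(prof["spectral"], [col.mean() for col in w.T])


class TestPopulationMean:
    def test_identical_members(self, rng):
        cgf = random_cgf(rng)
        out = population_mean_cgf([cgf, CGFField(cgf.weights.copy())])
        mean, se, n = out["all"]
        np.testing.assert_allclose(mean, cgf.weights)
        np.testing.assert_allclose(se, 0.0, atol=1e-15)
        assert n == 2

    def test_two_member_hand_mean_and_groups(self):
        a = CGFField.zeros(2, 1)
        w = np.zeros((2, 3))
        w[1, 0] = 2.0
        b = CGFField(w)
        out = population_mean_cgf([a, b, a], groups=["x", "x", "y"])
        mean_x, se_x, n_x = out["x"]
        assert mean_x[1, 0] == pytest.approx(1.0)
        assert n_x == 2
        assert out["y"][2] == 1


class TestRegions:
    def test_suppression_preset_covers_printed_window(self):
        """20-120 ms delays within 1/3 octave of the anchor frequency."""
        mask = region_mask(13, 3, 20.0, 3.0, **REGION_PRESETS["suppression"])
        rows = np.flatnonzero(mask.any(axis=1))
        np.testing.assert_array_equal(rows, [1, 2, 3, 4, 5, 6])  # 20..120 ms
        cols = np.flatnonzero(mask.any(axis=0))
        np.testing.assert_array_equal(cols, [2, 3, 4])  # within 1 channel = 1/3 oct
        assert not mask[0, 3]

    def test_enhancement_presets(self):
        mask = region_mask(13, 3, 20.0, 3.0, **REGION_PRESETS["enhancement"])
        rows = np.flatnonzero(mask.any(axis=1))
        np.testing.assert_array_equal(rows, [0, 1])  # delays < 40 ms
        assert not mask[0, 3]  # zero-offset entry excluded
        off = region_mask(13, 3, 20.0, 3.0, **REGION_PRESETS["enhancement_offfreq"])
        assert not off[:, 2:5].any()  # nothing within 1/3 octave
        assert off[0, 0] and off[1, 6]

    def test_control_mask_same_size_disjoint_later(self):
        feature = region_mask(13, 3, 20.0, 3.0, **REGION_PRESETS["suppression"])
        control = shifted_control_mask(feature)
        assert control.sum() == feature.sum()
        assert not np.any(control & feature)
        assert np.flatnonzero(control.any(axis=1)).min() > np.flatnonzero(
            feature.any(axis=1)
        ).max()


class TestElisionNoiseless:
    def test_eliding_truly_empty_region_costs_nothing(self):
        """If the ground-truth CGF is zero inside the elided region, the
        refit recovers identical generalization."""
        from contextgain.analysis import elide_and_compare
        from contextgain.evaluation import TrialResponses
        from contextgain.fitting import FitConfig, ModelDims
        from contextgain.models import predict_cgf

        dims = ModelDims(4, 6, 2)
        feature = np.zeros((6, 5), dtype=bool)
        feature[4:6, 1:4] = True
        control = np.zeros((6, 5), dtype=bool)
        control[2:4, 1:4] = True  # also empty of truth below
        # keep truth only outside both test regions
        truth_mask = ~(feature | control)
        neuron = make_ground_truth(
            seed=24, n_lags=4, n_channels=9, n_delays=6, n_offsets=2,
            channels_per_octave=2.0, suppression_amp=0.3, enhancement_amp=0.2,
            suppression_delay_ms=10.0, cgf_mask=truth_mask,
        )
        spec = generate_drc(
            DRCParams(n_time_bins=3000, presence_prob=0.3,
                      level_set=(0.5, 1.0), channels_per_octave=2, seed=25)
        )
        rate = predict_cgf(neuron.model, spec)
        trials = TrialResponses(np.tile(np.clip(rate, 0, None), (2, 1)))
        cfg = FitConfig(ridge_lambda_prf=(1e-6,), ridge_lambda_cgf=(1e-6,),
                        convergence_tol=1e-8, max_als_iterations=25)
        res = elide_and_compare([(spec, trials)], dims, cfg, feature, control)
        assert abs(res.delta_feature[0]) < 1e-3
        assert abs(res.delta_control[0]) < 1e-3


class TestCGFPCA:
    def test_single_mode_population(self, rng):
        base = random_cgf(rng)
        comp = random_cgf(rng)
        cgfs = []
        for alpha in np.linspace(-1, 1, 9):
            w = base.weights + alpha * comp.weights
            w[0, 2] = 0.0
            cgfs.append(CGFField(w))
        res = cgf_pca(cgfs)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-10)

    def test_components_orthonormal_and_fractions_sum_to_one(self, rng):
        cgfs = [random_cgf(rng) for _ in range(12)]
        res = cgf_pca(cgfs)
        keep = np.ones((4, 5), dtype=bool)
        keep[0, 2] = False
        vecs = np.stack([c[keep] for c in res.components])
        gram = vecs @ vecs.T
        np.testing.assert_allclose(gram, np.eye(len(vecs)), atol=1e-10)
        assert res.variance_fractions.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.variance_fractions) <= 1e-12)
        # zero-offset entry carries no component mass
        assert all(c[0, 2] == 0.0 for c in res.components)

    def test_two_motif_population_spans_motif_plane(self, rng):
        from contextgain.synth import enhancement_motif, suppression_motif

        m1 = suppression_motif(4, 2, channels_per_octave=2.0)
        m2 = enhancement_motif(4, 2, channels_per_octave=2.0)
        keep = np.ones((4, 5), dtype=bool)
        keep[0, 2] = False
        basis = np.stack([m1[keep], m2[keep]])
        basis /= np.linalg.norm(basis, axis=1, keepdims=True)
        cgfs = []
        for _ in range(100):
            a, b = rng.standard_normal(2)
            w = a * m1 + b * m2 + 0.01 * rng.standard_normal((4, 5))
            w[0, 2] = 0.0
            cgfs.append(CGFField(w))
        res = cgf_pca(cgfs)
        lead = np.stack([c[keep] for c in res.components[:2]])
        # principal angles between fitted 2-D subspace and the motif plane
        q1, _ = np.linalg.qr(lead.T)
        q2, _ = np.linalg.qr(basis.T)
        sv = np.linalg.svd(q1.T @ q2, compute_uv=False)
        angles_deg = np.degrees(np.arccos(np.clip(sv, -1, 1)))
        assert np.all(angles_deg < 5.0)

    def test_needs_two_fields(self, rng):
        with pytest.raises(ValueError):
            cgf_pca([random_cgf(rng)])
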