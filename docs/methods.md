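# Methods

## Model

The contextual-gain model predicts a binned firing rate from a stimulus
spectrogram through a principal receptive field (PRF) whose inputs are
multiplicatively modulated by a shared contextual gain field (CGF):

    r(i) = c + Σ_{j=0..J} Σ_{k=1..K} w^tf_{j,k} s(i−j,k) · (1 + Σ_{m=0..M} Σ_{n=−N..N} w^τφ_{m,n} s(i−j−m,k+n))

Assumptions built into this form: context is integrated *linearly* within
the CGF window; the integrated context affects the input's gain linearly;
and the same CGF applies at every PRF position. The rate is therefore a
quadratic function of the stimulus — a second-order Volterra expansion
whose linear kernel is the PRF and whose quadratic kernel is the outer
structure of PRF x CGF products (`models.to_volterra` makes this
explicit). The zero-offset CGF weight (τ=0, φ=0) is structurally zero so
that no stimulus tile modulates its own gain; an isolated tone therefore
produces an exactly linear response. Model rates are unconstrained reals:
the quadratic form can go negative, and rectification happens only in the
spike simulator, because all fitting is least squares on trial-averaged
rates.

### Conventions

* Spectrograms are `(time bins, channels)` arrays; channels are log-spaced
  with both band edges included. Levels are stored as fractions of the
  loudest possible tone (1.0 = loudest), so CGF weights read directly as
  the change in gain caused by one of the loudest tones at that offset.
* All sums zero-pad outside the stimulus: times before onset and
  frequencies beyond the band edges are silent. This is the physically
  correct convention for a band-limited stimulus and reproduces the
  band-edge asymmetries one expects there (the outer part of the context
  window receives no energy).
* Time indexing is 0-based; CGF frequency offsets are signed with column
  N the anchor channel.

## Fitting

The model is bilinear in `(c, PRF)` and in the CGF, so it is fit by
alternating least squares. With the CGF fixed, the gain grid
`1 + s (*) CGF` is formed, and `(c, PRF)` solves a ridge least-squares
problem on gain-scaled lagged regressors; with the PRF fixed, the free CGF
entries solve a ridge problem on regressors
`z_mn(i) = Σ_{j,k} w^tf_{j,k} s(i−j,k) s(i−j−m,k+n)`, with the pure linear
prediction as a fixed offset. Each step solves its subproblem exactly, so
the penalized training objective is non-increasing (asserted on every
`FitTrace`). Details:

* **Initialization.** The CGF starts at zero, making the first PRF step
  exactly the STRF fit; ALS is fully deterministic.
* **Regularization.** Ridge per factor, with the weight chosen by inner
  cross-validation on contiguous blocks of the training rows (grid
  `1e-2 … 1e6`; the top of the grid lets the CGF shrink to ~0 when the
  data carry no contextual structure). An optional second-difference
  smoothness penalty per field is available but off by default. Ridge
  weights are selected once (PRF weight at the initial STRF fit, CGF
  weight at the first CGF step) and then frozen so the monotonicity
  guarantee holds.
* **Convergence.** Relative training-MSE change below `convergence_tol`
  (default 1e-6) or `max_als_iterations` (default 100). On noisy data the
  weight fields stop moving within ~5 iterations while the MSE keeps
  creeping along a regularization path, so the simulation studies use
  `tol=1e-4, max 25` — measured to change recovered-field correlations by
  < 0.001.
* **Degeneracy.** Normal equations are solved as positive-definite
  systems with a minimum-norm least-squares fallback; an all-silent
  stimulus is caught with a warning (the fit is then determined by the
  ridge alone).
* **Masks.** A boolean CGF mask forces entries to zero by excluding their
  columns from the CGF step; the structural zero-offset entry is always
  masked. This one mechanism implements both the model constraint and the
  elision experiments.

The **dual-CGF** model fits separate context fields to two partitions of
the PRF (default: excitatory vs. inhibitory tiles of the initial STRF
fit) by three-block ALS. The **separable** model stores the factors of a
rank-1 CGF (`u_τ ⊗ v_φ`, zero-offset entry zeroed after the product) and
alternates exact solves for u and v; u is renormalized to unit norm each
iteration since the product is identifiable only up to reciprocal scaling,
and the spectral factor is initialized as a deterministic broad bump. The
**low-rank quadratic** comparison model (`r = c + w·x + Σ_d λ_d (b_d·x)²`,
with signed free λ) is not bilinear and is fit by L-BFGS with analytic
gradients and seeded restarts, initialized at the STRF solution. The
**shared-CGF** population fit pools the CGF-step normal equations across
neurons while keeping per-neuron `(c, PRF)` steps.

Cross-validation uses contiguous time segments as folds. Fold boundaries
depend only on the bin count and fold number, so every model family is
scored on identical folds and can be compared pairwise per recording.
Regressors are formed over the whole timeline (they depend only on the
stimulus); responses are split cleanly into training and test rows.

## Evaluation

With R repeated trials and P(·) the variance over time bins, the response
power decomposes as

    P_signal = (R·P(PSTH) − mean_r P(trial_r)) / (R − 1),   P_noise = mean_r P(trial_r) − P_signal,

an identity (`mean trial power = signal + noise`) that holds exactly by
construction and is unbiased for additive trial noise. A prediction is
scored by `PP_raw = P_signal + P_noise − mean_r P(trial_r − prediction)`
and normalized by `P_signal`; the normalized value is 1 for the true
underlying rate, 0 for the mean rate, and can be negative. Powers are
variances across time bins in (spikes/bin)².

Recordings are screened by requiring the signal power to exceed z (default
2) leave-one-trial-out jackknife standard errors. Population summaries
regress normalized predictive power on normalized noise power
(`P_noise / P_signal`) by unweighted ordinary least squares, separately
for training and test roles, and report the zero-noise intercepts; the two
intercepts bracket the attainable predictive power of a model family
(training overfits upward, test pays a generalization penalty).
Weighted/robust variants are deliberately not defaulted.

## Analyses

* **Effective gains.** `1 + s (*) CGF` per stimulus tile. Distribution
  statistics are quartiles over *occupied* tiles by default (gain only
  acts where there is input to scale); an all-tiles rule is available.
  Pooled-population medians are tested against 1 with a two-sided sign
  test (ties dropped).
* **Context-sorted slopes.** For an anchor offset (lag, channel), the
  regressor is the anchor level per bin and bins are split into terciles
  of the CGF-weighted context energy around the anchor (or around a
  distant control channel). Per-tercile slopes come from least-squares
  lines; pairwise slope differences are tested by permuting tercile labels
  across bins (default 10,000 resamples, two-sided, with the +1
  small-sample correction, so p-values are valid at any resample count).
  Tercile ties are broken by stable sort order. The distant control in the
  simulation studies sits two octaves from the anchor because the context
  window spans ±1 octave — the smallest separation with non-overlapping
  neighbourhoods.
* **Elision.** A CGF region given in physical units (ms, octaves) is
  mapped to grid tiles, forced to zero, and the whole model refit; the
  change in cross-validated predictive power over a population is tested
  with one-tailed sign tests (feature region, equal-size control region,
  and paired feature-vs-control), uncorrected. Built-in presets: delayed
  narrowband suppression (20–120 ms inclusive, |φ| ≤ 1/3 octave),
  near-simultaneous enhancement (τ < 40 ms, all φ), its off-frequency
  part (τ < 40 ms, |φ| > 1/3 octave); the control region is the feature
  mask time-shifted to the longest delays, preserving tile count and
  spectral footprint.
* **CGF PCA.** Context fields are vectorized with the structurally zero
  entry removed (it would otherwise masquerade as zero-variance
  structure), mean-centred, and decomposed by SVD. Reported: orthonormal
  component fields, variance fractions, and the fraction of the mean
  field's sum of squares inside the span of the leading components.

## Synthetic data

The generator emulates the study conditions end to end. Stimuli are
dynamic random chords: independent tone presence per tile
(default probability 0.25), levels uniform on {0.4, 0.6, 0.8, 1.0}
(normalized to the loudest tone), 20 ms bins, 2–32 kHz. The full
49-channel (12 channels/octave) grid is supported, but the simulation
studies use 3 channels/octave (13 channels) with an 8-lag (160 ms) PRF and
an 8-delay × ±1-octave CGF window — coarse enough for the full study suite
to run on one CPU in minutes while preserving every structural feature of
the problem.

Ground-truth neurons have a localized excitatory PRF peak with a weaker
delayed inhibitory flank (centre frequency and latency seeded per neuron)
and a CGF built from the two motifs that dominate real cortical and
thalamic context fields: narrowband delayed suppression (negative
Gaussian lobe, default centre 60 ms, widths 30 ms × 0.25 octave) and
broadband near-simultaneous enhancement (positive lobe, widths 15 ms ×
0.7 octave), with per-neuron amplitudes (defaults: suppression uniform on
0.2–0.5, enhancement on 0.05–0.3, giving pooled median effective gains
≈ 0.8 and IQRs ≈ 0.3 — realistically suppressive without frequent negative
gains). The baseline (1 spike/bin = 50 Hz) and PRF amplitude (0.7) keep
rate rectification rare (~2% of bins), since heavy rectification would
bias the least-squares fits the framework assumes. Spikes are Poisson
around the rectified rate, independently per trial and bin.

What the generator does *not* emulate: non-Poisson overdispersion, spike
history and adaptation, output nonlinearities, context structure beyond
the assumed bilinear form, and correlated (natural-sound-like) stimulus
statistics. Passing the recovery and comparison studies therefore shows
the estimators and statistics are correct and calibrated under the model's
own assumptions — not that real neurons satisfy them.

## Study sizes and numerical choices

The reproduction script and the integration tests use: 100 random
instances for oracle equivalence (float-precision agreement with a
nested-loop reference); 20 neurons × 500 s × 20 trials for parameter
recovery (median fitted-vs-true correlation, both fields); one 500 s
noiseless fit at ridge 1e-9 and tolerance 1e-13 for exact recovery; 20
contextual and 15 linear-truth neurons × 200 s × 10 trials × 2 folds for
the model comparison; 30 neurons × 150 s for the elision experiment (truth
confined to the suppression preset region); 200 runs × 60 s with 199
permutations for null calibration of the slope test (KS against uniform)
and one 400 s recording with 999 permutations for the detection check.
These sizes were chosen once as the smallest populations at which the
qualitative contrasts are decisively powered.

Known limitations: ALS is guaranteed monotone but not globally convergent
(the zero-CGF start has always reached the generating optimum in the
noiseless studies, but multimodality is possible in principle); ridge
grids are coarse by design; the low-rank quadratic fit depends on restart
seeds; and the zero-noise extrapolation assumes the linear trend of
predictive power in normalized noise extends to zero.
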