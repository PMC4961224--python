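"""Trial-based power decomposition and predictive-power normalization.

Repeated presentations of the same stimulus let the response variance be
split into a stimulus-locked *signal* part and a trial-varying *noise*
part. Writing ``P(x)`` for the variance of a series over time bins and
``R`` for the trial count, the unbiased decomposition is

    P_signal = (R * P(PSTH) - mean_r P(trial_r)) / (R - 1)
    P_noise  = mean_r P(trial_r) - P_signal

which satisfies ``mean_r P(trial_r) = P_signal + P_noise`` exactly.

A model prediction is scored by its raw predictive power
``P_signal + P_noise - mean_r P(trial_r - prediction)`` and reported as a
fraction of the signal power ("normalized predictive power"): 1 means the
prediction captures all stimulus-locked response power, 0 is no better
than the mean rate, and negative values are possible for bad predictions.
Because each recording's score degrades with its noise level, population
summaries regress normalized predictive power against normalized noise
power and read off the zero-noise intercept, separately for training and
test roles; the two intercepts bracket the attainable predictive power of
the model class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "TrialResponses",
    "PowerEstimates",
    "PredictivePower",
    "estimate_signal_noise_power",
    "jackknife_signal_power_se",
    "predictive_power",
    "select_recordings",
    "population_extrapolation",
]


@dataclass
class TrialResponses:
    """Binned spike counts, trials x time, aligned to the stimulus grid."""

    counts: np.ndarray
    bin_duration: float = 20.0
    alignment_offset: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (trials x time bins)")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_time_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def psth(self) -> np.ndarray:
        """Trial-averaged rate, spikes per bin."""
        return self.counts.mean(axis=0)


@dataclass
class PowerEstimates:
    """Signal/noise decomposition of trial-based response power.

    All powers are variances over time bins, in (spikes/bin)^2.
    """

    signal_power: float
    noise_power: float
    mean_trial_power: float

    @property
    def normalized_noise(self) -> float:
        return self.noise_power / self.signal_power


@dataclass
class PredictivePower:
    """Raw and signal-normalized predictive power of one prediction."""

    raw: float
    normalized: float
    error_power: float


def _time_variance(x: np.ndarray) -> float:
    return float(np.var(x))


def estimate_signal_noise_power(trials: TrialResponses) -> PowerEstimates:
    """Unbiased signal/noise power decomposition from repeated trials.

    Requires at least two trials. The decomposition identity
    ``mean_trial_power == signal_power + noise_power`` holds exactly by
    construction; for additive independent trial noise the signal-power
    estimate is unbiased.
    """
    r = trials.n_trials
    if r < 2:
        raise ValueError("signal/noise decomposition requires at least 2 trials")
    per_trial = np.var(trials.counts, axis=1)
    mean_trial_power = float(per_trial.mean())
    psth_power = _time_variance(trials.psth)
    signal = (r * psth_power - mean_trial_power) / (r - 1)
    return PowerEstimates(
        signal_power=float(signal),
        noise_power=float(mean_trial_power - signal),
        mean_trial_power=mean_trial_power,
    )


def jackknife_signal_power_se(trials: TrialResponses) -> float:
    """Leave-one-trial-out jackknife standard error of the signal power."""
    r = trials.n_trials
    if r < 3:
        raise ValueError("jackknife over trials requires at least 3 trials")
    estimates = np.empty(r)
    for i in range(r):
        keep = np.ones(r, dtype=bool)
        keep[i] = False
        estimates[i] = estimate_signal_noise_power(
            TrialResponses(trials.counts[keep], trials.bin_duration)
        ).signal_power
    return float(np.sqrt((r - 1) / r * np.sum((estimates - estimates.mean()) ** 2)))


def predictive_power(
    prediction: np.ndarray, trials: TrialResponses, powers: PowerEstimates
) -> PredictivePower:
    """Score a rate prediction against repeated trials.

    The error power is the mean over trials of the variance of the
    per-trial residual; raw predictive power is
    ``signal + noise - error``, and the normalized value divides by the
    signal power. Both prediction and trials may be shifted by a common
    constant without changing the result.
    """
    prediction = np.asarray(prediction, dtype=float).ravel()
    if prediction.size != trials.n_time_bins:
        raise ValueError("prediction length must match the trial time axis")
    residuals = trials.counts - prediction[None, :]
    error_power = float(np.mean(np.var(residuals, axis=1)))
    raw = powers.signal_power + powers.noise_power - error_power
    return PredictivePower(
        raw=float(raw),
        normalized=float(raw / powers.signal_power),
        error_power=error_power,
    )


def select_recordings(
    recordings: Iterable[TrialResponses], z: float = 2.0
) -> list:
    """Indices of recordings with significantly nonzero signal power.

    A recording is kept when its estimated signal power exceeds ``z``
    jackknife standard errors; this screens out units whose apparent
    stimulus-locked power is within noise of zero.
    """
    kept = []
    for idx, rec in enumerate(recordings):
        powers = estimate_signal_noise_power(rec)
        se = jackknife_signal_power_se(rec)
        if powers.signal_power > z * se:
            kept.append(idx)
    return kept


def population_extrapolation(points_by_role: dict) -> dict:
    """Zero-noise extrapolation of population predictive power.

    ``points_by_role`` maps a role name (e.g. ``'test'``, ``'training'``)
    to a sequence of ``(normalized_noise, normalized_pp)`` pairs, one per
    recording. For each role an ordinary least-squares line of predictive
    power against normalized noise power is fit; the value of the line at
    zero noise is the extrapolated population limit. Returns
    ``{role: {'intercept': ..., 'slope': ..., 'n': ...}}``.
    """
    out = {}
    for role, pts in points_by_role.items():
        pts = np.asarray(list(pts), dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2:
            raise ValueError(f"role {role!r} needs at least 2 recordings")
        x, y = pts[:, 0], pts[:, 1]
        if np.ptp(x) == 0:
            raise ValueError(f"role {role!r} has identical noise levels; cannot extrapolate")
        slope, intercept = np.polyfit(x, y, 1)
        out[role] = {"intercept": float(intercept), "slope": float(slope), "n": int(x.size)}
    return out
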