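"""Ground-truth neurons and Poisson spike simulation.

Synthetic neurons follow the same generative structure the models assume:
a localized principal receptive field (excitatory peak with a delayed
inhibitory flank) whose inputs are multiplicatively modulated by a context
field built from the two motifs that dominate real cortical/thalamic
context fields — narrowband delayed suppression (a negative lobe at small
frequency offsets and delays of tens of milliseconds) and broadband
near-simultaneous enhancement (a positive lobe at short delays across a
wide band of frequency offsets). Trial responses are Poisson counts drawn
around the rectified model rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .drc import DRCParams, Spectrogram, generate_drc
from .evaluation import TrialResponses
from .models import CGFField, CGFModel, PRFField, predict_cgf

__all__ = [
    "GroundTruthNeuron",
    "SimulatedRecording",
    "suppression_motif",
    "enhancement_motif",
    "make_ground_truth",
    "simulate_trials",
    "make_population",
]

# Desk-scale defaults for simulation studies: 20 ms chord bins over
# 2-32 kHz at 3 channels/octave (13 channels), an 8-lag (160 ms) PRF
# window and an 8-delay x +/-3-channel (+/-1 octave) CGF window.
DEFAULT_GRID = dict(
    bin_duration=20.0,
    freq_lo=2000.0,
    freq_hi=32000.0,
    channels_per_octave=3,
)
DEFAULT_N_LAGS = 8
DEFAULT_N_DELAYS = 8
DEFAULT_N_OFFSETS = 3
DEFAULT_PRESENCE_PROB = 0.25
DEFAULT_LEVELS = (0.4, 0.6, 0.8, 1.0)


@dataclass
class GroundTruthNeuron:
    """A known (c, PRF, CGF) triple plus the motif amplitudes that built it."""

    c: float
    prf: PRFField
    cgf: CGFField
    suppression_amp: float
    enhancement_amp: float

    @property
    def model(self) -> CGFModel:
        return CGFModel(self.c, self.prf, self.cgf)


@dataclass
class SimulatedRecording:
    """One synthetic recording: stimulus, ground truth, and Poisson trials."""

    spectrogram: Spectrogram
    neuron: GroundTruthNeuron
    trials: TrialResponses
    seed: int
    rate: np.ndarray = field(repr=False, default=None)


def _gauss2(tau: np.ndarray, phi: np.ndarray, tau0, sig_t, sig_f) -> np.ndarray:
    return np.exp(
        -0.5 * ((tau[:, None] - tau0) / sig_t) ** 2 - 0.5 * (phi[None, :] / sig_f) ** 2
    )


def suppression_motif(
    n_delays: int,
    n_offsets: int,
    bin_duration: float = 20.0,
    channels_per_octave: float = 3.0,
    delay_ms: float = 60.0,
    delay_width_ms: float = 30.0,
    freq_width_oct: float = 0.25,
) -> np.ndarray:
    """Unit-amplitude narrowband delayed suppression (returned positive;
    subtract it scaled to build a CGF)."""
    tau = np.arange(n_delays) * bin_duration
    phi = np.arange(-n_offsets, n_offsets + 1) / channels_per_octave
    m = _gauss2(tau, phi, delay_ms, delay_width_ms, freq_width_oct)
    m[0, n_offsets] = 0.0
    return m


def enhancement_motif(
    n_delays: int,
    n_offsets: int,
    bin_duration: float = 20.0,
    channels_per_octave: float = 3.0,
    delay_width_ms: float = 15.0,
    freq_width_oct: float = 0.7,
) -> np.ndarray:
    """Unit-amplitude broadband near-simultaneous enhancement."""
    tau = np.arange(n_delays) * bin_duration
    phi = np.arange(-n_offsets, n_offsets + 1) / channels_per_octave
    m = _gauss2(tau, phi, 0.0, delay_width_ms, freq_width_oct)
    m[0, n_offsets] = 0.0
    return m


def make_ground_truth(
    seed: int = 0,
    n_lags: int = DEFAULT_N_LAGS,
    n_channels: int = 13,
    n_delays: int = DEFAULT_N_DELAYS,
    n_offsets: int = DEFAULT_N_OFFSETS,
    bin_duration: float = 20.0,
    channels_per_octave: float = 3.0,
    c: float = 1.0,
    prf_amp: float = 0.7,
    suppression_amp: float = 0.35,
    enhancement_amp: float = 0.2,
    suppression_delay_ms: float = 60.0,
    cgf_mask: Optional[np.ndarray] = None,
) -> GroundTruthNeuron:
    """Deterministic ground-truth neuron from motif parameters.

    The PRF is an excitatory Gaussian peak at a seed-dependent centre
    frequency and short latency, with a weaker, delayed, spectrally offset
    inhibitory flank. The CGF is ``enhancement_amp * enhancement -
    suppression_amp * suppression``; zero amplitudes give a pure-STRF
    neuron. ``cgf_mask`` optionally zeroes entries outside a region, for
    truths confined to a known feature.
    """
    rng = np.random.default_rng(seed)
    lag = np.arange(n_lags)[:, None]
    chan = np.arange(n_channels)[None, :]
    centre = rng.uniform(0.25, 0.75) * (n_channels - 1)
    peak_lag = rng.uniform(0.5, 1.5)
    exc = np.exp(-0.5 * ((lag - peak_lag) / 1.0) ** 2 - 0.5 * ((chan - centre) / 1.2) ** 2)
    inh = np.exp(
        -0.5 * ((lag - peak_lag - 2.0) / 1.5) ** 2 - 0.5 * ((chan - centre) / 2.0) ** 2
    )
    prf = prf_amp * (exc - 0.5 * inh)

    cgf = enhancement_amp * enhancement_motif(
        n_delays, n_offsets, bin_duration, channels_per_octave
    ) - suppression_amp * suppression_motif(
        n_delays,
        n_offsets,
        bin_duration,
        channels_per_octave,
        delay_ms=suppression_delay_ms,
    )
    if cgf_mask is not None:
        cgf = np.where(cgf_mask, cgf, 0.0)
    cgf[0, n_offsets] = 0.0
    return GroundTruthNeuron(
        c=c,
        prf=PRFField(prf),
        cgf=CGFField(cgf),
        suppression_amp=suppression_amp,
        enhancement_amp=enhancement_amp,
    )


def simulate_trials(
    neuron: GroundTruthNeuron, spec: Spectrogram, n_trials: int, seed: int = 0
) -> TrialResponses:
    """Poisson trials around the rectified model rate.

    The model rate can be negative (it is an unconstrained quadratic);
    spike generation clips it at zero, which is the only place in the
    package where rectification happens.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    rate = predict_cgf(neuron.model, spec)
    clipped = np.clip(rate, 0.0, None)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(clipped, size=(n_trials, rate.size)).astype(float)
    return TrialResponses(counts, spec.bin_duration)


def _drc_params(n_time_bins: int, seed: int, **overrides) -> DRCParams:
    grid = dict(DEFAULT_GRID)
    grid.update({k: overrides.pop(k) for k in list(overrides) if k in grid})
    return DRCParams(
        n_time_bins=n_time_bins,
        presence_prob=overrides.pop("presence_prob", DEFAULT_PRESENCE_PROB),
        level_set=overrides.pop("level_set", DEFAULT_LEVELS),
        seed=seed,
        **grid,
    )


def make_population(
    n_neurons: int,
    duration_s: float = 500.0,
    n_trials: int = 20,
    seed: int = 0,
    suppression_amp_range: tuple = (0.2, 0.5),
    enhancement_amp_range: tuple = (0.05, 0.3),
    n_channels: int = 13,
    dims: tuple = (DEFAULT_N_LAGS, DEFAULT_N_DELAYS, DEFAULT_N_OFFSETS),
    cgf_mask: Optional[np.ndarray] = None,
    **drc_overrides,
) -> list:
    """Independent synthetic recordings with per-neuron motif amplitudes.

    Each neuron gets its own DRC stimulus and Poisson trials; per-neuron
    seeds are spawned deterministically from the master seed. Amplitudes
    are drawn uniformly from the given ranges (set a range to ``(0, 0)``
    for pure-STRF populations).
    """
    n_lags, n_delays, n_offsets = dims
    bin_ms = drc_overrides.get("bin_duration", DEFAULT_GRID["bin_duration"])
    n_bins = int(round(duration_s * 1000.0 / bin_ms))
    master = np.random.SeedSequence(seed)
    recordings = []
    for child in master.spawn(n_neurons):
        sub = child.generate_state(4)
        rng = np.random.default_rng(sub[0])
        s_amp = rng.uniform(*suppression_amp_range)
        e_amp = rng.uniform(*enhancement_amp_range)
        neuron = make_ground_truth(
            seed=int(sub[1] % 2**31),
            n_lags=n_lags,
            n_channels=n_channels,
            n_delays=n_delays,
            n_offsets=n_offsets,
            bin_duration=bin_ms,
            channels_per_octave=drc_overrides.get(
                "channels_per_octave", DEFAULT_GRID["channels_per_octave"]
            ),
            suppression_amp=s_amp,
            enhancement_amp=e_amp,
            cgf_mask=cgf_mask,
        )
        spec = generate_drc(_drc_params(n_bins, int(sub[2] % 2**31), **dict(drc_overrides)))
        trials = simulate_trials(neuron, spec, n_trials, seed=int(sub[3] % 2**31))
        rec = SimulatedRecording(
            spectrogram=spec,
            neuron=neuron,
            trials=trials,
            seed=int(sub[0] % 2**31),
            rate=np.clip(predict_cgf(neuron.model, spec), 0.0, None),
        )
        recordings.append(rec)
    return recordings
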