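"""Dynamic random chord (DRC) stimuli and the shared time-frequency grid.

A DRC is a sequence of brief chords on a regular time x log-frequency grid:
in every time bin, each frequency channel independently carries a tone pip
with some probability, at a level drawn from a discrete set. Levels are
stored as fractions of the loudest possible tone (1.0 = loudest), so that
downstream gain weights read directly as "change in gain per loudest tone".

This module also defines the two array conventions every other module
relies on:

* spectrograms are ``(n_time_bins, n_channels)`` arrays, time first;
* the lagged context sum zero-pads outside the stimulus, both before
  stimulus onset and beyond the band edges, i.e. silence outside the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import oaconvolve


def log_spaced_channels(freq_lo: float, freq_hi: float, channels_per_octave: int) -> np.ndarray:
    """Geometrically spaced channel centre frequencies from ``freq_lo`` to ``freq_hi``.

    The grid always includes both edges; the number of channels is
    ``round(channels_per_octave * log2(freq_hi / freq_lo)) + 1``.
    """
    if freq_lo <= 0 or freq_hi <= freq_lo:
        raise ValueError("need 0 < freq_lo < freq_hi")
    n_octaves = np.log2(freq_hi / freq_lo)
    n_channels = int(round(channels_per_octave * n_octaves)) + 1
    return freq_lo * 2.0 ** (np.arange(n_channels) * n_octaves / (n_channels - 1))


@dataclass
class Spectrogram:
    """Stimulus levels on a time x log-frequency grid.

    Parameters
    ----------
    levels
        ``(n_time_bins, n_channels)`` array of normalized tone levels in
        ``[0, 1]``; 0 means silence in that tile.
    bin_duration
        Duration of one time bin, ms.
    freq_lo, freq_hi
        Band edges, Hz.
    channels_per_octave
        Channel density of the log-frequency grid.
    """

    levels: np.ndarray
    bin_duration: float = 20.0
    freq_lo: float = 2000.0
    freq_hi: float = 32000.0
    channels_per_octave: int = 12
    channel_freqs: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.ndim != 2:
            raise ValueError("levels must be 2-D (time bins x channels)")
        if not np.all(np.isfinite(self.levels)) or np.any(self.levels < 0):
            raise ValueError("levels must be finite and non-negative")
        self.channel_freqs = log_spaced_channels(
            self.freq_lo, self.freq_hi, self.channels_per_octave
        )
        if self.levels.shape[1] != self.channel_freqs.size:
            raise ValueError(
                f"levels has {self.levels.shape[1]} channels but the grid "
                f"defines {self.channel_freqs.size}"
            )

    @property
    def n_time_bins(self) -> int:
        return self.levels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.levels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_time_bins * self.bin_duration / 1000.0


@dataclass
class DRCParams:
    """Parameters of a dynamic random chord stimulus.

    ``presence_prob`` is the probability that any tile carries a tone;
    present tones draw their level uniformly from ``level_set`` (normalized
    levels in (0, 1], 1.0 = loudest tone).
    """

    n_time_bins: int
    presence_prob: float = 0.1
    level_set: tuple = (0.2, 0.4, 0.6, 0.8, 1.0)
    bin_duration: float = 20.0
    freq_lo: float = 2000.0
    freq_hi: float = 32000.0
    channels_per_octave: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.presence_prob <= 1.0:
            raise ValueError("presence_prob must lie in [0, 1]")
        if self.presence_prob > 0 and len(self.level_set) == 0:
            raise ValueError("level_set must be non-empty when presence_prob > 0")
        if any(not (0.0 < v <= 1.0) for v in self.level_set):
            raise ValueError("level_set values must lie in (0, 1]")


def generate_drc(params: DRCParams) -> Spectrogram:
    """Draw a DRC spectrogram: independent tone presence and level per tile."""
    rng = np.random.default_rng(params.seed)
    n_channels = log_spaced_channels(
        params.freq_lo, params.freq_hi, params.channels_per_octave
    ).size
    shape = (params.n_time_bins, n_channels)
    present = rng.random(shape) < params.presence_prob
    if len(params.level_set):
        levels = rng.choice(np.asarray(params.level_set, dtype=float), size=shape)
    else:
        levels = np.zeros(shape)
    return Spectrogram(
        levels=np.where(present, levels, 0.0),
        bin_duration=params.bin_duration,
        freq_lo=params.freq_lo,
        freq_hi=params.freq_hi,
        channels_per_octave=params.channels_per_octave,
    )


def lagged_context_sum(spec: "Spectrogram | np.ndarray", cgf_weights: np.ndarray) -> np.ndarray:
    """Convolve a spectrogram with a context field over relative offsets.

    Entry ``(t, f)`` of the result is

    ``sum_{m=0..M} sum_{n=-N..N} w[m, n+N] * s(t - m, f + n)``

    with zero-padding outside the stimulus grid: times before onset and
    frequencies beyond the band edges contribute nothing. ``cgf_weights``
    is ``(M+1, 2N+1)`` with row 0 the zero-delay row and column ``N`` the
    zero-frequency-offset column.
    """
    levels = spec.levels if isinstance(spec, Spectrogram) else np.asarray(spec, dtype=float)
    w = np.asarray(cgf_weights, dtype=float)
    if w.ndim != 2 or w.shape[1] % 2 == 0:
        raise ValueError("context weights must be (M+1, 2N+1) with odd width")
    n_half = (w.shape[1] - 1) // 2
    t_bins, n_chan = levels.shape
    # s(t-m, f+n) as a 2-D convolution: flip the frequency axis of the kernel.
    full = oaconvolve(levels, w[:, ::-1], mode="full")
    return full[:t_bins, n_half : n_half + n_chan]
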