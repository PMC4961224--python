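"""Encoding model classes and their exact prediction semantics.

The core model predicts a firing rate from a stimulus spectrogram
``s(t, f)`` through two weight fields:

* a principal receptive field (PRF) ``w_tf`` over absolute time lag ``j``
  and frequency channel ``k`` — the spectrotemporal sensitivity of the
  neuron to an isolated tone;
* a contextual gain field (CGF) ``w_tauphi`` over *relative* time offset
  ``tau`` and signed frequency offset ``phi`` — the weights with which the
  acoustic neighbourhood of each stimulus tile sets that tile's
  multiplicative gain.

The modeled rate at time bin ``i`` is

    r(i) = c + sum_{j,k} w_tf[j,k] * s(i-j, k) * (1 + sum_{m,n} w_tauphi[m,n] * s(i-j-m, k+n))

with the zero-offset CGF weight (tau=0, phi=0) structurally fixed to 0, so
that no tile contributes to its own context and an isolated tone is still
handled linearly. The model is an unconstrained quadratic in the stimulus;
rates may go negative, and rectification is left to simulators.

Also here: the baseline linear STRF, a dual-CGF variant (separate context
fields for two partitions of the PRF), a rank-1 separable CGF, the
low-rank quadratic (outer-product Volterra) comparison model, expansion of
the CGF model to explicit Volterra kernels, and parameter counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .drc import Spectrogram, lagged_context_sum

__all__ = [
    "PRFField",
    "CGFField",
    "STRFModel",
    "CGFModel",
    "DualCGFModel",
    "SeparableCGFModel",
    "LowRankQuadraticModel",
    "lagged_design",
    "apply_linear_field",
    "predict_strf",
    "effective_gain_field",
    "predict_cgf",
    "predict_dual_cgf",
    "predict_separable",
    "predict_lowrank_quadratic",
    "to_volterra",
    "evaluate_volterra",
    "count_parameters",
]


def _levels(spec) -> np.ndarray:
    return spec.levels if isinstance(spec, Spectrogram) else np.asarray(spec, dtype=float)


@dataclass
class PRFField:
    """Linear weights over (time lag, frequency channel).

    ``weights[j, k]`` multiplies ``s(i - j, k)``: row 0 is the
    instantaneous lag, later rows reach further into the past. Units are
    rate change (spikes/bin) per unit normalized level.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("PRF weights must be 2-D (lags x channels)")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("PRF weights must be finite")

    @property
    def n_lags(self) -> int:
        return self.weights.shape[0]

    @property
    def n_channels(self) -> int:
        return self.weights.shape[1]


@dataclass
class CGFField:
    """Contextual gain weights over (relative delay tau, signed frequency offset phi).

    Shape ``(M+1, 2N+1)``: row ``m`` is delay ``tau = m`` bins, column
    ``n + N`` is frequency offset ``phi = n`` channels (column ``N`` is the
    anchor channel). The zero-offset entry ``(0, N)`` is structurally 0.
    Weights are dimensionless gain change per unit normalized level.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] % 2 == 0:
            raise ValueError("CGF weights must be (M+1, 2N+1) with odd width")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("CGF weights must be finite")
        if self.weights[0, self.n_offsets] != 0.0:
            raise ValueError("zero-offset CGF weight must be exactly 0")

    @property
    def n_delays(self) -> int:
        """M + 1, number of delay rows."""
        return self.weights.shape[0]

    @property
    def n_offsets(self) -> int:
        """N, the half-width of the frequency-offset axis."""
        return (self.weights.shape[1] - 1) // 2

    @classmethod
    def zeros(cls, n_delays: int, n_offsets: int) -> "CGFField":
        return cls(np.zeros((n_delays, 2 * n_offsets + 1)))


@dataclass
class STRFModel:
    """Linear spectrotemporal receptive field model: ``r = c + w * s``."""

    c: float
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)


@dataclass
class CGFModel:
    """Constant + PRF + CGF: the multiplicative input-specific-gain model."""

    c: float
    prf: PRFField
    cgf: CGFField


@dataclass
class DualCGFModel:
    """CGF model with separate context fields for two partitions of the PRF.

    ``partition`` is a boolean mask over PRF tiles; ``True`` tiles take
    their gain from ``cgf_a``, ``False`` tiles from ``cgf_b``.
    """

    c: float
    prf: PRFField
    partition: np.ndarray
    cgf_a: CGFField
    cgf_b: CGFField

    def __post_init__(self) -> None:
        self.partition = np.asarray(self.partition, dtype=bool)
        if self.partition.shape != self.prf.weights.shape:
            raise ValueError("partition mask must match the PRF shape")


@dataclass
class SeparableCGFModel:
    """CGF constrained to a rank-1 outer product ``u_tau (x) v_phi``.

    The factors are stored, not their product, so the rank-1 constraint is
    exact under fitting; the zero-offset entry is forced to 0 after the
    product is formed.
    """

    c: float
    prf: PRFField
    u_tau: np.ndarray
    v_phi: np.ndarray

    def __post_init__(self) -> None:
        self.u_tau = np.asarray(self.u_tau, dtype=float).ravel()
        self.v_phi = np.asarray(self.v_phi, dtype=float).ravel()
        if self.v_phi.size % 2 == 0:
            raise ValueError("v_phi must have odd length (2N+1)")

    @property
    def cgf(self) -> CGFField:
        w = np.outer(self.u_tau, self.v_phi)
        w[0, (self.v_phi.size - 1) // 2] = 0.0
        return CGFField(w)


@dataclass
class LowRankQuadraticModel:
    """Quadratic model with a low-rank second-order kernel.

    ``r(i) = c + w . x_i + sum_d lambda_d (b_d . x_i)^2`` where ``x_i`` is
    the lagged stimulus patch at time ``i`` (same window as the PRF).
    ``components`` is a sequence of ``(b_d, lambda_d)`` pairs with ``b_d``
    a vector over PRF tiles and ``lambda_d`` a free signed coefficient.
    """

    c: float
    linear: np.ndarray
    components: Sequence = field(default_factory=list)

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float)
        self.components = [
            (np.asarray(b, dtype=float).ravel(), float(lam)) for b, lam in self.components
        ]
        d = self.linear.size
        for b, _ in self.components:
            if b.size != d:
                raise ValueError("component vectors must match the PRF tile count")

    @property
    def rank(self) -> int:
        return len(self.components)


# ---------------------------------------------------------------------------
# prediction


def lagged_design(levels: np.ndarray, n_lags: int) -> np.ndarray:
    """Lagged stimulus patches as a design matrix.

    Returns ``X`` of shape ``(T, n_lags * K)`` with ``X[i]`` the flattened
    patch ``s(i - j, k)`` for ``j = 0..n_lags-1`` (row-major in ``(j, k)``),
    zero-padded before stimulus onset.
    """
    t_bins, n_chan = levels.shape
    padded = np.pad(levels, ((n_lags - 1, 0), (0, 0)))
    win = sliding_window_view(padded, n_lags, axis=0)  # (T, K, n_lags); win[i,k,a]=s(i+a-(J), k)
    return np.ascontiguousarray(win[:, :, ::-1].transpose(0, 2, 1)).reshape(t_bins, -1)


def apply_linear_field(levels: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Causal application of a (lags x channels) weight field to a spectrogram."""
    n_lags, n_chan = weights.shape
    if levels.shape[1] != n_chan:
        raise ValueError(
            f"stimulus has {levels.shape[1]} channels, weights expect {n_chan}"
        )
    t_bins = levels.shape[0]
    out = np.zeros(t_bins)
    # one matrix-vector product per lag keeps everything contiguous
    out += levels @ weights[0]
    for j in range(1, min(n_lags, t_bins)):
        out[j:] += levels[: t_bins - j] @ weights[j]
    return out


def predict_strf(model: STRFModel, spec) -> np.ndarray:
    """Rate series of the linear STRF model, zero-padded before onset."""
    return model.c + apply_linear_field(_levels(spec), model.weights)


def effective_gain_field(cgf: CGFField, spec) -> np.ndarray:
    """Realized multiplicative gain at every stimulus tile: ``1 + s (*) CGF``.

    A gain of 1 everywhere means a purely linear response; values above 1
    mark tiles whose influence is boosted by their local acoustic context,
    values below 1 tiles that are contextually suppressed.
    """
    return 1.0 + lagged_context_sum(_levels(spec), cgf.weights)


def predict_cgf(model: CGFModel, spec) -> np.ndarray:
    """Rate series of the CGF model.

    Computed in two stages: the stimulus is convolved with the CGF to form
    the effective gain at each tile, then the gain-scaled stimulus is passed
    through the PRF and offset by the baseline ``c``.
    """
    levels = _levels(spec)
    gain = effective_gain_field(model.cgf, levels)
    return model.c + apply_linear_field(levels * gain, model.prf.weights)


def predict_dual_cgf(model: DualCGFModel, spec) -> np.ndarray:
    """Rate series of the dual-CGF model: per-tile gain from the tile's partition."""
    levels = _levels(spec)
    gain_a = effective_gain_field(model.cgf_a, levels)
    gain_b = effective_gain_field(model.cgf_b, levels)
    prf_a = np.where(model.partition, model.prf.weights, 0.0)
    prf_b = np.where(model.partition, 0.0, model.prf.weights)
    return (
        model.c
        + apply_linear_field(levels * gain_a, prf_a)
        + apply_linear_field(levels * gain_b, prf_b)
    )


def predict_separable(model: SeparableCGFModel, spec) -> np.ndarray:
    """Rate series of the rank-1 separable CGF model."""
    return predict_cgf(CGFModel(model.c, model.prf, model.cgf), spec)


def predict_lowrank_quadratic(model: LowRankQuadraticModel, spec) -> np.ndarray:
    """Rate series of the low-rank quadratic model."""
    levels = _levels(spec)
    n_lags = model.linear.size // levels.shape[1]
    if n_lags * levels.shape[1] != model.linear.size:
        raise ValueError("linear weight length is not a multiple of the channel count")
    x = lagged_design(levels, n_lags)
    rate = model.c + x @ model.linear
    for b, lam in model.components:
        rate = rate + lam * (x @ b) ** 2
    return rate


# ---------------------------------------------------------------------------
# Volterra expansion


def to_volterra(model: CGFModel):
    """Expand a CGF model into explicit Volterra kernels.

    Returns ``(c, linear, quadratic)`` where ``linear`` equals the PRF
    weights and ``quadratic[j, k, a, b]`` couples the PRF tile
    ``s(i-j, k)`` with the context tile ``s(i-a, k + (b - N))`` for
    ``a = 0..J+M`` and frequency column ``b`` spanning ``K + 2N`` channels
    (context channels may fall outside the stimulus band; those tiles are
    silent by the padding convention). Entries are products
    ``prf[j, k] * cgf[m, n]`` placed at ``a = j + m``, ``b = k + n + N``.
    """
    prf = model.prf.weights
    cgf = model.cgf.weights
    n_lags, n_chan = prf.shape
    n_delays, width = cgf.shape
    n_half = (width - 1) // 2
    quad = np.zeros((n_lags, n_chan, n_lags - 1 + n_delays, n_chan + 2 * n_half))
    for m in range(n_delays):
        for n in range(-n_half, n_half + 1):
            w = cgf[m, n + n_half]
            if w == 0.0:
                continue
            for j in range(n_lags):
                for k in range(n_chan):
                    quad[j, k, j + m, k + n + n_half] += prf[j, k] * w
    return model.c, prf.copy(), quad


def evaluate_volterra(c: float, linear: np.ndarray, quadratic: np.ndarray, spec) -> np.ndarray:
    """Evaluate an expanded Volterra form on a spectrogram.

    Context channels beyond the band edges and times before onset are
    silent, matching the padding convention of the direct model.
    """
    levels = _levels(spec)
    t_bins, n_chan = levels.shape
    n_lags = linear.shape[0]
    _, _, n_ctx_lags, n_ctx_chan = quadratic.shape
    n_half = (n_ctx_chan - n_chan) // 2
    padded = np.pad(levels, ((0, 0), (n_half, n_half)))
    rate = c + apply_linear_field(levels, linear)
    for i in range(t_bins):
        acc = 0.0
        for j in range(min(n_lags, i + 1)):
            for k in range(n_chan):
                s1 = levels[i - j, k]
                if s1 == 0.0:
                    continue
                for a in range(min(n_ctx_lags, i + 1)):
                    row = padded[i - a]
                    acc += s1 * float(quadratic[j, k, a] @ row)
        rate[i] += acc
    return rate


def count_parameters(
    kind: str,
    n_lags: int,
    n_channels: int,
    n_delays: int = 0,
    n_offsets: int = 0,
    rank: int = 0,
) -> int:
    """Free-parameter count of a model class.

    ``kind`` is one of ``'strf'``, ``'cgf'``, ``'full_volterra'``,
    ``'lowrank_quadratic'``. ``n_lags`` is J+1, ``n_delays`` is M+1,
    ``n_offsets`` is N. The CGF count subtracts 1 for the structurally
    zero entry; the full Volterra count uses the symmetric quadratic
    kernel over D = n_lags * n_channels tiles.
    """
    d = n_lags * n_channels
    if kind == "strf":
        return 1 + d
    if kind == "cgf":
        return 1 + d + n_delays * (2 * n_offsets + 1) - 1
    if kind == "full_volterra":
        return 1 + d + d * (d + 1) // 2
    if kind == "lowrank_quadratic":
        return 1 + d + rank * d
    raise ValueError(f"unknown model kind: {kind!r}")
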