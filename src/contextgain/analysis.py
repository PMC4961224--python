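"""Population analyses of contextual gain.

Everything downstream of fitting lives here: distributions of effective
input-specific gains over a stimulus, the model-free context-sorted slope
analysis with permutation tests, temporal/spectral profiles and population
means of context fields, feature-elision refits with sign tests, and PCA
of context fields across a population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .drc import Spectrogram, lagged_context_sum
from .models import CGFField, effective_gain_field
from .fitting import FitConfig, ModelDims, cross_validate

__all__ = [
    "GainStats",
    "SlopeAnalysis",
    "ElisionResult",
    "CGFPCAResult",
    "gain_distribution_stats",
    "pooled_gain_stats",
    "gain_vs_advantage",
    "context_sorted_slopes",
    "cgf_profiles",
    "population_mean_cgf",
    "region_mask",
    "REGION_PRESETS",
    "elide_and_compare",
    "cgf_pca",
]


# ---------------------------------------------------------------------------
# effective-gain distributions


@dataclass
class GainStats:
    """Quartile summary of effective input-specific gains over a stimulus."""

    median: float
    lower_quartile: float
    upper_quartile: float
    n_tiles: int

    @property
    def iqr(self) -> float:
        return self.upper_quartile - self.lower_quartile

    @property
    def iqr_excludes_unity(self) -> bool:
        return not (self.lower_quartile <= 1.0 <= self.upper_quartile)


def _select_gains(cgf: CGFField, spec, tile_rule: str) -> np.ndarray:
    gains = effective_gain_field(cgf, spec)
    levels = spec.levels if isinstance(spec, Spectrogram) else np.asarray(spec)
    if tile_rule == "occupied":
        return gains[levels > 0]
    if tile_rule == "all":
        return gains.ravel()
    raise ValueError("tile_rule must be 'occupied' or 'all'")


def gain_distribution_stats(cgf: CGFField, spec, tile_rule: str = "occupied") -> GainStats:
    """Quartiles of the effective gain across stimulus tiles.

    By default only occupied tiles (nonzero stimulus level) enter the
    distribution — gain acts only where there is input to scale; pass
    ``tile_rule='all'`` to pool every tile.
    """
    gains = _select_gains(cgf, spec, tile_rule)
    lo, med, hi = np.percentile(gains, [25, 50, 75])
    return GainStats(float(med), float(lo), float(hi), int(gains.size))


def pooled_gain_stats(
    pairs: Sequence, tile_rule: str = "occupied"
) -> tuple:
    """Pooled gain quartiles across recordings, plus per-recording summaries.

    Returns ``(pooled GainStats, per-recording [GainStats], sign-test p)``
    where the p-value tests whether the pooled median gain differs from 1
    (two-sided sign test on pooled gains; exact ties with 1 are dropped).
    """
    per_rec = [gain_distribution_stats(cgf, spec, tile_rule) for cgf, spec in pairs]
    pooled = np.concatenate([_select_gains(cgf, spec, tile_rule) for cgf, spec in pairs])
    lo, med, hi = np.percentile(pooled, [25, 50, 75])
    below = int(np.sum(pooled < 1.0))
    above = int(np.sum(pooled > 1.0))
    n_eff = below + above
    p = stats.binomtest(below, n_eff, 0.5).pvalue if n_eff else 1.0
    return GainStats(float(med), float(lo), float(hi), int(pooled.size)), per_rec, float(p)


def gain_vs_advantage(
    gain_stats: Sequence[GainStats], advantage: Sequence[float]
) -> dict:
    """Spearman rank correlations between gain statistics and the per-recording
    predictive advantage of the contextual model over the linear STRF.

    Returns ``{'iqr': (rho, p), 'median': (rho, p)}`` with ties handled as
    average ranks.
    """
    adv = np.asarray(advantage, dtype=float)
    iqr = np.array([g.iqr for g in gain_stats])
    med = np.array([g.median for g in gain_stats])
    rho_i, p_i = stats.spearmanr(iqr, adv)
    rho_m, p_m = stats.spearmanr(med, adv)
    return {"iqr": (float(rho_i), float(p_i)), "median": (float(rho_m), float(p_m))}


# ---------------------------------------------------------------------------
# context-sorted slope analysis


@dataclass
class SlopeAnalysis:
    """Per-tercile stimulus-response slopes and permutation p-values.

    ``slopes[g]`` is the least-squares slope of response on anchor level
    within context-energy tercile ``g`` (0 = low, 2 = high); ``p_values``
    maps pair labels (``'low_mid'``, ``'mid_high'``, ``'low_high'``) to
    two-sided permutation p-values for the slope difference.
    """

    anchor: tuple
    slopes: np.ndarray
    slope_ses: np.ndarray
    p_values: dict
    tercile_counts: np.ndarray


def _group_slopes(x: np.ndarray, y: np.ndarray, labels: np.ndarray, n_groups: int) -> np.ndarray:
    """Vectorized per-group regression slope of y on x."""
    counts = np.bincount(labels, minlength=n_groups).astype(float)
    sx = np.bincount(labels, weights=x, minlength=n_groups)
    sy = np.bincount(labels, weights=y, minlength=n_groups)
    sxx = np.bincount(labels, weights=x * x, minlength=n_groups)
    sxy = np.bincount(labels, weights=x * y, minlength=n_groups)
    denom = sxx - sx * sx / counts
    with np.errstate(invalid="ignore", divide="ignore"):
        return (sxy - sx * sy / counts) / denom


def context_sorted_slopes(
    spec,
    responses,
    anchor: tuple,
    context_cgf: CGFField,
    distant_channel: Optional[int] = None,
    groups: int = 3,
    n_perm: int = 10_000,
    seed: int = 0,
) -> SlopeAnalysis:
    """Does local context modulate the gain of a single spectrotemporal input?

    For every response bin ``i`` the regressor is the stimulus level at the
    anchor offset ``(lag j_a, channel k_a)``, i.e. ``s(i - j_a, k_a)``, and
    the response is the PSTH at ``i``. Bins are split into terciles of the
    context energy — the CGF-weighted integrated level in the neighbourhood
    of the anchor tile (or of a distant control tile on another channel if
    ``distant_channel`` is given). A least-squares line is fit within each
    tercile; if context sets the gain of this input, the slope should grow
    from the low- to the high-context tercile when sorting by *local*
    context but not by distant context. Pairwise slope differences are
    tested by permuting tercile labels across bins (two-sided, with the
    +1 small-sample correction).
    """
    levels = spec.levels if isinstance(spec, Spectrogram) else np.asarray(spec, dtype=float)
    j_a, k_a = anchor
    t_bins = levels.shape[0]
    counts = responses.counts if hasattr(responses, "counts") else np.asarray(responses)
    y = counts.mean(axis=0) if counts.ndim == 2 else counts
    if y.size != t_bins:
        raise ValueError("response length must match the stimulus")
    x = np.zeros(t_bins)
    x[j_a:] = levels[: t_bins - j_a if j_a else t_bins, k_a]

    context_channel = k_a if distant_channel is None else distant_channel
    energy_grid = lagged_context_sum(levels, context_cgf.weights)
    energy = np.zeros(t_bins)
    energy[j_a:] = energy_grid[: t_bins - j_a if j_a else t_bins, context_channel]
    if np.ptp(energy) == 0:
        raise ValueError("context energy is constant; terciles are undefined")

    order = np.argsort(energy, kind="stable")
    labels = np.empty(t_bins, dtype=np.intp)
    for g, chunk in enumerate(np.array_split(order, groups)):
        labels[chunk] = g
    counts_per = np.bincount(labels, minlength=groups)
    if counts_per.min() < 20:
        raise ValueError("too few bins per tercile (need >= 20)")

    slopes = _group_slopes(x, y, labels, groups)
    ses = np.empty(groups)
    for g in range(groups):
        sel = labels == g
        xg, yg = x[sel], y[sel]
        slope, intercept = np.polyfit(xg, yg, 1)
        resid = yg - (slope * xg + intercept)
        sxx = np.sum((xg - xg.mean()) ** 2)
        ses[g] = np.sqrt(resid @ resid / (xg.size - 2) / sxx)

    pairs = {"low_mid": (0, 1), "mid_high": (1, 2), "low_high": (0, 2)}
    observed = {k: slopes[b] - slopes[a] for k, (a, b) in pairs.items()}
    rng = np.random.default_rng(seed)
    exceed = {k: 0 for k in pairs}
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        s = _group_slopes(x, y, perm, groups)
        for k, (a, b) in pairs.items():
            if abs(s[b] - s[a]) >= abs(observed[k]):
                exceed[k] += 1
    p_values = {k: (exceed[k] + 1) / (n_perm + 1) for k in pairs}
    return SlopeAnalysis(
        anchor=(j_a, k_a),
        slopes=slopes,
        slope_ses=ses,
        p_values=p_values,
        tercile_counts=counts_per,
    )


# ---------------------------------------------------------------------------
# CGF profiles, population means


def cgf_profiles(cgf_weights: np.ndarray) -> dict:
    """Temporal, spectral, and zero-delay spectral profiles of a context field.

    Temporal profile: mean over frequency offsets per delay; spectral
    profile: mean over delays per frequency offset; zero-lag profile: the
    delay-0 row itself. The structurally zero entry participates in the
    averages like any other entry.
    """
    w = np.asarray(cgf_weights, dtype=float)
    return {
        "temporal": w.mean(axis=1),
        "spectral": w.mean(axis=0),
        "zero_lag_spectral": w[0].copy(),
    }


def population_mean_cgf(
    cgfs: Sequence[CGFField], groups: Optional[Sequence] = None
) -> dict:
    """Mean and SE context fields, optionally per group label.

    Returns ``{group: (mean_field, se_field, n)}``; with ``groups=None``
    a single entry keyed ``'all'``.
    """
    stack = np.stack([c.weights for c in cgfs])
    labels = ["all"] * len(cgfs) if groups is None else list(groups)
    out = {}
    for lab in dict.fromkeys(labels):
        sel = stack[[i for i, l in enumerate(labels) if l == lab]]
        n = sel.shape[0]
        se = sel.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(sel[0])
        out[lab] = (sel.mean(axis=0), se, n)
    return out


# ---------------------------------------------------------------------------
# feature elision


def region_mask(
    n_delays: int,
    n_offsets: int,
    bin_duration: float,
    channels_per_octave: float,
    tau_range_ms: tuple,
    phi_rule: tuple,
    inclusive_hi: bool = False,
) -> np.ndarray:
    """Boolean CGF mask for a region in physical units.

    ``tau_range_ms = (lo, hi)`` selects delays with ``lo <= tau < hi``
    (``lo <= tau <= hi`` when ``inclusive_hi``; tau of row m is
    ``m * bin_duration``). ``phi_rule`` is ``('within', x)`` or
    ``('beyond', x)`` selecting frequency offsets ``|phi| <= x`` or
    ``|phi| > x`` octaves. The structural zero-offset entry is never part
    of a region mask.
    """
    tau = np.arange(n_delays) * bin_duration
    phi = np.arange(-n_offsets, n_offsets + 1) / channels_per_octave
    if inclusive_hi:
        t_sel = (tau >= tau_range_ms[0]) & (tau <= tau_range_ms[1])
    else:
        t_sel = (tau >= tau_range_ms[0]) & (tau < tau_range_ms[1])
    kind, x = phi_rule
    if kind == "within":
        f_sel = np.abs(phi) <= x + 1e-12
    elif kind == "beyond":
        f_sel = np.abs(phi) > x + 1e-12
    else:
        raise ValueError("phi_rule kind must be 'within' or 'beyond'")
    mask = np.outer(t_sel, f_sel)
    mask[0, n_offsets] = False
    return mask


#: Named CGF regions in physical units (ms, octaves). ``suppression`` covers
#: the narrowband delayed-suppression feature, ``enhancement`` the broadband
#: near-simultaneous enhancement, ``enhancement_offfreq`` its off-frequency
#: part only; ``control_late`` is built per-use by time-shifting a feature
#: region to the longest delays.
REGION_PRESETS = {
    "suppression": {
        "tau_range_ms": (20.0, 120.0),
        "phi_rule": ("within", 1.0 / 3.0),
        "inclusive_hi": True,
    },
    "enhancement": {"tau_range_ms": (0.0, 40.0), "phi_rule": ("within", np.inf)},
    "enhancement_offfreq": {"tau_range_ms": (0.0, 40.0), "phi_rule": ("beyond", 1.0 / 3.0)},
}


def shifted_control_mask(feature: np.ndarray) -> np.ndarray:
    """Control region: the feature mask time-shifted to the latest delays.

    Preserves the tile count and spectral footprint of the feature while
    moving it to long delays where consistent context structure is absent.
    """
    rows = np.flatnonzero(feature.any(axis=1))
    if rows.size == 0:
        raise ValueError("feature mask is empty")
    n_delays = feature.shape[0]
    shift = (n_delays - 1) - rows.max()
    if shift <= 0:
        raise ValueError("no room to shift the control region to later delays")
    control = np.zeros_like(feature)
    control[rows + shift] = feature[rows]
    if control[0, (feature.shape[1] - 1) // 2]:
        raise ValueError("control region would cover the zero-offset entry")
    if np.any(control & feature):
        raise ValueError("control region overlaps the feature region")
    return control


@dataclass
class ElisionResult:
    """Cross-validated cost of zeroing a CGF region and refitting.

    ``delta_feature[i]`` / ``delta_control[i]`` are recording ``i``'s
    changes in test normalized predictive power (elided minus full);
    p-values are one-tailed sign tests of "elision does not hurt".
    """

    feature_mask: np.ndarray
    control_mask: np.ndarray
    delta_feature: np.ndarray
    delta_control: np.ndarray
    p_feature: float
    p_control: float
    p_paired: float


def _sign_test_negative(deltas: np.ndarray) -> float:
    """One-tailed sign test that the median delta is negative (ties dropped)."""
    neg = int(np.sum(deltas < 0))
    n = int(np.sum(deltas != 0))
    if n == 0:
        return 1.0
    return float(stats.binomtest(neg, n, 0.5, alternative="greater").pvalue)


def elide_and_compare(
    recordings: Sequence,
    dims: ModelDims,
    cfg: FitConfig,
    feature_mask: np.ndarray,
    control_mask: Optional[np.ndarray] = None,
    k_folds: int = 2,
) -> ElisionResult:
    """Refit with a CGF region zeroed and compare generalization.

    ``recordings`` is a list of ``(spectrogram, TrialResponses)``. For each
    recording the full model and two elided models (feature region and an
    equal-size control region) are cross-validated on identical folds; the
    change in test normalized predictive power quantifies how essential the
    region is. One-tailed sign tests ask whether each elision systematically
    hurts, and a paired sign test whether the feature elision hurts more
    than the control.
    """
    if control_mask is None:
        control_mask = shifted_control_mask(feature_mask)
    if feature_mask.sum() != control_mask.sum():
        raise ValueError("feature and control regions must have equal tile counts")
    from dataclasses import replace

    d_feat, d_ctrl = [], []
    for spec, responses in recordings:
        cv_full = cross_validate("cgf", spec, responses, k_folds, dims, cfg)
        cfg_f = replace(cfg, cgf_mask=feature_mask)
        cfg_c = replace(cfg, cgf_mask=control_mask)
        cv_feat = cross_validate("cgf", spec, responses, k_folds, dims, cfg_f)
        cv_ctrl = cross_validate("cgf", spec, responses, k_folds, dims, cfg_c)
        d_feat.append(cv_feat.mean_test_pp - cv_full.mean_test_pp)
        d_ctrl.append(cv_ctrl.mean_test_pp - cv_full.mean_test_pp)
    d_feat = np.asarray(d_feat)
    d_ctrl = np.asarray(d_ctrl)
    return ElisionResult(
        feature_mask=feature_mask,
        control_mask=control_mask,
        delta_feature=d_feat,
        delta_control=d_ctrl,
        p_feature=_sign_test_negative(d_feat),
        p_control=_sign_test_negative(d_ctrl),
        p_paired=_sign_test_negative(d_feat - d_ctrl),
    )


# ---------------------------------------------------------------------------
# PCA of context fields


@dataclass
class CGFPCAResult:
    """Principal components of a population of context fields.

    ``components[i]`` is a CGF-shaped orthonormal field;
    ``variance_fractions`` are the per-component fractions of total scatter
    (non-increasing, summing to 1 over all components);
    ``mean_projection_fractions[k]`` is the fraction of the mean field's
    sum of squares lying in the span of the first ``k+1`` components.
    """

    components: np.ndarray
    variances: np.ndarray
    variance_fractions: np.ndarray
    mean_field: np.ndarray
    mean_projection_fractions: np.ndarray


def cgf_pca(cgfs: Sequence[CGFField]) -> CGFPCAResult:
    """PCA of mean-centred, vectorized context fields.

    The structurally zero entry is excluded from the vectorization so it
    cannot appear as spurious zero-variance structure; components are
    re-embedded into CGF shape with a zero there.
    """
    if len(cgfs) < 2:
        raise ValueError("PCA requires at least 2 context fields")
    shape = cgfs[0].weights.shape
    n_half = (shape[1] - 1) // 2
    keep = np.ones(shape, dtype=bool)
    keep[0, n_half] = False
    data = np.stack([c.weights[keep] for c in cgfs])
    mean_vec = data.mean(axis=0)
    centred = data - mean_vec
    # economy SVD of the centred data: rows are recordings
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    variances = svals**2 / (data.shape[0] - 1)
    total = variances.sum()
    fractions = variances / total if total > 0 else variances
    comps = np.zeros((vt.shape[0],) + shape)
    comps[:, keep] = vt
    mean_field = np.zeros(shape)
    mean_field[keep] = mean_vec
    proj = vt @ mean_vec
    denom = mean_vec @ mean_vec
    cum = np.cumsum(proj**2)
    mean_proj = cum / denom if denom > 0 else np.zeros_like(cum)
    return CGFPCAResult(
        components=comps,
        variances=variances,
        variance_fractions=fractions,
        mean_field=mean_field,
        mean_projection_fractions=mean_proj,
    )
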