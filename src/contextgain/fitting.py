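"""Model estimation from stimulus-response pairs.

The linear STRF is fit by ridge-penalized least squares with the ridge
weight chosen by inner cross-validation on contiguous blocks of the
training data. The CGF-family models are bilinear in their weight fields,
so they are fit by alternating least squares (ALS): holding the CGF fixed
the model is linear in ``(c, PRF)``, and holding the PRF fixed it is linear
in the CGF weights, so each step solves an exact ridge subproblem and the
penalized training objective can never increase. The CGF is initialized at
zero, which makes the first PRF step exactly the STRF fit and removes any
initialization randomness from ALS. The low-rank quadratic model is not
bilinear (its components enter squared), so it is fit by L-BFGS with
analytic gradients and seeded restarts.

All fitting targets are trial-averaged rates (PSTHs); trial-to-trial noise
is handled separately by the evaluation module. Weight masks (entries
forced to zero) support feature elision and the structural zero-offset
constraint. An optional second-difference smoothness penalty on the weight
fields is available but off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, optimize

from .drc import Spectrogram, lagged_context_sum
from .models import (
    CGFField,
    CGFModel,
    DualCGFModel,
    LowRankQuadraticModel,
    PRFField,
    STRFModel,
    SeparableCGFModel,
    lagged_design,
    apply_linear_field,
)

__all__ = [
    "ModelDims",
    "FitConfig",
    "FitTrace",
    "fit_strf",
    "fit_cgf_als",
    "fit_dual_cgf",
    "fit_separable_cgf",
    "fit_lowrank_quadratic",
    "fit_shared_cgf",
    "cross_validate",
    "CrossValidation",
]

DEFAULT_LAMBDA_GRID = (1e-2, 1.0, 1e2, 1e4, 1e6)


@dataclass(frozen=True)
class ModelDims:
    """Window dimensions: ``n_lags`` = J+1 PRF lags, ``n_delays`` = M+1 CGF
    delays, ``n_offsets`` = N (CGF frequency half-width in channels)."""

    n_lags: int
    n_delays: int = 1
    n_offsets: int = 0


@dataclass
class FitConfig:
    """Estimator settings shared by all fitters.

    ``ridge_lambda_prf`` / ``ridge_lambda_cgf`` are grids searched by inner
    cross-validation (a single-element grid fixes the value). ``cgf_mask``
    is a boolean (M+1, 2N+1) grid of CGF entries forced to zero; the
    structural zero-offset entry is always included regardless.
    """

    ridge_lambda_prf: Sequence[float] = DEFAULT_LAMBDA_GRID
    ridge_lambda_cgf: Sequence[float] = DEFAULT_LAMBDA_GRID
    smoothness: float = 0.0
    max_als_iterations: int = 100
    convergence_tol: float = 1e-6
    inner_cv_folds: int = 4
    n_restarts: int = 3
    seed: int = 0
    cgf_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.cgf_mask is not None:
            self.cgf_mask = np.asarray(self.cgf_mask, dtype=bool)


@dataclass
class FitTrace:
    """Per-iteration record of an ALS fit.

    ``mse`` is the training mean squared error after each full iteration;
    ``objective`` additionally includes the ridge/smoothness penalties
    (normalized by the number of training bins), and is the quantity each
    ALS step provably cannot increase.
    """

    mse: list = field(default_factory=list)
    objective: list = field(default_factory=list)
    lambdas: dict = field(default_factory=dict)
    converged: bool = False
    iterations: int = 0


# ---------------------------------------------------------------------------
# linear-algebra helpers


def second_diff_penalty(shape: tuple) -> np.ndarray:
    """Gram matrix of second differences along both axes of a 2-D field.

    For weights ``w`` of the given shape flattened row-major, returns ``P``
    with ``w @ P @ w = ||D2_rows w||^2 + ||D2_cols w||^2``.
    """
    r, c = shape
    p = np.zeros((r * c, r * c))
    idx = np.arange(r * c).reshape(r, c)
    trips = []
    for j in range(r - 2):
        for k in range(c):
            trips.append((idx[j, k], idx[j + 1, k], idx[j + 2, k]))
    for j in range(r):
        for k in range(c - 2):
            trips.append((idx[j, k], idx[j, k + 1], idx[j, k + 2]))
    for a, b, cc in trips:
        v = np.zeros(r * c)
        v[a] = 1.0
        v[b] = -2.0
        v[cc] = 1.0
        p += np.outer(v, v)
    return p


def _solve(gram: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve a (regularized) normal-equation system, falling back to the
    minimum-norm least-squares solution if the system is singular."""
    try:
        return linalg.solve(gram, rhs, assume_a="pos")
    except linalg.LinAlgError:
        return linalg.lstsq(gram, rhs, lapack_driver="gelsd")[0]


def _contiguous_folds(n_rows: int, k: int):
    return np.array_split(np.arange(n_rows), k)


def _select_lambda(
    a: np.ndarray,
    y: np.ndarray,
    grid: Sequence[float],
    n_folds: int,
    penalty_diag: np.ndarray,
    penalty_mat: Optional[np.ndarray] = None,
) -> float:
    """Pick the ridge weight minimizing inner-CV error on contiguous folds.

    ``penalty_diag`` marks which coefficients the ridge applies to (1 for
    penalized weights, 0 for the intercept); ``penalty_mat`` is an optional
    fixed extra penalty (e.g. smoothness) applied at every grid point.
    """
    grid = list(grid)
    if len(grid) == 1:
        return float(grid[0])
    folds = _contiguous_folds(a.shape[0], n_folds)
    grams = [a[f].T @ a[f] for f in folds]
    rhss = [a[f].T @ y[f] for f in folds]
    gram_all = np.sum(grams, axis=0)
    rhs_all = np.sum(rhss, axis=0)
    best_lam, best_err = grid[0], np.inf
    base = np.diag(penalty_diag).astype(float)
    if penalty_mat is not None:
        extra = penalty_mat
    else:
        extra = 0.0
    for lam in grid:
        err = 0.0
        for f, gram_f, rhs_f in zip(folds, grams, rhss):
            g = gram_all - gram_f + lam * base
            if penalty_mat is not None:
                g = g + extra
            beta = _solve(g, rhs_all - rhs_f)
            resid = a[f] @ beta - y[f]
            err += resid @ resid
        if err < best_err:
            best_err, best_lam = err, float(lam)
    return best_lam


def _ridge_fit(
    a: np.ndarray,
    y: np.ndarray,
    lam: float,
    penalty_diag: np.ndarray,
    penalty_mat: Optional[np.ndarray] = None,
) -> np.ndarray:
    gram = a.T @ a + lam * np.diag(penalty_diag)
    if penalty_mat is not None:
        gram = gram + penalty_mat
    return _solve(gram, a.T @ y)


# ---------------------------------------------------------------------------
# STRF


def _prepare(spec, psth, time_mask):
    levels = spec.levels if isinstance(spec, Spectrogram) else np.asarray(spec, dtype=float)
    y = np.asarray(psth, dtype=float).ravel()
    if y.size != levels.shape[0]:
        raise ValueError("response length must match the stimulus time axis")
    if time_mask is None:
        rows = np.ones(y.size, dtype=bool)
    else:
        rows = np.asarray(time_mask, dtype=bool)
        if rows.size != y.size:
            raise ValueError("time_mask length must match the response")
    return levels, y, rows


def fit_strf(
    spec,
    psth,
    dims: ModelDims,
    cfg: FitConfig = FitConfig(),
    time_mask: Optional[np.ndarray] = None,
):
    """Ridge least-squares STRF estimate; the intercept is unpenalized.

    Returns ``(STRFModel, FitTrace)``. The ridge weight is chosen by inner
    cross-validation over ``cfg.ridge_lambda_prf`` on contiguous blocks of
    the (masked) training rows.
    """
    levels, y, rows = _prepare(spec, psth, time_mask)
    n_chan = levels.shape[1]
    x = lagged_design(levels, dims.n_lags)
    if not np.any(levels):
        warnings.warn("all-silent stimulus: STRF determined by regularization only")
    a = np.column_stack([np.ones(rows.sum()), x[rows]])
    pen_diag = np.r_[0.0, np.ones(x.shape[1])]
    pen_mat = None
    if cfg.smoothness > 0:
        pen_mat = np.zeros((a.shape[1], a.shape[1]))
        pen_mat[1:, 1:] = cfg.smoothness * second_diff_penalty((dims.n_lags, n_chan))
    lam = _select_lambda(a, y[rows], cfg.ridge_lambda_prf, cfg.inner_cv_folds, pen_diag, pen_mat)
    beta = _ridge_fit(a, y[rows], lam, pen_diag, pen_mat)
    model = STRFModel(float(beta[0]), beta[1:].reshape(dims.n_lags, n_chan))
    resid = a @ beta - y[rows]
    trace = FitTrace(
        mse=[float(resid @ resid / rows.sum())],
        objective=[float((resid @ resid + lam * beta[1:] @ beta[1:]) / rows.sum())],
        lambdas={"prf": lam},
        converged=True,
        iterations=1,
    )
    return model, trace


# ---------------------------------------------------------------------------
# CGF family (alternating least squares)


def _shift_channels(arr: np.ndarray, n: int) -> np.ndarray:
    """``out[:, f] = arr[:, f + n]`` with zeros where ``f + n`` leaves the band."""
    out = np.zeros_like(arr)
    k = arr.shape[1]
    if n >= 0:
        if n < k:
            out[:, : k - n] = arr[:, n:]
    else:
        if -n < k:
            out[:, -n:] = arr[:, : k + n]
    return out


def _shift_time(arr: np.ndarray, m: int) -> np.ndarray:
    """``out[t] = arr[t - m]`` with zeros before stimulus onset."""
    if m == 0:
        return arr
    out = np.zeros_like(arr)
    out[m:] = arr[:-m]
    return out


def _context_products(levels: np.ndarray, dims: ModelDims) -> np.ndarray:
    """Stacked product grids ``P[t, (m,n), f] = s(t, f) * s(t-m, f+n)``.

    These depend only on the stimulus and the CGF window, so they are
    computed once per fit and reused across ALS iterations.
    """
    t_bins, n_chan = levels.shape
    n_cols = dims.n_delays * (2 * dims.n_offsets + 1)
    products = np.empty((t_bins, n_cols, n_chan))
    i = 0
    for m in range(dims.n_delays):
        lagged = _shift_time(levels, m)
        for n in range(-dims.n_offsets, dims.n_offsets + 1):
            products[:, i, :] = levels * _shift_channels(lagged, n)
            i += 1
    return products


def _context_regressors(products: np.ndarray, prf: np.ndarray) -> np.ndarray:
    """Design matrix of the CGF subproblem.

    Column ``(m, n)`` holds ``z_mn(i) = sum_{j,k} prf[j,k] s(i-j,k) s(i-j-m,k+n)``,
    so the quadratic part of the model is linear in the CGF weights:
    ``quad(i) = sum_mn w[m,n] z_mn(i)``. One batched matrix product per
    PRF lag.
    """
    t_bins = products.shape[0]
    cols = products @ prf[0]
    for j in range(1, min(prf.shape[0], t_bins)):
        cols[j:] += products[: t_bins - j] @ prf[j]
    return cols


def _cgf_free_indices(dims: ModelDims, mask: Optional[np.ndarray]) -> np.ndarray:
    width = 2 * dims.n_offsets + 1
    fixed = np.zeros((dims.n_delays, width), dtype=bool)
    fixed[0, dims.n_offsets] = True  # structural zero offset
    if mask is not None:
        if mask.shape != fixed.shape:
            raise ValueError("cgf_mask shape must match the CGF window")
        fixed |= mask
    return np.flatnonzero(~fixed.ravel())


def _assemble_cgf(dims: ModelDims, free_idx: np.ndarray, w_free: np.ndarray) -> CGFField:
    flat = np.zeros(dims.n_delays * (2 * dims.n_offsets + 1))
    flat[free_idx] = w_free
    return CGFField(flat.reshape(dims.n_delays, -1))


def fit_cgf_als(
    spec,
    psth,
    dims: ModelDims,
    cfg: FitConfig = FitConfig(),
    time_mask: Optional[np.ndarray] = None,
):
    """Alternating least squares for the CGF model.

    Iterates (i) a PRF step that solves the ridge problem in ``(c, PRF)``
    on gain-scaled regressors with the CGF fixed, and (ii) a CGF step that
    solves the ridge problem in the free CGF weights with the PRF fixed,
    the pure linear prediction acting as an offset. Ridge weights are
    selected once (PRF weight in the initial STRF fit, CGF weight by inner
    CV at the first CGF step) and then held fixed so every later step
    weakly decreases the penalized objective. Stops when the relative
    change in training MSE falls below ``cfg.convergence_tol``.
    """
    levels, y, rows = _prepare(spec, psth, time_mask)
    n_chan = levels.shape[1]
    if dims.n_delays == 1 and dims.n_offsets == 0:
        # the CGF window holds only the structural zero: pure STRF
        strf, trace = fit_strf(spec, psth, dims, cfg, time_mask)
        return CGFModel(strf.c, PRFField(strf.weights), CGFField.zeros(1, 0)), trace

    strf, strf_trace = fit_strf(spec, psth, dims, cfg, time_mask)
    lam_prf = strf_trace.lambdas["prf"]
    c = strf.c
    prf = strf.weights
    free_idx = _cgf_free_indices(dims, cfg.cgf_mask)
    w_free = np.zeros(free_idx.size)

    pen_diag_prf = np.r_[0.0, np.ones(dims.n_lags * n_chan)]
    pen_mat_prf = None
    pen_mat_cgf = None
    if cfg.smoothness > 0:
        pen_mat_prf = np.zeros((1 + dims.n_lags * n_chan,) * 2)
        pen_mat_prf[1:, 1:] = cfg.smoothness * second_diff_penalty((dims.n_lags, n_chan))
        full_pen = cfg.smoothness * second_diff_penalty(
            (dims.n_delays, 2 * dims.n_offsets + 1)
        )
        pen_mat_cgf = full_pen[np.ix_(free_idx, free_idx)]

    x_lin = lagged_design(levels, dims.n_lags)
    products = _context_products(levels, dims)
    lam_cgf: Optional[float] = None
    trace = FitTrace(lambdas={"prf": lam_prf})
    trace.mse.append(strf_trace.mse[0])
    trace.objective.append(strf_trace.objective[0])
    n_rows = rows.sum()

    best = (c, prf.copy(), w_free.copy())
    for iteration in range(cfg.max_als_iterations):
        # --- CGF step (PRF fixed) ---
        z = _context_regressors(products, prf)[:, free_idx]
        offset = c + x_lin @ prf.ravel()
        target = (y - offset)[rows]
        zr = z[rows]
        if free_idx.size:
            if lam_cgf is None:
                lam_cgf = _select_lambda(
                    zr,
                    target,
                    cfg.ridge_lambda_cgf,
                    cfg.inner_cv_folds,
                    np.ones(free_idx.size),
                    pen_mat_cgf,
                )
                trace.lambdas["cgf"] = lam_cgf
            w_free = _ridge_fit(zr, target, lam_cgf, np.ones(free_idx.size), pen_mat_cgf)
        cgf = _assemble_cgf(dims, free_idx, w_free)

        # --- PRF step (CGF fixed) ---
        gain = 1.0 + lagged_context_sum(levels, cgf.weights)
        x_gain = lagged_design(levels * gain, dims.n_lags)
        a = np.column_stack([np.ones(n_rows), x_gain[rows]])
        beta = _ridge_fit(a, y[rows], lam_prf, pen_diag_prf, pen_mat_prf)
        c = float(beta[0])
        prf = beta[1:].reshape(dims.n_lags, n_chan)

        resid = a @ beta - y[rows]
        mse = float(resid @ resid / n_rows)
        pen = lam_prf * beta[1:] @ beta[1:] + (lam_cgf or 0.0) * w_free @ w_free
        if pen_mat_prf is not None:
            pen += beta[1:] @ pen_mat_prf[1:, 1:] @ beta[1:]
        if pen_mat_cgf is not None:
            pen += w_free @ pen_mat_cgf @ w_free
        obj = float((resid @ resid + pen) / n_rows)
        trace.mse.append(mse)
        trace.objective.append(obj)
        trace.iterations = iteration + 1
        best = (c, prf.copy(), w_free.copy())
        if abs(trace.mse[-2] - mse) <= cfg.convergence_tol * max(trace.mse[-2], 1e-300):
            trace.converged = True
            break

    c, prf, w_free = best
    model = CGFModel(c, PRFField(prf), _assemble_cgf(dims, free_idx, w_free))
    return model, trace


def fit_dual_cgf(
    spec,
    psth,
    dims: ModelDims,
    cfg: FitConfig = FitConfig(),
    partition: Optional[np.ndarray] = None,
    time_mask: Optional[np.ndarray] = None,
):
    """ALS over three blocks: (c, PRF), context field A, context field B.

    ``partition`` marks the PRF tiles governed by context field A; by
    default it is the sign of the initial STRF fit (excitatory tiles -> A,
    inhibitory -> B).
    """
    levels, y, rows = _prepare(spec, psth, time_mask)
    n_chan = levels.shape[1]
    strf, strf_trace = fit_strf(spec, psth, dims, cfg, time_mask)
    lam_prf = strf_trace.lambdas["prf"]
    c = strf.c
    prf = strf.weights
    if partition is None:
        partition = strf.weights > 0
    partition = np.asarray(partition, dtype=bool)
    if partition.shape != prf.shape:
        raise ValueError("partition mask must match the PRF window")

    free_idx = _cgf_free_indices(dims, cfg.cgf_mask)
    w_a = np.zeros(free_idx.size)
    w_b = np.zeros(free_idx.size)
    x_lin = lagged_design(levels, dims.n_lags)
    products = _context_products(levels, dims)
    pen_diag_prf = np.r_[0.0, np.ones(dims.n_lags * n_chan)]
    lam_cgf: Optional[float] = None
    trace = FitTrace(lambdas={"prf": lam_prf})
    trace.mse.append(strf_trace.mse[0])
    trace.objective.append(strf_trace.objective[0])
    n_rows = rows.sum()

    for iteration in range(cfg.max_als_iterations):
        prf_a = np.where(partition, prf, 0.0)
        prf_b = np.where(partition, 0.0, prf)
        z_a = _context_regressors(products, prf_a)[:, free_idx]
        z_b = _context_regressors(products, prf_b)[:, free_idx]
        lin = c + x_lin @ prf.ravel()
        if free_idx.size:
            if lam_cgf is None:
                lam_cgf = _select_lambda(
                    z_a[rows],
                    (y - lin - z_b @ w_b)[rows],
                    cfg.ridge_lambda_cgf,
                    cfg.inner_cv_folds,
                    np.ones(free_idx.size),
                )
                trace.lambdas["cgf"] = lam_cgf
            w_a = _ridge_fit(
                z_a[rows], (y - lin - z_b @ w_b)[rows], lam_cgf, np.ones(free_idx.size)
            )
            w_b = _ridge_fit(
                z_b[rows], (y - lin - z_a @ w_a)[rows], lam_cgf, np.ones(free_idx.size)
            )
        cgf_a = _assemble_cgf(dims, free_idx, w_a)
        cgf_b = _assemble_cgf(dims, free_idx, w_b)

        gain_a = 1.0 + lagged_context_sum(levels, cgf_a.weights)
        gain_b = 1.0 + lagged_context_sum(levels, cgf_b.weights)
        xa = lagged_design(levels * gain_a, dims.n_lags)
        xb = lagged_design(levels * gain_b, dims.n_lags)
        flat_part = partition.ravel()
        x_mix = np.where(flat_part[None, :], xa, xb)
        a = np.column_stack([np.ones(n_rows), x_mix[rows]])
        beta = _ridge_fit(a, y[rows], lam_prf, pen_diag_prf)
        c = float(beta[0])
        prf = beta[1:].reshape(dims.n_lags, n_chan)

        resid = a @ beta - y[rows]
        mse = float(resid @ resid / n_rows)
        pen = lam_prf * beta[1:] @ beta[1:] + (lam_cgf or 0.0) * (w_a @ w_a + w_b @ w_b)
        trace.mse.append(mse)
        trace.objective.append(float((resid @ resid + pen) / n_rows))
        trace.iterations = iteration + 1
        if abs(trace.mse[-2] - mse) <= cfg.convergence_tol * max(trace.mse[-2], 1e-300):
            trace.converged = True
            break

    model = DualCGFModel(
        c,
        PRFField(prf),
        partition,
        _assemble_cgf(dims, free_idx, w_a),
        _assemble_cgf(dims, free_idx, w_b),
    )
    return model, trace


def fit_separable_cgf(
    spec,
    psth,
    dims: ModelDims,
    cfg: FitConfig = FitConfig(),
    time_mask: Optional[np.ndarray] = None,
):
    """ALS over (c, PRF), the temporal factor u, and the spectral factor v.

    The CGF is the outer product ``u (x) v`` with the zero-offset entry
    forced to 0 after the product, so each factor step is an exact linear
    subproblem. After every iteration ``u`` is renormalized to unit norm
    (the outer product is identifiable only up to reciprocal scaling).
    """
    levels, y, rows = _prepare(spec, psth, time_mask)
    n_chan = levels.shape[1]
    width = 2 * dims.n_offsets + 1
    strf, strf_trace = fit_strf(spec, psth, dims, cfg, time_mask)
    lam_prf = strf_trace.lambdas["prf"]
    c = strf.c
    prf = strf.weights
    # deterministic spectral-factor seed: broad positive bump
    v = np.exp(-0.5 * (np.arange(width) - dims.n_offsets) ** 2 / max(1.0, dims.n_offsets) ** 2)
    v /= np.linalg.norm(v)
    u = np.zeros(dims.n_delays)
    x_lin = lagged_design(levels, dims.n_lags)
    pen_diag_prf = np.r_[0.0, np.ones(dims.n_lags * n_chan)]
    lam_cgf: Optional[float] = None
    trace = FitTrace(lambdas={"prf": lam_prf})
    trace.mse.append(strf_trace.mse[0])
    trace.objective.append(strf_trace.objective[0])
    n_rows = rows.sum()

    def reconstruct(u_vec, v_vec):
        w = np.outer(u_vec, v_vec)
        w[0, dims.n_offsets] = 0.0
        return CGFField(w)

    products = _context_products(levels, dims)
    for iteration in range(cfg.max_als_iterations):
        z = _context_regressors(products, prf)  # (T, (M+1)*width)
        z3 = z.reshape(-1, dims.n_delays, width)
        target = (y - c - x_lin @ prf.ravel())[rows]
        # u step: regressor for u_m is sum_n v_n z_mn, minus the zeroed entry
        ru = z3 @ v
        ru[:, 0] -= v[dims.n_offsets] * z3[:, 0, dims.n_offsets]
        if lam_cgf is None:
            lam_cgf = _select_lambda(
                ru[rows], target, cfg.ridge_lambda_cgf, cfg.inner_cv_folds,
                np.ones(dims.n_delays),
            )
            trace.lambdas["cgf"] = lam_cgf
        u = _ridge_fit(ru[rows], target, lam_cgf, np.ones(dims.n_delays))
        # v step
        rv = np.einsum("tmw,m->tw", z3, u, optimize=True)
        rv[:, dims.n_offsets] -= u[0] * z3[:, 0, dims.n_offsets]
        v = _ridge_fit(rv[rows], target, lam_cgf, np.ones(width))
        norm_u = np.linalg.norm(u)
        if norm_u > 0:
            u, v = u / norm_u, v * norm_u
        cgf = reconstruct(u, v)

        gain = 1.0 + lagged_context_sum(levels, cgf.weights)
        x_gain = lagged_design(levels * gain, dims.n_lags)
        a = np.column_stack([np.ones(n_rows), x_gain[rows]])
        beta = _ridge_fit(a, y[rows], lam_prf, pen_diag_prf)
        c = float(beta[0])
        prf = beta[1:].reshape(dims.n_lags, n_chan)

        resid = a @ beta - y[rows]
        mse = float(resid @ resid / n_rows)
        trace.mse.append(mse)
        trace.objective.append(
            float((resid @ resid + lam_prf * beta[1:] @ beta[1:]
                   + lam_cgf * ((u @ u) * (v @ v))) / n_rows)
        )
        trace.iterations = iteration + 1
        if abs(trace.mse[-2] - mse) <= cfg.convergence_tol * max(trace.mse[-2], 1e-300):
            trace.converged = True
            break

    model = SeparableCGFModel(c, PRFField(prf), u, v)
    return model, trace


def fit_lowrank_quadratic(
    spec,
    psth,
    rank: int,
    dims: ModelDims,
    cfg: FitConfig = FitConfig(),
    time_mask: Optional[np.ndarray] = None,
):
    """Low-rank quadratic fit by L-BFGS with seeded restarts.

    The second-order kernel is ``sum_d lambda_d b_d b_d^T`` with signed
    free coefficients, so both facilitatory and suppressive quadratic axes
    are reachable. The best of ``cfg.n_restarts`` seeded starts (by final
    penalized objective) is returned. ``rank=0`` reduces to the STRF fit.
    """
    levels, y, rows = _prepare(spec, psth, time_mask)
    n_chan = levels.shape[1]
    strf, strf_trace = fit_strf(spec, psth, dims, cfg, time_mask)
    if rank == 0:
        model = LowRankQuadraticModel(strf.c, strf.weights.ravel(), [])
        return model, strf_trace
    lam = strf_trace.lambdas["prf"]
    x = lagged_design(levels, dims.n_lags)[rows]
    yr = y[rows]
    t_rows, d = x.shape

    def unpack(theta):
        c = theta[0]
        w = theta[1 : 1 + d]
        rest = theta[1 + d :].reshape(rank, d + 1)
        return c, w, rest[:, 0], rest[:, 1:]

    def objective(theta):
        c, w, lams, bs = unpack(theta)
        q = x @ bs.T  # (T, rank)
        resid = c + x @ w + (q**2) @ lams - yr
        f = resid @ resid + lam * (w @ w + np.sum(bs * bs))
        grad = np.empty_like(theta)
        grad[0] = 2 * resid.sum()
        grad[1 : 1 + d] = 2 * (x.T @ resid) + 2 * lam * w
        gl = 2 * (q**2).T @ resid
        gb = 4 * lams[:, None] * (x.T @ (resid[:, None] * q)).T + 2 * lam * bs
        grad[1 + d :] = np.column_stack([gl, gb]).ravel()
        return f / t_rows, grad / t_rows

    rng = np.random.default_rng(cfg.seed)
    best_theta, best_f = None, np.inf
    scale = max(np.linalg.norm(strf.weights), 1e-6)
    for restart in range(max(1, cfg.n_restarts)):
        theta0 = np.zeros(1 + d + rank * (d + 1))
        theta0[0] = strf.c
        theta0[1 : 1 + d] = strf.weights.ravel()
        for r_i in range(rank):
            b0 = rng.standard_normal(d) * scale / np.sqrt(d)
            lam0 = 0.1 * (1 if (restart + r_i) % 2 == 0 else -1)
            theta0[1 + d + r_i * (d + 1)] = lam0
            theta0[1 + d + r_i * (d + 1) + 1 :][:d] = b0
        res = optimize.minimize(
            objective, theta0, jac=True, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if res.fun < best_f:
            best_f, best_theta = res.fun, res.x
    c, w, lams, bs = unpack(best_theta)
    model = LowRankQuadraticModel(c, w, [(bs[i], lams[i]) for i in range(rank)])
    resid = c + x @ w + ((x @ bs.T) ** 2) @ lams - yr
    trace = FitTrace(
        mse=[float(resid @ resid / t_rows)],
        objective=[float(best_f)],
        lambdas={"prf": lam},
        converged=True,
        iterations=1,
    )
    return model, trace


def fit_shared_cgf(
    population,
    dims: ModelDims,
    cfg: FitConfig = FitConfig(),
):
    """One CGF shared across a population, per-neuron constants and PRFs.

    ``population`` is a list of ``(spectrogram, psth)`` pairs. The CGF step
    pools the normal equations of every neuron's context subproblem; PRF
    steps stay independent per neuron. Returns
    ``(CGFField, [(c, PRFField), ...], FitTrace)``.
    """
    if not population:
        raise ValueError("population must be non-empty")
    prepped = [_prepare(spec, psth, None) for spec, psth in population]
    strfs = [fit_strf(spec, psth, dims, cfg) for spec, psth in population]
    lam_prfs = [tr.lambdas["prf"] for _, tr in strfs]
    cs = [m.c for m, _ in strfs]
    prfs = [m.weights for m, _ in strfs]
    x_lins = [lagged_design(lv, dims.n_lags) for lv, _, _ in prepped]
    free_idx = _cgf_free_indices(dims, cfg.cgf_mask)
    w_free = np.zeros(free_idx.size)
    lam_cgf = cfg.ridge_lambda_cgf[len(cfg.ridge_lambda_cgf) // 2] if len(
        cfg.ridge_lambda_cgf
    ) > 1 else cfg.ridge_lambda_cgf[0]
    total_rows = sum(lv.shape[0] for lv, _, _ in prepped)
    trace = FitTrace(lambdas={"cgf": float(lam_cgf)})
    trace.mse.append(
        float(sum(tr.mse[0] * lv.shape[0] for (_, tr), (lv, _, _) in zip(strfs, prepped))
              / total_rows)
    )
    trace.objective.append(trace.mse[0])

    for iteration in range(cfg.max_als_iterations):
        gram = lam_cgf * np.eye(free_idx.size)
        rhs = np.zeros(free_idx.size)
        zs = []
        for (lv, y, _), c, prf, x_lin in zip(prepped, cs, prfs, x_lins):
            z = _context_regressors(_context_products(lv, dims), prf)[:, free_idx]
            zs.append(z)
            resid = y - c - x_lin @ prf.ravel()
            gram += z.T @ z
            rhs += z.T @ resid
        w_free = _solve(gram, rhs)
        cgf = _assemble_cgf(dims, free_idx, w_free)

        sse = 0.0
        for idx, ((lv, y, _), lam_p) in enumerate(zip(prepped, lam_prfs)):
            gain = 1.0 + lagged_context_sum(lv, cgf.weights)
            x_gain = lagged_design(lv * gain, dims.n_lags)
            a = np.column_stack([np.ones(lv.shape[0]), x_gain])
            beta = _ridge_fit(a, y, lam_p, np.r_[0.0, np.ones(x_gain.shape[1])])
            cs[idx] = float(beta[0])
            prfs[idx] = beta[1:].reshape(dims.n_lags, lv.shape[1])
            r = a @ beta - y
            sse += r @ r
        mse = float(sse / total_rows)
        trace.mse.append(mse)
        trace.objective.append(mse)
        trace.iterations = iteration + 1
        if abs(trace.mse[-2] - mse) <= cfg.convergence_tol * max(trace.mse[-2], 1e-300):
            trace.converged = True
            break

    per_neuron = [(c, PRFField(prf)) for c, prf in zip(cs, prfs)]
    return _assemble_cgf(dims, free_idx, w_free), per_neuron, trace


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CrossValidation:
    """Per-fold predictive-power results of one model family."""

    folds: list
    mean_test_pp: float
    mean_train_pp: float


def cross_validate(
    model_family: str,
    spec,
    responses,
    k_folds: int,
    dims: ModelDims,
    cfg: FitConfig = FitConfig(),
    rank: int = 1,
    partition: Optional[np.ndarray] = None,
) -> CrossValidation:
    """Contiguous-segment cross-validation with normalized predictive power.

    Folds are contiguous time segments; the fold boundaries depend only on
    the number of bins and ``k_folds``, so different model families evaluated
    on the same recording see identical folds and can be compared pairwise.
    ``model_family`` is one of ``'strf'``, ``'cgf'``, ``'dual'``,
    ``'separable'``, ``'quadratic'``.
    """
    from .evaluation import estimate_signal_noise_power, predictive_power

    if k_folds < 2:
        raise ValueError("need at least 2 folds")
    counts = responses.counts
    t_bins = counts.shape[1]
    psth = counts.mean(axis=0)
    folds = _contiguous_folds(t_bins, k_folds)
    if min(f.size for f in folds) < dims.n_lags:
        raise ValueError("fold shorter than the PRF window")

    fitters = {
        "strf": lambda mask: fit_strf(spec, psth, dims, cfg, mask),
        "cgf": lambda mask: fit_cgf_als(spec, psth, dims, cfg, mask),
        "dual": lambda mask: fit_dual_cgf(spec, psth, dims, cfg, partition, mask),
        "separable": lambda mask: fit_separable_cgf(spec, psth, dims, cfg, mask),
        "quadratic": lambda mask: fit_lowrank_quadratic(spec, psth, rank, dims, cfg, mask),
    }
    from . import models as _models

    predict_fns = {
        "strf": _models.predict_strf,
        "cgf": _models.predict_cgf,
        "dual": _models.predict_dual_cgf,
        "separable": _models.predict_separable,
        "quadratic": _models.predict_lowrank_quadratic,
    }
    if model_family not in fitters:
        raise ValueError(f"unknown model family: {model_family!r}")

    results = []
    for fold_idx, test_rows in enumerate(folds):
        train_mask = np.ones(t_bins, dtype=bool)
        train_mask[test_rows] = False
        model, trace = fitters[model_family](train_mask)
        prediction = predict_fns[model_family](model, spec)

        from .evaluation import TrialResponses

        test_trials = TrialResponses(counts[:, test_rows], responses.bin_duration)
        train_trials = TrialResponses(counts[:, train_mask], responses.bin_duration)
        test_powers = estimate_signal_noise_power(test_trials)
        train_powers = estimate_signal_noise_power(train_trials)
        pp_test = predictive_power(prediction[test_rows], test_trials, test_powers)
        pp_train = predictive_power(prediction[train_mask], train_trials, train_powers)
        results.append(
            {
                "fold": fold_idx,
                "model": model,
                "trace": trace,
                "prediction": prediction,
                "test_pp": pp_test,
                "train_pp": pp_train,
            }
        )
    return CrossValidation(
        folds=results,
        mean_test_pp=float(np.mean([r["test_pp"].normalized for r in results])),
        mean_train_pp=float(np.mean([r["train_pp"].normalized for r in results])),
    )
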