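"""Conventional model-based R2* estimators.

Pixel-wise fitting of the mono-exponential decay S0*exp(-TE*R2*) and its
noise-aware variants, the standard baselines for liver iron quantification
from magnitude mGRE data:

- ``loglinear``   ordinary least squares on log-signal (initializer)
- ``nlls``        plain nonlinear least squares on the mono-exponential
- ``offset``      exponential plus a constant, approximating the noise floor
- ``truncation``  iterative discard of late low-SNR echoes before refitting
- ``m1ncm``       first-moment noise-corrected model: fits the exact Rician
                  expectation of the decaying signal (needs sigma)
- ``m2ncm``       second-moment variant: fits squared magnitudes to
                  s^2 + 2 sigma^2 (needs sigma)

All voxels inside the mask are fitted independently with a vectorized
Levenberg-Marquardt solver (all voxels advance simultaneously; each keeps its
own damping and convergence state).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import special

from .signal_model import (
    EchoTimes,
    MultiEchoSeries,
    ParameterMaps,
    RAYLEIGH_MEAN_FACTOR,
    rician_first_moment,
)

__all__ = ["FitOptions", "FitResult", "fit_map", "FIT_METHODS",
           "fit_loglinear", "fit_nlls_mono", "fit_offset",
           "fit_truncation_auto", "fit_m1ncm", "fit_m2ncm"]


@dataclass(frozen=True)
class FitOptions:
    """Common fitting knobs.

    ``sigma`` is the Gaussian noise sd (required by m1ncm/m2ncm/truncation);
    ``r2_bounds`` clamps R2* to a physical window — the default ceiling
    2000 s^-1 covers severe iron overload with headroom and stops runaway
    fits on pure noise.  ``truncation_multiplier`` is the clean-signal floor
    (in units of sigma) below which trailing echoes are discarded.
    """

    sigma: float | None = None
    r2_bounds: tuple[float, float] = (0.0, 2000.0)
    truncation_multiplier: float = 2.0
    max_iter: int = 200
    tol: float = 1e-10

    def require_sigma(self) -> float:
        if self.sigma is None or self.sigma < 0:
            raise ValueError("this method requires a non-negative sigma")
        return float(self.sigma)


@dataclass
class FitResult:
    """Fitted maps plus per-voxel extras and convergence flags.

    ``flags`` is an int map: 0 fitted normally, 1 degenerate input (fallback
    values), 2 did not converge (initializer returned), -1 outside mask.
    ``extras`` may hold an ``offset`` map (offset model) or a
    ``retained_echoes`` count map (truncation model).
    """

    maps: ParameterMaps
    flags: np.ndarray
    extras: dict[str, np.ndarray] = field(default_factory=dict)


def _as_mask(mask, shape) -> np.ndarray:
    if mask is None:
        return np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape does not match image shape")
    return mask


def _loglinear_core(y: np.ndarray, te_s: np.ndarray, weights=None):
    """Weighted OLS of log(y) on TE for each row of y (N, E).

    Echoes with non-positive signal get zero weight.  Returns (s0, r2,
    n_used); rows with fewer than 2 usable echoes get (y[:,0], 0) and
    n_used reflects that.
    """
    w = (y > 0).astype(float)
    if weights is not None:
        w = w * weights
    n_used = w.sum(axis=1)
    logy = np.where(y > 0, np.log(np.maximum(y, 1e-300)), 0.0)
    sw = n_used
    ok = sw >= 2
    swx = (w * te_s).sum(axis=1)
    swy = (w * logy).sum(axis=1)
    swxx = (w * te_s**2).sum(axis=1)
    swxy = (w * te_s * logy).sum(axis=1)
    denom = sw * swxx - swx**2
    denom = np.where(np.abs(denom) > 1e-300, denom, 1.0)
    slope = (sw * swxy - swx * swy) / denom
    intercept = (swy - slope * swx) / np.maximum(sw, 1.0)
    r2 = np.where(ok, -slope, 0.0)
    s0 = np.where(ok, np.exp(np.clip(intercept, -300, 300)), y[:, 0])
    return s0, r2, n_used


def _lm(
    y: np.ndarray,
    p0: np.ndarray,
    model: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]],
    lower: np.ndarray,
    upper: np.ndarray,
    weights: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-10,
):
    """Vectorized projected Levenberg-Marquardt over N independent problems.

    ``model(p)`` returns (f, J) with f (N, E) and J (N, E, K).  Bounds are
    enforced by projection after each trial step.  The per-voxel objective is
    non-increasing across accepted steps by construction.  Returns (p,|
    converged flags).
    """
    p = p0.copy()
    n, k = p.shape
    lam = np.full(n, 1e-3)
    w = np.ones_like(y) if weights is None else weights
    f, jac = model(p)
    r = (y - f) * w
    loss = (r**2).sum(axis=1)
    converged = np.zeros(n, dtype=bool)
    eye = np.eye(k)

    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        jw = jac * w[..., None]
        jtj = np.einsum("nek,nel->nkl", jw, jw)
        jtr = np.einsum("nek,ne->nk", jw, r)
        a = jtj + lam[:, None, None] * (eye[None] + jtj * eye[None])
        try:
            step = np.linalg.solve(a, jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            a = a + 1e-12 * eye[None]
            step = np.linalg.solve(a, jtr[..., None])[..., 0]
        trial = np.clip(p + step, lower, upper)
        f_t, jac_t = model(trial)
        r_t = (y - f_t) * w
        loss_t = (r_t**2).sum(axis=1)

        better = (loss_t <= loss) & active
        rel = np.abs(loss - loss_t) / np.maximum(loss, 1e-300)
        p[better] = trial[better]
        r[better] = r_t[better]
        jac[better] = jac_t[better]
        lam[better] = np.maximum(lam[better] / 3.0, 1e-12)
        worse = (~better) & active
        lam[worse] = np.minimum(lam[worse] * 4.0, 1e12)
        converged |= (better & (rel < tol)) | (lam >= 1e12)
        loss[better] = loss_t[better]
    return p, converged


def _mono_model(te_s: np.ndarray):
    def model(p):
        s0, r2 = p[:, 0:1], p[:, 1:2]
        e = np.exp(-te_s[None, :] * r2)
        f = s0 * e
        jac = np.stack([e, -s0 * te_s[None, :] * e], axis=-1)
        return f, jac

    return model


def _offset_model(te_s: np.ndarray):
    def model(p):
        s0, r2, c = p[:, 0:1], p[:, 1:2], p[:, 2:3]
        e = np.exp(-te_s[None, :] * r2)
        f = s0 * e + c
        ones = np.ones_like(e)
        jac = np.stack([e, -s0 * te_s[None, :] * e, ones], axis=-1)
        return f, jac

    return model


def _rician_moment_and_slope(s: np.ndarray, sigma: float):
    """First moment E(s) and its derivative dE/ds for Gaussian sd sigma."""
    a = 0.5 * (s / sigma) ** 2
    half = 0.5 * a
    i0, i1 = special.ive(0, half), special.ive(1, half)
    moment = sigma * RAYLEIGH_MEAN_FACTOR * ((1.0 + a) * i0 + a * i1)
    slope = RAYLEIGH_MEAN_FACTOR * (s / (2.0 * sigma)) * (i0 + i1)
    return moment, slope


def _m1ncm_model(te_s: np.ndarray, sigma: float):
    def model(p):
        s0, r2 = p[:, 0:1], p[:, 1:2]
        e = np.exp(-te_s[None, :] * r2)
        s = s0 * e
        moment, slope = _rician_moment_and_slope(s, sigma)
        jac = np.stack([slope * e, -slope * s0 * te_s[None, :] * e], axis=-1)
        return moment, jac

    return model


def _m2ncm_model(te_s: np.ndarray, sigma: float):
    def model(p):
        s0, r2 = p[:, 0:1], p[:, 1:2]
        e = np.exp(-te_s[None, :] * r2)
        s = s0 * e
        f = s**2 + 2.0 * sigma**2
        jac = np.stack([2.0 * s * e, -2.0 * s**2 * te_s[None, :]], axis=-1)
        return f, jac

    return model


def _prepare(series: MultiEchoSeries, mask):
    mask = _as_mask(mask, series.data.shape[:2])
    y = series.data[mask, :]
    return mask, y, series.te.te_s


def _result_from_flat(series, mask, s0, r2, flags_flat, opts, extras_flat=None):
    lo, hi = opts.r2_bounds
    r2 = np.clip(r2, lo, hi)
    s0 = np.maximum(s0, 0.0)
    shape = series.data.shape[:2]
    s0_map = np.zeros(shape)
    r2_map = np.zeros(shape)
    flags = np.full(shape, -1, dtype=int)
    s0_map[mask], r2_map[mask], flags[mask] = s0, r2, flags_flat
    extras = {}
    if extras_flat:
        for name, v in extras_flat.items():
            m = np.zeros(shape, dtype=v.dtype)
            m[mask] = v
            extras[name] = m
    return FitResult(ParameterMaps(s0_map, r2_map), flags, extras)


def fit_loglinear(
    series: MultiEchoSeries, mask=None, opts: FitOptions = FitOptions()
) -> FitResult:
    """OLS on log-signal vs TE; exact on noise-free mono-exponential data.

    Non-positive echoes are excluded from the regression; voxels with fewer
    than two usable echoes are flagged (flag 1) and returned as
    (s0 = first echo, r2 = 0).
    """
    mask, y, te_s = _prepare(series, mask)
    s0, r2, n_used = _loglinear_core(y, te_s)
    flags = np.where(n_used >= 2, 0, 1)
    return _result_from_flat(series, mask, s0, r2, flags, opts)


def _init_params(y, te_s, opts, extra_cols=0):
    s0, r2, _ = _loglinear_core(y, te_s)
    lo, hi = opts.r2_bounds
    p0 = np.column_stack(
        [np.maximum(s0, 1e-6), np.clip(r2, lo, hi)]
        + [np.zeros_like(s0)] * extra_cols
    )
    return p0


def _run_lm(series, mask, opts, model_builder, extra_cols=0, weights=None):
    mask, y, te_s = _prepare(series, mask)
    if y.shape[0] == 0:
        return _result_from_flat(
            series, mask, np.empty(0), np.empty(0), np.empty(0, int), opts
        )
    p0 = _init_params(y, te_s, opts, extra_cols)
    lo, hi = opts.r2_bounds
    lower = np.array([0.0, lo] + [0.0] * extra_cols)
    upper = np.array([np.inf, hi] + [np.inf] * extra_cols)
    p, converged = _lm(
        y, p0, model_builder(te_s), lower, upper,
        weights=weights, max_iter=opts.max_iter, tol=opts.tol,
    )
    flags = np.where(converged, 0, 2)
    # Non-converged voxels fall back to the initializer.
    p[~converged] = p0[~converged]
    extras = {"offset": p[:, 2]} if extra_cols else None
    return _result_from_flat(series, mask, p[:, 0], p[:, 1], flags, opts, extras)


def fit_nlls_mono(
    series: MultiEchoSeries, mask=None, opts: FitOptions = FitOptions()
) -> FitResult:
    """Plain nonlinear least squares on S0*exp(-TE*R2*)."""
    return _run_lm(series, mask, opts, _mono_model)


def fit_offset(
    series: MultiEchoSeries, mask=None, opts: FitOptions = FitOptions()
) -> FitResult:
    """Exponential-plus-constant fit S0*exp(-TE*R2*) + C with C >= 0.

    The constant approximates the Rician noise floor; at high noise this
    model tends to overestimate R2*.  C is returned in ``extras['offset']``.
    """
    return _run_lm(series, mask, opts, _offset_model, extra_cols=1)


def fit_m1ncm(
    series: MultiEchoSeries, mask=None, opts: FitOptions = FitOptions()
) -> FitResult:
    """First-moment noise-corrected fit: y_i ~ E_rice[S0*exp(-TE_i*R2*); sigma].

    With sigma = 0 the expectation reduces to the clean signal and the method
    coincides with plain NLLS.
    """
    sigma = opts.require_sigma()
    if sigma == 0:
        return fit_nlls_mono(series, mask, opts)
    return _run_lm(series, mask, opts, lambda te_s: _m1ncm_model(te_s, sigma))


def fit_m2ncm(
    series: MultiEchoSeries, mask=None, opts: FitOptions = FitOptions()
) -> FitResult:
    """Second-moment variant: fits y^2 to s^2 + 2 sigma^2."""
    sigma = opts.require_sigma()
    mask_, y, te_s = _prepare(series, mask)
    if y.shape[0] == 0:
        return _result_from_flat(
            series, mask_, np.empty(0), np.empty(0), np.empty(0, int), opts
        )
    p0 = _init_params(y, te_s, opts)
    lo, hi = opts.r2_bounds
    p, converged = _lm(
        y**2, p0, _m2ncm_model(te_s, sigma),
        np.array([0.0, lo]), np.array([np.inf, hi]),
        max_iter=opts.max_iter, tol=opts.tol,
    )
    flags = np.where(converged, 0, 2)
    p[~converged] = p0[~converged]
    return _result_from_flat(series, mask_, p[:, 0], p[:, 1], flags, opts)


def fit_truncation_auto(
    series: MultiEchoSeries, mask=None, opts: FitOptions = FitOptions()
) -> FitResult:
    """Truncation model: drop trailing low-SNR echoes, refit until stable.

    Per voxel, echoes whose *estimated clean* signal S0*exp(-TE*R2*) falls
    below ``truncation_multiplier * sigma`` are discarded (always a trailing
    run, since the model is monotone decreasing), the mono-exponential is
    refitted on the retained prefix, and the procedure repeats until the
    retained set is stable.  At least 3 echoes are always kept; voxels forced
    to that floor carry flag 1.  Retained counts are returned in
    ``extras['retained_echoes']``.
    """
    sigma = opts.require_sigma()
    mask_, y, te_s = _prepare(series, mask)
    n, n_echo = y.shape
    if n == 0:
        return _result_from_flat(
            series, mask_, np.empty(0), np.empty(0), np.empty(0, int), opts
        )
    lo, hi = opts.r2_bounds
    lower, upper = np.array([0.0, lo]), np.array([np.inf, hi])
    model = _mono_model(te_s)
    floor = opts.truncation_multiplier * sigma

    p = _init_params(y, te_s, opts)
    keep = np.full(n, n_echo)
    forced = np.zeros(n, dtype=bool)
    converged = np.zeros(n, dtype=bool)
    for _ in range(n_echo):
        pred = p[:, 0:1] * np.exp(-te_s[None, :] * p[:, 1:2])
        above = pred >= floor
        new_keep = above.cumprod(axis=1).sum(axis=1)  # leading run above floor
        forced = new_keep < 3
        new_keep = np.clip(new_keep, 3, n_echo)
        weights = (np.arange(n_echo)[None, :] < new_keep[:, None]).astype(float)
        p, converged = _lm(
            y, p, model, lower, upper, weights=weights,
            max_iter=opts.max_iter, tol=opts.tol,
        )
        if np.array_equal(new_keep, keep):
            keep = new_keep
            break
        keep = new_keep
    flags = np.where(forced, 1, np.where(converged, 0, 2))
    return _result_from_flat(
        series, mask_, p[:, 0], p[:, 1], flags, opts,
        {"retained_echoes": keep.astype(int)},
    )


FIT_METHODS: dict[str, Callable] = {
    "loglinear": fit_loglinear,
    "nlls": fit_nlls_mono,
    "offset": fit_offset,
    "truncation": fit_truncation_auto,
    "m1ncm": fit_m1ncm,
    "m2ncm": fit_m2ncm,
}


def fit_map(
    series: MultiEchoSeries,
    method: str,
    mask=None,
    opts: FitOptions = FitOptions(),
) -> FitResult:
    """Dispatch to one of the registered pixel-wise fitting methods."""
    try:
        fn = FIT_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(FIT_METHODS)}"
        ) from None
    return fn(series, mask, opts)
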