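"""Sigmoid melting-curve model: evaluation, fitting, melting point, slope.

The soluble fraction of a protein after heating to temperature ``T`` (°C) is
modelled as

    f(T) = (1 - plateau) / (1 + exp(-(a/T - b))) + plateau

with constants ``a`` (°C; sets steepness via the 1/T coordinate), ``b``
(dimensionless offset) and ``plateau`` (lower asymptote, the fraction that
never precipitates).  For ``a > 0`` the curve decreases from 1 (fully folded,
low T) towards ``plateau`` (high T).  The melting point Tm is where the curve
crosses 0.5, i.e. half the protein is denatured; it exists only when
``plateau < 0.5``.

Fold changes are defined relative to the lowest temperature, so f(T_min) = 1
enters every fit as a data point rather than as an explicit constraint.

Two fitting paths are provided:

* :func:`fit_melting_curve` — the canonical per-curve fit via
  :func:`scipy.optimize.least_squares` (bounded trust-region), used for all
  reported per-protein parameters.
* :func:`batch_fit_melting_curves` — a vectorised damped Gauss-Newton
  (Levenberg-Marquardt) solver that fits thousands of curves at once; it
  powers the permutation NPARC engine where per-curve scipy calls would be
  prohibitively slow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .design import TemperatureGradient

# Solver bounds: a > 0 (steepness), b free-ish, plateau in [0, 1).
_LOWER = np.array([1e-2, -100.0, 0.0])
_UPPER = np.array([1e6, 500.0, 1.0 - 1e-6])

#: Default extrapolation margin E (°C): a Tm further than this beyond the
#: gradient span is reported as undefined rather than wildly extrapolated.
DEFAULT_EXTRAPOLATION = 10.0

#: Default minimum number of non-missing fold-change points (incl. T_min).
DEFAULT_MIN_POINTS = 5

#: Grid step (°C) for the steepest-slope search.
SLOPE_GRID_STEP = 0.01


def model_value(T, a, b, plateau):
    """Fraction of protein remaining soluble at temperature ``T`` (°C).

    Accepts scalars or arrays; ``T`` must be positive.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (°C)")
    u = a / T - b
    out = (1.0 - plateau) / (1.0 + np.exp(-u)) + plateau
    return out if out.ndim else float(out)


def model_derivative(T, a, b, plateau):
    """Analytic df/dT of the melting model (per °C); negative for a > 0."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (°C)")
    u = a / T - b
    e = np.exp(-u)
    out = -(1.0 - plateau) * (a / T**2) * e / (1.0 + e) ** 2
    return out if out.ndim else float(out)


def melting_point(
    a: float,
    b: float,
    plateau: float,
    span: tuple[float, float] | None = None,
    extrapolation: float = DEFAULT_EXTRAPOLATION,
) -> float | None:
    """Temperature (°C) at which half the protein is denatured, or ``None``.

    Closed form: Tm = a / (b - ln(0.5 / (0.5 - plateau))).  Undefined when
    ``plateau >= 0.5`` (the curve never reaches 0.5), when the denominator is
    non-positive, or when the root falls outside ``span`` widened by
    ``extrapolation`` on each side.
    """
    if plateau >= 0.5:
        return None
    denom = b - math.log(0.5 / (0.5 - plateau))
    if denom <= 0:
        return None
    tm = a / denom
    if tm <= 0:
        return None
    if span is not None:
        lo, hi = span
        if not (lo - extrapolation <= tm <= hi + extrapolation):
            return None
    return tm


def steepest_slope(
    a: float, b: float, plateau: float, gradient: TemperatureGradient
) -> float:
    """Most negative df/dT over the gradient span, on a 0.01 °C grid."""
    lo, hi = gradient.span
    grid = np.arange(lo, hi + SLOPE_GRID_STEP / 2, SLOPE_GRID_STEP)
    return float(np.min(model_derivative(grid, a, b, plateau)))


@dataclass(frozen=True)
class MeltingCurveFit:
    """Result of fitting the melting model to one fold-change profile."""

    a: float
    b: float
    plateau: float
    r_squared: float
    tm: float | None
    steepest_slope: float
    converged: bool
    n_points: int
    reason: str | None = None

    @classmethod
    def failure(cls, reason: str, n_points: int = 0) -> "MeltingCurveFit":
        return cls(
            a=math.nan,
            b=math.nan,
            plateau=math.nan,
            r_squared=math.nan,
            tm=None,
            steepest_slope=math.nan,
            converged=False,
            n_points=n_points,
            reason=reason,
        )


def _initial_params(temps: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Deterministic start: plateau = min(y)/2, a = 550, b = a / Tm_guess.

    Tm_guess is the temperature where the profile first drops below 0.5,
    linearly interpolated; profiles that never cross 0.5 start at the hottest
    observed temperature.
    """
    p0 = min(max(float(np.min(y)) / 2.0, 0.0), 0.4)
    a0 = 550.0
    tm0 = float(temps[-1])
    below = np.nonzero(y < 0.5)[0]
    if below.size:
        i = int(below[0])
        if i == 0:
            tm0 = float(temps[0])
        else:
            t1, t2 = temps[i - 1], temps[i]
            y1, y2 = y[i - 1], y[i]
            # linear interpolation to the 0.5 crossing
            tm0 = float(t1 + (y1 - 0.5) / (y1 - y2) * (t2 - t1)) if y1 != y2 else float(t2)
    b0 = a0 / tm0
    return np.array([a0, b0, p0])


def fit_melting_curve(
    fc_profile,
    gradient: TemperatureGradient,
    min_points: int = DEFAULT_MIN_POINTS,
    extrapolation: float = DEFAULT_EXTRAPOLATION,
) -> MeltingCurveFit:
    """Fit the melting model to one per-temperature fold-change profile.

    ``fc_profile`` holds one fold change per gradient temperature, in gradient
    order, with missing measurements as NaN.  The reference point
    FC(T_min) = 1 must be present; fewer than ``min_points`` non-missing
    values (reference included) yields a non-converged fit with a reason.
    """
    temps = gradient.as_array()
    y = np.asarray(fc_profile, dtype=float)
    if y.shape != temps.shape:
        raise ValueError(
            f"profile has {y.size} values but gradient has {temps.size} temperatures"
        )
    keep = np.isfinite(y)
    if not keep[0]:
        return MeltingCurveFit.failure("missing_reference", n_points=int(keep.sum()))
    n = int(keep.sum())
    if n < min_points:
        return MeltingCurveFit.failure("too_few_points", n_points=n)
    t_used, y_used = temps[keep], y[keep]

    x0 = np.clip(_initial_params(t_used, y_used), _LOWER, _UPPER)

    def residuals(theta):
        return model_value(t_used, *theta) - y_used

    try:
        sol = least_squares(residuals, x0, bounds=(_LOWER, _UPPER), method="trf")
    except Exception:
        return MeltingCurveFit.failure("solver_error", n_points=n)
    if not sol.success:
        return MeltingCurveFit.failure("no_convergence", n_points=n)

    a, b, plateau = (float(v) for v in sol.x)
    rss = float(np.sum(sol.fun**2))
    tss = float(np.sum((y_used - y_used.mean()) ** 2))
    r_squared = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else -math.inf)
    tm = melting_point(a, b, plateau, span=gradient.span, extrapolation=extrapolation)
    slope = steepest_slope(a, b, plateau, gradient)
    return MeltingCurveFit(
        a=a,
        b=b,
        plateau=plateau,
        r_squared=r_squared,
        tm=tm,
        steepest_slope=slope,
        converged=True,
        n_points=n,
    )


# ---------------------------------------------------------------------------
# Batched solver
# ---------------------------------------------------------------------------

def _batch_initial_params(temps: np.ndarray, Y: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Vectorised version of :func:`_initial_params` for K problems at once."""
    K, n = Y.shape
    Ym = np.where(W > 0, Y, np.nan)
    ymin = np.nanmin(np.where(W > 0, Y, np.inf), axis=1)
    ymin = np.where(np.isfinite(ymin), ymin, 1.0)
    p0 = np.clip(ymin / 2.0, 0.0, 0.4)

    below = (Ym < 0.5) & (W > 0)
    has_cross = below.any(axis=1)
    idx = np.argmax(below, axis=1)
    tm0 = np.full(K, temps[:, -1] if temps.ndim == 2 else temps[-1], dtype=float)
    T2d = temps if temps.ndim == 2 else np.broadcast_to(temps, (K, n))
    rows = np.arange(K)
    t_at = T2d[rows, idx]
    prev = np.maximum(idx - 1, 0)
    t_prev = T2d[rows, prev]
    y_at = np.where(np.isfinite(Ym[rows, idx]), Ym[rows, idx], 0.0)
    y_prev = np.where(np.isfinite(Ym[rows, prev]), Ym[rows, prev], 1.0)
    dy = y_prev - y_at
    frac = np.where(np.abs(dy) > 1e-12, (y_prev - 0.5) / np.where(dy == 0, 1, dy), 1.0)
    interp = t_prev + np.clip(frac, 0.0, 1.0) * (t_at - t_prev)
    tm_guess = np.where(idx > 0, interp, t_at)
    tm0 = np.where(has_cross, tm_guess, tm0)
    tm0 = np.clip(tm0, 1.0, None)

    a0 = np.full(K, 550.0)
    b0 = a0 / tm0
    return np.column_stack([a0, b0, p0])


def _batch_slope_start(temps: np.ndarray, Y: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Second start point: steepness estimated from the observed decline.

    The fixed a = 550 start underestimates steep high-Tm curves; this start
    sets a from the largest observed per-°C drop, |slope| ~ a/(4 Tm²) near
    the midpoint for small plateau.
    """
    start = _batch_initial_params(temps, Y, W)
    T2d = temps if temps.ndim == 2 else np.broadcast_to(temps, Y.shape)
    Ym = np.where(W > 0, Y, np.nan)
    with np.errstate(invalid="ignore"):
        drops = -np.diff(Ym, axis=1) / np.diff(T2d, axis=1)
    slope = np.nanmax(np.where(np.isfinite(drops), drops, -np.inf), axis=1)
    slope = np.clip(np.where(np.isfinite(slope), slope, 0.05), 0.02, 2.0)
    tm0 = start[:, 0] / start[:, 1]
    a0 = 4.0 * slope * tm0**2
    return np.column_stack([a0, a0 / tm0, start[:, 2]])


def _batch_model_and_jac(T2d, theta):
    a = theta[:, 0:1]
    b = theta[:, 1:2]
    p = theta[:, 2:3]
    u = a / T2d - b
    e = np.exp(-np.clip(u, -500, 500))
    s = 1.0 / (1.0 + e)
    f = (1.0 - p) * s + p
    sp = s * (1.0 - s)  # sigma'(u)
    dfa = (1.0 - p) * sp / T2d
    dfb = -(1.0 - p) * sp
    dfp = 1.0 - s
    return f, np.stack([dfa, dfb, dfp], axis=2)


def batch_fit_melting_curves(
    temps,
    Y,
    weights=None,
    x0=None,
    max_iter: int = 80,
    ftol: float = 1e-12,
):
    """Fit the melting model to ``K`` profiles simultaneously.

    Parameters
    ----------
    temps : (n,) or (K, n) array of temperatures (°C).
    Y : (K, n) array of fold changes; entries with zero weight are ignored.
    weights : (K, n) 0/1 array marking which entries belong to each problem
        (missing data and, in NPARC, condition membership).  Default all-ones;
        NaNs in ``Y`` are always dropped.
    x0 : optional (K, 3) start parameters; default is the same deterministic
        rule the scalar fitter uses.

    Returns
    -------
    params : (K, 3) fitted (a, b, plateau), clipped to the model bounds.
    rss : (K,) weighted residual sums of squares.
    converged : (K,) bool; problems with < 3 usable points are marked failed.
    """
    Y = np.asarray(Y, dtype=float)
    K, n = Y.shape
    T2d = np.asarray(temps, dtype=float)
    if T2d.ndim == 1:
        T2d = np.broadcast_to(T2d, (K, n)).copy()
    W = np.ones((K, n)) if weights is None else np.asarray(weights, dtype=float).copy()
    W = np.where(np.isfinite(Y), W, 0.0)
    Yc = np.where(W > 0, Y, 0.0)
    n_used = (W > 0).sum(axis=1)
    fittable = n_used >= 3

    if x0 is None:
        # two deterministic starts; keep the better optimum per problem
        starts = [
            _batch_initial_params(T2d, Yc, W),
            _batch_slope_start(T2d, Yc, W),
        ]
    else:
        starts = [np.array(x0, dtype=float)]

    best_theta = best_rss = None
    for start in starts:
        theta, rss = _batch_lm(T2d, Yc, W, start, fittable, max_iter, ftol)
        if best_theta is None:
            best_theta, best_rss = theta, rss
        else:
            better = rss < best_rss
            best_theta = np.where(better[:, None], theta, best_theta)
            best_rss = np.where(better, rss, best_rss)
    return best_theta, best_rss, fittable


def _solve3(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batched 3x3 solve by the adjugate (much faster than LAPACK here)."""
    a11, a12, a13 = A[:, 0, 0], A[:, 0, 1], A[:, 0, 2]
    a21, a22, a23 = A[:, 1, 0], A[:, 1, 1], A[:, 1, 2]
    a31, a32, a33 = A[:, 2, 0], A[:, 2, 1], A[:, 2, 2]
    c11 = a22 * a33 - a23 * a32
    c12 = a13 * a32 - a12 * a33
    c13 = a12 * a23 - a13 * a22
    c21 = a23 * a31 - a21 * a33
    c22 = a11 * a33 - a13 * a31
    c23 = a13 * a21 - a11 * a23
    c31 = a21 * a32 - a22 * a31
    c32 = a12 * a31 - a11 * a32
    c33 = a11 * a22 - a12 * a21
    det = a11 * c11 + a12 * c21 + a13 * c31
    det = np.where(np.abs(det) < 1e-300, 1e-300, det)
    b1, b2, b3 = b[:, 0], b[:, 1], b[:, 2]
    return np.stack(
        [
            (c11 * b1 + c12 * b2 + c13 * b3) / det,
            (c21 * b1 + c22 * b2 + c23 * b3) / det,
            (c31 * b1 + c32 * b2 + c33 * b3) / det,
        ],
        axis=1,
    )


def _batch_lm(T2d, Yc, W, theta0, fittable, max_iter, ftol):
    """Damped Gauss-Newton on a shrinking active set of problems.

    Converged problems are compacted out of the working arrays, so the
    per-iteration cost tracks the number of still-active fits.
    """
    K = Yc.shape[0]
    theta_out = np.clip(theta0, _LOWER, _UPPER)
    rss_out = np.empty(K)

    def rss_of(T, Yl, Wl, th):
        f, _ = _batch_model_and_jac(T, th)
        r = Wl * (f - Yl)
        return np.einsum("kn,kn->k", r, r)

    rss_out[:] = rss_of(T2d, Yc, W, theta_out)
    idx = np.nonzero(fittable)[0]
    T_w, Y_w, W_w = T2d[idx], Yc[idx], W[idx]
    theta = theta_out[idx].copy()
    rss = rss_out[idx].copy()
    lam = np.full(idx.size, 1e-3)

    for _ in range(max_iter):
        if idx.size == 0:
            break
        f, J = _batch_model_and_jac(T_w, theta)
        r = W_w * (f - Y_w)
        Jw = J * W_w[:, :, None]
        g = np.einsum("knp,kn->kp", Jw, r)
        H = Jw.transpose(0, 2, 1) @ Jw
        # freeze parameters sitting on a bound whose unconstrained step would
        # leave the box (plain clipping creeps along the boundary and stalls,
        # typically at plateau = 0)
        frozen = ((theta <= _LOWER) & (g > 0)) | ((theta >= _UPPER) & (g < 0))
        if frozen.any():
            keep = ~frozen
            H = H * keep[:, :, None] * keep[:, None, :]
            H[:, np.arange(3), np.arange(3)] += frozen.astype(float)
            g = np.where(frozen, 0.0, g)
        diag = np.maximum(np.einsum("kpp->kp", H), 1e-12)
        A = H.copy()  # Marquardt scaling: A = H + lam * diag(H)
        A[:, np.arange(3), np.arange(3)] += lam[:, None] * diag + 1e-14
        delta = _solve3(A, -g)
        trial = np.clip(theta + delta, _LOWER, _UPPER)
        rss_trial = rss_of(T_w, Y_w, W_w, trial)
        better = rss_trial < rss
        improvement = np.where(better, rss - rss_trial, 0.0)
        theta = np.where(better[:, None], trial, theta)
        lam = np.where(better, np.maximum(lam / 3.0, 1e-10), np.minimum(lam * 4.0, 1e8))
        rss = np.where(better, rss_trial, rss)
        done = better & (improvement <= ftol * (rss + 1e-30))
        stuck = (~better) & (lam >= 1e8)
        finished = done | stuck
        if finished.any():
            theta_out[idx] = theta
            rss_out[idx] = rss
            keep = ~finished
            idx = idx[keep]
            T_w, Y_w, W_w = T_w[keep], Y_w[keep], W_w[keep]
            theta, rss, lam = theta[keep], rss[keep], lam[keep]
    if idx.size:
        theta_out[idx] = theta
        rss_out[idx] = rss
    return theta_out, rss_out
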