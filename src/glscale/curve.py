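"""Generalized-logistic curve fitting to empirical CDFs.

The scaling map at the heart of this package is the four-parameter
generalized logistic (Richards) curve

    L(x) = (1 + Q * exp(-B * (x - M))) ** (-1 / nu),        Q, B, nu > 0,

a strictly increasing bijection from the reals onto the open interval
(0, 1).  Fitting ``L`` to a variable's empirical CDF by least squares
yields a smooth, bounded surrogate for the CDF that can scale unseen
values; because a single extreme observation moves the empirical CDF by
only 1/n, the fitted map is intrinsically robust to outliers.

This module provides the curve itself (:func:`gl_eval`,
:func:`gl_inverse`), the empirical CDF (:func:`ecdf`), the sum-of-squares
objective and its analytic gradient (:func:`objective`,
:func:`gradient`), the quantile-anchored parameter initialization
(:func:`init_q0`, :func:`init_params`), and the quasi-Newton fitting loop
(:func:`fit_gl`).

Initialization anchors the curve at three order statistics: L(x_med) =
0.5 (exact, via nu0 = log2(1 + Q0)), L(x_min) = 0.1 (exact, via the B0
formula), and L(x_max) ~= 0.9, obtained by solving a one-dimensional
root equation for Q0.  That equation has a positive root only when the
spacing ratio (x_max - x_med)/(x_med - x_min) lies in roughly
(0.365, 1.569); outside that band :func:`init_q0` raises
:class:`ConvergenceError` and the fitting loop falls back to the
best-achievable Q0 on a bounded grid (see :func:`fit_gl`).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "ConvergenceError",
    "GLParams",
    "FeatureSample",
    "ECDFTable",
    "FitConfig",
    "FitReport",
    "gl_eval",
    "gl_inverse",
    "ecdf",
    "objective",
    "gradient",
    "init_q0",
    "init_params",
    "init_params_from_anchors",
    "fit_gl",
]

_LOG2_10 = math.log2(10.0)
_LN2 = math.log(2.0)
_LN_09 = math.log(0.9)
# Smallest positive subnormal / largest float < 1: clamp targets that keep
# every curve output inside the open interval (0, 1).
_TINY = 5e-324
_ALMOST_ONE = float(np.nextafter(1.0, 0.0))


class ConvergenceError(RuntimeError):
    """Raised when the Q0 root equation has no bracketable root."""


@dataclass(frozen=True)
class GLParams:
    """Parameters of the generalized logistic curve.

    Attributes
    ----------
    Q : float
        Shape/asymmetry parameter, > 0.
    B : float
        Growth rate, > 0.
    M : float
        Location (the curve's center region).
    nu : float
        Asymmetry exponent, > 0.
    """

    Q: float
    B: float
    M: float
    nu: float

    def __post_init__(self) -> None:
        for name in ("Q", "B", "M", "nu"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"GLParams.{name} must be finite, got {v!r}")
            object.__setattr__(self, name, v)
        if self.Q <= 0 or self.B <= 0 or self.nu <= 0:
            raise ValueError(
                f"GLParams requires Q, B, nu > 0, got Q={self.Q}, B={self.B}, nu={self.nu}"
            )

    def as_array(self) -> np.ndarray:
        """Parameters in the order (B, M, Q, nu) used by :func:`gradient`."""
        return np.array([self.B, self.M, self.Q, self.nu], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "GLParams":
        b, m, q, nu = (float(t) for t in theta)
        return cls(Q=q, B=b, M=m, nu=nu)


@dataclass(frozen=True)
class FeatureSample:
    """Observed values of one variable with cached order statistics."""

    values: np.ndarray
    sorted_values: np.ndarray
    n: int
    x_min: float
    x_med: float
    x_max: float

    @classmethod
    def from_values(cls, values) -> "FeatureSample":
        arr = np.atleast_1d(np.asarray(values, dtype=float)).ravel()
        if arr.size == 0:
            raise ValueError("sample must contain at least one value")
        if not np.all(np.isfinite(arr)):
            raise ValueError("sample contains non-finite values")
        srt = np.sort(arr)
        return cls(
            values=arr,
            sorted_values=srt,
            n=int(arr.size),
            x_min=float(srt[0]),
            x_med=float(np.median(srt)),
            x_max=float(srt[-1]),
        )


@dataclass(frozen=True)
class ECDFTable:
    """Empirical CDF evaluated at the distinct sample values.

    ``heights[i]`` is the fraction of sample values <= ``points[i]``;
    heights are non-decreasing multiples of 1/n and the height at the
    sample maximum is exactly 1.
    """

    points: np.ndarray
    heights: np.ndarray

    def evaluate(self, v) -> np.ndarray:
        """Step-function value of the ECDF at ``v`` (scalar or array)."""
        v = np.asarray(v, dtype=float)
        idx = np.searchsorted(self.points, v, side="right")
        out = np.where(idx > 0, self.heights[np.maximum(idx - 1, 0)], 0.0)
        return out if out.ndim else float(out)


def gl_eval(params: GLParams, x):
    """Evaluate the generalized logistic curve at ``x``.

    Accepts a scalar or array; returns values strictly inside (0, 1).
    Evaluation runs in log space, so arguments far outside the curve's
    active region neither overflow nor collapse onto 0 or 1.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    # log(1 + Q e^{-B(x-M)}) = logaddexp(0, log Q - B (x - M))
    a = math.log(params.Q) - params.B * (x - params.M)
    log_l = -np.logaddexp(0.0, a) / params.nu
    out = np.clip(np.exp(log_l), _TINY, _ALMOST_ONE)
    return out if out.ndim else float(out)


def gl_inverse(params: GLParams, u):
    """Inverse of :func:`gl_eval`: the x with L(x) = u, for u in (0, 1)."""
    u = np.asarray(u, dtype=float)
    if np.any(~np.isfinite(u)) or np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("u must lie strictly inside (0, 1)")
    # u^{-nu} - 1 = expm1(-nu log u), accurate also for u near 1
    x = params.M - (np.log(np.expm1(-params.nu * np.log(u))) - math.log(params.Q)) / params.B
    return x if x.ndim else float(x)


def ecdf(sample: FeatureSample) -> ECDFTable:
    """Empirical CDF of ``sample``: P(v) = #{x_i <= v} / n at each distinct value."""
    points = np.unique(sample.sorted_values)
    counts = np.searchsorted(sample.sorted_values, points, side="right")
    return ECDFTable(points=points, heights=counts / sample.n)


def _check_table(sample: FeatureSample, table: ECDFTable) -> None:
    pts = np.unique(sample.sorted_values)
    if table.points.shape != pts.shape or not np.array_equal(table.points, pts):
        raise ValueError("ECDF table does not match the sample it is paired with")


def objective(params: GLParams, sample: FeatureSample, table: ECDFTable) -> float:
    """Sum of squared residuals between the curve and the ECDF.

    eta = sum_i (L(x_i) - P(x_i))^2 over all n sample points; tied values
    contribute one identical residual term per occurrence.
    """
    _check_table(sample, table)
    resid = gl_eval(params, sample.values) - table.evaluate(sample.values)
    return float(np.sum(resid**2))


def gradient(params: GLParams, sample: FeatureSample, table: ECDFTable) -> np.ndarray:
    """Analytic gradient of the objective: (d eta/dB, d eta/dM, d eta/dQ, d eta/d nu).

    With E = e^{-B(x-M)}, T1 = 2 (P(x) - L(x)) and
    T2 = nu (1 + Q E)^{1/nu + 1}, the partial sums are

        d eta/dB  = sum -T1 * Q E (x - M) / T2
        d eta/dM  = sum  T1 * B Q E / T2
        d eta/dQ  = sum  T1 * E / T2
        d eta/dnu = sum -T1 * log(1 + Q E) / (nu^2 (1 + Q E)^{1/nu})

    computed in log space so that large |B (x - M)| cannot overflow.
    """
    _check_table(sample, table)
    q, b, m, nu = params.Q, params.B, params.M, params.nu
    x = sample.values
    p_hat = table.evaluate(x)
    a = math.log(q) - b * (x - m)          # log(Q E)
    lse = np.logaddexp(0.0, a)             # log(1 + Q E) >= 0
    l_val = np.exp(-lse / nu)
    t1 = 2.0 * (p_hat - l_val)
    # Q E / T2 = exp(a - (1 + 1/nu) lse) / nu; the exponent is <= 0.
    core = np.exp(a - (1.0 + 1.0 / nu) * lse) / nu
    d_b = np.sum(-t1 * (x - m) * core)
    d_m = np.sum(t1 * b * core)
    d_q = np.sum(t1 * core / q)
    d_nu = np.sum(-t1 * lse * np.exp(-lse / nu) / nu**2)
    return np.array([d_b, d_m, d_q, d_nu])


# ---------------------------------------------------------------------------
# Parameter initialization


def _g(q: float) -> float:
    """log((1+Q)^{log2 10} - 1) - log Q, the numerator of the B0 formula."""
    return math.log(math.expm1(_LOG2_10 * math.log1p(q))) - math.log(q)


def _g_prime(q: float) -> float:
    u = _LOG2_10 * math.log1p(q)
    return _LOG2_10 * math.exp(u) / ((1.0 + q) * math.expm1(u)) - 1.0 / q


def _max_anchor_log_misfit(q: float, r: float) -> float:
    """log L(x_max) - log 0.9 for the curve anchored at (0.1, 0.5) with shape Q.

    ``r`` is the spacing ratio (x_max - x_med)/(x_min - x_med), always
    negative for a non-degenerate sample.  The root of this function in Q
    is exactly the root of the initialization equation for Q0.
    """
    a = math.log(q) + r * _g(q)
    nu0 = math.log1p(q) / _LN2
    return -np.logaddexp(0.0, a) / nu0 - _LN_09


def _q0_equation_residual(q: float, r: float) -> float:
    """Residual of the initialization root equation in its printed form."""
    a = math.log(q) + r * _g(q)
    lhs = float(np.exp(-np.logaddexp(0.0, a)))
    rhs = 0.9 ** (math.log1p(q) / _LN2)
    return lhs - rhs


def init_q0(
    x_min: float,
    x_med: float,
    x_max: float,
    *,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> float:
    """Solve the one-dimensional root equation for the initial shape Q0.

    Q0 is the shape for which the curve anchored at L(x_med) = 0.5 and
    L(x_min) = 0.1 also satisfies L(x_max) = 0.9.  The root is found by
    Newton's method in log Q, safeguarded by bisection on a sign-change
    bracket located by geometric scan over [1e-8, 1e8].

    Raises
    ------
    ValueError
        If the anchors are not strictly ordered.
    ConvergenceError
        If no sign change exists in [1e-8, 1e8].  This is not a numerical
        failure: the equation provably has no positive root when
        (x_max - x_med)/(x_med - x_min) falls outside ~(0.365, 1.569).
    """
    if not (x_min < x_med < x_max):
        raise ValueError(
            f"anchors must satisfy x_min < x_med < x_max, got ({x_min}, {x_med}, {x_max})"
        )
    r = (x_max - x_med) / (x_min - x_med)

    f = lambda q: _max_anchor_log_misfit(q, r)

    def f_prime(q: float) -> float:
        a = math.log(q) + r * _g(q)
        big_a = float(np.logaddexp(0.0, a))
        nu0 = math.log1p(q) / _LN2
        nu0_prime = 1.0 / ((1.0 + q) * _LN2)
        sig = float(expit(a))
        return (-sig * (1.0 / q + r * _g_prime(q)) * nu0 + big_a * nu0_prime) / nu0**2

    grid = np.geomspace(1e-8, 1e8, 129)
    fg = np.array([f(q) for q in grid])
    hits = np.where(fg == 0.0)[0]
    if hits.size:
        return float(grid[hits[0]])
    sign_change = np.where(np.sign(fg[:-1]) * np.sign(fg[1:]) < 0)[0]
    if sign_change.size == 0:
        raise ConvergenceError(
            "the Q0 initialization equation has no root for spacing ratio "
            f"(x_max-x_med)/(x_med-x_min) = {-r:.4g}; no sign change in [1e-8, 1e8]"
        )
    i = int(sign_change[0])
    lo, hi = float(grid[i]), float(grid[i + 1])
    f_lo = float(fg[i])

    # Newton from Q = 1 when it lies inside the bracket (exact under
    # symmetric spacing), otherwise from the bracket's geometric center.
    q = 1.0 if lo < 1.0 < hi else math.sqrt(lo * hi)
    for _ in range(max_iter):
        fq = f(q)
        if abs(fq) <= tol:
            return q
        if np.sign(fq) == np.sign(f_lo):
            lo = q
        else:
            hi = q
        fp = f_prime(q) * q  # derivative with respect to log Q
        if fp != 0.0 and math.isfinite(fp):
            q_new = math.exp(math.log(q) - fq / fp)
        else:
            q_new = math.sqrt(lo * hi)
        if not (lo < q_new < hi) or not math.isfinite(q_new):
            q_new = math.sqrt(lo * hi)  # bisection safeguard
        q = q_new
    if abs(f(q)) <= 1e-9:
        return q
    raise ConvergenceError("Newton/bisection failed to refine the Q0 root")


def _params_from_q0(q0: float, x_min: float, x_center: float) -> GLParams:
    nu0 = math.log1p(q0) / _LN2
    b0 = _g(q0) / (x_center - x_min)
    return GLParams(Q=q0, B=b0, M=x_center, nu=nu0)


def _fallback_q0(r: float) -> float:
    """Best-achievable Q0 on a bounded grid when the root equation has no root."""
    grid = np.geomspace(1e-4, 1e4, 161)
    misfit = np.abs([_max_anchor_log_misfit(q, r) for q in grid])
    return float(grid[int(np.argmin(misfit))])


def init_params_from_anchors(
    x_min: float, x_center: float, x_max: float, *, strict: bool = True
) -> GLParams:
    """Initial parameters anchored at three strictly ordered quantiles.

    With ``strict=True`` (default) a missing Q0 root raises
    :class:`ConvergenceError`; with ``strict=False`` the best-achievable
    Q0 on [1e-4, 1e4] is used instead, preserving the exact 0.5 and 0.1
    anchors while letting L(x_max) land as close to 0.9 as the curve
    family allows.
    """
    if not (x_min < x_center < x_max):
        raise ValueError(
            f"anchors must satisfy x_min < x_center < x_max, got ({x_min}, {x_center}, {x_max})"
        )
    try:
        q0 = init_q0(x_min, x_center, x_max)
    except ConvergenceError:
        if strict:
            raise
        q0 = _fallback_q0((x_max - x_center) / (x_min - x_center))
    return _params_from_q0(q0, x_min, x_center)


def init_params(sample: FeatureSample) -> GLParams:
    """Initialization from a sample's (min, median, max).

    The returned curve satisfies L(x_med) = 0.5 and L(x_min) = 0.1
    exactly (algebraic identities of the formulas) and L(x_max) = 0.9 to
    the Q0 root tolerance.

    Raises ValueError for degenerate spacing (median equal to an extreme)
    and ConvergenceError when the sample's spacing admits no Q0 root.
    """
    return init_params_from_anchors(sample.x_min, sample.x_med, sample.x_max, strict=True)


# ---------------------------------------------------------------------------
# Fitting


@dataclass(frozen=True)
class FitConfig:
    """Stopping rules for the least-squares fit.

    gtol is the projected-gradient max-norm tolerance, step_tol the
    relative objective-decrease tolerance of the quasi-Newton loop, and
    max_iter the iteration budget.
    """

    gtol: float = 1e-8
    step_tol: float = 1e-10
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.gtol <= 0 or self.step_tol <= 0 or self.max_iter < 1:
            raise ValueError("tolerances must be positive and max_iter >= 1")


@dataclass(frozen=True)
class FitReport:
    eta_init: float
    eta_final: float
    iterations: int
    converged: bool
    gradient_norm_final: float


def fit_gl(
    sample: FeatureSample,
    config: FitConfig = FitConfig(),
    *,
    init: GLParams | None = None,
) -> tuple[GLParams, FitReport]:
    """Least-squares fit of the curve to the sample's ECDF.

    Minimizes eta over (B, M, Q, nu) by L-BFGS-B with the analytic
    gradient; Q, B, nu positivity is enforced by optimizing their
    logarithms.  On non-convergence within the iteration budget the best
    iterate is returned with ``converged=False`` and a warning; the
    objective never ends above its value at the initialization.
    """
    if init is None:
        init = init_params_from_anchors(
            sample.x_min, sample.x_med, sample.x_max, strict=False
        )
    table = ecdf(sample)
    x = sample.values
    p_hat = table.evaluate(x)

    def fun_and_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        b, m = math.exp(theta[0]), theta[1]
        q, nu = math.exp(theta[2]), math.exp(theta[3])
        a = math.log(q) - b * (x - m)
        lse = np.logaddexp(0.0, a)
        l_val = np.exp(-lse / nu)
        resid = l_val - p_hat
        eta = float(np.sum(resid**2))
        t1 = -2.0 * resid
        core = np.exp(a - (1.0 + 1.0 / nu) * lse) / nu
        d_b = float(np.sum(-t1 * (x - m) * core))
        d_m = float(np.sum(t1 * b * core))
        d_q = float(np.sum(t1 * core / q))
        d_nu = float(np.sum(-t1 * lse * np.exp(-lse / nu) / nu**2))
        # chain rule for the log-parameterization of B, Q, nu
        return eta, np.array([d_b * b, d_m, d_q * q, d_nu * nu])

    theta0 = np.array(
        [math.log(init.B), init.M, math.log(init.Q), math.log(init.nu)]
    )
    eta_init = fun_and_grad(theta0)[0]
    res = minimize(
        fun_and_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": config.max_iter,
            "gtol": config.gtol,
            "ftol": config.step_tol,
        },
    )
    theta = res.x
    eta_final = float(res.fun)
    if eta_final > eta_init:  # descent guarantee: never worse than the start
        theta, eta_final = theta0, eta_init
    _, grad = fun_and_grad(theta)
    converged = bool(res.success)
    if not converged:
        warnings.warn(
            f"GL fit did not converge within {config.max_iter} iterations: {res.message}",
            RuntimeWarning,
            stacklevel=2,
        )
    params = GLParams(
        Q=math.exp(theta[2]), B=math.exp(theta[0]), M=float(theta[1]), nu=math.exp(theta[3])
    )
    report = FitReport(
        eta_init=float(eta_init),
        eta_final=eta_final,
        iterations=int(res.nit),
        converged=converged,
        gradient_norm_final=float(np.linalg.norm(grad)),
    )
    return params, report
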