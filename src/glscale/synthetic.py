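"""Seeded synthetic-data generators for tests, demos and benchmarks.

Every generator is deterministic under a fixed integer seed (all draws
go through numpy's PCG64 bit generator, fixed here so seeds stay
portable across releases) and produces one of the study scenarios:

* plain distributional samples (normal / log-normal / heavy-tailed),
* samples drawn exactly from a known generalized-logistic CDF by
  inverse-transform sampling,
* outlier-contaminated samples (a bulk sample plus a few extreme points
  far above the bulk range),
* two-class 2-D data whose within-class density increases toward the
  inter-class boundary, the regime where a nonlinear CDF scaling expands
  the margin.
"""
from __future__ import annotations

import numpy as np

from .curve import FeatureSample, GLParams, gl_inverse

__all__ = [
    "BIT_GENERATOR",
    "sample_normal",
    "sample_lognormal",
    "sample_heavy_tail",
    "sample_from_gl",
    "gen_contaminated",
    "gen_two_class",
    "gen_benchmark_scenario",
]

BIT_GENERATOR = "PCG64"


def _rng(seed: int) -> np.random.Generator:
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    return np.random.Generator(np.random.PCG64(seed))


def _check_n(n: int) -> None:
    if n < 1:
        raise ValueError("n must be >= 1")


def sample_normal(n: int, seed: int, loc: float = 0.0, scale: float = 1.0) -> FeatureSample:
    _check_n(n)
    return FeatureSample.from_values(_rng(seed).normal(loc, scale, size=n))


def sample_lognormal(n: int, seed: int, mean: float = 0.0, sigma: float = 1.0) -> FeatureSample:
    _check_n(n)
    return FeatureSample.from_values(_rng(seed).lognormal(mean, sigma, size=n))


def sample_heavy_tail(n: int, seed: int, df: float = 2.0) -> FeatureSample:
    """Student-t draws; df=2 has infinite variance, a hard case for z-scoring."""
    _check_n(n)
    return FeatureSample.from_values(_rng(seed).standard_t(df, size=n))


def sample_from_gl(params: GLParams, n: int, seed: int) -> FeatureSample:
    """i.i.d. draws whose CDF is exactly the given curve (inverse transform)."""
    _check_n(n)
    u = _rng(seed).uniform(size=n)
    # uniform() can return 0.0; reflect into the open interval
    u = np.where(u == 0.0, 0.5, u)
    return FeatureSample.from_values(gl_inverse(params, u))


def gen_contaminated(
    base: FeatureSample,
    outlier_magnitude: float,
    n_outliers: int = 1,
) -> tuple[FeatureSample, np.ndarray]:
    """Append outliers at base_max + magnitude * (base range).

    Returns the contaminated sample and the indices of the injected
    outliers.  Each outlier moves the ECDF of the original points by only
    1/(n + n_outliers) — the mechanism that makes CDF-based scaling
    robust.
    """
    if outlier_magnitude <= 0:
        raise ValueError("outlier_magnitude must be positive")
    if n_outliers < 1:
        raise ValueError("n_outliers must be >= 1")
    if n_outliers >= base.n / 10:
        raise ValueError("n_outliers must stay below a tenth of the base sample size")
    span = base.x_max - base.x_min
    value = base.x_max + outlier_magnitude * span
    contaminated = np.concatenate([base.values, np.full(n_outliers, value)])
    idx = np.arange(base.n, base.n + n_outliers)
    return FeatureSample.from_values(contaminated), idx


def gen_two_class(
    n_per_class: int,
    separation: float = 1.0,
    boundary_density: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two 2-D clusters crowded against their common decision boundary.

    The boundary is the vertical line x = 0.  Each class sits at a
    horizontal offset of ``separation / 2`` plus a log-normal excursion
    pointing away from the boundary, so most points pile up near it;
    larger ``boundary_density`` concentrates them harder.  The second
    coordinate is uninformative standard-normal noise.  Returns
    ``(X, y)`` with shape (2 * n_per_class, 2) and balanced 0/1 labels.
    """
    if n_per_class < 10:
        raise ValueError("n_per_class must be >= 10")
    if separation <= 0:
        raise ValueError("separation must be positive")
    if boundary_density <= 0:
        raise ValueError("boundary_density must be positive")
    rng = _rng(seed)
    gap = separation / 2.0
    off_neg = rng.lognormal(0.0, 1.0, n_per_class) / boundary_density
    off_pos = rng.lognormal(0.0, 1.0, n_per_class) / boundary_density
    noise = rng.normal(0.0, 1.0, 2 * n_per_class)
    x = np.concatenate([-gap - off_neg, gap + off_pos])
    X = np.column_stack([x, noise])
    y = np.concatenate([np.zeros(n_per_class, int), np.ones(n_per_class, int)])
    return X, y


def gen_benchmark_scenario(
    seed: int,
    n_per_class: int = 60,
    scale_factor: float = 1e6,
    n_outliers: int = 3,
    outlier_magnitude: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-class data with wildly mismatched feature scales plus outliers.

    Starts from :func:`gen_two_class`, inflates the uninformative noise
    coordinate by ``scale_factor``, and pushes ``n_outliers`` randomly
    chosen positive-class points to ``outlier_magnitude`` times the range
    of the informative coordinate.  The outliers are extreme but
    correctly labeled, so range-based scaling squeezes the informative
    signal while CDF-based scaling barely notices them.
    """
    X, y = gen_two_class(n_per_class, separation=1.0, boundary_density=1.0, seed=seed)
    X = X.copy()
    X[:, 1] *= scale_factor
    rng = _rng(seed + 7919)
    pos_idx = np.flatnonzero(y == 1)
    chosen = rng.choice(pos_idx, size=n_outliers, replace=False)
    col = X[:, 0]
    X[chosen, 0] = col.max() + outlier_magnitude * (col.max() - col.min())
    return X, y
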