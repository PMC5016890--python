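"""Unit and property tests for the generalized-logistic curve machinery."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glscale.curve import (
    ConvergenceError,
    FeatureSample,
    GLParams,
    ecdf,
    gl_eval,
    gl_inverse,
    gradient,
    init_params,
    init_params_from_anchors,
    init_q0,
    objective,
)

from conftest import random_params

# ---------------------------------------------------------------------------
# curve evaluation and inverse


def test_logistic_center_is_half(standard_logistic):
    assert gl_eval(standard_logistic, 0.0) == pytest.approx(0.5, abs=1e-15)


def test_hand_computed_value():
    # 1 / (1 + e^{ln 9}) = 1/10 for the unit logistic shifted to M=1
    p = GLParams(Q=1.0, B=math.log(9.0), M=1.0, nu=1.0)
    assert gl_eval(p, 0.0) == pytest.approx(0.1, abs=1e-15)


def test_asymptotes_and_open_range():
    p = GLParams(Q=2.0, B=1.5, M=0.0, nu=0.8)
    lo = gl_eval(p, -1e12)
    hi = gl_eval(p, 1e12)
    assert 0.0 < lo < 1e-6
    assert 1.0 - 1e-6 < hi < 1.0  # approaches but never attains 1


def test_extreme_arguments_stay_inside_unit_interval():
    p = GLParams(Q=1.0, B=50.0, M=0.0, nu=0.5)
    vals = gl_eval(p, np.array([-1e300, -1e6, 0.0, 1e6, 1e300]))
    assert np.all(vals > 0.0) and np.all(vals < 1.0)
    assert np.all(np.diff(vals) >= 0.0)


def test_invalid_inputs_raise():
    with pytest.raises(ValueError):
        GLParams(Q=-1.0, B=1.0, M=0.0, nu=1.0)
    with pytest.raises(ValueError):
        GLParams(Q=1.0, B=1.0, M=np.nan, nu=1.0)
    p = GLParams(Q=1.0, B=1.0, M=0.0, nu=1.0)
    with pytest.raises(ValueError):
        gl_eval(p, np.inf)
    for bad_u in (0.0, 1.0, -0.5, 1.5):
        with pytest.raises(ValueError):
            gl_inverse(p, bad_u)


def test_inverse_hand_examples():
    assert gl_inverse(GLParams(Q=1, B=1, M=3, nu=1), 0.5) == pytest.approx(3.0, abs=1e-12)
    p = GLParams(Q=1.0, B=math.log(9.0), M=1.0, nu=1.0)
    assert gl_inverse(p, 0.1) == pytest.approx(0.0, abs=1e-12)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    u=st.floats(min_value=1e-6, max_value=1.0 - 1e-6),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_inverse_round_trip(u, seed):
    rng = np.random.Generator(np.random.PCG64(seed))
    p = random_params(rng)
    assert gl_eval(p, gl_inverse(p, u)) == pytest.approx(u, abs=1e-10)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    x1=st.floats(min_value=-20.0, max_value=20.0),
    dx=st.floats(min_value=1e-6, max_value=40.0),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_strict_monotonicity(x1, dx, seed):
    rng = np.random.Generator(np.random.PCG64(seed))
    p = random_params(rng)
    assert gl_eval(p, x1) < gl_eval(p, x1 + dx)


# ---------------------------------------------------------------------------
# ECDF


def test_ecdf_simple_counts(small_sample):
    table = ecdf(small_sample)
    assert table.evaluate(2.0) == pytest.approx(2.0 / 3.0)
    assert table.evaluate(3.0) == 1.0
    assert table.evaluate(0.5) == 0.0


def test_ecdf_ties_share_height():
    table = ecdf(FeatureSample.from_values([5.0, 5.0, 5.0, 9.0]))
    assert table.evaluate(5.0) == pytest.approx(0.75)
    assert table.evaluate(9.0) == 1.0


def test_ecdf_invariants(rng):
    sample = FeatureSample.from_values(rng.normal(size=57))
    table = ecdf(sample)
    assert np.all(np.diff(table.heights) > 0)
    assert table.heights[-1] == 1.0
    # all heights are multiples of 1/n
    assert np.allclose(table.heights * sample.n, np.round(table.heights * sample.n))


def test_ecdf_matches_brute_force_enumeration():
    """Double-loop indicator count on every multiset of size <= 6 over {0,1,2}."""
    alphabet = [0.0, 1.0, 2.0]
    for size in range(1, 7):
        for combo in itertools.combinations_with_replacement(alphabet, size):
            sample = FeatureSample.from_values(combo)
            table = ecdf(sample)
            for v in alphabet + [-0.5, 0.5, 2.5]:
                brute = sum(1 for x in combo if x <= v) / size
                assert table.evaluate(v) == pytest.approx(brute)


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        FeatureSample.from_values([])


# ---------------------------------------------------------------------------
# objective and gradient


def test_objective_hand_summation(small_sample):
    params = GLParams(Q=1.0, B=1.0, M=2.0, nu=1.0)
    # independent arithmetic: logistic values against heights 1/3, 2/3, 1
    l1 = 1.0 / (1.0 + math.exp(1.0))
    l2 = 0.5
    l3 = 1.0 / (1.0 + math.exp(-1.0))
    expected = (l1 - 1 / 3) ** 2 + (l2 - 2 / 3) ** 2 + (l3 - 1.0) ** 2
    table = ecdf(small_sample)
    assert objective(params, small_sample, table) == pytest.approx(expected, rel=1e-14)
    assert objective(params, small_sample, table) == pytest.approx(0.10425358569805147)


def test_objective_counts_duplicates_with_multiplicity():
    tied = FeatureSample.from_values([1.0, 1.0, 3.0])
    table = ecdf(tied)
    params = GLParams(Q=1.0, B=1.0, M=2.0, nu=1.0)
    l1 = 1.0 / (1.0 + math.exp(1.0))
    l3 = 1.0 / (1.0 + math.exp(-1.0))
    expected = 2 * (l1 - 2 / 3) ** 2 + (l3 - 1.0) ** 2
    assert objective(params, tied, table) == pytest.approx(expected, rel=1e-14)


def test_objective_mismatched_table_rejected(small_sample):
    other = ecdf(FeatureSample.from_values([4.0, 5.0, 6.0]))
    with pytest.raises(ValueError):
        objective(GLParams(Q=1, B=1, M=0, nu=1), small_sample, other)


def _fd_gradient(params, sample, table, rel_step=1e-6):
    """Central finite differences of the objective in (B, M, Q, nu)."""
    theta = params.as_array()
    out = np.empty(4)
    for i in range(4):
        h = rel_step * (1.0 + abs(theta[i]))
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] -= h
        out[i] = (
            objective(GLParams.from_array(up), sample, table)
            - objective(GLParams.from_array(dn), sample, table)
        ) / (2 * h)
    return out


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_gradient_matches_finite_differences(seed):
    rng = np.random.Generator(np.random.PCG64(seed))
    sample = FeatureSample.from_values(rng.normal(size=30))
    table = ecdf(sample)
    params = random_params(rng)
    analytic = gradient(params, sample, table)
    fd = _fd_gradient(params, sample, table)
    np.testing.assert_allclose(analytic, fd, rtol=1e-5, atol=1e-7)


def test_gradient_two_point_oracle(rng):
    """Random 2-point case against finite differences (smallest nontrivial n)."""
    sample = FeatureSample.from_values(rng.normal(size=2))
    table = ecdf(sample)
    params = random_params(rng)
    np.testing.assert_allclose(
        gradient(params, sample, table),
        _fd_gradient(params, sample, table),
        rtol=1e-5,
        atol=1e-8,
    )


# ---------------------------------------------------------------------------
# initialization


def _q0_equation_residual(q, x_min, x_med, x_max):
    """The printed root equation, written out independently of the package."""
    c = math.log2(10.0)
    expo = (math.log((1 + q) ** c - 1) - math.log(q)) * (x_max - x_med) / (x_min - x_med)
    lhs = 1.0 / (1.0 + q * math.exp(expo))
    rhs = 0.9 ** math.log2(1 + q)
    return lhs - rhs


def _bisection_oracle(x_min, x_med, x_max, lo=1e-6, hi=1e6):
    """Fine-grid scan + bisection on the independently coded equation."""
    grid = np.geomspace(lo, hi, 2001)
    vals = [_q0_equation_residual(q, x_min, x_med, x_max) for q in grid]
    bracket = None
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            return a
        if fa * fb < 0:
            bracket = (a, b)
            break
    assert bracket is not None, "oracle found no sign change"
    a, b = bracket
    for _ in range(200):
        mid = math.sqrt(a * b)
        if _q0_equation_residual(a, x_min, x_med, x_max) * _q0_equation_residual(
            mid, x_min, x_med, x_max
        ) <= 0:
            b = mid
        else:
            a = mid
    return math.sqrt(a * b)


def test_symmetric_spacing_gives_unit_q0():
    assert init_q0(0.0, 1.0, 2.0) == pytest.approx(1.0, abs=1e-10)
    assert init_q0(-3.0, 1.5, 6.0) == pytest.approx(1.0, abs=1e-10)


def test_q0_matches_bisection_oracle():
    for trip in [(0.0, 2.0, 3.0), (0.0, 1.0, 2.4), (-1.0, 0.2, 1.0)]:
        got = init_q0(*trip)
        want = _bisection_oracle(*trip)
        assert got == pytest.approx(want, rel=1e-6)
        assert abs(_q0_equation_residual(got, *trip)) <= 1e-10


def test_q0_rootless_spacing_raises():
    # (x_max - x_med) / (x_med - x_min) = 2 lies outside the band where the
    # root equation has a positive root; the error contract applies.
    with pytest.raises(ConvergenceError):
        init_q0(0.0, 1.0, 3.0)


def test_q0_degenerate_anchors_raise():
    with pytest.raises(ValueError):
        init_q0(0.0, 0.0, 1.0)
    with pytest.raises(ValueError):
        init_q0(0.0, 1.0, 1.0)


def test_init_params_symmetric_hand_values():
    params = init_params(FeatureSample.from_values([0.0, 1.0, 2.0]))
    assert params.M == 1.0
    assert params.Q == pytest.approx(1.0, abs=1e-9)
    assert params.nu == pytest.approx(1.0, abs=1e-9)
    assert params.B == pytest.approx(math.log(9.0), rel=1e-9)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_init_anchor_identities(seed):
    """Initialized curve passes through (x_min, 0.1), (x_med, 0.5), (x_max, 0.9)."""
    rng = np.random.Generator(np.random.PCG64(seed))
    sample = FeatureSample.from_values(rng.uniform(size=100))
    params = init_params(sample)
    assert gl_eval(params, sample.x_med) == pytest.approx(0.5, abs=1e-12)
    assert gl_eval(params, sample.x_min) == pytest.approx(0.1, abs=1e-12)
    assert gl_eval(params, sample.x_max) == pytest.approx(0.9, abs=1e-8)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(q0=st.floats(min_value=1e-4, max_value=1e4))
def test_median_identity_holds_for_every_shape(q0):
    """(1+Q)^(-1/log2(1+Q)) = 1/2 algebraically, for any Q > 0."""
    nu0 = math.log2(1 + q0)
    p = GLParams(Q=q0, B=1.0, M=0.0, nu=nu0)
    assert gl_eval(p, 0.0) == pytest.approx(0.5, abs=1e-12)


def test_strict_vs_fallback_anchor_initialization():
    with pytest.raises(ConvergenceError):
        init_params_from_anchors(0.0, 1.0, 3.0, strict=True)
    params = init_params_from_anchors(0.0, 1.0, 3.0, strict=False)
    # the 0.5 / 0.1 anchors are exact even in the fallback regime
    assert gl_eval(params, 1.0) == pytest.approx(0.5, abs=1e-12)
    assert gl_eval(params, 0.0) == pytest.approx(0.1, abs=1e-12)
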