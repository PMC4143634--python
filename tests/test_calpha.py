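import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarewin.calpha import (
    CAlphaInput,
    calpha_T,
    calpha_variance,
    calpha_z,
    case_allele_counts,
    permutation_p,
    run_window_test,
)


def brute_T(y, n, p0):
    """Plain per-variant accumulation of the statistic."""
    total = 0.0
    for yi, ni in zip(y, n):
        total += (yi - ni * p0) ** 2 - ni * p0 * (1 - p0)
    return total


def brute_variance(n, p0):
    """Naive per-variant enumeration, no grouping of equal copy counts."""
    from scipy.stats import binom

    total = 0.0
    for ni in n:
        for u in range(ni + 1):
            term = (u - ni * p0) ** 2 - ni * p0 * (1 - p0)
            total += binom.pmf(u, ni, p0) * term**2
    return total


@pytest.mark.parametrize(
    "y,n,p0,expected",
    [([1], [2], 0.5, -0.5), ([2], [2], 0.5, 0.5), ([0], [2], 0.5, 0.5)],
)
def test_T_hand_values(y, n, p0, expected):
    assert calpha_T(CAlphaInput(y=y, n=n, p0=p0)) == pytest.approx(expected)


def test_T_balanced_case_is_negative():
    n = np.array([4, 4, 8])
    p0 = 0.5
    inp = CAlphaInput(y=n * p0, n=n, p0=p0)
    assert calpha_T(inp) == pytest.approx(-np.sum(n * p0 * (1 - p0)))


@pytest.mark.parametrize("p0", [0.3, 0.5, 60 / 94])
def test_T_exhaustive_small_inputs_match_brute_force(p0):
    """Every (n, y) configuration with m <= 4 variants and n_i <= 4 copies."""
    for m in (1, 2, 3, 4):
        for n in itertools.combinations_with_replacement((2, 3, 4), m):
            for y in itertools.product(*(range(ni + 1) for ni in n)):
                inp = CAlphaInput(y=list(y), n=list(n), p0=p0)
                assert calpha_T(inp) == pytest.approx(brute_T(y, n, p0), rel=1e-12)


def test_variance_hand_value_and_grouped_fast_path():
    assert calpha_variance([2], 0.5) == pytest.approx(0.25)
    n = [2, 2, 3, 4, 4, 4]
    assert calpha_variance(n, 0.3) == pytest.approx(brute_variance(n, 0.3), rel=1e-12)


def test_variance_additivity():
    n = [2, 3, 5]
    assert calpha_variance(n + n, 0.4) == pytest.approx(2 * calpha_variance(n, 0.4))


def test_variance_matches_monte_carlo():
    rng = np.random.default_rng(17)
    n = np.array([2, 3, 5, 8, 8, 12])
    p0 = 0.6
    draws = rng.binomial(n, p0, size=(100_000, len(n)))
    T = ((draws - n * p0) ** 2 - n * p0 * (1 - p0)).sum(axis=1)
    assert calpha_variance(n, p0) == pytest.approx(T.var(), rel=0.02)


def test_z_and_asymptotic_p():
    Z, p = calpha_z(-0.5, 0.25)
    assert Z == pytest.approx(-1.0)
    assert calpha_z(0.0, 1.0)[1] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        calpha_z(1.0, 0.0)


def test_z_is_standard_normal_under_null():
    rng = np.random.default_rng(23)
    n = np.full(60, 10)
    p0 = 0.5
    c = calpha_variance(n, p0)
    draws = rng.binomial(n, p0, size=(4000, len(n)))
    T = ((draws - n * p0) ** 2 - n * p0 * (1 - p0)).sum(axis=1)
    Z = T / np.sqrt(c)
    assert abs(Z.mean()) < 0.05
    assert Z.std() == pytest.approx(1.0, abs=0.1)


@given(
    st.lists(st.tuples(st.integers(2, 6), st.integers(0, 6)), min_size=1, max_size=6),
    st.floats(0.1, 0.9),
)
@settings(deadline=None, max_examples=80)
def test_label_symmetry(pairs, p0):
    """Swapping case/control labels (y -> n-y, p0 -> 1-p0) leaves T unchanged."""
    n = np.array([a for a, _ in pairs], dtype=float)
    y = np.array([min(b, a) for a, b in pairs], dtype=float)
    a = calpha_T(CAlphaInput(y=y, n=n, p0=p0))
    b = calpha_T(CAlphaInput(y=n - y, n=n, p0=1 - p0))
    assert a == pytest.approx(b, rel=1e-9, abs=1e-9)


def test_case_allele_counts():
    G = np.array([[2, 1], [0, 1], [0, 0], [np.nan, 1]])
    status = np.array([2, 2, 1, 1], dtype=float)
    inp = case_allele_counts(G, status)
    assert inp.p0 == pytest.approx(0.5)
    assert list(inp.n) == [2, 3] and list(inp.y) == [2, 2]
    with pytest.raises(ValueError):
        case_allele_counts(G, np.array([2, 2, 2, 2], dtype=float))


def test_case_fraction_matches_cohort_composition():
    """60 cases and 34 controls give p0 = 60/94."""
    status = np.array([2.0] * 60 + [1.0] * 34)
    G = np.zeros((94, 2))
    G[:5] = 1
    inp = case_allele_counts(G, status)
    assert inp.p0 == pytest.approx(60 / 94)


def test_permutation_p_extremes_with_controlled_samplers():
    # one case carries every copy; all other labelings lower T
    G = np.array([[2.0, 2.0], [0, 0], [0, 0], [0, 0]])
    status = np.array([2.0, 1.0, 1.0, 1.0])

    def always_subject1(rng, n, k, B):
        m = np.zeros((B, n), dtype=bool)
        m[:, 1] = True
        return m

    def identity(rng, n, k, B):
        m = np.zeros((B, n), dtype=bool)
        m[:, 0] = True
        return m

    assert permutation_p(G, status, B=1000, sampler=always_subject1) == pytest.approx(1 / 1001)
    assert permutation_p(G, status, B=1000, sampler=identity) == pytest.approx(1.0)


def test_permutation_p_on_grid_and_deterministic():
    rng_g = np.random.default_rng(2)
    G = rng_g.binomial(2, 0.05, size=(50, 6)).astype(float)
    status = np.array([2.0] * 30 + [1.0] * 20)
    B = 200
    p1 = permutation_p(G, status, B=B, rng=np.random.default_rng(42))
    p2 = permutation_p(G, status, B=B, rng=np.random.default_rng(42))
    assert p1 == p2
    assert round(p1 * (B + 1)) == pytest.approx(p1 * (B + 1))  # on the (b+1)/(B+1) grid


def test_window_test_bundles_consistently():
    rng_g = np.random.default_rng(4)
    G = rng_g.binomial(2, 0.04, size=(80, 5)).astype(float)
    status = np.array([2.0] * 48 + [1.0] * 32)
    res = run_window_test(G, status, B=300, rng=np.random.default_rng(1))
    assert res.applicable and res.n_rv == 5
    assert res.Z == pytest.approx(res.T / np.sqrt(res.c))
    assert 0 <= res.p_permutation <= 1 and 0 <= res.p_asymptotic <= 1
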