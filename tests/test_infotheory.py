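import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize

from funcfeat.infotheory import (
    bin_equipopulated,
    entropy_bits,
    exceedance_fraction,
    mutual_information_mm,
    permutation_null,
    redundancy_iccs,
)
from funcfeat.infotheory.iccs import maxent_pairwise

# ----------------------------------------------------------------- binning


def test_equipopulated_counts_1_to_9():
    b = bin_equipopulated(np.arange(1.0, 10.0), 3)
    np.testing.assert_array_equal(np.bincount(b.labels), [3, 3, 3])


def test_tied_block_stays_in_one_bin():
    x = np.array([1.0, 2.0, 5.0, 5.0, 5.0, 5.0, 5.0, 8.0, 9.0])
    b = bin_equipopulated(x, 3)
    assert len(set(b.labels[x == 5.0])) == 1


def test_large_sample_quantile_property():
    rng = np.random.default_rng(0)
    b = bin_equipopulated(rng.standard_normal(3000), 3)
    counts = np.bincount(b.labels)
    assert counts.max() - counts.min() <= 1


def test_constant_input_raises():
    with pytest.raises(ValueError, match="constant"):
        bin_equipopulated(np.ones(10), 3)


def test_too_few_observations_raises():
    with pytest.raises(ValueError):
        bin_equipopulated(np.array([1.0, 2.0]), 3)


# ---------------------------------------------------------------------- MI


def test_identical_uniform_plugin_mi_is_log2_3():
    x = np.tile([0, 1, 2], 30)
    mi = mutual_information_mm(x, x, corrected=False)
    np.testing.assert_allclose(mi, math.log2(3), atol=1e-12)


def test_mi_of_variable_with_itself_is_entropy():
    rng = np.random.default_rng(1)
    x = rng.integers(0, 3, 200)
    counts = np.bincount(x)
    np.testing.assert_allclose(
        mutual_information_mm(x, x, corrected=False), entropy_bits(counts), atol=1e-12
    )


def test_independent_variables_near_zero_mi():
    rng = np.random.default_rng(2)
    mis = []
    for _ in range(50):
        x = rng.integers(0, 3, 10_000)
        y = rng.integers(0, 3, 10_000)
        mis.append(mutual_information_mm(x, y))
    assert abs(np.median(mis)) < 0.01


def _mi_oracle_with_mm(table):
    """Direct-summation MI plus hand-applied Miller-Madow terms."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    px = table.sum(axis=1) / n
    py = table.sum(axis=0) / n
    mi = 0.0
    for i, j in itertools.product(range(table.shape[0]), range(table.shape[1])):
        p = table[i, j] / n
        if p > 0:
            mi += p * math.log2(p / (px[i] * py[j]))
    kx = np.sum(table.sum(axis=1) > 0)
    ky = np.sum(table.sum(axis=0) > 0)
    kxy = np.sum(table > 0)
    return mi + (kx - 1 + ky - 1 - (kxy - 1)) / (2 * n * math.log(2))


def test_mi_matches_direct_summation_oracle_on_3x3_table():
    table = np.array([[10, 3, 1], [2, 8, 4], [0, 5, 12]])
    x, y = [], []
    for i, j in itertools.product(range(3), range(3)):
        x += [i] * table[i, j]
        y += [j] * table[i, j]
    np.testing.assert_allclose(
        mutual_information_mm(np.array(x), np.array(y)), _mi_oracle_with_mm(table), atol=1e-12
    )


def test_mi_symmetry():
    rng = np.random.default_rng(3)
    x = rng.integers(0, 3, 500)
    y = rng.integers(0, 4, 500)
    assert mutual_information_mm(x, y) == mutual_information_mm(y, x)


# ------------------------------------------------------------------- I_ccs


def _maxent_dual_oracle(p):
    """Maxent over pairwise marginals via exponential-family dual fitting.

    Independent of the fast path's iterative proportional fitting: the
    joint is parameterized as ``q \\propto exp(a_12 + a_1t + a_2t)`` and
    the smooth convex dual is minimized with L-BFGS-B. Positivity is
    automatic; boundary (forced-zero) solutions are reached in the limit.
    """
    m12, m1t, m2t = p.sum(axis=2), p.sum(axis=1), p.sum(axis=0)
    n1, n2, nt = p.shape

    def unpack(th):
        a = th[: n1 * n2].reshape(n1, n2, 1)
        b = th[n1 * n2 : n1 * n2 + n1 * nt].reshape(n1, 1, nt)
        c = th[n1 * n2 + n1 * nt :].reshape(1, n2, nt)
        return a + b + c

    def negdual(th):
        e = unpack(th)
        logz = np.log(np.sum(np.exp(e)))
        val = (
            logz
            - np.sum(th[: n1 * n2] * m12.ravel())
            - np.sum(th[n1 * n2 : n1 * n2 + n1 * nt] * m1t.ravel())
            - np.sum(th[n1 * n2 + n1 * nt :] * m2t.ravel())
        )
        q = np.exp(e - logz)
        grad = np.concatenate(
            [(q.sum(2) - m12).ravel(), (q.sum(1) - m1t).ravel(), (q.sum(0) - m2t).ravel()]
        )
        return val, grad

    th0 = np.zeros(n1 * n2 + n1 * nt + n2 * nt)
    res = minimize(negdual, th0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 5000, "ftol": 1e-18, "gtol": 1e-12})
    e = unpack(res.x)
    return np.exp(e - np.log(np.sum(np.exp(e))))


def _iccs_oracle(counts):
    """Exhaustive pointwise oracle, independent of the fast path.

    Maximum entropy from the dual-space fit; pointwise terms accumulated
    by explicit loops. Normative definition for small alphabets.
    """
    p = np.asarray(counts, dtype=float)
    p = p / p.sum()
    shape = p.shape
    m12, m1t, m2t = p.sum(axis=2), p.sum(axis=1), p.sum(axis=0)
    q = _maxent_dual_oracle(p)
    q = np.where(q < 1e-12, 0.0, q)
    q = q / q.sum()

    qt = q.sum(axis=(0, 1))
    q1 = q.sum(axis=(1, 2))
    q2 = q.sum(axis=(0, 2))
    eps = 1e-6  # same structural-zero guard as the implementation under test
    red = 0.0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if q[i, j, k] <= 0:
                    continue
                di1 = math.log2(q.sum(axis=1)[i, k] / (q1[i] * qt[k]))
                di2 = math.log2(q.sum(axis=0)[j, k] / (q2[j] * qt[k]))
                di12 = math.log2(q[i, j, k] / (q.sum(axis=2)[i, j] * qt[k]))
                coi = di1 + di2 - di12
                if (di1 > eps and di2 > eps and coi > eps) or (
                    di1 < -eps and di2 < -eps and coi < -eps
                ):
                    red += q[i, j, k] * coi

    def mi(mar):
        out = 0.0
        for a in range(mar.shape[0]):
            for b in range(mar.shape[1]):
                if mar[a, b] > 0:
                    out += mar[a, b] * math.log2(mar[a, b] / (mar.sum(axis=1)[a] * mar.sum(axis=0)[b]))
        return out

    return float(np.clip(red, 0.0, min(mi(m1t), mi(m2t))))


def _labels_from_counts(counts):
    s1, s2, t = [], [], []
    for idx, c in np.ndenumerate(counts):
        s1 += [idx[0]] * int(c)
        s2 += [idx[1]] * int(c)
        t += [idx[2]] * int(c)
    return np.array(s1), np.array(s2), np.array(t)


def test_identical_sources_redundancy_is_full_mi():
    x = np.tile([0, 1, 2], 20)
    np.testing.assert_allclose(redundancy_iccs(x, x, x), math.log2(3), atol=1e-9)


def test_xor_target_zero_redundancy():
    s1 = np.array([0, 0, 1, 1] * 25)
    s2 = np.array([0, 1, 0, 1] * 25)
    assert redundancy_iccs(s1, s2, s1 ^ s2) == 0.0


def test_and_target_matches_exhaustive_oracle():
    s1 = np.array([0, 0, 1, 1] * 25)
    s2 = np.array([0, 1, 0, 1] * 25)
    t = s1 & s2
    counts = np.zeros((2, 2, 2))
    for a, b, c in zip(s1, s2, t):
        counts[a, b, c] += 1
    np.testing.assert_allclose(redundancy_iccs(s1, s2, t), _iccs_oracle(counts), atol=1e-6)


def test_fast_path_matches_oracle_on_random_3x3x3_tables():
    rng = np.random.default_rng(4)
    for _ in range(8):
        counts = rng.integers(0, 6, size=(3, 3, 3))
        if counts.sum() == 0:
            continue
        s1, s2, t = _labels_from_counts(counts)
        np.testing.assert_allclose(
            redundancy_iccs(s1, s2, t), _iccs_oracle(counts), atol=5e-5
        )


def test_redundancy_bounded_by_source_mis():
    rng = np.random.default_rng(5)
    for _ in range(10):
        s1 = rng.integers(0, 3, 300)
        s2 = rng.integers(0, 3, 300)
        t = (s1 + rng.integers(0, 2, 300)) % 3
        r = redundancy_iccs(s1, s2, t)
        i1 = mutual_information_mm(s1, t, corrected=False)
        i2 = mutual_information_mm(s2, t, corrected=False)
        assert -1e-9 <= r <= min(i1, i2) + 1e-9


def test_bijective_relabeling_preserves_redundancy():
    rng = np.random.default_rng(6)
    s1 = rng.integers(0, 3, 400)
    t = (s1 + rng.integers(0, 2, 400)) % 3
    relabeled = (2 - s1) % 3  # a bijection of the alphabet
    np.testing.assert_allclose(
        redundancy_iccs(s1, relabeled, t),
        mutual_information_mm(s1, t, corrected=False),
        atol=1e-9,
    )


def test_maxent_preserves_pairwise_marginals():
    rng = np.random.default_rng(7)
    p = rng.random((3, 3, 3))
    p /= p.sum()
    q = maxent_pairwise(p)
    np.testing.assert_allclose(q.sum(axis=2), p.sum(axis=2), atol=1e-10)
    np.testing.assert_allclose(q.sum(axis=1), p.sum(axis=1), atol=1e-10)
    np.testing.assert_allclose(q.sum(axis=0), p.sum(axis=0), atol=1e-10)
    assert entropy_bits(q.ravel() * 1000) >= entropy_bits(p.ravel() * 1000) - 1e-9


def test_estimators_deterministic():
    rng = np.random.default_rng(8)
    s1 = rng.integers(0, 3, 100)
    s2 = rng.integers(0, 3, 100)
    t = rng.integers(0, 3, 100)
    assert redundancy_iccs(s1, s2, t) == redundancy_iccs(s1, s2, t)
    assert mutual_information_mm(s1, t) == mutual_information_mm(s1, t)


# ----------------------------------------------------- nulls and exceedance


def test_permutation_null_reproducible():
    rng = np.random.default_rng(9)
    y = rng.standard_normal(50)
    fn = lambda v: float(np.mean(v[:25]) - np.mean(v[25:]))
    assert permutation_null(fn, y, n_perm=30, seed=1) == permutation_null(fn, y, n_perm=30, seed=1)


def test_permutation_count_guard():
    with pytest.raises(ValueError, match="n_perm"):
        permutation_null(lambda v: 0.0, np.arange(10.0), n_perm=1)


def test_eval_failure_annotated_with_index():
    def bad(v):
        raise RuntimeError("boom")

    with pytest.raises(RuntimeError, match="permutation 0"):
        permutation_null(bad, np.arange(30.0), n_perm=20)


def test_exceedance_all_above():
    assert exceedance_fraction([1, 2, 3], [0, 0, 0]) == 1.0


def test_exceedance_none_above():
    assert exceedance_fraction([0, 0], [1, 1]) == 0.0


def test_exceedance_mixed():
    assert exceedance_fraction([1, 2, 3, 0], [0, 0, 0, 1]) == 0.75


def test_exceedance_empty_raises():
    with pytest.raises(ValueError):
        exceedance_fraction([], [])
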