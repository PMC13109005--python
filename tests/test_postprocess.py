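import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multistudyfa import (choose_num_factors_evd, op_align, pfa_mode_k,
                          reorder_factors, sd_loadings, varimax_criterion,
                          varimax_rotate)


def _signed_permutations(k):
    """All orthogonal matrices that are signed permutations of size k."""
    for perm in itertools.permutations(range(k)):
        for signs in itertools.product([-1.0, 1.0], repeat=k):
            G = np.zeros((k, k))
            for i, j in enumerate(perm):
                G[i, j] = signs[i]
            yield G


@pytest.mark.parametrize("k", [1, 2, 3])
def test_op_align_beats_exhaustive_signed_permutations(k):
    """OP alignment optimizes over all orthogonal matrices, so the aligned
    residual of each draw can never exceed the best achievable with the
    (finite) subgroup of signed permutations."""
    rng = np.random.default_rng(40 + k)
    ref = rng.normal(size=(5, k))
    for _ in range(5):
        G_true = rng.normal(size=(k, k))
        Q, _ = np.linalg.qr(G_true)
        draw = ref @ Q + 0.01 * rng.normal(size=(5, k))
        aligned = op_align(draw[None], reference=ref)
        best_sp = min(np.linalg.norm(draw @ G - ref)
                      for G in _signed_permutations(k))
        assert np.linalg.norm(aligned - ref) <= best_sp + 1e-10


def test_op_align_recovers_reference_under_rotations():
    rng = np.random.default_rng(44)
    ref = rng.normal(size=(6, 3))
    draws = []
    for _ in range(30):
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        draws.append(ref @ Q)
    assert np.allclose(op_align(np.stack(draws), reference=ref), ref,
                       atol=1e-8)


def test_op_align_rejects_mismatched_shapes():
    with pytest.raises(ValueError, match="reference"):
        op_align(np.zeros((2, 4, 2)), reference=np.zeros((4, 3)))


def test_sd_loadings_exact_for_rank_k_covariance():
    """If cov = L L' with orthogonal-column L, SD loadings reproduce cov
    exactly and span the same column space."""
    rng = np.random.default_rng(45)
    A = rng.normal(size=(7, 3))
    U, _ = np.linalg.qr(A)
    L = U * np.array([3.0, 2.0, 1.0])
    cov = L @ L.T
    Lhat = sd_loadings(cov, 3)
    assert np.allclose(Lhat @ Lhat.T, cov, atol=1e-10)


def test_sd_loadings_is_best_rank_k_approximation():
    """Truncating the spectrum is the Frobenius-optimal rank-k
    approximation (Eckart-Young), checked against the direct eigentruncation
    oracle."""
    rng = np.random.default_rng(46)
    A = rng.normal(size=(6, 6))
    cov = A @ A.T
    w, U = np.linalg.eigh(cov)
    oracle = (U[:, -2:] * w[-2:]) @ U[:, -2:].T
    Lhat = sd_loadings(cov, 2)
    assert np.allclose(Lhat @ Lhat.T, oracle, atol=1e-10)
    with pytest.raises(ValueError):
        sd_loadings(cov, 7)


def test_varimax_never_decreases_criterion_and_is_orthogonal():
    rng = np.random.default_rng(47)
    L = rng.normal(size=(8, 3))
    R = varimax_rotate(L)
    assert varimax_criterion(R) >= varimax_criterion(L) - 1e-10
    # rotation: same configuration L L'
    assert np.allclose(R @ R.T, L @ L.T, atol=1e-8)


def test_varimax_single_column_unchanged():
    L = np.arange(5.0)[:, None]
    assert np.array_equal(varimax_rotate(L), L)


def test_evd_rule_matches_direct_spectrum_oracle():
    """The selection must equal a brute-force count on the eigenvalues."""
    rng = np.random.default_rng(48)
    for _ in range(20):
        A = rng.normal(size=(6, 4))
        cov = A @ A.T + 0.1 * np.eye(6)
        k = choose_num_factors_evd(cov, threshold=0.05)
        w = np.linalg.eigvalsh(cov)
        oracle = sum(1 for v in w if v / w.sum() >= 0.05)
        assert k == oracle


def test_evd_rule_known_spectrum():
    # eigenvalues 10, 5, 0.5, 0.5: shares 0.625, 0.3125, 0.03125 x2
    cov = np.diag([10.0, 5.0, 0.5, 0.5])
    assert choose_num_factors_evd(cov, 0.05) == 2
    assert choose_num_factors_evd(cov, 0.03) == 4
    with pytest.raises(ValueError):
        choose_num_factors_evd(cov, 0.0)
    with pytest.raises(ValueError):
        choose_num_factors_evd(-np.eye(3))


def test_mode_k_ties_resolve_upward():
    assert pfa_mode_k(np.array([3, 3, 4, 4, 2])) == 4
    assert pfa_mode_k(np.array([5, 5, 5, 2])) == 5
    with pytest.raises(ValueError):
        pfa_mode_k(np.array([]))


def test_reorder_factors_by_explained_variance():
    L = np.array([[1.0, 3.0], [0.0, 4.0]])
    out, perm = reorder_factors(L)
    assert list(perm) == [1, 0]
    assert np.array_equal(out, L[:, [1, 0]])
    with pytest.raises(ValueError):
        reorder_factors(L, criterion="bogus")


def test_reorder_factors_by_nonzero_count():
    L = np.array([[1.0, 3.0, 0.0], [0.0, 4.0, 2.0], [0.0, 1.0, 0.0]])
    out, perm = reorder_factors(L, criterion="nonzero_count")
    # counts are (1, 3, 1); ties keep original order (stable sort)
    assert list(perm) == [1, 0, 2]


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2 ** 30))
def test_evd_count_invariant_to_rotation(seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(5, 3))
    cov = A @ A.T + 0.05 * np.eye(5)
    Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
    assert (choose_num_factors_evd(cov)
            == choose_num_factors_evd(Q @ cov @ Q.T))
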