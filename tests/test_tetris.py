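import numpy as np
import pytest
from scipy import stats

from multistudyfa import (MultiStudyDataset, Tetris, center_by_study,
                          choose_T, classify_factors, refit_fixed_T,
                          rv_coefficient)
from multistudyfa.tetris import _study_marglik


def test_classify_factors_worked_example():
    T = np.array([[1, 0, 1, 0],
                  [1, 1, 0, 1],
                  [1, 1, 0, 0]])
    info = classify_factors(T)
    assert info["common"] == [0]
    assert info["partial"] == [1]
    assert info["specific"] == [2, 3]
    assert info["empty"] == []
    assert info["studies"][1] == (1, 2)
    with pytest.raises(ValueError):
        classify_factors(np.array([[0, 2]]))


def test_choose_t_prefers_locally_dense_draw_and_breaks_ties_earliest():
    a = np.array([[1, 0], [1, 1]])
    b = np.array([[1, 1], [1, 1]])
    # three identical draws of a, one lone b: a's neighborhood wins
    from multistudyfa.priors import left_order
    picked = choose_T([b, a, a.copy(), a.copy()], radius=0)
    assert np.array_equal(picked, left_order(a))
    # exact tie between two singleton draws: the earliest wins
    c = np.array([[1, 0], [0, 1]])
    d = np.array([[0, 1], [1, 0]])  # same left-ordered form as c
    assert np.array_equal(choose_T([c, d], radius=0), choose_T([c], radius=0))
    with pytest.raises(ValueError):
        choose_T([])


def test_study_marglik_matches_multivariate_normal_oracle():
    rng = np.random.default_rng(90)
    n, P, k = 6, 4, 2
    Y = rng.normal(size=(n, P))
    W = rng.normal(size=(P, k))
    psi = rng.uniform(0.5, 2.0, size=P)
    cov = W @ W.T + np.diag(psi)
    oracle = stats.multivariate_normal.logpdf(Y, mean=np.zeros(P),
                                              cov=cov).sum()
    assert _study_marglik(Y, W, psi) == pytest.approx(oracle, abs=1e-10)
    # zero-factor special case: diagonal Gaussian
    oracle0 = stats.multivariate_normal.logpdf(
        Y, mean=np.zeros(P), cov=np.diag(psi)).sum()
    assert _study_marglik(Y, np.zeros((P, 0)), psi) == pytest.approx(
        oracle0, abs=1e-10)


def test_fit_discovers_common_and_specific_structure():
    """Two studies, one strong common factor and one strong factor specific
    to study 0: the selected sharing matrix must contain a common column and
    a study-0-only column, and the common covariance must match the truth.

    The number of common *columns* is not asserted exactly: a single factor
    may split into parallel low-mass duplicates (the likelihood cannot
    distinguish c c' from c1 c1' + c2 c2' with c1, c2 parallel), so the
    identified quantities are the covariance and the study-membership
    pattern, not the column count."""
    rng = np.random.default_rng(91)
    P, n = 12, 200
    phi_c = rng.choice([-1.0, 1.0], size=P) * rng.uniform(0.8, 1.2, size=P)
    phi_s = np.zeros(P)
    phi_s[:6] = rng.choice([-1.0, 1.0], size=6) * rng.uniform(0.8, 1.2, 6)
    y1 = (rng.standard_normal((n, 1)) @ phi_c[None, :]
          + rng.standard_normal((n, 1)) @ phi_s[None, :]
          + 0.4 * rng.standard_normal((n, P)))
    y2 = (rng.standard_normal((n, 1)) @ phi_c[None, :]
          + 0.4 * rng.standard_normal((n, P)))
    data = center_by_study(MultiStudyDataset([y1, y2]))
    res = Tetris(data, kmax=4).fit(n_iter=500, n_burnin=350, seed=3)
    info = classify_factors(res.sharing_matrix)
    assert len(info["common"]) >= 1
    assert len(info["specific"]) == 1
    assert info["studies"][info["specific"][0]] == (0,)
    assert rv_coefficient(res.decomposition.common_cov,
                          np.outer(phi_c, phi_c)) >= 0.95
    assert res.decomposition.extras["sharing_matrix"].shape[0] == 2


def test_refit_with_known_sharing_matrix():
    rng = np.random.default_rng(92)
    P, n = 8, 100
    phi = rng.normal(size=(P, 1))
    ys = [rng.standard_normal((n, 1)) @ phi.T
          + 0.4 * rng.standard_normal((n, P)) for _ in range(2)]
    data = center_by_study(MultiStudyDataset(ys))
    T = np.ones((2, 1), dtype=int)
    res = refit_fixed_T(data, T, cfg=None)
    assert np.array_equal(res.sharing_matrix, T)
    assert res.decomposition.common_loadings.shape == (P, 1)
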