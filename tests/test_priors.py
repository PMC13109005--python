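import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from multistudyfa import (DlState, IbpSpec, MgpsState, NlpSpec,
                          dl_gibbs_update, ibp_sample, mgps_gibbs_update,
                          mgps_prior_variance, nlp_densities,
                          sufa_residual_lognormal_hyperparams)
from multistudyfa.priors import left_order


# ---------------------------------------------------------------------------
# MGPS
# ---------------------------------------------------------------------------

def test_mgps_prior_variance_matches_construction():
    rng = np.random.default_rng(0)
    st_ = MgpsState.initialize(4, 3, rng)
    v = mgps_prior_variance(st_)
    theta = np.cumprod(st_.deltas)
    expect = 1.0 / (st_.local_precisions * theta[None, :])
    assert np.allclose(v, expect)


def test_mgps_conditional_moments_at_zero_loadings():
    """At phi = 0 the omega conditional is Gam((kappa+1)/2, kappa/2):
    for kappa = 3 that is Gam(2, rate 3/2) with mean 4/3 and
    variance 8/9 (independent of the current global precisions)."""
    rng = np.random.default_rng(1)
    P, K = 5, 2
    state = MgpsState.initialize(P, K, rng)
    draws = np.stack([
        mgps_gibbs_update(state, np.zeros((P, K)), rng).local_precisions
        for _ in range(4000)])
    assert abs(draws.mean() - 4.0 / 3.0) < 0.02
    assert abs(draws.var() - 8.0 / 9.0) < 0.05


def test_mgps_delta_conditional_shape_at_zero_loadings():
    """At phi = 0 the delta_h conditional is Gam(a_h + P(K-h)/2, 1) where
    a_1 = 2.1 and a_h = 3.1: the posterior mean equals the shape."""
    rng = np.random.default_rng(2)
    P, K = 4, 3
    state = MgpsState.initialize(P, K, rng)
    d = np.stack([mgps_gibbs_update(state, np.zeros((P, K)), rng).deltas
                  for _ in range(4000)])
    expect = np.array([2.1 + P * K / 2.0,
                       3.1 + P * (K - 1) / 2.0,
                       3.1 + P * (K - 2) / 2.0])
    assert np.allclose(d.mean(axis=0), expect, rtol=0.03)


def test_mgps_update_rejects_nonfinite_loadings():
    rng = np.random.default_rng(3)
    state = MgpsState.initialize(3, 2, rng)
    bad = np.zeros((3, 2))
    bad[0, 0] = np.inf
    with pytest.raises(ValueError):
        mgps_gibbs_update(state, bad, rng)


def test_mgps_drop_columns_preserves_hyperparameters():
    rng = np.random.default_rng(4)
    state = MgpsState.initialize(4, 3, rng)
    kept = state.drop_columns(np.array([True, False, True]))
    assert kept.local_precisions.shape == (4, 2)
    assert np.allclose(kept.deltas, state.deltas[[0, 2]])
    assert kept.kappa == state.kappa


# ---------------------------------------------------------------------------
# Dirichlet-Laplace
# ---------------------------------------------------------------------------

def test_dl_weights_stay_on_simplex_and_scale_positive():
    rng = np.random.default_rng(5)
    state = DlState.initialize(6, 3, rng)
    for _ in range(20):
        phi = rng.normal(size=(6, 3))
        state = dl_gibbs_update(state, phi, rng)
        assert state.dirichlet_weights.min() > 0
        assert abs(state.dirichlet_weights.sum() - 1.0) < 1e-12
        assert state.global_scale > 0
        assert (state.conditional_variances() > 0).all()


def test_dl_shrinks_small_rows_harder():
    """A row of near-zero loadings should end with a much smaller Laplace
    scale (weight) than a row of large loadings."""
    rng = np.random.default_rng(6)
    P, K = 4, 3
    phi = np.full((P, K), 3.0)
    phi[0] = 1e-3
    state = DlState.initialize(P, K, rng)
    w = np.zeros(P)
    for _ in range(300):
        state = dl_gibbs_update(state, phi, rng)
        w += state.dirichlet_weights
    assert w[0] < 0.2 * w[1:].mean()


# ---------------------------------------------------------------------------
# Non-local spike-and-slab
# ---------------------------------------------------------------------------

def test_nlp_slab_vanishes_at_origin_and_integrates_to_one():
    spec = NlpSpec()
    spike0, slab0 = nlp_densities(0.0, spec)
    assert slab0 == 0.0
    assert spike0 == pytest.approx(stats.norm.pdf(0, scale=np.sqrt(0.026)))
    total, _ = integrate.quad(lambda x: nlp_densities(x, spec)[1],
                              -np.inf, np.inf)
    assert total == pytest.approx(1.0, abs=1e-8)


def test_nlp_requires_spike_smaller_than_slab():
    with pytest.raises(ValueError):
        NlpSpec(tau0=0.5, tau1=0.3)


# ---------------------------------------------------------------------------
# IBP
# ---------------------------------------------------------------------------

def test_ibp_expected_number_of_columns():
    """Two-parameter IBP: E[#columns] = alpha * sum_s beta / (beta + s - 1)."""
    spec = IbpSpec(alpha=2.0, beta=1.5)
    S = 5
    rng = np.random.default_rng(7)
    expect = spec.alpha * sum(spec.beta / (spec.beta + s)
                              for s in range(S))
    counts = [ibp_sample(spec, S, rng).shape[1] for _ in range(4000)]
    se = np.std(counts) / np.sqrt(len(counts))
    assert abs(np.mean(counts) - expect) < 5 * se + 0.05


def test_ibp_sample_columns_are_nonempty_and_left_ordered():
    rng = np.random.default_rng(8)
    for _ in range(50):
        T = ibp_sample(IbpSpec.default(4), 4, rng)
        if T.shape[1]:
            assert (T.sum(axis=0) >= 1).all()
            assert np.array_equal(T, left_order(T))


def test_ibp_default_scales_alpha_with_studies():
    assert IbpSpec.default(4).alpha == 5.0
    with pytest.raises(ValueError):
        IbpSpec(alpha=0.0)


def test_left_order_idempotent_and_sorted():
    T = np.array([[0, 1, 1], [1, 0, 1], [0, 0, 1]])
    lo = left_order(T)
    keys = (lo * (2.0 ** np.arange(2, -1, -1))[:, None]).sum(axis=0)
    assert (np.diff(keys) <= 0).all()
    assert np.array_equal(left_order(lo), lo)


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2 ** 30))
def test_left_order_invariant_to_column_permutation(seed):
    rng = np.random.default_rng(seed)
    T = rng.integers(0, 2, size=(4, 6))
    perm = rng.permutation(6)
    assert np.array_equal(left_order(T), left_order(T[:, perm]))


# ---------------------------------------------------------------------------
# Residual-variance hyperprior
# ---------------------------------------------------------------------------

def test_lognormal_hyperparams_reproduce_target_moments():
    mu, s2 = sufa_residual_lognormal_hyperparams(mean=1.0, variance=7.0)
    mean = np.exp(mu + s2 / 2.0)
    var = (np.exp(s2) - 1.0) * mean ** 2
    assert mean == pytest.approx(1.0, abs=1e-12)
    assert var == pytest.approx(7.0, abs=1e-9)
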