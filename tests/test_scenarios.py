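import numpy as np
import pytest

from multistudyfa import (ScenarioTruth, generate_scenario, rv_coefficient,
                          sparse_signed_loadings)


def test_sparse_loadings_exact_zero_count_and_range():
    rng = np.random.default_rng(20)
    L = sparse_signed_loadings(10, 4, 0.4, 0.6, 1.0, rng)
    assert (L == 0).sum() == round(0.4 * 40)
    nz = np.abs(L[L != 0])
    assert nz.min() >= 0.6 and nz.max() <= 1.0
    assert (L < 0).any() and (L > 0).any()
    Lu = sparse_signed_loadings(10, 4, 0.25, 0.6, 1.0, rng, signed=False)
    assert (Lu >= 0).all()
    with pytest.raises(ValueError):
        sparse_signed_loadings(5, 2, 1.0, 0.6, 1.0, rng)
    with pytest.raises(ValueError):
        sparse_signed_loadings(5, 2, 0.4, 1.0, 0.6, rng)


def test_generation_is_seed_reproducible():
    d1, t1 = generate_scenario(3, seed=7)
    d2, t2 = generate_scenario(3, seed=7)
    for a, b in zip(d1.studies, d2.studies):
        assert np.array_equal(a, b)
    assert np.array_equal(t1.phi, t2.phi)
    with pytest.raises(ValueError):
        generate_scenario(7, seed=0)


@pytest.mark.parametrize("scenario", [1, 2, 3, 4])
def test_truth_decomposition_is_internally_consistent(scenario):
    """The recorded per-study marginal covariance must equal the sum of the
    recorded common part, specific part, and residual variances."""
    data, t = generate_scenario(scenario, seed=1)
    S = data.n_studies
    assert len(t.js_true) == S
    for s in range(S):
        psi = t.psi[s] if isinstance(t.psi, list) else t.psi
        if scenario == 1:
            # perturbed model: marginal = Q (Sigma_phi) Q', and the recorded
            # specific covariance is the marginal minus the common part
            if s == 0:
                assert np.allclose(t.sigma_marginal[0], t.sigma_phi)
                assert np.allclose(t.sigma_lambda[0], t.sigma_phi)
            else:
                assert np.allclose(t.sigma_phi + t.sigma_lambda[s],
                                   t.sigma_marginal[s], atol=1e-10)
        elif scenario == 2:
            assert np.allclose(t.sigma_phi + np.diag(psi),
                               t.sigma_marginal[s], atol=1e-10)
        elif scenario == 3:
            # sigma_phi already includes the residual diagonal here
            assert np.allclose(t.sigma_phi + t.sigma_lambda[s],
                               t.sigma_marginal[s], atol=1e-10)
            assert np.allclose(t.lambdas[s],
                               t.phi @ t.extras["A"][s], atol=1e-12)
        else:
            assert np.allclose(
                t.sigma_phi + t.sigma_lambda[s] + np.diag(psi),
                t.sigma_marginal[s], atol=1e-10)
        if t.lambdas is not None and scenario != 1:
            assert np.allclose(t.lambdas[s] @ t.lambdas[s].T,
                               t.sigma_lambda[s], atol=1e-10)


@pytest.mark.parametrize("scenario", [5, 6])
def test_sharing_matrix_scenarios_partition_factors(scenario):
    overrides = {} if scenario == 5 else dict(P=80, n_obs=[60] * 4)
    data, t = generate_scenario(scenario, seed=2, **overrides)
    T = t.extras["T"]
    common = T.all(axis=0)
    assert common.sum() == t.k_true
    # every partial/specific column is active in at least one study but not
    # all, and the per-study specific counts match the mask
    assert ((T.sum(axis=0) >= 1) & (T.sum(axis=0) <= T.shape[0])).all()
    for s in range(data.n_studies):
        assert t.js_true[s] == int((T[s].astype(bool) & ~common).sum())
    assert t.phi.shape[1] == t.k_true


def test_nutrition_scenario_prints_expected_sizes():
    data, t = generate_scenario(5, seed=3)
    assert data.n_studies == 12
    assert data.n_variables == 42
    assert data.covariates is not None
    assert data.covariates[0].shape[1] == 12
    assert t.k_true == 4


def test_expression_scenario_is_high_dimensional_and_sparse():
    data, t = generate_scenario(6, seed=4, n_obs=[30] * 4)
    assert data.n_variables == 1060
    assert t.k_true == 15
    phi_star = t.extras["phi_star"]
    assert (phi_star == 0).mean() == pytest.approx(0.8, abs=0.01)


@pytest.mark.parametrize("scenario", [1, 2, 3, 4])
def test_sample_covariance_converges_to_truth(scenario):
    """Law of large numbers: at inflated sample sizes the per-study sample
    covariance of centered data approaches the recorded marginal covariance
    (RV >= 0.98), validating that the generators draw from the distributions
    their truth objects describe."""
    n = 20_000
    data, t = generate_scenario(scenario, seed=5, n_obs=[n], S=1)
    Y = data.studies[0]
    if scenario == 2:
        X = data.covariates[0]
        Y = Y - t.extras["alpha"][:, 0][None, :] - X @ t.extras["beta"].T
    Y = Y - Y.mean(axis=0)
    C = Y.T @ Y / (n - 1)
    assert rv_coefficient(C, t.sigma_marginal[0]) >= 0.98


def test_overrides_are_recorded():
    _, t = generate_scenario(1, seed=6, P=10, K=2)
    assert t.extras["overrides"] == {"P": 10, "K": 2}
    assert t.extras["scenario"] == 1
    assert isinstance(t, ScenarioTruth)
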