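"""Synthetic multi-study data generators with ground truth.

Six generative scenarios cover the spectrum of multi-study latent structure:

1. a pooled factor model observed through small per-study perturbation
   matrices (near-identity linear distortions of each study);
2. a covariate- and batch-adjusted common-factor model (study intercepts,
   observed covariates, study-specific residual variances);
3. shared loadings plus weak study-specific subspace loadings Phi A_s;
4. shared + strong, dense study-specific loadings (more specific factors
   than shared ones, larger per-study samples);
5. a combinatorial sharing structure mimicking a multi-site nutrition
   cohort: 12 studies, common + partially shared + study-specific factors,
   observed covariates;
6. a high-dimensional (P=1060) combinatorial structure mimicking multi-study
   gene-expression data, with very sparse loadings.

Each generator returns the dataset together with a :class:`ScenarioTruth`
holding the generating loadings and the covariance decomposition used as
the evaluation reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import MultiStudyDataset

__all__ = ["ScenarioTruth", "sparse_signed_loadings", "generate_scenario"]


@dataclass
class ScenarioTruth:
    """Generating parameters of a simulated scenario (evaluation reference)."""

    k_true: int
    js_true: list[int]
    phi: np.ndarray | None                 # (P, K) common loadings
    lambdas: list[np.ndarray] | None       # S x (P, J_s) study loadings
    sigma_phi: np.ndarray                  # common covariance
    sigma_lambda: list[np.ndarray] | None  # study-specific covariances
    sigma_marginal: list[np.ndarray]       # per-study marginal covariances
    psi: np.ndarray | list[np.ndarray]     # residual variances
    extras: dict = field(default_factory=dict)


def sparse_signed_loadings(P: int, K: int, zero_frac: float,
                           lo: float, hi: float, rng: np.random.Generator,
                           signed: bool = True) -> np.ndarray:
    """Sparse loading matrix: exactly ``round(zero_frac*P*K)`` zeros placed
    uniformly at random; non-zeros uniform on [lo, hi], optionally given
    independent random signs."""
    if not 0.0 <= zero_frac < 1.0:
        raise ValueError("zero_frac must be in [0, 1)")
    if not lo < hi:
        raise ValueError("need lo < hi")
    n = P * K
    n_zero = int(round(zero_frac * n))
    vals = rng.uniform(lo, hi, size=n)
    if signed:
        vals *= rng.choice([-1.0, 1.0], size=n)
    zero_pos = rng.choice(n, size=n_zero, replace=False)
    vals[zero_pos] = 0.0
    return vals.reshape(P, K)


def _psi_uniform(P: int, rng: np.random.Generator) -> np.ndarray:
    # residual variances U(0,1), floored away from exact zero
    return np.maximum(rng.uniform(0.0, 1.0, size=P), 1e-3)


def _gaussian_data(n: int, phi_blocks: list[np.ndarray], psi: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw n rows of sum_b Phi_b f_b + eps with standard-normal factors."""
    P = psi.shape[0]
    y = rng.standard_normal((n, P)) * np.sqrt(psi)[None, :]
    for L in phi_blocks:
        f = rng.standard_normal((n, L.shape[1]))
        y += f @ L.T
    return y


# ---------------------------------------------------------------------------
# Individual scenarios
# ---------------------------------------------------------------------------

def _scenario1(rng, S=4, n_obs=None, P=40, K=4, alpha_q=0.01):
    n_obs = n_obs or [100] * S
    phi = sparse_signed_loadings(P, K, 0.4, 0.6, 1.0, rng)
    psi = _psi_uniform(P, rng)
    sigma_phi = phi @ phi.T + np.diag(psi)
    Qs = [np.eye(P)]
    for _ in range(1, S):
        Qs.append(np.eye(P) + alpha_q * rng.standard_normal((P, P)))
    studies, lambdas, sig_lam, sig_marg = [], [], [], []
    for s in range(S):
        Y = _gaussian_data(n_obs[s], [phi], psi, rng)
        studies.append(Y @ Qs[s].T)
        sig_s = Qs[s] @ sigma_phi @ Qs[s].T
        sig_marg.append((sig_s + sig_s.T) / 2.0)
        if s == 0:
            # reference-study convention: its signal IS the common signal
            lambdas.append(phi.copy())
            sig_lam.append(sigma_phi.copy())
        else:
            Qinv = np.linalg.inv(Qs[s])
            lambdas.append((Qinv - np.eye(P)) @ phi)
            sig_lam.append(sig_marg[-1] - sigma_phi)
    truth = ScenarioTruth(K, [K] * S, phi, lambdas, sigma_phi, sig_lam,
                          sig_marg, psi, extras={"Q": Qs, "alpha_q": alpha_q})
    return MultiStudyDataset(studies), truth


def _scenario2(rng, S=4, n_obs=None, P=40, K=4, Q=2, beta_scale=0.1):
    n_obs = n_obs or [100] * S
    phi = sparse_signed_loadings(P, K, 0.4, 0.6, 1.0, rng)
    alphas = rng.standard_normal((P, S))
    beta = rng.normal(0.0, beta_scale, size=(P, Q))
    psis = [_psi_uniform(P, rng) for _ in range(S)]
    sigma_phi = phi @ phi.T
    studies, covs, sig_marg = [], [], []
    for s in range(S):
        X = rng.standard_normal((n_obs[s], Q))
        Y = _gaussian_data(n_obs[s], [phi], psis[s], rng)
        Y += alphas[:, s][None, :] + X @ beta.T
        studies.append(Y)
        covs.append(X)
        sig_marg.append(sigma_phi + np.diag(psis[s]))
    truth = ScenarioTruth(K, [0] * S, phi, None, sigma_phi, None, sig_marg,
                          psis, extras={"alpha": alphas, "beta": beta})
    return MultiStudyDataset(studies, covariates=covs), truth


def _scenario3(rng, S=4, n_obs=None, P=40, K=4, J=1, a_sd=0.4):
    n_obs = n_obs or [100] * S
    phi = sparse_signed_loadings(P, K, 0.4, 0.6, 1.0, rng)
    psi = _psi_uniform(P, rng)
    As = [rng.normal(0.0, a_sd, size=(K, J)) for _ in range(S)]
    sigma_phi = phi @ phi.T + np.diag(psi)
    studies, lambdas, sig_lam, sig_marg = [], [], [], []
    for s in range(S):
        lam = phi @ As[s]
        Y = _gaussian_data(n_obs[s], [phi, lam], psi, rng)
        studies.append(Y)
        lambdas.append(lam)
        sl = lam @ lam.T
        sig_lam.append((sl + sl.T) / 2.0)
        sig_marg.append(sigma_phi + sig_lam[-1])
    truth = ScenarioTruth(K, [J] * S, phi, lambdas, sigma_phi, sig_lam,
                          sig_marg, psi, extras={"A": As})
    return MultiStudyDataset(studies), truth


def _scenario4(rng, S=4, n_obs=None, P=50, K=2, J=5):
    n_obs = n_obs or [200] * S
    phi = sparse_signed_loadings(P, K, 0.25, 0.6, 1.0, rng, signed=False)
    psis = [_psi_uniform(P, rng) for _ in range(S)]
    sigma_phi = phi @ phi.T
    studies, lambdas, sig_lam, sig_marg = [], [], [], []
    for s in range(S):
        lam = sparse_signed_loadings(P, J, 0.25, 0.6, 1.0, rng, signed=False)
        Y = _gaussian_data(n_obs[s], [phi, lam], psis[s], rng)
        studies.append(Y)
        lambdas.append(lam)
        sig_lam.append(lam @ lam.T)
        sig_marg.append(sigma_phi + sig_lam[-1] + np.diag(psis[s]))
    truth = ScenarioTruth(K, [J] * S, phi, lambdas, sigma_phi, sig_lam,
                          sig_marg, psis)
    return MultiStudyDataset(studies), truth


def _make_sharing_matrix(S: int, n_common: int, n_specific_per_study: int,
                         n_partial: int, rng: np.random.Generator
                         ) -> np.ndarray:
    """Binary study-by-factor activation matrix with the requested counts.

    Partial columns activate a uniformly random strict subset of >= 2
    studies.
    """
    cols = [np.ones(S, dtype=int) for _ in range(n_common)]
    for s in range(S):
        for _ in range(n_specific_per_study):
            c = np.zeros(S, dtype=int)
            c[s] = 1
            cols.append(c)
    for _ in range(n_partial):
        size = int(rng.integers(2, S))  # strict subset, at least 2 studies
        members = rng.choice(S, size=size, replace=False)
        c = np.zeros(S, dtype=int)
        c[members] = 1
        cols.append(c)
    return np.column_stack(cols)


def _scenario_tetris(rng, S, n_obs, P, n_common, n_specific, n_partial,
                     zero_frac, Q=0, beta_scale=0.5):
    T = _make_sharing_matrix(S, n_common, n_specific, n_partial, rng)
    K_star = T.shape[1]
    phi_star = sparse_signed_loadings(P, K_star, zero_frac, 0.6, 1.0, rng)
    psis = [_psi_uniform(P, rng) for _ in range(S)]
    beta = rng.normal(0.0, beta_scale, size=(P, Q)) if Q else None
    common_mask = T.all(axis=0)
    phi = phi_star[:, common_mask]
    sigma_phi = phi @ phi.T
    studies, covs, lambdas, sig_lam, sig_marg = [], [], [], [], []
    for s in range(S):
        active = T[s].astype(bool)
        spec_mask = active & ~common_mask
        W = phi_star[:, active]
        Y = _gaussian_data(n_obs[s], [W], psis[s], rng)
        if Q:
            X = rng.standard_normal((n_obs[s], Q))
            Y += X @ beta.T
            covs.append(X)
        studies.append(Y)
        lam = phi_star[:, spec_mask]
        lambdas.append(lam)
        sig_lam.append(lam @ lam.T)
        sig_marg.append(W @ W.T + np.diag(psis[s]))
    truth = ScenarioTruth(n_common, [int((T[s] & ~common_mask).sum())
                                     for s in range(S)],
                          phi, lambdas, sigma_phi, sig_lam, sig_marg, psis,
                          extras={"T": T, "phi_star": phi_star, "beta": beta})
    data = MultiStudyDataset(studies, covariates=covs if Q else None)
    return data, truth


_NUTRITION_NS = [1362, 217, 417, 1012, 2241, 205, 2403, 3775, 1790, 761, 373,
                 465]
_EXPRESSION_NS = [157, 195, 285, 117]


def generate_scenario(scenario: int, seed: int, **overrides
                      ) -> tuple[MultiStudyDataset, ScenarioTruth]:
    """Generate one replicate of a simulation scenario.

    Parameters
    ----------
    scenario : int in 1..6
    seed : int
        Seeds all randomness; fixed seed gives byte-identical output.
    **overrides
        Scaled-down dimensions for fast tests, e.g. ``n_obs=[50]*4``,
        ``P=20``.  Overrides are recorded in the truth's extras.

    Returns
    -------
    (MultiStudyDataset, ScenarioTruth)
    """
    rng = np.random.default_rng(seed)
    if scenario == 1:
        data, truth = _scenario1(rng, **overrides)
    elif scenario == 2:
        data, truth = _scenario2(rng, **overrides)
    elif scenario == 3:
        data, truth = _scenario3(rng, **overrides)
    elif scenario == 4:
        data, truth = _scenario4(rng, **overrides)
    elif scenario == 5:
        kw = dict(S=12, n_obs=list(_NUTRITION_NS), P=42, n_common=4,
                  n_specific=1, n_partial=7, zero_frac=0.4, Q=12)
        kw.update(overrides)
        data, truth = _scenario_tetris(rng, **kw)
    elif scenario == 6:
        kw = dict(S=4, n_obs=list(_EXPRESSION_NS), P=1060, n_common=15,
                  n_specific=2, n_partial=3, zero_frac=0.8, Q=0)
        kw.update(overrides)
        data, truth = _scenario_tetris(rng, **kw)
    else:
        raise ValueError(f"unknown scenario {scenario!r} (expected 1..6)")
    truth.extras["scenario"] = scenario
    truth.extras["seed"] = seed
    if overrides:
        truth.extras["overrides"] = dict(overrides)
    return data, truth
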