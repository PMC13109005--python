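"""PFA: perturbed factor analysis.

Model: each study measures a common factor model through a study-specific
linear perturbation, ``Q_s y_is = Phi f_i + eps``, with ``Q_1 = I`` fixed
for identifiability and ``Q_s`` (s >= 2) shrunk toward the identity by a
matrix-normal prior whose entry variance ``alpha`` is learned (or fixed).
Because the model specifies the law of the transformed vector ``Q_s y``,
the likelihood of the observed ``y`` carries a ``|det Q_s|^{n_s}`` Jacobian
factor; the perturbation rows are updated by Metropolis-within-Gibbs with
the Gaussian regression conditional as the proposal and the determinant
ratio as the acceptance correction (a plain regression update without the
Jacobian drives ``Q_s`` to zero).
Factors have diagonal prior covariance ``V = diag(nu_k)``; the residual
covariance is shared across studies.

The number of factors adapts during sampling: the chain starts at the
requested ``k`` (at least 3) and, beginning 20% of the way through the run,
prunes loading columns whose largest absolute entry falls below a cutoff.
Pruning is one-way, so the active-factor trace ``k_trace`` is
non-increasing; the reported decomposition restricts the posterior sample
to draws at the modal active count (ties resolved upward).

Priors: MGPS on Phi; ``nu_k ~ IG(10, 0.1)``; ``psi_p ~ IG(0.1, 0.1)``;
``alpha ~ IG(0.1, 0.1)`` when sampled.  Study 1's loadings equal Phi by the
``Q_1 = I`` convention.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .base import (FactorDecomposition, FactorModel, FactorResults,
                   PosteriorDraws)
from .data import MultiStudyDataset
from .gibbs import GibbsConfig, _sample_loading_rows
from .postprocess import op_align, pfa_mode_k
from .priors import MgpsState, mgps_gibbs_update

__all__ = ["PFA", "PfaResults", "fit_pfa", "pfa_extract_decomposition"]

_A_NU, _B_NU = 10.0, 0.1
_A_PSI, _B_PSI = 0.1, 0.1
_A_ALPHA, _B_ALPHA = 0.1, 0.1
_PRUNE_CUTOFF = 1e-3


def _sample_scores_v(Z: np.ndarray, phi: np.ndarray, nu: np.ndarray,
                     psi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Scores with prior N(0, diag(nu)): A = diag(1/nu) + Phi' Psi^-1 Phi."""
    d = phi.shape[1]
    Lp = phi / psi[:, None]
    A = np.diag(1.0 / nu) + phi.T @ Lp
    A[np.diag_indices_from(A)] += 1e-10 * max(np.trace(A), 1.0)
    cf = linalg.cho_factor(A, lower=True)
    mean = linalg.cho_solve(cf, (Z @ Lp).T).T
    Lo_inv = linalg.solve_triangular(cf[0], np.eye(d), lower=True)
    return mean + rng.standard_normal((Z.shape[0], d)) @ Lo_inv


def _pfa_step(Ys, YtY, phi, nu, psi, Qs, alpha, mgps, rng,
              sample_alpha: bool):
    """One sweep of the perturbed-factor sampler: projected scores ->
    loadings -> MGPS -> factor variances -> residual variances ->
    perturbation rows (s >= 2, Metropolis with the Jacobian correction) ->
    perturbation scale.

    Returns (phi, nu, psi, Qs, alpha, mgps)."""
    S = len(Ys)
    P = phi.shape[0]
    K = phi.shape[1]
    N_tot = sum(Y.shape[0] for Y in Ys)
    eye = np.eye(P)

    Zs = [Ys[s] @ Qs[s].T for s in range(S)]
    Fs = [_sample_scores_v(Zs[s], phi, nu, psi, rng) for s in range(S)]
    F_all = np.vstack(Fs)
    Z_all = np.vstack(Zs)

    prior_prec = mgps.local_precisions * mgps.global_precisions[None, :]
    phi = _sample_loading_rows(F_all, Z_all, psi, prior_prec, rng)
    mgps = mgps_gibbs_update(mgps, phi, rng)

    # factor variances and shared residual variances
    nu = (_B_NU + 0.5 * (F_all ** 2).sum(axis=0)) / rng.gamma(
        _A_NU + N_tot / 2.0, 1.0, size=K)
    resid = Z_all - F_all @ phi.T
    psi = (_B_PSI + 0.5 * (resid ** 2).sum(axis=0)) / rng.gamma(
        _A_PSI + N_tot / 2.0, 1.0, size=P)

    # perturbations (rows of Q_s, s >= 2).  The observation density carries
    # a |det Q_s|^{n_s} Jacobian (the model specifies the law of Q_s y, so
    # the law of y is the pushforward); the Gaussian regression conditional
    # alone ignores it and provably collapses Q toward 0 (zero residuals at
    # no likelihood cost).  det Q_s is linear in each row, so the row
    # conditional factorizes into an exactly Gaussian part orthogonal to
    # the cofactor direction and a scalar t = a' q with density
    # |t|^n N(t; m, s^2); t is updated by independence Metropolis from the
    # Gaussian (Laplace) approximation at its mode.
    Qs = list(Qs)
    for s in range(1, S):
        n_s = Ys[s].shape[0]
        M = Fs[s] @ phi.T  # (N_s, P): target of each projected row
        Q = Qs[s].copy()
        for p in range(P):
            prec = eye / alpha + YtY[s] / psi[p]
            prec[np.diag_indices_from(prec)] += 1e-10 * max(
                np.trace(prec), 1.0)
            cf = linalg.cho_factor(prec, lower=True)
            rhs = eye[p] / alpha + Ys[s].T @ M[:, p] / psi[p]
            mu = linalg.cho_solve(cf, rhs)
            # cofactor vector of row p: a_j = C_pj = det(Q) inv(Q)_{jp}
            # (independent of the current row p itself)
            sign_det, ld = np.linalg.slogdet(Q)
            a = sign_det * np.exp(ld) * np.linalg.inv(Q)[:, p]
            La = linalg.cho_solve(cf, a)       # prec^{-1} a
            s2 = float(a @ La)
            m_t = float(a @ mu)
            t_cur = float(a @ Q[p])
            # mode of |t|^n exp(-(t-m)^2 / (2 s^2)) on the branch of t_cur
            br = 1.0 if (t_cur >= 0 or m_t > 0) else -1.0
            t_star = 0.5 * (m_t + br * np.sqrt(m_t ** 2 + 4.0 * n_s * s2))
            sig2 = 1.0 / (n_s / t_star ** 2 + 1.0 / s2)
            t_prop = t_star + np.sqrt(sig2) * rng.standard_normal()

            def logpi(t):
                return n_s * np.log(abs(t)) - (t - m_t) ** 2 / (2.0 * s2)

            def logq(t):
                return -(t - t_star) ** 2 / (2.0 * sig2)

            log_acc = (logpi(t_prop) - logpi(t_cur)
                       + logq(t_cur) - logq(t_prop))
            if t_prop != 0.0 and np.log(rng.random()) < log_acc:
                # exact draw of the Gaussian complement given t = t_prop
                Lo_inv = linalg.solve_triangular(cf[0], np.eye(P),
                                                 lower=True)
                q0 = mu + rng.standard_normal(P) @ Lo_inv
                Q[p] = q0 + La * (t_prop - float(a @ q0)) / s2
        Qs[s] = Q
    if sample_alpha and S > 1:
        dev = sum(((Qs[s] - eye) ** 2).sum() for s in range(1, S))
        alpha = (_B_ALPHA + dev / 2.0) / rng.gamma(
            _A_ALPHA + (S - 1) * P * P / 2.0, 1.0)
    return phi, nu, psi, Qs, alpha, mgps


class PfaResults(FactorResults):
    """Posterior summaries of the perturbed-factor fit.

    ``k_trace`` (on ``draws``) is the non-increasing active-factor count;
    the decomposition is built from modal-K draws only and stores the
    posterior-mean perturbations in ``extras['Q']``.
    """

    @property
    def k_trace(self) -> np.ndarray:
        return self.draws.k_trace


class PFA(FactorModel):
    """Perturbed factor analysis with adaptive factor truncation.

    Parameters
    ----------
    data : MultiStudyDataset
        Centered per study.
    k : int
        Initial (upper-bound) number of factors; must be at least 3 so the
        perturbations are identified.
    """

    def __init__(self, data: MultiStudyDataset, k: int):
        super().__init__(data)
        if k < 3:
            raise ValueError("the perturbed factor model requires k >= 3")
        if k > data.n_variables:
            raise ValueError("k exceeds the number of variables")
        self.k = k

    def fit(self, n_iter: int = 10_000, n_burnin: int = 8_000, thin: int = 1,
            seed: int = 0, sample_alpha: bool = True,
            alpha: float = 1.0) -> PfaResults:
        cfg = GibbsConfig(n_iter, n_burnin, thin, seed)
        rng = np.random.default_rng(cfg.seed)
        data = self.data
        S, P = data.n_studies, data.n_variables
        Ys = data.studies
        YtY = [Ys[s].T @ Ys[s] for s in range(S)]

        K = self.k
        mgps = MgpsState.initialize(P, K, rng)
        phi = rng.standard_normal((P, K)) * 0.1
        nu = np.full(K, 1.0)
        psi = np.full(P, 1.0)
        Qs = [np.eye(P) for _ in range(S)]
        start_prune = int(0.2 * cfg.n_iter)

        kept: list[dict] = []
        k_trace = np.empty(cfg.n_iter, dtype=int)
        for it in range(cfg.n_iter):
            phi, nu, psi, Qs, alpha, mgps = _pfa_step(
                Ys, YtY, phi, nu, psi, Qs, alpha, mgps, rng, sample_alpha)
            K = phi.shape[1]

            # adaptive truncation (one-way, starts after 20% of the run)
            if it >= start_prune and K > 1:
                keep = np.abs(phi).max(axis=0) >= _PRUNE_CUTOFF
                if not keep.all() and keep.sum() >= 1:
                    phi = phi[:, keep]
                    nu = nu[keep]
                    mgps = mgps.drop_columns(keep)
                    K = int(keep.sum())
            k_trace[it] = K

            if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
                kept.append({"phi": phi.copy(), "nu": nu.copy(),
                             "psi": psi.copy(),
                             "Q": [q.copy() for q in Qs],
                             "alpha": float(alpha), "k": K})
        draws = PosteriorDraws(kept, cfg.n_iter, cfg.n_burnin, cfg.seed,
                               "PFA", k_trace=k_trace)
        decomp = pfa_extract_decomposition(draws)
        return PfaResults(self, decomp, draws)


def pfa_extract_decomposition(draws: PosteriorDraws) -> FactorDecomposition:
    """Summarize a perturbed-factor chain at its modal active-factor count.

    Only draws whose active count equals the post-burn-in mode (ties to the
    larger count) enter the posterior means; study 1's loadings are Phi and
    study s's marginal covariance is ``Q_s^{-1} (Sigma_Phi + Psi) Q_s^{-T}``.
    """
    k_post = np.array([d["k"] for d in draws.draws])
    k_hat = pfa_mode_k(k_post)
    sel = [d for d in draws.draws if d["k"] == k_hat]
    S = len(sel[0]["Q"])
    phis = np.stack([d["phi"] * np.sqrt(d["nu"])[None, :] for d in sel])
    phi_hat = op_align(phis)
    common_cov = np.einsum("npk,nqk->pq", phis, phis) / len(phis)
    common_cov = (common_cov + common_cov.T) / 2.0
    psi_hat = np.stack([d["psi"] for d in sel]).mean(axis=0)
    Q_hat = [np.stack([d["Q"][s] for d in sel]).mean(axis=0)
             for s in range(S)]
    inner = common_cov + np.diag(psi_hat)
    marginals = []
    for s in range(S):
        Qi = np.linalg.inv(Q_hat[s])
        m = Qi @ inner @ Qi.T
        marginals.append((m + m.T) / 2.0)
    return FactorDecomposition(
        method_tag="PFA", common_loadings=phi_hat,
        residual_variances=psi_hat, common_cov=common_cov,
        marginal_covs=marginals,
        extras={"Q": Q_hat, "k_modal": int(k_hat),
                "alpha": float(np.mean([d["alpha"] for d in sel])),
                "n_modal_draws": len(sel)})


def fit_pfa(data: MultiStudyDataset, k: int, cfg: GibbsConfig | None = None,
            **fit_kwargs) -> PfaResults:
    cfg = cfg or GibbsConfig()
    return PFA(data, k).fit(cfg.n_iter, cfg.n_burnin, cfg.thin, cfg.seed,
                            **fit_kwargs)
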