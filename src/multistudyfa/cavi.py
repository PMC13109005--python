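"""Coordinate-ascent variational inference (CAVI) for the shared +
study-specific factor model.

Mean-field approximation of the same model fitted by :class:`~multistudyfa.
gibbs.BMSFA`: y = Phi f + Lambda_s l + eps with MGPS shrinkage on both
loading matrices and inverse-gamma residual variances.  The variational
family factorizes over

* rows of Phi and of each Lambda_s (full-covariance Gaussians),
* the joint (shared, specific) score vector per observation (one shared
  covariance per study -- the Gaussian conditional covariance does not
  depend on the observation),
* residual variances (inverse-gamma),
* MGPS local precisions (gamma) and global multipliers (gamma).

Every update is the exact coordinate maximizer, so the evidence lower bound
(ELBO) is non-decreasing over sweeps; the fit raises if it ever drops beyond
floating-point tolerance, which would indicate a broken update.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import digamma, gammaln

from .base import FactorDecomposition, FactorModel, FactorResults
from .data import MultiStudyDataset

__all__ = ["CAVI", "CaviResults", "fit_cavi"]

_A_PSI, _B_PSI = 1.0, 0.3
_KAPPA, _A1, _A2 = 3.0, 2.1, 3.1


class _MgpsBlock:
    """Variational MGPS block for one loading matrix (P x K).

    q(omega_pk) = Gamma(a_w, b_w[p, k]) with a_w = (kappa+1)/2 fixed;
    q(delta_h) = Gamma(a_d[h], b_d[h]) with a_d fixed by conjugacy.
    """

    def __init__(self, P: int, K: int):
        self.P, self.K = P, K
        self.a_w = (_KAPPA + 1.0) / 2.0
        self.b_w = np.full((P, K), _KAPPA / 2.0 + 0.5)
        h = np.arange(K)
        self.a_d = np.where(h == 0, _A1, _A2) + P * (K - h) / 2.0
        self.b_d = self.a_d.copy()  # E[delta] = 1 at start

    @property
    def e_omega(self) -> np.ndarray:
        return self.a_w / self.b_w

    @property
    def e_delta(self) -> np.ndarray:
        return self.a_d / self.b_d

    @property
    def e_theta(self) -> np.ndarray:
        return np.cumprod(self.e_delta)

    @property
    def e_log_theta(self) -> np.ndarray:
        return np.cumsum(digamma(self.a_d) - np.log(self.b_d))

    def prior_precisions(self) -> np.ndarray:
        """E[omega_pk] E[theta_k]: the Gaussian prior precision of each
        loading entry under the variational MGPS marginals."""
        return self.e_omega * self.e_theta[None, :]

    def update(self, e_sq: np.ndarray) -> None:
        """Exact coordinate updates given E[phi_pk^2] = ``e_sq``."""
        self.b_w = (_KAPPA + self.e_theta[None, :] * e_sq) / 2.0
        c = (self.e_omega * e_sq).sum(axis=0)  # per-column shrinkage mass
        ed = self.e_delta
        for h in range(self.K):
            theta_wo_h = np.cumprod(ed)[h:] / ed[h]
            self.b_d[h] = 1.0 + 0.5 * float(theta_wo_h @ c[h:])
            ed = self.a_d / self.b_d
        self.b_d = np.maximum(self.b_d, 1e-12)

    def elbo_terms(self, e_sq: np.ndarray) -> float:
        """E[log p(phi | omega, delta)] + E[log p(omega)] + E[log p(delta)]
        + entropies of q(omega), q(delta).  The Gaussian entropy of the
        loading rows is accounted for by the caller."""
        e_log_w = digamma(self.a_w) - np.log(self.b_w)
        e_w = self.e_omega
        e_th, e_log_th = self.e_theta, self.e_log_theta
        # loadings prior
        val = 0.5 * float(e_log_w.sum() + self.P * e_log_th.sum())
        val -= 0.5 * float((e_w * e_th[None, :] * e_sq).sum())
        val -= 0.5 * self.P * self.K * np.log(2.0 * np.pi)
        # omega prior + entropy
        k2 = _KAPPA / 2.0
        val += float((k2 * np.log(k2) - gammaln(k2)
                      + (k2 - 1.0) * e_log_w - k2 * e_w).sum())
        val += float((self.a_w - np.log(self.b_w) + gammaln(self.a_w)
                      + (1.0 - self.a_w) * digamma(self.a_w)).sum())
        # delta prior + entropy
        a_pr = np.where(np.arange(self.K) == 0, _A1, _A2)
        e_log_d = digamma(self.a_d) - np.log(self.b_d)
        val += float(((a_pr - 1.0) * e_log_d - self.e_delta
                      - gammaln(a_pr)).sum())
        val += float((self.a_d - np.log(self.b_d) + gammaln(self.a_d)
                      + (1.0 - self.a_d) * digamma(self.a_d)).sum())
        return val


def _logdet(M: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(M)
    if sign <= 0:
        raise np.linalg.LinAlgError("non-PD variational covariance")
    return float(ld)


class CaviResults(FactorResults):
    """Variational fit: point estimates are variational means; ``elbo_trace``
    records the per-sweep ELBO (non-decreasing)."""

    def __init__(self, model, decomposition, elbo_trace, n_sweeps, converged):
        super().__init__(model, decomposition, None)
        self.elbo_trace = np.asarray(elbo_trace)
        self.n_sweeps = n_sweeps
        self.converged = converged

    @property
    def elbo(self) -> float:
        return float(self.elbo_trace[-1])


class CAVI(FactorModel):
    """Variational shared + study-specific factor model.

    Parameters
    ----------
    data : MultiStudyDataset
        Centered per study.
    k : int
        Shared factors.
    js : int or list of int
        Study-specific factors; the mean-field score factorization needs at
        least 2 per study (J_s = 1 is floored to 2 with a warning).
    """

    def __init__(self, data: MultiStudyDataset, k: int, js: int | list[int]):
        super().__init__(data)
        P = data.n_variables
        if not 1 <= k <= P:
            raise ValueError("k must be in [1, P]")
        js_list = [js] * data.n_studies if np.isscalar(js) else list(js)
        if any(j < 2 for j in js_list):
            warnings.warn("variational approximation requires at least 2 "
                          "study-specific factors per study; flooring J_s to 2",
                          UserWarning, stacklevel=2)
            js_list = [max(2, j) for j in js_list]
        if any(j > P for j in js_list):
            raise ValueError("each J_s must be <= P")
        self.k = k
        self.js = js_list

    def fit(self, max_sweeps: int = 500, tol: float = 1e-7,
            seed: int = 0) -> CaviResults:
        data, K, js = self.data, self.k, self.js
        S, P = data.n_studies, data.n_variables
        Ys = data.studies
        Ns = data.n_obs
        rng = np.random.default_rng(seed)

        # --- initialization: pooled SVD for Phi, per-study residual SVD for
        # Lambda, plus small seeded jitter to break exact symmetry
        Yall = data.stacked()
        U0, sv0, Vt0 = np.linalg.svd(Yall, full_matrices=False)
        kk = min(K, len(sv0))
        m_phi = np.zeros((P, K))
        m_phi[:, :kk] = Vt0[:kk].T * (sv0[:kk] / np.sqrt(Yall.shape[0]))
        m_phi += 0.01 * rng.standard_normal((P, K))
        S_phi = np.tile(0.01 * np.eye(K), (P, 1, 1))
        m_lam, S_lam = [], []
        for s in range(S):
            R = Ys[s] - (Ys[s] @ m_phi) @ np.linalg.pinv(m_phi.T @ m_phi + np.eye(K)) @ m_phi.T
            Ur, svr, Vtr = np.linalg.svd(R, full_matrices=False)
            jj = min(js[s], len(svr))
            ml = np.zeros((P, js[s]))
            ml[:, :jj] = Vtr[:jj].T * (svr[:jj] / np.sqrt(Ns[s]))
            ml += 0.01 * rng.standard_normal((P, js[s]))
            m_lam.append(ml)
            S_lam.append(np.tile(0.01 * np.eye(js[s]), (P, 1, 1)))
        a_psi = [_A_PSI + Ns[s] / 2.0 for s in range(S)]
        b_psi = [np.full(P, _B_PSI + Ns[s] / 2.0) for s in range(S)]
        blk_phi = _MgpsBlock(P, K)
        blk_lam = [_MgpsBlock(P, js[s]) for s in range(S)]

        yty = [np.einsum("np,np->p", Ys[s], Ys[s]) for s in range(S)]
        M_sc = [np.zeros((Ns[s], K + js[s])) for s in range(S)]
        V_sc = [np.eye(K + js[s]) for s in range(S)]

        elbo_trace: list[float] = []
        converged = False
        for sweep in range(max_sweeps):
            e_psi_inv = [a_psi[s] / b_psi[s] for s in range(S)]

            # -- scores
            for s in range(S):
                c = e_psi_inv[s]
                W = np.hstack([m_phi, m_lam[s]])
                d = K + js[s]
                A = np.eye(d) + (W * c[:, None]).T @ W
                A[:K, :K] += np.einsum("p,pij->ij", c, S_phi)
                A[K:, K:] += np.einsum("p,pij->ij", c, S_lam[s])
                V = np.linalg.inv((A + A.T) / 2.0)
                V = (V + V.T) / 2.0
                V_sc[s] = V
                M_sc[s] = (Ys[s] * c[None, :]) @ W @ V

            # per-study score Gram blocks
            Gff, Gfl, Gll = [], [], []
            for s in range(S):
                G = M_sc[s].T @ M_sc[s] + Ns[s] * V_sc[s]
                Gff.append(G[:K, :K])
                Gfl.append(G[:K, K:])
                Gll.append(G[K:, K:])

            # -- Phi rows
            pp = blk_phi.prior_precisions()
            b_mat = np.zeros((P, K))
            for s in range(S):
                b_mat += e_psi_inv[s][:, None] * (
                    Ys[s].T @ M_sc[s][:, :K] - (Gfl[s] @ m_lam[s].T).T)
            for p in range(P):
                A = np.diag(pp[p]).astype(float)
                for s in range(S):
                    A += e_psi_inv[s][p] * Gff[s]
                Sp = np.linalg.inv((A + A.T) / 2.0)
                S_phi[p] = (Sp + Sp.T) / 2.0
                m_phi[p] = Sp @ b_mat[p]
            e_sq_phi = m_phi ** 2 + np.einsum("pkk->pk", S_phi)
            blk_phi.update(e_sq_phi)

            # -- Lambda rows, psi
            e_sq_lam = []
            for s in range(S):
                pp_s = blk_lam[s].prior_precisions()
                b_s = e_psi_inv[s][:, None] * (
                    Ys[s].T @ M_sc[s][:, K:] - m_phi @ Gfl[s])
                for p in range(P):
                    A = np.diag(pp_s[p]) + e_psi_inv[s][p] * Gll[s]
                    Sp = np.linalg.inv((A + A.T) / 2.0)
                    S_lam[s][p] = (Sp + Sp.T) / 2.0
                    m_lam[s][p] = Sp @ b_s[p]
                e_sq = m_lam[s] ** 2 + np.einsum("pkk->pk", S_lam[s])
                e_sq_lam.append(e_sq)
                blk_lam[s].update(e_sq)

                # residual variances: quad_ps = E sum_i (y - w'm)^2
                W = np.hstack([m_phi, m_lam[s]])
                MtY = M_sc[s].T @ Ys[s]  # (d, P)
                quad = yty[s] - 2.0 * np.einsum("pd,dp->p", W, MtY)
                # tr(E[w w'] G): mean part + covariance part
                quad += (np.einsum("pk,kl,pl->p", m_phi, Gff[s], m_phi)
                         + 2.0 * np.einsum("pk,kj,pj->p", m_phi, Gfl[s], m_lam[s])
                         + np.einsum("pj,jl,pl->p", m_lam[s], Gll[s], m_lam[s])
                         + np.einsum("pij,ij->p", S_phi, Gff[s])
                         + np.einsum("pij,ij->p", S_lam[s], Gll[s]))
                quad = np.maximum(quad, 0.0)
                b_psi[s] = _B_PSI + quad / 2.0

            # -- ELBO
            elbo = 0.0
            for s in range(S):
                e_li = a_psi[s] / b_psi[s]
                e_log_psi = np.log(b_psi[s]) - digamma(a_psi[s])
                quad = 2.0 * (b_psi[s] - _B_PSI)
                elbo += float((-0.5 * Ns[s] * np.log(2 * np.pi)
                               - 0.5 * Ns[s] * e_log_psi
                               - 0.5 * e_li * quad).sum())
                # scores KL
                d = K + js[s]
                elbo -= 0.5 * (Ns[s] * (np.trace(V_sc[s]) - d
                                        - _logdet(V_sc[s]))
                               + float((M_sc[s] ** 2).sum()))
                # psi prior + entropy
                elbo += float((_A_PSI * np.log(_B_PSI) - gammaln(_A_PSI)
                               - (_A_PSI + 1.0) * e_log_psi
                               - _B_PSI * e_li).sum())
                elbo += float((a_psi[s] + np.log(b_psi[s]) + gammaln(a_psi[s])
                               - (1.0 + a_psi[s]) * digamma(a_psi[s])).sum())
                # Lambda block priors + Gaussian entropies
                elbo += blk_lam[s].elbo_terms(e_sq_lam[s])
                for p in range(P):
                    elbo += 0.5 * (_logdet(S_lam[s][p])
                                   + js[s] * (1.0 + np.log(2 * np.pi)))
            elbo += blk_phi.elbo_terms(e_sq_phi)
            for p in range(P):
                elbo += 0.5 * (_logdet(S_phi[p]) + K * (1.0 + np.log(2 * np.pi)))

            if elbo_trace:
                prev = elbo_trace[-1]
                slack = 1e-6 * (1.0 + abs(prev))
                if elbo < prev - slack:
                    raise RuntimeError(
                        f"ELBO decreased at sweep {sweep}: {prev:.6f} -> "
                        f"{elbo:.6f}")
                if abs(elbo - prev) <= tol * (1.0 + abs(prev)):
                    elbo_trace.append(elbo)
                    converged = True
                    break
            elbo_trace.append(elbo)

        # --- point estimates (variational means) and implied covariances
        common_cov = m_phi @ m_phi.T + np.diag(
            np.einsum("pkk->pk", S_phi).sum(axis=1))
        common_cov = (common_cov + common_cov.T) / 2.0
        study_covs, marginals, psis = [], [], []
        for s in range(S):
            sc = m_lam[s] @ m_lam[s].T + np.diag(
                np.einsum("pkk->pk", S_lam[s]).sum(axis=1))
            sc = (sc + sc.T) / 2.0
            psi = b_psi[s] / (a_psi[s] - 1.0)
            study_covs.append(sc)
            psis.append(psi)
            marginals.append(common_cov + sc + np.diag(psi))
        decomp = FactorDecomposition(
            method_tag="CAVI", common_loadings=m_phi.copy(),
            study_loadings=[m.copy() for m in m_lam],
            residual_variances=psis, common_cov=common_cov,
            study_covs=study_covs, marginal_covs=marginals,
            extras={"elbo": elbo_trace[-1]})
        return CaviResults(self, decomp, elbo_trace, len(elbo_trace), converged)


def fit_cavi(data: MultiStudyDataset, k: int, js, max_sweeps: int = 500,
             tol: float = 1e-7, seed: int = 0) -> CaviResults:
    return CAVI(data, k, js).fit(max_sweeps=max_sweeps, tol=tol, seed=seed)
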