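"""BLAST: spectral-training estimation of the shared + study-specific
factor model.

The model is the shared/specific decomposition ``Y_s = F_s Phi' + L_s
Lambda_s' + E_s`` with Normal-Inverse-Gamma priors on loading rows.  Instead
of MCMC, estimation proceeds in spectral stages followed by surrogate
Gaussian regressions:

1. *Screening.*  A direction is a shared-factor candidate only if it lies
   inside **every** study's signal subspace (the eigenvectors of the study
   covariance above a noise-calibrated threshold) and carries above-noise
   energy in every study.  Membership is tested at the subspace level:
   with ``P_s`` the projector onto study s's estimated signal subspace,
   the averaged projector ``M = mean_s P_s`` (restricted to the span of
   the leading pooled eigenvectors) has eigenvalues near 1 on the shared
   subspace, at most the study coverage (e.g. (S-1)/S for a factor active
   in S-1 studies) on partially shared or study-specific structure, and
   near 0 on noise.  Candidates are the eigenvectors of ``M`` with
   eigenvalue above the midpoint ``1 - 1/(2S)``; working in the
   eigenbasis of ``M`` (rather than testing pooled eigenvectors one by
   one) unmixes shared components from partial ones with nearby pooled
   eigenvalues.  This rejects mixtures of study-specific or partially
   shared components whose *union* covers all studies: such a mixture has
   energy everywhere but sits well outside the signal subspace of any
   study missing one of its ingredients.

2. *Specific subspaces and sweep.*  Per-study residuals off the screened
   shared scores are screened against the study's own noise scale; the
   retained directions estimate the specific score subspaces.  Each study's
   full specific contribution (loadings re-estimated against the raw data,
   so components inside the screened span are swept too) is regressed out.

3. *Confirmation.*  The final shared dimension K counts the screened
   directions whose per-study energy survives on the swept data.  This
   removes directions whose apparent sharedness came entirely from
   study-specific structure with loadings *correlated across studies*
   (e.g. nonnegative loadings drawn from a common law): they pass the
   energy screen and can sit largely inside every signal subspace, but
   their energy vanishes once each study's own specific component is swept.

4. *Loadings.*  Phi and Lambda_s are posterior means of ridge (NIG)
   regressions on the estimated scores; prior scales tau^2 and the residual
   hyperparameters are set by moment-based empirical Bayes from OLS-stage
   estimates.

The noise scale of a matrix is the median positive eigenvalue of its sample
covariance; "signal" means energy above ``edge * noise`` (default edge 5).
"""

from __future__ import annotations

import numpy as np

from .base import FactorDecomposition, FactorModel, FactorResults
from .data import MultiStudyDataset

__all__ = ["BLAST", "BlastResults", "fit_blast"]

_EDGE = 5.0  # signal-to-noise multiplier of the screening rule


def _median_positive_eig(Y: np.ndarray) -> float:
    """Median positive eigenvalue of Y'Y/N, via the Gram matrix when P > N."""
    n, P = Y.shape
    if P <= n:
        w = np.linalg.eigvalsh(Y.T @ Y / n)
    else:
        w = np.linalg.eigvalsh(Y @ Y.T / n)
    w = w[w > 1e-12]
    return float(np.median(w)) if w.size else 1e-12


def _ridge_loadings(F: np.ndarray, Y: np.ndarray, tau2: float) -> np.ndarray:
    """Posterior-mean loadings of the surrogate regression Y = F L' + E
    under the NIG prior (rows of L have prior variance tau2 * psi)."""
    d = F.shape[1]
    A = F.T @ F + np.eye(d) / tau2
    return np.linalg.solve(A, F.T @ Y).T  # (P, d)


def _eb_tau2(F: np.ndarray, Y: np.ndarray) -> float:
    """Moment-based empirical-Bayes prior scale from the OLS stage."""
    L = np.linalg.lstsq(F, Y, rcond=None)[0].T
    resid = Y - F @ L.T
    psi0 = max(float((resid ** 2).mean()), 1e-10)
    return max(float((L ** 2).mean() / psi0), 1e-6)


class BlastResults(FactorResults):
    """Point estimates from the spectral-training fit.

    ``estimated_k`` / ``estimated_js`` are the data-driven dimensions; the
    empirical-Bayes prior scales are in ``decomposition.extras``.
    """

    @property
    def estimated_k(self) -> int:
        return self.decomposition.n_common_factors

    @property
    def estimated_js(self) -> list[int]:
        return self.decomposition.study_factor_counts


class BLAST(FactorModel):
    """Spectral-training estimator with automatic rank selection.

    Parameters
    ----------
    data : MultiStudyDataset
        Centered per study.
    kmax : int
        Total factor budget; the estimated shared rank K and each study's
        J_s satisfy ``K <= kmax`` and ``K + J_s <= kmax``.
    """

    def __init__(self, data: MultiStudyDataset, kmax: int,
                 edge: float = _EDGE):
        super().__init__(data)
        if kmax < 1:
            raise ValueError("kmax must be >= 1")
        if kmax > min(sum(data.n_obs), data.n_variables):
            raise ValueError(f"kmax={kmax} exceeds min(N, P)")
        self.kmax = kmax
        self.edge = edge
        # midpoint between full membership (eigenvalue 1 of the averaged
        # signal-subspace projector) and the best a partially shared
        # component can achieve ((S-1)/S coverage)
        self.membership = 1.0 - 1.0 / (2.0 * data.n_studies)

    # ------------------------------------------------------------------
    def _specific_scores(self, R: np.ndarray, noise: float,
                         j_cap: int) -> np.ndarray:
        """Unit-variance specific scores from the top residual directions
        whose eigenvalues clear the noise threshold (at least 1 retained)."""
        n = R.shape[0]
        Ur, svr, _ = np.linalg.svd(R, full_matrices=False)
        evals = svr ** 2 / n
        J = int((evals[:j_cap] >= self.edge * noise).sum())
        J = max(J, 1)
        return Ur[:, :J] * np.sqrt(n)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0) -> BlastResults:
        data = self.data
        Ys = data.studies
        S, P = data.n_studies, data.n_variables
        Ns = data.n_obs
        Y = data.stacked()
        n = Y.shape[0]
        offsets = np.cumsum([0] + Ns)

        # per-study noise scales and estimated signal subspaces
        noise = [_median_positive_eig(Ys[s]) for s in range(S)]
        Vsig = []
        for s in range(S):
            _, svs, Vts = np.linalg.svd(Ys[s], full_matrices=False)
            evals = svs ** 2 / Ns[s]
            r = max(int((evals >= self.edge * noise[s]).sum()), 1)
            Vsig.append(Vts[:r].T)  # (P, r_s)

        # --- stage 1: screen for sharedness (membership + energy)
        _, sv, Vt = np.linalg.svd(Y, full_matrices=False)
        m = min(self.kmax, Vt.shape[0])
        B = Vt[:m].T  # (P, m) leading pooled directions
        # averaged signal-subspace projector restricted to span(B)
        M = np.zeros((m, m))
        for s in range(S):
            G = Vsig[s].T @ B  # (r_s, m)
            M += G.T @ G
        M /= S
        w, W = np.linalg.eigh(M)
        order = np.argsort(w)[::-1]
        w, W = w[order], W[:, order]
        cand = []
        for i in range(m):
            if w[i] < self.membership:
                break
            u = B @ W[:, i]
            if all(float(u @ (Ys[s].T @ (Ys[s] @ u))) / Ns[s]
                   >= self.edge * noise[s] for s in range(S)):
                cand.append(u)
        if not cand:
            cand = [Vt[0]]
        K0 = len(cand)
        D0 = np.column_stack(cand)  # (P, K0) candidate shared directions
        F0 = Y @ D0
        F0 *= np.sqrt(n) / np.linalg.norm(F0, axis=0)
        phi0 = _ridge_loadings(F0, Y, _eb_tau2(F0, Y))

        # --- stage 2: specific subspaces off the screened span, full sweep.
        # The sweep is internal, so it removes ALL above-noise residual
        # structure (the kmax budget applies to the reported model only).
        E = Y.copy()
        for s in range(S):
            sl = slice(offsets[s], offsets[s + 1])
            R = Ys[s] - F0[sl] @ phi0.T
            noise_r = _median_positive_eig(R)
            Ls = self._specific_scores(R, noise_r, self.kmax)
            # regress the RAW study data on the specific scores so that
            # specific components inside the screened span are swept too
            lam_full = _ridge_loadings(Ls, Ys[s], _eb_tau2(Ls, Ys[s]))
            E[sl] = Ys[s] - Ls @ lam_full.T

        # --- stage 3: confirm each screened direction on the swept data
        noise_sw = [_median_positive_eig(E[offsets[s]:offsets[s + 1]])
                    for s in range(S)]
        K = 0
        for i in range(K0):
            u = D0[:, i]
            if all(float(u @ (E[offsets[s]:offsets[s + 1]].T
                              @ (E[offsets[s]:offsets[s + 1]] @ u))) / Ns[s]
                   >= self.edge * noise_sw[s] for s in range(S)):
                K += 1
        K = max(K, 1)

        # --- stage 4: final scores and loadings from the swept data
        Ue, sve, Vte = np.linalg.svd(E, full_matrices=False)
        F = Ue[:, :K] * np.sqrt(n)
        tau_phi2 = _eb_tau2(F, E)
        phi = _ridge_loadings(F, E, tau_phi2)

        lams, psis, tau_lam2s = [], [], []
        for s in range(S):
            sl = slice(offsets[s], offsets[s + 1])
            R = Ys[s] - F[sl] @ phi.T
            noise_r = _median_positive_eig(R)
            Ls = self._specific_scores(R, noise_r, max(self.kmax - K, 1))
            tau_lam2 = _eb_tau2(Ls, R)
            lam = _ridge_loadings(Ls, R, tau_lam2)
            lams.append(lam)
            tau_lam2s.append(tau_lam2)
            Efin = R - Ls @ lam.T
            psis.append(np.maximum((Efin ** 2).mean(axis=0), 1e-10))

        # empirical-Bayes residual hyperparameters (IG moments)
        pall = np.concatenate(psis)
        psi0_hat = float(pall.mean())
        var = float(pall.var())
        nu0_hat = 4.0 if var <= 0 else max(
            2.0 * psi0_hat ** 2 / var + 4.0, 4.0)

        common_cov = phi @ phi.T
        study_covs = [l @ l.T for l in lams]
        marginals = [common_cov + study_covs[s] + np.diag(psis[s])
                     for s in range(S)]
        decomp = FactorDecomposition(
            method_tag="BLAST", common_loadings=phi, study_loadings=lams,
            residual_variances=psis, common_cov=common_cov,
            study_covs=study_covs, marginal_covs=marginals,
            extras={"tau_phi2": tau_phi2, "tau_lambda2": tau_lam2s,
                    "nu0": nu0_hat, "psi0": psi0_hat,
                    "screened_k": K0, "shared_scores": F,
                    "kmax": self.kmax})
        res = BlastResults(self, decomp)
        # identifiability: concatenated [Phi Lambda_s] must be full rank
        for s in range(S):
            M = np.hstack([phi, lams[s]])
            if np.linalg.matrix_rank(M) < M.shape[1]:
                raise np.linalg.LinAlgError(
                    f"[Phi Lambda_{s}] is rank deficient; reduce kmax")
        return res


def fit_blast(data: MultiStudyDataset, kmax: int, seed: int = 0
              ) -> BlastResults:
    return BLAST(data, kmax).fit(seed=seed)
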