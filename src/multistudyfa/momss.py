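"""MOM-SS: batch-adjusted factor analysis with a non-local spike-and-slab
prior, estimated by EM.

Model: ``y_is = alpha_s + B x_is + Phi f_i + eps``, with a study intercept
``alpha_s``, regression on known covariates shared across studies, a single
common loading matrix, and per-study residual variances.  Each loading gets
a two-group prior: a point-mass-like Gaussian spike and a *moment* slab
``(phi^2 / tau1) N(phi; 0, tau1)`` that vanishes at zero, so loadings judged
active are pushed away from the origin.  Column-specific inclusion
probabilities ``zeta_k ~ Beta(a/k, b)`` shrink later columns harder,
providing factor-number selection within a single fit.

Estimation is EM to a posterior mode: latent factors and spike/slab
indicators are the missing data; M-steps are exact coordinate maximizers,
so the marginal log posterior (factors and indicators integrated out) is
non-decreasing -- the fit raises if it ever drops beyond tolerance.  Two
starts are tried (spectral loadings of the pooled covariance, with and
without varimax rotation) and the higher-objective solution is kept.

After convergence, loadings with inclusion probability below 5% are set to
zero, all-zero columns are dropped (giving the estimated K), and columns
are reordered by their number of active loadings.
"""

from __future__ import annotations

import numpy as np

from .base import FactorDecomposition, FactorModel, FactorResults
from .data import MultiStudyDataset
from .postprocess import reorder_factors, sd_loadings, varimax_rotate
from .priors import NlpSpec, nlp_densities

__all__ = ["MOMSS", "MomssResults", "fit_momss"]

_A_PSI, _B_PSI = 0.5, 0.5
_SIGMA_REG2 = 1.0   # prior variance of intercepts / regression coefficients
_GAMMA_CUT = 0.05   # inclusion-probability threshold


class MomssResults(FactorResults):
    """Posterior-mode estimates.

    ``inclusion_probs`` are the final spike/slab responsibilities (on the
    pre-threshold loading matrix); ``objective_trace`` is the non-decreasing
    marginal log posterior; ``estimated_k`` counts the retained columns."""

    def __init__(self, model, decomposition, inclusion_probs,
                 objective_trace, converged):
        super().__init__(model, decomposition, None)
        self.inclusion_probs = inclusion_probs
        self.objective_trace = np.asarray(objective_trace)
        self.converged = converged

    @property
    def estimated_k(self) -> int:
        return self.decomposition.n_common_factors


class MOMSS(FactorModel):
    """Batch-adjusted spike-and-slab factor model (EM).

    Parameters
    ----------
    data : MultiStudyDataset
        Raw (uncentered) data: the model estimates study intercepts itself.
        Covariates, when present on the dataset, enter the shared regression.
    k : int
        Maximum number of factors; the spike-and-slab prior prunes within it.
    """

    def __init__(self, data: MultiStudyDataset, k: int,
                 spec: NlpSpec | None = None):
        super().__init__(data)
        if not 1 <= k <= data.n_variables:
            raise ValueError("k must be in [1, P]")
        self.k = k
        self.spec = spec or NlpSpec()

    # ------------------------------------------------------------------
    def fit(self, max_iter: int = 500, tol: float = 1e-8,
            seed: int = 0) -> MomssResults:
        best = None
        for rotate in (False, True):
            out = self._run_em(max_iter, tol, rotate)
            if best is None or out["objective"][-1] > best["objective"][-1]:
                best = out
        return self._package(best)

    # ------------------------------------------------------------------
    def _run_em(self, max_iter: int, tol: float, rotate: bool) -> dict:
        data, K, spec = self.data, self.k, self.spec
        S, P = data.n_studies, data.n_variables
        Ys = data.studies
        Ns = data.n_obs
        Xs = data.covariates
        Q = data.n_covariates or 0

        # spectral start from the pooled covariance of study-centered data
        means = [Y.mean(axis=0) for Y in Ys]
        Yc = np.vstack([Ys[s] - means[s] for s in range(S)])
        C = Yc.T @ Yc / Yc.shape[0]
        phi = sd_loadings(C, K)
        if rotate:
            phi = varimax_rotate(phi)
        alpha = np.column_stack(means)           # (P, S)
        beta = np.zeros((P, Q)) if Q else None
        psis = [np.full(P, 1.0) for _ in range(S)]
        zeta = np.full(K, 0.5)
        a_z = spec.a_zeta / (np.arange(K) + 1.0)

        trace: list[float] = []
        converged = False
        for it in range(max_iter):
            # offsets and residuals toward the factor part
            Rs = []
            for s in range(S):
                off = alpha[:, s][None, :]
                if Q:
                    off = off + Xs[s] @ beta.T
                Rs.append(Ys[s] - off)

            # E-step: factor moments and inclusion responsibilities
            Ms, Gffs, e_inv = [], [], []
            for s in range(S):
                c = 1.0 / psis[s]
                A = np.eye(K) + (phi * c[:, None]).T @ phi
                V = np.linalg.inv((A + A.T) / 2.0)
                M = (Rs[s] * c[None, :]) @ phi @ V
                Ms.append(M)
                Gffs.append(M.T @ M + Ns[s] * V)
                e_inv.append(c)
            spike, slab = nlp_densities(phi, spec)
            num = zeta[None, :] * slab
            gam = num / np.maximum(num + (1.0 - zeta[None, :]) * spike, 1e-300)

            # M-step: loadings, coordinate-wise exact maximizers
            a_diag = sum(e_inv[s][:, None] * np.diag(Gffs[s])[None, :]
                         for s in range(S))  # (P, K)
            rty = np.zeros((P, K))
            for s in range(S):
                rty += e_inv[s][:, None] * (Rs[s].T @ Ms[s])
            for k in range(K):
                b = rty[:, k].copy()
                for s in range(S):
                    cross = Gffs[s][k] @ phi.T - Gffs[s][k, k] * phi[:, k]
                    b -= e_inv[s] * cross
                g = gam[:, k]
                c_q = a_diag[:, k] + g / spec.tau1 + (1.0 - g) / spec.tau0
                disc = np.sqrt(b ** 2 + 8.0 * g * c_q)
                sign = np.where(b >= 0, 1.0, -1.0)
                phi[:, k] = (b + sign * disc) / (2.0 * c_q)

            # inclusion probabilities (MAP of the beta posteriors, clipped)
            zeta = (gam.sum(axis=0) + a_z - 1.0) / (
                P + a_z + spec.b_zeta - 2.0)
            zeta = np.clip(zeta, 1e-6, 1.0 - 1e-6)

            # intercepts, regression, residual variances
            for s in range(S):
                resid = Ys[s] - Ms[s] @ phi.T
                if Q:
                    resid = resid - Xs[s] @ beta.T
                alpha[:, s] = resid.sum(axis=0) / (Ns[s] + psis[s] / _SIGMA_REG2)
            if Q:
                for p in range(P):
                    Apz = np.eye(Q) / _SIGMA_REG2
                    bpz = np.zeros(Q)
                    for s in range(S):
                        r = (Ys[s][:, p] - alpha[p, s]
                             - Ms[s] @ phi[p])
                        Apz += Xs[s].T @ Xs[s] / psis[s][p]
                        bpz += Xs[s].T @ r / psis[s][p]
                    beta[p] = np.linalg.solve(Apz, bpz)
            for s in range(S):
                off = alpha[:, s][None, :]
                if Q:
                    off = off + Xs[s] @ beta.T
                R = Ys[s] - off
                ss = ((R - Ms[s] @ phi.T) ** 2).sum(axis=0)
                # + phi' (N_s V_s) phi: the factor-uncertainty part of E[SS]
                ss += np.einsum("pk,kl,pl->p", phi,
                                Gffs[s] - Ms[s].T @ Ms[s], phi)
                psis[s] = (ss + 2.0 * _B_PSI) / (Ns[s] + 2.0 * _A_PSI + 2.0)

            obj = self._log_posterior(phi, alpha, beta, psis, zeta, a_z)
            if trace:
                prev = trace[-1]
                if obj < prev - 1e-6 * (1.0 + abs(prev)):
                    raise RuntimeError(
                        f"EM objective decreased at iteration {it}: "
                        f"{prev:.6f} -> {obj:.6f}")
                if abs(obj - prev) <= tol * (1.0 + abs(prev)):
                    trace.append(obj)
                    converged = True
                    break
            trace.append(obj)

        spike, slab = nlp_densities(phi, self.spec)
        num = zeta[None, :] * slab
        gam = num / np.maximum(num + (1.0 - zeta[None, :]) * spike, 1e-300)
        return {"phi": phi, "alpha": alpha, "beta": beta, "psis": psis,
                "zeta": zeta, "gamma": gam, "objective": trace,
                "converged": converged}

    # ------------------------------------------------------------------
    def _log_posterior(self, phi, alpha, beta, psis, zeta, a_z) -> float:
        """Marginal log posterior: factors and spike/slab indicators
        integrated out (Gaussian marginal likelihood + mixture prior)."""
        data, spec = self.data, self.spec
        S, P = data.n_studies, data.n_variables
        Xs = data.covariates
        val = 0.0
        for s in range(S):
            off = alpha[:, s][None, :]
            if beta is not None and Xs is not None:
                off = off + Xs[s] @ beta.T
            R = data.studies[s] - off
            Sig = phi @ phi.T + np.diag(psis[s])
            sign, ld = np.linalg.slogdet(Sig)
            Si = np.linalg.inv(Sig)
            n = R.shape[0]
            val += -0.5 * n * (P * np.log(2 * np.pi) + ld)
            val += -0.5 * float(np.einsum("np,pq,nq->", R, Si, R))
            # residual-variance prior IG(a, b)
            val += float((-(_A_PSI + 1.0) * np.log(psis[s])
                          - _B_PSI / psis[s]).sum())
        # loadings: indicator-marginalized mixture prior
        spike, slab = nlp_densities(phi, spec)
        mix = zeta[None, :] * slab + (1.0 - zeta[None, :]) * spike
        val += float(np.log(np.maximum(mix, 1e-300)).sum())
        # inclusion probabilities: Beta(a/k, b)
        val += float(((a_z - 1.0) * np.log(zeta)
                      + (spec.b_zeta - 1.0) * np.log1p(-zeta)).sum())
        # Gaussian priors on intercepts and regression coefficients
        val += -0.5 * float((alpha ** 2).sum()) / _SIGMA_REG2
        if beta is not None:
            val += -0.5 * float((beta ** 2).sum()) / _SIGMA_REG2
        return val

    # ------------------------------------------------------------------
    def _package(self, out: dict) -> MomssResults:
        data = self.data
        S = data.n_studies
        phi = out["phi"] * (out["gamma"] >= _GAMMA_CUT)
        keep = (phi != 0).any(axis=0)
        if not keep.any():
            keep[0] = True  # retain the strongest column even if all shrunk
        phi = phi[:, keep]
        gam = out["gamma"][:, keep]
        phi, perm = reorder_factors(phi, "nonzero_count")
        gam = gam[:, perm]
        common_cov = phi @ phi.T
        psis = out["psis"]
        marginals = [common_cov + np.diag(psis[s]) for s in range(S)]
        decomp = FactorDecomposition(
            method_tag="MOM-SS", common_loadings=phi,
            residual_variances=psis, common_cov=common_cov,
            marginal_covs=marginals, intercepts=out["alpha"],
            regression=out["beta"],
            extras={"zeta": out["zeta"][keep][perm],
                    "raw_loadings": out["phi"]})
        return MomssResults(self, decomp, gam, out["objective"],
                            out["converged"])


def fit_momss(data: MultiStudyDataset, k: int, max_iter: int = 500,
              tol: float = 1e-8, seed: int = 0) -> MomssResults:
    return MOMSS(data, k).fit(max_iter=max_iter, tol=tol, seed=seed)
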