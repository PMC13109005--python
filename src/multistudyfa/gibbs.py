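"""Gibbs samplers for pooled, per-study, and shared+specific factor models.

Three estimators live here, all under MGPS shrinkage priors on the loadings
and inverse-gamma priors on residual variances:

* :class:`StackFA` -- all studies stacked into one matrix and fitted with a
  single factor model (homogeneous covariance across studies);
* :class:`IndFA` -- a separate factor model per study, pooling nothing;
* :class:`BMSFA` -- shared loadings plus study-specific loadings fitted
  jointly, decomposing each study's covariance into common, study-specific
  and residual parts.

Update order per sweep is: latent factors -> loadings (row-wise conjugate
normal) -> MGPS hyperparameters -> residual variances.  The order is fixed
for reproducibility; shared and study-specific factors are drawn jointly per
observation from their joint Gaussian conditional, which mixes better than
alternating the two blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .base import (FactorDecomposition, FactorModel, FactorResults,
                   PosteriorDraws)
from .data import MultiStudyDataset
from .priors import MgpsState, mgps_gibbs_update, mgps_prior_variance

__all__ = ["GibbsConfig", "StackFA", "IndFA", "BMSFA",
           "fit_stack_fa", "fit_ind_fa", "fit_bmsfa"]

_JITTER = 1e-10
# residual-variance hyperprior psi ~ IG(1, 0.3)
_A_PSI, _B_PSI = 1.0, 0.3


@dataclass
class GibbsConfig:
    """MCMC schedule shared by the Gibbs-based estimators."""

    n_iter: int = 10_000
    n_burnin: int = 8_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


# ---------------------------------------------------------------------------
# Conjugate building blocks
# ---------------------------------------------------------------------------

def _sample_scores(Y: np.ndarray, L: np.ndarray, psi: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw latent scores for all rows of Y at once.

    Scores have prior N(0, I) and likelihood y = L f + eps, eps ~ N(0, Psi);
    the conditional is N(A^{-1} L' Psi^{-1} y, A^{-1}) with
    A = I + L' Psi^{-1} L.
    """
    d = L.shape[1]
    Lp = L / psi[:, None]
    A = np.eye(d) + L.T @ Lp
    A[np.diag_indices_from(A)] += _JITTER * max(np.trace(A), 1.0)
    try:
        cf = linalg.cho_factor(A, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError("singular score-update covariance") from exc
    mean = linalg.cho_solve(cf, (Y @ Lp).T).T
    z = rng.standard_normal((Y.shape[0], d))
    # cov = A^{-1} = Lo^{-T} Lo^{-1}; sample = mean + z @ Lo^{-1}
    Lo_inv = linalg.solve_triangular(cf[0], np.eye(d), lower=True)
    return mean + z @ Lo_inv


def _sample_loading_rows(F: np.ndarray, Y: np.ndarray, psi: np.ndarray,
                         prior_prec: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Row-wise conjugate normal update of a loading matrix.

    Row p has prior N(0, diag(prior_prec[p])^{-1}) and regression likelihood
    Y[:, p] = F @ row + noise(psi_p).
    """
    P = Y.shape[1]
    d = F.shape[1]
    FtF = F.T @ F
    FtY = F.T @ Y  # (d, P)
    out = np.empty((P, d))
    z = rng.standard_normal((P, d))
    for p in range(P):
        prec = FtF / psi[p]
        prec = prec + np.diag(prior_prec[p])
        prec[np.diag_indices_from(prec)] += _JITTER * max(np.trace(prec), 1.0)
        cf = linalg.cho_factor(prec, lower=True)
        mean = linalg.cho_solve(cf, FtY[:, p] / psi[p])
        Lo_inv = linalg.solve_triangular(cf[0], np.eye(d), lower=True)
        out[p] = mean + z[p] @ Lo_inv
    return out


def _sample_psi(resid_sq_sums: np.ndarray, n: int,
                rng: np.random.Generator,
                a: float = _A_PSI, b: float = _B_PSI) -> np.ndarray:
    """Inverse-gamma residual-variance update from summed squared residuals."""
    shape = a + n / 2.0
    rate = b + resid_sq_sums / 2.0
    return rate / rng.gamma(shape, 1.0, size=resid_sq_sums.shape)


# ---------------------------------------------------------------------------
# Stack FA
# ---------------------------------------------------------------------------

class StackFAResults(FactorResults):
    pass


class StackFA(FactorModel):
    """Pooled factor analysis: studies stacked, one Phi and Psi for all.

    Parameters
    ----------
    data : MultiStudyDataset
        Should be centered per study beforehand (see ``center_by_study``).
    k : int
        Number of latent factors (``k <= P``).
    """

    def __init__(self, data: MultiStudyDataset, k: int):
        super().__init__(data)
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > data.studies[0].shape[1]:
            raise ValueError(f"k={k} exceeds number of variables P")
        self.k = k

    def fit(self, n_iter: int = 10_000, n_burnin: int = 8_000, thin: int = 1,
            seed: int = 0) -> StackFAResults:
        cfg = GibbsConfig(n_iter, n_burnin, thin, seed)
        Y = self.data.stacked()
        draws = _run_single_fa(Y, self.k, cfg, method_tag="StackFA")
        decomp = _single_fa_decomposition(draws, self.data.n_studies, "StackFA")
        return StackFAResults(self, decomp, draws)


def _single_fa_step(Y: np.ndarray, phi: np.ndarray, psi: np.ndarray,
                    mgps: MgpsState, rng: np.random.Generator):
    """One Gibbs sweep of the single-matrix factor model:
    scores -> loadings -> MGPS hyperparameters -> residual variances."""
    F = _sample_scores(Y, phi, psi, rng)
    prior_prec = mgps.local_precisions * mgps.global_precisions[None, :]
    phi = _sample_loading_rows(F, Y, psi, prior_prec, rng)
    mgps = mgps_gibbs_update(mgps, phi, rng)
    resid = Y - F @ phi.T
    psi = _sample_psi((resid ** 2).sum(axis=0), Y.shape[0], rng)
    return F, phi, psi, mgps


def _run_single_fa(Y: np.ndarray, K: int, cfg: GibbsConfig,
                   method_tag: str) -> PosteriorDraws:
    rng = np.random.default_rng(cfg.seed)
    N, P = Y.shape
    mgps = MgpsState.initialize(P, K, rng)
    # spectral initialization (top-K principal directions scaled by their
    # standard deviations) so the chain starts near the dominant structure
    w, V = np.linalg.eigh(Y.T @ Y / N)
    w, V = w[::-1][:K], V[:, ::-1][:, :K]
    phi = V * np.sqrt(np.clip(w, 0.0, None))
    psi = np.full(P, 1.0)
    kept: list[dict] = []
    for it in range(cfg.n_iter):
        F, phi, psi, mgps = _single_fa_step(Y, phi, psi, mgps, rng)
        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
            kept.append({"phi": phi.copy(), "psi": psi.copy(),
                         "delta": mgps.deltas.copy()})
    return PosteriorDraws(kept, cfg.n_iter, cfg.n_burnin, cfg.seed, method_tag)


def _single_fa_decomposition(draws: PosteriorDraws, S: int,
                             tag: str) -> FactorDecomposition:
    from .postprocess import op_align

    phis = draws.stack("phi")
    psis = draws.stack("psi")
    phi_hat = op_align(phis)
    common_cov = np.einsum("npk,nqk->pq", phis, phis) / len(phis)
    common_cov = (common_cov + common_cov.T) / 2.0
    psi_hat = psis.mean(axis=0)
    marg = common_cov + np.diag(psi_hat)
    if tag == "StackFA":
        return FactorDecomposition(
            method_tag=tag, common_loadings=phi_hat,
            residual_variances=psi_hat, common_cov=common_cov,
            marginal_covs=[marg.copy() for _ in range(S)])
    # per-study fit: the low-rank part is study-specific
    return FactorDecomposition(
        method_tag=tag, study_loadings=[phi_hat],
        residual_variances=[psi_hat], study_covs=[common_cov],
        marginal_covs=[marg])


def fit_stack_fa(data: MultiStudyDataset, k: int,
                 cfg: GibbsConfig | None = None) -> StackFAResults:
    cfg = cfg or GibbsConfig()
    return StackFA(data, k).fit(cfg.n_iter, cfg.n_burnin, cfg.thin, cfg.seed)


# ---------------------------------------------------------------------------
# Ind FA
# ---------------------------------------------------------------------------

class IndFAResults(FactorResults):
    """Results of independent per-study fits.

    ``study_draws`` holds one chain per study; the decomposition collects
    the per-study loadings/covariances (no common component).
    """

    def __init__(self, model, decomposition, study_draws):
        super().__init__(model, decomposition, None)
        self.study_draws = study_draws


class IndFA(FactorModel):
    """Independent factor analysis: one model per study, no pooling."""

    def __init__(self, data: MultiStudyDataset, js: int | list[int]):
        super().__init__(data)
        S = data.n_studies
        js_list = [js] * S if np.isscalar(js) else list(js)
        P = data.n_variables
        for j in js_list:
            if not 1 <= j <= P:
                raise ValueError(f"each J_s must be in [1, P]; got {j}")
        self.js = js_list

    def fit(self, n_iter: int = 10_000, n_burnin: int = 8_000, thin: int = 1,
            seed: int = 0) -> IndFAResults:
        cfg0 = GibbsConfig(n_iter, n_burnin, thin, seed)
        study_draws = []
        ss = np.random.SeedSequence(seed).spawn(self.data.n_studies)
        for s, Y in enumerate(self.data.studies):
            sub_seed = int(ss[s].generate_state(1)[0] % (2 ** 31))
            cfg = GibbsConfig(n_iter, n_burnin, thin, sub_seed)
            study_draws.append(_run_single_fa(Y, self.js[s], cfg, "IndFA"))
        decomps = [_single_fa_decomposition(d, 1, "IndFA") for d in study_draws]
        decomp = FactorDecomposition(
            method_tag="IndFA",
            study_loadings=[d.study_loadings[0] for d in decomps],
            residual_variances=[d.residual_variances[0] for d in decomps],
            study_covs=[d.study_covs[0] for d in decomps],
            marginal_covs=[d.marginal_covs[0] for d in decomps])
        return IndFAResults(self, decomp, study_draws)


def fit_ind_fa(data: MultiStudyDataset, js, cfg: GibbsConfig | None = None
               ) -> IndFAResults:
    cfg = cfg or GibbsConfig()
    return IndFA(data, js).fit(cfg.n_iter, cfg.n_burnin, cfg.thin, cfg.seed)


# ---------------------------------------------------------------------------
# BMSFA
# ---------------------------------------------------------------------------

class BMSFAResults(FactorResults):
    pass


class BMSFA(FactorModel):
    """Bayesian multi-study FA: shared loadings Phi plus per-study Lambda_s.

    Marginal covariance per study: Sigma_s = Phi Phi' + Lambda_s Lambda_s'
    + Psi_s.  MGPS priors act separately on Phi and on each Lambda_s.
    """

    def __init__(self, data: MultiStudyDataset, k: int, js: int | list[int]):
        super().__init__(data)
        P = data.n_variables
        if not 1 <= k <= P:
            raise ValueError("k must be in [1, P]")
        js_list = [js] * data.n_studies if np.isscalar(js) else list(js)
        for j in js_list:
            if not 1 <= j <= P:
                raise ValueError("each J_s must be in [1, P]")
        self.k = k
        self.js = js_list

    def fit(self, n_iter: int = 10_000, n_burnin: int = 8_000, thin: int = 1,
            seed: int = 0) -> BMSFAResults:
        cfg = GibbsConfig(n_iter, n_burnin, thin, seed)
        rng = np.random.default_rng(cfg.seed)
        data, K, js = self.data, self.k, self.js
        S, P = data.n_studies, data.n_variables
        Ys = data.studies
        Ns = data.n_obs

        mgps_phi = MgpsState.initialize(P, K, rng)
        mgps_lam = [MgpsState.initialize(P, j, rng) for j in js]
        # spectral initialization: start the shared loadings at the top-K
        # eigenvectors of the pooled covariance so shared structure begins
        # in phi rather than having to migrate out of the lambda_s, which
        # traps the chain at short schedules (information-switching
        # non-identifiability of the shared/specific split)
        pooled = sum(Y.T @ Y for Y in Ys) / sum(Ns)
        w, V = np.linalg.eigh(pooled)
        w, V = w[::-1][:K], V[:, ::-1][:, :K]
        phi = V * np.sqrt(np.clip(w, 0.0, None))
        lams = [rng.standard_normal((P, j)) * 0.1 for j in js]
        psis = [np.full(P, 1.0) for _ in range(S)]

        kept: list[dict] = []
        for it in range(cfg.n_iter):
            Fs, Ls, phi, lams, psis, mgps_phi, mgps_lam = _bmsfa_step(
                Ys, Ns, phi, lams, psis, mgps_phi, mgps_lam, rng)
            if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
                kept.append({
                    "phi": phi.copy(),
                    "lambda": [l.copy() for l in lams],
                    "psi": [p.copy() for p in psis],
                })
        draws = PosteriorDraws(kept, cfg.n_iter, cfg.n_burnin, cfg.seed, "BMSFA")
        decomp = bmsfa_decomposition(draws)
        return BMSFAResults(self, decomp, draws)


def _bmsfa_step(Ys, Ns, phi, lams, psis, mgps_phi, mgps_lam, rng):
    """One Gibbs sweep of the shared + study-specific model: joint scores
    per study -> shared loadings (weighted regression across studies) ->
    per-study loadings -> residual variances."""
    S = len(Ys)
    K = phi.shape[1]
    Fs, Ls = [], []
    for s in range(S):
        W = np.hstack([phi, lams[s]])
        M = _sample_scores(Ys[s], W, psis[s], rng)
        Fs.append(M[:, :K])
        Ls.append(M[:, K:])
    # shared loadings given specific components removed; rows of Phi
    # see study-specific residual variances -> weighted regression
    R_all = np.vstack([Ys[s] - Ls[s] @ lams[s].T for s in range(S)])
    F_all = np.vstack(Fs)
    phi = _sample_loading_rows_weighted(
        F_all, R_all, np.vstack([np.tile(psis[s], (Ns[s], 1))
                                 for s in range(S)]),
        mgps_phi.local_precisions * mgps_phi.global_precisions[None, :],
        rng)
    mgps_phi = mgps_gibbs_update(mgps_phi, phi, rng)
    lams, psis = list(lams), list(psis)
    mgps_lam = list(mgps_lam)
    for s in range(S):
        R = Ys[s] - Fs[s] @ phi.T
        prior_prec = (mgps_lam[s].local_precisions *
                      mgps_lam[s].global_precisions[None, :])
        lams[s] = _sample_loading_rows(Ls[s], R, psis[s], prior_prec, rng)
        mgps_lam[s] = mgps_gibbs_update(mgps_lam[s], lams[s], rng)
        resid = R - Ls[s] @ lams[s].T
        psis[s] = _sample_psi((resid ** 2).sum(axis=0), Ns[s], rng)
    return Fs, Ls, phi, lams, psis, mgps_phi, mgps_lam


def _sample_loading_rows_weighted(F, Y, psi_rows, prior_prec, rng):
    """As _sample_loading_rows but with per-(row, variable) residual
    variances (used when rows of Y come from studies with different Psi_s).

    psi_rows has the same shape as Y.
    """
    P = Y.shape[1]
    d = F.shape[1]
    out = np.empty((P, d))
    z = rng.standard_normal((P, d))
    for p in range(P):
        w = 1.0 / psi_rows[:, p]
        Fw = F * w[:, None]
        prec = F.T @ Fw + np.diag(prior_prec[p])
        prec[np.diag_indices_from(prec)] += _JITTER * max(np.trace(prec), 1.0)
        cf = linalg.cho_factor(prec, lower=True)
        mean = linalg.cho_solve(cf, Fw.T @ Y[:, p])
        Lo_inv = linalg.solve_triangular(cf[0], np.eye(d), lower=True)
        out[p] = mean + z[p] @ Lo_inv
    return out


def bmsfa_decomposition(draws: PosteriorDraws) -> FactorDecomposition:
    """Posterior-mean covariance decomposition with OP-aligned loadings."""
    from .postprocess import op_align

    phis = draws.stack("phi")
    S = len(draws.draws[0]["lambda"])
    phi_hat = op_align(phis)
    common_cov = np.einsum("npk,nqk->pq", phis, phis) / len(phis)
    common_cov = (common_cov + common_cov.T) / 2.0
    study_loads, study_covs, marginals, psi_hats = [], [], [], []
    for s in range(S):
        lams = np.stack([d["lambda"][s] for d in draws.draws])
        psi = np.stack([d["psi"][s] for d in draws.draws]).mean(axis=0)
        lam_hat = op_align(lams)
        sc = np.einsum("npk,nqk->pq", lams, lams) / len(lams)
        sc = (sc + sc.T) / 2.0
        study_loads.append(lam_hat)
        study_covs.append(sc)
        psi_hats.append(psi)
        marginals.append(common_cov + sc + np.diag(psi))
    return FactorDecomposition(
        method_tag="BMSFA", common_loadings=phi_hat,
        study_loadings=study_loads, residual_variances=psi_hats,
        common_cov=common_cov, study_covs=study_covs, marginal_covs=marginals)


def fit_bmsfa(data: MultiStudyDataset, k: int, js,
              cfg: GibbsConfig | None = None) -> BMSFAResults:
    cfg = cfg or GibbsConfig()
    return BMSFA(data, k, js).fit(cfg.n_iter, cfg.n_burnin, cfg.thin, cfg.seed)
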