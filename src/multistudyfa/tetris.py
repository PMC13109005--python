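"""Tetris: combinatorial sharing of factors across studies.

One loading matrix ``Phi*`` (P x K*) is shared by all studies; a binary
sharing matrix ``T`` (S x K*) says which studies load on which factors:
``y_is = Phi* diag(T_s) f_i + eps_s``.  A factor active in every study is a
common factor, one active in a single study is study-specific, and anything
in between is *partially shared* -- the structure the simpler decompositions
cannot express.  ``T`` gets a (truncated) two-parameter Indian buffet
process prior.

Sampling alternates conjugate blocks (scores, MGPS loadings, residual
variances) with entry-wise updates of ``T``: each entry is redrawn from its
two-point conditional, combining the beta-Bernoulli finite approximation of
the IBP conditional prior with the study's marginal likelihood (factors
integrated out via Woodbury).  This is the Metropolis-within-Gibbs scheme
with the proposal equal to the full conditional, so every move is accepted.

Point estimation is two-stage: :func:`choose_T` picks the posterior draw of
``T`` with the most posterior mass near it (most other draws within a
Hamming radius of its left-ordered form; ties go to the earliest draw), and
the model is refitted with ``T`` fixed to that choice.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .base import (FactorDecomposition, FactorModel, FactorResults,
                   PosteriorDraws)
from .data import MultiStudyDataset
from .gibbs import (GibbsConfig, _sample_scores, _sample_loading_rows_weighted,
                    _sample_psi)
from .postprocess import op_align
from .priors import IbpSpec, MgpsState, left_order, mgps_gibbs_update

__all__ = ["Tetris", "TetrisResults", "fit_tetris", "classify_factors",
           "choose_T", "refit_fixed_T"]


def classify_factors(T: np.ndarray) -> dict:
    """Partition the columns of a sharing matrix into common, partially
    shared and study-specific factors.

    Returns a dict with index lists ``"common"`` (active in every study),
    ``"partial"`` (active in at least two but not all), ``"specific"``
    (active in exactly one) and ``"empty"``, plus ``"studies"``: for each
    column the tuple of active study indices.
    """
    T = np.asarray(T, dtype=int)
    if T.ndim != 2 or not np.isin(T, (0, 1)).all():
        raise ValueError("sharing matrix must be binary and 2-D")
    S = T.shape[0]
    m = T.sum(axis=0)
    out = {"common": [], "partial": [], "specific": [], "empty": [],
           "studies": []}
    for k in range(T.shape[1]):
        active = tuple(np.flatnonzero(T[:, k]))
        out["studies"].append(active)
        if m[k] == S:
            out["common"].append(k)
        elif m[k] == 1:
            out["specific"].append(k)
        elif m[k] == 0:
            out["empty"].append(k)
        else:
            out["partial"].append(k)
    return out


def choose_T(T_draws: list[np.ndarray], radius: int = 1) -> np.ndarray:
    """Select the sharing matrix with the highest local posterior mass.

    Every draw is put in left-ordered form; the score of a draw is the
    number of draws within Hamming distance ``radius`` of it (itself
    included).  The earliest draw attaining the maximum is returned.
    """
    if not T_draws:
        raise ValueError("no sharing-matrix draws supplied")
    los = [left_order(t) for t in T_draws]
    width = max(t.shape[1] for t in los)
    S = los[0].shape[0]
    padded = np.stack([
        np.hstack([t, np.zeros((S, width - t.shape[1]), dtype=int)])
        for t in los])
    flat = padded.reshape(len(los), -1)
    dist = (flat[:, None, :] != flat[None, :, :]).sum(axis=2)
    counts = (dist <= radius).sum(axis=1)
    return los[int(np.argmax(counts))]


class TetrisResults(FactorResults):
    """Two-stage fit: ``sharing_matrix`` is the selected T (left-ordered,
    empty columns dropped); the decomposition comes from the fixed-T refit.
    ``exploration_draws`` holds the stage-one chain."""

    def __init__(self, model, decomposition, draws, sharing_matrix,
                 exploration_draws):
        super().__init__(model, decomposition, draws)
        self.sharing_matrix = sharing_matrix
        self.exploration_draws = exploration_draws


def _study_marglik(Y: np.ndarray, W: np.ndarray, psi: np.ndarray) -> float:
    """Gaussian log marginal likelihood of one study with factors
    integrated out: Y rows iid N(0, W W' + diag(psi)), via Woodbury."""
    n, P = Y.shape
    if W.shape[1] == 0:
        quad = float((Y ** 2 / psi[None, :]).sum())
        return -0.5 * (n * P * np.log(2 * np.pi)
                       + n * float(np.log(psi).sum()) + quad)
    Wp = W / psi[:, None]
    C = np.eye(W.shape[1]) + W.T @ Wp
    sign, ld_c = np.linalg.slogdet(C)
    B = Y @ Wp  # (n, K)
    quad = float((Y ** 2 / psi[None, :]).sum())
    quad -= float(np.einsum("nk,nk->", B @ np.linalg.inv(C), B))
    return -0.5 * (n * P * np.log(2 * np.pi)
                   + n * (float(np.log(psi).sum()) + ld_c) + quad)


def _tetris_step(Ys, Ns, T, phi, psis, mgps, a_bb, beta, rng,
                 update_T: bool):
    """One sweep of the sharing-matrix sampler: masked scores per study ->
    loadings (weighted regression) -> MGPS -> residual variances ->
    (optionally) entry-wise two-point conditionals of T.

    Returns (T, phi, psis, mgps)."""
    S = len(Ys)
    K = phi.shape[1]
    # scores: per study on the active columns only
    F_blocks = []
    for s in range(S):
        act = np.flatnonzero(T[s])
        F = np.zeros((Ns[s], K))
        if act.size:
            F[:, act] = _sample_scores(Ys[s], phi[:, act],
                                       psis[s], rng)
        F_blocks.append(F)
    F_all = np.vstack(F_blocks)
    Y_all = np.vstack(Ys)
    psi_rows = np.vstack([np.tile(psis[s], (Ns[s], 1))
                          for s in range(S)])
    prior_prec = mgps.local_precisions * mgps.global_precisions[None, :]
    phi = _sample_loading_rows_weighted(F_all, Y_all, psi_rows,
                                        prior_prec, rng)
    mgps = mgps_gibbs_update(mgps, phi, rng)
    psis = list(psis)
    for s in range(S):
        resid = Ys[s] - F_blocks[s] @ phi.T
        psis[s] = _sample_psi((resid ** 2).sum(axis=0), Ns[s], rng)

    # sharing matrix: entry-wise two-point conditionals
    if update_T:
        T = T.copy()
        for s in range(S):
            for k in range(K):
                m = T[:, k].sum() - T[s, k]
                p1 = (m + a_bb) / (S - 1 + a_bb + beta)
                act1 = T[s].copy()
                act1[k] = 1
                act0 = act1.copy()
                act0[k] = 0
                ll1 = _study_marglik(
                    Ys[s], phi[:, np.flatnonzero(act1)], psis[s])
                ll0 = _study_marglik(
                    Ys[s], phi[:, np.flatnonzero(act0)], psis[s])
                lo = np.log(p1) - np.log1p(-p1) + ll1 - ll0
                T[s, k] = int(rng.random() < expit(lo))
    return T, phi, psis, mgps


class Tetris(FactorModel):
    """Sharing-matrix factor model with a truncated IBP prior.

    Parameters
    ----------
    data : MultiStudyDataset
        Centered per study.
    kmax : int
        Truncation level of the IBP (maximum number of factors).
    ibp : IbpSpec, optional
        Defaults to ``alpha = 1.25 * S``, ``beta = 1``.
    """

    def __init__(self, data: MultiStudyDataset, kmax: int,
                 ibp: IbpSpec | None = None):
        super().__init__(data)
        if not 1 <= kmax <= data.n_variables:
            raise ValueError("kmax must be in [1, P]")
        self.kmax = kmax
        self.ibp = ibp or IbpSpec.default(data.n_studies)

    def fit(self, n_iter: int = 4000, n_burnin: int = 3000, thin: int = 1,
            seed: int = 0) -> TetrisResults:
        cfg = GibbsConfig(n_iter, n_burnin, thin, seed)
        explore = self._run_chain(cfg, fixed_T=None)
        T_hat = choose_T([d["T"] for d in explore.draws])
        T_hat = T_hat[:, T_hat.sum(axis=0) > 0]
        if T_hat.shape[1] == 0:
            T_hat = np.ones((self.data.n_studies, 1), dtype=int)
        cfg2 = GibbsConfig(n_iter, n_burnin, thin, cfg.seed + 1)
        refit = self._run_chain(cfg2, fixed_T=T_hat)
        decomp = _tetris_decomposition(refit, T_hat, self.data.n_studies)
        return TetrisResults(self, decomp, refit, T_hat, explore)

    def _run_chain(self, cfg: GibbsConfig,
                   fixed_T: np.ndarray | None) -> PosteriorDraws:
        rng = np.random.default_rng(cfg.seed)
        data = self.data
        S, P = data.n_studies, data.n_variables
        Ys = data.studies
        Ns = data.n_obs
        K = self.kmax if fixed_T is None else fixed_T.shape[1]
        a_bb = self.ibp.alpha * self.ibp.beta / K  # beta-Bernoulli pseudo-count

        if fixed_T is None:
            # start from the IBP-ish prior mean: every factor on
            T = np.ones((S, K), dtype=int)
        else:
            T = fixed_T.copy()
        mgps = MgpsState.initialize(P, K, rng)
        phi = rng.standard_normal((P, K)) * 0.1
        psis = [np.full(P, 1.0) for _ in range(S)]

        kept: list[dict] = []
        for it in range(cfg.n_iter):
            T, phi, psis, mgps = _tetris_step(
                Ys, Ns, T, phi, psis, mgps, a_bb, self.ibp.beta, rng,
                update_T=fixed_T is None)
            if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
                kept.append({"phi": phi.copy(), "T": T.copy(),
                             "psi": [p.copy() for p in psis]})
        return PosteriorDraws(kept, cfg.n_iter, cfg.n_burnin, cfg.seed,
                              "Tetris")


def _tetris_decomposition(draws: PosteriorDraws, T: np.ndarray,
                          S: int) -> FactorDecomposition:
    info = classify_factors(T)
    common = np.asarray(info["common"], dtype=int)
    phis = draws.stack("phi")
    if common.size:
        phic = phis[:, :, common]
        common_loadings = op_align(phic)
        common_cov = np.einsum("npk,nqk->pq", phic, phic) / len(phis)
        common_cov = (common_cov + common_cov.T) / 2.0
    else:
        common_loadings = None
        common_cov = np.zeros((phis.shape[1], phis.shape[1]))
    study_loads, study_covs, marginals, psi_hats = [], [], [], []
    for s in range(S):
        rest = np.array([k for k in range(T.shape[1])
                         if T[s, k] and k not in set(common.tolist())],
                        dtype=int)
        psi = np.stack([np.asarray(d["psi"][s]) for d in draws.draws]
                       ).mean(axis=0)
        if rest.size:
            lam_d = phis[:, :, rest]
            lam = op_align(lam_d)
            sc = np.einsum("npk,nqk->pq", lam_d, lam_d) / len(phis)
            sc = (sc + sc.T) / 2.0
        else:
            lam = np.zeros((phis.shape[1], 0))
            sc = np.zeros((phis.shape[1], phis.shape[1]))
        study_loads.append(lam)
        study_covs.append(sc)
        psi_hats.append(psi)
        marginals.append(common_cov + sc + np.diag(psi))
    return FactorDecomposition(
        method_tag="Tetris", common_loadings=common_loadings,
        study_loadings=study_loads, residual_variances=psi_hats,
        common_cov=common_cov, study_covs=study_covs,
        marginal_covs=marginals,
        extras={"sharing_matrix": T, "classification": info})


def fit_tetris(data: MultiStudyDataset, kmax: int,
               cfg: GibbsConfig | None = None) -> TetrisResults:
    cfg = cfg or GibbsConfig(4000, 3000)
    return Tetris(data, kmax).fit(cfg.n_iter, cfg.n_burnin, cfg.thin,
                                  cfg.seed)


def refit_fixed_T(data: MultiStudyDataset, T: np.ndarray,
                  cfg: GibbsConfig | None = None) -> TetrisResults:
    """Fit the model with a known sharing matrix (no IBP exploration)."""
    cfg = cfg or GibbsConfig(4000, 3000)
    T = np.asarray(T, dtype=int)
    model = Tetris(data, T.shape[1])
    refit = model._run_chain(cfg, fixed_T=T)
    decomp = _tetris_decomposition(refit, T, data.n_studies)
    return TetrisResults(model, decomp, refit, T, None)
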