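"""Shrinkage-prior families shared across the estimators.

Four prior families appear throughout the package:

* the multiplicative gamma process (MGPS) prior, a column-ordered
  global-local shrinkage prior that penalizes higher-indexed factors
  increasingly strongly;
* the Dirichlet-Laplace (DL) prior, a global-local prior that places
  Laplace kernels with Dirichlet-distributed local scales on loadings;
* the non-local spike-and-slab (moment) prior, whose slab density vanishes
  at the origin so that "active" loadings are forced away from zero;
* the two-parameter Indian buffet process (IBP), a nonparametric prior over
  binary activation matrices with an unbounded number of columns.

The full conditionals implemented here follow from conjugacy of the
constructions (gamma-gamma for MGPS; generalized-inverse-Gaussian
auxiliaries for DL); correctness is asserted by two-simulator tests and
prior-moment checks in the test suite rather than by matching any
particular reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MgpsState",
    "DlState",
    "NlpSpec",
    "IbpSpec",
    "mgps_prior_variance",
    "mgps_gibbs_update",
    "dl_gibbs_update",
    "nlp_densities",
    "ibp_sample",
    "sufa_residual_lognormal_hyperparams",
]


# ---------------------------------------------------------------------------
# Multiplicative gamma process shrinkage
# ---------------------------------------------------------------------------

@dataclass
class MgpsState:
    """State of the MGPS prior for one ``P x K`` loading matrix.

    ``local_precisions[p, k]`` is the local gamma precision of loading
    ``(p, k)``; ``deltas`` are the K multiplicative gamma increments whose
    cumulative product gives the column-wise global precisions
    ``global_precisions[k] = prod_{l<=k} deltas[l]``.
    """

    local_precisions: np.ndarray  # (P, K), omega
    deltas: np.ndarray            # (K,)
    kappa: float = 3.0
    a1: float = 2.1
    a2: float = 3.1

    @property
    def global_precisions(self) -> np.ndarray:
        return np.cumprod(self.deltas)

    @classmethod
    def initialize(cls, P: int, K: int, rng: np.random.Generator,
                   kappa: float = 3.0, a1: float = 2.1, a2: float = 3.1
                   ) -> "MgpsState":
        omega = rng.gamma(kappa / 2.0, 2.0 / kappa, size=(P, K))
        deltas = np.empty(K)
        deltas[0] = rng.gamma(a1, 1.0)
        if K > 1:
            deltas[1:] = rng.gamma(a2, 1.0, size=K - 1)
        return cls(omega, deltas, kappa, a1, a2)

    def drop_columns(self, keep: np.ndarray) -> "MgpsState":
        """Restrict the state to the retained columns (adaptive truncation)."""
        return MgpsState(self.local_precisions[:, keep], self.deltas[keep],
                         self.kappa, self.a1, self.a2)


def mgps_prior_variance(state: MgpsState) -> np.ndarray:
    """Elementwise prior variances ``1 / (omega_pk * theta_k)``."""
    theta = state.global_precisions
    return 1.0 / (state.local_precisions * theta[None, :])


def mgps_gibbs_update(state: MgpsState, loadings: np.ndarray,
                      rng: np.random.Generator) -> MgpsState:
    """Draw new local and global precisions from their full conditionals.

    Given loadings phi with ``phi_pk ~ N(0, 1/(omega_pk theta_k))``:

    * ``omega_pk | - ~ Gam((kappa+1)/2, (kappa + theta_k phi_pk^2)/2)``;
    * each increment ``delta_h`` is gamma with shape ``a + P(K-h+1)/2`` and a
      rate accumulating the column sums of ``omega * phi^2`` weighted by the
      global precisions with ``delta_h`` divided out.
    """
    loadings = np.asarray(loadings, dtype=float)
    if not np.isfinite(loadings).all():
        raise ValueError("non-finite loadings passed to MGPS update")
    P, K = loadings.shape
    phi2 = loadings ** 2
    theta = state.global_precisions
    kappa = state.kappa

    omega = rng.gamma(
        (kappa + 1.0) / 2.0,
        2.0 / (kappa + theta[None, :] * phi2),
    )

    deltas = state.deltas.copy()
    col_mass = (omega * phi2).sum(axis=0)  # sum_p omega_pk phi_pk^2
    for h in range(K):
        theta = np.cumprod(deltas)
        # global precision of column l with delta_h factored out, l >= h
        theta_mh = theta[h:] / deltas[h]
        shape = (state.a1 if h == 0 else state.a2) + P * (K - h) / 2.0
        rate = 1.0 + 0.5 * float(np.dot(theta_mh, col_mass[h:]))
        deltas[h] = rng.gamma(shape, 1.0 / rate)
    return MgpsState(omega, deltas, state.kappa, state.a1, state.a2)


# ---------------------------------------------------------------------------
# Dirichlet-Laplace
# ---------------------------------------------------------------------------

@dataclass
class DlState:
    """State of the row-scaled Dirichlet-Laplace prior for a P x K matrix.

    Row ``p`` of the loading matrix has Laplace scale
    ``dirichlet_weights[p] * global_scale``; ``aux_locals[p, k]`` are the
    exponential auxiliaries of the normal-exponential mixture representation
    (``phi ~ N(0, chi * (omega_p theta)^2)`` with ``chi ~ Exp(1/2)`` is
    marginally ``Laplace(omega_p theta)``).
    """

    dirichlet_weights: np.ndarray  # (P,), on the simplex
    global_scale: float
    concentration: float = 0.5
    aux_locals: np.ndarray | None = None  # (P, K), chi

    @classmethod
    def initialize(cls, P: int, K: int, rng: np.random.Generator,
                   a_dl: float = 0.5) -> "DlState":
        w = rng.dirichlet(np.full(P, a_dl))
        w = np.maximum(w, 1e-300)
        w /= w.sum()
        theta = rng.gamma(a_dl * P, 2.0)
        chi = rng.exponential(2.0, size=(P, K))
        return cls(w, float(theta), a_dl, chi)

    def conditional_variances(self) -> np.ndarray:
        """Conditionally Gaussian prior variances chi * (omega_p theta)^2."""
        scale = self.dirichlet_weights[:, None] * self.global_scale
        return self.aux_locals * scale ** 2


def _rgig(rng: np.random.Generator, lam: float, chi: float, psi: float,
          size=None) -> np.ndarray:
    """Draw from the generalized inverse Gaussian GIG(lam, chi, psi) with
    density ~ x^(lam-1) exp(-(chi/x + psi*x)/2)."""
    chi = np.maximum(chi, 1e-30)
    b = np.sqrt(chi * psi)
    # scipy's geninvgauss(p, b): density ~ x^(p-1) exp(-b(x + 1/x)/2)
    draw = stats.geninvgauss.rvs(lam, b, size=size, random_state=rng)
    return draw * np.sqrt(chi / psi)


def dl_gibbs_update(state: DlState, loadings: np.ndarray,
                    rng: np.random.Generator) -> DlState:
    """Resample the DL auxiliaries, Dirichlet weights and global scale.

    Follows the conjugate block updates of the normal-exponential-gamma
    construction: inverse-Gaussian draws for the local mixing variables and
    generalized-inverse-Gaussian draws for the joint (weights, scale) block,
    with one shared scale per row of the loading matrix.
    """
    phi = np.atleast_2d(np.asarray(loadings, dtype=float))
    if phi.size == 0:
        raise ValueError("empty loadings passed to DL update")
    P, K = phi.shape
    a = state.concentration
    abs_phi = np.abs(phi)
    row_scale = np.maximum(state.dirichlet_weights * state.global_scale, 1e-12)

    # local mixing: 1/chi ~ InvGaussian(omega_p theta / |phi|, 1)
    mu = row_scale[:, None] / np.maximum(abs_phi, 1e-12)
    inv_chi = rng.wald(np.minimum(mu, 1e12), 1.0)
    chi = 1.0 / np.maximum(inv_chi, 1e-12)

    # joint update of (weights, scale) via independent GIG draws per row
    row_mass = abs_phi.sum(axis=1)  # R_p = sum_k |phi_pk|
    T = np.array([
        _rgig(rng, a - K, 2.0 * max(row_mass[p], 1e-12), 1.0) for p in range(P)
    ])
    total = float(T.sum())
    w = np.maximum(T / total, 1e-300)
    w /= w.sum()
    return DlState(w, total, a, chi)


# ---------------------------------------------------------------------------
# Non-local spike-and-slab (moment prior)
# ---------------------------------------------------------------------------

@dataclass
class NlpSpec:
    """Hyperparameters of the non-local spike-and-slab prior on loadings.

    The spike is ``N(0, tau0)`` with small ``tau0``; the slab is the moment
    density ``(x^2 / tau1) N(x; 0, tau1)``, which is zero at the origin.
    """

    tau0: float = 0.026
    tau1: float = 0.28
    a_zeta: float = 1.0
    b_zeta: float = 1.0

    def __post_init__(self) -> None:
        if not self.tau0 < self.tau1:
            raise ValueError("spike variance tau0 must be smaller than tau1")


def nlp_densities(x: np.ndarray | float, spec: NlpSpec):
    """Evaluate the spike and slab densities of the non-local prior at x."""
    x = np.asarray(x, dtype=float)
    spike = stats.norm.pdf(x, scale=np.sqrt(spec.tau0))
    slab = (x ** 2 / spec.tau1) * stats.norm.pdf(x, scale=np.sqrt(spec.tau1))
    return spike, slab


# ---------------------------------------------------------------------------
# Indian buffet process
# ---------------------------------------------------------------------------

@dataclass
class IbpSpec:
    """Two-parameter IBP hyperparameters (alpha scales the expected number
    of columns, beta spreads activations across rows)."""

    alpha: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("IBP parameters must be positive")

    @classmethod
    def default(cls, S: int) -> "IbpSpec":
        return cls(alpha=1.25 * S, beta=1.0)


def left_order(T: np.ndarray) -> np.ndarray:
    """Canonicalize a binary matrix by sorting columns by their binary value
    read top-to-bottom (left-ordered form), descending."""
    T = np.asarray(T, dtype=int)
    if T.shape[1] == 0:
        return T
    S = T.shape[0]
    keys = (T * (2.0 ** np.arange(S - 1, -1, -1))[:, None]).sum(axis=0)
    order = np.argsort(-keys, kind="stable")
    return T[:, order]


def ibp_sample(spec: IbpSpec, S: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a binary activation matrix from the two-parameter IBP.

    Sequential (restaurant) construction: row s activates an existing column
    k with probability ``m_k / (beta + s - 1)`` (``m_k`` = number of earlier
    rows active in k) and opens ``Poisson(alpha * beta / (beta + s - 1))``
    new columns.  Columns are returned in left-ordered form; every column
    has at least one active row by construction.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    cols: list[np.ndarray] = []
    for s in range(S):
        for c in cols:
            m = c[:s].sum()
            if rng.random() < m / (spec.beta + s):
                c[s] = 1
        n_new = rng.poisson(spec.alpha * spec.beta / (spec.beta + s))
        for _ in range(n_new):
            c = np.zeros(S, dtype=int)
            c[s] = 1
            cols.append(c)
    T = np.column_stack(cols) if cols else np.zeros((S, 0), dtype=int)
    return left_order(T)


# ---------------------------------------------------------------------------
# Residual-variance hyperpriors
# ---------------------------------------------------------------------------

def sufa_residual_lognormal_hyperparams(mean: float = 1.0,
                                        variance: float = 7.0
                                        ) -> tuple[float, float]:
    """Log-normal (mu, sigma^2) such that E(psi)=mean and var(psi)=variance.

    From E = exp(mu + s2/2) and var = (exp(s2) - 1) E^2:
    s2 = log(1 + var/E^2), mu = log(E) - s2/2.
    """
    s2 = float(np.log1p(variance / mean ** 2))
    mu = float(np.log(mean) - s2 / 2.0)
    return mu, s2
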