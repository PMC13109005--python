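"""Identifiability post-processing and factor-number selection.

Factor models are invariant to orthogonal rotation of the latent space, so
raw MCMC draws of a loading matrix can differ by rotations, column
permutations and sign flips.  This module provides the standard remedies:

* orthogonal Procrustes (OP) alignment of posterior draws to a reference;
* spectral-decomposition (SD) loadings from an estimated covariance;
* varimax rotation for interpretability;
* the eigenvalue proportion-of-variance rule for choosing the number of
  factors, and the posterior-mode rule for adaptive-truncation chains.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy import linalg
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = [
    "op_align", "sd_loadings", "varimax_rotate", "varimax_criterion",
    "choose_num_factors_evd", "pfa_mode_k", "reorder_factors",
    "fit_with_refit",
]


def op_align(draws, reference: np.ndarray | str = "first") -> np.ndarray:
    """Align loading-matrix draws by orthogonal Procrustes; return the mean.

    Each draw ``Phi_t`` is rotated by the orthogonal ``G_t`` minimizing
    ``||Phi_t G_t - ref||_F``; the element-wise mean of the aligned draws is
    returned.  ``reference`` defaults to the first draw.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        draws = draws[None]
    if draws.ndim != 3:
        raise ValueError("draws must be a sequence of P x K matrices")
    shapes = {d.shape for d in draws}
    if len(shapes) != 1:
        raise ValueError("all draws must share dimensions")
    ref = draws[0] if isinstance(reference, str) else np.asarray(reference)
    if ref.shape != draws[0].shape:
        raise ValueError("reference dimensions do not match draws")
    out = np.zeros_like(ref)
    for d in draws:
        G, _ = linalg.orthogonal_procrustes(d, ref)
        out += d @ G
    return out / len(draws)


def sd_loadings(cov: np.ndarray, k_star: int) -> np.ndarray:
    """Spectral-decomposition loadings: top-k eigenvectors scaled by the
    square roots of their eigenvalues (best rank-k_star factorization of
    ``cov`` in Frobenius norm)."""
    cov = np.asarray(cov, dtype=float)
    P = cov.shape[0]
    if k_star > P:
        raise ValueError("k_star cannot exceed the matrix dimension")
    w, U = np.linalg.eigh((cov + cov.T) / 2.0)
    w, U = w[::-1], U[:, ::-1]
    lead = w[:k_star]
    if (lead < -1e-8 * max(abs(w).max(), 1.0)).any():
        raise ValueError("leading eigenvalues are negative beyond tolerance")
    return U[:, :k_star] * np.sqrt(np.maximum(lead, 0.0))[None, :]


def varimax_criterion(loadings: np.ndarray) -> float:
    """The varimax objective: sum over factors of the variance of squared
    loadings."""
    L2 = np.asarray(loadings) ** 2
    return float(((L2 - L2.mean(axis=0)) ** 2).sum())


def varimax_rotate(loadings: np.ndarray) -> np.ndarray:
    """Orthogonal rotation maximizing the varimax criterion.

    A single-column matrix is returned unchanged (no rotation freedom).
    """
    loadings = np.asarray(loadings, dtype=float)
    if loadings.shape[1] < 2:
        return loadings.copy()
    rotated, _ = rotate_factors(loadings, "varimax")
    if varimax_criterion(rotated) < varimax_criterion(loadings) - 1e-10:
        return loadings.copy()
    return rotated


def choose_num_factors_evd(cov: np.ndarray, threshold: float = 0.05) -> int:
    """Count the eigenvalues of ``cov`` whose share of the total spectrum is
    at least ``threshold`` (the >=5%-of-variance rule by default)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    cov = np.asarray(cov, dtype=float)
    w = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    if w[0] < -1e-8 * max(abs(w).max(), 1.0):
        raise ValueError("covariance is not PSD beyond tolerance")
    w = np.maximum(w, 0.0)
    total = w.sum()
    if total <= 0:
        return 0
    return int((w / total >= threshold).sum())


def pfa_mode_k(k_trace: np.ndarray) -> int:
    """Modal active-factor count of a post-burn-in trace; ties go to the
    larger value."""
    k_trace = np.asarray(k_trace)
    if k_trace.size == 0:
        raise ValueError("empty active-factor trace")
    counts = Counter(int(k) for k in k_trace)
    best = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    return best[0]


def reorder_factors(loadings: np.ndarray,
                    criterion: str = "explained_variance"
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Sort factor columns descending by a prominence criterion.

    ``explained_variance`` orders by column sum of squares;
    ``nonzero_count`` by the number of non-zero loadings (used by the
    spike-and-slab EM model).  Returns (permuted loadings, permutation).
    """
    loadings = np.asarray(loadings, dtype=float)
    if criterion == "explained_variance":
        key = (loadings ** 2).sum(axis=0)
    elif criterion == "nonzero_count":
        key = (loadings != 0).sum(axis=0).astype(float)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    perm = np.argsort(-key, kind="stable")
    return loadings[:, perm], perm


def fit_with_refit(model_cls, data, k: int, js=None, threshold: float = 0.05,
                   **fit_kwargs):
    """Two-step workflow: fit a generously sized model, select the number of
    factors by the EVD rule on the estimated common (and study-specific)
    covariances, then refit at the selected sizes.

    Returns ``(final_results, selected_k, selected_js)``; for per-study
    models ``selected_k`` is None.
    """
    kwargs = {} if js is None else {"js": js}
    if k is not None:
        kwargs["k"] = k
    first = model_cls(data, **kwargs).fit(**fit_kwargs)
    d = first.decomposition
    sel_k = None
    if d.common_cov is not None:
        sel_k = max(1, choose_num_factors_evd(d.common_cov, threshold))
    sel_js = None
    if d.study_covs is not None:
        sel_js = [max(1, choose_num_factors_evd(c, threshold))
                  for c in d.study_covs]
    kwargs2 = {}
    if sel_k is not None and "k" in kwargs:
        kwargs2["k"] = sel_k
    if sel_js is not None and "js" in kwargs:
        kwargs2["js"] = sel_js
    final = model_cls(data, **{**kwargs, **kwargs2}).fit(**fit_kwargs)
    return final, sel_k, sel_js
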