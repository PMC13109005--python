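"""Accuracy metrics and predictive evaluation.

* RV coefficient: a [0, 1] similarity between the column-space
  configurations of two matrices, invariant to orthogonal rotation --
  the natural metric for comparing estimated and true loading matrices
  that are only identified up to rotation.
* Frobenius distance: element-wise error between two matrices.
* Bartlett factor scores: generalized-least-squares estimates of latent
  scores for new observations given fitted loadings and residual
  variances, used to reconstruct held-out data and compute predictive MSE.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .base import FactorDecomposition, FactorResults
from .data import MultiStudyDataset, TrainTestSplit, apply_centering

__all__ = [
    "rv_coefficient", "frobenius_distance", "bartlett_scores",
    "predict_studies", "prediction_mse", "summarize_recovery",
]


def rv_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    """RV coefficient between the configurations XX' and YY'.

    ``RV = tr(XX'YY') / sqrt(tr((XX')^2) tr((YY')^2))``; requires equal row
    counts and non-zero matrices.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("matrices must have the same number of rows")
    num = float((np.linalg.norm(X.T @ Y, "fro")) ** 2)
    dx = float((np.linalg.norm(X.T @ X, "fro")) ** 2)
    dy = float((np.linalg.norm(Y.T @ Y, "fro")) ** 2)
    if dx <= 0 or dy <= 0:
        raise ValueError("RV coefficient undefined for a zero matrix")
    return num / np.sqrt(dx * dy)


def frobenius_distance(X: np.ndarray, Y: np.ndarray) -> float:
    """sqrt of the sum of squared element differences."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("matrices must have the same shape")
    return float(np.linalg.norm(X - Y, "fro"))


def bartlett_scores(loadings: np.ndarray, psi: np.ndarray,
                    Y: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """GLS (Bartlett) factor scores: f = (L' Psi^-1 L)^-1 L' Psi^-1 y.

    ``Y`` is (N, P); returns (N, d).  A small ridge is added on retry if the
    normal-equation matrix is singular.
    """
    L = np.asarray(loadings, dtype=float)
    psi = np.asarray(psi, dtype=float)
    Lp = L / psi[:, None]
    A = L.T @ Lp
    if ridge:
        A = A + ridge * np.eye(A.shape[0])
    B = Lp.T @ Y.T  # (d, N)
    try:
        return np.linalg.solve(A, B).T
    except np.linalg.LinAlgError:
        if ridge:
            raise
        return bartlett_scores(loadings, psi, Y, ridge=1e-8)


def _study_loadings_psi(decomp: FactorDecomposition, s: int):
    """Assemble the scoring loadings and residual variances for study s."""
    blocks = []
    if decomp.common_loadings is not None:
        blocks.append(decomp.common_loadings)
    if decomp.study_loadings is not None:
        lam = decomp.study_loadings[s]
        if lam.shape[1] > 0:
            blocks.append(lam)
    if not blocks:
        raise ValueError("decomposition has no loadings to score against")
    L = np.hstack(blocks)
    rv = decomp.residual_variances
    psi = np.asarray(rv[s] if isinstance(rv, (list, tuple)) else rv)
    return L, psi


def predict_studies(decomp: FactorDecomposition,
                    new_data: MultiStudyDataset) -> list[np.ndarray]:
    """Reconstruct held-out observations from Bartlett scores.

    Uses the stacked-loading generalization: models with study loadings
    score against [Phi  Lambda_s]; the batch-adjusted model first removes
    its fitted intercepts and covariate effects (and adds them back to the
    reconstruction); the perturbed-factor model maps each observation
    through its study's fitted perturbation before scoring and maps the
    reconstruction back.
    """
    S = new_data.n_studies
    if decomp.study_loadings is not None and len(decomp.study_loadings) != S:
        raise ValueError("fit and test data disagree on the number of studies")
    preds = []
    Qs = decomp.extras.get("Q")  # perturbed-factor model
    for s in range(S):
        Y = new_data.studies[s]
        offset = 0.0
        if decomp.intercepts is not None:
            offset = decomp.intercepts[:, s][None, :]
            if decomp.regression is not None and new_data.covariates is not None:
                offset = offset + new_data.covariates[s] @ decomp.regression.T
            Y = Y - offset
        if Qs is not None:
            Y = Y @ Qs[s].T
        L, psi = _study_loadings_psi(decomp, s)
        F = bartlett_scores(L, psi, Y)
        Yhat = F @ L.T
        if Qs is not None:
            Yhat = Yhat @ np.linalg.inv(Qs[s]).T
        preds.append(Yhat + offset)
    return preds


def prediction_mse(fit: FactorResults | FactorDecomposition,
                   split: TrainTestSplit, center_with_train: bool = True
                   ) -> float:
    """Out-of-sample reconstruction MSE on the held-out split.

    ``(1 / (P * sum N_s^test)) * sum of squared reconstruction errors``;
    test data are centered with the training per-study means when the
    training data were centered (no leakage from the test rows).
    """
    decomp = fit.decomposition if isinstance(fit, FactorResults) else fit
    test = split.test
    if center_with_train and split.train.center_means is not None:
        test = apply_centering(test, split.train.center_means,
                               split.train.center_scales)
    preds = predict_studies(decomp, test)
    sq = 0.0
    n_total = 0
    P = test.n_variables
    for s, Y in enumerate(test.studies):
        sq += float(((preds[s] - Y) ** 2).sum())
        n_total += Y.shape[0]
    return sq / (P * n_total)


def summarize_recovery(results: dict[str, dict]) -> pd.DataFrame:
    """Tabulate per-method factor-count recovery as ``mean (SD)`` strings.

    ``results`` maps method name to a dict with keys ``"k"`` (list of
    per-replicate estimated K, optional) and ``"js"`` (list of
    per-replicate lists of per-study estimates, optional).
    """
    def fmt(vals) -> str:
        vals = np.asarray(vals, dtype=float)
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        return f"{vals.mean():.2f} ({sd:.2f})"

    rows = []
    for method, res in results.items():
        k_txt = fmt(res["k"]) if res.get("k") else "—"
        js = res.get("js")
        if js:
            arr = np.asarray(js, dtype=float)  # (reps, S)
            js_txt = ", ".join(fmt(arr[:, s]) for s in range(arr.shape[1]))
        else:
            js_txt = "—"
        rows.append({"Model": method, "Estimated K": k_txt,
                     "Estimated Js": js_txt})
    return pd.DataFrame(rows)
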