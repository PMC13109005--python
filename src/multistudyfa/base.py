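"""Shared model/results machinery and fitted-decomposition containers.

Every estimator in the package is a model class constructed from a
:class:`~multistudyfa.data.MultiStudyDataset`; calling ``fit()`` returns a
results object that carries point estimates, the implied covariance
decomposition, and (for samplers) the posterior draws.  ``summary()`` renders
a compact text table in the spirit of statsmodels results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .data import MultiStudyDataset

__all__ = ["FactorDecomposition", "PosteriorDraws", "FactorModel",
           "FactorResults", "load_decomposition"]

_SYM_TOL = 1e-8


@dataclass
class FactorDecomposition:
    """Point estimates of a fitted multi-study factor decomposition.

    The marginal covariance of study s decomposes into a shared low-rank
    part ``common_cov`` (Sigma_Phi), a study-unique low-rank part
    ``study_covs[s]`` (Sigma_Lambda_s) and diagonal residual variances.
    Exactly which pieces exist depends on the estimator (``method_tag``):
    e.g. a pooled single-study fit has no study loadings, and the
    batch-adjusted EM model has intercepts/regression but no Sigma_Lambda_s.
    """

    method_tag: str
    common_loadings: np.ndarray | None = None          # (P, K)
    study_loadings: list[np.ndarray] | None = None     # S x (P, J_s)
    residual_variances: Any = None                     # (P,) or list of (P,)
    common_cov: np.ndarray | None = None               # (P, P)
    study_covs: list[np.ndarray] | None = None         # S x (P, P)
    marginal_covs: list[np.ndarray] | None = None      # S x (P, P)
    intercepts: np.ndarray | None = None               # (P, S)
    regression: np.ndarray | None = None               # (P, Q)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mats in (("common_cov", [self.common_cov] if self.common_cov
                            is not None else []),
                           ("study_covs", self.study_covs or []),
                           ("marginal_covs", self.marginal_covs or [])):
            for m in mats:
                if m is None:
                    continue
                scale = max(np.abs(m).max(), 1.0)
                if np.abs(m - m.T).max() > _SYM_TOL * scale:
                    raise ValueError(f"{name} not symmetric within tolerance")
        if self.marginal_covs is not None:
            for s, m in enumerate(self.marginal_covs):
                w = np.linalg.eigvalsh(m)
                if w[0] < -1e-8 * max(np.trace(m), 1.0):
                    raise ValueError(f"marginal covariance {s} is not PSD")

    @property
    def n_common_factors(self) -> int:
        return 0 if self.common_loadings is None else self.common_loadings.shape[1]

    @property
    def study_factor_counts(self) -> list[int] | None:
        if self.study_loadings is None:
            return None
        return [l.shape[1] for l in self.study_loadings]

    def save(self, out_dir: str | Path) -> None:
        """Serialize to a directory of CSV matrices plus JSON metadata."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)

        def _w(name: str, arr: np.ndarray) -> None:
            pd.DataFrame(np.asarray(arr)).to_csv(out / f"{name}.csv", index=False)

        if self.common_loadings is not None:
            _w("common_loadings", self.common_loadings)
        if self.common_cov is not None:
            _w("common_cov", self.common_cov)
        for coll, stem in ((self.study_loadings, "study_loadings"),
                           (self.study_covs, "study_cov"),
                           (self.marginal_covs, "marginal_cov")):
            if coll is not None:
                for s, m in enumerate(coll):
                    _w(f"{stem}_{s + 1}", m)
        rv = self.residual_variances
        if rv is not None:
            if isinstance(rv, (list, tuple)):
                for s, v in enumerate(rv):
                    _w(f"residual_variances_{s + 1}", np.asarray(v)[None, :])
            else:
                _w("residual_variances", np.asarray(rv)[None, :])
        if self.intercepts is not None:
            _w("intercepts", self.intercepts)
        if self.regression is not None:
            _w("regression", self.regression)
        meta = {
            "method": self.method_tag,
            "k": self.n_common_factors,
            "js": self.study_factor_counts,
        }
        with open(out / "metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2)


def load_decomposition(in_dir: str | Path) -> "FactorDecomposition":
    """Load a decomposition previously written by
    :meth:`FactorDecomposition.save`."""
    src = Path(in_dir)
    meta_path = src / "metadata.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.json under {src}")
    with open(meta_path) as fh:
        meta = json.load(fh)

    def _r(name: str) -> np.ndarray | None:
        fp = src / f"{name}.csv"
        return pd.read_csv(fp).to_numpy(dtype=float) if fp.exists() else None

    def _series(stem: str) -> list[np.ndarray] | None:
        out = []
        s = 1
        while (src / f"{stem}_{s}.csv").exists():
            out.append(_r(f"{stem}_{s}"))
            s += 1
        return out or None

    rv: Any = _r("residual_variances")
    if rv is not None:
        rv = rv.ravel()
    else:
        per_study = _series("residual_variances")
        rv = [v.ravel() for v in per_study] if per_study else None
    return FactorDecomposition(
        method_tag=meta.get("method", "unknown"),
        common_loadings=_r("common_loadings"),
        study_loadings=_series("study_loadings"),
        residual_variances=rv,
        common_cov=_r("common_cov"),
        study_covs=_series("study_cov"),
        marginal_covs=_series("marginal_cov"),
        intercepts=_r("intercepts"),
        regression=_r("regression"),
    )


@dataclass
class PosteriorDraws:
    """Ordered post-burn-in MCMC parameter snapshots for one chain.

    ``draws`` is a list of dicts mapping parameter names to arrays; all
    snapshots in a chain share P and S.  ``k_trace``, when present, records
    the per-iteration active-factor count (used by the adaptive-truncation
    sampler, where it is non-increasing).
    """

    draws: list[dict]
    n_iter: int
    n_burnin: int
    seed: int
    method_tag: str = ""
    k_trace: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.draws)

    def stack(self, key: str) -> np.ndarray:
        """Stack one parameter across draws into a (n_draws, ...) array."""
        return np.stack([d[key] for d in self.draws])


class FactorModel:
    """Base class: holds the (validated) dataset and fit configuration."""

    def __init__(self, data: MultiStudyDataset):
        from .data import validate_dataset

        self.data = validate_dataset(data)

    @classmethod
    def from_dataframes(cls, frames: list[pd.DataFrame], **kwargs) -> "FactorModel":
        data = MultiStudyDataset([f.to_numpy(dtype=float) for f in frames],
                                 variable_names=list(frames[0].columns))
        return cls(data, **kwargs)

    def fit(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class FactorResults:
    """Base results object wrapping a :class:`FactorDecomposition`."""

    def __init__(self, model: FactorModel, decomposition: FactorDecomposition,
                 draws: PosteriorDraws | None = None):
        self.model = model
        self.decomposition = decomposition
        self.draws = draws

    @property
    def common_loadings(self):
        return self.decomposition.common_loadings

    @property
    def study_loadings(self):
        return self.decomposition.study_loadings

    @property
    def n_common_factors(self) -> int:
        return self.decomposition.n_common_factors

    @property
    def study_factor_counts(self):
        return self.decomposition.study_factor_counts

    def summary(self) -> str:
        d = self.decomposition
        data = self.model.data
        lines = [
            f"{d.method_tag} multi-study factor analysis results",
            "=" * 50,
            f"studies:            {data.n_studies}",
            f"variables (P):      {data.n_variables}",
            f"observations:       {data.n_obs}",
            f"common factors (K): {d.n_common_factors}",
        ]
        if d.study_factor_counts is not None:
            lines.append(f"study factors (Js): {d.study_factor_counts}")
        if self.draws is not None:
            lines.append(
                f"posterior draws:    {len(self.draws)} "
                f"(iter={self.draws.n_iter}, burn-in={self.draws.n_burnin})"
            )
        if d.common_cov is not None:
            ev = np.linalg.eigvalsh(d.common_cov)[::-1]
            share = ev / max(ev.sum(), 1e-300)
            top = ", ".join(f"{x:.1%}" for x in share[: min(6, len(share))])
            lines.append(f"common-cov variance shares (top): {top}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<{type(self).__name__}: {self.decomposition.method_tag}>"
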