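"""Containers and pre-processing for multi-study data.

A *multi-study* dataset is a collection of S independent studies measuring the
same P variables on different samples: study ``s`` contributes an ``N_s x P``
matrix.  Optional per-study covariate matrices (``N_s x Q``) carry observed
batch or design information for models that adjust for them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MultiStudyDataset",
    "TrainTestSplit",
    "validate_dataset",
    "center_by_study",
    "split_train_test",
    "load_manifest",
    "save_dataset",
]


@dataclass
class MultiStudyDataset:
    """S per-study observation matrices over one shared variable set.

    Parameters
    ----------
    studies : list of ndarray
        One ``(N_s, P)`` float matrix per study; rows are observations,
        columns are the shared variables.
    study_ids : list of str, optional
        Labels for the studies; defaults to ``study_1 .. study_S``.
    covariates : list of ndarray, optional
        One ``(N_s, Q)`` matrix per study of observed covariates.
    variable_names : list of str, optional
        P labels for the columns; defaults to ``v1 .. vP``.
    """

    studies: list[np.ndarray]
    study_ids: list[str] | None = None
    covariates: list[np.ndarray] | None = None
    variable_names: list[str] | None = None
    # per-study column means/scales recorded by center_by_study, used to apply
    # the training transform to held-out data
    center_means: list[np.ndarray] | None = field(default=None, repr=False)
    center_scales: list[np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.studies = [np.asarray(y, dtype=float) for y in self.studies]
        if self.study_ids is None:
            self.study_ids = [f"study_{s + 1}" for s in range(len(self.studies))]
        if self.variable_names is None and self.studies:
            self.variable_names = [f"v{p + 1}" for p in range(self.studies[0].shape[1])]
        if self.covariates is not None:
            self.covariates = [np.asarray(x, dtype=float) for x in self.covariates]

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def n_variables(self) -> int:
        return self.studies[0].shape[1]

    @property
    def n_obs(self) -> list[int]:
        return [y.shape[0] for y in self.studies]

    @property
    def n_covariates(self) -> int:
        if self.covariates is None:
            return 0
        return self.covariates[0].shape[1]

    def stacked(self) -> np.ndarray:
        """All observations stacked into one ``(sum N_s, P)`` matrix."""
        return np.vstack(self.studies)

    def study_index(self) -> np.ndarray:
        """Length-N vector mapping each stacked row to its study index."""
        return np.repeat(np.arange(self.n_studies), self.n_obs)


def validate_dataset(data: MultiStudyDataset) -> MultiStudyDataset:
    """Check the dataset invariants and return the dataset unchanged.

    Raises
    ------
    ValueError
        If study matrices disagree on the number of columns, any study is
        empty, covariate row counts mismatch their study, or a non-finite
        entry is present (reported with its study/row/column coordinate).
    """
    if not data.studies:
        raise ValueError("dataset contains no studies")
    P = data.studies[0].shape[1]
    for s, y in enumerate(data.studies):
        if y.ndim != 2:
            raise ValueError(f"study {data.study_ids[s]!r} is not a matrix")
        if y.shape[1] != P:
            raise ValueError(
                f"dimension mismatch: study {data.study_ids[s]!r} has "
                f"{y.shape[1]} columns, expected {P}"
            )
        if y.shape[0] < 1:
            raise ValueError(f"study {data.study_ids[s]!r} has no rows")
        if not np.isfinite(y).all():
            i, p = np.argwhere(~np.isfinite(y))[0]
            raise ValueError(
                f"non-finite value in study {data.study_ids[s]!r} "
                f"at row {i}, column {p}"
            )
    if data.covariates is not None:
        if len(data.covariates) != data.n_studies:
            raise ValueError("covariate list length differs from number of studies")
        for s, x in enumerate(data.covariates):
            if x.shape[0] != data.studies[s].shape[0]:
                raise ValueError(
                    f"covariate rows ({x.shape[0]}) do not match study "
                    f"{data.study_ids[s]!r} rows ({data.studies[s].shape[0]})"
                )
            if not np.isfinite(x).all():
                raise ValueError(
                    f"non-finite covariate value in study {data.study_ids[s]!r}"
                )
    return data


def center_by_study(
    data: MultiStudyDataset, scale: bool = False
) -> MultiStudyDataset:
    """Column-center (optionally scale) each study separately.

    Statistics are computed per study, never pooled.  Constant columns under
    ``scale=True`` are centered but not divided (divide-by-zero guard).  The
    per-study means/scales are stored on the returned dataset so the same
    transform can later be applied to held-out data.
    """
    import warnings

    centered, means, scales = [], [], []
    for s, y in enumerate(data.studies):
        mu = y.mean(axis=0)
        out = y - mu
        sd = np.ones(y.shape[1])
        if scale:
            sd = out.std(axis=0, ddof=1)
            const = sd <= 0
            if const.any():
                warnings.warn(
                    f"study {data.study_ids[s]!r}: {int(const.sum())} constant "
                    "column(s) centered but not scaled",
                    stacklevel=2,
                )
                sd = np.where(const, 1.0, sd)
            out = out / sd
        centered.append(out)
        means.append(mu)
        scales.append(sd)
    return replace(data, studies=centered, center_means=means, center_scales=scales)


def apply_centering(
    data: MultiStudyDataset, means: Sequence[np.ndarray],
    scales: Sequence[np.ndarray] | None = None,
) -> MultiStudyDataset:
    """Apply previously computed per-study centering statistics (e.g., from
    the training split) to ``data``."""
    out = []
    for s, y in enumerate(data.studies):
        z = y - means[s]
        if scales is not None:
            z = z / scales[s]
        out.append(z)
    return replace(data, studies=out, center_means=list(means),
                   center_scales=None if scales is None else list(scales))


@dataclass
class TrainTestSplit:
    """Per-study random partition of a dataset into train and test rows."""

    train: MultiStudyDataset
    test: MultiStudyDataset
    fraction: float
    seed: int
    train_indices: list[np.ndarray] = field(default_factory=list)
    test_indices: list[np.ndarray] = field(default_factory=list)


def split_train_test(
    data: MultiStudyDataset, fraction: float, seed: int
) -> TrainTestSplit:
    """Randomly partition each study's rows at the given training fraction.

    Reproducible for a fixed seed; every study must have at least 2 rows.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    tr_idx, te_idx, tr_y, te_y = [], [], [], []
    tr_x, te_x = [], []
    for s, y in enumerate(data.studies):
        n = y.shape[0]
        if n < 2:
            raise ValueError(
                f"study {data.study_ids[s]!r} has {n} row(s); need >= 2 to split"
            )
        n_train = int(round(fraction * n))
        n_train = min(max(n_train, 1), n - 1)
        perm = rng.permutation(n)
        a, b = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        tr_idx.append(a)
        te_idx.append(b)
        tr_y.append(y[a])
        te_y.append(y[b])
        if data.covariates is not None:
            tr_x.append(data.covariates[s][a])
            te_x.append(data.covariates[s][b])
    cov_tr = tr_x if data.covariates is not None else None
    cov_te = te_x if data.covariates is not None else None
    train = MultiStudyDataset(tr_y, list(data.study_ids), cov_tr,
                              list(data.variable_names))
    test = MultiStudyDataset(te_y, list(data.study_ids), cov_te,
                             list(data.variable_names))
    return TrainTestSplit(train, test, fraction, seed, tr_idx, te_idx)


# ---------------------------------------------------------------------------
# File interfaces: per-study delimited matrices + a YAML/JSON manifest.
# ---------------------------------------------------------------------------

def load_manifest(path: str | Path) -> MultiStudyDataset:
    """Load a dataset described by a manifest file.

    The manifest (YAML or JSON) maps study ids to data files::

        studies:
          - id: bronx
            data: bronx.csv          # CSV/TSV with a header of variable names
            covariates: bronx_x.csv  # optional
    """
    path = Path(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    entries = manifest["studies"]
    ids, mats, covs = [], [], []
    any_cov = False
    for e in entries:
        fp = path.parent / e["data"]
        if not fp.exists():
            raise FileNotFoundError(f"manifest references missing file: {fp}")
        sep = "\t" if fp.suffix in {".tsv", ".tab"} else ","
        df = pd.read_csv(fp, sep=sep)
        ids.append(str(e.get("id", fp.stem)))
        mats.append(df.to_numpy(dtype=float))
        if "covariates" in e:
            any_cov = True
            xp = path.parent / e["covariates"]
            covs.append(pd.read_csv(xp, sep=sep).to_numpy(dtype=float))
        else:
            covs.append(None)
    variable_names = list(pd.read_csv(
        path.parent / entries[0]["data"],
        sep="\t" if str(entries[0]["data"]).endswith(".tsv") else ",",
        nrows=0).columns)
    if any_cov and any(c is None for c in covs):
        raise ValueError("either all or no studies may declare covariates")
    data = MultiStudyDataset(mats, ids, covs if any_cov else None, variable_names)
    return validate_dataset(data)


def save_dataset(data: MultiStudyDataset, out_dir: str | Path) -> Path:
    """Write per-study CSVs plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for s, y in enumerate(data.studies):
        name = f"{data.study_ids[s]}.csv"
        pd.DataFrame(y, columns=data.variable_names).to_csv(out / name, index=False)
        entry = {"id": data.study_ids[s], "data": name}
        if data.covariates is not None:
            xname = f"{data.study_ids[s]}_covariates.csv"
            pd.DataFrame(data.covariates[s]).to_csv(out / xname, index=False)
            entry["covariates"] = xname
        entries.append(entry)
    manifest = out / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump({"studies": entries}, fh)
    return manifest
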