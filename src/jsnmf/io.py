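"""Readers and writers for the delimited-matrix, clinical-table and GMT formats.

Matrix files are plain text (tab or comma delimited, auto-detected on read,
always tab on write) with a header row of feature identifiers and the first
column holding sample identifiers.  The clinical table must contain a binary
column named ``recurrence``; every other numeric column is treated as a
covariate.  Gene sets use the standard GMT layout: one set per line,
``name <TAB> description <TAB> member ...``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: float format that round-trips IEEE doubles exactly through text
FLOAT_FMT = "%.17g"

#: minimum number of samples shared by all modality files and the clinical table
MIN_SAMPLE_OVERLAP = 3


class ValidationError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class MultiOmicsDataset:
    """Three nonnegative feature blocks over one shared set of samples.

    ``blocks[0]`` holds image-derived patient-level features, ``blocks[1]``
    gene expression, ``blocks[2]`` pathway scores; each block is an
    ``n x q_I`` array whose rows follow ``sample_ids``.
    """

    sample_ids: list[str]
    blocks: list[np.ndarray]
    feature_ids: list[list[str]]
    labels: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(self.blocks) != 3 or len(self.feature_ids) != 3:
            raise ValidationError("expected exactly three modality blocks")
        for b, (X, ids) in enumerate(zip(self.blocks, self.feature_ids)):
            X = np.asarray(X, dtype=float)
            self.blocks[b] = X
            if X.shape != (n, len(ids)):
                raise ValidationError(
                    f"block {b + 1} shape {X.shape} does not match "
                    f"{n} samples x {len(ids)} features"
                )
            if len(set(ids)) != len(ids):
                raise ValidationError(f"block {b + 1} has duplicated feature ids")
            if not np.all(np.isfinite(X)):
                raise ValidationError(f"block {b + 1} contains non-finite values")
            if (X < 0).any():
                i, j = np.argwhere(X < 0)[0]
                raise ValidationError(
                    f"negative value in block {b + 1} at "
                    f"{self.sample_ids[i]}, {ids[j]}"
                )
        self.labels = np.asarray(self.labels).astype(int)
        if self.labels.shape != (n,) or not set(np.unique(self.labels)) <= {0, 1}:
            raise ValidationError("labels must be a binary vector of length n")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def block_widths(self) -> tuple[int, int, int]:
        return tuple(X.shape[1] for X in self.blocks)  # type: ignore[return-value]


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional explicit background universe."""

    sets: dict[str, set[str]]
    background: set[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class RunConfig:
    """Validated hyperparameters for the fusion + factorization pipeline.

    ``K`` is the number of latent components; ``alpha`` weighs the
    similarity-prior term ``alpha * ||W - R||_F^2`` and ``beta`` the
    orthogonality penalty on each coefficient matrix.  ``k_neighbors`` of
    ``None`` means the ceil(n/10) heuristic is applied at run time.
    """

    K: int = 10
    alpha: float = 0.01
    beta: float = 0.01
    max_iter: int = 500
    tol: float = 1e-6
    k_neighbors: int | None = None
    epsilon: float = 0.01
    mu: float = 0.5
    fusion_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    ortho_target: str = "identity"
    zscore_T: float = 1.5
    seed: int = 0
    scale_blocks: bool = True
    variant: str = "jsnmf"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValidationError("K must be a positive integer")
        if self.alpha < 0 or self.beta < 0:
            raise ValidationError("alpha and beta must be nonnegative")
        if self.max_iter < 0:
            raise ValidationError("max_iter must be >= 0")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if not 0 < self.epsilon < 0.5:
            raise ValidationError("epsilon must lie in (0, 0.5)")
        if self.k_neighbors is not None and self.k_neighbors < 1:
            raise ValidationError("k_neighbors must be a positive integer")
        w = np.asarray(self.fusion_weights, dtype=float)
        if w.shape != (3,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError("fusion_weights must be a nonnegative simplex vector of length 3")
        self.fusion_weights = tuple(float(x) for x in w)
        if self.ortho_target not in ("identity", "ones"):
            raise ValidationError("ortho_target must be 'identity' or 'ones'")
        if self.variant not in ("jnmf", "oc_jnmf", "snf_jnmf", "jsnmf"):
            raise ValidationError(f"unknown variant {self.variant!r}")
        if self.zscore_T <= 0:
            raise ValidationError("zscore_T must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fusion_weights"] = list(self.fusion_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "fusion_weights" in d:
            d["fusion_weights"] = tuple(d["fusion_weights"])
        return cls(**d)


def read_config(path: str | Path) -> RunConfig:
    """Load a YAML config file whose keys mirror :class:`RunConfig` fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def _sniff_sep(path: str | Path) -> str:
    # delimiter auto-detected between tab and comma
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    # round_trip parsing keeps read(write(x)) bitwise-exact
    return pd.read_csv(path, sep=_sniff_sep(path), index_col=0,
                       float_precision="round_trip", **kwargs)


def _read_matrix(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read one delimited matrix (samples x features) with identifiers."""
    return _read_matrix(path)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix as tab-delimited text at full float precision."""
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_dataset(
    block_paths: Sequence[str | Path],
    clinical_path: str | Path,
) -> MultiOmicsDataset:
    """Load and harmonize the three modality matrices and the clinical table.

    Sample order is harmonized by intersecting the sample ids of all four
    files and sorting them; blocks are re-indexed to that shared order.
    All-zero feature columns are dropped with a logged warning because
    multiplicative updates cannot move them.
    """
    if len(block_paths) != 3:
        raise ValidationError("expected three modality file paths")
    frames = [_read_matrix(p) for p in block_paths]
    clinical = _read_table(clinical_path)
    clinical.index = clinical.index.astype(str)
    if "recurrence" not in clinical.columns:
        raise ValidationError("clinical table must contain a 'recurrence' column")

    shared = set(clinical.index)
    for f in frames:
        if f.index.has_duplicates:
            raise ValidationError("duplicated sample ids in a modality file")
        shared &= set(f.index)
    if len(shared) < MIN_SAMPLE_OVERLAP:
        raise ValidationError(
            f"only {len(shared)} samples shared across inputs "
            f"(minimum {MIN_SAMPLE_OVERLAP})"
        )
    order = sorted(shared)
    dropped = sum(len(f) for f in frames) + len(clinical) - 4 * len(order)
    if dropped:
        logger.warning("dropped %d non-shared sample rows during harmonization", dropped)

    blocks: list[np.ndarray] = []
    feature_ids: list[list[str]] = []
    for b, f in enumerate(frames):
        f = f.loc[order]
        if f.columns.has_duplicates:
            raise ValidationError(f"block {b + 1} has duplicated feature ids")
        X = f.to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValidationError(f"block {b + 1} contains non-finite values")
        if (X < 0).any():
            i, j = np.argwhere(X < 0)[0]
            raise ValidationError(
                f"negative value in block {b + 1} at {order[i]}, {f.columns[j]}"
            )
        zero = ~X.any(axis=0)
        if zero.any():
            names = list(f.columns[zero])
            logger.warning(
                "block %d: dropping %d all-zero feature column(s): %s",
                b + 1, len(names), ", ".join(names[:5]),
            )
            f = f.loc[:, ~zero]
            X = X[:, ~zero]
        blocks.append(X)
        feature_ids.append(list(f.columns))

    clinical = clinical.loc[order]
    labels = clinical["recurrence"].to_numpy()
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValidationError("'recurrence' column must be binary 0/1")
    cov = clinical.drop(columns=["recurrence"]).select_dtypes("number")
    return MultiOmicsDataset(
        sample_ids=order,
        blocks=blocks,
        feature_ids=feature_ids,
        labels=labels,
        covariates=cov if cov.shape[1] else None,
    )


def write_dataset(dataset: MultiOmicsDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset as the standard matrix/clinical files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for b, (X, ids) in enumerate(zip(dataset.blocks, dataset.feature_ids), start=1):
        df = pd.DataFrame(X, index=dataset.sample_ids, columns=ids)
        df.index.name = "sample_id"
        p = out / f"block{b}.tsv"
        write_matrix(df, p)
        paths[f"block{b}"] = p
    clin = pd.DataFrame({"recurrence": dataset.labels}, index=dataset.sample_ids)
    if dataset.covariates is not None:
        clin = pd.concat([clin, dataset.covariates], axis=1)
    clin.index.name = "sample_id"
    p = out / "clinical.tsv"
    clin.to_csv(p, sep="\t", float_format=FLOAT_FMT)
    paths["clinical"] = p
    return paths


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file; duplicate member ids within a line are deduplicated."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields (need >= 3)"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicated set name {name!r}")
            members = {m for m in fields[2:] if m}
            if not members:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def write_model(model, trace, out_dir: str | Path) -> dict[str, Path]:
    """Write W, the three H_I, the per-iteration trace, and the config.

    Matrices round-trip losslessly at full float precision; an empty trace
    yields a header-only table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    comp = [f"comp_{k + 1}" for k in range(model.W.shape[1])]
    dfw = pd.DataFrame(model.W, index=model.sample_ids, columns=comp)
    dfw.index.name = "sample_id"
    paths["W"] = out / "W.tsv"
    write_matrix(dfw, paths["W"])
    for b, H in enumerate(model.H, start=1):
        dfh = pd.DataFrame(H, index=comp, columns=model.feature_ids[b - 1])
        dfh.index.name = "component"
        paths[f"H{b}"] = out / f"H{b}.tsv"
        write_matrix(dfh, paths[f"H{b}"])
    paths["trace"] = out / "trace.tsv"
    trace.to_frame().to_csv(paths["trace"], sep="\t", index=False, float_format=FLOAT_FMT)
    paths["config"] = out / "config.yaml"
    write_config(model.config, paths["config"])
    return paths


def read_model(out_dir: str | Path):
    """Load a model written by :func:`write_model`."""
    from .factorization import FactorizationModel

    out = Path(out_dir)
    dfw = _read_matrix(out / "W.tsv")
    H = []
    feature_ids = []
    for b in range(1, 4):
        dfh = _read_matrix(out / f"H{b}.tsv")
        H.append(dfh.to_numpy(dtype=float))
        feature_ids.append(list(dfh.columns))
    config = read_config(out / "config.yaml")
    return FactorizationModel(
        W=dfw.to_numpy(dtype=float),
        H=H,
        config=config,
        variant=config.variant,
        sample_ids=list(dfw.index),
        feature_ids=feature_ids,
    )
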