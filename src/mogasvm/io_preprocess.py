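"""Reading, writing and preprocessing of expression matrices.

Expression data arrive as a delimited text matrix with identifiers in the
first row and first column.  Distribution files commonly ship genes-in-rows;
internally everything is held samples x genes.  The preprocessing pipeline
mirrors standard microarray practice: keep the most variable genes, log the
intensities, then z-score each sample profile.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("mogasvm")

__all__ = [
    "ExpressionMatrix",
    "MatrixFormatError",
    "read_expression_matrix",
    "read_labels",
    "write_expression_matrix",
    "write_labels",
    "variance_filter",
    "log_transform",
    "standardize_samples",
    "preprocess",
]


class MatrixFormatError(ValueError):
    """Raised when an input file violates the expected matrix layout."""


def _default_flags() -> dict[str, bool]:
    return {"variance_filtered": False, "log_transformed": False, "standardized": False}


@dataclass
class ExpressionMatrix:
    """A samples x genes real-valued expression matrix.

    Parameters
    ----------
    values
        ``(n_samples, n_genes)`` float array.
    sample_ids, gene_ids
        Unique string identifiers for rows and columns of ``values``.
    gene_meta
        Optional per-gene annotation (indexed like ``gene_ids``).
    flags
        Preprocessing provenance: which of the three pipeline stages have
        been applied.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    gene_meta: pd.DataFrame | None = None
    flags: dict[str, bool] = field(default_factory=_default_flags)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise MatrixFormatError("expression values must be a 2-D matrix")
        n, g = self.values.shape
        if n != len(self.sample_ids) or g != len(self.gene_ids):
            raise MatrixFormatError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} sample ids / {len(self.gene_ids)} gene ids"
            )
        for name, ids in (("sample", self.sample_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
                raise MatrixFormatError(f"duplicate {name} id: {dup!r}")
        if not np.isfinite(self.values).all():
            raise MatrixFormatError("matrix contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def with_values(self, values: np.ndarray, **flag_updates: bool) -> "ExpressionMatrix":
        flags = {**self.flags, **flag_updates}
        return ExpressionMatrix(values, list(self.sample_ids), list(self.gene_ids),
                                gene_meta=self.gene_meta, flags=flags)


def read_expression_matrix(path: str | Path,
                           orientation: str = "genes_in_rows",
                           delimiter: str = "\t") -> ExpressionMatrix:
    """Load a delimited expression matrix, normalising orientation.

    The first row and first column must carry identifiers; every data cell
    must be numeric (missing values are rejected rather than imputed).
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, header=0,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise MatrixFormatError(f"{path}: ragged or malformed rows ({exc})") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise MatrixFormatError(f"{path}: duplicate row identifier {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise MatrixFormatError(f"{path}: duplicate column identifier {dup!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise MatrixFormatError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        df[col] = coerced
    if df.isna().to_numpy().any():
        raise MatrixFormatError(f"{path}: missing values are not supported")
    if orientation == "genes_in_rows":
        df = df.T
    return ExpressionMatrix(df.to_numpy(dtype=float),
                            list(df.index.astype(str)),
                            list(df.columns.astype(str)))


def write_expression_matrix(X: ExpressionMatrix, path: str | Path,
                            orientation: str = "genes_in_rows",
                            delimiter: str = "\t",
                            sidecar: bool = True) -> None:
    """Write the matrix back to delimited text plus a provenance sidecar."""
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    df = X.to_frame()
    if orientation == "genes_in_rows":
        df = df.T
    # str() is the shortest round-trip representation of a double
    df.to_csv(path, sep=delimiter)
    if sidecar:
        meta = Path(str(path) + ".meta")
        lines = [f"n_samples: {X.n_samples}", f"n_genes: {X.n_genes}"]
        lines += [f"{k}: {str(v).lower()}" for k, v in X.flags.items()]
        meta.write_text("\n".join(lines) + "\n")


def read_labels(path: str | Path, delimiter: str = "\t") -> pd.Series:
    """Read a two-column ``sample_id <sep> class_label`` file."""
    df = pd.read_csv(path, sep=delimiter, header=None, names=["sample_id", "label"],
                     dtype={0: str})
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise MatrixFormatError(f"{path}: duplicate sample id {dup!r} in label file")
    return df.set_index("sample_id")["label"]


def write_labels(sample_ids: list[str], labels: np.ndarray, path: str | Path,
                 delimiter: str = "\t") -> None:
    pd.DataFrame({"sample_id": sample_ids, "label": np.asarray(labels)}).to_csv(
        path, sep=delimiter, header=False, index=False)


def variance_filter(X: ExpressionMatrix, top_n: int = 200) -> ExpressionMatrix:
    """Keep the ``top_n`` genes with the largest variance across samples.

    Variance uses the unbiased (n-1) estimator.  The relative order of the
    retained genes is preserved.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if X.flags["variance_filtered"]:
        raise ValueError("matrix is already variance-filtered")
    if top_n >= X.n_genes:
        logger.warning("variance_filter: top_n=%d >= %d genes, keeping all",
                       top_n, X.n_genes)
        keep = np.arange(X.n_genes)
    else:
        var = X.values.var(axis=0, ddof=1)
        order = np.argsort(-var, kind="stable")[:top_n]
        keep = np.sort(order)
    out = ExpressionMatrix(X.values[:, keep],
                           list(X.sample_ids),
                           [X.gene_ids[i] for i in keep],
                           gene_meta=None if X.gene_meta is None
                           else X.gene_meta.iloc[keep],
                           flags={**X.flags, "variance_filtered": True})
    return out


def log_transform(X: ExpressionMatrix, base: float = 2.0,
                  floor: float = 1e-8) -> ExpressionMatrix:
    """Replace every value ``v`` by ``log_base(max(v, floor))``.

    Non-positive entries are floored rather than rejected; the number of
    floored cells is logged so silent damage to ratio data is visible.
    """
    if X.flags["log_transformed"]:
        raise ValueError("matrix is already log-transformed")
    if floor <= 0:
        raise ValueError("floor must be positive")
    n_floored = int((X.values < floor).sum())
    if n_floored:
        logger.warning("log_transform: floored %d non-positive cells at %g",
                       n_floored, floor)
    vals = np.log(np.maximum(X.values, floor)) / math.log(base)
    return X.with_values(vals, log_transformed=True)


def standardize_samples(X: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every sample row to mean 0 and (population) variance 1."""
    mu = X.values.mean(axis=1, keepdims=True)
    sd = X.values.std(axis=1, ddof=0, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        raise ValueError(
            f"sample {X.sample_ids[zero[0]]!r} has constant expression; "
            "cannot standardize")
    return X.with_values((X.values - mu) / sd, standardized=True)


def preprocess(X: ExpressionMatrix, top_n: int = 200, base: float = 2.0,
               floor: float = 1e-8, apply_log: bool = True) -> ExpressionMatrix:
    """Full pipeline: variance filter -> log transform -> per-sample z-score.

    The filter runs first, on raw-scale variances.  ``apply_log=False``
    skips the log step for data already on a log-like scale (the provenance
    flag is still set so downstream stages see a consistent state).
    """
    out = variance_filter(X, top_n=top_n)
    if apply_log:
        out = log_transform(out, base=base, floor=floor)
    else:
        out = replace_flag(out, "log_transformed")
    return standardize_samples(out)


def replace_flag(X: ExpressionMatrix, flag: str) -> ExpressionMatrix:
    return ExpressionMatrix(X.values, list(X.sample_ids), list(X.gene_ids),
                            gene_meta=X.gene_meta, flags={**X.flags, flag: True})
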