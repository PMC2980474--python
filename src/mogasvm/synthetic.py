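"""Seeded synthetic expression datasets with planted cluster structure.

Emulates the shape of small tumor-subtype microarray studies: K sample
classes (possibly unequal sizes, e.g. the 23/8/12/20 split typical of a
four-subtype childhood-tumor panel), a few dozen to a couple hundred
samples, ~200 retained genes, and per-class marker genes that are up- or
down-regulated against a Gaussian background.  Optional outlier injection
scales whole sample profiles to stress mean-based center updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_preprocess import ExpressionMatrix

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "inject_outliers"]


@dataclass
class SyntheticSpec:
    """Recipe for one planted-structure dataset.

    ``effect_size`` is the class-mean shift of marker genes in units of the
    within-class standard deviation ``noise_sd``; 3 gives well-separated
    classes, 1.5 a hard regime.  ``markers_per_class`` is split half up-,
    half down-regulated.
    """

    n_classes: int = 4
    samples_per_class: int | Sequence[int] = 15
    n_genes: int = 200
    markers_per_class: int = 10
    effect_size: float = 3.0
    noise_sd: float = 1.0
    outlier_fraction: float = 0.0
    outlier_scale: float = 10.0
    seed: int = 0

    def class_sizes(self) -> list[int]:
        if isinstance(self.samples_per_class, int):
            return [self.samples_per_class] * self.n_classes
        sizes = list(self.samples_per_class)
        if len(sizes) != self.n_classes:
            raise ValueError("samples_per_class length must equal n_classes")
        return sizes

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if any(s < 1 for s in self.class_sizes()):
            raise ValueError("every class must be non-empty")
        if self.markers_per_class * self.n_classes > self.n_genes:
            raise ValueError("markers_per_class x n_classes exceeds n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ValueError("outlier_fraction must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SyntheticDataset:
    X: ExpressionMatrix
    true_labels: np.ndarray                    # (n,) in 1..K
    planted: dict[int, dict[str, list[str]]]   # class -> {"up": ids, "down": ids}
    outlier_ids: list[str] = field(default_factory=list)

    @property
    def planted_gene_ids(self) -> dict[int, list[str]]:
        return {c: d["up"] + d["down"] for c, d in self.planted.items()}


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw the dataset: Gaussian background (mean 0, sd ``noise_sd``) with
    each class's up-/down-markers shifted by +/- effect_size x noise_sd in
    that class's samples only.  Byte-identical under equal seeds."""
    rng = np.random.default_rng(spec.seed)
    sizes = spec.class_sizes()
    n = sum(sizes)
    K = spec.n_classes
    labels = np.repeat(np.arange(1, K + 1), sizes)

    gene_ids = [f"G{j:04d}" for j in range(spec.n_genes)]
    sample_ids = [f"S{i:03d}" for i in range(n)]

    marker_pool = rng.choice(spec.n_genes, size=K * spec.markers_per_class,
                             replace=False)
    n_up = (spec.markers_per_class + 1) // 2
    planted: dict[int, dict[str, list[str]]] = {}
    values = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_genes))
    shift = spec.effect_size * spec.noise_sd
    for c in range(1, K + 1):
        block = marker_pool[(c - 1) * spec.markers_per_class:
                            c * spec.markers_per_class]
        up, down = block[:n_up], block[n_up:]
        rows = labels == c
        values[np.ix_(rows, up)] += shift
        values[np.ix_(rows, down)] -= shift
        planted[c] = {"up": [gene_ids[j] for j in up],
                      "down": [gene_ids[j] for j in down]}

    outlier_ids: list[str] = []
    if spec.outlier_fraction > 0:
        values, out_idx = inject_outliers(values, spec.outlier_fraction,
                                          spec.outlier_scale, rng)
        outlier_ids = [sample_ids[i] for i in out_idx]

    X = ExpressionMatrix(values, sample_ids, gene_ids)
    return SyntheticDataset(X=X, true_labels=labels, planted=planted,
                            outlier_ids=outlier_ids)


def inject_outliers(X: np.ndarray, fraction: float, scale: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Multiply ``ceil(fraction * n)`` uniformly chosen sample rows by
    ``scale``; returns the perturbed copy and the chosen row indices."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    if scale <= 1.0:
        raise ValueError("scale must exceed 1")
    values = np.asarray(X, dtype=float).copy()
    n = values.shape[0]
    n_out = int(np.ceil(fraction * n))
    if n_out == 0:
        return values, np.empty(0, dtype=int)
    idx = rng.choice(n, size=n_out, replace=False)
    values[idx] *= scale
    return values, np.sort(idx)
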