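"""Consensus clustering from a Pareto front via an SVM kernel ensemble.

The front's label vectors are made label-consistent by optimal assignment
against a reference member, high-confidence samples are selected by
majority voting at threshold ``beta``, K one-against-all soft-margin SVMs
are trained per kernel (linear, polynomial, sigmoidal, RBF), the remaining
samples are classified, and the four kernel labelings are fused by a final
majority vote with seeded random tie-breaking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .moga import GAConfig, ParetoFront, run_moga

logger = logging.getLogger("mogasvm")

__all__ = [
    "KernelSpec",
    "EnsembleConfig",
    "LabelMatrix",
    "TrainingSet",
    "MogasvmResult",
    "align_labels",
    "build_label_matrix",
    "select_training_points",
    "train_classify",
    "kernel_vote",
    "ensemble_from_front",
    "run_mogasvm",
    "default_kernels",
]

_SKLEARN_KERNEL = {"linear": "linear", "polynomial": "poly",
                   "sigmoidal": "sigmoid", "rbf": "rbf"}


@dataclass
class KernelSpec:
    """One SVM kernel and its hyperparameters.

    ``gamma=None`` resolves to ``1/d`` at fit time.  The maximum-margin
    quadratic program behind the kernel is delegated to a standard
    soft-margin solver.
    """

    name: str
    degree: int = 3
    gamma: float | None = None
    coef0: float = 0.0
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in _SKLEARN_KERNEL:
            raise ValueError(f"unknown kernel {self.name!r}")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.C <= 0:
            raise ValueError("C must be positive")


def default_kernels() -> list[KernelSpec]:
    return [KernelSpec("linear"), KernelSpec("polynomial"),
            KernelSpec("sigmoidal"), KernelSpec("rbf")]


@dataclass
class EnsembleConfig:
    """Voting threshold, kernel list, seed and missing-class fallback.

    ``beta`` is the fraction of non-dominated solutions that must agree on
    a sample's label for it to become an SVM training point.
    """

    beta: float = 0.5
    kernels: list[KernelSpec] = field(default_factory=default_kernels)
    seed: int = 0
    fallback_beta_step: float = 0.1
    fallback_beta_min: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must lie in (0, 1]")
        if not self.kernels:
            raise ValueError("at least one kernel is required")


@dataclass
class LabelMatrix:
    """S aligned label vectors (rows) over n samples, entries in 1..K."""

    labels: np.ndarray        # (S, n) int
    reference_index: int
    K: int

    @property
    def n_solutions(self) -> int:
        return self.labels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.labels.shape[1]


@dataclass
class TrainingSet:
    indices: np.ndarray   # unique sample indices
    labels: np.ndarray    # voted class labels, 1..K
    coverage: float       # |indices| / n


def align_labels(reference: np.ndarray, other: np.ndarray, K: int) -> np.ndarray:
    """Permute ``other``'s cluster labels to maximise exact agreement with
    ``reference`` (optimal assignment on the K x K agreement matrix)."""
    reference = np.asarray(reference)
    other = np.asarray(other)
    if reference.shape != other.shape:
        raise ValueError("label vectors must have equal length")
    agree = np.zeros((K, K), dtype=int)
    np.add.at(agree, (reference - 1, other - 1), 1)
    ref_idx, oth_idx = linear_sum_assignment(-agree)
    mapping = np.empty(K, dtype=int)
    mapping[oth_idx] = ref_idx + 1
    return mapping[other - 1]


def build_label_matrix(front: ParetoFront, K: int | None = None) -> LabelMatrix:
    """Stack the front members' label vectors, aligned to the member with
    the smallest compactness sigma (the reference)."""
    if len(front) == 0:
        raise ValueError("empty Pareto front")
    if K is None:
        K = front.members[0].k
    sigmas = [m.objectives[0] for m in front.members]
    ref = int(np.argmin(sigmas))
    reference = np.asarray(front.members[ref].labels)
    rows = [reference if i == ref else
            align_labels(reference, np.asarray(m.labels), K)
            for i, m in enumerate(front.members)]
    return LabelMatrix(labels=np.vstack(rows), reference_index=ref, K=K)


def select_training_points(L: LabelMatrix, beta: float) -> TrainingSet:
    """Keep samples whose top label reaches ``ceil(beta * S)`` votes.

    A sample becomes a training point iff its most-voted label has at least
    ``t = ceil(beta * S)`` votes AND is the unique maximum; samples where
    two labels tie at the top (possible for beta <= 0.5) are excluded, so
    only unambiguous majorities train the classifier.  This makes coverage
    non-increasing in beta.
    """
    if not 0.0 < beta <= 1.0:
        raise ValueError("beta must lie in (0, 1]")
    S, n = L.labels.shape
    t = math.ceil(beta * S)
    counts = np.zeros((L.K, n), dtype=int)
    for c in range(1, L.K + 1):
        counts[c - 1] = (L.labels == c).sum(axis=0)
    top = counts.max(axis=0)
    unique_top = (counts == top).sum(axis=0) == 1
    idx = np.flatnonzero((top >= t) & unique_top)
    if idx.size == 0:
        raise ValueError(
            f"no sample reaches {t} agreeing votes of {S}; lower beta")
    labels = counts[:, idx].argmax(axis=0) + 1
    return TrainingSet(indices=idx, labels=labels, coverage=idx.size / n)


def _fit_kernel(kernel: KernelSpec, d: int) -> OneVsRestClassifier:
    gamma = kernel.gamma if kernel.gamma is not None else 1.0 / d
    svc = SVC(kernel=_SKLEARN_KERNEL[kernel.name], C=kernel.C, gamma=gamma,
              degree=kernel.degree, coef0=kernel.coef0)
    return OneVsRestClassifier(svc)


def train_classify(X: np.ndarray, train: TrainingSet, kernel: KernelSpec,
                   K: int) -> np.ndarray:
    """Fit K one-against-all SVMs on the voted training points and label the
    remaining samples; training points keep their voted labels."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    present = np.unique(train.labels)
    if present.size < 2:
        raise ValueError("training set must cover at least two classes")
    out = np.zeros(n, dtype=int)
    out[train.indices] = train.labels
    rest = np.setdiff1d(np.arange(n), train.indices, assume_unique=False)
    if rest.size == 0:
        return out
    clf = _fit_kernel(kernel, X.shape[1])
    clf.fit(X[train.indices], train.labels)
    out[rest] = clf.predict(X[rest])
    return out


def kernel_vote(label_vectors: list[np.ndarray],
                rng: np.random.Generator) -> np.ndarray:
    """Per-sample majority vote across kernel labelings; ties are broken by
    a seeded uniform choice among the tied labels."""
    stacked = np.vstack([np.asarray(v) for v in label_vectors])
    n = stacked.shape[1]
    out = np.empty(n, dtype=int)
    for j in range(n):
        votes = np.bincount(stacked[:, j])
        top = votes.max()
        tied = np.flatnonzero(votes == top)
        out[j] = tied[0] if tied.size == 1 else rng.choice(tied)
    return out


@dataclass
class MogasvmResult:
    """Final consensus labels plus the run's intermediate artefacts."""

    labels: np.ndarray
    front: ParetoFront
    label_matrix: LabelMatrix
    training: TrainingSet | None
    per_kernel: dict[str, np.ndarray]
    beta_used: float
    fallback: bool
    K: int

    @property
    def front_size(self) -> int:
        return len(self.front)

    @property
    def coverage(self) -> float:
        return self.training.coverage if self.training is not None else 0.0

    def report(self) -> str:
        lines = [
            f"K: {self.K}",
            f"front size: {self.front_size}",
            f"beta used: {self.beta_used:g}",
            f"training coverage: {self.coverage:.4f}",
            f"fallback to reference labels: {self.fallback}",
            f"kernels: {', '.join(self.per_kernel)}",
        ]
        return "\n".join(lines)


def ensemble_from_front(X: np.ndarray, front: ParetoFront, K: int,
                        config: EnsembleConfig) -> MogasvmResult:
    """Steps 2-8 given an existing front: align, vote, train per kernel,
    classify, fuse.

    If the voted training set misses a class, beta is lowered in steps of
    ``fallback_beta_step``; if classes are still missing at
    ``fallback_beta_min``, the reference member's labels are returned.
    """
    X = np.asarray(X, dtype=float)
    L = build_label_matrix(front, K)
    rng = np.random.default_rng(config.seed)

    beta = config.beta
    train: TrainingSet | None = None
    while True:
        try:
            cand = select_training_points(L, beta)
        except ValueError:
            cand = None
        if cand is not None and np.unique(cand.labels).size == K:
            train = cand
            break
        next_beta = beta - config.fallback_beta_step
        if next_beta < config.fallback_beta_min - 1e-12:
            break
        beta = next_beta
        logger.warning("training set missing classes; lowering beta to %.2f", beta)

    if train is None:
        logger.warning("fallback: returning reference member's labels")
        ref_labels = L.labels[L.reference_index].copy()
        return MogasvmResult(labels=ref_labels, front=front, label_matrix=L,
                             training=None, per_kernel={}, beta_used=beta,
                             fallback=True, K=K)

    per_kernel = {k.name: train_classify(X, train, k, K)
                  for k in config.kernels}
    final = kernel_vote(list(per_kernel.values()), rng)
    return MogasvmResult(labels=final, front=front, label_matrix=L,
                         training=train, per_kernel=per_kernel,
                         beta_used=beta, fallback=False, K=K)


def run_mogasvm(X: np.ndarray, K: int, ga_config: GAConfig,
                ensemble_config: EnsembleConfig | None = None) -> MogasvmResult:
    """Full pipeline: evolve a Pareto front, then fuse it into one
    clustering through the four-kernel SVM ensemble."""
    if ensemble_config is None:
        ensemble_config = EnsembleConfig(seed=ga_config.seed)
    front = run_moga(X, K, ga_config)
    return ensemble_from_front(X, front, K, ensemble_config)
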