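"""Cluster-number selection and external validation.

Provides the mean silhouette index used to pick K, two pair-counting
agreement measures between partitions — percentage classification accuracy
(%CA, the Rand index on a 0-100 scale) and the Hubert-Arabie adjusted Rand
index (ARI) — and the two-sample t-test used to compare per-run score
groups of competing algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb

from .ensemble import EnsembleConfig, run_mogasvm
from .moga import GAConfig, pairwise_distances

__all__ = [
    "SilhouetteResult",
    "PairCounts",
    "silhouette_index",
    "select_k",
    "pair_counts",
    "percent_ca",
    "adjusted_rand",
    "two_sample_ttest",
]


@dataclass
class SilhouetteResult:
    per_point: np.ndarray   # widths s(x) in [-1, 1]
    index: float            # mean silhouette


@dataclass
class PairCounts:
    n11: int   # co-clustered in both partitions
    n00: int   # separated in both
    n10: int   # together in the first only
    n01: int   # together in the second only

    @property
    def total(self) -> int:
        return self.n11 + self.n00 + self.n10 + self.n01


def silhouette_index(X: np.ndarray, labels: np.ndarray,
                     distance: str = "euclidean") -> SilhouetteResult:
    """Mean silhouette width.

    For each point, ``a`` is its average distance to the rest of its own
    cluster and ``b`` the smallest average distance to another cluster;
    the width is ``(b - a) / max(a, b)``.  Points in singleton clusters get
    width 0 (standard convention).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("silhouette requires at least two clusters")
    D = pairwise_distances(X, X, distance)
    masks = {c: labels == c for c in classes}
    sizes = {c: int(masks[c].sum()) for c in classes}
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        if sizes[own] > 1:
            a = D[i, masks[own]].sum() / (sizes[own] - 1)
        else:
            s[i] = 0.0
            continue
        b = min(D[i, masks[c]].mean() for c in classes if c != own)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return SilhouetteResult(per_point=s, index=float(s.mean()))


def select_k(X: np.ndarray, ga_config: GAConfig,
             ensemble_config: EnsembleConfig | None = None,
             k_min: int = 2, k_max: int | None = None,
             runs_per_k: int = 10) -> tuple[int, pd.DataFrame]:
    """Sweep K, keep each K's best-silhouette run, return the argmax K.

    For each K the pipeline is run ``runs_per_k`` times from seeds derived
    deterministically from ``ga_config.seed``; the K whose best run attains
    the largest silhouette index wins (ties to the smaller K).  Default
    ``k_max`` is ``floor(sqrt(n))``.  A run that collapses to a single
    cluster scores silhouette -1.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k_max is None:
        k_max = int(np.floor(np.sqrt(n)))
    if not 2 <= k_min <= k_max <= n - 1:
        raise ValueError(f"need 2 <= k_min <= k_max <= n-1, got "
                         f"[{k_min}, {k_max}] with n={n}")
    if ensemble_config is None:
        ensemble_config = EnsembleConfig(seed=ga_config.seed)
    seed_rng = np.random.default_rng(ga_config.seed)
    rows = []
    for K in range(k_min, k_max + 1):
        for run in range(runs_per_k):
            seed = int(seed_rng.integers(2**31 - 1))
            res = run_mogasvm(X, K,
                              replace(ga_config, seed=seed),
                              replace(ensemble_config, seed=seed))
            if np.unique(res.labels).size < 2:
                sil = -1.0
            else:
                sil = silhouette_index(X, res.labels, ga_config.distance).index
            rows.append({"K": K, "run": run, "seed": seed, "silhouette": sil})
    sweep = pd.DataFrame(rows)
    best = sweep.groupby("K")["silhouette"].max()
    k_star = int(best.idxmax())  # idxmax takes the first (smallest K) on ties
    sweep["best_for_k"] = [
        r.silhouette == best[r.K] for r in sweep.itertuples()]
    return k_star, sweep


def pair_counts(c_true: np.ndarray, c_pred: np.ndarray) -> PairCounts:
    """Classify every unordered sample pair by co-membership in the two
    partitions."""
    c_true = np.asarray(c_true)
    c_pred = np.asarray(c_pred)
    if c_true.shape != c_pred.shape:
        raise ValueError("partitions must have equal length")
    n = len(c_true)
    if n < 2:
        raise ValueError("need at least two samples")
    iu = np.triu_indices(n, k=1)
    same_t = (c_true[:, None] == c_true[None, :])[iu]
    same_p = (c_pred[:, None] == c_pred[None, :])[iu]
    n11 = int((same_t & same_p).sum())
    n00 = int((~same_t & ~same_p).sum())
    n10 = int((same_t & ~same_p).sum())
    n01 = int((~same_t & same_p).sum())
    return PairCounts(n11=n11, n00=n00, n10=n10, n01=n01)


def percent_ca(c_true: np.ndarray, c_pred: np.ndarray) -> float:
    """Percentage classification accuracy: 100 x (concordant pairs / all
    pairs)."""
    pc = pair_counts(c_true, c_pred)
    return 100.0 * (pc.n11 + pc.n00) / pc.total


def adjusted_rand(c_true: np.ndarray, c_pred: np.ndarray) -> float:
    """Hubert-Arabie adjusted Rand index from the contingency table.

    ``(sum_ij C(n_ij,2) - E) / (M - E)`` with expectation ``E`` under the
    permutation model and ``M`` the mean of the two marginal pair sums.
    Identical single-cluster partitions score 1; the degenerate 0/0 case is
    guarded to 0.  Negative values are reported as computed.
    """
    c_true = np.asarray(c_true)
    c_pred = np.asarray(c_pred)
    if c_true.shape != c_pred.shape:
        raise ValueError("partitions must have equal length")
    n = len(c_true)
    if n < 2:
        raise ValueError("need at least two samples")
    ti = pd.factorize(c_true)[0]
    pi = pd.factorize(c_pred)[0]
    table = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
    np.add.at(table, (ti, pi), 1)
    sum_ij = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    mean_ab = 0.5 * (sum_a + sum_b)
    if mean_ab == expected:
        return 1.0 if np.array_equal(ti, pi) else 0.0
    return float((sum_ij - expected) / (mean_ab - expected))


def two_sample_ttest(group_a: np.ndarray, group_b: np.ndarray,
                     variant: str = "pooled") -> tuple[float, float]:
    """Two-sample t statistic and two-sided p-value.

    ``pooled`` assumes equal variances (classic Student form); ``welch``
    does not.  Two zero-variance groups with equal means return the
    conventional (t=0, p=1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(t), float(p)
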