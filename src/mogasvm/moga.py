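"""NSGA-II multiobjective clustering of expression profiles.

Each chromosome encodes K cluster centers as a flat real vector in gene
space.  Two conflicting objectives are minimised simultaneously:

* global compactness ``sigma`` — the summed distance from every sample to
  its assigned center, and
* the reciprocal of cluster separation ``Sep`` — by default the minimum
  pairwise distance between centers (a sum-of-pairs variant is available
  via ``GAConfig.separation``).  The minimum saturates once every center
  sits in its own data cluster, so the evolved front concentrates around
  genuinely good partitions instead of chasing ever-larger center spread;
  the consensus step downstream depends on that concentration.

Objective evaluation embeds a single reassign/recompute cycle (one k-means
or k-medoids step): samples are assigned to their nearest center, centers
are recomputed from the assignment, samples are reassigned, and the updated
centers are written back into the chromosome.  The generational loop is the
standard elitist NSGA-II scheme: crowded binary tournament selection,
single-point crossover on the flattened center string, per-chromosome
mutation that nudges one center, merge of parents and children, and
truncation by non-dominated rank then crowding distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "GAConfig",
    "Individual",
    "ParetoFront",
    "pairwise_distances",
    "init_population",
    "assign_points",
    "update_centers",
    "compactness",
    "separation",
    "evaluate_individual",
    "dominates",
    "nondominated_sort",
    "crowding_distance",
    "select_parents",
    "crossover",
    "mutate",
    "run_moga",
]

_WORST = (np.inf, np.inf)


@dataclass
class GAConfig:
    """Parameters of the evolutionary clustering run.

    Defaults follow common practice for this family of algorithms:
    population 50, 100 generations, crossover probability 0.8 and
    per-chromosome mutation probability 0.01.
    """

    pop_size: int = 50
    generations: int = 100
    p_c: float = 0.8
    p_m: float = 0.01
    distance: Literal["euclidean", "pearson"] = "euclidean"
    center_update: Literal["mean", "medoid"] = "mean"
    separation: Literal["min", "sum"] = "min"
    mutation_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 4 or self.pop_size % 2:
            raise ValueError("pop_size must be even and >= 4")
        for name in ("p_c", "p_m"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mutation_scale <= 0:
            raise ValueError("mutation_scale must be positive")
        if self.distance not in ("euclidean", "pearson"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.center_update not in ("mean", "medoid"):
            raise ValueError(f"unknown center_update {self.center_update!r}")
        if self.separation not in ("sum", "min"):
            raise ValueError(f"unknown separation mode {self.separation!r}")


@dataclass
class Individual:
    """One candidate clustering: centers, induced labels, objective pair."""

    centers: np.ndarray              # (K, d)
    labels: np.ndarray | None = None  # (n,) in 1..K after evaluation
    objectives: tuple[float, float] | None = None  # (sigma, 1/Sep)
    rank: int = 0
    crowding: float = 0.0

    @property
    def k(self) -> int:
        return self.centers.shape[0]


@dataclass
class ParetoFront:
    """The mutually non-dominated solutions of the final generation."""

    members: list[Individual]
    seed: int
    generations: int
    sigma_history: list[float] = field(default_factory=list)
    repair_events: int = 0

    def __len__(self) -> int:
        return len(self.members)


def pairwise_distances(A: np.ndarray, B: np.ndarray,
                       metric: str = "euclidean") -> np.ndarray:
    """Distance matrix between row vectors of ``A`` and ``B``.

    ``pearson`` is the correlation distance ``1 - r``; constant rows (zero
    variance) are treated as uncorrelated with everything (distance 1).
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if metric == "euclidean":
        return cdist(A, B)
    if metric == "pearson":
        Ac = A - A.mean(axis=1, keepdims=True)
        Bc = B - B.mean(axis=1, keepdims=True)
        na = np.linalg.norm(Ac, axis=1)
        nb = np.linalg.norm(Bc, axis=1)
        denom = np.outer(na, nb)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, Ac @ Bc.T / np.where(denom > 0, denom, 1.0), 0.0)
        return 1.0 - np.clip(r, -1.0, 1.0)
    raise ValueError(f"unknown distance metric {metric!r}")


def init_population(X: np.ndarray, K: int, config: GAConfig,
                    rng: np.random.Generator | None = None) -> list[Individual]:
    """Seed each chromosome with K distinct data points as centers."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds the number of samples ({n})")
    if K < 2:
        raise ValueError("K must be >= 2")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop = []
    for _ in range(config.pop_size):
        idx = rng.choice(n, size=K, replace=False)
        pop.append(Individual(centers=X[idx].copy()))
    return pop


def assign_points(X: np.ndarray, centers: np.ndarray,
                  distance: str = "euclidean") -> np.ndarray:
    """Label each sample with its nearest center (1-based); ties go to the
    lowest center index."""
    D = pairwise_distances(X, centers, distance)
    return D.argmin(axis=1) + 1


def update_centers(X: np.ndarray, labels: np.ndarray, K: int,
                   mode: str = "mean",
                   rng: np.random.Generator | None = None,
                   distance: str = "euclidean",
                   dist_matrix: np.ndarray | None = None) -> np.ndarray:
    """Recompute centers from an assignment.

    ``mean`` takes the arithmetic mean of each cluster; ``medoid`` picks the
    member minimising the summed distance to the cluster's other members
    (so medoid centers are always actual data rows).  An empty cluster is
    re-seeded at a uniformly random data point.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    centers = np.empty((K, X.shape[1]), dtype=float)
    for k in range(1, K + 1):
        members = np.flatnonzero(labels == k)
        if members.size == 0:
            if rng is None:
                raise ValueError(f"cluster {k} is empty and no rng supplied for repair")
            centers[k - 1] = X[rng.integers(X.shape[0])]
        elif mode == "mean":
            centers[k - 1] = X[members].mean(axis=0)
        elif mode == "medoid":
            if dist_matrix is not None:
                sub = dist_matrix[np.ix_(members, members)]
            else:
                sub = pairwise_distances(X[members], X[members], distance)
            centers[k - 1] = X[members[sub.sum(axis=1).argmin()]]
        else:
            raise ValueError(f"unknown center update mode {mode!r}")
    return centers


def compactness(X: np.ndarray, labels: np.ndarray, centers: np.ndarray,
                distance: str = "euclidean") -> float:
    """Global compactness sigma: summed distance of each sample to its
    assigned center (smaller is tighter)."""
    D = pairwise_distances(X, centers, distance)
    return float(D[np.arange(len(labels)), np.asarray(labels) - 1].sum())


def separation(centers: np.ndarray, distance: str = "euclidean",
               mode: str = "min") -> float:
    """Cluster separation Sep over all unordered center pairs.

    ``min`` (default) takes the smallest pairwise center distance; ``sum``
    totals all pair distances.  The GA minimises ``1/Sep``.
    """
    centers = np.asarray(centers, dtype=float)
    K = centers.shape[0]
    if K < 2:
        raise ValueError("separation requires at least two centers")
    D = pairwise_distances(centers, centers, distance)
    iu = np.triu_indices(K, k=1)
    pair = D[iu]
    return float(pair.sum() if mode == "sum" else pair.min())


def _assign_with_repair(X: np.ndarray, centers: np.ndarray, config: GAConfig,
                        rng: np.random.Generator,
                        max_tries: int = 10) -> tuple[np.ndarray, np.ndarray, int]:
    """Assign points; re-seed any empty cluster's center at a random data
    point and reassign.  Returns (labels, possibly-repaired centers, #repairs)."""
    K = centers.shape[0]
    centers = centers.copy()
    repairs = 0
    for _ in range(max_tries):
        labels = assign_points(X, centers, config.distance)
        counts = np.bincount(labels, minlength=K + 1)[1:]
        empty = np.flatnonzero(counts == 0)
        if empty.size == 0:
            return labels, centers, repairs
        repairs += 1
        for k in empty:
            centers[k] = X[rng.integers(X.shape[0])]
    # Last resort: hand each still-empty cluster its re-seeded point.
    labels = assign_points(X, centers, config.distance)
    counts = np.bincount(labels, minlength=K + 1)[1:]
    for k in np.flatnonzero(counts == 0):
        j = int(rng.integers(X.shape[0]))
        labels[j] = k + 1
        centers[k] = X[j]
    return labels, centers, repairs


def evaluate_individual(X: np.ndarray, individual: Individual, config: GAConfig,
                        rng: np.random.Generator,
                        dist_matrix: np.ndarray | None = None) -> int:
    """Evaluate in place: assign -> recompute centers -> reassign.

    The updated centers are written back into the chromosome, the final
    labels stored, and the objective pair (sigma, 1/Sep) computed on the
    final assignment.  Returns the number of empty-cluster repairs fired.
    """
    K = individual.k
    labels, centers, r1 = _assign_with_repair(X, individual.centers, config, rng)
    centers = update_centers(X, labels, K, mode=config.center_update, rng=rng,
                             distance=config.distance, dist_matrix=dist_matrix)
    labels, centers, r2 = _assign_with_repair(X, centers, config, rng)
    individual.centers = centers
    individual.labels = labels
    sigma = compactness(X, labels, centers, config.distance)
    sep = separation(centers, config.distance, config.separation)
    individual.objectives = _WORST if sep <= 0 else (sigma, 1.0 / sep)
    return r1 + r2


def dominates(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """Pareto dominance for minimisation: a is no worse everywhere and
    strictly better somewhere."""
    return a[0] <= b[0] and a[1] <= b[1] and (a[0] < b[0] or a[1] < b[1])


def nondominated_sort(objectives: list[tuple[float, float]] | np.ndarray
                      ) -> list[list[int]]:
    """Partition indices into successive non-dominated fronts (F1 best)."""
    objs = np.asarray(objectives, dtype=float)
    N = objs.shape[0]
    if N == 0:
        return []
    A = objs[:, None, :]
    B = objs[None, :, :]
    dom = (A <= B).all(axis=2) & (A < B).any(axis=2)  # dom[i, j]: i dominates j
    n_dominators = dom.sum(axis=0)
    remaining = np.ones(N, dtype=bool)
    fronts: list[list[int]] = []
    while remaining.any():
        current = remaining & (n_dominators == 0)
        if not current.any():  # inf-vs-inf cannot occur, but stay safe
            current = remaining.copy()
        idx = np.flatnonzero(current)
        fronts.append(idx.tolist())
        remaining[idx] = False
        n_dominators = n_dominators - dom[idx].sum(axis=0)
    return fronts


def crowding_distance(front_objectives: list[tuple[float, float]] | np.ndarray
                      ) -> np.ndarray:
    """NSGA-II crowding distance within one front.

    Boundary members along each objective get +inf; interior members sum
    normalised neighbour gaps.  A zero-range objective contributes 0.
    """
    objs = np.asarray(front_objectives, dtype=float)
    N = objs.shape[0]
    dist = np.zeros(N)
    if N <= 2:
        return np.full(N, np.inf)
    for m in range(objs.shape[1]):
        order = np.argsort(objs[:, m], kind="stable")
        lo, hi = objs[order[0], m], objs[order[-1], m]
        dist[order[0]] = dist[order[-1]] = np.inf
        span = hi - lo
        if span <= 0 or not np.isfinite(span):
            continue
        gaps = (objs[order[2:], m] - objs[order[:-2], m]) / span
        dist[order[1:-1]] += gaps
    return dist


def _crowded_better(a: Individual, b: Individual,
                    rng: np.random.Generator) -> Individual:
    if a.rank != b.rank:
        return a if a.rank < b.rank else b
    if a.crowding != b.crowding:
        return a if a.crowding > b.crowding else b
    return a if rng.random() < 0.5 else b


def select_parents(population: list[Individual],
                   rng: np.random.Generator,
                   n_parents: int | None = None) -> list[Individual]:
    """Crowded binary tournament selection: lower rank wins, then larger
    crowding, then a seeded coin flip."""
    if n_parents is None:
        n_parents = len(population)
    draws = rng.integers(0, len(population), size=(n_parents, 2))
    return [_crowded_better(population[i], population[j], rng) for i, j in draws]


def crossover(p1: np.ndarray, p2: np.ndarray, p_c: float,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Single-point crossover on the flattened center strings."""
    K, d = p1.shape
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() < p_c and K * d >= 2:
        cut = int(rng.integers(1, K * d))
        f1, f2 = c1.ravel(), c2.ravel()
        f1[cut:], f2[cut:] = f2[cut:].copy(), f1[cut:].copy()
    return c1, c2


def mutate(chrom: np.ndarray, p_m: float, mutation_scale: float,
           data_ranges: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """With probability ``p_m`` (per chromosome), nudge one randomly chosen
    center by a uniform draw within +/- mutation_scale x per-gene range."""
    out = chrom.copy()
    if rng.random() < p_m:
        k = int(rng.integers(chrom.shape[0]))
        out[k] += rng.uniform(-1.0, 1.0, size=chrom.shape[1]) * \
            (mutation_scale * data_ranges)
    return out


def _rank_and_crowd(population: list[Individual]) -> list[list[int]]:
    objs = np.array([ind.objectives for ind in population])
    fronts = nondominated_sort(objs)
    for f_idx, front in enumerate(fronts, start=1):
        cd = crowding_distance(objs[front])
        for i, member in enumerate(front):
            population[member].rank = f_idx
            population[member].crowding = float(cd[i])
    return fronts


def _truncate(population: list[Individual], size: int) -> list[Individual]:
    fronts = _rank_and_crowd(population)
    survivors: list[Individual] = []
    for front in fronts:
        if len(survivors) + len(front) <= size:
            survivors.extend(population[i] for i in front)
        else:
            by_crowd = sorted(front, key=lambda i: -population[i].crowding)
            survivors.extend(population[i]
                             for i in by_crowd[: size - len(survivors)])
            break
    return survivors


def run_moga(X: np.ndarray, K: int, config: GAConfig) -> ParetoFront:
    """Run the elitist NSGA-II generational loop and return the first front
    of the final population (duplicates retained)."""
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(config.seed)
    data_ranges = X.max(axis=0) - X.min(axis=0)
    dist_matrix = (pairwise_distances(X, X, config.distance)
                   if config.center_update == "medoid" else None)

    population = init_population(X, K, config, rng)
    repairs = 0
    for ind in population:
        repairs += evaluate_individual(X, ind, config, rng, dist_matrix)

    sigma_history: list[float] = []
    for _ in range(config.generations):
        _rank_and_crowd(population)
        parents = select_parents(population, rng)
        children: list[Individual] = []
        for i in range(0, len(parents), 2):
            c1, c2 = crossover(parents[i].centers, parents[i + 1].centers,
                               config.p_c, rng)
            for c in (c1, c2):
                child = Individual(centers=mutate(c, config.p_m,
                                                  config.mutation_scale,
                                                  data_ranges, rng))
                repairs += evaluate_individual(X, child, config, rng, dist_matrix)
                children.append(child)
        population = _truncate(population + children, config.pop_size)
        sigma_history.append(min(ind.objectives[0] for ind in population
                                 if ind.rank == 1))

    fronts = _rank_and_crowd(population)
    members = [population[i] for i in fronts[0]]
    return ParetoFront(members=members, seed=config.seed,
                       generations=config.generations,
                       sigma_history=sigma_history, repair_events=repairs)
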