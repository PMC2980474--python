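"""Gene-marker identification from a clustering of tumor samples.

For each cluster, samples are split one-vs-rest and every gene is scored
with the signal-to-noise ratio SNR = (mu1 - mu2) / (sd1 + sd2) (or,
alternatively, a two-sample t statistic).  The most positive scores mark
up-regulated genes in the target class and the most negative mark
down-regulated ones; by default the top 5 of each are reported per class.
Because stochastic clustering runs select slightly different genes, tables
from repeated runs can be aggregated by selection frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("mogasvm")

__all__ = [
    "MarkerTable",
    "class_snr",
    "class_tstat",
    "top_markers",
    "markers_per_class",
    "marker_frequency",
    "plot_marker_heatmap",
]


@dataclass
class MarkerTable:
    """Selected markers for one target class.

    ``table`` has columns gene_id, score, direction (up/down), rank and
    frequency_pct (100 for a single run; across-run frequency after
    aggregation).
    """

    class_id: int
    scorer: str
    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])


def _group_stats(X: np.ndarray, labels: np.ndarray, target_class: int,
                 ddof: int) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                     np.ndarray, int, int]:
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    in_c = labels == target_class
    n1, n2 = int(in_c.sum()), int((~in_c).sum())
    if n1 == 0:
        raise ValueError(f"class {target_class} has no samples")
    if n1 < 2 or n2 < 2:
        raise ValueError("both the target class and the rest need >= 2 samples")
    mu1 = X[in_c].mean(axis=0)
    mu2 = X[~in_c].mean(axis=0)
    sd1 = X[in_c].std(axis=0, ddof=ddof)
    sd2 = X[~in_c].std(axis=0, ddof=ddof)
    return mu1, mu2, sd1, sd2, n1, n2


def _guard_zero_denominator(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """0/0 -> 0; nonzero/0 -> signed infinity so perfectly separating genes
    rank first instead of crashing."""
    out = np.empty_like(num)
    zero = den == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out[~zero] = num[~zero] / den[~zero]
    out[zero & (num == 0)] = 0.0
    out[zero & (num > 0)] = np.inf
    out[zero & (num < 0)] = -np.inf
    return out


def class_snr(X: np.ndarray, labels: np.ndarray, target_class: int,
              ddof: int = 1) -> np.ndarray:
    """Per-gene signal-to-noise ratio of the target class against the rest:
    (mu1 - mu2) / (sd1 + sd2), sample standard deviations by default."""
    mu1, mu2, sd1, sd2, _, _ = _group_stats(X, labels, target_class, ddof)
    return _guard_zero_denominator(mu1 - mu2, sd1 + sd2)


def class_tstat(X: np.ndarray, labels: np.ndarray, target_class: int,
                variant: str = "welch", ddof: int = 1) -> np.ndarray:
    """Per-gene two-sample t statistic of the target class against the rest.

    Welch form ``(mu1 - mu2) / sqrt(sd1^2/n1 + sd2^2/n2)`` by default; the
    pooled-variance form is available via ``variant='pooled'``.
    """
    mu1, mu2, sd1, sd2, n1, n2 = _group_stats(X, labels, target_class, ddof)
    if variant == "welch":
        den = np.sqrt(sd1**2 / n1 + sd2**2 / n2)
    elif variant == "pooled":
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        den = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        raise ValueError(f"unknown t-statistic variant {variant!r}")
    return _guard_zero_denominator(mu1 - mu2, den)


def _take_direction(scores: np.ndarray, gene_ids: list[str], n_take: int,
                    direction: str) -> pd.DataFrame:
    if direction == "up":
        pool = np.flatnonzero(scores > 0)
    else:
        pool = np.flatnonzero(scores < 0)
    # |score| descending, ties by gene index (lexsort: last key is primary)
    order = pool[np.lexsort((pool, -np.abs(scores[pool])))][:n_take]
    return pd.DataFrame({
        "gene_id": [gene_ids[i] for i in order],
        "score": scores[order],
        "direction": direction,
    })


def top_markers(scores: np.ndarray, gene_ids: list[str] | None = None,
                n_up: int = 5, n_down: int = 5, class_id: int = 0,
                scorer: str = "snr") -> MarkerTable:
    """Select the ``n_up`` largest positive and ``n_down`` most negative
    scores as up-/down-regulated markers, each sorted by |score|."""
    scores = np.asarray(scores, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(len(scores))]
    if len(gene_ids) != len(scores):
        raise ValueError("gene_ids length must match scores")
    up = _take_direction(scores, list(gene_ids), n_up, "up")
    down = _take_direction(scores, list(gene_ids), n_down, "down")
    if len(up) < n_up:
        logger.warning("class %s: only %d of %d positive scores available",
                       class_id, len(up), n_up)
    if len(down) < n_down:
        logger.warning("class %s: only %d of %d negative scores available",
                       class_id, len(down), n_down)
    table = pd.concat([up, down], ignore_index=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["frequency_pct"] = 100.0
    return MarkerTable(class_id=class_id, scorer=scorer, table=table)


def markers_per_class(X: np.ndarray, labels: np.ndarray,
                      gene_ids: list[str] | None = None,
                      scorer: str = "snr", n_up: int = 5, n_down: int = 5,
                      **scorer_kwargs) -> list[MarkerTable]:
    """One-vs-rest marker table for every cluster present in ``labels``."""
    if scorer == "snr":
        score_fn = class_snr
    elif scorer == "tstat":
        score_fn = class_tstat
    else:
        raise ValueError(f"unknown scorer {scorer!r}")
    tables = []
    for c in np.unique(np.asarray(labels)):
        scores = score_fn(X, labels, int(c), **scorer_kwargs)
        tables.append(top_markers(scores, gene_ids, n_up=n_up, n_down=n_down,
                                  class_id=int(c), scorer=scorer))
    return tables


def marker_frequency(per_run_tables: list[MarkerTable],
                     n_final: int = 10) -> MarkerTable:
    """Aggregate one class's marker tables across R runs.

    Reports, per gene, the percentage of runs in which it was selected, and
    returns the ``n_final`` most frequent genes (ties broken by mean
    |score|, then gene id).  Direction is taken from the sign of the mean
    score.
    """
    if not per_run_tables:
        raise ValueError("need at least one per-run table")
    class_ids = {t.class_id for t in per_run_tables}
    if len(class_ids) != 1:
        raise ValueError("all tables must target the same class")
    R = len(per_run_tables)
    rows = pd.concat([t.table.assign(run=i)
                      for i, t in enumerate(per_run_tables)], ignore_index=True)
    agg = rows.groupby("gene_id").agg(
        n_selected=("run", "nunique"),
        mean_score=("score", "mean"),
        mean_abs=("score", lambda s: np.abs(s).mean()),
    ).reset_index()
    agg["frequency_pct"] = 100.0 * agg["n_selected"] / R
    agg = agg.sort_values(["frequency_pct", "mean_abs", "gene_id"],
                          ascending=[False, False, True],
                          kind="stable").head(n_final)
    table = pd.DataFrame({
        "gene_id": agg["gene_id"].to_numpy(),
        "score": agg["mean_score"].to_numpy(),
        "direction": np.where(agg["mean_score"] >= 0, "up", "down"),
        "rank": np.arange(1, len(agg) + 1),
        "frequency_pct": agg["frequency_pct"].to_numpy(),
    })
    return MarkerTable(class_id=per_run_tables[0].class_id,
                       scorer=per_run_tables[0].scorer, table=table)


def plot_marker_heatmap(X: np.ndarray, labels: np.ndarray,
                        tables: list[MarkerTable], gene_ids: list[str],
                        path: str) -> None:
    """Optional genes x samples heatmap of the selected markers (samples
    grouped by cluster, diverging color scale)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    marker_rows = [gene_index[g] for t in tables for g in t.gene_ids]
    sample_order = np.argsort(labels, kind="stable")
    M = np.asarray(X, dtype=float)[sample_order][:, marker_rows].T
    fig, ax = plt.subplots(figsize=(8, 0.18 * len(marker_rows) + 2))
    vmax = np.abs(M).max()
    im = ax.imshow(M, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_yticks(range(len(marker_rows)))
    ax.set_yticklabels([gene_ids[i] for i in marker_rows], fontsize=5)
    ax.set_xlabel("samples (grouped by cluster)")
    fig.colorbar(im, ax=ax, label="expression")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
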