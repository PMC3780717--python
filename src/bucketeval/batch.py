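"""Batch-effect assessment of similarity scores and experiment clustering.

Pairs of experiments are split by a metadata factor (same label vs
different label) and the two score vectors are compared with a two-sided
Wilcoxon rank-sum test: exact enumeration of the null for small samples,
tie-corrected normal approximation with continuity correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu, rankdata

from .core import (
    FitnessMatrix,
    SimilarityMatrix,
    all_pairs_similarity,
)
from .comparators import CORRELATION_METHODS, correlation_similarity
from .errors import ParameterError, UntestableError

__all__ = [
    "ExperimentMetadata",
    "BatchTestResult",
    "ClusterTree",
    "partition_pair_scores",
    "wilcoxon_rank_sum",
    "cluster_experiments",
    "batch_effect_report",
]

#: Exact null enumeration is used when both vectors are at most this long.
EXACT_LIMIT = 10


@dataclass(frozen=True)
class ExperimentMetadata:
    """Per-experiment categorical factors (date, compound, ...)."""

    table: pd.DataFrame  # index: experiment_id; columns: factor labels

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ParameterError("duplicate experiment ids in metadata")

    @property
    def experiment_ids(self) -> list:
        return list(self.table.index)

    @property
    def factors(self) -> list[str]:
        return list(self.table.columns)

    def labels(self, factor: str) -> pd.Series:
        if factor not in self.table.columns:
            raise ParameterError(
                f"unknown factor {factor!r}; available: {self.factors}"
            )
        return self.table[factor]


@dataclass(frozen=True)
class BatchTestResult:
    """Wilcoxon rank-sum outcome for one (method, factor) comparison."""

    factor: str
    W: float
    p_value: float
    n_same: int
    n_diff: int
    method: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ParameterError("p-value must lie in (0, 1]")


def partition_pair_scores(
    sim: SimilarityMatrix, meta: ExperimentMetadata, factor: str
) -> tuple[np.ndarray, np.ndarray]:
    """Split off-diagonal pair scores by label equality under ``factor``.

    Returns ``(same_scores, diff_scores)``; every unordered pair lands in
    exactly one vector, self-pairs are excluded.
    """
    labels = meta.labels(factor)
    experiments = sim.experiment_ids
    missing = [e for e in experiments if e not in labels.index]
    if missing:
        raise ParameterError(f"experiments missing metadata: {missing[:5]}")
    same, diff = [], []
    for a, b in combinations(experiments, 2):
        score = sim.pair(a, b)
        (same if labels.at[a] == labels.at[b] else diff).append(score)
    return np.asarray(same, dtype=float), np.asarray(diff, dtype=float)


def _exact_rank_sum_p(same: np.ndarray, diff: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p: 2 * min(P(W <= w), P(W >= w)), capped at 1.

    The null distribution of the rank sum over all subsets of the pooled
    (tie-averaged) ranks is built by dynamic programming on twice the
    ranks, which are integers.
    """
    pooled = np.concatenate([same, diff])
    ranks = rankdata(pooled)  # average ranks handle ties
    n = len(same)
    w_obs = float(ranks[:n].sum())

    scaled = np.round(ranks * 2).astype(int)  # average ranks are half-integral
    top = int(scaled.sum())
    # counts[k, s]: subsets of size k with scaled rank sum s
    counts = np.zeros((n + 1, top + 1), dtype=np.int64)
    counts[0, 0] = 1
    for r in scaled:
        for k in range(min(n, 1_000_000), 0, -1):
            counts[k, r:] += counts[k - 1, : top + 1 - r]
    null = counts[n]
    total = int(null.sum())
    w2 = int(round(w_obs * 2))
    le = int(null[: w2 + 1].sum())
    ge = int(null[w2:].sum())
    p = min(1.0, 2.0 * min(le, ge) / total)
    return w_obs, p


def wilcoxon_rank_sum(
    same: Sequence[float], diff: Sequence[float], factor: str = "", method: str = ""
) -> BatchTestResult:
    """Two-sided Wilcoxon rank-sum test of ``same`` vs ``diff`` scores.

    ``W`` is the rank sum of the ``same`` vector in the pooled ranking.
    Exact enumeration is used when both vectors have at most
    ``EXACT_LIMIT`` entries; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    same = np.asarray(same, dtype=float)
    diff = np.asarray(diff, dtype=float)
    if same.size == 0 or diff.size == 0:
        raise UntestableError("both score vectors must be non-empty")

    if same.size <= EXACT_LIMIT and diff.size <= EXACT_LIMIT:
        w, p = _exact_rank_sum_p(same, diff)
    else:
        res = mannwhitneyu(
            same, diff, alternative="two-sided", method="asymptotic"
        )
        w = float(res.statistic) + same.size * (same.size + 1) / 2.0
        p = float(res.pvalue)
    return BatchTestResult(
        factor=factor,
        W=w,
        p_value=min(max(p, np.nextafter(0, 1)), 1.0),
        n_same=int(same.size),
        n_diff=int(diff.size),
        method=method,
    )


@dataclass(frozen=True)
class ClusterTree:
    """Average-linkage dendrogram over experiments."""

    labels: tuple
    linkage_matrix: np.ndarray

    def to_newick(self) -> str:
        """Serialize with experiment ids as leaf labels and branch lengths."""
        root = to_tree(self.linkage_matrix)

        def render(node) -> str:
            if node.is_leaf():
                return str(self.labels[node.id])
            left, right = node.get_left(), node.get_right()
            parts = []
            for child in (left, right):
                length = node.dist - child.dist
                parts.append(f"{render(child)}:{length:.10g}")
            return "(" + ",".join(parts) + ")"

        return render(root) + ";"

    def cut(self, k: int) -> dict:
        """Cut into ``k`` flat clusters; returns experiment id -> cluster."""
        from scipy.cluster.hierarchy import fcluster

        assignments = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in assignments)))


def cluster_experiments(sim: SimilarityMatrix) -> ClusterTree:
    """Agglomerative (average linkage) clustering of experiments.

    Distance is ``1 - score / max(score)`` so the most similar pair has
    the smallest distance regardless of whether scores were normalized.
    """
    values = sim.data.to_numpy(dtype=float, copy=True)
    if values.shape[0] < 2:
        raise ParameterError("need at least 2 experiments to cluster")
    if np.isnan(values).any():
        raise ParameterError("similarity matrix contains missing entries")
    if not np.allclose(values, values.T, rtol=1e-9, atol=1e-12):
        raise ParameterError("similarity matrix is not symmetric")
    top = values.max()
    if top <= 0:
        raise ParameterError("maximum similarity must be positive")
    dist = 1.0 - values / top
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # exact symmetry for squareform
    Z = linkage(squareform(dist, checks=False), method="average")
    return ClusterTree(labels=tuple(sim.experiment_ids), linkage_matrix=Z)


def batch_effect_report(
    fm: FitnessMatrix,
    meta: ExperimentMetadata,
    methods: Sequence[str],
    factors: Sequence[str] = ("date", "compound"),
    initial_fraction: float = 0.0005,
    growth_factor: float = 2.0,
    max_buckets: int = 20,
) -> pd.DataFrame:
    """One Wilcoxon row per (method, factor).

    Untestable combinations (a factor with an empty same- or
    different-label vector) are kept as rows with missing statistics and
    ``untestable=True``.
    """
    rows = []
    for method in methods:
        if method == "be":
            sim = all_pairs_similarity(
                fm, initial_fraction, growth_factor, max_buckets
            )
        elif method in CORRELATION_METHODS:
            sim = correlation_similarity(fm, method)
        else:
            raise ParameterError(f"unknown method {method!r}")
        for factor in factors:
            same, diff = partition_pair_scores(sim, meta, factor)
            if same.size == 0 or diff.size == 0:
                rows.append(
                    {
                        "method": method,
                        "factor": factor,
                        "W": np.nan,
                        "p_value": np.nan,
                        "n_same": int(same.size),
                        "n_diff": int(diff.size),
                        "untestable": True,
                    }
                )
                continue
            result = wilcoxon_rank_sum(same, diff, factor=factor, method=method)
            rows.append(
                {
                    "method": method,
                    "factor": factor,
                    "W": result.W,
                    "p_value": result.p_value,
                    "n_same": result.n_same,
                    "n_diff": result.n_diff,
                    "untestable": False,
                }
            )
    columns = ["method", "factor", "W", "p_value", "n_same", "n_diff", "untestable"]
    return pd.DataFrame(rows, columns=columns)
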