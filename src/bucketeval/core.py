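"""Rank-bucket similarity scoring.

Profiles (one column of fitness-defect scores per experiment) are ranked,
partitioned into buckets of increasing size — small early buckets hold the
most sensitive genes — and pairs of experiments are scored by summing, over
shared genes, a levelled score that rewards co-occurrence in small and
nearby buckets.

The levelled score for bucket indices ``i`` and ``j`` (1-based) under an
``n``-bucket scheme is::

    S(i, j) = 2**(n - 1) / (m! * m**d),   m = max(i, j),  d = |i - j|

which is symmetric, strictly positive, has a strictly decreasing diagonal,
and decays with bucket distance at any fixed row.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    IncompatibleSchemeError,
    NormalizationError,
    ParameterError,
    ShapeError,
)

__all__ = [
    "FitnessMatrix",
    "BucketScheme",
    "ScoringMatrix",
    "BucketAssignment",
    "SimilarityMatrix",
    "PRESETS",
    "build_bucket_scheme",
    "build_scoring_matrix",
    "scoring_entry_exact",
    "assign_buckets",
    "pair_similarity",
    "all_pairs_similarity",
    "normalize_similarity",
    "split_signed_matrix",
]

#: Named parameter presets: (initial_fraction, growth_factor, max_buckets).
PRESETS: Mapping[str, tuple[float, float, int]] = {
    "stringent": (0.0005, 2.0, 20),
    "intermediate": (0.01, 2.0, 15),
    "broad": (0.05, 2.0, 10),
}

#: Default cap on the number of buckets; factorials beyond ~20 push
#: off-diagonal scores toward denormal floats.
DEFAULT_BUCKET_CAP = 20

_CEIL_EPS = 1e-9


def _ceil(x: float) -> int:
    # float-noise-tolerant ceiling: 0.0005 * 6000 == 3.0000000000000004
    return math.ceil(x - _CEIL_EPS)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitnessMatrix:
    """Genes x experiments table of fitness-defect scores.

    Parameters
    ----------
    data
        Numeric DataFrame; rows indexed by gene id, columns by experiment
        id.  ``NaN`` marks a missing measurement; infinities are rejected.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ParameterError(f"duplicate gene ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ParameterError(f"duplicate experiment ids: {dups[:5]}")
        values = self.data.to_numpy(dtype=float, copy=False)
        if np.isinf(values).any():
            raise ParameterError("fitness matrix contains non-finite values")
        if self.data.to_numpy().dtype != np.float64:
            object.__setattr__(self, "data", self.data.astype(float))

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def experiment_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def profile(self, experiment_id) -> pd.Series:
        """Return one experiment's column of scores."""
        return self.data[experiment_id]

    @classmethod
    def from_arrays(
        cls, gene_ids: Iterable, experiment_ids: Iterable, values
    ) -> "FitnessMatrix":
        frame = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=pd.Index(gene_ids, name="gene"),
            columns=pd.Index(experiment_ids, name="experiment"),
        )
        return cls(frame)


@dataclass(frozen=True)
class BucketScheme:
    """Ordered bucket sizes partitioning ``num_genes`` ranked genes.

    ``sizes[0]`` is the smallest, most significant bucket; the final
    bucket absorbs any remainder of the geometric schedule.
    """

    num_genes: int
    sizes: tuple[int, ...]
    initial_fraction: float
    growth_factor: float
    max_buckets: int

    def __post_init__(self) -> None:
        if sum(self.sizes) != self.num_genes:
            raise ParameterError("bucket sizes must sum to the gene count")
        if len(self.sizes) > self.max_buckets:
            raise ParameterError("more buckets than max_buckets")
        if any(b < a for a, b in zip(self.sizes, self.sizes[1:])):
            raise ParameterError("bucket sizes must be non-decreasing")
        if any(s < 1 for s in self.sizes):
            raise ParameterError("bucket sizes must be positive")

    @property
    def n_buckets(self) -> int:
        return len(self.sizes)

    def bucket_labels(self) -> np.ndarray:
        """1-based bucket index for each rank position (descending score)."""
        return np.repeat(np.arange(1, len(self.sizes) + 1), self.sizes)


@dataclass(frozen=True)
class ScoringMatrix:
    """Symmetric n x n table of levelled scores, 1-based bucket indices."""

    n: int
    entries: np.ndarray

    def score(self, i: int, j: int) -> float:
        """Score for bucket pair ``(i, j)``, 1-based."""
        if not (1 <= i <= self.n and 1 <= j <= self.n):
            raise ParameterError(f"bucket indices out of range 1..{self.n}")
        return float(self.entries[i - 1, j - 1])

    def to_frame(self) -> pd.DataFrame:
        idx = pd.RangeIndex(1, self.n + 1, name="bucket")
        return pd.DataFrame(self.entries, index=idx, columns=idx.copy())


@dataclass(frozen=True)
class BucketAssignment:
    """Mapping gene id -> 1-based bucket index for one experiment."""

    experiment_id: object
    buckets: pd.Series  # index: gene id; values: int bucket, rank order
    scheme: BucketScheme

    def __post_init__(self) -> None:
        counts = self.buckets.value_counts()
        for b, size in enumerate(self.scheme.sizes, start=1):
            if counts.get(b, 0) != size:
                raise ShapeError(
                    f"bucket {b} holds {counts.get(b, 0)} genes, expected {size}"
                )

    def bucket_of(self, gene_id) -> int:
        return int(self.buckets.at[gene_id])


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric experiments x experiments score table."""

    data: pd.DataFrame
    method: str
    normalized: bool = False

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.data.columns):
            raise ParameterError("similarity matrix must be square with matching ids")

    @property
    def experiment_ids(self) -> list:
        return list(self.data.index)

    def pair(self, a, b) -> float:
        return float(self.data.at[a, b])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def build_bucket_scheme(
    num_genes: int,
    initial_fraction: float = 0.0005,
    growth_factor: float = 2.0,
    max_buckets: int = 20,
) -> BucketScheme:
    """Build a geometric bucket-size schedule for ``num_genes`` ranks.

    The first bucket holds ``max(1, ceil(initial_fraction * num_genes))``
    genes; each subsequent bucket is ``ceil(previous * growth_factor)``.
    Generation stops when the schedule would exceed the gene count or the
    bucket cap, and the final bucket absorbs every remaining gene (merged
    into the previous bucket if the remainder would otherwise shrink).

    Examples
    --------
    >>> build_bucket_scheme(7, 0.14, 2, 3).sizes
    (1, 2, 4)
    """
    if num_genes == 0:
        raise EmptyInputError("num_genes must be positive")
    if num_genes < 0:
        raise ParameterError("num_genes must be positive")
    if not (0.0 < initial_fraction < 1.0):
        raise ParameterError("initial_fraction must be in (0, 1)")
    if growth_factor < 1.0:
        raise ParameterError("growth_factor must be >= 1")
    if max_buckets < 2:
        raise ParameterError("max_buckets must be >= 2")

    first = max(1, _ceil(initial_fraction * num_genes))
    sizes: list[int] = []
    remaining = num_genes
    size = first
    while remaining > 0:
        if len(sizes) == max_buckets - 1 or size >= remaining:
            # terminal bucket absorbs the remainder; keep sizes monotone
            if sizes and remaining < sizes[-1]:
                sizes[-1] += remaining
            else:
                sizes.append(remaining)
            remaining = 0
        else:
            sizes.append(size)
            remaining -= size
            size = _ceil(size * growth_factor)

    return BucketScheme(
        num_genes=num_genes,
        sizes=tuple(sizes),
        initial_fraction=initial_fraction,
        growth_factor=growth_factor,
        max_buckets=max_buckets,
    )


def scoring_entry_exact(i: int, j: int, n: int) -> Fraction:
    """Exact rational value of the levelled score for bucket pair (i, j)."""
    if not (1 <= i <= n and 1 <= j <= n):
        raise ParameterError(f"bucket indices out of range 1..{n}")
    m = max(i, j)
    d = abs(i - j)
    return Fraction(2) ** (n - 1) / (math.factorial(m) * Fraction(m) ** d)


def build_scoring_matrix(n: int, cap: int = DEFAULT_BUCKET_CAP) -> ScoringMatrix:
    """Build the n x n levelled scoring matrix.

    Entries follow ``S(i, j) = 2**(n-1) / (max(i,j)! * max(i,j)**|i-j|)``,
    evaluated in exact rational arithmetic before conversion to float.

    Raises
    ------
    ParameterError
        If ``n < 1`` or ``n`` exceeds ``cap`` (factorial growth would push
        small-score entries into a numerically extreme range).
    """
    if n < 1:
        raise ParameterError("number of buckets must be >= 1")
    if n > cap:
        raise ParameterError(f"number of buckets exceeds cap {cap}")
    entries = np.empty((n, n), dtype=float)
    for i in range(1, n + 1):
        for j in range(i, n + 1):
            v = float(scoring_entry_exact(i, j, n))
            entries[i - 1, j - 1] = v
            entries[j - 1, i - 1] = v
    return ScoringMatrix(n=n, entries=entries)


def assign_buckets(
    profile: pd.Series, scheme: BucketScheme, experiment_id=None
) -> BucketAssignment:
    """Rank a profile by descending fitness defect and fill the buckets.

    Highest defect (most sensitive) genes land in bucket 1.  Ties break by
    ascending gene id so assignments are deterministic across platforms.
    Missing values must have been removed upstream; the number of scored
    genes must equal ``scheme.num_genes``.
    """
    clean = profile.dropna()
    if len(clean) != scheme.num_genes:
        raise ShapeError(
            f"profile has {len(clean)} scored genes, scheme expects {scheme.num_genes}"
        )
    values = clean.to_numpy(dtype=float)
    if scheme.num_genes > 1 and np.all(values == values[0]):
        warnings.warn(
            "profile is constant; bucket assignment is tie-break determined",
            stacklevel=2,
        )
    gene_keys = clean.index.to_numpy().astype(str)
    # primary key: descending score; secondary: ascending gene id
    order = np.lexsort((gene_keys, -values))
    buckets = pd.Series(
        scheme.bucket_labels(),
        index=clean.index[order],
        name=experiment_id if experiment_id is not None else profile.name,
    )
    return BucketAssignment(
        experiment_id=buckets.name, buckets=buckets, scheme=scheme
    )


def pair_similarity(
    a: BucketAssignment, b: BucketAssignment, sm: ScoringMatrix
) -> float:
    """Summed levelled score over shared genes of two assignments."""
    if a.scheme != b.scheme:
        raise IncompatibleSchemeError("assignments use different bucket schemes")
    if sm.n != a.scheme.n_buckets:
        raise IncompatibleSchemeError(
            f"scoring matrix has n={sm.n}, scheme has {a.scheme.n_buckets} buckets"
        )
    if len(a.buckets) == 0:
        raise EmptyInputError("no shared genes to compare")
    if not a.buckets.index.sort_values().equals(b.buckets.index.sort_values()):
        raise IncompatibleSchemeError("assignments cover different gene sets")
    bj = b.buckets.reindex(a.buckets.index).to_numpy(dtype=int)
    bi = a.buckets.to_numpy(dtype=int)
    return float(sm.entries[bi - 1, bj - 1].sum())


def all_pairs_similarity(
    fm: FitnessMatrix,
    initial_fraction: float = 0.0005,
    growth_factor: float = 2.0,
    max_buckets: int = 20,
) -> SimilarityMatrix:
    """Bucket-evaluation similarity for every pair of experiments.

    Genes missing in either member of a pair are dropped for that pair
    only (pairwise-complete), and the scheme is rebuilt on the intersection
    size so each comparison remains a complete partition.
    """
    experiments = fm.experiment_ids
    if len(experiments) < 2:
        raise ParameterError("need at least 2 experiments")

    scheme_cache: dict[int, BucketScheme] = {}
    matrix_cache: dict[int, ScoringMatrix] = {}

    def scheme_for(g: int) -> BucketScheme:
        if g not in scheme_cache:
            scheme_cache[g] = build_bucket_scheme(
                g, initial_fraction, growth_factor, max_buckets
            )
        return scheme_cache[g]

    def matrix_for(n: int) -> ScoringMatrix:
        if n not in matrix_cache:
            matrix_cache[n] = build_scoring_matrix(n)
        return matrix_cache[n]

    df = fm.data
    complete = not df.isna().to_numpy().any()
    p = len(experiments)
    out = np.zeros((p, p), dtype=float)

    if complete:
        scheme = scheme_for(len(df))
        sm = matrix_for(scheme.n_buckets)
        assignments = [assign_buckets(df[e], scheme, e) for e in experiments]
        for i in range(p):
            for j in range(i, p):
                s = pair_similarity(assignments[i], assignments[j], sm)
                out[i, j] = out[j, i] = s
    else:
        for i in range(p):
            for j in range(i, p):
                cols = df[[experiments[i]]] if i == j else df[
                    [experiments[i], experiments[j]]
                ]
                shared = cols.dropna()
                if shared.empty:
                    raise EmptyInputError(
                        f"experiments {experiments[i]!r} and {experiments[j]!r} "
                        "share no scored genes"
                    )
                scheme = scheme_for(len(shared))
                sm = matrix_for(scheme.n_buckets)
                ai = assign_buckets(shared[experiments[i]], scheme, experiments[i])
                aj = (
                    ai
                    if i == j
                    else assign_buckets(shared[experiments[j]], scheme, experiments[j])
                )
                s = pair_similarity(ai, aj, sm)
                out[i, j] = out[j, i] = s

    frame = pd.DataFrame(out, index=pd.Index(experiments), columns=pd.Index(experiments))
    return SimilarityMatrix(data=frame, method="BE", normalized=False)


def normalize_similarity(sim: SimilarityMatrix) -> SimilarityMatrix:
    """Rescale every entry to percent of the global maximum (idempotent)."""
    values = sim.data.to_numpy()
    if values.size == 0:
        raise EmptyInputError("similarity matrix has no entries")
    top = np.nanmax(values)
    if not np.isfinite(top) or top <= 0:
        raise NormalizationError("maximum similarity is not positive")
    return replace(sim, data=sim.data / top * 100.0, normalized=True)


def split_signed_matrix(fm: FitnessMatrix) -> tuple[FitnessMatrix, FitnessMatrix]:
    """Split into a positive matrix and an absolute-negative matrix.

    The first output keeps positive values and zeroes negatives; the
    second keeps ``|negative|`` values and zeroes positives.  Missing
    values stay missing in both, so ``positive - negative_abs`` recovers
    the original wherever it was observed.
    """
    df = fm.data
    positive = df.clip(lower=0.0)
    negative_abs = (-df).clip(lower=0.0)
    if not (df < 0).any().any():
        warnings.warn("no negative values; second matrix is all zeros", stacklevel=2)
    return FitnessMatrix(positive), FitnessMatrix(negative_abs)
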