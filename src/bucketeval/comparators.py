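"""Baseline all-pairs correlation similarity (Pearson, Spearman, Kendall).

These are established statistics; the module's contract is matrix assembly
and the pairwise-complete missing-data policy, so the coefficients are
delegated to pandas/scipy.  Kendall is the tie-corrected tau-b variant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import FitnessMatrix, SimilarityMatrix
from .errors import ParameterError

__all__ = ["CORRELATION_METHODS", "correlation_similarity"]

CORRELATION_METHODS = ("pearson", "spearman", "kendall")


def correlation_similarity(fm: FitnessMatrix, method: str) -> SimilarityMatrix:
    """All-pairs correlation matrix over experiments.

    Genes missing in either member of a pair are dropped for that pair
    (pairwise-complete).  Pairs involving a constant column have no
    defined correlation and are reported as missing with a warning.
    """
    if method not in CORRELATION_METHODS:
        raise ParameterError(
            f"unknown correlation method {method!r}; choose from {CORRELATION_METHODS}"
        )
    if len(fm.experiment_ids) < 2:
        raise ParameterError("need at least 2 experiments")

    with warnings.catch_warnings():
        # scipy warns on constant input inside kendalltau; we report NaN below
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = fm.data.corr(method=method, min_periods=1)

    values = corr.to_numpy(dtype=float, copy=True)
    np.fill_diagonal(values, 1.0)  # self-correlation is 1 even for constants
    if np.isnan(values).any():
        warnings.warn(
            f"{method} correlation undefined for some pairs "
            "(constant or empty overlap); reported as missing",
            stacklevel=2,
        )
    frame = pd.DataFrame(values, index=corr.index, columns=corr.columns)
    return SimilarityMatrix(data=frame, method=method, normalized=False)
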