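"""Synthetic chemogenomic fitness matrices with known ground truth.

Each generated experiment combines four layers:

* a Gaussian background over all genes;
* a compound-specific sensitive set with large fitness defects on a
  per-experiment scale (replicates share the set but differ in scale and,
  through jitter, in rank order);
* a general stress-response set whose intensity varies per experiment
  independently of compound and date, giving pair scores realistic
  heterogeneity;
* a date-linked additive shift on a fixed subset of midrange genes — the
  batch effect — kept small enough never to reach the sensitive range.

Replicates of each compound are spread evenly over dates so date and
compound are not confounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .batch import ExperimentMetadata
from .core import FitnessMatrix
from .errors import ParameterError

__all__ = ["SyntheticConfig", "GroundTruth", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generator; defaults emulate a small screen."""

    num_genes: int = 6000
    compounds: int = 3
    replicates_per_compound: int = 8
    num_dates: int = 2
    sensitive_set_size: int = 80
    signal_top_range: tuple[float, float] = (22.0, 31.0)
    rank_jitter_sd: float = 1.5
    batch_shift_sd: float = 0.8
    batch_set_size: int = 1000
    stress_set_size: int = 60
    stress_top: float = 6.5
    stress_jitter_sd: float = 0.5
    background_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.num_genes,
            self.compounds,
            self.replicates_per_compound,
            self.num_dates,
            self.sensitive_set_size,
            self.batch_set_size,
        )
        if any(c < 1 for c in counts):
            raise ParameterError("all counts must be positive")
        if self.signal_top_range[0] >= self.signal_top_range[1]:
            raise ParameterError("signal_top_range must satisfy low < high")
        if self.sensitive_set_size * self.compounds > self.num_genes:
            raise ParameterError("sensitive sets exceed the gene pool")
        special = (
            self.sensitive_set_size * self.compounds
            + self.batch_set_size
            + self.stress_set_size
        )
        if special > self.num_genes:
            raise ParameterError(
                "sensitive, batch, and stress gene sets exceed the gene pool"
            )
        sds = (
            self.rank_jitter_sd,
            self.batch_shift_sd,
            self.stress_jitter_sd,
            self.background_sd,
        )
        if any(s < 0 for s in sds):
            raise ParameterError("standard deviations must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Labels and gene sets the generator committed to."""

    compound_of: dict  # experiment id -> compound label
    date_of: dict  # experiment id -> date label
    sensitive_genes: dict  # compound label -> tuple of gene ids
    batch_genes: tuple = field(default=())
    stress_genes: tuple = field(default=())


def _experiment_layout(config: SyntheticConfig) -> list[tuple[str, str, str]]:
    """(experiment_id, compound, date) triples, dates balanced per compound."""
    layout = []
    for c in range(config.compounds):
        compound = f"cmpd{c + 1}"
        for r in range(config.replicates_per_compound):
            date = f"d{r % config.num_dates + 1}"
            layout.append((f"{compound}_rep{r + 1}", compound, date))
    return layout


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[FitnessMatrix, ExperimentMetadata, GroundTruth]:
    """Generate a fitness matrix, its metadata, and the ground truth.

    Deterministic given ``config.seed``: a single generator drives all
    randomness.
    """
    rng = np.random.default_rng(config.seed)
    width = len(str(config.num_genes))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(config.num_genes)]
    layout = _experiment_layout(config)
    experiment_ids = [e for e, _, _ in layout]

    # disjoint special gene sets: per-compound sensitive, batch, stress
    n_sensitive = config.compounds * config.sensitive_set_size
    special = rng.choice(
        config.num_genes,
        size=n_sensitive + config.batch_set_size + config.stress_set_size,
        replace=False,
    )
    sensitive_idx = {}
    for c in range(config.compounds):
        compound = f"cmpd{c + 1}"
        lo = c * config.sensitive_set_size
        sensitive_idx[compound] = special[lo : lo + config.sensitive_set_size]
    batch_idx = special[n_sensitive : n_sensitive + config.batch_set_size]
    stress_idx = special[n_sensitive + config.batch_set_size :]

    n_exp = len(layout)
    values = rng.normal(0.0, config.background_sd, size=(config.num_genes, n_exp))

    # compound signal: per-experiment scale times a decreasing weight,
    # jittered so replicate top lists overlap but reorder; plus a
    # per-experiment stress response uncorrelated with compound and date
    weights = np.linspace(1.0, 0.35, config.sensitive_set_size)
    stress_weights = np.linspace(config.stress_top, 2.0, config.stress_set_size)
    low, high = config.signal_top_range
    for k, (_, compound, _) in enumerate(layout):
        scale = rng.uniform(low, high)
        jitter = rng.normal(0.0, config.rank_jitter_sd, size=config.sensitive_set_size)
        values[sensitive_idx[compound], k] = scale * weights + jitter
        intensity = rng.uniform(0.0, 1.0)
        values[stress_idx, k] += intensity * stress_weights + rng.normal(
            0.0, config.stress_jitter_sd, size=config.stress_set_size
        )

    # date batch effect: one fixed per-gene shift vector per date
    dates = sorted({d for _, _, d in layout})
    date_shift = {
        d: rng.normal(0.0, config.batch_shift_sd, size=config.batch_set_size)
        for d in dates
    }
    for k, (_, _, date) in enumerate(layout):
        values[batch_idx, k] += date_shift[date]

    fm = FitnessMatrix.from_arrays(gene_ids, experiment_ids, values)
    meta = ExperimentMetadata(
        pd.DataFrame(
            {
                "date": [d for _, _, d in layout],
                "compound": [c for _, c, d in layout],
            },
            index=pd.Index(experiment_ids, name="experiment_id"),
        )
    )
    truth = GroundTruth(
        compound_of={e: c for e, c, _ in layout},
        date_of={e: d for e, _, d in layout},
        sensitive_genes={
            c: tuple(gene_ids[i] for i in idx) for c, idx in sensitive_idx.items()
        },
        batch_genes=tuple(gene_ids[i] for i in batch_idx),
        stress_genes=tuple(gene_ids[i] for i in stress_idx),
    )
    return fm, meta, truth
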