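"""Tab-delimited readers/writers and fitness-defect computation.

Fitness matrices are UTF-8 TSV: header row of experiment ids, first
column of gene ids, decimal cells; empty cells or ``NA`` mark missing
values.  Metadata tables are TSV with an ``experiment_id`` column plus
one column per factor.  Similarity matrices round-trip through the same
square-TSV dialect.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .batch import ExperimentMetadata
from .core import PRESETS, FitnessMatrix, SimilarityMatrix
from .errors import FormatError, ParameterError

__all__ = [
    "CountTable",
    "RunConfig",
    "compute_fitness_defect",
    "read_fitness_matrix",
    "write_fitness_matrix",
    "read_metadata",
    "write_metadata",
    "read_similarity_matrix",
    "write_similarity_matrix",
]

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "na"}


@dataclass(frozen=True)
class CountTable:
    """Per-gene barcode counts for paired treatment/control pools."""

    treatment: pd.DataFrame  # genes x experiments, non-negative counts
    control: pd.DataFrame

    def __post_init__(self) -> None:
        shared = self.treatment.index.intersection(self.control.index)
        if len(shared) == 0:
            raise ParameterError("treatment and control share no genes")
        if not self.treatment.columns.equals(self.control.columns):
            raise ParameterError("treatment and control experiment ids differ")
        for name, df in (("treatment", self.treatment), ("control", self.control)):
            if (df.loc[shared].to_numpy(dtype=float) < 0).any():
                raise ParameterError(f"negative counts in {name} table")


@dataclass(frozen=True)
class RunConfig:
    """Resolved scoring parameters plus method/factor selections."""

    initial_fraction: float = 0.0005
    growth_factor: float = 2.0
    max_buckets: int = 20
    methods: tuple[str, ...] = ("be",)
    factors: tuple[str, ...] = ("date", "compound")
    seed: int = 0
    normalize: bool = False

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "RunConfig":
        if name not in PRESETS:
            raise ParameterError(
                f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
            )
        frac, growth, cap = PRESETS[name]
        params = {
            "initial_fraction": frac,
            "growth_factor": growth,
            "max_buckets": cap,
        }
        params.update(overrides)
        return cls(**params)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: config must be a key-value mapping")
        preset = raw.pop("preset", None)
        for key in ("methods", "factors"):
            if key in raw:
                raw[key] = tuple(raw[key])
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        if preset is not None:
            return cls.from_preset(preset, **raw)
        return cls(**raw)


def compute_fitness_defect(
    counts: CountTable,
    pseudocount: float = 1.0,
    orientation: str = "control-over-treatment",
) -> FitnessMatrix:
    """Log2 count-ratio fitness defects from paired pools.

    With the default orientation the defect is
    ``log2((control + pseudocount) / (treatment + pseudocount))`` so
    strains depleted by the treatment score high; pass
    ``orientation="treatment-over-control"`` for the opposite sign.
    """
    if pseudocount <= 0:
        raise ParameterError("pseudocount must be positive")
    if orientation not in ("control-over-treatment", "treatment-over-control"):
        raise ParameterError(f"unknown orientation {orientation!r}")
    shared = counts.treatment.index.intersection(counts.control.index)
    t = counts.treatment.loc[shared].to_numpy(dtype=float)
    c = counts.control.loc[shared].to_numpy(dtype=float)
    ratio = np.log2((c + pseudocount) / (t + pseudocount))
    if orientation == "treatment-over-control":
        ratio = -ratio
    return FitnessMatrix.from_arrays(shared, counts.treatment.columns, ratio)


def _parse_square_tsv(path) -> tuple[list[str], list[str], np.ndarray]:
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if len(header) < 2:
            raise FormatError(f"{path}: header must name at least one experiment")
        column_ids = header[1:]
        row_ids: list[str] = []
        rows: list[list[float]] = []
        seen: dict[str, int] = {}
        for lineno, record in enumerate(reader, start=2):
            if not record:
                continue
            if len(record) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(record)}"
                )
            rid = record[0]
            if rid in seen:
                raise FormatError(
                    f"{path}:{lineno}: duplicate row id {rid!r} "
                    f"(first seen at line {seen[rid]})"
                )
            seen[rid] = lineno
            parsed = []
            for col, cell in enumerate(record[1:], start=2):
                token = cell.strip()
                if token in _MISSING_TOKENS:
                    parsed.append(np.nan)
                    continue
                try:
                    parsed.append(float(token))
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: field {col} is not numeric: {cell!r}"
                    ) from None
            row_ids.append(rid)
            rows.append(parsed)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return row_ids, column_ids, np.asarray(rows, dtype=float)


def read_fitness_matrix(path) -> FitnessMatrix:
    """Read a genes x experiments fitness-defect TSV."""
    gene_ids, experiment_ids, values = _parse_square_tsv(path)
    if len(set(experiment_ids)) != len(experiment_ids):
        raise FormatError(f"{path}: duplicate experiment ids in header")
    return FitnessMatrix.from_arrays(gene_ids, experiment_ids, values)


def write_fitness_matrix(fm: FitnessMatrix, path) -> None:
    _write_square(fm.data, path, index_name="gene")


def read_similarity_matrix(path, method: str = "unknown") -> SimilarityMatrix:
    row_ids, column_ids, values = _parse_square_tsv(path)
    if row_ids != column_ids:
        raise FormatError(f"{path}: similarity matrix row/column ids differ")
    frame = pd.DataFrame(values, index=pd.Index(row_ids), columns=pd.Index(column_ids))
    return SimilarityMatrix(data=frame, method=method, normalized=False)


def write_similarity_matrix(sim: SimilarityMatrix, path) -> None:
    _write_square(sim.data, path, index_name="experiment")


def _write_square(frame: pd.DataFrame, path, index_name: str) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([index_name, *map(str, frame.columns)])
        for rid, row in zip(frame.index, frame.to_numpy()):
            writer.writerow(
                [str(rid)] + ["" if np.isnan(v) else repr(float(v)) for v in row]
            )


def read_metadata(path) -> ExperimentMetadata:
    """Read a metadata TSV with an ``experiment_id`` column."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "experiment_id" not in table.columns:
        raise FormatError(f"{path}: missing required column 'experiment_id'")
    table = table.set_index("experiment_id")
    if table.index.has_duplicates:
        raise FormatError(f"{path}: duplicate experiment ids")
    return ExperimentMetadata(table)


def write_metadata(meta: ExperimentMetadata, path) -> None:
    meta.table.reset_index(names="experiment_id").to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
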