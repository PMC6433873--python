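"""Data model and tabular I/O for time-course expression analysis.

The central container is :class:`ExpressionMatrix`: a genes × samples table
of normalized log2 intensities together with a sample sheet annotating each
column with condition (``treated``/``control``), timepoint in minutes and
replicate number.  All downstream statistics consume this container.

Reference gene tables from the source study (cell-wall genes, ABA
biosynthesis/signaling genes, uniquely identified early-induced genes) ship
with the package as TSV fixtures and load through
:func:`load_fixture_table`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("treated", "control")

#: Names of the packaged printed-table fixtures.
FIXTURE_TABLES = ("table1_cellwall", "table2_aba", "table3_early")


class FormatError(ValueError):
    """A file violates the expected tabular format."""


class ConsistencyError(ValueError):
    """Matrix and sample sheet disagree (missing/extra samples, etc.)."""


@dataclass(frozen=True)
class SampleInfo:
    """Annotation of one array/sample column."""

    sample_id: str
    condition: str
    timepoint_min: int
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.timepoint_min < 0:
            raise ValueError("timepoint_min must be non-negative")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


class ExpressionMatrix:
    """Genes × samples log2 expression with per-sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id; all
        entries must be finite (no missing values after loading).
    samples
        List of :class:`SampleInfo`, one per column of ``values``, in
        column order.
    """

    def __init__(self, values: pd.DataFrame, samples: list[SampleInfo]):
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene id(s): {dupes}")
        sample_ids = [s.sample_id for s in samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ConsistencyError("duplicate sample ids in sample sheet")
        if list(values.columns) != sample_ids:
            missing = set(sample_ids) - set(values.columns)
            extra = set(values.columns) - set(sample_ids)
            if missing or extra:
                raise ConsistencyError(
                    f"matrix/sample-sheet mismatch: missing={sorted(missing)} "
                    f"extra={sorted(extra)}"
                )
            values = values[sample_ids]
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric cell(s) in expression matrix")
        if not np.isfinite(arr).all():
            raise FormatError("non-finite value(s) in expression matrix")
        triples = [(s.condition, s.timepoint_min, s.replicate) for s in samples]
        if len(set(triples)) != len(triples):
            raise ConsistencyError(
                "duplicate (condition, timepoint, replicate) triple in sample sheet"
            )
        self.values = values.astype(float)
        self.samples = list(samples)

    # -- convenience accessors -------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def sample_frame(self) -> pd.DataFrame:
        """Sample sheet as a DataFrame indexed by sample_id."""
        return pd.DataFrame(
            {
                "condition": [s.condition for s in self.samples],
                "timepoint_min": [s.timepoint_min for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            },
            index=pd.Index([s.sample_id for s in self.samples], name="sample_id"),
        )

    def timepoints(self, condition: str | None = None) -> list[int]:
        """Sorted distinct timepoints, optionally restricted to a condition."""
        tps = {
            s.timepoint_min
            for s in self.samples
            if condition is None or s.condition == condition
        }
        return sorted(tps)

    def group_columns(self, condition: str, timepoint_min: int) -> list[str]:
        """Sample ids of one (condition, timepoint) replicate group."""
        return [
            s.sample_id
            for s in self.samples
            if s.condition == condition and s.timepoint_min == timepoint_min
        ]

    def group_values(self, condition: str, timepoint_min: int) -> pd.DataFrame:
        cols = self.group_columns(condition, timepoint_min)
        if not cols:
            raise ConsistencyError(f"no samples for ({condition}, {timepoint_min})")
        return self.values[cols]

    def group_keys(self) -> list[tuple[str, int]]:
        """All distinct (condition, timepoint) groups in canonical order.

        Canonical order: control before treated, timepoints ascending — the
        pair ordering used by association profiles downstream.
        """
        keys = sorted(
            {(s.condition, s.timepoint_min) for s in self.samples},
            key=lambda k: (k[0] != "control", k[1]),
        )
        return keys

    def group_means(self) -> pd.DataFrame:
        """Genes × groups mean expression; columns labelled 'cond:tp'."""
        data = {
            f"{c}:{t}": self.group_values(c, t).mean(axis=1)
            for c, t in self.group_keys()
        }
        return pd.DataFrame(data, index=self.gene_ids)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpressionMatrix({self.n_genes} genes × {len(self.samples)} samples)"
        )


@dataclass
class PipelineConfig:
    """Thresholds and knobs shared across pipeline stages.

    Defaults follow the study design: pairwise calls at q ≤ 0.05,
    time-course calls at q < 0.001, ranked gene subsets of 50–500 genes,
    and a cubic (degree-3) polynomial for the time-course fit.
    """

    q_cutoff_pairwise: float = 0.05
    q_cutoff_timecourse: float = 0.001
    subset_min: int = 50
    subset_max: int = 500
    poly_degree_max: int = 3
    mi_bins: int | None = None  # None → max(4, floor(sqrt(subset size)))
    rng_seed: int = 0
    fdr_method_timecourse: str = "storey"

    def __post_init__(self) -> None:
        for name in ("q_cutoff_pairwise", "q_cutoff_timecourse"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")
        if self.subset_min > self.subset_max:
            raise ValueError("subset_min must not exceed subset_max")
        if self.poly_degree_max < 1:
            raise ValueError("poly_degree_max must be ≥ 1")
        if self.fdr_method_timecourse not in ("storey", "bh"):
            raise ValueError("fdr_method_timecourse must be 'storey' or 'bh'")


@dataclass
class PrintedGeneTable:
    """A reference gene table with per-timepoint signed fold changes.

    ``frame`` has columns ``gene_id``, ``annotation``, ``fc_30``, ``fc_60``,
    ``fc_180`` (floats; NaN encodes an absent call, printed as "–") and,
    for the biosynthesis/signaling table, ``section``.  Signed fold changes
    use the negative-reciprocal convention and therefore never fall in the
    open interval (−1, 1).
    """

    name: str
    frame: pd.DataFrame

    FC_COLUMNS = ("fc_30", "fc_60", "fc_180")

    def __post_init__(self) -> None:
        fcs = self.frame[list(self.FC_COLUMNS)].to_numpy(dtype=float)
        bad = (np.abs(fcs) < 1) & ~np.isnan(fcs)
        if bad.any():
            raise FormatError(
                f"{self.name}: signed fold changes in (−1, 1) are invalid"
            )

    def __len__(self) -> int:
        return len(self.frame)


def read_expression(matrix_path: str | Path, samplesheet_path: str | Path,
                    impute_missing: bool = False) -> ExpressionMatrix:
    """Load an expression matrix TSV and its sample sheet.

    The matrix is tab-delimited with header ``gene_id<TAB>sample...``; the
    sample sheet has columns ``sample_id, condition, timepoint_min,
    replicate``.  Sample order is taken from the sheet.  Missing values are
    rejected unless ``impute_missing`` is set, in which case per-gene mean
    imputation is applied (and logged).
    """
    try:
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(str(exc)) from exc
    values.index = values.index.astype(str)
    if values.index.has_duplicates:
        dupes = values.index[values.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene id(s): {dupes}")
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in expression matrix: {exc}") from exc

    sheet = pd.read_csv(samplesheet_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "condition", "timepoint_min", "replicate"}
    if not required.issubset(sheet.columns):
        raise FormatError(
            f"sample sheet must have columns {sorted(required)}"
        )
    samples = [
        SampleInfo(
            sample_id=row.sample_id,
            condition=row.condition,
            timepoint_min=int(row.timepoint_min),
            replicate=int(row.replicate),
        )
        for row in sheet.itertuples()
    ]
    if values.isna().to_numpy().any():
        if not impute_missing:
            raise FormatError(
                "missing values in expression matrix (pass impute_missing=True "
                "for per-gene mean imputation)"
            )
        n_missing = int(values.isna().to_numpy().sum())
        logger.warning("imputing %d missing cells with per-gene means", n_missing)
        values = values.apply(lambda r: r.fillna(r.mean()), axis=1)
    return ExpressionMatrix(values, samples)


def write_expression(matrix: ExpressionMatrix, matrix_path: str | Path,
                     samplesheet_path: str | Path) -> None:
    """Write matrix and sample sheet as tab-delimited UTF-8 files."""
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t")
    matrix.sample_frame.to_csv(samplesheet_path, sep="\t")


def read_gene_set(path: str | Path) -> set[str]:
    """Read a gene set: one id per line; blanks and '#' comments ignored."""
    genes: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(line)
    if not genes:
        logger.warning("gene set file %s contained no identifiers", path)
    return genes


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(set(genes)):
            fh.write(f"{g}\n")


def load_fixture_table(name: str) -> PrintedGeneTable:
    """Load one of the packaged reference gene tables.

    ``table1_cellwall``: 6 cell-wall related regulated genes.
    ``table2_aba``: ABA biosynthesis / core regulatory / signaling genes
    (extra ``section`` column).  ``table3_early``: the 16 uniquely
    identified early-induced genes.
    """
    if name not in FIXTURE_TABLES:
        raise KeyError(
            f"unknown fixture table {name!r}; available: {FIXTURE_TABLES}"
        )
    ref = resources.files("abatime") / "data" / "tables" / f"{name}.tsv"
    na = {col: ["-"] for col in PrintedGeneTable.FC_COLUMNS}
    with resources.as_file(ref) as path:
        frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, na_values=na,
                            keep_default_na=False)
    for col in PrintedGeneTable.FC_COLUMNS:
        frame[col] = pd.to_numeric(frame[col])
    return PrintedGeneTable(name=name, frame=frame)
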