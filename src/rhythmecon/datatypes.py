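"""Core in-memory containers shared across the pipeline stages.

The pipeline works on ordinary pandas objects wherever possible; the
dataclasses here only add the metadata that plain DataFrames cannot carry
(sample times, replicate labels, expression level, cell-type labels) plus
validation of the structural invariants every downstream stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTimeSeries",
    "SingleCellMatrix",
    "AACostTable",
    "ProteinRecord",
    "ComparisonResult",
    "STANDARD_AA",
]

#: the 20 standard one-letter amino-acid codes
STANDARD_AA = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ExpressionTimeSeries:
    """A gene x sample abundance matrix with per-sample time metadata.

    Parameters
    ----------
    values
        Non-negative abundance matrix, genes as rows, samples as columns.
        Missing measurements are NaN and are tolerated (rhythm detectors
        omit them per gene).
    time_h
        Sampling time in hours for each column of ``values``.
    replicate
        Biological replicate label per sample. Replicates are treated as
        additional cycles by the detectors, not averaged.
    level
        ``"mRNA"`` or ``"protein"``.
    tissue
        Optional tissue label for multi-tissue analyses.
    """

    values: pd.DataFrame
    time_h: pd.Series
    replicate: pd.Series
    level: str = "mRNA"
    tissue: str | None = None

    def __post_init__(self) -> None:
        if self.level not in ("mRNA", "protein"):
            raise ValueError(f"level must be 'mRNA' or 'protein', got {self.level!r}")
        self.time_h = pd.Series(self.time_h, dtype=float)
        self.replicate = pd.Series(self.replicate)
        if not self.values.columns.equals(self.time_h.index):
            self.time_h.index = self.values.columns[: len(self.time_h)]
        if len(self.time_h) != self.values.shape[1]:
            raise ValueError(
                f"{self.values.shape[1]} samples but {len(self.time_h)} time values"
            )
        if len(self.replicate) != self.values.shape[1]:
            raise ValueError("replicate labels do not match the number of samples")
        self.replicate.index = self.values.columns
        if not np.isfinite(self.time_h.to_numpy()).all():
            raise ValueError("every sample needs a finite time_h")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() < 0).any():
                raise ValueError("abundances must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def sorted_by_sample(self) -> "ExpressionTimeSeries":
        """Return a copy with samples ordered by (replicate, time)."""
        order = sorted(
            range(self.values.shape[1]),
            key=lambda i: (str(self.replicate.iloc[i]), self.time_h.iloc[i]),
        )
        cols = self.values.columns[order]
        return ExpressionTimeSeries(
            values=self.values[cols],
            time_h=self.time_h[cols],
            replicate=self.replicate[cols],
            level=self.level,
            tissue=self.tissue,
        )


@dataclass
class SingleCellMatrix:
    """Gene x cell expression matrix (counts or FPKM-like) with cell types."""

    values: pd.DataFrame
    cell_types: pd.Series
    tissue: str | None = None

    def __post_init__(self) -> None:
        self.cell_types = pd.Series(self.cell_types)
        if len(self.cell_types) != self.values.shape[1]:
            raise ValueError("cell_types must label every cell (column)")
        self.cell_types.index = self.values.columns
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class AACostTable:
    """Per-amino-acid biosynthetic cost, in high-energy phosphate bonds."""

    costs: dict[str, float]
    source: str = "custom"

    def __post_init__(self) -> None:
        missing = set(STANDARD_AA) - set(self.costs)
        extra = set(self.costs) - set(STANDARD_AA)
        if missing or extra:
            raise ValueError(
                f"cost table must cover exactly the 20 standard codes; "
                f"missing={sorted(missing)}, extra={sorted(extra)}"
            )
        if any(c <= 0 for c in self.costs.values()):
            raise ValueError("all amino-acid costs must be positive")

    def __getitem__(self, aa: str) -> float:
        return self.costs[aa]

    def as_series(self) -> pd.Series:
        return pd.Series(self.costs, dtype=float).loc[list(STANDARD_AA)]


@dataclass
class ProteinRecord:
    """A protein sequence; length counts every residue including ambiguity codes."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.protein_id}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ComparisonResult:
    """Outcome of a two-group location test (Welch by default).

    ``direction`` is ``"group1_lower"`` / ``"group1_higher"`` depending on the
    group means; group 1 is the rhythmic (or set-A) group throughout.
    """

    category: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    statistic: float
    df: float
    pvalue: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    controlled: bool = False
    test: str = "welch"
    group_labels: tuple[str, str] = field(default=("group1", "group2"))

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0 or np.isnan(self.pvalue)):
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")

    @property
    def direction(self) -> str:
        return "group1_lower" if self.mean1 < self.mean2 else "group1_higher"

    def as_dict(self) -> dict:
        return {
            "category": self.category,
            "n1": self.n1,
            "n2": self.n2,
            "mean1": self.mean1,
            "mean2": self.mean2,
            "statistic": self.statistic,
            "df": self.df,
            "pvalue": self.pvalue,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "controlled": self.controlled,
            "test": self.test,
            "direction": self.direction,
        }
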