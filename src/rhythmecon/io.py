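"""Readers, writers, and pre-processing filters for every external format.

Formats: TSV expression matrices (genes as rows, header row of sample ids)
with a sample metadata TSV; FASTA protein sequences; per-amino-acid cost
tables (builtin "wagner" / "akashi_gojobori" or a custom TSV); single-cell
matrices as dense TSV or MatrixMarket MTX triplets; gene -> dN/dS TSV.
Gzip transparency comes from pandas/Biopython themselves.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import io as scipy_io
from scipy import sparse

from .datatypes import STANDARD_AA, AACostTable, ExpressionTimeSeries, ProteinRecord, SingleCellMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "preprocess",
    "read_fasta",
    "write_fasta",
    "read_aacost",
    "BUILTIN_AA_COSTS",
    "read_single_cell",
    "write_single_cell_mtx",
    "read_dnds",
    "write_dnds",
    "filter_cell_types",
]

#: Biosynthetic cost per amino acid, high-energy phosphate bonds per molecule.
#: "wagner": aerobic-respiration opportunity costs (yeast/E. coli accounting);
#: "akashi_gojobori": E. coli chemostat-based estimates. The two scales are
#: strongly linearly related, so analyses are robust to the choice.
BUILTIN_AA_COSTS: dict[str, dict[str, float]] = {
    "wagner": {
        "A": 14.5, "R": 20.5, "N": 18.5, "D": 15.5, "C": 26.5,
        "E": 9.5, "Q": 10.5, "G": 14.5, "H": 29.0, "I": 38.0,
        "L": 37.0, "K": 36.0, "M": 36.5, "F": 61.0, "P": 14.5,
        "S": 14.5, "T": 21.5, "W": 75.5, "Y": 59.0, "V": 29.0,
    },
    "akashi_gojobori": {
        "A": 11.7, "R": 27.3, "N": 14.7, "D": 12.7, "C": 24.7,
        "E": 15.3, "Q": 16.3, "G": 11.7, "H": 38.3, "I": 32.3,
        "L": 27.3, "K": 30.3, "M": 34.3, "F": 52.0, "P": 20.3,
        "S": 11.7, "T": 18.7, "W": 74.3, "Y": 50.0, "V": 23.3,
    },
}

_NA_VALUES = ["", "NA", "NaN", "nan"]


def read_expression_tsv(
    path: str | Path,
    metadata_path: str | Path,
    level: str = "mRNA",
    tissue: str | None = None,
) -> ExpressionTimeSeries:
    """Load an expression matrix TSV plus its sample metadata TSV.

    The metadata table must have columns ``sample``, ``time_h``, and
    ``replicate`` covering every sample column of the matrix. Samples are
    returned ordered by (replicate, time).
    """
    mat = pd.read_csv(path, sep="\t", index_col=0, na_values=_NA_VALUES)
    bad = [c for c in mat.columns if not pd.api.types.is_numeric_dtype(mat[c])]
    if bad:
        raise ValueError(f"non-numeric expression columns: {bad}")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample": str})
    for col in ("sample", "time_h", "replicate"):
        if col not in meta.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    if meta["sample"].duplicated().any():
        dups = meta.loc[meta["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    meta = meta.set_index("sample")
    missing = [s for s in mat.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    meta = meta.loc[mat.columns]
    ts = ExpressionTimeSeries(
        values=mat,
        time_h=meta["time_h"].astype(float),
        replicate=meta["replicate"],
        level=level,
        tissue=tissue,
    )
    return ts.sorted_by_sample()


def write_expression_tsv(
    ts: ExpressionTimeSeries, path: str | Path, metadata_path: str | Path
) -> None:
    ts.values.to_csv(path, sep="\t", index_label="gene_id")
    meta = pd.DataFrame(
        {"sample": ts.sample_ids, "time_h": ts.time_h.values, "replicate": ts.replicate.values}
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def preprocess(
    ts: ExpressionTimeSeries,
    id_map: pd.DataFrame | None = None,
    max_missing: int = 7,
    biotype_col: str = "biotype",
    keep_biotype: str = "protein_coding",
) -> ExpressionTimeSeries:
    """Apply the standard row filters before rhythm detection.

    * probes assigned to several genes are removed (ambiguous identity);
    * rows with more than ``max_missing`` missing values are removed
      (remaining NaNs are left in place for the detectors to omit);
    * if ``id_map`` carries a biotype column, non-protein-coding rows are
      removed;
    * probe ids are mapped to gene ids; several probes may map to the same
      gene (they are combined later by Brown's method). Ids absent from the
      map pass through unchanged, which makes the operation idempotent.
    """
    values = ts.values
    if id_map is not None:
        if not {"probe", "gene"} <= set(id_map.columns):
            raise ValueError("id_map needs 'probe' and 'gene' columns")
        counts = id_map.groupby("probe")["gene"].nunique()
        multi = set(counts[counts > 1].index)
        if multi:
            dropped = values.index.intersection(multi)
            if len(dropped):
                logger.info("dropping %d probes mapped to several genes", len(dropped))
            values = values.loc[~values.index.isin(multi)]
        unique_map = id_map[~id_map["probe"].isin(multi)].drop_duplicates("probe")
        unique_map = unique_map.set_index("probe")
        if biotype_col in unique_map.columns:
            noncoding = unique_map.index[unique_map[biotype_col] != keep_biotype]
            values = values.loc[~values.index.isin(noncoding)]
        renames = unique_map["gene"].to_dict()
        values = values.rename(index=lambda p: renames.get(p, p))
    n_missing = values.isna().sum(axis=1)
    kept = n_missing <= max_missing
    if (~kept).any():
        logger.info("dropping %d rows with > %d missing values", int((~kept).sum()), max_missing)
    values = values.loc[kept]
    if values.empty:
        logger.warning("preprocessing removed every row")
    return ExpressionTimeSeries(
        values=values,
        time_h=ts.time_h,
        replicate=ts.replicate,
        level=ts.level,
        tissue=ts.tissue,
    )


# -- protein sequences --------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        records = [ProteinRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def read_aacost(source: str | Path) -> AACostTable:
    """Load a builtin cost table by name, or a custom 2-column TSV (aa, cost)."""
    if isinstance(source, str) and source in BUILTIN_AA_COSTS:
        return AACostTable(costs=dict(BUILTIN_AA_COSTS[source]), source=source)
    tab = pd.read_csv(source, sep="\t")
    if tab.shape[1] < 2:
        raise ValueError("custom cost table needs columns (aa, cost)")
    aa_col, cost_col = tab.columns[:2]
    costs = dict(zip(tab[aa_col].astype(str).str.upper(), tab[cost_col].astype(float)))
    return AACostTable(costs=costs, source="custom")


# -- single cell ---------------------------------------------------------------

def read_single_cell(
    path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    tissue: str | None = None,
) -> SingleCellMatrix:
    """Read a gene x cell matrix from dense TSV or an MTX triplet.

    For MTX, ``genes_path`` is a one-column (or headered ``gene_id``) TSV and
    ``cells_path`` a TSV with columns ``cell_id`` and ``cell_type``.
    For TSV, cell types default to a single pooled type unless ``cells_path``
    is given.
    """
    path = Path(path)
    if path.suffix == ".mtx" or path.suffixes[-2:] == [".mtx", ".gz"]:
        if genes_path is None or cells_path is None:
            raise ValueError("MTX input requires genes and cells sidecar files")
        mat = scipy_io.mmread(path)
        genes = pd.read_csv(genes_path, sep="\t")
        gene_ids = genes.iloc[:, 0].astype(str).tolist()
        cells = pd.read_csv(cells_path, sep="\t")
        cell_ids = cells.iloc[:, 0].astype(str).tolist()
        dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
        if dense.shape != (len(gene_ids), len(cell_ids)):
            raise ValueError(
                f"MTX shape {dense.shape} does not match sidecars "
                f"({len(gene_ids)} genes, {len(cell_ids)} cells)"
            )
        values = pd.DataFrame(dense, index=gene_ids, columns=cell_ids)
        ctype = (
            cells["cell_type"].astype(str).values
            if "cell_type" in cells.columns
            else np.repeat("pooled", len(cell_ids))
        )
        return SingleCellMatrix(values=values, cell_types=pd.Series(ctype, index=cell_ids), tissue=tissue)
    values = pd.read_csv(path, sep="\t", index_col=0, na_values=_NA_VALUES)
    if cells_path is not None:
        cells = pd.read_csv(cells_path, sep="\t")
        cells = cells.set_index(cells.columns[0])
        ctype = cells.loc[values.columns, "cell_type"].astype(str)
    else:
        ctype = pd.Series("pooled", index=values.columns)
    return SingleCellMatrix(values=values, cell_types=ctype, tissue=tissue)


def write_single_cell_mtx(
    sc: SingleCellMatrix,
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    scipy_io.mmwrite(str(mtx_path), sparse.coo_matrix(sc.values.to_numpy()))
    pd.DataFrame({"gene_id": sc.gene_ids}).to_csv(genes_path, sep="\t", index=False)
    pd.DataFrame({"cell_id": sc.cell_ids, "cell_type": sc.cell_types.values}).to_csv(
        cells_path, sep="\t", index=False
    )


def filter_cell_types(sc: SingleCellMatrix, min_cells: int = 100) -> SingleCellMatrix:
    """Keep only cell types represented by at least ``min_cells`` cells."""
    counts = sc.cell_types.value_counts()
    keep_types = counts[counts >= min_cells].index
    mask = sc.cell_types.isin(keep_types)
    if not mask.any():
        raise ValueError(
            f"no cell type has >= {min_cells} cells (largest: {counts.max() if len(counts) else 0})"
        )
    return SingleCellMatrix(
        values=sc.values.loc[:, mask],
        cell_types=sc.cell_types[mask],
        tissue=sc.tissue,
    )


# -- dN/dS ---------------------------------------------------------------------

def read_dnds(path: str | Path) -> pd.Series:
    """Gene -> dN/dS table. Multiple entries per gene are collapsed by median."""
    tab = pd.read_csv(path, sep="\t", na_values=_NA_VALUES)
    if tab.shape[1] < 2:
        raise ValueError("dN/dS table needs columns (gene_id, dnds)")
    gene_col, val_col = tab.columns[:2]
    tab = tab.dropna(subset=[val_col])
    vals = tab.groupby(gene_col)[val_col].median().astype(float)
    if (vals < 0).any():
        raise ValueError("negative dN/dS values")
    vals.name = "dnds"
    return vals


def write_dnds(dnds: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"gene_id": dnds.index, "dnds": dnds.values}).to_csv(path, sep="\t", index=False)
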