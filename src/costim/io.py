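"""Readers and writers for all on-disk formats.

No science happens here: readers validate structure and never rescale or
otherwise mutate numeric values; every normalization is an explicit,
logged pipeline stage.

Formats
-------
bulk counts      TSV/CSV, gene identifiers in the first column, sample ids
                 in the header.
design           TSV/CSV with columns sample_id, patient_id, condition,
                 replicate.
NPX              CSV with columns protein_id, panel_id, sample_id,
                 condition, replicate, npx.
single cell      MatrixMarket triplet (genes in rows, the CellRanger
                 convention; transposed to cells x genes on load) plus
                 features/barcodes files with one identifier per line —
                 or a dense TSV laid out like the bulk matrix (genes in
                 rows, barcodes in the header).
sample tags      TSV, cells x tags, barcode in the first column, tag names
                 in the header.
marker panel     TSV with columns cell_type, role (positive | exclusion),
                 gene.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import (
    BulkExperiment,
    CellExperiment,
    FormatError,
    MarkerPanel,
    NPXTable,
)

logger = logging.getLogger(__name__)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def _read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        return pd.read_csv(path, sep=_sep_for(path), index_col=index_col)
    except Exception as exc:  # malformed CSV/TSV
        raise FormatError(f"could not parse {path.name}: {exc}") from exc


def read_bulk_experiment(counts_path: str | Path, design_path: str | Path) -> BulkExperiment:
    """Load a gene x sample count matrix and its design table.

    Sample order is harmonized between the two files; mismatched sample
    sets raise a :class:`FormatError` naming the offending identifiers.
    """
    counts = _read_table(counts_path, index_col=0)
    counts.index = counts.index.astype(str)
    design = _read_table(design_path)
    exp = BulkExperiment(counts=counts, design=design)
    logger.info(
        "read bulk experiment: %d genes x %d samples from %s",
        len(exp.genes), len(exp.samples), Path(counts_path).name,
    )
    return exp


def write_bulk_experiment(exp: BulkExperiment, counts_path: str | Path, design_path: str | Path) -> None:
    counts_path, design_path = Path(counts_path), Path(design_path)
    exp.counts.rename_axis("gene").to_csv(counts_path, sep=_sep_for(counts_path))
    exp.design.to_csv(design_path, sep=_sep_for(design_path), index=False)


def read_npx_table(path: str | Path) -> NPXTable:
    """Load a long-format NPX table (CSV)."""
    table = NPXTable(records=_read_table(path))
    logger.info("read NPX table: %d records from %s", len(table), Path(path).name)
    return table


def write_npx_table(table: NPXTable, path: str | Path) -> None:
    path = Path(path)
    table.records.to_csv(path, sep=_sep_for(path), index=False)


def _read_id_list(path: str | Path) -> list[str]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if not ids:
        raise FormatError(f"{path.name} contains no identifiers")
    return ids


def read_cell_experiment(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    tags_path: str | Path,
) -> CellExperiment:
    """Load targeted single-cell counts plus the per-cell sample-tag matrix.

    ``matrix_path`` may be MatrixMarket (``.mtx``, genes in rows) or a dense
    TSV in the same orientation; either way the in-memory matrix is
    cells x genes.
    """
    matrix_path = Path(matrix_path)
    genes = _read_id_list(features_path)
    barcodes = _read_id_list(barcodes_path)

    if matrix_path.suffix.lower() == ".mtx":
        try:
            mat = scipy.io.mmread(matrix_path)
        except Exception as exc:
            raise FormatError(f"could not parse {matrix_path.name}: {exc}") from exc
        mat = sp.csr_matrix(mat)
        if mat.shape != (len(genes), len(barcodes)):
            raise FormatError(
                f"{matrix_path.name} is {mat.shape[0]} x {mat.shape[1]} but "
                f"{len(genes)} features and {len(barcodes)} barcodes were supplied"
            )
        counts = mat.T.tocsr()
    else:
        dense = _read_table(matrix_path, index_col=0)
        if dense.shape != (len(genes), len(barcodes)):
            raise FormatError(
                f"{matrix_path.name} is {dense.shape[0]} x {dense.shape[1]} but "
                f"{len(genes)} features and {len(barcodes)} barcodes were supplied"
            )
        if list(dense.index.astype(str)) != genes:
            raise FormatError(f"{matrix_path.name} row ids do not match the features file")
        if [str(c) for c in dense.columns] != barcodes:
            raise FormatError(f"{matrix_path.name} column ids do not match the barcodes file")
        counts = sp.csr_matrix(dense.to_numpy().T)

    tags = _read_table(tags_path, index_col=0)
    tags.index = tags.index.astype(str)
    if list(tags.index) != barcodes:
        raise FormatError(
            f"{Path(tags_path).name} barcodes do not match the barcodes file "
            f"({len(tags)} rows for {len(barcodes)} barcodes)"
        )
    ce = CellExperiment.from_arrays(
        counts=counts, barcodes=barcodes, genes=genes, tag_counts=tags
    )
    logger.info(
        "read cell experiment: %d cells x %d genes, %d sample tags",
        ce.n_cells, ce.n_genes, tags.shape[1],
    )
    return ce


def write_cell_experiment(ce: CellExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write matrix.mtx (genes in rows) + features/barcodes/tags files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "features": outdir / "features.tsv",
        "barcodes": outdir / "barcodes.tsv",
        "tags": outdir / "tags.tsv",
    }
    scipy.io.mmwrite(paths["matrix"], sp.coo_matrix(ce.counts.T), field="integer")
    paths["features"].write_text("\n".join(ce.genes) + "\n")
    paths["barcodes"].write_text("\n".join(ce.cells) + "\n")
    ce.tag_counts.rename_axis("barcode").to_csv(paths["tags"], sep="\t")
    return paths


def read_marker_panel(path: str | Path) -> MarkerPanel:
    """Load a marker panel TSV (cell_type, role in {positive, exclusion}, gene)."""
    table = _read_table(path)
    required = {"cell_type", "role", "gene"}
    if not required.issubset(table.columns):
        raise FormatError(
            f"marker panel needs columns {sorted(required)}, got {list(table.columns)}"
        )
    bad_roles = sorted(set(table["role"]) - {"positive", "exclusion"})
    if bad_roles:
        raise FormatError(f"unknown marker roles {bad_roles}")
    positive: dict[str, list[str]] = {}
    exclusion: dict[str, list[str]] = {}
    for row in table.itertuples(index=False):
        target = positive if row.role == "positive" else exclusion
        target.setdefault(str(row.cell_type), []).append(str(row.gene))
    return MarkerPanel(positive=positive, exclusion=exclusion)


def write_marker_panel(panel: MarkerPanel, path: str | Path) -> None:
    rows = [
        {"cell_type": t, "role": role, "gene": g}
        for role, mapping in (("positive", panel.positive), ("exclusion", panel.exclusion))
        for t, genes in mapping.items()
        for g in genes
    ]
    pd.DataFrame(rows, columns=["cell_type", "role", "gene"]).to_csv(
        Path(path), sep="\t", index=False
    )


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write an output table as TSV with a header row."""
    frame.to_csv(Path(path), sep="\t", index=index)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
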