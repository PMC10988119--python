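"""Shared domain containers for the co-stimulation synergy pipelines.

Every experiment analysed here follows the same two-factor layout: samples
(or conditioned-medium replicates, or single-cell source donors) receive one
of four treatments — untreated ``control``, IL-17A alone, TNF alone, or the
``combo`` of both cytokines.  The containers below validate that structure
once, at construction, so the analysis stages can assume it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

CONDITIONS = ("control", "IL17A", "TNF", "combo")
TREATMENTS = ("IL17A", "TNF", "combo")

DESIGN_COLUMNS = ("sample_id", "patient_id", "condition", "replicate")
NPX_COLUMNS = ("protein_id", "panel_id", "sample_id", "condition", "replicate", "npx")


class CostimError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(CostimError, ValueError):
    """An in-memory object violates one of its documented invariants."""


class FormatError(CostimError, ValueError):
    """An on-disk input cannot be interpreted as the expected format."""


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample design table.

    Required columns: ``sample_id, patient_id, condition, replicate``.
    Conditions must be drawn from ``control/IL17A/TNF/combo``; each
    (patient, condition, replicate) triple may appear at most once, and any
    patient with a treated sample must also have a control sample.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise FormatError(f"design table lacks required columns: {missing}")
    design = design.loc[:, list(DESIGN_COLUMNS)].copy()
    design["sample_id"] = design["sample_id"].astype(str)
    design["patient_id"] = design["patient_id"].astype(str)
    design["condition"] = design["condition"].astype(str)
    design["replicate"] = design["replicate"].astype(int)

    bad = sorted(set(design["condition"]) - set(CONDITIONS))
    if bad:
        raise ValidationError(f"unknown conditions {bad}; expected one of {CONDITIONS}")
    if (design["replicate"] < 1).any():
        raise ValidationError("replicate indices must be >= 1")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicated sample_id(s): {dup}")
    key = design[["patient_id", "condition", "replicate"]]
    if key.duplicated().any():
        dup = key.loc[key.duplicated()].to_records(index=False).tolist()
        raise ValidationError(
            f"duplicated (patient, condition, replicate) combination(s): {dup}"
        )
    treated = design.loc[design["condition"] != "control", "patient_id"]
    with_control = set(design.loc[design["condition"] == "control", "patient_id"])
    orphans = sorted(set(treated) - with_control)
    if orphans:
        raise ValidationError(
            f"patients with treated samples but no control sample: {orphans}"
        )
    return design.reset_index(drop=True)


@dataclass
class BulkExperiment:
    """A gene x sample raw count matrix bound to its treatment design.

    ``counts`` is indexed by gene identifier with one column per sample; the
    column order is harmonized with ``design`` at construction.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.design = validate_design(self.design)
        mat_samples = [str(c) for c in self.counts.columns]
        self.counts.columns = mat_samples
        design_samples = list(self.design["sample_id"])
        missing_in_design = sorted(set(mat_samples) - set(design_samples))
        if missing_in_design:
            raise FormatError(
                f"samples present in count matrix but absent from design: {missing_in_design}"
            )
        missing_in_matrix = sorted(set(design_samples) - set(mat_samples))
        if missing_in_matrix:
            raise FormatError(
                f"samples present in design but absent from count matrix: {missing_in_matrix}"
            )
        # harmonize sample order to the design
        self.counts = self.counts.loc[:, design_samples]
        values = self.counts.to_numpy()
        if not np.isfinite(values).all():
            raise ValidationError("counts contain non-finite values")
        if (values < 0).any():
            raise ValidationError("counts must be non-negative")
        if not np.array_equal(values, np.round(values)):
            raise ValidationError("counts must be integral")
        self.counts = self.counts.astype(np.int64)
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicated gene identifier(s): {dup}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, patient_id: str, condition: str) -> list[str]:
        mask = (self.design["patient_id"] == patient_id) & (
            self.design["condition"] == condition
        )
        return list(self.design.loc[mask, "sample_id"])

    @property
    def patients(self) -> list[str]:
        return list(dict.fromkeys(self.design["patient_id"]))


@dataclass
class NPXTable:
    """Long-format Olink-style NPX measurements.

    One record per (protein, panel, sample); NPX is a log2-scale arbitrary
    unit, so differences between conditions are log2 fold changes.  The same
    protein may legitimately appear on several panels — merging duplicate
    assays is an explicit downstream step, not an I/O side effect.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in NPX_COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"NPX table lacks required columns: {missing}")
        rec = self.records.loc[:, list(NPX_COLUMNS)].copy()
        for col in ("protein_id", "panel_id", "sample_id", "condition"):
            rec[col] = rec[col].astype(str)
        rec["replicate"] = rec["replicate"].astype(int)
        rec["npx"] = rec["npx"].astype(float)
        bad = sorted(set(rec["condition"]) - set(CONDITIONS))
        if bad:
            raise ValidationError(f"unknown conditions {bad}; expected one of {CONDITIONS}")
        if not np.isfinite(rec["npx"]).all():
            n = int((~np.isfinite(rec["npx"])).sum())
            raise ValidationError(f"{n} non-finite NPX value(s)")
        key = rec[["protein_id", "panel_id", "sample_id"]]
        if key.duplicated().any():
            dup = key.loc[key.duplicated()].to_records(index=False).tolist()
            raise ValidationError(f"duplicated (protein, panel, sample) record(s): {dup}")
        self.records = rec.reset_index(drop=True)

    @property
    def proteins(self) -> list[str]:
        return sorted(self.records["protein_id"].unique())

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class CellExperiment:
    """Targeted single-cell counts plus per-cell sample-tag counts.

    Wraps an :class:`anndata.AnnData` (cells x genes, sparse counts in
    ``.X``) with the tag-count matrix in ``.obsm["tag_counts"]`` as a
    DataFrame whose columns are tag names.  Per-cell annotations filled in
    by the pipeline stages live in ``.obs``: ``source_sample`` (after
    demultiplexing), ``cluster`` and ``cell_type`` (after clustering and
    annotation).
    """

    adata: AnnData

    def __post_init__(self) -> None:
        if "tag_counts" not in self.adata.obsm:
            raise ValidationError("CellExperiment requires obsm['tag_counts']")
        tags = self.adata.obsm["tag_counts"]
        if not isinstance(tags, pd.DataFrame):
            raise ValidationError("obsm['tag_counts'] must be a DataFrame keyed by tag name")
        if not sp.issparse(self.adata.X):
            self.adata.X = sp.csr_matrix(self.adata.X)
        X = self.adata.X
        if X.data.size and (X.data < 0).any():
            raise ValidationError("cell counts must be non-negative")
        if (tags.to_numpy() < 0).any():
            raise ValidationError("tag counts must be non-negative")

    @classmethod
    def from_arrays(
        cls,
        counts,
        barcodes: Sequence[str],
        genes: Sequence[str],
        tag_counts: pd.DataFrame | np.ndarray,
        tag_names: Sequence[str] | None = None,
    ) -> "CellExperiment":
        counts = sp.csr_matrix(counts)
        if counts.shape != (len(barcodes), len(genes)):
            raise FormatError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(barcodes)} barcodes x {len(genes)} features"
            )
        if not isinstance(tag_counts, pd.DataFrame):
            if tag_names is None:
                tag_names = [f"tag{i + 1}" for i in range(np.asarray(tag_counts).shape[1])]
            tag_counts = pd.DataFrame(
                np.asarray(tag_counts), index=list(barcodes), columns=list(tag_names)
            )
        if tag_counts.shape[0] != len(barcodes):
            raise FormatError(
                f"tag matrix has {tag_counts.shape[0]} rows for {len(barcodes)} barcodes"
            )
        tag_counts = tag_counts.copy()
        tag_counts.index = list(barcodes)
        adata = AnnData(
            X=counts,
            obs=pd.DataFrame(index=pd.Index(list(barcodes), name="barcode")),
            var=pd.DataFrame(index=pd.Index(list(genes), name="gene")),
        )
        adata.obsm["tag_counts"] = tag_counts
        return cls(adata)

    @property
    def cells(self) -> list[str]:
        return list(self.adata.obs_names)

    @property
    def genes(self) -> list[str]:
        return list(self.adata.var_names)

    @property
    def counts(self) -> sp.csr_matrix:
        return sp.csr_matrix(self.adata.X)

    @property
    def tag_counts(self) -> pd.DataFrame:
        return self.adata.obsm["tag_counts"]

    @property
    def n_cells(self) -> int:
        return self.adata.n_obs

    @property
    def n_genes(self) -> int:
        return self.adata.n_vars

    def subset_cells(self, mask) -> "CellExperiment":
        return CellExperiment(self.adata[np.asarray(mask)].copy())

    def subset_genes(self, mask) -> "CellExperiment":
        return CellExperiment(self.adata[:, np.asarray(mask)].copy())


@dataclass
class MarkerPanel:
    """Named marker gene lists for cell-type identification.

    ``positive`` maps a cell type to genes whose expression identifies it
    (e.g. mesothelial: ITLN1, HP, UPK3B); ``exclusion`` maps a cell type to
    genes whose expression disqualifies a cell from that type (lineage
    markers of contaminating populations).
    """

    positive: Mapping[str, Sequence[str]] = field(default_factory=dict)
    exclusion: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positive = {t: list(g) for t, g in self.positive.items()}
        self.exclusion = {t: list(g) for t, g in self.exclusion.items()}
        for cell_type, pos in self.positive.items():
            overlap = set(pos) & set(self.exclusion.get(cell_type, []))
            if overlap:
                raise ValidationError(
                    f"genes {sorted(overlap)} are both positive and exclusion "
                    f"markers for cell type {cell_type!r}"
                )

    @property
    def cell_types(self) -> list[str]:
        return list(self.positive)


# The study's marker assignments: mesothelial identity markers, and the
# lineage markers of the contaminating populations used for purification.
MESOTHELIAL_MARKERS = ("ITLN1", "HP", "UPK3B")
EXCLUSION_MARKERS: Mapping[str, tuple[str, ...]] = {
    "epithelial": ("CLDN4", "EPCAM"),
    "macrophage": ("FCER1G", "LYZ"),
    "t_cell": ("CD3E", "GZMB"),
    "b_cell": ("IGHM", "JCHAIN"),
    "adipocyte": ("JCAD", "S1PR1", "VWF"),
}


def default_marker_panel() -> MarkerPanel:
    """The study's marker panel: mesothelial positives plus the lineage
    markers of every contaminating cell type as mesothelial exclusions."""
    positive = {"mesothelial": list(MESOTHELIAL_MARKERS)}
    exclusion_flat: list[str] = []
    for cell_type, genes in EXCLUSION_MARKERS.items():
        positive.setdefault(cell_type, list(genes))
        exclusion_flat.extend(genes)
    return MarkerPanel(
        positive=positive, exclusion={"mesothelial": exclusion_flat}
    )
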