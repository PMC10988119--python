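import numpy as np
import pandas as pd
import pytest

from costim.types import BulkExperiment, CellExperiment, NPXTable


def make_design(n_patients: int, conditions=("control", "IL17A", "TNF", "combo")):
    rows = [
        {
            "sample_id": f"P{p}_{c}",
            "patient_id": f"P{p}",
            "condition": c,
            "replicate": 1,
        }
        for p in range(1, n_patients + 1)
        for c in conditions
    ]
    return pd.DataFrame(rows)


def make_bulk(counts_by_sample: dict[str, list[int]], genes=None, design=None) -> BulkExperiment:
    """Build a BulkExperiment from {sample_id: counts}; the design is
    inferred from 'P<k>_<condition>' sample ids unless given."""
    n_genes = len(next(iter(counts_by_sample.values())))
    genes = genes or [f"g{i + 1}" for i in range(n_genes)]
    counts = pd.DataFrame(counts_by_sample, index=pd.Index(genes, name="gene"))
    if design is None:
        rows = []
        for sid in counts_by_sample:
            patient, condition = sid.split("_", 1)
            rows.append(
                {"sample_id": sid, "patient_id": patient, "condition": condition, "replicate": 1}
            )
        design = pd.DataFrame(rows)
    return BulkExperiment(counts=counts, design=design)


def make_npx(rows) -> NPXTable:
    """rows: iterable of (protein, panel, condition, replicate, npx)."""
    records = pd.DataFrame(
        rows, columns=["protein_id", "panel_id", "condition", "replicate", "npx"]
    )
    records["sample_id"] = records["condition"] + "_r" + records["replicate"].astype(str)
    return NPXTable(records=records)


def make_cells(counts, genes, tag_counts=None, barcodes=None) -> CellExperiment:
    counts = np.asarray(counts)
    barcodes = barcodes or [f"c{i + 1}" for i in range(counts.shape[0])]
    if tag_counts is None:
        tag_counts = np.full((counts.shape[0], 1), 10)
    return CellExperiment.from_arrays(
        counts=counts, barcodes=barcodes, genes=list(genes), tag_counts=np.asarray(tag_counts)
    )


@pytest.fixture
def two_patient_bulk() -> BulkExperiment:
    """2 patients x 4 conditions, 3 genes, equal library sizes."""
    return make_bulk(
        {
            "P1_control": [10, 20, 70],
            "P1_IL17A": [20, 20, 60],
            "P1_TNF": [10, 30, 60],
            "P1_combo": [40, 30, 30],
            "P2_control": [10, 20, 70],
            "P2_IL17A": [20, 20, 60],
            "P2_TNF": [10, 30, 60],
            "P2_combo": [40, 30, 30],
        }
    )
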