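"""Bulk RNA-seq two-factor synergy analysis.

The design is four arms per patient — untreated control, IL-17A, TNF, and
the IL-17A+TNF combination.  Counts are normalized to tags per million
(CPM), fold changes are computed per patient against that patient's matched
control and summarized as the median across patients, and differential
genes are filtered on total reads, FDR and |log2FC|.

The synergy statistic compares the observed combination fold change with
an additive expectation formed by *adding the two single-treatment linear
fold changes*:

    ratio = FC_combo / (FC_IL17A + FC_TNF)

A gene is called synergistic when the observed combination FC is at least
one log2 unit (a factor of ``ratio_threshold``, default 2) above that
additive expectation, the gene passes the DE filter in the combination arm,
and the gene is induced (FC_combo > 1).

The differential-expression test is a paired two-sided t-test on the
per-patient log2 fold changes with Benjamini-Hochberg correction.  This is
a deliberate, documented divergence from negative-binomial DE frameworks;
externally computed DE tables can be injected by building a summary table
with the same columns and passing it to :func:`filter_de`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .types import BulkExperiment, CostimError, TREATMENTS, ValidationError

logger = logging.getLogger(__name__)

VENN_REGIONS = (
    "IL17A_only",
    "TNF_only",
    "combo_only",
    "IL17A_TNF",
    "IL17A_combo",
    "TNF_combo",
    "IL17A_TNF_combo",
)


class AnalysisError(CostimError, RuntimeError):
    """The experiment cannot support the requested computation."""


@dataclass
class FoldChangeTable:
    """Per-gene, per-condition fold changes with test results.

    ``per_patient_log2fc`` maps each treated condition to a genes x patients
    matrix of paired log2 fold changes.  ``table`` is the long summary with
    one row per (gene, condition): ``median_fc`` (linear, median across
    patients), ``log2_median_fc``, ``mean_norm_control`` (mean control CPM),
    ``total_reads`` (raw counts summed over all samples), ``p_value`` and
    ``fdr``.
    """

    per_patient_log2fc: dict[str, pd.DataFrame]
    table: pd.DataFrame

    def condition(self, condition: str) -> pd.DataFrame:
        sub = self.table[self.table["condition"] == condition]
        return sub.set_index("gene")

    def __post_init__(self) -> None:
        med = self.table["median_fc"]
        if (med <= 0).any():
            raise ValidationError("median_fc must be positive (linear scale)")


def normalize_cpm(exp: BulkExperiment) -> pd.DataFrame:
    """Normalize raw counts to tags per million: every column sums to 1e6."""
    totals = exp.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise AnalysisError(
            f"sample(s) with all-zero counts cannot be CPM-normalized: {list(zero.index)}"
        )
    return exp.counts / totals * 1e6


def _paired_patient_means(
    exp: BulkExperiment, cpm: pd.DataFrame, condition: str
) -> tuple[list[str], pd.DataFrame, pd.DataFrame]:
    """Per-patient mean CPM for a condition and its matched control.

    Patients lacking either arm are skipped (and logged).  Replicates within
    a (patient, condition) cell are averaged on the CPM scale.
    """
    treated_cols, control_cols, patients = [], [], []
    for patient in exp.patients:
        t = exp.samples_for(patient, condition)
        c = exp.samples_for(patient, "control")
        if not t or not c:
            logger.info(
                "fold change %s: patient %s skipped (treated=%d, control=%d samples)",
                condition, patient, len(t), len(c),
            )
            continue
        patients.append(patient)
        treated_cols.append(cpm[t].mean(axis=1))
        control_cols.append(cpm[c].mean(axis=1))
    if not patients:
        raise AnalysisError(f"no patient has a complete control/{condition} pair")
    treated = pd.concat(treated_cols, axis=1)
    control = pd.concat(control_cols, axis=1)
    treated.columns = control.columns = patients
    return patients, treated, control


def compute_fold_changes(exp: BulkExperiment, pseudocount: float = 1.0) -> FoldChangeTable:
    """Per-patient paired log2 fold changes and their across-patient medians.

    For every treated condition and every patient with both arms:
    ``log2FC = log2((CPM_treated + pseudocount) / (CPM_control + pseudocount))``.
    The per-gene summary FC is the median across patients of ``2**log2FC``
    (a linear-scale median).  Tests are *not* run here; see
    :func:`test_differential` / :func:`add_differential_tests`.
    """
    cpm = normalize_cpm(exp)
    total_reads = exp.counts.sum(axis=1)
    control_samples = exp.design.loc[exp.design["condition"] == "control", "sample_id"]
    mean_norm_control = cpm[list(control_samples)].mean(axis=1)

    per_patient: dict[str, pd.DataFrame] = {}
    rows = []
    for condition in TREATMENTS:
        patients, treated, control = _paired_patient_means(exp, cpm, condition)
        log2fc = np.log2((treated + pseudocount) / (control + pseudocount))
        per_patient[condition] = log2fc
        median_fc = np.median(np.exp2(log2fc.to_numpy()), axis=1)
        rows.append(
            pd.DataFrame(
                {
                    "gene": exp.genes,
                    "condition": condition,
                    "median_fc": median_fc,
                    "log2_median_fc": np.log2(median_fc),
                    "mean_norm_control": mean_norm_control.to_numpy(),
                    "total_reads": total_reads.to_numpy(),
                    "p_value": np.nan,
                    "fdr": np.nan,
                }
            )
        )
        logger.info("fold changes for %s: %d patients with complete pairs", condition, len(patients))
    return FoldChangeTable(per_patient_log2fc=per_patient, table=pd.concat(rows, ignore_index=True))


def paired_t_against_zero(log2fc: pd.DataFrame) -> pd.DataFrame:
    """Two-sided paired t-test of per-patient log2 fold changes against 0.

    Rows (genes) with zero variance across patients get p = 1 by convention
    (no evidence against the null is obtainable from constant differences).
    Benjamini-Hochberg FDR is computed across all genes in the table.
    """
    values = log2fc.to_numpy(dtype=float)
    if values.shape[1] < 3:
        raise AnalysisError(
            f"paired test needs >= 3 complete patient pairs, got {values.shape[1]}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = scipy.stats.ttest_1samp(values, 0.0, axis=1)
    zero_var = np.isclose(values.std(axis=1), 0.0)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    if zero_var.any():
        logger.info("paired t: %d gene(s) with zero variance set to p = 1", int(zero_var.sum()))
    fdr = benjamini_hochberg(p)
    return pd.DataFrame({"p_value": p, "fdr": fdr}, index=log2fc.index)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def test_differential(exp: BulkExperiment, condition: str, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene (p_value, fdr) for one treated condition vs matched control."""
    cpm = normalize_cpm(exp)
    _, treated, control = _paired_patient_means(exp, cpm, condition)
    log2fc = np.log2((treated + pseudocount) / (control + pseudocount))
    return paired_t_against_zero(log2fc)


def add_differential_tests(fct: FoldChangeTable) -> FoldChangeTable:
    """Fill p_value/fdr in a fold-change table using the paired t-test."""
    for condition, log2fc in fct.per_patient_log2fc.items():
        result = paired_t_against_zero(log2fc)
        mask = fct.table["condition"] == condition
        genes = fct.table.loc[mask, "gene"]
        fct.table.loc[mask, "p_value"] = result.loc[genes, "p_value"].to_numpy()
        fct.table.loc[mask, "fdr"] = result.loc[genes, "fdr"].to_numpy()
    return fct


def filter_de(
    fct: FoldChangeTable | pd.DataFrame,
    min_total_reads: int = 15,
    max_fdr: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> dict[str, set[str]]:
    """Differential gene sets per condition.

    A gene is differential in a condition iff total_reads >= min_total_reads
    AND fdr <= max_fdr AND |log2(median FC)| >= min_abs_log2fc; all three
    boundaries are inclusive.  Accepts either a :class:`FoldChangeTable` or
    any long table with the summary columns (the injection point for
    externally computed DE results).
    """
    table = fct.table if isinstance(fct, FoldChangeTable) else fct
    if table["fdr"].isna().any():
        raise AnalysisError("fdr is unset; run add_differential_tests first")
    keep = (
        (table["total_reads"] >= min_total_reads)
        & (table["fdr"] <= max_fdr)
        & (table["log2_median_fc"].abs() >= min_abs_log2fc)
    )
    de_sets: dict[str, set[str]] = {}
    for condition in TREATMENTS:
        mask = keep & (table["condition"] == condition)
        de_sets[condition] = set(table.loc[mask, "gene"])
        logger.info(
            "DE filter %s: %d of %d genes pass",
            condition, len(de_sets[condition]), int((table["condition"] == condition).sum()),
        )
    return de_sets


@dataclass
class VennPartition:
    """The 7 disjoint regions of the three-condition DE Venn diagram."""

    regions: dict[str, frozenset]

    @property
    def counts(self) -> dict[str, int]:
        return {name: len(genes) for name, genes in self.regions.items()}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def combo_only_percent(self) -> float:
        """Combo-only genes as a percentage of the union of all DE genes."""
        return 100.0 * len(self.regions["combo_only"]) / self.total if self.total else 0.0

    @property
    def combo_only_percent_of_combo(self) -> float:
        """Combo-only genes as a percentage of all combo-DE genes."""
        combo = sum(
            len(self.regions[r])
            for r in ("combo_only", "IL17A_combo", "TNF_combo", "IL17A_TNF_combo")
        )
        return 100.0 * len(self.regions["combo_only"]) / combo if combo else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": name, "count": len(genes), "genes": ";".join(sorted(genes))}
            for name, genes in self.regions.items()
        ]
        rows.append({"region": "total", "count": self.total, "genes": ""})
        return pd.DataFrame(rows, columns=["region", "count", "genes"])


def venn_partition(de_sets: dict[str, set[str]]) -> VennPartition:
    """Partition three DE gene sets (IL17A, TNF, combo) into 7 disjoint regions."""
    missing = [c for c in TREATMENTS if c not in de_sets]
    if missing:
        raise ValidationError(f"de_sets lacks condition(s): {missing}")
    a, b, ab = (set(de_sets[c]) for c in TREATMENTS)
    regions = {
        "IL17A_only": a - b - ab,
        "TNF_only": b - a - ab,
        "combo_only": ab - a - b,
        "IL17A_TNF": (a & b) - ab,
        "IL17A_combo": (a & ab) - b,
        "TNF_combo": (b & ab) - a,
        "IL17A_TNF_combo": a & b & ab,
    }
    part = VennPartition(regions={k: frozenset(v) for k, v in regions.items()})
    logger.info(
        "venn partition: total %d DE genes, combo-only %.1f%% of union",
        part.total, part.combo_only_percent,
    )
    return part


def call_synergy(
    fct: FoldChangeTable,
    de_sets: dict[str, set[str]],
    ratio_threshold: float = 2.0,
    include_repressed: bool = False,
) -> pd.DataFrame:
    """Observed-vs-additive fold-change synergy calls.

    For every gene with median FCs in all three conditions:
    ``fc_expected = fc_a + fc_b`` (linear scale) and
    ``ratio = fc_combo / fc_expected``.  A gene is synergistic iff
    ``ratio >= ratio_threshold`` (inclusive) AND it passes the DE filter in
    the combination arm AND it is induced (``fc_combo > 1``).

    With ``include_repressed`` a mirrored call for repressed genes is added
    (reciprocal fold changes, ``fc_combo < 1``), flagged in ``direction``.
    Output is sorted by descending ratio (gene id breaks ties).
    """
    wide = fct.table.pivot(index="gene", columns="condition", values="median_fc")
    incomplete = wide.index[wide[list(TREATMENTS)].isna().any(axis=1)]
    if len(incomplete):
        logger.info("synergy: %d gene(s) lacking a condition excluded", len(incomplete))
        wide = wide.drop(index=incomplete)
    fc_a, fc_b, fc_combo = (wide[c] for c in TREATMENTS)
    fc_expected = fc_a + fc_b
    ratio = fc_combo / fc_expected
    de_combo = wide.index.isin(de_sets["combo"])
    induced = fc_combo > 1
    synergistic = (ratio >= ratio_threshold) & de_combo & induced

    out = pd.DataFrame(
        {
            "gene": wide.index,
            "fc_a": fc_a.to_numpy(),
            "fc_b": fc_b.to_numpy(),
            "fc_combo": fc_combo.to_numpy(),
            "fc_expected": fc_expected.to_numpy(),
            "ratio": ratio.to_numpy(),
            "de_combo": de_combo,
            "direction": "induced",
            "synergistic": synergistic.to_numpy(),
        }
    )
    if include_repressed:
        rec_ratio = (1.0 / fc_combo) / (1.0 / fc_a + 1.0 / fc_b)
        repressed = (rec_ratio >= ratio_threshold) & de_combo & (fc_combo < 1)
        out.loc[repressed.to_numpy(), ["direction", "synergistic"]] = ["repressed", True]
    out = out.sort_values(["ratio", "gene"], ascending=[False, True]).reset_index(drop=True)
    logger.info(
        "synergy: %d of %d genes called synergistic (ratio >= %g)",
        int(out["synergistic"].sum()), len(out), ratio_threshold,
    )
    return out


def run_bulk_pipeline(
    exp: BulkExperiment,
    pseudocount: float = 1.0,
    min_total_reads: int = 15,
    max_fdr: float = 0.05,
    min_abs_log2fc: float = 1.0,
    ratio_threshold: float = 2.0,
    include_repressed: bool = False,
) -> tuple[FoldChangeTable, dict[str, set[str]], VennPartition, pd.DataFrame]:
    """Fold changes -> paired tests -> DE filter -> Venn -> synergy calls."""
    fct = add_differential_tests(compute_fold_changes(exp, pseudocount=pseudocount))
    de_sets = filter_de(
        fct,
        min_total_reads=min_total_reads,
        max_fdr=max_fdr,
        min_abs_log2fc=min_abs_log2fc,
    )
    venn = venn_partition(de_sets)
    synergy = call_synergy(
        fct, de_sets, ratio_threshold=ratio_threshold, include_repressed=include_repressed
    )
    return fct, de_sets, venn, synergy
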