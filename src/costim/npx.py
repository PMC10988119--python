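"""Olink-style NPX secretome synergy analysis.

NPX is a log2-scale arbitrary unit, so the regulation of a protein by a
treatment is ``2**dNPX`` where dNPX is the difference between the treated
and control NPX of replicate-matched samples.  Per-protein regulation is
summarized as the median fold change across biological replicates.

Protein synergy uses the same additive null as the transcriptome analysis
but with the published protein-specific factor: a protein is synergistic
iff the combination fold change strictly exceeds 1.5x the *sum* of the two
single-treatment fold changes, and the combination effect is nominally
significant (p < 0.05).

Assays measured on more than one panel are merged up front by averaging
their NPX values per sample (arithmetic mean on the NPX/log2 scale).

The t-test pairing mode is configurable: the default is the paired test on
per-replicate dNPX (the mode used for the headline synergy calls); an
unpaired mode comparing treated and control NPX vectors is also provided.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from .bulk import AnalysisError, benjamini_hochberg
from .types import NPXTable, TREATMENTS, ValidationError

logger = logging.getLogger(__name__)


def merge_duplicate_assays(npx: NPXTable) -> NPXTable:
    """Average NPX over panels for every (protein, sample) measured on
    more than one panel.  Idempotent; single-panel records pass through."""
    rec = npx.records
    merged = (
        rec.groupby(["protein_id", "sample_id", "condition", "replicate"], sort=False)
        .agg(panel_id=("panel_id", lambda p: ";".join(sorted(set(p)))), npx=("npx", "mean"))
        .reset_index()
    )
    n_merged = len(rec) - len(merged)
    if n_merged:
        logger.info("merged %d duplicate-panel NPX record(s)", n_merged)
    return NPXTable(records=merged[list(rec.columns)])


def _paired_deltas(rec: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Per-protein per-replicate dNPX = treated - control, replicate-matched."""
    treated = rec[rec["condition"] == condition]
    control = rec[rec["condition"] == "control"]
    merged = treated.merge(
        control, on=["protein_id", "replicate"], suffixes=("_t", "_c"), how="left"
    )
    unmatched = merged["npx_c"].isna()
    if unmatched.any():
        logger.info(
            "npx fold change %s: %d treated replicate(s) without a matched "
            "control skipped", condition, int(unmatched.sum()),
        )
        merged = merged[~unmatched]
    if merged.empty:
        raise AnalysisError(f"no complete control/{condition} replicate pairs")
    merged["delta_npx"] = merged["npx_t"] - merged["npx_c"]
    return merged[["protein_id", "replicate", "delta_npx"]]


def npx_fold_change(npx: NPXTable, condition: str) -> pd.DataFrame:
    """Per-protein regulation by one treatment.

    Returns one row per protein: ``per_replicate_fc`` (list of 2**dNPX),
    ``median_fc`` (median across replicates), ``n_replicates``; p_value and
    fdr are NaN until :func:`test_protein_regulation` is applied.
    """
    if condition not in TREATMENTS:
        raise ValidationError(f"condition must be one of {TREATMENTS}, got {condition!r}")
    deltas = _paired_deltas(npx.records, condition)
    deltas = deltas.assign(fc=np.exp2(deltas["delta_npx"]))
    out = (
        deltas.sort_values(["protein_id", "replicate"])
        .groupby("protein_id")
        .agg(
            per_replicate_fc=("fc", list),
            median_fc=("fc", "median"),
            n_replicates=("fc", "size"),
        )
        .reset_index()
    )
    out.insert(1, "condition", condition)
    out["p_value"] = np.nan
    out["fdr"] = np.nan
    return out


def test_protein_regulation(
    npx: NPXTable, regulation: pd.DataFrame, paired: bool = True
) -> pd.DataFrame:
    """Attach p_value/fdr to a per-protein regulation table.

    Paired mode: two-sided one-sample t on the replicate-matched dNPX
    values against 0.  Unpaired mode: two-sided two-sample t (equal
    variance) of treated vs control NPX vectors.  Zero-variance cases get
    p = 1 by convention.  BH correction runs across all proteins of the
    condition.
    """
    regulation = regulation.copy()
    for condition in regulation["condition"].unique():
        sub = regulation["condition"] == condition
        proteins = regulation.loc[sub, "protein_id"]
        pvals = []
        rec = npx.records
        deltas = _paired_deltas(rec, condition) if paired else None
        for protein in proteins:
            if paired:
                x = deltas.loc[deltas["protein_id"] == protein, "delta_npx"].to_numpy()
                if len(x) < 3:
                    raise AnalysisError(
                        f"paired test needs >= 3 replicate pairs for {protein} ({condition})"
                    )
                if np.isclose(x.std(), 0.0):
                    logger.info("npx test %s/%s: zero variance, p = 1", protein, condition)
                    pvals.append(1.0)
                    continue
                p = scipy.stats.ttest_1samp(x, 0.0).pvalue
            else:
                t = rec[(rec["protein_id"] == protein) & (rec["condition"] == condition)]["npx"]
                c = rec[(rec["protein_id"] == protein) & (rec["condition"] == "control")]["npx"]
                if len(t) < 3 or len(c) < 3:
                    raise AnalysisError(
                        f"unpaired test needs >= 3 replicates per arm for {protein} ({condition})"
                    )
                if np.isclose(np.concatenate([t, c]).std(), 0.0) or np.isclose(
                    t.std(), 0.0
                ) and np.isclose(c.std(), 0.0) and np.isclose(t.mean(), c.mean()):
                    logger.info("npx test %s/%s: zero variance, p = 1", protein, condition)
                    pvals.append(1.0)
                    continue
                p = scipy.stats.ttest_ind(t, c).pvalue
            pvals.append(1.0 if not np.isfinite(p) else float(p))
        regulation.loc[sub, "p_value"] = pvals
        regulation.loc[sub, "fdr"] = benjamini_hochberg(np.asarray(pvals))
    return regulation


def compute_protein_regulation(npx: NPXTable, paired: bool = True) -> pd.DataFrame:
    """Fold changes plus tests for all three treated conditions."""
    merged = merge_duplicate_assays(npx)
    parts = [npx_fold_change(merged, condition) for condition in TREATMENTS]
    return test_protein_regulation(merged, pd.concat(parts, ignore_index=True), paired=paired)


def call_protein_synergy(
    regulation: pd.DataFrame, synergy_factor: float = 1.5, max_p: float = 0.05
) -> pd.DataFrame:
    """Protein synergy calls against the 1.5x-additive null.

    synergistic iff ``fc_combo > (fc_a + fc_b) * synergy_factor`` (strict)
    AND the combination p-value < ``max_p`` (nominal, per the published
    definition; fdr is carried along for reference).  ``display_relative_*``
    columns give each condition's FC normalized to the combination FC
    (combination = 1 by construction).
    """
    wide_fc = regulation.pivot(index="protein_id", columns="condition", values="median_fc")
    missing = wide_fc.index[wide_fc.reindex(columns=list(TREATMENTS)).isna().any(axis=1)]
    if len(missing):
        logger.info(
            "protein synergy: %d protein(s) lacking a condition excluded: %s",
            len(missing), sorted(missing),
        )
        wide_fc = wide_fc.drop(index=missing)
    wide_p = regulation.pivot(index="protein_id", columns="condition", values="p_value")
    wide_fdr = regulation.pivot(index="protein_id", columns="condition", values="fdr")

    fc_a, fc_b, fc_combo = (wide_fc[c] for c in TREATMENTS)
    threshold = (fc_a + fc_b) * synergy_factor
    p_combo = wide_p.loc[wide_fc.index, "combo"]
    synergistic = (fc_combo > threshold) & (p_combo < max_p)

    out = pd.DataFrame(
        {
            "protein_id": wide_fc.index,
            "fc_a": fc_a.to_numpy(),
            "fc_b": fc_b.to_numpy(),
            "fc_combo": fc_combo.to_numpy(),
            "additive_fc": (fc_a + fc_b).to_numpy(),
            "synergy_threshold": threshold.to_numpy(),
            "p_combo": p_combo.to_numpy(),
            "fdr_combo": wide_fdr.loc[wide_fc.index, "combo"].to_numpy(),
            "synergistic": synergistic.to_numpy(),
            "display_relative_IL17A": (fc_a / fc_combo).to_numpy(),
            "display_relative_TNF": (fc_b / fc_combo).to_numpy(),
            "display_relative_combo": np.ones(len(wide_fc)),
        }
    ).reset_index(drop=True)
    logger.info(
        "protein synergy: %d of %d proteins called synergistic (> %gx additive, p < %g)",
        int(out["synergistic"].sum()), len(out), synergy_factor, max_p,
    )
    return out


def run_npx_pipeline(
    npx: NPXTable,
    synergy_factor: float = 1.5,
    max_p: float = 0.05,
    paired: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge duplicate assays -> fold changes -> tests -> synergy calls."""
    regulation = compute_protein_regulation(npx, paired=paired)
    synergy = call_protein_synergy(regulation, synergy_factor=synergy_factor, max_p=max_p)
    return regulation, synergy
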