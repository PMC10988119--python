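# costim

Analysis toolkit for **two-factor cytokine co-stimulation experiments**:
quantifying how IL-17A and TNF act *synergistically* — rather than
additively — on the transcriptome, the secretome, and the in-vivo cell
states of mesothelial cells.

It is written for the typical design in this field: cells from several
patients receive four treatments (untreated control, IL-17A alone, TNF
alone, and the IL-17A+TNF combination), profiled by bulk RNA-seq, by
Olink-style NPX proteomics of conditioned medium, and by multiplexed,
targeted single-cell RNA-seq of patient tissue.

## The statistics at the core

**Transcript synergy.** Counts are normalized to tags per million (CPM).
For each gene and treatment, the fold change is computed per patient
against that patient's matched control and summarized as the median
across patients:

```
FC_c(g) = median_p  2^( log2[(CPM_treated(g,p) + 1) / (CPM_control(g,p) + 1)] )
```

The additive null for the combination is the **sum of the single-treatment
linear fold changes**, and the synergy ratio compares the observed
combination effect with it:

```
ratio(g) = FC_combo(g) / (FC_IL17A(g) + FC_TNF(g))
```

A gene is called synergistic when `ratio >= 2` (one log2 unit above the
additive expectation), the gene passes the differential-expression filter
in the combination arm (total reads >= 15, BH-FDR <= 0.05,
|log2 FC| >= 1; paired t-test on per-patient log2 fold changes), and the
gene is induced (`FC_combo > 1`).

**Protein synergy.** NPX is a log2-scale unit, so regulation is
`2^dNPX` per replicate-matched pair, summarized as the median across
replicates. Assays duplicated across panels are merged by averaging NPX.
A protein is synergistic when
`FC_combo > 1.5 x (FC_IL17A + FC_TNF)` (strict) with a nominal
`p < 0.05` for the combination effect.

**Single-cell annotation and purification.** Cells are assigned to source
samples from sample-tag counts (>= 5 tags; a cell whose second tag reaches
25% of its top tag is a multiplet), filtered (>= 20 genes, >= 400 reads
per cell; genes in > 21 cells), normalized to 10k counts and
log-transformed, Louvain-clustered on a kNN/PCA graph, annotated from
positive markers (mesothelial: *ITLN1*, *HP*, *UPK3B*), and the
mesothelial clusters are purified by removing every cell expressing any
contaminating-lineage marker (*CLDN4*, *EPCAM*, *FCER1G*, *LYZ*, *CD3E*,
*GZMB*, *IGHM*, *JCHAIN*, *JCAD*, *S1PR1*, *VWF*). Purified cells are
re-clustered and profiled for a cytokine-induced gene panel.

A seeded synthetic-data generator (`costim.simulate`) produces bulk, NPX
and tagged single-cell datasets with planted null / single-factor /
additive / synergistic features, so every pipeline stage is testable
against known ground truth. See `docs/methods.md` for models,
parameters and limitations.

## Worked example

Simulate a 5-patient, 2000-gene experiment with 50 planted synergistic
genes (ratio 4) and 50 exactly-additive genes, then analyze it:

```
costim simulate bulk --seed 7 --outdir sim
costim bulk-synergy --counts sim/counts.tsv --design sim/design.tsv --seed 7 --outdir out
```

The run log reports each stage:

```
INFO costim.bulk: DE filter IL17A: 1 of 2000 genes pass
INFO costim.bulk: DE filter TNF: 6 of 2000 genes pass
INFO costim.bulk: DE filter combo: 99 of 2000 genes pass
INFO costim.bulk: synergy: 48 of 2000 genes called synergistic (ratio >= 2)
```

IL-17A alone does little, TNF does more, and the combination dominates —
the planted structure mirrors the biology. `out/venn.tsv` partitions the
differential genes (92 of 99 are combination-only here), and
`out/synergy.tsv` ranks genes by their observed/additive ratio:

```
gene    fc_a   fc_b   fc_combo  fc_expected  ratio  synergistic
G00696  1.49   2.04   20.36     3.53         5.77   True
G00274  2.41   4.12   37.42     6.53         5.74   True
```

All 48 calls are planted synergists (sensitivity 0.96 at this seed); none
of the exactly-additive genes is called. `costim npx-synergy` and
`costim scrna-annotate` run the other two pipelines with the same
config/seed/outdir conventions.

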