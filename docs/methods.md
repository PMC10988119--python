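# Methods

## Design assumptions

All three pipelines assume the same two-factor layout: each biological
unit (patient, or conditioned-medium replicate, or tissue donor) is
measured under four conditions — untreated `control`, `IL17A`, `TNF` and
the `combo` of both cytokines. Validation enforces that every patient
with a treated sample has a matched control, because every fold change in
the toolkit is a *paired* contrast against that control.

## Bulk transcriptome synergy

**Normalization.** Counts are scaled per library to tags per million
(CPM). CPM removes sequencing depth exactly (scaling a library by a
constant leaves all downstream fold changes unchanged; covered by a
test), but it is compositional: if the combination massively induces a
set of genes, every other gene's CPM is deflated by the same factor. The
synergy ratio partially cancels this (numerator and denominator are both
deflated), but absolute fold changes from strongly perturbed libraries
are mildly conservative. This is a property of CPM itself, not of this
implementation.

**Fold changes.** Per patient and gene,
`log2FC = log2((CPM_t + c)/(CPM_0 + c))` with pseudocount `c = 1` CPM
(configurable) to damp zero-count noise; replicates within a
patient-condition cell are averaged on the CPM scale first. The per-gene
summary is the **median across patients of the linear fold changes** —
robust to a single outlier patient at n = 5.

**Differential test.** A paired two-sided t-test of the per-patient log2
fold changes against zero, with Benjamini-Hochberg correction per
condition. Genes with zero variance across patients get p = 1 (constant
differences carry no evidence either way at n patients). This stage
deliberately does not re-implement negative-binomial empirical-Bayes DE
machinery; it is a transparent, assumption-light test suited to the
paired design, and the DE filter accepts any externally computed summary
table with the same columns (`gene`, `condition`, `log2_median_fc`,
`fdr`, `total_reads`), so results from a dedicated DE package can be
injected unchanged. Requires >= 3 complete patient pairs.

**DE filter.** `total_reads >= 15` (raw counts summed over *all*
samples — the least restrictive defensible reading of a per-gene read
floor; configurable), `FDR <= 0.05`, `|log2 median FC| >= 1`. All
boundaries inclusive.

**Synergy call.** The additive null adds the *linear* single-treatment
fold changes: `FC_expected = FC_a + FC_b`. Note this null is >= 2
whenever both single FCs are >= 1; it is the natural "sum of independent
effects" reference for induced genes. `ratio = FC_combo / FC_expected`;
a gene is synergistic iff `ratio >= 2` (inclusive), it passes the DE
filter in the combination arm, and `FC_combo > 1`. Synergy is defined for
induced genes; a mirrored call for repressed genes (reciprocal fold
changes) exists behind `include_repressed`, default off, because the
additive-sum null is not symmetric under inversion.

**Venn partition.** The three DE sets are split into the 7 disjoint
regions; the summary percentage is the combination-only region as a share
of the union. The share of the combination DE set is reported as a
secondary field (`combo_only_percent_of_combo`) since "percent of
combination-regulated genes" is the other common way this figure is
quoted.

## NPX secretome synergy

NPX is log2-scale, so `2^dNPX` of replicate-matched treated/control pairs
is a linear fold change; the per-protein summary is the median across
replicates (reciprocity `fc(d) * fc(-d) = 1` holds exactly per
replicate). Assays present on multiple panels are averaged per sample on
the NPX scale before any analysis; the merge is idempotent. The synergy
rule is `FC_combo > 1.5 x (FC_a + FC_b)` — strict, matching a ">"
definition — gated on a *nominal* combination p < 0.05; BH-adjusted FDR
is reported alongside but does not gate the call. Both paired (on dNPX,
the default) and unpaired t-tests are implemented because published
descriptions of this analysis vary between the two; the choice is a
config flag (`npx.paired_test`).

## Targeted single-cell pipeline

Fixed stage order, each stage logging input/output dimensions:
demux -> cell filter -> gene filter -> normalize -> cluster -> annotate
-> purify -> re-cluster -> profile.

* **Demux**: total tags < 5 -> unassigned; second tag >= 25% of the top
  tag -> multiplet (ties are multiplets by construction); otherwise the
  argmax tag. The vectorized implementation is checked against an
  exhaustive per-cell rule evaluation over all 2,197 small tag tables.
* **Filters**: cells need >= 20 detected genes and >= 400 total counts
  (both inclusive; the gene floor is printed as "20 or more", and the
  read floor is treated the same way for symmetry); genes need > 21
  expressing cells (strict).
* **Normalization**: counts scaled to 10,000 per cell, then ln(1 + x).
* **Clustering**: top-20 PCA of the normalized matrix, symmetrized
  15-nearest-neighbor graph, Louvain community detection (igraph's
  multilevel optimizer with a seeded RNG; Leiden available as
  `cluster_method: leiden`). No resolution was published for the original
  analysis, so the default (1.0) follows ecosystem convention and the
  cluster count is not treated as a target quantity. Labels are
  relabeled by decreasing cluster size for stability; identical seeds
  give identical labels.
* **Annotation**: "expression" means raw count > 0 throughout. A cluster
  gets a cell type when more than half of its cells (configurable)
  express ANY of that type's positive markers; the highest qualifying
  fraction wins, ties break by type name. This explicit marker rule
  replaces classifier-based pre-annotation: the final cell-type calls in
  this workflow are defined by the marker lists themselves.
* **Purification**: mesothelial-cluster cells are removed if they carry
  >= 1 count of any exclusion lineage marker. The post-condition (no
  surviving cell expresses any exclusion marker) is asserted in tests.
* **Re-clustering** of the purified subset reuses the clusterer with an
  independent seed (seed + 1).
* **Profiling**: per cluster, the number of induced-panel genes with at
  least one expressing cell; the display set keeps genes expressed in
  >= 20% of the cells of at least one cluster (inclusive), with mean
  log-normalized expression as the heatmap matrix.

## Synthetic data

The generators define the conditions under which the recovery properties
are measured; they emulate the statistical structure of the real designs,
not their full biology.

**Bulk**: negative binomial with mean
`depth x w_g x 2^(patient effect) x FC(class, condition) / total`,
dispersion 0.1 (typical bulk RNA-seq), depths 1-3 M, log-normal baselines
(sigma 1.0), per-(gene, patient) log2 random effect sigma 0.25 — which
cancels in paired fold changes, as in the real design. Planted classes:
null, IL-17A-only (log2 effect 1.0), TNF-only (1.5), additive
(`FC_combo = FC_a + FC_b`, exactly the pipeline's null, making type-I
behaviour directly measurable) and synergistic
(`FC_combo = 4 x (FC_a + FC_b)` by default). Effect-class genes draw
their baseline from the same log-normal scaled by 0.25: stimulus-
responsive cytokine/chemokine genes are lowly expressed in resting cells,
and concentrating planted mass in high-baseline genes would make the
simulated libraries unrealistically lopsided. Defaults: 5 patients,
2000 genes, 50 genes per planted class.

**NPX**: `NPX = baseline + condition effect + N(0, 0.25)` on the log2
scale, 4 conditions x 5 replicates; synergists at 2.1x the additive sum
(1.4x above the 1.5x calling threshold); six proteins are emitted on two
panels to exercise duplicate-assay merging.

**Cells**: six cell types with the study's marker assignments
(mesothelial cells the major population at 40%), Poisson marker counts
(rate 8) over 60 shared background genes, a 20-gene induced program
active in 40% of mesothelial cells, multinomial sample tags (depth 60,
92% purity), doublets as sums of two singlets from distinct sources with
mixed tags, and optional contaminants inside the mesothelial population
whose exclusion-marker counts are drawn as `1 + Poisson(rate - 1)` — i.e.
guaranteed expressed, which is the "zero-noise" contamination limit the
exact-removal property quantifies over.

What the generators do **not** model: gene-gene correlation, batch and
plate effects, library-preparation biases, ambient RNA, zero inflation
beyond NB/Poisson sparsity, NPX limits of detection, or cluster substructure
within non-mesothelial types. Passing recovery tests therefore shows the
statistics behave correctly under their stated assumptions — not that
those assumptions hold in any particular dataset.

## Numerical and engineering choices

* All thresholds live in one YAML config; defaults are the published
  values, flags override the file.
* Every stochastic step takes an explicit seed; CLI outputs (including
  logs and the JSON manifest) contain no timestamps or absolute paths, so
  identical seed + config + inputs reproduce byte-identical output trees.
* Boundary conventions: printed thresholds are inclusive ("at least",
  ">=", "<=") except the protein-synergy factor (">", strict) and the
  gene filter ("more than", strict).
* Problem sizes in the test suite and acceptance script (2000-gene bulk
  runs over 5 seeds, 80-protein NPX runs over 10 seeds, 200-1200-cell
  single-cell fixtures) are chosen so the full suite completes in well
  under a minute while keeping the binomial uncertainty of the measured
  rates small relative to their thresholds.

## Known limitations

* The paired-t DE stage is less powerful than NB empirical-Bayes methods
  at very low counts; with n = 5 patients, genes need consistent
  per-patient effects to pass FDR <= 0.05. Injecting an external DE
  table is the supported path where that matters.
* The additive-sum null treats single-treatment fold changes < 1 as
  reducing the expectation; for genes repressed by one factor and induced
  by the other the ratio can exceed 2 without biological synergy. The DE
  and induction gates bound, but do not eliminate, this effect.
* Cluster-level annotation assigns whole clusters; mixed clusters below
  the marker-fraction threshold come out "unknown" rather than being
  split.
* The Venn percentage of a 3-set partition is reported on two
  denominators (union and combination set) because published figures are
  quoted both ways; users should state which they cite.
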