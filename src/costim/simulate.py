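"""Seeded generators for bulk, NPX and tagged single-cell data with planted
ground truth.

Each generator emulates the statistical structure its pipeline assumes:

* ``simulate_bulk`` — negative-binomial counts for a paired design of
  patients x 4 conditions, with a log-normal baseline, a per-(gene,
  patient) log2-scale random effect (cancelled by paired fold changes) and
  planted effect classes.  Combination effects are constructed on the
  linear fold-change scale so "additive" genes sit exactly on the
  pipeline's additive null (FC_combo = FC_a + FC_b) and "synergistic"
  genes exceed it by a fixed ratio (FC_combo = r x (FC_a + FC_b)).

* ``simulate_npx`` — Gaussian log2-scale NPX values (baseline + condition
  effect + noise) for conditions x replicates, with a configurable subset
  of proteins duplicated across two panels.

* ``simulate_tagged_cells`` — targeted-panel single cells from several
  cell types with Poisson marker expression, per-cell sample-tag counts
  (multinomial, true source dominant), a controlled doublet rate (doublets
  sum two singlets from distinct sources and mix their tags), optional
  exclusion-marker-positive contaminants inside the mesothelial
  population, and an induced-gene program active in a subpopulation of
  mesothelial cells.

All generators are deterministic under a fixed seed and emit a truth table
in the same TSV dialect the pipeline reports use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import BulkExperiment, CellExperiment, NPXTable, TREATMENTS, ValidationError

BULK_CLASSES = ("null", "a_only", "b_only", "additive", "synergistic")

# Cytokine-induced genes used as the default targeted panel: chemokines,
# cytokines and matrix-remodeling genes characteristic of the
# mesenchymal/inflammatory program of stimulated mesothelial cells.
DEFAULT_INDUCED_GENES = (
    "CXCL1", "CXCL2", "CXCL3", "CXCL6", "CXCL8", "IL6", "IL1A", "IL33",
    "CCL20", "CSF3", "LIF", "ANGPTL4", "FN1", "CDH2", "MMP2", "MMP3",
    "COL16A1", "TNFAIP3", "NFKBIZ", "AREG",
)


def _planted_fcs(
    classes: np.ndarray, fc_a: float, fc_b: float, synergy_ratio: float
) -> pd.DataFrame:
    """Linear fold changes per condition implied by each effect class."""
    n = len(classes)
    fc = pd.DataFrame(
        {"IL17A": np.ones(n), "TNF": np.ones(n), "combo": np.ones(n)}
    )
    a = np.isin(classes, ("a_only",))
    b = np.isin(classes, ("b_only",))
    both = np.isin(classes, ("additive", "synergistic"))
    fc.loc[a, ["IL17A", "combo"]] = fc_a
    fc.loc[b, ["TNF", "combo"]] = fc_b
    fc.loc[both, "IL17A"] = fc_a
    fc.loc[both, "TNF"] = fc_b
    fc.loc[classes == "additive", "combo"] = fc_a + fc_b
    fc.loc[classes == "synergistic", "combo"] = synergy_ratio * (fc_a + fc_b)
    return fc


@dataclass
class BulkSimSpec:
    """Planted-effect bulk RNA-seq simulation parameters.

    The defaults mirror the assumed study design: 5 patients x 4
    conditions, one library each, 1-3 M reads, NB dispersion 0.1.  Effect
    sizes are log2 fold changes of the single treatments (IL-17A weaker
    than TNF); combination effects follow from the class.  Effect-class
    genes draw their baseline from the same log-normal as null genes,
    scaled down by ``effect_baseline_scale`` (stimulus-responsive genes
    are lowly expressed in resting cells).
    """

    n_genes: int = 2000
    n_patients: int = 5
    class_counts: dict[str, int] | None = None
    log2_effect_a: float = 1.0
    log2_effect_b: float = 1.5
    synergy_ratio: float = 4.0
    nb_dispersion: float = 0.1
    patient_sd: float = 0.25
    depth_range: tuple[int, int] = (1_000_000, 3_000_000)
    baseline_sigma: float = 1.0
    effect_baseline_scale: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_counts is None:
            planted = {"a_only": 50, "b_only": 50, "additive": 50, "synergistic": 50}
            n_planted = sum(planted.values())
            if self.n_genes < n_planted:
                raise ValidationError(f"n_genes must be >= {n_planted} for default classes")
            self.class_counts = {"null": self.n_genes - n_planted, **planted}
        unknown = set(self.class_counts) - set(BULK_CLASSES)
        if unknown:
            raise ValidationError(f"unknown effect class(es): {sorted(unknown)}")
        if any(v < 0 for v in self.class_counts.values()):
            raise ValidationError("class counts must be >= 0")
        if sum(self.class_counts.values()) != self.n_genes:
            raise ValidationError(
                f"class counts sum to {sum(self.class_counts.values())}, expected {self.n_genes}"
            )
        if self.log2_effect_a <= 0 or self.log2_effect_b <= 0:
            raise ValidationError("single-treatment log2 effects must be > 0")
        if self.synergy_ratio <= 0:
            raise ValidationError("synergy_ratio must be > 0")
        if self.nb_dispersion < 0 or self.patient_sd < 0:
            raise ValidationError("nb_dispersion and patient_sd must be >= 0")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ValidationError("depth_range must satisfy 0 < low <= high")
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean mu, var mu + dispersion*mu^2); Poisson in the limit."""
    mu = np.asarray(mu, dtype=float)
    if dispersion < 1e-12:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mu))


def simulate_bulk(spec: BulkSimSpec) -> tuple[BulkExperiment, pd.DataFrame]:
    """Simulate a paired 4-condition bulk experiment with planted effects.

    Returns the experiment and a truth table (gene, class, planted linear
    fold changes per condition, baseline weight).
    """
    rng = np.random.default_rng(spec.seed)
    classes = np.repeat(
        list(spec.class_counts), list(spec.class_counts.values())
    ).astype(object)
    classes = classes[rng.permutation(spec.n_genes)]
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]

    weights = rng.lognormal(0.0, spec.baseline_sigma, spec.n_genes)
    weights[classes != "null"] *= spec.effect_baseline_scale

    fc_a = float(np.exp2(spec.log2_effect_a))
    fc_b = float(np.exp2(spec.log2_effect_b))
    fcs = _planted_fcs(classes, fc_a, fc_b, spec.synergy_ratio)

    patient_mult = np.exp2(
        rng.normal(0.0, spec.patient_sd, size=(spec.n_genes, spec.n_patients))
    )

    conditions = ("control",) + TREATMENTS
    columns, design_rows = {}, []
    for p in range(spec.n_patients):
        patient = f"P{p + 1}"
        for condition in conditions:
            depth = int(rng.integers(spec.depth_range[0], spec.depth_range[1] + 1))
            fc = np.ones(spec.n_genes) if condition == "control" else fcs[condition].to_numpy()
            expr = weights * patient_mult[:, p] * fc
            mu = depth * expr / expr.sum()
            sample_id = f"{patient}_{condition}"
            columns[sample_id] = _nb_draw(rng, mu, spec.nb_dispersion)
            design_rows.append(
                {"sample_id": sample_id, "patient_id": patient,
                 "condition": condition, "replicate": 1}
            )

    counts = pd.DataFrame(columns, index=pd.Index(genes, name="gene"), dtype=np.int64)
    exp = BulkExperiment(counts=counts, design=pd.DataFrame(design_rows))
    truth = pd.DataFrame(
        {
            "gene": genes,
            "class": classes,
            "fc_a": fcs["IL17A"].to_numpy(),
            "fc_b": fcs["TNF"].to_numpy(),
            "fc_combo": fcs["combo"].to_numpy(),
            "baseline_weight": weights,
        }
    )
    return exp, truth


@dataclass
class NPXSimSpec:
    """Planted-effect NPX (log2-scale proteomics) simulation parameters.

    Defaults mirror the assumed secretome design: 4 conditions x 5
    biological replicates, Gaussian NPX noise sigma 0.25, and a handful of
    proteins measured on two panels.  Synergistic proteins get a
    combination FC of ``synergy_multiple`` x the additive sum (default 2.1,
    i.e. 1.4x above the 1.5x calling threshold); additive proteins sit
    exactly on FC_a + FC_b.
    """

    n_proteins: int = 80
    n_replicates: int = 5
    sigma_npx: float = 0.25
    class_counts: dict[str, int] | None = None
    log2_effect_a: float = 1.0
    log2_effect_b: float = 1.5
    synergy_multiple: float = 2.1
    n_duplicated: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 3:
            raise ValidationError("n_replicates must be >= 3 for the downstream tests")
        if self.class_counts is None:
            planted = {"a_only": 10, "b_only": 10, "additive": 10, "synergistic": 10}
            n_planted = sum(planted.values())
            if self.n_proteins < n_planted:
                raise ValidationError(f"n_proteins must be >= {n_planted} for default classes")
            self.class_counts = {"null": self.n_proteins - n_planted, **planted}
        unknown = set(self.class_counts) - set(BULK_CLASSES)
        if unknown:
            raise ValidationError(f"unknown effect class(es): {sorted(unknown)}")
        if sum(self.class_counts.values()) != self.n_proteins:
            raise ValidationError("class counts must sum to n_proteins")
        if self.sigma_npx < 0:
            raise ValidationError("sigma_npx must be >= 0")
        if self.synergy_multiple <= 0:
            raise ValidationError("synergy_multiple must be > 0")
        if not 0 <= self.n_duplicated <= self.n_proteins:
            raise ValidationError("n_duplicated must be in [0, n_proteins]")


def simulate_npx(spec: NPXSimSpec) -> tuple[NPXTable, pd.DataFrame]:
    """Simulate a long-format NPX table with planted protein classes."""
    rng = np.random.default_rng(spec.seed)
    classes = np.repeat(
        list(spec.class_counts), list(spec.class_counts.values())
    ).astype(object)
    classes = classes[rng.permutation(spec.n_proteins)]
    proteins = [f"PR{i:04d}" for i in range(spec.n_proteins)]

    fc_a = float(np.exp2(spec.log2_effect_a))
    fc_b = float(np.exp2(spec.log2_effect_b))
    fcs = _planted_fcs(classes, fc_a, fc_b, spec.synergy_multiple)
    baselines = rng.uniform(2.0, 10.0, spec.n_proteins)
    duplicated = set(proteins[: spec.n_duplicated])

    conditions = ("control",) + TREATMENTS
    records = []
    for i, protein in enumerate(proteins):
        panels = ("panel_A", "panel_B") if protein in duplicated else ("panel_A",)
        for condition in conditions:
            effect = 0.0 if condition == "control" else float(np.log2(fcs.loc[i, condition]))
            for replicate in range(1, spec.n_replicates + 1):
                for panel in panels:
                    records.append(
                        {
                            "protein_id": protein,
                            "panel_id": panel,
                            "sample_id": f"{condition}_r{replicate}",
                            "condition": condition,
                            "replicate": replicate,
                            "npx": baselines[i] + effect + rng.normal(0.0, spec.sigma_npx),
                        }
                    )
    table = NPXTable(records=pd.DataFrame(records))
    truth = pd.DataFrame(
        {
            "protein_id": proteins,
            "class": classes,
            "fc_a": fcs["IL17A"].to_numpy(),
            "fc_b": fcs["TNF"].to_numpy(),
            "fc_combo": fcs["combo"].to_numpy(),
            "duplicated": [p in duplicated for p in proteins],
        }
    )
    return table, truth


@dataclass
class SimCellType:
    """One simulated cell type: its marker genes and their Poisson rate."""

    name: str
    markers: tuple[str, ...]
    proportion: float
    marker_rate: float = 8.0


def default_cell_types() -> list[SimCellType]:
    """Six cell types matching the study's marker assignments, with
    mesothelial cells as the major population."""
    return [
        SimCellType("mesothelial", ("ITLN1", "HP", "UPK3B"), 0.40),
        SimCellType("epithelial", ("CLDN4", "EPCAM"), 0.12),
        SimCellType("macrophage", ("FCER1G", "LYZ"), 0.12),
        SimCellType("t_cell", ("CD3E", "GZMB"), 0.12),
        SimCellType("b_cell", ("IGHM", "JCHAIN"), 0.12),
        SimCellType("adipocyte", ("JCAD", "S1PR1", "VWF"), 0.12),
    ]


@dataclass
class CellSimSpec:
    """Tagged targeted-panel single-cell simulation parameters.

    Singlets draw background-gene counts shared by all types plus
    Poisson marker counts for their own type (off-type markers at the
    ``bleed_through`` rate, default 0).  A fraction of mesothelial cells
    runs the induced-gene program; a fraction are contaminants expressing
    ``contaminant_markers`` (guaranteed >= 1 count: the zero-noise
    contamination limit).  Doublets sum two singlets from distinct sources
    and mix their tag distributions.
    """

    cell_types: list[SimCellType] = field(default_factory=default_cell_types)
    n_cells: int = 1200
    n_sources: int = 3
    doublet_rate: float = 0.05
    tag_depth: int = 60
    tag_purity: float = 0.92
    n_background_genes: int = 60
    background_rate: float = 8.0
    bleed_through: float = 0.0
    induced_genes: tuple[str, ...] = DEFAULT_INDUCED_GENES
    induced_fraction: float = 0.4
    induced_rate: float = 3.0
    contaminant_fraction: float = 0.0
    contaminant_markers: tuple[str, ...] = ("EPCAM",)
    contaminant_rate: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cell_types:
            raise ValidationError("at least one cell type is required")
        if not 0 <= self.doublet_rate < 0.5:
            raise ValidationError("doublet_rate must be in [0, 0.5)")
        props = [t.proportion for t in self.cell_types]
        if any(p <= 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
            raise ValidationError("cell type proportions must be positive and sum to 1")
        marker_owner: dict[str, str] = {}
        for t in self.cell_types:
            if not t.markers:
                raise ValidationError(f"cell type {t.name!r} has no markers")
            for m in t.markers:
                marker_owner.setdefault(m, t.name)
        for t in self.cell_types:
            if not any(marker_owner[m] == t.name and
                       sum(m in o.markers for o in self.cell_types) == 1
                       for m in t.markers):
                raise ValidationError(f"cell type {t.name!r} has no unique marker")
        if self.n_sources < 2:
            raise ValidationError("n_sources must be >= 2 (tags are uninformative otherwise)")
        if self.tag_depth < 1:
            raise ValidationError("tag_depth must be >= 1")
        if not 0.5 < self.tag_purity <= 1:
            raise ValidationError("tag_purity must be in (0.5, 1]")
        if not 0 <= self.induced_fraction <= 1 or not 0 <= self.contaminant_fraction <= 1:
            raise ValidationError("fractions must be in [0, 1]")
        if self.contaminant_rate < 1:
            raise ValidationError("contaminant_rate must be >= 1")


def simulate_tagged_cells(spec: CellSimSpec) -> tuple[CellExperiment, pd.DataFrame]:
    """Simulate tagged targeted single cells with planted ground truth.

    Truth table columns: barcode, cell_type ("doublet" for doublets, with
    the two constituent types recorded), source ("mixed" for doublets),
    is_doublet, is_contaminant, is_activated.
    """
    rng = np.random.default_rng(spec.seed)
    marker_genes = [m for t in spec.cell_types for m in t.markers]
    genes = (
        [f"BG{i:03d}" for i in range(spec.n_background_genes)]
        + list(dict.fromkeys(marker_genes))
        + [g for g in spec.induced_genes if g not in marker_genes]
    )
    for m in spec.contaminant_markers:
        if m not in genes:
            genes.append(m)
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    n_doublets = int(round(spec.n_cells * spec.doublet_rate))
    n_singlets = spec.n_cells - n_doublets
    type_names = [t.name for t in spec.cell_types]
    props = np.array([t.proportion for t in spec.cell_types])

    def singlet_counts(ct: SimCellType, activated: bool) -> np.ndarray:
        row = np.zeros(n_genes)
        row[: spec.n_background_genes] = rng.poisson(
            spec.background_rate, spec.n_background_genes
        )
        if spec.bleed_through > 0:
            for t in spec.cell_types:
                for m in t.markers:
                    row[gene_index[m]] = rng.poisson(spec.bleed_through)
        for m in ct.markers:
            row[gene_index[m]] = rng.poisson(ct.marker_rate)
        if activated:
            for g in spec.induced_genes:
                row[gene_index[g]] = rng.poisson(spec.induced_rate)
        return row

    def tag_probs(source: int) -> np.ndarray:
        p = np.full(spec.n_sources, (1.0 - spec.tag_purity) / (spec.n_sources - 1))
        p[source] = spec.tag_purity
        return p

    counts = np.zeros((spec.n_cells, n_genes), dtype=np.int64)
    tag_counts = np.zeros((spec.n_cells, spec.n_sources), dtype=np.int64)
    truth_rows = []

    type_idx = rng.choice(len(spec.cell_types), size=n_singlets, p=props)
    sources = rng.integers(spec.n_sources, size=n_singlets)
    meso = [i for i, ti in enumerate(type_idx) if type_names[ti] == "mesothelial"]
    n_contam = int(round(spec.contaminant_fraction * len(meso)))
    contaminants = set(meso[:n_contam])
    activated_draw = rng.random(n_singlets) < spec.induced_fraction

    for i in range(n_singlets):
        ct = spec.cell_types[type_idx[i]]
        is_meso = ct.name == "mesothelial"
        activated = bool(is_meso and activated_draw[i])
        counts[i] = singlet_counts(ct, activated)
        is_contam = i in contaminants
        if is_contam:
            for m in spec.contaminant_markers:
                counts[i, gene_index[m]] = 1 + rng.poisson(spec.contaminant_rate - 1)
        tag_counts[i] = rng.multinomial(spec.tag_depth, tag_probs(int(sources[i])))
        truth_rows.append(
            {
                "cell_type": ct.name,
                "source": f"tag{sources[i] + 1}",
                "is_doublet": False,
                "is_contaminant": is_contam,
                "is_activated": activated,
            }
        )

    for j in range(n_doublets):
        i = n_singlets + j
        ti1, ti2 = rng.choice(len(spec.cell_types), size=2, p=props)
        s1 = int(rng.integers(spec.n_sources))
        s2 = int((s1 + 1 + rng.integers(spec.n_sources - 1)) % spec.n_sources)
        counts[i] = singlet_counts(spec.cell_types[ti1], False) + singlet_counts(
            spec.cell_types[ti2], False
        )
        mix = rng.uniform(0.35, 0.65)
        p = mix * tag_probs(s1) + (1 - mix) * tag_probs(s2)
        tag_counts[i] = rng.multinomial(spec.tag_depth, p)
        truth_rows.append(
            {
                "cell_type": f"doublet:{type_names[ti1]}+{type_names[ti2]}",
                "source": "mixed",
                "is_doublet": True,
                "is_contaminant": False,
                "is_activated": False,
            }
        )

    order = rng.permutation(spec.n_cells)
    counts = counts[order]
    tag_counts = tag_counts[order]
    barcodes = [f"cell{i:05d}" for i in range(spec.n_cells)]
    truth = pd.DataFrame([truth_rows[k] for k in order])
    truth.insert(0, "barcode", barcodes)

    ce = CellExperiment.from_arrays(
        counts=counts,
        barcodes=barcodes,
        genes=genes,
        tag_counts=tag_counts,
        tag_names=[f"tag{i + 1}" for i in range(spec.n_sources)],
    )
    return ce, truth


def class_call_rates(truth: pd.DataFrame, calls: pd.Series, id_column: str) -> pd.Series:
    """Fraction of features of each planted class that the pipeline called.

    ``calls`` is a boolean Series indexed by feature id; features absent
    from ``calls`` (e.g. filtered out upstream) count as not called.  The
    sensitivity on planted synergists is ``rates["synergistic"]``; the
    false-call rate on exactly-additive features is ``rates["additive"]``.
    """
    called = truth[id_column].map(calls).fillna(False).astype(bool)
    return called.groupby(truth["class"]).mean()
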