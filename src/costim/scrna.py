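"""Targeted single-cell annotation and mesothelial purification.

The post-quantification procedure for multiplexed, targeted-panel
single-cell data runs in a fixed stage order:

    demux -> cell filter -> gene filter -> normalize -> cluster ->
    annotate -> purify -> re-cluster -> profile

Demultiplexing assigns each cell to its source sample from per-cell
sample-tag counts (>= 5 tags required; a cell whose second most common tag
reaches 25% of its top tag is a multiplet).  Cells are kept with >= 20
detected genes and >= 400 reads; genes are kept when detected in more than
21 cells.  Counts are scaled to 10,000 per cell and log-transformed
(ln(1 + x)).  Cells are clustered with Louvain community detection on a
k-nearest-neighbor graph over the top principal components.  Clusters are
annotated from positive marker genes (mesothelial: ITLN1, HP, UPK3B);
mesothelial clusters are then purified by removing every cell that
expresses any exclusion lineage marker (epithelial CLDN4/EPCAM, macrophage
FCER1G/LYZ, T cell CD3E/GZMB, B cell IGHM/JCHAIN, adipocyte
JCAD/S1PR1/VWF).  Finally the purified cells are re-clustered and profiled
for the cytokine-induced gene panel.

"Expression" throughout means a raw count > 0.
"""

from __future__ import annotations

import logging
import random
import warnings
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .bulk import AnalysisError
from .types import CellExperiment, MarkerPanel

logger = logging.getLogger(__name__)

UNASSIGNED_LOW_TAGS = "unassigned_low_tags"
MULTIPLET = "multiplet"


def demux_sample_tags(
    tag_counts: pd.DataFrame, min_tags: int = 5, second_fraction: float = 0.25
) -> pd.DataFrame:
    """Assign each cell to a source sample from its tag counts.

    Rules, applied per cell: total tags < ``min_tags`` -> unassigned;
    second-highest tag count >= ``second_fraction`` x highest -> multiplet
    (ties for the top tag are therefore always multiplets); otherwise the
    cell is assigned to the most common tag.
    """
    counts = tag_counts.to_numpy(dtype=np.int64)
    tags = np.asarray(tag_counts.columns, dtype=object)
    totals = counts.sum(axis=1)
    order = np.sort(counts, axis=1)
    top = order[:, -1]
    second = order[:, -2] if counts.shape[1] > 1 else np.zeros_like(top)

    assigned = tags[np.argmax(counts, axis=1)].copy()
    multiplet = second >= second_fraction * top
    low = totals < min_tags
    assigned[multiplet] = MULTIPLET
    assigned[low] = UNASSIGNED_LOW_TAGS  # low-tag rule takes precedence

    result = pd.DataFrame(
        {
            "assigned_source": assigned,
            "total_tag_count": totals,
            "top_tag_count": top,
            "second_tag_count": second,
        },
        index=tag_counts.index,
    )
    n_ok = int((~(multiplet | low)).sum())
    logger.info(
        "demux: %d cells -> %d assigned, %d multiplet, %d low-tag",
        len(result), n_ok, int((multiplet & ~low).sum()), int(low.sum()),
    )
    return result


def apply_demux(ce: CellExperiment, demux: pd.DataFrame) -> CellExperiment:
    """Keep assigned cells only and record their source sample."""
    keep = ~demux["assigned_source"].isin([UNASSIGNED_LOW_TAGS, MULTIPLET])
    out = ce.subset_cells(keep.to_numpy())
    out.adata.obs["source_sample"] = demux.loc[keep, "assigned_source"].to_numpy()
    logger.info("demux filter: %d -> %d cells", ce.n_cells, out.n_cells)
    return out


def filter_cells(ce: CellExperiment, min_genes: int = 20, min_reads: int = 400) -> CellExperiment:
    """Keep cells with >= min_genes detected genes and >= min_reads total
    counts (both boundaries inclusive)."""
    X = ce.counts
    genes_per_cell = X.getnnz(axis=1)
    reads_per_cell = np.asarray(X.sum(axis=1)).ravel()
    keep = (genes_per_cell >= min_genes) & (reads_per_cell >= min_reads)
    removed = np.flatnonzero(~keep)
    for i in removed[:50]:
        logger.info(
            "cell filter: removed %s (genes=%d, reads=%d)",
            ce.cells[i], genes_per_cell[i], reads_per_cell[i],
        )
    logger.info("cell filter: %d -> %d cells", ce.n_cells, int(keep.sum()))
    if not keep.any():
        raise AnalysisError(
            "no cells survive the cell filter; review min_genes/min_reads "
            f"({min_genes}/{min_reads}) against the library depth"
        )
    return ce.subset_cells(keep)


def filter_genes(ce: CellExperiment, min_cells_strict: int = 21) -> CellExperiment:
    """Keep genes detected in strictly more than ``min_cells_strict`` cells."""
    cells_per_gene = ce.counts.getnnz(axis=0)
    keep = cells_per_gene > min_cells_strict
    logger.info("gene filter: %d -> %d genes", ce.n_genes, int(keep.sum()))
    return ce.subset_genes(keep)


def normalize_log10k(ce: CellExperiment, target_sum: float = 10000.0) -> sp.csr_matrix:
    """Scale each cell to ``target_sum`` total counts, then ln(1 + x)."""
    reads = np.asarray(ce.counts.sum(axis=1)).ravel()
    zero = np.flatnonzero(reads == 0)
    if len(zero):
        raise AnalysisError(
            f"cell(s) with zero total counts cannot be normalized: "
            f"{[ce.cells[i] for i in zero[:10]]}"
        )
    adata = ce.adata.copy()
    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    return sp.csr_matrix(adata.X)


def cluster_cells(
    norm_matrix,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    n_pcs: int = 20,
    method: str = "louvain",
) -> np.ndarray:
    """Community detection on a kNN graph over principal components.

    The graph is built from the ``n_neighbors`` nearest neighbors (cosine
    of Euclidean distance on the top ``n_pcs`` components), symmetrized,
    and clustered with Louvain (igraph's multilevel modularity optimizer,
    seeded) or Leiden (``method="leiden"``).  Labels are integers 0..K-1,
    relabeled by decreasing cluster size; deterministic given the seed.
    """
    X = norm_matrix.toarray() if sp.issparse(norm_matrix) else np.asarray(norm_matrix)
    n_cells = X.shape[0]
    if n_cells < n_neighbors + 1:
        raise AnalysisError(
            f"clustering needs more cells ({n_cells}) than neighbors ({n_neighbors})"
        )
    n_comps = min(n_pcs, n_cells - 1, X.shape[1] - 1)
    if n_comps >= 1:
        X = PCA(n_components=n_comps, svd_solver="full", random_state=seed).fit_transform(X)
    adj = kneighbors_graph(X, n_neighbors=n_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    graph = igraph.Graph(n=n_cells, edges=edges)

    if method == "louvain":
        igraph.set_random_number_generator(random.Random(int(seed)))
        try:
            partition = graph.community_multilevel(resolution=resolution)
        except TypeError:  # older igraph without the resolution argument
            partition = graph.community_multilevel()
        membership = np.asarray(partition.membership)
    elif method == "leiden":
        import leidenalg

        partition = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=int(seed),
            n_iterations=2,
        )
        membership = np.asarray(partition.membership)
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    # stable relabeling: by decreasing size, ties by smallest original label
    sizes = pd.Series(membership).value_counts().sort_index()
    order = sizes.sort_values(ascending=False, kind="stable").index
    remap = {old: new for new, old in enumerate(order)}
    labels = np.asarray([remap[m] for m in membership], dtype=np.int64)
    logger.info(
        "%s clustering: %d cells -> %d clusters (resolution %g)",
        method, n_cells, labels.max() + 1, resolution,
    )
    return labels


def _positive_fraction(ce: CellExperiment, labels: np.ndarray, genes: list[str]) -> pd.Series:
    """Per cluster: fraction of cells with count > 0 for ANY of the genes."""
    present = [g for g in genes if g in ce.genes]
    idx = [ce.genes.index(g) for g in present]
    if not idx:
        return pd.Series(0.0, index=np.unique(labels))
    positive = np.asarray((ce.counts[:, idx] > 0).sum(axis=1)).ravel() > 0
    return pd.Series(positive).groupby(labels).mean()


def annotate_cell_types(
    ce: CellExperiment,
    labels: np.ndarray,
    panel: MarkerPanel,
    marker_fraction: float = 0.5,
) -> pd.Series:
    """Label each cluster with a cell type from positive marker expression.

    A cluster gets a type when the fraction of its cells expressing ANY of
    that type's positive markers exceeds ``marker_fraction``; with several
    qualifying types the highest fraction wins (ties broken by type name
    for determinism).  Clusters matching no type are "unknown".  Panel
    genes absent from the (targeted) gene list are skipped with a warning.
    """
    clusters = np.unique(labels)
    fractions = {}
    for cell_type, genes in panel.positive.items():
        missing = [g for g in genes if g not in ce.genes]
        if missing:
            warnings.warn(
                f"positive marker(s) {missing} for {cell_type!r} absent from the "
                "gene list; skipped", stacklevel=2,
            )
        fractions[cell_type] = _positive_fraction(ce, labels, list(genes)).reindex(
            clusters, fill_value=0.0
        )
    frac = pd.DataFrame(fractions)  # clusters x types
    assigned = {}
    for cluster in clusters:
        row = frac.loc[cluster]
        qualifying = row[row > marker_fraction]
        if qualifying.empty:
            assigned[cluster] = "unknown"
        else:
            best = qualifying.sort_index().idxmax()  # sort first: ties -> name order
            assigned[cluster] = best
    result = pd.Series(assigned, name="cell_type")
    logger.info("annotation: %s", dict(result))
    return result


def purify_mesothelial(
    ce: CellExperiment,
    labels: np.ndarray,
    panel: MarkerPanel,
    cluster_types: pd.Series,
    mesothelial_type: str = "mesothelial",
) -> CellExperiment:
    """Retain mesothelial-cluster cells free of every exclusion marker.

    A cell survives iff its cluster is annotated ``mesothelial_type`` and it
    has zero counts for each of that type's exclusion markers.  Removal
    tallies per marker are logged.
    """
    meso_clusters = set(cluster_types.index[cluster_types == mesothelial_type])
    if not meso_clusters:
        raise AnalysisError(f"no cluster annotated as {mesothelial_type!r}")
    in_meso = np.isin(labels, sorted(meso_clusters))

    exclusion = [g for g in panel.exclusion.get(mesothelial_type, []) if g in ce.genes]
    contaminated = np.zeros(ce.n_cells, dtype=bool)
    for gene in exclusion:
        gi = ce.genes.index(gene)
        positive = np.asarray((ce.counts[:, gi] > 0).todense()).ravel()
        n_hit = int((positive & in_meso).sum())
        if n_hit:
            logger.info("purification: %d mesothelial-cluster cell(s) express %s", n_hit, gene)
        contaminated |= positive
    keep = in_meso & ~contaminated
    logger.info(
        "purification: %d mesothelial-cluster cells -> %d after exclusion-marker filter",
        int(in_meso.sum()), int(keep.sum()),
    )
    out = ce.subset_cells(keep)
    out.adata.obs["cell_type"] = mesothelial_type
    return out


@dataclass
class ClusterProfiles:
    """Per-cluster summaries of an induced-gene panel.

    ``profiles``: one row per cluster (cell_count, induced_gene_count =
    panel genes with >= 1 expressing cell in the cluster).
    ``fraction_positive``: genes x clusters fractions of expressing cells.
    ``display_genes``: induced genes expressed in at least
    ``display_fraction`` of the cells of at least one cluster.
    ``display_matrix``: mean log-normalized expression (genes x clusters)
    for the display genes.
    """

    profiles: pd.DataFrame
    fraction_positive: pd.DataFrame
    display_genes: list[str] = field(default_factory=list)
    display_matrix: pd.DataFrame = field(default_factory=pd.DataFrame)


def profile_clusters(
    ce: CellExperiment,
    labels: np.ndarray,
    induced_genes: list[str],
    display_fraction: float = 0.20,
    target_sum: float = 10000.0,
) -> ClusterProfiles:
    """Score each cluster for detection of the induced-gene panel."""
    clusters = np.unique(labels)
    present = [g for g in induced_genes if g in ce.genes]
    absent = [g for g in induced_genes if g not in ce.genes]
    if absent:
        warnings.warn(
            f"{len(absent)} induced panel gene(s) absent from the gene list "
            "(counted as undetected)", stacklevel=2,
        )
    idx = [ce.genes.index(g) for g in present]
    positive = sp.csr_matrix(ce.counts[:, idx] > 0) if idx else sp.csr_matrix((ce.n_cells, 0))
    lognorm = normalize_log10k(ce, target_sum=target_sum)[:, idx] if idx else None

    frac = pd.DataFrame(index=present, columns=clusters, dtype=float)
    mean_log = pd.DataFrame(index=present, columns=clusters, dtype=float)
    cell_counts, induced_counts = {}, {}
    for cluster in clusters:
        mask = labels == cluster
        n = int(mask.sum())
        cell_counts[cluster] = n
        pos_counts = np.asarray(positive[mask].sum(axis=0)).ravel()
        frac[cluster] = pos_counts / n
        induced_counts[cluster] = int((pos_counts > 0).sum())
        if lognorm is not None:
            mean_log[cluster] = np.asarray(lognorm[mask].mean(axis=0)).ravel()
    profiles = pd.DataFrame(
        {
            "cluster": clusters,
            "cell_count": [cell_counts[c] for c in clusters],
            "induced_gene_count": [induced_counts[c] for c in clusters],
        }
    )
    display = [g for g in present if (frac.loc[g] >= display_fraction).any()]
    logger.info(
        "profiles: %d clusters; %d of %d induced genes detected overall; "
        "%d genes in the display set",
        len(clusters), int((frac.to_numpy().sum(axis=1) > 0).sum()), len(induced_genes),
        len(display),
    )
    return ClusterProfiles(
        profiles=profiles,
        fraction_positive=frac,
        display_genes=display,
        display_matrix=mean_log.loc[display],
    )


@dataclass
class ScrnaResult:
    demux: pd.DataFrame
    qc_summary: pd.DataFrame
    cells: pd.DataFrame  # barcode, source_sample, cluster, cell_type
    cluster_types: pd.Series
    purified: CellExperiment
    purified_labels: np.ndarray
    profiles: ClusterProfiles


def run_scrna_pipeline(
    ce: CellExperiment,
    panel: MarkerPanel,
    induced_genes: list[str],
    seed: int = 0,
    min_tags: int = 5,
    second_fraction: float = 0.25,
    min_genes: int = 20,
    min_reads: int = 400,
    min_cells_strict: int = 21,
    target_sum: float = 10000.0,
    n_pcs: int = 20,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    cluster_method: str = "louvain",
    marker_fraction: float = 0.5,
    display_fraction: float = 0.20,
    mesothelial_type: str = "mesothelial",
) -> ScrnaResult:
    """The full fixed-order pipeline; every stage logs its dimensions."""
    qc_rows = [("input", ce.n_cells, ce.n_genes)]
    demux = demux_sample_tags(ce.tag_counts, min_tags=min_tags, second_fraction=second_fraction)
    ce1 = apply_demux(ce, demux)
    qc_rows.append(("demux", ce1.n_cells, ce1.n_genes))
    ce2 = filter_cells(ce1, min_genes=min_genes, min_reads=min_reads)
    qc_rows.append(("cell_filter", ce2.n_cells, ce2.n_genes))
    ce3 = filter_genes(ce2, min_cells_strict=min_cells_strict)
    qc_rows.append(("gene_filter", ce3.n_cells, ce3.n_genes))
    norm = normalize_log10k(ce3, target_sum=target_sum)
    labels = cluster_cells(
        norm, n_neighbors=n_neighbors, resolution=resolution, seed=seed,
        n_pcs=n_pcs, method=cluster_method,
    )
    cluster_types = annotate_cell_types(ce3, labels, panel, marker_fraction=marker_fraction)
    purified = purify_mesothelial(
        ce3, labels, panel, cluster_types, mesothelial_type=mesothelial_type
    )
    qc_rows.append(("purified", purified.n_cells, purified.n_genes))

    # re-clustering of the purified subset uses an independent seed
    if purified.n_cells >= n_neighbors + 1:
        purified_labels = cluster_cells(
            normalize_log10k(purified, target_sum=target_sum),
            n_neighbors=n_neighbors, resolution=resolution, seed=seed + 1,
            n_pcs=n_pcs, method=cluster_method,
        )
    else:
        logger.info(
            "re-clustering skipped: only %d purified cells for %d neighbors",
            purified.n_cells, n_neighbors,
        )
        purified_labels = np.zeros(purified.n_cells, dtype=np.int64)
    profiles = profile_clusters(
        purified, purified_labels, induced_genes,
        display_fraction=display_fraction, target_sum=target_sum,
    )

    cells = pd.DataFrame(
        {
            "barcode": ce3.cells,
            "source_sample": ce3.adata.obs["source_sample"].to_numpy(),
            "cluster": labels,
            "cell_type": cluster_types.loc[labels].to_numpy(),
        }
    )
    qc = pd.DataFrame(qc_rows, columns=["stage", "cells", "genes"])
    return ScrnaResult(
        demux=demux,
        qc_summary=qc,
        cells=cells,
        cluster_types=cluster_types,
        purified=purified,
        purified_labels=purified_labels,
        profiles=profiles,
    )
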