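"""Expression analysis: normalisation, variable genes, clustering,
markers, reference classification and sample-profile comparison.

Normalisation follows the median-scaling recipe: UMI counts are divided
by the cell total, multiplied by the median of cell totals, log
transformed (ln(1 + x), the pseudocount handling zeros), and finally
each gene is standardised to mean 0 / sd 1 across cells.  Variable
genes are ranked by normalised dispersion within 20 equal-frequency
mean-expression bins.  PCA + k-means operate on the standardised
matrix restricted to the top variable genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io_formats import GeneBarcodeMatrix

logger = logging.getLogger(__name__)

_EPS_MAD = 1e-12


@dataclass
class NormalizedMatrix:
    """Normalised expression with both log and standardised layers.

    ``lognorm`` is ln(1 + median-scaled counts), genes x cells;
    ``standardized`` additionally z-scores each gene (zero-variance
    genes dropped and listed).  Marker scoring uses the log layer, PCA
    the standardised one.
    """

    genes: list[str]                 # genes retained in ``standardized``
    cells: list[str]
    standardized: np.ndarray         # len(genes) x n_cells
    lognorm: np.ndarray              # lognorm_genes x n_cells
    lognorm_genes: list[str]
    scale_factors: np.ndarray        # per cell: median(total) / total
    gene_mean: np.ndarray
    gene_sd: np.ndarray
    dropped_zero_variance: list[str] = field(default_factory=list)
    dropped_cells: list[str] = field(default_factory=list)

    def subset_genes(self, genes: Sequence[str]) -> "NormalizedMatrix":
        """Restrict the standardised layer to ``genes`` (order preserved)."""
        index = {g: i for i, g in enumerate(self.genes)}
        keep = [index[g] for g in genes if g in index]
        sub_genes = [self.genes[i] for i in keep]
        return NormalizedMatrix(
            genes=sub_genes,
            cells=self.cells,
            standardized=self.standardized[keep],
            lognorm=self.lognorm,
            lognorm_genes=self.lognorm_genes,
            scale_factors=self.scale_factors,
            gene_mean=self.gene_mean[keep],
            gene_sd=self.gene_sd[keep],
            dropped_zero_variance=self.dropped_zero_variance,
            dropped_cells=self.dropped_cells,
        )


@dataclass
class ClusterResult:
    """K-means labels on the first PCs, with the scree for model choice."""

    labels: np.ndarray               # per-cell cluster label in 1..k
    k: int
    seed: int
    projections: np.ndarray          # n_cells x n_pcs PC coordinates
    sse_by_k: dict[int, float] = field(default_factory=dict)
    tsne: np.ndarray | None = None


@dataclass
class ReferenceProfileSet:
    """Mean expression profiles of purified populations.

    ``containment`` maps a population to the set of populations that
    are biological subsets of it (e.g. CD4+ helper contains CD4+
    naive); it drives the second-pass reassignment during
    classification and must be acyclic.
    """

    profiles: pd.DataFrame           # genes x populations
    containment: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.containment) - set(self.profiles.columns)
        if unknown:
            raise ValueError(f"containment for unknown populations {sorted(unknown)}")
        # cycle check by DFS
        visiting: set[str] = set()
        done: set[str] = set()

        def visit(p: str) -> None:
            if p in done:
                return
            if p in visiting:
                raise ValueError("containment map has a cycle")
            visiting.add(p)
            for q in self.containment.get(p, ()):  # q is a subset of p
                visit(q)
            visiting.discard(p)
            done.add(p)

        for p in self.containment:
            visit(p)

    @property
    def populations(self) -> list[str]:
        return list(self.profiles.columns)


def median_scaled(matrix: GeneBarcodeMatrix) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Median-of-totals scaling; returns (scaled dense counts, scale factors,
    kept cell indices).  Cells with zero totals are dropped with a warning."""
    totals = matrix.barcode_totals().astype(float)
    keep = [i for i, t in enumerate(totals) if t > 0]
    if len(keep) < len(totals):
        logger.warning("dropping %d cells with zero total UMIs", len(totals) - len(keep))
    if not keep:
        raise ValueError("no cell with a nonzero total")
    dense = np.asarray(matrix.counts[:, keep].todense(), dtype=float)
    totals = totals[keep]
    median_total = float(np.median(totals))
    scale = median_total / totals
    return dense * scale[None, :], scale, keep


def normalize(matrix: GeneBarcodeMatrix) -> NormalizedMatrix:
    """Median-scale, ln(1+x) transform and per-gene standardise."""
    scaled, scale, keep_cells = median_scaled(matrix)
    cells = [matrix.barcodes[i] for i in keep_cells]
    dropped_cells = [b for i, b in enumerate(matrix.barcodes) if i not in set(keep_cells)]

    detected = scaled.sum(axis=1) > 0  # genes with >=1 UMI in >=1 cell
    lognorm = np.log1p(scaled[detected])
    lognorm_genes = [g for g, d in zip(matrix.genes, detected) if d]

    mean = lognorm.mean(axis=1)
    sd = lognorm.std(axis=1)
    nonzero_var = sd > 0
    dropped = [g for g, ok in zip(lognorm_genes, nonzero_var) if not ok]
    standardized = (lognorm[nonzero_var] - mean[nonzero_var, None]) / sd[nonzero_var, None]
    return NormalizedMatrix(
        genes=[g for g, ok in zip(lognorm_genes, nonzero_var) if ok],
        cells=cells,
        standardized=standardized,
        lognorm=lognorm,
        lognorm_genes=lognorm_genes,
        scale_factors=scale,
        gene_mean=mean[nonzero_var],
        gene_sd=sd[nonzero_var],
        dropped_zero_variance=dropped,
        dropped_cells=dropped_cells,
    )


def select_variable_genes(
    matrix: GeneBarcodeMatrix, n_top: int = 1000, n_bins: int = 20
) -> list[str]:
    """Rank genes by normalised dispersion and return the top ``n_top``.

    Dispersion (variance/mean) is computed on median-scaled counts.
    Genes are placed into ``n_bins`` equal-frequency bins by mean
    expression; the normalised dispersion is the absolute difference
    from the bin median dispersion divided by the bin median absolute
    deviation (raw MAD, epsilon-guarded).  Ties break by gene ID so
    the ranking is invariant to input gene order.
    """
    scaled, _, _ = median_scaled(matrix)
    mean = scaled.mean(axis=1)
    var = scaled.var(axis=1)
    expressed = mean > 0
    if expressed.sum() < n_bins:
        raise ValueError(
            f"need >= {n_bins} genes with nonzero mean, found {int(expressed.sum())}"
        )
    genes = np.array(matrix.genes)[expressed]
    mean = mean[expressed]
    disp = var[expressed] / mean

    order = np.lexsort((genes, mean))  # mean-sorted, gene-ID tie-break
    bins = np.empty(len(genes), dtype=int)
    bins[order] = np.minimum((np.arange(len(genes)) * n_bins) // len(genes), n_bins - 1)

    norm_disp = np.empty(len(genes))
    for b in range(n_bins):
        sel = bins == b
        if not sel.any():
            continue
        med = np.median(disp[sel])
        mad = np.median(np.abs(disp[sel] - med))
        norm_disp[sel] = np.abs(disp[sel] - med) / max(mad, _EPS_MAD)

    rank = sorted(range(len(genes)), key=lambda i: (-norm_disp[i], genes[i]))
    return [genes[i] for i in rank[:n_top]]


def reduce_and_cluster(
    normalized: NormalizedMatrix,
    k: int,
    n_pcs: int = 50,
    seed: int = 0,
    k_range: Sequence[int] | None = None,
    compute_tsne: bool = False,
) -> ClusterResult:
    """PCA to ``n_pcs`` components, then seeded k-means on the projections.

    ``k_range`` additionally records the within-cluster sum of squared
    errors for each candidate k (the scree used to choose k).  tSNE
    coordinates, when requested, come from the standard Barnes-Hut
    implementation and are for visualisation only.
    """
    X = normalized.standardized.T  # cells x genes
    n_cells = X.shape[0]
    if k > n_cells:
        raise ValueError(f"k={k} exceeds {n_cells} cells")
    n_pcs = min(n_pcs, min(X.shape))
    proj = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)

    def _fit(kk: int) -> KMeans:
        return KMeans(n_clusters=kk, n_init=10, random_state=seed).fit(proj)

    km = _fit(k)
    sse = {k: float(km.inertia_)}
    if k_range is not None:
        for kk in k_range:
            if kk == k or kk > n_cells:
                continue
            sse[kk] = float(_fit(kk).inertia_)
    tsne = None
    if compute_tsne:
        from sklearn.manifold import TSNE

        tsne = TSNE(n_components=2, random_state=seed).fit_transform(proj)
    return ClusterResult(
        labels=km.labels_ + 1, k=k, seed=seed, projections=proj,
        sse_by_k=dict(sorted(sse.items())), tsne=tsne,
    )


def cluster_marker_genes(
    normalized: NormalizedMatrix,
    labels: Sequence[int],
    top_n: int = 10,
    other_summary: str = "median",
) -> tuple[dict[int, list[tuple[str, float]]], np.ndarray | None]:
    """Rank cluster-enriched genes and build a cluster dendrogram.

    The score of gene g in cluster c is the mean log-normalised
    expression over cells in c minus the median (or mean, via
    ``other_summary``) over the pooled cells of all other clusters.
    The dendrogram is average-linkage hierarchical clustering on
    1 - Pearson correlation between cluster mean expression vectors
    (None when fewer than 3 clusters).
    """
    labels = np.asarray(labels)
    X = normalized.lognorm  # genes x cells
    clusters = sorted(set(labels.tolist()))
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    summarise = np.median if other_summary == "median" else np.mean
    gene_ids = normalized.lognorm_genes

    markers: dict[int, list[tuple[str, float]]] = {}
    means = {}
    for c in clusters:
        in_c = labels == c
        if in_c.sum() == 1:
            logger.warning("cluster %s has a single cell", c)
        mean_c = X[:, in_c].mean(axis=1)
        other = summarise(X[:, ~in_c], axis=1)
        score = mean_c - other
        order = sorted(range(len(score)), key=lambda i: (-score[i], gene_ids[i]))
        markers[c] = [(gene_ids[i], float(score[i])) for i in order[:top_n]]
        means[c] = mean_c

    dendrogram = None
    if len(clusters) >= 3:
        M = np.column_stack([means[c] for c in clusters])
        corr = np.corrcoef(M.T)
        dist = squareform(1.0 - corr, checks=False)
        dendrogram = linkage(dist, method="average")
    return markers, dendrogram


def _spearman_vs_refs(cell: np.ndarray, ref_ranks: np.ndarray) -> np.ndarray:
    """Spearman correlations of one cell against pre-ranked references."""
    r = rankdata(cell)
    r = r - r.mean()
    denom = np.linalg.norm(r)
    if denom == 0:
        return np.full(ref_ranks.shape[1], np.nan)
    ref_norms = np.linalg.norm(ref_ranks, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (r @ ref_ranks) / (denom * ref_norms)


def classify_by_reference(
    matrix: GeneBarcodeMatrix, references: ReferenceProfileSet
) -> pd.DataFrame:
    """Assign each cell the reference population it best correlates with.

    Each cell's expression is compared with every purified-population
    mean profile by Spearman correlation over the common genes, and the
    cell takes the top population's label.  When the winner contains
    other populations as subsets (per the containment map) and the
    runner-up is one of those subsets, the label is refined to the
    runner-up — applied once, mirroring the CD4/CD8 subset rule.
    Cells with undefined correlations are labelled "unassigned".
    """
    common = [g for g in matrix.genes if g in set(references.profiles.index)]
    if not common:
        raise ValueError("no genes shared between matrix and references")
    g_idx = {g: i for i, g in enumerate(matrix.genes)}
    rows = [g_idx[g] for g in common]
    X = np.asarray(matrix.counts[rows].todense(), dtype=float)  # common genes x cells
    ref = references.profiles.loc[common]
    pops = references.populations
    ref_ranks = np.column_stack([rankdata(ref[p].to_numpy()) for p in pops])
    ref_ranks = ref_ranks - ref_ranks.mean(axis=0, keepdims=True)

    out_labels, out_rho = [], []
    for j in range(X.shape[1]):
        rho = _spearman_vs_refs(X[:, j], ref_ranks)
        if np.all(np.isnan(rho)):
            out_labels.append("unassigned")
            out_rho.append(np.nan)
            continue
        order = np.argsort(-np.where(np.isnan(rho), -np.inf, rho))
        winner = pops[order[0]]
        label = winner
        subsets = references.containment.get(winner, set())
        if subsets and len(order) > 1:
            runner_up = pops[order[1]]
            if runner_up in subsets:
                label = runner_up
        out_labels.append(label)
        out_rho.append(float(np.nanmax(rho)))
    return pd.DataFrame(
        {"barcode": matrix.barcodes, "label": out_labels, "correlation": out_rho}
    )


def compare_profiles(
    matrix_a: GeneBarcodeMatrix,
    matrix_b: GeneBarcodeMatrix,
    fold: float = 2.0,
    pseudocount: float = 0.0,
) -> tuple[float, list[str]]:
    """Compare two samples via their mean expression profiles.

    Returns the Pearson correlation between per-gene means (over genes
    detected in at least one cell of either sample) and the list of
    genes whose mean in B is at least ``fold`` times the mean in A.
    Callers should downsample both matrices to comparable depth first.
    Genes absent from A but present in B count as upregulated.
    """
    common = [g for g in matrix_a.genes if g in set(matrix_b.genes)]
    if not common:
        raise ValueError("empty gene intersection")
    ia = {g: i for i, g in enumerate(matrix_a.genes)}
    ib = {g: i for i, g in enumerate(matrix_b.genes)}
    mean_a = np.asarray(matrix_a.counts.mean(axis=1)).ravel()[[ia[g] for g in common]]
    mean_b = np.asarray(matrix_b.counts.mean(axis=1)).ravel()[[ib[g] for g in common]]
    detected = (mean_a > 0) | (mean_b > 0)
    mean_a, mean_b = mean_a[detected], mean_b[detected]
    genes = [g for g, d in zip(common, detected) if d]
    if len(genes) < 2:
        raise ValueError("fewer than 2 detected genes in common")
    r = float(np.corrcoef(mean_a, mean_b)[0, 1])
    a, b = mean_a + pseudocount, mean_b + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(a > 0, b / a, np.where(b > 0, np.inf, 1.0))
    up = [g for g, keep in zip(genes, ratio >= fold) if keep]
    return r, up
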