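"""QC, normalization, PCA, SNN graph construction, Louvain spot clustering,
marker-gene detection, and the intratissue replicate-consistency check.

The normalization is log1p of library-size-scaled counts (counts per
``scale_factor``), the dominant convention for UMI data.  Spots are
clustered on expression alone: a k-nearest-neighbour graph in PC space
with shared-nearest-neighbour Jaccard edge weights, partitioned by Louvain
modularity optimization.  Marker genes are called one-vs-rest with the
Wilcoxon rank-sum test and Seurat-style fraction/fold-change filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix
from .stats import bh_adjust, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedMatrix",
    "ClusterResult",
    "qc_filter",
    "normalize_log_cpm",
    "select_hvgs",
    "run_pca",
    "build_knn_graph",
    "louvain_cluster",
    "sweep_resolution",
    "find_markers",
    "replicate_consistency",
]


@dataclass
class NormalizedMatrix:
    """Log-scaled library-normalized expression, spots x genes."""

    values: np.ndarray
    barcodes: list[str]
    gene_ids: list[str]
    scale_factor: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.barcodes), len(self.gene_ids)):
            raise ValueError("values shape does not match barcode/gene lists")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        self.values = values


@dataclass
class ClusterResult:
    """Total partition of spots into size-ordered 0-based clusters."""

    labels: np.ndarray  # per-spot cluster id
    barcodes: list[str]
    resolution: float
    embedding: np.ndarray | None = None
    graph: nx.Graph | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        if labels.size != len(self.barcodes):
            raise ValueError("one label per barcode required")
        uniq = np.unique(labels)
        if labels.size and not np.array_equal(uniq, np.arange(uniq.size)):
            raise ValueError("cluster ids must be contiguous 0-based")
        self.labels = labels

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def members(self, cluster: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster)[0]


def qc_filter(
    matrix: CountMatrix, min_counts_per_spot: int = 0, min_spots_per_gene: int = 0
) -> CountMatrix:
    """Drop low-coverage spots and rarely detected genes."""
    if min_counts_per_spot < 0 or min_spots_per_gene < 0:
        raise ValueError("thresholds must be >= 0")
    spot_totals = np.asarray(matrix.counts.sum(axis=1)).ravel()
    spot_mask = spot_totals >= min_counts_per_spot
    if not spot_mask.any():
        raise ValueError("empty matrix after QC: all spots removed")
    kept = matrix.counts[spot_mask]
    detected = np.asarray((kept > 0).sum(axis=0)).ravel()
    gene_mask = detected >= min_spots_per_gene
    out = matrix.subset(spot_mask, gene_mask)
    logger.info(
        "QC kept %d/%d spots and %d/%d genes",
        out.n_spots, matrix.n_spots, out.n_genes, matrix.n_genes,
    )
    return out


def normalize_log_cpm(matrix: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """``log(1 + count * scale_factor / spot_total)`` per entry.

    All-zero spots stay all-zero rows (with a warning); every other spot's
    expm1 row sum equals ``scale_factor`` exactly, making the values
    invariant to per-spot sequencing depth.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    counts = matrix.dense().astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    zero = totals.ravel() == 0
    if zero.any():
        logger.warning("%d spot(s) have zero total counts", int(zero.sum()))
    safe_totals = np.where(totals == 0, 1.0, totals)
    values = np.log1p(counts * scale_factor / safe_totals)
    return NormalizedMatrix(values, list(matrix.barcodes), list(matrix.gene_ids), scale_factor)


def select_hvgs(norm: NormalizedMatrix, n_top: int = 2000) -> np.ndarray:
    """Mask of the top-``n_top`` genes by variance of normalized expression."""
    disp = norm.values.var(axis=0, ddof=1) if norm.values.shape[0] > 1 else norm.values.var(axis=0)
    n_top = min(n_top, disp.size)
    cutoff_idx = np.argsort(disp, kind="stable")[::-1][:n_top]
    mask = np.zeros(disp.size, dtype=bool)
    mask[cutoff_idx] = True
    return mask


def run_pca(
    norm: NormalizedMatrix,
    n_pcs: int = 30,
    center: bool = True,
    scale_genes: bool = True,
) -> np.ndarray:
    """Principal components of the normalized matrix, spots x n_pcs.

    Components come in decreasing explained-variance order; each
    component's sign is fixed so that its largest-magnitude gene loading
    is positive, making the embedding deterministic.
    """
    X = norm.values
    n_pcs_max = min(X.shape)
    if n_pcs > n_pcs_max:
        raise ValueError(f"n_pcs={n_pcs} exceeds min(spots, genes)={n_pcs_max}")
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if scale_genes:
        sd = X.std(axis=0, ddof=1, keepdims=True) if X.shape[0] > 1 else np.ones((1, X.shape[1]))
        sd = np.where(sd == 0, 1.0, sd)
        X = X / sd
    pca = PCA(n_components=n_pcs, svd_solver="full")
    emb = pca.fit_transform(X)
    # deterministic sign convention
    for j in range(n_pcs):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            emb[:, j] = -emb[:, j]
    return emb


def build_knn_graph(embedding: np.ndarray, k: int = 15, metric: str = "euclidean") -> nx.Graph:
    """Shared-nearest-neighbour graph over the embedding.

    An edge (i, j) exists iff j is among i's k nearest neighbours or vice
    versa; its weight is the Jaccard overlap of the two k-neighbourhoods.
    Zero-overlap edges are dropped.
    """
    n = embedding.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError("k must be smaller than the number of spots")
    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    neigh = idx[:, 1:]  # drop self
    # sparse neighbourhood indicator for fast set intersections
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix(
        (np.ones(n * k, dtype=np.int32), (rows, neigh.ravel())), shape=(n, n)
    )
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    sym = A.maximum(A.T)
    inter = (A @ A.T).toarray()
    sizes = np.full(n, k)
    cand = sp.triu(sym, k=1).tocoo()
    for i, j in zip(cand.row, cand.col):
        shared = inter[i, j]
        if shared == 0:
            continue
        union = sizes[i] + sizes[j] - shared
        graph.add_edge(int(i), int(j), weight=float(shared / union))
    return graph


def louvain_cluster(
    graph: nx.Graph,
    barcodes: list[str],
    resolution: float = 1.0,
    seed: int = 0,
    embedding: np.ndarray | None = None,
) -> ClusterResult:
    """Louvain community detection on the SNN graph.

    Deterministic at a fixed seed; communities are relabeled by decreasing
    size (ties broken by smallest member index).  A graph with no edges
    degenerates to singleton clusters with a warning.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if graph.number_of_edges() == 0:
        logger.warning("graph has no edges: every spot is its own cluster")
        communities = [{n} for n in graph.nodes]
    else:
        communities = nx.community.louvain_communities(
            graph, weight="weight", resolution=resolution, seed=seed
        )
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    labels = np.empty(graph.number_of_nodes(), dtype=int)
    for cid, members in enumerate(communities):
        labels[list(members)] = cid
    return ClusterResult(labels, list(barcodes), resolution, embedding, graph)


def sweep_resolution(
    graph: nx.Graph,
    barcodes: list[str],
    target_clusters: int,
    seed: int = 0,
    embedding: np.ndarray | None = None,
    low: float = 0.05,
    high: float = 4.0,
    max_iter: int = 12,
) -> ClusterResult:
    """Bisect the Louvain resolution toward a requested cluster count.

    The cluster count achieved on a given dataset depends on the
    resolution, which tissue atlases tune to the granularity of interest;
    this helper returns the result whose count is closest to the target
    (preferring lower resolution on ties).
    """
    best = None
    for _ in range(max_iter):
        mid = (low + high) / 2.0
        res = louvain_cluster(graph, barcodes, resolution=mid, seed=seed, embedding=embedding)
        if best is None or abs(res.n_clusters - target_clusters) < abs(
            best.n_clusters - target_clusters
        ):
            best = res
        if res.n_clusters == target_clusters:
            return res
        if res.n_clusters < target_clusters:
            low = mid
        else:
            high = mid
    return best


def find_markers(
    norm: NormalizedMatrix,
    clusters: ClusterResult,
    min_frac_in: float = 0.1,
    min_log2fc: float = 0.25,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker table.

    Per cluster and gene: two-sided rank-sum of in-cluster vs rest spots,
    detection fractions, and log2 fold change of mean expm1 expression
    (with a +1 stabilizer).  Genes must pass ``frac_in >= min_frac_in``
    and ``log2_fold_change >= min_log2fc``; q-values are BH-adjusted over
    the full tested set.  Clusters of size < 2 are skipped with a warning.
    """
    if clusters.n_clusters < 2:
        raise ValueError("need at least 2 clusters for marker detection")
    X = norm.values
    rows = []
    for c in range(clusters.n_clusters):
        mask = clusters.labels == c
        if mask.sum() < 2:
            logger.warning("cluster %d has fewer than 2 spots; skipped", c)
            continue
        inside = X[mask]
        outside = X[~mask]
        frac_in = (inside > 0).mean(axis=0)
        frac_out = (outside > 0).mean(axis=0)
        lfc = np.log2(
            (np.expm1(inside).mean(axis=0) + 1.0)
            / (np.expm1(outside).mean(axis=0) + 1.0)
        )
        keep = (frac_in >= min_frac_in) & (lfc >= min_log2fc)
        for g in np.nonzero(keep)[0]:
            p = wilcoxon_rank_sum(inside[:, g], outside[:, g])
            rows.append(
                (c, norm.gene_ids[g], float(lfc[g]), float(frac_in[g]), float(frac_out[g]), p)
            )
    if not rows:
        return pd.DataFrame(
            columns=["cluster", "gene", "log2_fold_change", "frac_in", "frac_out", "p", "q"]
        )
    table = pd.DataFrame(
        rows, columns=["cluster", "gene", "log2_fold_change", "frac_in", "frac_out", "p"]
    )
    table["q"] = np.maximum(bh_adjust(table["p"].to_numpy()), table["p"].to_numpy())
    return table.sort_values(
        ["cluster", "q", "log2_fold_change"], ascending=[True, True, False], ignore_index=True
    )


def replicate_consistency(
    matrix: CountMatrix, region_a, region_b, scale_factor: float = 1e4
) -> float:
    """Squared Pearson correlation of two regions' pseudo-bulk profiles.

    Each region's profile is the mean log1p-CPM expression over its spots;
    the return value is the transcriptome-wide R^2 between the two
    profiles, the statistic used to argue that spatially independent
    regions of one tissue are interchangeable replicates.
    """
    region_a = list(region_a)
    region_b = list(region_b)
    if not region_a or not region_b:
        raise ValueError("regions must be non-empty")
    if set(region_a) & set(region_b):
        raise ValueError("regions must be disjoint")
    norm = normalize_log_cpm(matrix, scale_factor)
    index = {b: i for i, b in enumerate(matrix.barcodes)}
    prof_a = norm.values[[index[b] for b in region_a]].mean(axis=0)
    prof_b = norm.values[[index[b] for b in region_b]].mean(axis=0)
    r = np.corrcoef(prof_a, prof_b)[0, 1]
    return float(r**2)
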