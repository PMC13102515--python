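"""Per-cluster pseudo-bulk profiles and K-means coexpression modules.

Spots are collapsed to a genes x clusters matrix of mean normalized
expression, low-expression genes are filtered on their best cluster,
profiles are z-scored per gene, and genes are grouped into K coexpression
modules with K-means.  The module labels are the backbone of the
spatial-coexpression screen: a TF sharing a module with a structural gene
is a candidate for regulating it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .preprocess import ClusterResult, NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterProfile",
    "ModuleAssignment",
    "pseudobulk",
    "filter_low_expression",
    "standardize",
    "kmeans_modules",
]


@dataclass
class ClusterProfile:
    """Mean expression per gene per spot cluster (genes x clusters)."""

    values: np.ndarray
    gene_ids: list[str]
    cluster_ids: list[int]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.gene_ids), len(self.cluster_ids)):
            raise ValueError("profile shape does not match gene/cluster lists")
        if not np.all(np.isfinite(values)):
            raise ValueError("profile contains non-finite entries")
        self.values = values

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cluster_ids)


@dataclass
class ModuleAssignment:
    """Gene -> module map from K-means on standardized profiles."""

    module_of: dict[str, int]
    K: int
    centroids: np.ndarray  # K x n_clusters
    inertia: float
    seed: int

    def __post_init__(self) -> None:
        mods = set(self.module_of.values())
        if mods and not mods <= set(range(self.K)):
            raise ValueError("module ids must lie in 0..K-1")

    def genes_in(self, module: int) -> list[str]:
        return sorted(g for g, m in self.module_of.items() if m == module)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.module_of.items()), columns=["gene_id", "module"]
        )


def pseudobulk(norm: NormalizedMatrix, clusters: ClusterResult) -> ClusterProfile:
    """Mean normalized expression of each gene within each spot cluster."""
    if clusters.labels.size != norm.values.shape[0]:
        raise ValueError("cluster labels do not match the normalized matrix")
    n_clusters = clusters.n_clusters
    values = np.empty((norm.values.shape[1], n_clusters))
    for c in range(n_clusters):
        members = clusters.members(c)
        if members.size == 0:
            raise ValueError(f"cluster {c} is empty")
        values[:, c] = norm.values[members].mean(axis=0)
    return ClusterProfile(values, list(norm.gene_ids), list(range(n_clusters)))


def filter_low_expression(profile: ClusterProfile, min_max_value: float = 0.1) -> ClusterProfile:
    """Keep genes whose best cluster reaches ``min_max_value`` (inclusive)."""
    if min_max_value < 0:
        raise ValueError("min_max_value must be >= 0")
    keep = profile.values.max(axis=1) >= min_max_value
    if not keep.any():
        raise ValueError("no genes retained after low-expression filter")
    logger.info("retained %d/%d genes", int(keep.sum()), keep.size)
    return ClusterProfile(
        profile.values[keep],
        [g for g, k in zip(profile.gene_ids, keep) if k],
        list(profile.cluster_ids),
    )


def standardize(profile: ClusterProfile, clamp: float | None = None) -> ClusterProfile:
    """Z-score each gene's profile across clusters (sample sd, ddof 1).

    Constant rows become all-zero with a warning rather than being
    dropped, so gene indices stay aligned with the annotation.  If
    ``clamp`` is given, values are truncated to [-clamp, +clamp].
    """
    if profile.values.shape[1] < 2:
        raise ValueError("standardization needs at least 2 clusters")
    values = profile.values
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = sd.ravel() == 0
    if constant.any():
        logger.warning("%d constant gene profile(s) set to zero", int(constant.sum()))
    z = np.where(sd == 0, 0.0, (values - mean) / np.where(sd == 0, 1.0, sd))
    if clamp is not None:
        if clamp <= 0:
            raise ValueError("clamp must be positive")
        z = np.clip(z, -clamp, clamp)
    return ClusterProfile(z, list(profile.gene_ids), list(profile.cluster_ids))


def kmeans_modules(
    zprofile: ClusterProfile, K: int = 9, seed: int = 0, n_init: int = 10
) -> ModuleAssignment:
    """Group standardized gene profiles into K modules with K-means.

    Lloyd's algorithm with k-means++ initialization, best of ``n_init``
    restarts by inertia; deterministic at a fixed seed.
    """
    n_genes = zprofile.values.shape[0]
    if K > n_genes:
        raise ValueError(f"K={K} exceeds the number of genes ({n_genes})")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed, init="k-means++")
    labels = km.fit_predict(zprofile.values)
    module_of = {g: int(m) for g, m in zip(zprofile.gene_ids, labels)}
    return ModuleAssignment(module_of, K, km.cluster_centers_.copy(), float(km.inertia_), seed)
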