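"""TF-target network inference by the dual spatial/cis-element criterion.

An edge from a TF to a structural gene requires BOTH lines of evidence:

1. a binding-site hit of the TF's family motif in the target's promoter,
2. spatial expression consistency — shared coexpression module or a
   Pearson correlation of the standardized cluster profiles at or above
   ``rho_min``.

Spatial coexpression alone confuses shared upstream signals with direct
regulation; motif presence alone is riddled with chance matches.  The
conjunction is what makes the screen specific.  Candidate coregulators of
several pathway gene sets are ranked lexicographically by (pathway sets
covered, targets covered, mean spatial correlation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coexpression import ClusterProfile, ModuleAssignment
from .io import GeneAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatoryNetwork",
    "spatial_consistency",
    "build_network",
    "family_connectivity",
    "rank_coregulators",
]


@dataclass(frozen=True)
class Edge:
    tf_gene: str
    target_gene: str
    same_module: bool
    spatial_r: float  # nan when undefined
    motif_hits: int

    def __post_init__(self) -> None:
        if self.motif_hits < 1:
            raise ValueError("an edge requires at least one motif hit")


@dataclass
class RegulatoryNetwork:
    """Edge set with evidence and the parameters that produced it."""

    edges: list[Edge]
    rho_min: float
    require_module: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.tf_gene, e.target_gene, e.same_module, e.spatial_r, e.motif_hits)
                for e in self.edges
            ],
            columns=["tf_gene", "target_gene", "same_module", "spatial_r", "motif_hits"],
        )

    def tfs(self) -> list[str]:
        return sorted({e.tf_gene for e in self.edges})

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.tf_gene, e.target_gene) for e in self.edges}


def spatial_consistency(zprofile: ClusterProfile, gene_a: str, gene_b: str) -> float:
    """Pearson r of two genes' standardized cluster profiles.

    Returns nan (a flagged missing value, excluded from edges) when either
    profile is constant; requires at least 3 clusters.
    """
    a = zprofile.row(gene_a)
    b = zprofile.row(gene_b)
    if a.size < 3:
        raise ValueError("need at least 3 clusters for spatial consistency")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return math.nan
    return float(np.corrcoef(a, b)[0, 1])


def build_network(
    modules: ModuleAssignment,
    zprofile: ClusterProfile,
    hits: pd.DataFrame,
    annotation: GeneAnnotation,
    targets: set[str],
    rho_min: float = 0.8,
    require_module: bool = False,
) -> RegulatoryNetwork:
    """Screen every (TF, target) pair through the dual criterion.

    ``hits`` is a MotifHitTable keyed by (gene_id, family).  An edge is
    kept iff the TF family's motif occurs in the target promoter AND the
    pair is spatially consistent (same module OR r >= rho_min; with
    ``require_module`` the module condition is mandatory).  Undefined
    correlations fail the correlation arm rather than counting as zero.
    """
    targets = set(targets)
    if not targets:
        logger.warning("empty target set: returning an empty network")
        return RegulatoryNetwork([], rho_min, require_module)
    profile_genes = set(zprofile.gene_ids)
    missing = targets - profile_genes
    if missing:
        raise ValueError(f"target genes absent from the profile: {sorted(missing)}")

    hit_counts: dict[tuple[str, str], int] = {}
    if len(hits):
        grouped = hits.groupby(["gene_id", "family"]).size()
        hit_counts = {key: int(v) for key, v in grouped.items()}

    edges: list[Edge] = []
    for tf in sorted(annotation.tf_genes):
        if tf not in profile_genes or tf not in modules.module_of:
            continue
        family = annotation.family_of(tf)
        for target in sorted(targets):
            if target == tf or target not in modules.module_of:
                continue
            n_hits = hit_counts.get((target, family), 0)
            if n_hits == 0:
                continue
            same_module = modules.module_of[tf] == modules.module_of[target]
            r = spatial_consistency(zprofile, tf, target)
            r_ok = (not math.isnan(r)) and r >= rho_min
            consistent = same_module if require_module else (same_module or r_ok)
            if not consistent:
                continue
            edges.append(Edge(tf, target, same_module, r, n_hits))
    return RegulatoryNetwork(edges, rho_min, require_module)


def family_connectivity(network: RegulatoryNetwork, annotation: GeneAnnotation) -> pd.DataFrame:
    """Count distinct connected TF genes per family (families with 0 omitted)."""
    counts: dict[str, set[str]] = {}
    for tf in network.tfs():
        counts.setdefault(annotation.family_of(tf), set()).add(tf)
    table = pd.DataFrame(
        sorted((fam, len(tfs)) for fam, tfs in counts.items()),
        columns=["family", "n_tfs"],
    )
    return table.sort_values(["n_tfs", "family"], ascending=[False, True], ignore_index=True)


def rank_coregulators(
    networks: dict[str, RegulatoryNetwork], annotation: GeneAnnotation
) -> pd.DataFrame:
    """Rank TFs across >= 2 pathway-set networks.

    Per TF: number of pathway sets with at least one edge, distinct
    targets covered, and mean spatial correlation over its edges; ranked
    lexicographically (sets desc, targets desc, mean r desc) with a
    deterministic gene-id tie-break.  A TF reaching several metabolite
    pathways at once is the candidate coregulator the screen nominates.
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 pathway networks to rank coregulators")
    stats: dict[str, dict] = {}
    for set_name, network in networks.items():
        for edge in network.edges:
            rec = stats.setdefault(
                edge.tf_gene, {"sets": set(), "targets": set(), "rs": []}
            )
            rec["sets"].add(set_name)
            rec["targets"].add(edge.target_gene)
            if not math.isnan(edge.spatial_r):
                rec["rs"].append(edge.spatial_r)
    if not stats:
        logger.warning("no TF has any edge: empty ranking")
        return pd.DataFrame(
            columns=["tf_gene", "tf_family", "sets_covered", "targets_covered", "mean_spatial_r"]
        )
    rows = [
        (
            tf,
            annotation.family_of(tf),
            len(rec["sets"]),
            len(rec["targets"]),
            float(np.mean(rec["rs"])) if rec["rs"] else math.nan,
        )
        for tf, rec in stats.items()
    ]
    table = pd.DataFrame(
        rows, columns=["tf_gene", "tf_family", "sets_covered", "targets_covered", "mean_spatial_r"]
    )
    return table.sort_values(
        ["sets_covered", "targets_covered", "mean_spatial_r", "tf_gene"],
        ascending=[False, False, False, True],
        ignore_index=True,
    )
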