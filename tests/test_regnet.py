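"""Dual-criterion network construction and coregulator ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from stregnet.coexpression import ClusterProfile, ModuleAssignment, standardize
from stregnet.io import GeneAnnotation
from stregnet.motifs import scan_promoters
from stregnet.regnet import (
    build_network,
    family_connectivity,
    rank_coregulators,
    spatial_consistency,
)
from stregnet.synthetic import default_screen_spec, simulate_promoters, simulate_tissue


def make_zprofile(rows: dict[str, list[float]]):
    genes = list(rows)
    values = np.asarray([rows[g] for g in genes], dtype=float)
    return ClusterProfile(values, genes, list(range(values.shape[1])))


def make_annotation(tf_families: dict[str, str], other_genes=()):
    genes = list(tf_families) + list(other_genes)
    table = pd.DataFrame(
        {
            "symbol": genes,
            "is_tf": [g in tf_families for g in genes],
            "tf_family": [tf_families.get(g, "") for g in genes],
            "pathway_tags": [set() for _ in genes],
            "term_ids": [set() for _ in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return GeneAnnotation(table)


def make_hits(entries):
    return pd.DataFrame(
        entries, columns=["gene_id", "family", "position", "strand", "score"]
    )


class TestSpatialConsistency:
    def test_identical_profiles(self):
        z = make_zprofile({"a": [1, 0, -1], "b": [1, 0, -1]})
        assert spatial_consistency(z, "a", "b") == pytest.approx(1.0)

    def test_antisymmetric_profiles(self):
        z = make_zprofile({"a": [1, 0, -1], "b": [-1, 0, 1]})
        assert spatial_consistency(z, "a", "b") == pytest.approx(-1.0)

    def test_hand_covariance_case(self):
        z = make_zprofile({"a": [1, 2, 3, 4], "b": [2, 1, 4, 3]})
        assert spatial_consistency(z, "a", "b") == pytest.approx(0.6)

    def test_constant_profile_flagged(self):
        z = make_zprofile({"a": [0, 0, 0], "b": [1, 2, 3]})
        assert math.isnan(spatial_consistency(z, "a", "b"))


class TestBuildNetwork:
    def _fixtures(self):
        z = make_zprofile(
            {
                "tfA": [2.0, 0.0, -2.0],
                "tfB": [-2.0, 0.0, 2.0],
                "gX": [2.0, 0.0, -2.0],
            }
        )
        annotation = make_annotation({"tfA": "TCP", "tfB": "MYB"}, ["gX"])
        modules = ModuleAssignment(
            {"tfA": 0, "gX": 0, "tfB": 1}, 2, np.zeros((2, 3)), 0.0, 0
        )
        return z, annotation, modules

    def test_no_motif_no_edge_despite_perfect_correlation(self):
        z, annotation, modules = self._fixtures()
        net = build_network(modules, z, make_hits([]), annotation, {"gX"})
        assert net.edges == []

    def test_no_spatial_consistency_no_edge_despite_motif(self):
        z, annotation, modules = self._fixtures()
        hits = make_hits([("gX", "MYB", 3, "+", 1.0)])
        net = build_network(modules, z, hits, annotation, {"gX"})
        assert net.edges == []  # tfB anti-correlated, different module

    def test_dual_evidence_makes_edge_with_reverifiable_record(self):
        z, annotation, modules = self._fixtures()
        hits = make_hits(
            [("gX", "TCP", 3, "+", 1.0), ("gX", "TCP", 9, "-", 0.9)]
        )
        net = build_network(modules, z, hits, annotation, {"gX"})
        assert len(net.edges) == 1
        edge = net.edges[0]
        assert (edge.tf_gene, edge.target_gene) == ("tfA", "gX")
        # evidence recomputable from the inputs
        assert edge.motif_hits == len(hits[(hits.gene_id == "gX") & (hits.family == "TCP")])
        assert edge.spatial_r == pytest.approx(spatial_consistency(z, "tfA", "gX"))
        assert edge.same_module

    def test_empty_target_set_warns(self, caplog):
        z, annotation, modules = self._fixtures()
        with caplog.at_level("WARNING"):
            net = build_network(modules, z, make_hits([]), annotation, set())
        assert net.edges == []

    def test_raising_rho_min_never_adds_edges(self):
        spec = default_screen_spec(seed=4)
        _, _, annotation, truth = simulate_tissue(spec)
        promoters, library = simulate_promoters(truth, spec)
        z, modules = truth_profile_and_modules(spec, truth)
        hits = scan_promoters(promoters, library, 0.8)
        targets = {tg for _, tg, _ in truth.true_edges}
        loose = build_network(modules, z, hits, annotation, targets, rho_min=0.5)
        tight = build_network(modules, z, hits, annotation, targets, rho_min=0.9)
        assert tight.edge_pairs() <= loose.edge_pairs()

    def test_perfect_recovery_on_noise_free_profiles(self):
        spec = default_screen_spec(seed=1)
        _, _, annotation, truth = simulate_tissue(spec)
        promoters, library = simulate_promoters(truth, spec)
        z, modules = truth_profile_and_modules(spec, truth)
        hits = scan_promoters(promoters, library, rel_threshold=1.0)
        targets = {tg for _, tg, _ in truth.true_edges}
        net = build_network(modules, z, hits, annotation, targets, rho_min=0.8)
        true_pairs = {(tf, tg) for tf, tg, _ in truth.true_edges}
        assert net.edge_pairs() == true_pairs  # precision and recall both 1


def truth_profile_and_modules(spec, truth):
    """Noise-free cluster profiles straight from the planted activities."""
    activity = spec.resolved_activity()
    genes = sorted(truth.module_of)
    values = activity[[truth.module_of[g] for g in genes]]
    profile = ClusterProfile(values, genes, list(range(spec.n_domains)))
    z = standardize(profile)
    modules = ModuleAssignment(
        {g: truth.module_of[g] for g in genes},
        spec.n_modules,
        np.zeros((spec.n_modules, spec.n_domains)),
        0.0,
        0,
    )
    return z, modules


class TestFamilyConnectivity:
    def test_empty_network(self):
        from stregnet.regnet import RegulatoryNetwork

        annotation = make_annotation({"tfA": "TCP"})
        table = family_connectivity(RegulatoryNetwork([], 0.8, False), annotation)
        assert len(table) == 0

    def test_distinct_tf_counting(self):
        from stregnet.regnet import Edge, RegulatoryNetwork

        annotation = make_annotation({"t1": "bHLH", "t2": "bHLH", "t3": "MYB"})
        edges = [
            Edge("t1", "gA", True, 0.9, 1),
            Edge("t1", "gB", True, 0.9, 1),
            Edge("t2", "gA", True, 0.9, 1),
            Edge("t3", "gA", True, 0.9, 1),
        ]
        table = family_connectivity(RegulatoryNetwork(edges, 0.8, False), annotation)
        counts = dict(zip(table["family"], table["n_tfs"]))
        assert counts == {"bHLH": 2, "MYB": 1}


class TestRanking:
    def _networks(self):
        from stregnet.regnet import Edge, RegulatoryNetwork

        dual = [Edge("tfDual", "gA", True, 0.95, 1)]
        dual2 = [Edge("tfDual", "gB", True, 0.9, 1), Edge("tfSolo", "gB", True, 0.99, 1)]
        return {
            "catechin_synthesis": RegulatoryNetwork(dual, 0.8, False),
            "theanine_hydrolysis": RegulatoryNetwork(dual2, 0.8, False),
        }

    def test_dual_pathway_tf_ranked_first(self):
        annotation = make_annotation({"tfDual": "TCP", "tfSolo": "MYB"})
        ranking = rank_coregulators(self._networks(), annotation)
        assert ranking.iloc[0]["tf_gene"] == "tfDual"
        assert ranking.iloc[0]["sets_covered"] == 2

    def test_exact_tie_broken_by_gene_id(self):
        from stregnet.regnet import Edge, RegulatoryNetwork

        annotation = make_annotation({"tfB": "TCP", "tfA": "TCP"})
        networks = {
            "s1": RegulatoryNetwork(
                [Edge("tfB", "gA", True, 0.9, 1), Edge("tfA", "gB", True, 0.9, 1)],
                0.8, False,
            ),
            "s2": RegulatoryNetwork([], 0.8, False),
        }
        ranking = rank_coregulators(networks, annotation)
        assert list(ranking["tf_gene"]) == ["tfA", "tfB"]

    def test_single_network_rejected(self):
        annotation = make_annotation({"tfA": "TCP"})
        with pytest.raises(ValueError):
            rank_coregulators({"only": None}, annotation)

    def test_no_edges_warns_and_returns_empty(self, caplog):
        from stregnet.regnet import RegulatoryNetwork

        annotation = make_annotation({"tfA": "TCP"})
        networks = {
            "s1": RegulatoryNetwork([], 0.8, False),
            "s2": RegulatoryNetwork([], 0.8, False),
        }
        with caplog.at_level("WARNING"):
            ranking = rank_coregulators(networks, annotation)
        assert len(ranking) == 0
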