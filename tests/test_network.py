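import numpy as np
import pytest

from qcoexp import (
    BaitSet,
    CoexpressionEdge,
    DEGeneList,
    ValidationError,
    build_network,
    collapse_edges_to_genes,
    export_network,
    extend_network,
    family_distribution,
    intersect_with_de,
    rank_tf_candidates,
    read_edge_tsv,
    screen_baits,
)


def _edge(bait, partner, bf=10, p=0.001, sign=1):
    return CoexpressionEdge(bait, partner, bf, frozenset(f"c{i}" for i in range(bf)), sign, p)


PROV = {"source": "test"}


class TestBuildNetwork:
    def test_tf_only_keeps_annotated_partners_and_baits(self, annotations):
        edges = [_edge("B01", "B01P1"), _edge("B01", "G0001"), _edge("B01", "UNKNOWN")]
        net = build_network(edges, annotations, tf_only=True, provenance=PROV)
        assert set(net.graph.nodes) == {"B01", "B01P1"}
        assert net.baits == {"B01"}

    def test_tf_only_off_keeps_everyone(self, annotations):
        edges = [_edge("B01", "B01P1"), _edge("B01", "G0001"), _edge("B01", "UNKNOWN")]
        net = build_network(edges, annotations, tf_only=False, provenance=PROV)
        assert set(net.graph.nodes) == {"B01", "B01P1", "G0001", "UNKNOWN"}

    def test_node_set_is_union_of_endpoints(self, rng):
        baits = [f"b{i}" for i in range(4)]
        edges = [
            _edge(rng.choice(baits), f"p{i}", bf=int(rng.integers(1, 20))) for i in range(20)
        ]
        net = build_network(edges, provenance=PROV)
        expected = {e.bait_id for e in edges} | {e.partner_id for e in edges}
        assert set(net.graph.nodes) == expected
        assert net.n_edges() == len({frozenset((e.bait_id, e.partner_id)) for e in edges})

    def test_self_loops_dropped(self):
        net = build_network([_edge("b", "b"), _edge("b", "x")], provenance=PROV)
        assert net.n_edges() == 1

    def test_empty_provenance_rejected(self):
        with pytest.raises(ValidationError, match="provenance"):
            build_network([_edge("b", "x")], provenance={})


class TestFamilyDistribution:
    def test_counts_distinct_tf_nodes_per_family(self, annotations):
        edges = [_edge("B01", "B01P1"), _edge("B01", "B01P2"), _edge("B02", "B02P1")]
        net = build_network(edges, annotations, provenance=PROV)
        assert family_distribution(net) == {"MYB": 2, "NAC": 1}

    def test_counts_sum_to_labelled_tf_nodes(self, rng, annotations):
        partners = ["B01P1", "B01P2", "B02P1", "G0001", "X1"]
        edges = [_edge("B01", p) for p in partners]
        net = build_network(edges, annotations, provenance=PROV)
        dist = family_distribution(net)
        labelled = sum(
            1 for _, d in net.graph.nodes(data=True) if d.get("tf_family")
        )
        assert sum(dist.values()) == labelled

    def test_empty_network_empty_distribution(self):
        net = build_network([], provenance=PROV)
        assert family_distribution(net) == {}


class TestExtendNetwork:
    def test_idempotent_when_readding_existing_baits(self, planted, baits2, fast_params, annotations):
        _, d, _ = planted
        edges = screen_baits(d, baits2, fast_params)
        net = build_network(edges, annotations, provenance=PROV)
        extended = extend_network(net, baits2, d, fast_params, annotations)
        assert set(extended.graph.nodes) == set(net.graph.nodes)
        assert set(map(frozenset, extended.graph.edges)) == set(map(frozenset, net.graph.edges))

    def test_commutative_over_bait_sets(self, planted, fast_params, annotations):
        _, d, _ = planted
        b1, b2 = BaitSet(("B01",)), BaitSet(("B02",))
        net0 = build_network(screen_baits(d, b1, fast_params), annotations, provenance=PROV)
        ab = extend_network(net0, b2, d, fast_params, annotations)
        net1 = build_network(screen_baits(d, b2, fast_params), annotations, provenance=PROV)
        ba = extend_network(net1, b1, d, fast_params, annotations)
        assert set(ab.graph.nodes) == set(ba.graph.nodes)
        assert {frozenset(e) for e in ab.graph.edges} == {frozenset(e) for e in ba.graph.edges}

    def test_bait_bait_edges_flagged(self, fast_params, annotations):
        """A TF bait sharing a planted module with a lignin bait yields a
        flagged bait-bait edge after extension."""
        from qcoexp import DiscretizationParams, ModuleSpec, SyntheticSpec, discretize_matrix, generate_matrix

        spec = SyntheticSpec(
            n_genes=30,
            n_conditions=40,
            modules=(ModuleSpec("B01", ("TF1", "TF2"), condition_subset=0.25, effect_size=5.0),),
            noise_sd=0.0,
            rng_seed=2,
        )
        m, _ = generate_matrix(spec)
        d = discretize_matrix(m, DiscretizationParams(q=0.25))
        net = build_network(screen_baits(d, BaitSet(("B01",)), fast_params), provenance=PROV)
        extended = extend_network(net, BaitSet(("TF1",)), d, fast_params)
        assert extended.graph.edges["B01", "TF1"]["bait_bait"]
        assert not extended.graph.edges["B01", "TF2"]["bait_bait"]


class TestIntersectWithDe:
    def test_set_algebra_over_two_lists(self):
        net = build_network([_edge("b", g) for g in "axyz"], provenance=PROV)
        de1 = DEGeneList("l1", frozenset({"a", "x"}), {"a": "up"})
        de2 = DEGeneList("l2", frozenset({"x", "z"}))
        genes, report = intersect_with_de(net, "b", [de1, de2])
        assert genes == {"x"}
        assert report.loc["x", "bf"] == 10

    def test_empty_de_list_gives_empty_result(self):
        net = build_network([_edge("b", "x")], provenance=PROV)
        genes, _ = intersect_with_de(net, "b", [DEGeneList("l", frozenset())])
        assert genes == set()

    def test_brute_force_random_fixture(self, rng):
        partners = [f"g{i}" for i in range(30)]
        net = build_network([_edge("b", p) for p in partners], provenance=PROV)
        lists = [
            DEGeneList(f"l{j}", frozenset(rng.choice(partners + ["other"], 15, replace=False)))
            for j in range(3)
        ]
        genes, _ = intersect_with_de(net, "b", lists)
        brute = set(partners)
        for dl in lists:
            brute &= set(dl.gene_ids)
        assert genes == brute

    def test_absent_bait_rejected(self):
        net = build_network([_edge("b", "x")], provenance=PROV)
        with pytest.raises(ValidationError, match="not in the network"):
            intersect_with_de(net, "nope", [DEGeneList("l", frozenset({"x"}))])


class TestExportImport:
    def test_single_edge_sif_and_attribute_rows(self, tmp_path, annotations):
        net = build_network([_edge("B01", "B01P1", bf=4)], annotations, provenance=PROV)
        paths = export_network(net, "sif", tmp_path / "net")
        sif = (tmp_path / "net.sif").read_text()
        assert sif == "B01\tcoexp\tB01P1\n"
        nodes = (tmp_path / "net.nodes.tsv").read_text().strip().splitlines()
        assert len(nodes) == 1 + 2  # header + two nodes
        eattr = (tmp_path / "net.edge_attrs.tsv").read_text().strip().splitlines()
        assert len(eattr) == 1 + 1
        assert len(paths) == 3

    def test_edge_tsv_round_trip_is_lossless(self, tmp_path, planted, baits2, fast_params):
        _, d, _ = planted
        edges = screen_baits(d, baits2, fast_params)
        net = build_network(edges, provenance=PROV)
        export_network(net, "edge-tsv", tmp_path / "net")
        back = read_edge_tsv(tmp_path / "net.edges.tsv")
        assert sorted(back, key=lambda e: (e.bait_id, e.partner_id)) == sorted(
            net.edge_list(), key=lambda e: (e.bait_id, e.partner_id)
        )

    def test_sif_line_count_equals_edge_count(self, tmp_path, planted, baits2, fast_params):
        _, d, _ = planted
        net = build_network(screen_baits(d, baits2, fast_params), provenance=PROV)
        export_network(net, "sif", tmp_path / "n")
        assert len((tmp_path / "n.sif").read_text().strip().splitlines()) == net.n_edges()

    def test_empty_network_export_rejected(self, tmp_path):
        net = build_network([], provenance=PROV)
        with pytest.raises(ValidationError, match="empty"):
            export_network(net, "sif", tmp_path / "x")

    def test_unknown_format_rejected(self, tmp_path):
        net = build_network([_edge("b", "x")], provenance=PROV)
        with pytest.raises(ValidationError, match="format"):
            export_network(net, "dot", tmp_path / "x")

    def test_graphml_written(self, tmp_path):
        net = build_network([_edge("b", "x")], provenance=PROV)
        (path,) = export_network(net, "graphml", tmp_path / "g")
        assert path.exists() and path.stat().st_size > 0


class TestReports:
    def test_rank_tf_candidates_orders_by_degree_then_bf(self, annotations):
        edges = [
            _edge("B01", "B01P1", bf=12),
            _edge("B02", "B01P1", bf=7),
            _edge("B01", "B02P1", bf=20),
        ]
        net = build_network(edges, annotations, provenance=PROV)
        report = rank_tf_candidates(net)
        assert list(report.index) == ["B01P1", "B02P1"]
        assert report.loc["B01P1", "n_bait_neighbors"] == 2
        assert report.loc["B01P1", "max_bf"] == 12

    def test_collapse_to_genes_keeps_max_bf_probe(self):
        pm = {"probe1": "geneA", "probe2": "geneA"}
        edges = [_edge("b", "probe1", bf=5), _edge("b", "probe2", bf=9)]
        out = collapse_edges_to_genes(edges, pm)
        assert len(out) == 1
        assert out[0].partner_id == "geneA" and out[0].bf == 9
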