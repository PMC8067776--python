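import numpy as np
import pandas as pd
import pytest

from cerna.expression import CoexpressionResult
from cerna.network import (
    ClassConflictError,
    MissingEvidenceError,
    build_network,
    compare_gene_sets,
    degree_distribution,
    export_network,
    extract_triads,
    fit_power_law,
    networks_equal,
    read_network,
    top_hubs,
)
from cerna.screen import CandidatePair, HypergeomParams
from cerna.simulate import powerlaw_degree_graph


def _edge(lnc, mrna, group="g", rho=0.9, shared=("m1", "m2")):
    cand = CandidatePair(
        lnc_id=lnc,
        mrna_id=mrna,
        params=HypergeomParams(50, 10, 12, len(shared)),
        shared_ids=frozenset(shared),
        p_value=0.001,
    )
    return CoexpressionResult(
        lnc_id=lnc, mrna_id=mrna, group=group, rho=rho, p_value=0.001,
        n_samples=10, method="asymptotic_t", candidate=cand,
    )


def _star(n_leaves=10, group="g"):
    return build_network(
        [_edge("HUB", f"G{i}", group) for i in range(n_leaves)], group
    )


class TestBuildNetwork:
    def test_nodes_edges_and_classes(self):
        net = build_network(
            [_edge("L1", "G1"), _edge("L1", "G2"), _edge("L1", "G3")], "g"
        )
        assert net.n_nodes == 4 and net.n_edges == 3
        assert net.graph.nodes["L1"]["cls"] == "lncRNA"
        assert net.graph.nodes["G1"]["cls"] == "mRNA"
        net.check_bipartite()

    def test_empty_edge_list_gives_empty_network(self):
        net = build_network([], "g")
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_class_conflict_rejected(self):
        with pytest.raises(ClassConflictError, match="both"):
            build_network([_edge("A", "B"), _edge("B", "C")], "g")

    def test_wrong_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            build_network([_edge("L1", "G1", group="other")], "g")

    def test_duplicate_edge_with_same_evidence_deduplicated(self):
        net = build_network([_edge("L1", "G1"), _edge("L1", "G1")], "g")
        assert net.n_edges == 1


class TestDegreeDistribution:
    def test_star_histogram(self):
        dist = degree_distribution(_star(10), "all")
        assert dict(zip(dist["degree"], dist["node_count"])) == {1: 10, 10: 1}

    def test_empty_network(self):
        assert degree_distribution(build_network([], "g")).empty

    def test_two_disjoint_edges(self):
        net = build_network([_edge("L1", "G1"), _edge("L2", "G2")], "g")
        dist = degree_distribution(net)
        assert dict(zip(dist["degree"], dist["node_count"])) == {1: 4}

    def test_degree_count_conservation(self):
        net = build_network(
            [_edge(f"L{i % 3}", f"G{j}") for i, j in enumerate(range(12))], "g"
        )
        dist = degree_distribution(net, "all")
        assert (dist["degree"] * dist["node_count"]).sum() == 2 * net.n_edges
        assert dist["node_count"].sum() == net.n_nodes

    def test_class_scoped_histogram(self):
        dist = degree_distribution(_star(10), "lncRNA")
        assert dict(zip(dist["degree"], dist["node_count"])) == {10: 1}


class TestFitPowerLaw:
    def test_analytic_histogram_recovers_exponent_two(self):
        d = np.arange(1, 51)
        counts = np.round(1e4 * d**-2.0).astype(int)
        fit = fit_power_law(pd.DataFrame({"degree": d, "node_count": counts}))
        assert fit.fitted
        assert fit.exponent == pytest.approx(2.0, abs=0.1)
        assert fit.r_squared >= 0.99

    def test_single_degree_value_flagged_no_fit(self):
        fit = fit_power_law(pd.DataFrame({"degree": [3], "node_count": [40]}))
        assert not fit.fitted and np.isnan(fit.exponent)

    def test_two_bins_flagged_no_fit(self):
        fit = fit_power_law(
            pd.DataFrame({"degree": [1, 2], "node_count": [10, 3]})
        )
        assert not fit.fitted

    def test_configuration_model_exponent_recovery(self):
        exps = []
        for seed in range(1, 11):
            g = powerlaw_degree_graph(2000, 2.5, seed=seed)
            degs = pd.Series([d for _, d in g.degree()])
            counts = degs.value_counts().sort_index()
            fit = fit_power_law(
                pd.DataFrame({"degree": counts.index, "node_count": counts.values})
            )
            exps.append(fit.exponent)
        assert abs(np.mean(exps) - 2.5) <= 0.25
        assert abs(exps[0] - 2.5) <= 0.4


class TestTopHubs:
    def test_star_hub_ranked_first(self):
        hubs = top_hubs(_star(10), k=3)
        assert hubs[0] == ("HUB", 10)

    def test_ties_broken_lexicographically(self):
        net = build_network(
            [_edge("LB", "G1"), _edge("LA", "G2"), _edge("LC", "G3")], "g"
        )
        assert [h[0] for h in top_hubs(net, k=3)] == ["LA", "LB", "LC"]

    def test_list_length_capped_by_class_size(self):
        assert len(top_hubs(_star(4), k=10)) == 1

    def test_mrna_scope(self):
        hubs = top_hubs(_star(4), k=2, node_class="mRNA")
        assert hubs == [("G0", 1), ("G1", 1)]


class TestCompareGeneSets:
    def test_identical_networks_have_no_unique_nodes(self):
        a, b = _star(5, "a"), _star(5, "b")
        ov = compare_gene_sets(a, b)
        assert ov.unique_a == () and ov.unique_b == ()
        assert len(ov.shared) == 6

    def test_disjoint_node_sets(self):
        a = build_network([_edge("L1", "G1", "a")], "a")
        b = build_network([_edge("L2", "G2", "b")], "b")
        ov = compare_gene_sets(a, b)
        assert ov.shared == () and len(ov.unique_a) == 2 and len(ov.unique_b) == 2

    def test_partial_overlap_counts_consistent(self):
        a = build_network([_edge("L1", "G1", "a"), _edge("L1", "G2", "a")], "a")
        b = build_network([_edge("L1", "G2", "b"), _edge("L1", "G3", "b")], "b")
        ov = compare_gene_sets(a, b)
        assert len(ov.shared) + len(ov.unique_a) == a.n_nodes
        assert len(ov.shared) + len(ov.unique_b) == b.n_nodes
        assert set(ov.shared) == {"L1", "G2"}

    def test_symmetric_up_to_label_swap(self):
        a = build_network([_edge("L1", "G1", "a")], "a")
        b = build_network([_edge("L1", "G2", "b")], "b")
        ov_ab = compare_gene_sets(a, b)
        ov_ba = compare_gene_sets(b, a)
        assert ov_ab.shared == ov_ba.shared
        assert ov_ab.unique_a == ov_ba.unique_b


class TestTriads:
    def test_one_triad_per_shared_mirna(self):
        net = build_network([_edge("L1", "G1", shared=("m2", "m3"))], "g")
        triads = extract_triads(net)
        assert {(t.lnc_id, t.mirna_id, t.mrna_id) for t in triads} == {
            ("L1", "m2", "G1"), ("L1", "m3", "G1"),
        }

    def test_total_count_is_sum_of_shared_sizes(self):
        net = build_network(
            [_edge("L1", "G1", shared=("m1", "m2")),
             _edge("L2", "G2", shared=("m1", "m2", "m3"))], "g"
        )
        assert len(extract_triads(net)) == 5

    def test_shared_mirna_reused_across_edges(self):
        net = build_network(
            [_edge("L1", "G1", shared=("m1",)), _edge("L1", "G2", shared=("m1",))], "g"
        )
        assert [t.mirna_id for t in extract_triads(net)] == ["m1", "m1"]

    def test_empty_network_gives_no_triads(self):
        assert extract_triads(build_network([], "g")) == []

    def test_missing_evidence_rejected(self):
        net = _star(2)
        for u, v in net.graph.edges:
            del net.graph.edges[u, v]["shared_mirnas"]
        with pytest.raises(MissingEvidenceError):
            extract_triads(net)


class TestExport:
    def test_graphml_roundtrip_identity(self, tmp_path):
        net = build_network(
            [_edge("L1", "G1"), _edge("L1", "G2", shared=("m5",)), _edge("L2", "G2")],
            "g",
        )
        path = tmp_path / "net.graphml"
        export_network(net, path, "graphml")
        back = read_network(path)
        assert networks_equal(net, back)

    def test_empty_network_exports_valid_files(self, tmp_path):
        net = build_network([], "g")
        for fmt, name in (("graphml", "e.graphml"), ("sif", "e.sif"), ("edge_tsv", "e.tsv")):
            export_network(net, tmp_path / name, fmt)
        assert networks_equal(net, read_network(tmp_path / "e.graphml"))

    def test_sif_line_format(self, tmp_path):
        net = build_network([_edge("LNC1", "MRNA1")], "g")
        path = tmp_path / "n.sif"
        export_network(net, path, "sif")
        assert path.read_text() == "LNC1\tcerna\tMRNA1\n"

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_network(_star(2), tmp_path / "x.bin", "parquet")
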