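"""Network indices: closed forms, brute-force oracle equivalence, and
structural invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import collabflow as cf
from collabflow import (
    CollaborationGraph,
    Corpus,
    KnowledgeFlowGraph,
    SectorMap,
    UndefinedIndexError,
)

from conftest import (
    assortativity_oracle,
    clustering_oracle,
    make_random_corpus,
    make_random_graph,
    make_record,
)


def triangle(w1, w2, w3):
    return CollaborationGraph(
        frozenset("xyz"), {("x", "y"): w1, ("x", "z"): w2, ("y", "z"): w3}
    )


class TestWeightedDegree:
    def test_worked_example_node_c(self, fig1):
        g = cf.build_collaboration(fig1)
        assert cf.weighted_degree(g, "c") == 3  # 2 to d, 1 to e

    def test_isolated_node_zero(self):
        g = CollaborationGraph(frozenset({"lonely", "x", "y"}), {("x", "y"): 1})
        assert cf.weighted_degree(g, "lonely") == 0

    def test_unknown_node_rejected(self, fig1):
        with pytest.raises(KeyError):
            cf.weighted_degree(cf.build_collaboration(fig1), "zz")

    def test_matches_row_sum(self):
        rng = np.random.default_rng(0)
        g = make_random_graph(rng)
        for node in g.nodes:
            expected = sum(w for (i, j), w in g.weights.items() if node in (i, j))
            assert cf.weighted_degree(g, node) == expected


class TestIndustrialFraction:
    def test_all_academic_zero(self, fig1):
        g = cf.build_collaboration(fig1)
        assert cf.industrial_fraction(g, SectorMap({})) == 0.0

    def test_all_industrial_one(self, fig1):
        g = cf.build_collaboration(fig1)
        sectors = SectorMap({n: "industrial" for n in g.nodes})
        assert cf.industrial_fraction(g, sectors) == 1.0

    def test_worked_example_three_fifths(self, fig1, fig1_collab_sectors):
        g = cf.build_collaboration(fig1)
        assert cf.industrial_fraction(g, fig1_collab_sectors) == pytest.approx(0.6)

    def test_edgeless_graph_undefined(self):
        g = CollaborationGraph(frozenset({"a"}), {})
        with pytest.raises(UndefinedIndexError):
            cf.industrial_fraction(g, SectorMap({}))

    def test_both_endpoints_industrial_counted_once(self):
        g = CollaborationGraph(frozenset("ab"), {("a", "b"): 3})
        sectors = SectorMap({"a": "industrial", "b": "industrial"})
        assert cf.industrial_fraction(g, sectors) == 1.0

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        seed=st.integers(0, 500),
        promote=st.sampled_from(["i00", "i01", "i02", "i03"]),
    )
    def test_monotone_under_relabeling(self, seed, promote):
        rng = np.random.default_rng(seed)
        g = make_random_graph(rng, max_n=8)
        if not g.weights:
            return
        base_ind = {n for n in g.nodes if rng.random() < 0.3}
        before = cf.industrial_fraction(
            g, SectorMap({n: "industrial" for n in base_ind})
        )
        after = cf.industrial_fraction(
            g, SectorMap({n: "industrial" for n in base_ind | {promote}})
        )
        assert after >= before - 1e-15


class TestAverageClustering:
    def test_uniform_triangle_is_one(self):
        assert cf.average_clustering(triangle(5, 5, 5)) == pytest.approx(1.0)

    def test_path_graph_is_zero(self):
        g = CollaborationGraph(frozenset("abc"), {("a", "b"): 1, ("b", "c"): 1})
        assert cf.average_clustering(g) == 0.0

    def test_weighted_triangle_half(self):
        # normalized weights 0.25, 0.5, 1 -> every node (0.125)^(1/3) = 0.5
        assert cf.average_clustering(triangle(1, 2, 4)) == pytest.approx(0.5)

    def test_empty_and_edgeless_undefined(self):
        with pytest.raises(UndefinedIndexError):
            cf.average_clustering(CollaborationGraph(frozenset(), {}))
        with pytest.raises(UndefinedIndexError):
            cf.average_clustering(CollaborationGraph(frozenset({"a"}), {}))

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(120):
            g = make_random_graph(rng)
            if not g.weights:
                continue
            assert cf.average_clustering(g) == pytest.approx(
                clustering_oracle(g), abs=1e-12
            )

    def test_matches_networkx(self):
        import networkx as nx

        rng = np.random.default_rng(7)
        for _ in range(40):
            g = make_random_graph(rng)
            if not g.weights:
                continue
            expected = nx.average_clustering(g.to_networkx(), weight="weight")
            assert cf.average_clustering(g) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 200), scale=st.integers(2, 50))
    def test_invariant_under_uniform_weight_scaling(self, seed, scale):
        rng = np.random.default_rng(seed)
        g = make_random_graph(rng, max_n=9)
        if not g.weights:
            return
        scaled = CollaborationGraph(
            g.nodes, {k: w * scale for k, w in g.weights.items()}
        )
        assert cf.average_clustering(scaled) == pytest.approx(
            cf.average_clustering(g), abs=1e-12
        )


class TestAssortativity:
    def test_three_leaf_star_is_minus_one(self):
        g = CollaborationGraph(
            frozenset("habc"),
            {("a", "h"): 1, ("b", "h"): 1, ("c", "h"): 1},
        )
        assert cf.assortativity(g) == pytest.approx(-1.0, abs=1e-12)

    def test_regular_ring_undefined(self):
        g = CollaborationGraph(
            frozenset("abcd"),
            {("a", "b"): 1, ("b", "c"): 1, ("c", "d"): 1, ("a", "d"): 1},
        )
        assert cf.assortativity(g) is None

    def test_edgeless_undefined(self):
        assert cf.assortativity(CollaborationGraph(frozenset({"a"}), {})) is None

    def test_matches_materialized_pair_oracle(self):
        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(120):
            g = make_random_graph(rng)
            expected = assortativity_oracle(g)
            got = cf.assortativity(g)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-12)
                checked += 1
        assert checked >= 100


class TestTopShareFraction:
    def test_hand_cumulative_examples(self):
        # Heavy pair + light pair: degrees {a:18, b:18, c:1, d:1},
        # total 38, threshold 34.2; cumulative 18, 36 -> 2 of 4 nodes.
        g = CollaborationGraph(
            frozenset("abcd"), {("a", "b"): 18, ("c", "d"): 1}
        )
        assert cf.top_share_fraction(g, 0.9) == pytest.approx(0.5)
        # Dominant hub with two light leaves: degrees {h:20, p:19, q:1},
        # total 40, threshold 36; cumulative 20, 39 -> 2 of 3 nodes.
        hub = CollaborationGraph(
            frozenset("hpq"), {("h", "p"): 19, ("h", "q"): 1}
        )
        assert cf.top_share_fraction(hub, 0.9) == pytest.approx(2 / 3)

    def test_tie_break_is_deterministic(self):
        # q and r tie on degree; ranking breaks ties by institution id,
        # and either choice reaches the threshold at the same m anyway.
        g = CollaborationGraph(
            frozenset("pqr"), {("p", "q"): 9, ("p", "r"): 9}
        )
        # degrees {p:18, q:9, r:9}, total 36, threshold 32.4 -> m=3
        assert cf.top_share_fraction(g, 0.9) == pytest.approx(1.0)
        assert cf.top_share_fraction(g, 0.5) == pytest.approx(1 / 3)

    def test_uniform_degrees_closed_form(self):
        for n in (4, 7, 10, 13):
            nodes = [f"n{k}" for k in range(n)]
            ring = {
                tuple(sorted((nodes[k], nodes[(k + 1) % n]))): 1 for k in range(n)
            }
            g = CollaborationGraph(frozenset(nodes), ring)
            assert cf.top_share_fraction(g, 0.9) == pytest.approx(
                math.ceil(0.9 * n) / n
            )

    def test_share_one_counts_nonzero_degree_nodes(self):
        g = CollaborationGraph(
            frozenset({"a", "b", "iso"}), {("a", "b"): 5}
        )
        assert cf.top_share_fraction(g, 1.0) == pytest.approx(2 / 3)

    def test_zero_total_degree_undefined(self):
        with pytest.raises(UndefinedIndexError):
            cf.top_share_fraction(CollaborationGraph(frozenset({"a"}), {}))

    def test_matches_prefix_sum_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(60):
            g = make_random_graph(rng)
            if not g.weights:
                continue
            degrees = sorted(
                (
                    (sum(g.adjacency[n].values()), n)
                    for n in g.nodes
                ),
                key=lambda t: (-t[0], t[1]),
            )
            total = sum(d for d, _ in degrees)
            cum, m = 0, 0
            for d, _ in degrees:
                cum += d
                m += 1
                # integer-exact comparison at share 0.9 = 9/10
                if 10 * cum >= 9 * total:
                    break
            assert cf.top_share_fraction(g, 0.9) == pytest.approx(m / len(g.nodes))


class TestFlowFractions:
    def test_no_self_loops_zero_internal(self, fig1):
        f = cf.build_flow(fig1, cf.collect_citations(fig1, {"II", "III"}))
        ff = cf.flow_fractions(f)
        assert ff.overall_internal == 0.0
        assert all(v == 0.0 for v in ff.per_institution_internal.values())

    def test_pure_self_citation_is_one(self):
        f = KnowledgeFlowGraph(frozenset({"x"}), {("x", "x"): 4})
        ff = cf.flow_fractions(f)
        assert ff.overall_internal == 1.0
        assert ff.per_institution_internal == {"x": 1.0}

    def test_zero_flow_undefined(self):
        with pytest.raises(UndefinedIndexError):
            cf.flow_fractions(KnowledgeFlowGraph(frozenset({"x"}), {}))

    def test_mixed_flows_hand_computed(self):
        f = KnowledgeFlowGraph(
            frozenset({"u", "v"}),
            {("u", "u"): 1, ("u", "v"): 3, ("v", "u"): 6},
        )
        ff = cf.flow_fractions(f)
        assert ff.overall_internal == pytest.approx(0.1)
        assert ff.per_institution_internal["u"] == pytest.approx(0.25)
        assert ff.per_institution_internal["v"] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [0, 2, 4])
    def test_overall_is_outflow_weighted_mean_of_per_institution(self, seed):
        corpus = make_random_corpus(seed)
        core = {p.paper_id for p in corpus if "focal topic" in p.tags}
        f = cf.build_flow(corpus, cf.collect_citations(corpus, core))
        if f.total_flow == 0:
            pytest.skip("no citations drawn")
        ff = cf.flow_fractions(f)
        assert 0.0 <= ff.overall_internal <= 1.0
        weighted = sum(
            ff.per_institution_internal[u] * f.out_flow(u)
            for u in ff.per_institution_internal
        )
        assert ff.overall_internal == pytest.approx(weighted / f.total_flow)


class TestInterInstitutionalFraction:
    def test_worked_example_all_multi(self, fig1):
        assert cf.inter_institutional_fraction(fig1, fig1.ids()) == 1.0

    def test_all_single_institution_zero(self):
        corpus = Corpus([make_record(f"p{i}", insts={f"x{i}"}) for i in range(4)])
        assert cf.inter_institutional_fraction(corpus, corpus.ids()) == 0.0

    def test_empty_selection_undefined(self, fig1):
        with pytest.raises(UndefinedIndexError):
            cf.inter_institutional_fraction(fig1, set())

    def test_empty_institution_sets_in_denominator(self):
        corpus = Corpus([
            make_record("multi", insts={"a", "b"}),
            make_record("none", insts=set()),
        ])
        assert cf.inter_institutional_fraction(corpus, corpus.ids()) == 0.5

    @pytest.mark.parametrize("seed", [1, 6])
    def test_matches_direct_count(self, seed):
        corpus = make_random_corpus(seed)
        expected = sum(1 for p in corpus if len(p.institutions) >= 2) / len(corpus)
        assert cf.inter_institutional_fraction(corpus, corpus.ids()) == pytest.approx(expected)


class TestCompileIndexReport:
    def test_worked_example_report(self, fig1, fig1_collab_sectors):
        g = cf.build_collaboration(fig1)
        report = cf.compile_index_report(fig1, fig1.ids(), g, fig1_collab_sectors)
        assert report.n_papers == 3
        assert report.n_institutions == 5
        assert report.n_authors == 7
        assert report.frac_inter_institutional == 1.0
        assert report.frac_industrial == pytest.approx(0.6)

    def test_edgeless_corpus_undefined_markers(self):
        corpus = Corpus([make_record("p", insts={"solo"})])
        g = cf.build_collaboration(corpus)
        report = cf.compile_index_report(corpus, corpus.ids(), g, SectorMap({}))
        assert report.frac_industrial is None
        assert report.avg_clustering is None
        assert report.assortativity is None
        assert report.frac_top_90 is None
        assert report.frac_inter_institutional == 0.0

    @pytest.mark.parametrize("seed", [0, 3])
    def test_fields_equal_independent_recomputation(self, seed):
        corpus = make_random_corpus(seed)
        ids = corpus.ids()
        g = cf.build_collaboration(corpus, ids)
        sectors = SectorMap(
            {n: "industrial" for k, n in enumerate(sorted(g.nodes)) if k % 3 == 0}
        )
        report = cf.compile_index_report(corpus, ids, g, sectors)
        assert report.n_papers == len(ids)
        assert report.n_authors == cf.author_count(corpus, ids)
        assert report.frac_industrial == pytest.approx(cf.industrial_fraction(g, sectors))
        assert report.avg_clustering == pytest.approx(cf.average_clustering(g))
        assert report.frac_top_90 == pytest.approx(cf.top_share_fraction(g))

    def test_csv_export_undefined_as_empty_cells(self, tmp_path):
        from collabflow.indices import write_index_reports

        corpus = Corpus([make_record("p", insts={"solo"})])
        g = cf.build_collaboration(corpus)
        report = cf.compile_index_report(corpus, corpus.ids(), g, SectorMap({}))
        path = tmp_path / "report.csv"
        write_index_reports([report], path)
        lines = path.read_text().splitlines()
        assert lines[0] == (
            "papers,authors,institutions,frac_inter_institutional,"
            "frac_industrial,avg_clustering,assortativity,frac_top_90"
        )
        assert lines[1] == "1,0,1,0.0,,,,"
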