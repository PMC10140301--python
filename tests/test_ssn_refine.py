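import numpy as np
import pandas as pd
import pytest

from ssnmine.ssn_builder import Network, SimilarityEdge
from ssnmine.ssn_refine import (
    classify_cluster,
    components_at,
    fragmentation_percent,
    refine,
    reference_percentage,
    summaries_to_frame,
    summarize_family,
)

from _oracles import dfs_components


def make_toy_network(node_sources: dict[str, str], weighted_edges) -> Network:
    """Network from explicit nodes and (u, v, identity) triples."""
    nodes = pd.DataFrame(
        {"source": node_sources, "length": {k: 100 for k in node_sources}},
        index=pd.Index(sorted(node_sources), name="id"),
    )
    edges = [
        SimilarityEdge(*sorted((u, v)), percent_identity=pid, alignment_score=pid, aligned_length=100)
        for u, v, pid in weighted_edges
    ]
    return Network(nodes=nodes, edges=edges)


class TestComponents:
    def test_threshold_above_all_edges_gives_singletons(self):
        net = make_toy_network(
            {"a": "metagenome", "b": "metagenome", "c": "reference"},
            [("a", "b", 40.0), ("b", "c", 35.0)],
        )
        part = components_at(net, 50.0)
        assert part.n_components == 3

    def test_threshold_zero_on_connected_graph_gives_one_component(self):
        net = make_toy_network(
            {"a": "metagenome", "b": "metagenome", "c": "reference"},
            [("a", "b", 40.0), ("b", "c", 35.0)],
        )
        assert components_at(net, 0.0).n_components == 1

    def test_matches_dfs_oracle_on_random_graphs(self, rng):
        """Connected components agree with a depth-first-search oracle on
        random graphs with random thresholds."""
        for _ in range(50):
            n = int(rng.integers(2, 50))
            names = [f"n{i:02d}" for i in range(n)]
            sources = {x: "metagenome" for x in names}
            edges = []
            seen = set()
            for _ in range(int(rng.integers(0, 3 * n))):
                u, v = rng.choice(n, size=2, replace=False)
                pair = tuple(sorted((names[u], names[v])))
                if pair in seen:
                    continue
                seen.add(pair)
                edges.append((*pair, float(rng.uniform(0, 100))))
            net = make_toy_network(sources, edges)
            threshold = float(rng.uniform(0, 100))
            part = components_at(net, threshold)
            expected = dfs_components(
                names, [(u, v) for u, v, pid in edges if pid >= threshold]
            )
            assert set(part.components) == set(expected)

    def test_component_order_is_deterministic(self):
        net = make_toy_network(
            {"z": "metagenome", "a": "metagenome", "m": "reference"}, []
        )
        part = components_at(net, 10.0)
        assert [min(c) for c in part.components] == ["a", "m", "z"]


class TestDerivedStatistics:
    @pytest.mark.parametrize(
        "n_components, n_nodes, exact, reported",
        [
            (366, 2094, 17.478, 17),  # mismatch endonuclease family network
            (427, 2844, 15.014, 15),  # resolvase family network
            (679, 6556, 10.357, 10),  # photolyase family network
            (10, 10, 100.0, 100),  # all singletons
        ],
    )
    def test_fragmentation_from_printed_counts(self, n_components, n_nodes, exact, reported):
        value = fragmentation_percent(n_components, n_nodes)
        assert value == pytest.approx(exact, abs=0.01)
        assert round(value) == reported

    @pytest.mark.parametrize(
        "n_reference, n_total, expected",
        [
            (516, 2094, 24.6),
            (868, 2844, 30.5),
            (2623, 6556, 40.0),
            (0, 57, 0.0),
        ],
    )
    def test_reference_percentage_one_decimal(self, n_reference, n_total, expected):
        assert reference_percentage(n_reference, n_total) == expected

    def test_zero_nodes_rejected(self):
        with pytest.raises(ValueError):
            fragmentation_percent(0, 0)
        with pytest.raises(ValueError):
            reference_percentage(0, 0)


class TestClassifyCluster:
    def test_pure_metagenome_cluster(self):
        sources = {f"m{i}": "metagenome" for i in range(115)}
        comp = classify_cluster(frozenset(sources), sources, purity_min=0.9)
        assert comp.klass == "metagenome_only"
        assert comp.n_metagenome == 115 and comp.n_reference == 0

    def test_even_split_is_mixed(self):
        sources = {"m1": "metagenome", "m2": "metagenome", "r1": "reference",
                   "r2": "reference", "m3": "metagenome", "r3": "reference"}
        comp = classify_cluster(frozenset(sources), sources, size_min=2)
        assert comp.klass == "mixed"

    def test_small_component_is_singleton_regardless_of_source(self):
        sources = {"m1": "metagenome"}
        comp = classify_cluster(frozenset(sources), sources, size_min=5)
        assert comp.klass == "singleton"

    def test_full_purity_requires_zero_references(self):
        sources = {f"m{i}": "metagenome" for i in range(19)} | {"r0": "reference"}
        strict = classify_cluster(frozenset(sources), sources, purity_min=1.0)
        assert strict.klass == "mixed"
        lax = classify_cluster(frozenset(sources), sources, purity_min=0.95)
        assert lax.klass == "metagenome_only"


def two_family_network():
    """A mixed family plus a tight metagenome-only cluster linked to it at
    25% identity (the planted-novelty phenomenology)."""
    sources = {}
    edges = []
    mixed = [f"a{i}" for i in range(6)]
    for i, node in enumerate(mixed):
        sources[node] = "reference" if i < 3 else "metagenome"
    novel = [f"b{i}" for i in range(6)]
    for node in novel:
        sources[node] = "metagenome"
    for group in (mixed, novel):
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                edges.append((group[i], group[j], 70.0))
    edges.append(("a0", "b0", 25.0))  # weak bridge between the clusters
    return make_toy_network(sources, edges)


class TestRefine:
    def test_planted_separation_stops_below_ceiling(self):
        net = two_family_network()
        result = refine(net, t_start=10.0, step=1.0, ceiling=50.0, size_min=3)
        assert result.stop_reason == "separated"
        assert result.final_threshold < 50.0
        assert result.final_threshold > 25.0  # bridge must be cut first
        mg_only = result.metagenome_only_clusters()
        assert len(mg_only) == 1
        assert mg_only[0].members == frozenset(f"b{i}" for i in range(6))

    def test_inseparable_mixture_hits_ceiling_not_unique(self):
        sources = {f"n{i}": ("metagenome" if i % 2 else "reference") for i in range(10)}
        edges = [
            (f"n{i}", f"n{j}", 100.0) for i in range(10) for j in range(i + 1, 10)
        ]
        net = make_toy_network(sources, edges)
        result = refine(net, size_min=3)
        assert result.stop_reason == "ceiling"
        assert not result.unique

    def test_trace_component_count_non_decreasing(self):
        net = two_family_network()
        result = refine(net, size_min=3)
        counts = [n for _, n, _ in result.trace]
        assert counts == sorted(counts)

    def test_cluster_sizes_sum_to_total_nodes(self):
        net = two_family_network()
        result = refine(net, size_min=3)
        assert sum(c.size for c in result.clusters) == len(net.nodes)

    def test_tiny_network_rejected(self):
        net = make_toy_network({"a": "metagenome", "b": "metagenome"}, [])
        with pytest.raises(ValueError):
            refine(net, size_min=5)

    def test_transient_splinter_does_not_stop_the_sweep(self):
        # a metagenome pair splits off at 20% but dissolves into singletons
        # one step later, so the hysteresis guard must not stop there
        sources = {"m1": "metagenome", "m2": "metagenome", "m3": "metagenome",
                   "r1": "reference", "r2": "reference"}
        edges = [
            ("m1", "m2", 20.5),  # transient pair: gone by 21
            ("m1", "r1", 19.0),
            ("m2", "r1", 19.0),
            ("m3", "r1", 60.0), ("m3", "r2", 60.0), ("r1", "r2", 60.0),
        ]
        net = make_toy_network(sources, edges)
        result = refine(net, t_start=20.0, step=1.0, ceiling=50.0, size_min=2)
        # at t=20 {m1,m2} is metagenome-only but not stable at t=21
        assert result.final_threshold > 20.0


class TestSummaries:
    def test_family_summary_reproduces_derived_columns(self):
        net = two_family_network()
        result = refine(net, size_min=3)
        summary = summarize_family("toy", 100, net, result)
        assert summary.total_nodes == summary.n_metagenome + summary.n_reference
        assert summary.pct_reference == reference_percentage(
            summary.n_reference, summary.total_nodes
        )
        assert summary.fragmentation_percent_int == round(result.fragmentation)

    def test_summary_frame_layout(self):
        net = two_family_network()
        result = refine(net, size_min=3)
        frame = summaries_to_frame([summarize_family("toy", 100, net, result)])
        assert list(frame.columns)[:5] == [
            "family",
            "length_threshold_aa",
            "total_nodes",
            "n_metagenome",
            "n_reference",
        ]
        assert len(frame) == 1
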