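"""Interactome loading, seed expansion, subnetworks and topology metrics."""

import math

import networkx as nx
import numpy as np
import pytest

from netseed.annotation import GeneInterval
from netseed.interactome import (
    build_categorized_subnetwork,
    expand_seed_network,
    genes_near_loci,
    largest_connected_component,
    load_interactome,
    topology_metrics,
)
from netseed.simulate import InteractomeSimSpec, simulate_interactome


class TestLoadInteractome:
    def test_dedup_and_self_loop_drop(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\nB\tA\nA\tA\n")
        g = load_interactome(p)
        assert sorted(g.nodes) == ["A", "B"]
        assert g.number_of_edges() == 1

    def test_empty_file_gives_empty_graph(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("")
        g = load_interactome(p)
        assert g.number_of_nodes() == 0

    def test_path_degrees_and_extra_columns(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\t0.9\nB\tC\t0.8\n")
        g = load_interactome(p)
        assert g.degree["B"] == 2

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\nlonely\n")
        with pytest.raises(ValueError, match="line 2"):
            load_interactome(p)


class TestExpandSeedNetwork:
    def test_star_center_seed_covers_graph(self):
        g = nx.star_graph(5)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        net = expand_seed_network(g, ["n0"])
        assert net.members == frozenset(g.nodes)

    def test_missing_seed_kept_isolated(self):
        g = nx.Graph([("a", "b")])
        net = expand_seed_network(g, ["x"])
        assert net.members == frozenset({"x"})
        assert net.missing_seeds == frozenset({"x"})

    def test_members_match_adjacency_union_oracle(self):
        g, seeds = simulate_interactome(InteractomeSimSpec(
            n_nodes=500, attachment_edges=2, seed_module_size=20,
            seed_module_extra_edge_prob=0.3, rng_seed=4))
        net = expand_seed_network(g, seeds)
        expected = set(seeds)
        for s in seeds:
            expected |= set(g[s])
        assert net.members == frozenset(expected)

    def test_idempotent_on_members(self):
        g, seeds = simulate_interactome(InteractomeSimSpec(
            n_nodes=200, attachment_edges=2, seed_module_size=10, rng_seed=1))
        first = expand_seed_network(g, seeds)
        again = expand_seed_network(g, seeds)
        assert first.members == again.members

    def test_empty_seed_list_rejected(self):
        with pytest.raises(ValueError):
            expand_seed_network(nx.Graph([("a", "b")]), [])


class TestCategorizedSubnetwork:
    def test_triangle_all_seed(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        sub = build_categorized_subnetwork(g, {n: {"SEED"} for n in "abc"})
        assert sub.graph.number_of_nodes() == 3
        assert sub.n_edges == 3
        assert sub.lcc_size == 3

    def test_two_disjoint_edges_lcc(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        sub = build_categorized_subnetwork(g, {n: {"GWAS_HIT"} for n in "abcd"})
        assert sub.lcc_size == 2

    def test_edge_count_matches_pair_scan_oracle(self):
        g, _ = simulate_interactome(InteractomeSimSpec(
            n_nodes=300, attachment_edges=2, rng_seed=9))
        rng = np.random.default_rng(0)
        chosen = [sorted(g.nodes)[i]
                  for i in rng.choice(g.number_of_nodes(), size=74, replace=False)]
        sub = build_categorized_subnetwork(g, {n: {"CANDIDATE"} for n in chosen})
        brute = sum(
            1 for i, a in enumerate(chosen) for b in chosen[i + 1:] if g.has_edge(a, b)
        )
        assert sub.n_edges == brute


class TestGenesNearLoci:
    GENE = GeneInterval("G1", "1", 1000, 2000)

    @pytest.mark.parametrize("flank,expected", [(500, {"G1"}), (499, set())])
    def test_flank_boundary(self, flank, expected):
        assert genes_near_loci([self.GENE], [("1", 2500)], flank) == expected

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(3)
        genes = []
        for i in range(50):
            s = int(rng.integers(1, 10**6))
            genes.append(GeneInterval(f"G{i}", str(rng.integers(1, 3)),
                                      s, s + int(rng.integers(100, 20_000))))
        loci = [(str(rng.integers(1, 3)), int(rng.integers(1, 10**6)))
                for _ in range(20)]
        flank = 250_000
        got = genes_near_loci(genes, loci, flank)
        expected = {
            g.gene_id
            for g in genes
            for chrom, pos in loci
            if g.chromosome == chrom and g.start <= pos + flank and g.end >= pos - flank
        }
        assert got == expected

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            genes_near_loci([self.GENE], [("1", 1500)], -1)


class TestLargestConnectedComponent:
    def test_triangle_beats_isolate(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        g.add_node("z")
        assert set(largest_connected_component(g).nodes) == {"a", "b", "c"}

    def test_tie_broken_by_smallest_identifier(self):
        g = nx.Graph([("C", "D"), ("A", "B")])
        assert set(largest_connected_component(g).nodes) == {"A", "B"}

    def test_sizes_match_flood_fill_oracle(self):
        g = nx.gnp_random_graph(60, 0.03, seed=5)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        lcc = largest_connected_component(g)
        visited, best = set(), 0
        for start in g.nodes:
            if start in visited:
                continue
            comp, stack = {start}, [start]
            while stack:
                for nb in g[stack.pop()]:
                    if nb not in comp:
                        comp.add(nb)
                        stack.append(nb)
            visited |= comp
            best = max(best, len(comp))
        assert lcc.number_of_nodes() == best

    def test_connected_graph_is_its_own_lcc(self):
        g = nx.path_graph(7)
        assert largest_connected_component(g).number_of_edges() == 6

    def test_empty_graph(self):
        assert largest_connected_component(nx.Graph()).number_of_nodes() == 0


class TestTopologyMetrics:
    def test_triangle(self):
        m = topology_metrics(nx.complete_graph(3))
        assert m.apl == 1.0 and m.acc == 1.0

    def test_path_of_three(self):
        m = topology_metrics(nx.path_graph(3))
        assert math.isclose(m.apl, 4 / 3)
        assert m.acc == 0.0

    def test_square_with_chord_hand_enumeration(self, square_with_chord):
        m = topology_metrics(square_with_chord)
        assert math.isclose(m.apl, 7 / 6)
        assert math.isclose(m.acc, 5 / 6)

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_complete_graph(self, n):
        m = topology_metrics(nx.complete_graph(n))
        assert m.apl == 1.0 and m.acc == 1.0

    def test_single_node_flagged(self):
        g = nx.Graph()
        g.add_node("a")
        m = topology_metrics(g)
        assert not m.apl_defined and m.acc == 0.0

    def test_apl_matches_bfs_oracle_on_random_graphs(self):
        def bfs_dist(g, src):
            dist = {src: 0}
            frontier = [src]
            while frontier:
                nxt = []
                for v in frontier:
                    for nb in g[v]:
                        if nb not in dist:
                            dist[nb] = dist[v] + 1
                            nxt.append(nb)
                frontier = nxt
            return dist

        for seed in range(5):
            g = nx.gnp_random_graph(40, 0.08, seed=seed)
            m = topology_metrics(g)
            lcc = largest_connected_component(g)
            nodes = list(lcc.nodes)
            total, npairs = 0, 0
            for i, a in enumerate(nodes):
                d = bfs_dist(lcc, a)
                for b in nodes[i + 1:]:
                    total += d[b]
                    npairs += 1
            assert math.isclose(m.apl, total / npairs, rel_tol=1e-12)
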