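import itertools

import networkx as nx
import pytest

from hapbarcode.network import (
    build_network,
    collapse_haplotypes,
    haplotype_labels,
    insert_ghosts,
    mutational_steps,
)

from conftest import make_catalog, random_catalog


def union_of_msts(catalog):
    """Brute-force oracle: union of edge sets over every minimum-weight
    spanning tree, enumerated exhaustively."""
    ids = list(catalog.haplotypes)
    n = len(ids)
    edges = [
        (a, b, mutational_steps(catalog.haplotypes[a], catalog.haplotypes[b]))
        for a, b in itertools.combinations(ids, 2)
    ]
    if n == 1:
        return set()
    best, best_sets = None, []
    for combo in itertools.combinations(edges, n - 1):
        g = nx.Graph()
        g.add_nodes_from(ids)
        g.add_edges_from((a, b) for a, b, _ in combo)
        if not nx.is_connected(g):
            continue
        w = sum(w for _, _, w in combo)
        if best is None or w < best:
            best, best_sets = w, [combo]
        elif w == best:
            best_sets.append(combo)
    union = set()
    for combo in best_sets:
        union.update(frozenset((a, b)) for a, b, _ in combo)
    return union


class TestCollapse:
    def test_merges_identical_sequences(self):
        cat = make_catalog(
            [("s1", "x", "i", "ACG"), ("s2", "x", "i", "ACG"), ("s3", "x", "i", "ACT")]
        )
        assert cat.counts == {"A": 2, "B": 1}
        assert cat.haplotypes["A"] == "ACG"

    def test_all_distinct(self, rng):
        cat = random_catalog(rng, 7)
        assert cat.n_haplotypes == 7
        assert all(c == 1 for c in cat.counts.values())

    def test_counts_sum_to_copies(self, rng):
        copies = [(f"s{i}", "x", "i", "ACGT") for i in range(5)] + [
            ("s9", "x", "i", "ACGA")
        ]
        cat = make_catalog(copies)
        assert cat.total_copies == 6

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            collapse_haplotypes([])

    def test_label_sequence(self):
        labels = haplotype_labels(29)
        assert labels[:3] == ["A", "B", "C"]
        assert labels[25:29] == ["Z", "AA", "AB", "AC"]


class TestMutationalSteps:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACGT", "ACGT", 0), ("ACGT", "ACGA", 1), ("ACGT", "TGCA", 4)],
    )
    def test_substitution_counts(self, a, b, expected):
        assert mutational_steps(a, b) == expected

    def test_indel_modes(self):
        assert mutational_steps("AC-T", "ACGT", indel_mode="exclude") == 0
        assert mutational_steps("AC-T", "ACGT", indel_mode="fifth-state-event") == 1

    def test_missing_data_excluded(self):
        assert mutational_steps("ACNT", "ACGT") == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutational_steps("ACG", "ACGT")

    def test_symmetry(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT-N"), size=15))
            b = "".join(rng.choice(list("ACGT-N"), size=15))
            for mode in ("exclude", "fifth-state-event"):
                assert mutational_steps(a, b, mode) == mutational_steps(b, a, mode)


class TestBuildNetwork:
    def test_two_haplotypes_single_edge(self):
        cat = make_catalog([("s1", "x", "i", "AAAA"), ("s2", "x", "i", "AAAT")])
        net = build_network(cat)
        assert set(net.graph.edges) == {("A", "B")}

    def test_star_topology(self):
        # central AAAA..., three tips one step away and >=2 steps apart
        seqs = ["AAAAAA", "TAAAAA", "AATAAA", "AAAATA"]
        cat = make_catalog(
            [("c", "x", "i", seqs[0])] * 2
            + [(f"s{i}", "x", "i", s) for i, s in enumerate(seqs[1:])]
        )
        net = build_network(cat)
        center = "A"  # highest count
        assert net.graph.degree[center] == 3
        assert net.graph.number_of_edges() == 3

    def test_triangle_loop_retained(self):
        # three haplotypes pairwise 1 step apart at the same column
        cat = make_catalog(
            [("s1", "x", "i", "AAAA"), ("s2", "x", "i", "CAAA"), ("s3", "x", "i", "GAAA")]
        )
        net = build_network(cat)
        assert net.graph.number_of_edges() == 3  # all edges lie in some MST

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_equals_union_of_all_msts(self, rng, n):
        for _ in range(8):
            cat = random_catalog(rng, n, length=6)
            net = build_network(cat)
            got = {frozenset(e) for e in net.graph.edges}
            assert got == union_of_msts(cat)

    def test_parsimony_limit_disconnects_into_components(self):
        seqs = ["AAAAAA", "TAAAAA", "TTTTTT", "TTTTTA"]
        cat = make_catalog([(f"s{i}", "x", "i", s) for i, s in enumerate(seqs)])
        net = build_network(cat, parsimony_limit=1)
        assert not net.is_connected()
        comps = net.components()
        assert len(comps) == 2
        assert sorted(len(c.graph) for c in comps) == [2, 2]

    def test_network_contains_an_mst(self, rng):
        cat = random_catalog(rng, 6, length=8)
        net = build_network(cat)
        dist = nx.Graph()
        ids = list(cat.haplotypes)
        for a, b in itertools.combinations(ids, 2):
            dist.add_edge(a, b, weight=mutational_steps(cat.haplotypes[a], cat.haplotypes[b]))
        mst_weight = sum(d["weight"] for _, _, d in nx.minimum_spanning_tree(dist).edges(data=True))
        assert net.is_connected()
        assert net.total_length() >= mst_weight


class TestInsertGhosts:
    def test_unit_edge_unchanged(self):
        cat = make_catalog([("s1", "x", "i", "AAAA"), ("s2", "x", "i", "AAAT")])
        net = insert_ghosts(build_network(cat))
        assert net.n_ghost == 0

    def test_weight_three_edge_gets_two_ghosts(self):
        cat = make_catalog([("s1", "x", "i", "AAAA"), ("s2", "x", "i", "TTTA")])
        net = insert_ghosts(build_network(cat))
        assert net.n_ghost == 2
        assert all(d["weight"] == 1 for _, _, d in net.graph.edges(data=True))
        assert all(net.graph.degree[g] == 2 for g in net.ghosts())

    def test_observed_geodesics_and_total_length_preserved(self, rng):
        for _ in range(10):
            cat = random_catalog(rng, 6, length=10)
            net = build_network(cat)
            ghosted = insert_ghosts(net)
            assert ghosted.total_length() == net.total_length()
            before = dict(nx.all_pairs_dijkstra_path_length(net.graph, weight="weight"))
            after = dict(nx.all_pairs_dijkstra_path_length(ghosted.graph, weight="weight"))
            for a, b in itertools.combinations(net.observed(), 2):
                assert before[a][b] == after[a][b]
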