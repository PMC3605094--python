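import itertools

import networkx as nx
import pytest

from hapbarcode.netstats import (
    diagnostic_haplotypes,
    four_gamete_screen,
    gene_report,
    ghost_percent,
    interspecific_gap,
    network_stats,
)
from hapbarcode.network import HaplotypeNetwork, build_network, insert_ghosts
from hapbarcode.phasing import clark_phase, genotypes_from_alignment
from hapbarcode.seqio import Alignment

from conftest import make_catalog, make_specimens, path_sequences


def unit_network(edges, observed=None):
    g = nx.Graph()
    nodes = {n for e in edges for n in e[:2]}
    observed = observed or nodes
    for n in nodes:
        g.add_node(
            n,
            kind="observed" if n in observed else "ghost",
            count=1 if n in observed else 0,
            sequence="",
        )
    for e in edges:
        w = e[2] if len(e) > 2 else 1
        g.add_edge(e[0], e[1], weight=w)
    return HaplotypeNetwork(graph=g, locus_name="loc")


def brute_force_stats(net):
    """Oracle: geodesics via exhaustive simple-path enumeration."""
    g = net.graph
    observed = net.observed()
    longest = 0
    for a, b in itertools.combinations(observed, 2):
        best = None
        for path in nx.all_simple_paths(g, a, b):
            w = sum(g[u][v]["weight"] for u, v in zip(path, path[1:]))
            best = w if best is None else min(best, w)
        longest = max(longest, best)
    total = sum(d["weight"] for _, _, d in g.edges(data=True))
    return longest, total


class TestRamificationIndex:
    def test_linear_path_is_zero(self):
        net = unit_network([(f"h{i}", f"h{i+1}") for i in range(5)])
        s = network_stats(net)
        assert (s.longest_distance, s.total_length, s.I) == (5, 5, 0.0)

    def test_star_is_half(self):
        net = unit_network([("c", t) for t in "wxyz"])
        s = network_stats(net)
        assert (s.longest_distance, s.total_length) == (2, 4)
        assert s.I == 0.5

    def test_triangle(self):
        net = unit_network([("a", "b"), ("b", "c"), ("a", "c")])
        s = network_stats(net)
        assert s.I == pytest.approx(1 - 1 / 3)

    def test_single_haplotype_undefined(self):
        g = nx.Graph()
        g.add_node("a", kind="observed", count=3, sequence="")
        assert network_stats(HaplotypeNetwork(graph=g)).I is None

    def test_ghosts_do_not_enter_diameter(self):
        # observed pair 3 steps apart through 2 ghosts: diameter 3, length 3
        net = unit_network(
            [("a", "g1"), ("g1", "g2"), ("g2", "b")], observed={"a", "b"}
        )
        s = network_stats(net)
        assert (s.longest_distance, s.total_length) == (3, 3)
        assert s.I == 0.0

    def test_matches_brute_force_on_random_networks(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 8))
            g = nx.gnp_random_graph(n, 0.6, seed=int(rng.integers(1 << 30)))
            if not nx.is_connected(g):
                continue
            edges = [
                (f"h{u}", f"h{v}", int(rng.integers(1, 4))) for u, v in g.edges
            ]
            net = unit_network(edges)
            s = network_stats(net)
            longest, total = brute_force_stats(net)
            assert (s.longest_distance, s.total_length) == (longest, total)
            if total > 0:
                assert s.I == pytest.approx(1 - longest / total)

    def test_disconnected_network_rejected(self):
        g = nx.Graph()
        for n in "ab":
            g.add_node(n, kind="observed", count=1, sequence="")
        with pytest.raises(ValueError, match="disconnected"):
            network_stats(HaplotypeNetwork(graph=g))


class TestGhostPercent:
    def test_one_of_nine(self):
        # chain of 9 observed haplotypes with one two-step edge -> 1 ghost
        seqs = path_sequences(9, step_positions=[1, 1, 1, 2, 1, 1, 1, 1])
        cat = make_catalog([(f"s{i}", "x", "i", s) for i, s in enumerate(seqs)])
        net = insert_ghosts(build_network(cat))
        assert (net.n_observed, net.n_ghost) == (9, 1)
        assert ghost_percent(net) == 11.1

    def test_no_ghosts(self):
        net = unit_network([("a", "b")])
        assert ghost_percent(net) == 0.0

    def test_nine_of_sixteen(self):
        g = nx.Graph()
        for i in range(16):
            g.add_node(f"obs{i}", kind="observed", count=1, sequence="")
        for i in range(9):
            g.add_node(f"gh{i}", kind="ghost", count=0, sequence="")
        nodes = [f"obs{i}" for i in range(16)] + [f"gh{i}" for i in range(9)]
        for a, b in zip(nodes, nodes[1:]):
            g.add_edge(a, b, weight=1)
        assert ghost_percent(HaplotypeNetwork(graph=g)) == 56.3


class TestDiagnosticHaplotypes:
    def test_unique_and_fixed_haplotype_is_diagnostic(self):
        copies = [
            ("a1", "spA", "K", "AAAA"),
            ("a2", "spA", "K", "AAAA"),
            ("b1", "spB", "K", "TTAA"),
        ]
        report = diagnostic_haplotypes(make_catalog(copies), make_specimens(copies))
        assert report.diagnostic_species == ["spA", "spB"]

    def test_shared_haplotype_excluded_even_if_fixed(self):
        copies = [
            ("a1", "spA", "K", "AAAA"),
            ("a2", "spA", "K", "AAAA"),
            ("b1", "spB", "K", "AAAA"),
            ("b2", "spB", "K", "TTAA"),
        ]
        report = diagnostic_haplotypes(make_catalog(copies), make_specimens(copies))
        assert "spA" not in report.diagnostic_species

    def test_unfixed_haplotype_excluded(self):
        copies = [
            ("a1", "spA", "K", "AAAA"),
            ("a2", "spA", "K", "CCAA"),
            ("b1", "spB", "K", "TTAA"),
        ]
        report = diagnostic_haplotypes(make_catalog(copies), make_specimens(copies))
        assert "spA" not in report.diagnostic_species

    def test_heterozygote_counts_as_carrying(self):
        # diploid: individual a2 carries the diagnostic haplotype on one copy
        copies = [
            ("a1", "spA", "K", "AAAA"),
            ("a1", "spA", "K", "AAAA"),
            ("a2", "spA", "K", "AAAA"),
            ("a2", "spA", "K", "GGGG"),
            ("b1", "spB", "K", "TTAA"),
        ]
        report = diagnostic_haplotypes(make_catalog(copies), make_specimens(copies))
        assert "spA" in report.diagnostic_species

    def test_single_species_dataset(self):
        copies = [("a1", "spA", "K", "AAAA"), ("a2", "spA", "K", "AAAA")]
        report = diagnostic_haplotypes(make_catalog(copies))
        assert report.diagnostic_species == ["spA"]
        assert report.percent_diagnostic == 100

    def test_removal_monotonicity(self):
        # dropping an individual can only preserve or enlarge the species'
        # diagnostic set recomputed on the remaining sample
        copies = [
            ("a1", "spA", "K", "AAAA"),
            ("a2", "spA", "K", "CCAA"),  # polymorphic -> nothing fixed
            ("b1", "spB", "K", "TTAA"),
        ]
        before = {
            e.haplotype_id
            for e in diagnostic_haplotypes(make_catalog(copies)).entries
            if e.species == "spA"
        }
        reduced = [c for c in copies if c[0] != "a2"]
        after = {
            e.haplotype_id
            for e in diagnostic_haplotypes(make_catalog(reduced)).entries
            if e.species == "spA"
        }
        assert before <= after


class TestInterspecificGap:
    def test_one_step_neighbour_is_no_gap(self):
        copies = [("a1", "spA", "K", "AAAA"), ("b1", "spB", "K", "TAAA")]
        cat = make_catalog(copies)
        assert interspecific_gap("A", cat) is False

    def test_three_steps_is_a_gap(self):
        copies = [("a1", "spA", "K", "AAAA"), ("b1", "spB", "K", "TTTA")]
        cat = make_catalog(copies)
        assert interspecific_gap("A", cat) is True

    def test_exactly_one_gapped_diagnostic(self):
        # several diagnostic species but only one beyond a single step
        copies = [
            ("a1", "spA", "K", "AAAAAA"),
            ("b1", "spB", "K", "TAAAAA"),
            ("c1", "spC", "K", "TATTTA"),
        ]
        cat = make_catalog(copies)
        report = diagnostic_haplotypes(cat, make_specimens(copies))
        gapped = [e for e in report.entries if e.gap]
        assert len(report.entries) == 3
        assert [e.species for e in gapped] == ["spC"]


class TestFourGameteScreen:
    def test_three_gametes_pass(self):
        cat = make_catalog(
            [("s1", "x", "i", "AA"), ("s2", "x", "i", "AT"), ("s3", "x", "i", "TA")]
        )
        assert four_gamete_screen(cat) == []

    def test_four_gametes_flagged(self):
        cat = make_catalog(
            [
                ("s1", "x", "i", "AA"),
                ("s2", "x", "i", "AT"),
                ("s3", "x", "i", "TA"),
                ("s4", "x", "i", "TT"),
            ]
        )
        assert four_gamete_screen(cat) == [(0, 1)]

    def test_tree_generated_haplotypes_pass(self):
        from hapbarcode.synthetic import SimulationConfig, simulate_radiation
        from hapbarcode.network import collapse_haplotypes

        ds = simulate_radiation(SimulationConfig(seed=5))
        for name, data in ds.loci.items():
            cat = collapse_haplotypes(data.copies, locus_name=name)
            assert four_gamete_screen(cat) == []


class TestGeneReport:
    def _locus(self):
        rows = {
            "a1": "AAGCT",
            "a2": "ARGYT",
            "b1": "AGGTT",
        }
        aln = Alignment("loc", rows)
        phased = clark_phase(genotypes_from_alignment(aln))
        copies = [
            ("a1", "spA", "K", phased.resolved["a1"][0]),
            ("a1", "spA", "K", phased.resolved["a1"][1]),
            ("a2", "spA", "K", phased.resolved["a2"][0]),
            ("a2", "spA", "K", phased.resolved["a2"][1]),
            ("b1", "spB", "K", phased.resolved["b1"][0]),
            ("b1", "spB", "K", phased.resolved["b1"][1]),
        ]
        cat = make_catalog(copies, locus_name="loc")
        net = insert_ghosts(build_network(cat))
        return aln, phased, cat, net, make_specimens(copies)

    def test_fields_match_independent_computation(self):
        aln, phased, cat, net, specimens = self._locus()
        report = gene_report(aln, phased, cat, net, specimens, mode="nuclear")
        assert report.n_haplotypes == cat.n_haplotypes
        assert report.heterozygosity_percent == pytest.approx(100 / 3, abs=0.05)
        # haplotype rows differ at columns 2 and 4 of 5
        assert report.n_variable_sites == 2
        assert report.percent_variable == 40.0
        assert report.n_components == 1

    def test_cross_locus_mixing_rejected(self):
        aln, phased, cat, net, specimens = self._locus()
        other = Alignment("other", aln.rows)
        with pytest.raises(ValueError, match="cross-locus"):
            gene_report(other, phased, cat, net, specimens, mode="nuclear")

    def test_plastid_mode_has_zero_heterozygosity(self):
        rows = {"a1": "AAAA", "b1": "ATAA"}
        aln = Alignment("loc", rows)
        copies = [("a1", "spA", "K", "AAAA"), ("b1", "spB", "K", "ATAA")]
        cat = make_catalog(copies, locus_name="loc")
        net = insert_ghosts(build_network(cat))
        report = gene_report(aln, None, cat, net, make_specimens(copies), mode="plastid")
        assert report.heterozygosity_percent == 0.0
        assert report.mode == "plastid"

    def test_invariant_locus_has_undefined_index(self):
        rows = {"a1": "AAAA", "a2": "AAAA"}
        aln = Alignment("loc", rows)
        copies = [("a1", "spA", "K", "AAAA"), ("a2", "spA", "K", "AAAA")]
        cat = make_catalog(copies, locus_name="loc")
        net = insert_ghosts(build_network(cat))
        report = gene_report(aln, None, cat, net, make_specimens(copies), mode="plastid")
        assert report.percent_variable == 0.0
        assert report.ramification_index is None
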