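"""Statistical-parsimony-style haplotype networks.

Observed sequences are collapsed into distinct haplotypes, which are then
connected by edges weighted in mutational steps.  The network retained is
the union of all minimum spanning trees of the pairwise-distance graph, so
that alternative equal-length connections survive as loops — the behaviour
seen in classic statistical-parsimony (TCS-style) haplotype networks for
closely related sequences.  Multi-step edges are finally subdivided into
chains of unit edges through inferred "ghost" nodes: intermediate
haplotypes required by the network but never recovered in any sampled
accession.

The classical 95% statistical-parsimony connection probability is replaced
by an explicit integer ``parsimony_limit`` (default: unlimited); when a
finite limit disconnects the graph, the network is returned with multiple
components which can be inspected via :meth:`HaplotypeNetwork.components`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import networkx as nx

from .seqio import NUCLEOTIDES, gap_runs

IndelMode = Literal["exclude", "fifth-state-event"]


@dataclass(frozen=True)
class GeneCopy:
    """One sampled gene copy with its carrier metadata.

    A diploid individual contributes two copies at a nuclear locus
    (suffixes _a/_b on the copy id), a plastid locus one copy.
    """

    specimen: str
    species: str
    island: str
    sequence: str


@dataclass
class HaplotypeCatalog:
    """Distinct haplotypes of one locus with copy counts and carriers."""

    locus_name: str
    haplotypes: dict[str, str]  # id -> sequence
    counts: dict[str, int]  # id -> number of gene copies
    carriers: dict[str, list[GeneCopy]]  # id -> carrier copies

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def total_copies(self) -> int:
        return sum(self.counts.values())

    def species_of(self, hap_id: str) -> set[str]:
        return {c.species for c in self.carriers[hap_id]}

    def islands_of(self, hap_id: str) -> set[str]:
        return {c.island for c in self.carriers[hap_id]}


def haplotype_labels(n: int) -> list[str]:
    """A, B, ... Z, AA, AB, ... labels as used on network figures."""
    labels = []
    for i in range(n):
        label = ""
        j = i
        while True:
            label = chr(ord("A") + j % 26) + label
            j = j // 26 - 1
            if j < 0:
                break
        labels.append(label)
    return labels


def collapse_haplotypes(
    copies: Sequence[GeneCopy], locus_name: str = ""
) -> HaplotypeCatalog:
    """Merge identical sequences into haplotypes.

    Ids are assigned A, B, C, ... by descending copy count, ties broken
    lexicographically on the sequence, so the most common haplotype is
    always "A".
    """
    if not copies:
        raise ValueError("no gene copies to collapse")
    lengths = {len(c.sequence) for c in copies}
    if len(lengths) > 1:
        raise ValueError(f"gene copies differ in length: {sorted(lengths)}")
    by_seq: dict[str, list[GeneCopy]] = {}
    for copy in copies:
        by_seq.setdefault(copy.sequence, []).append(copy)
    ordered = sorted(by_seq.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    labels = haplotype_labels(len(ordered))
    return HaplotypeCatalog(
        locus_name=locus_name,
        haplotypes={lab: seq for lab, (seq, _) in zip(labels, ordered)},
        counts={lab: len(members) for lab, (_, members) in zip(labels, ordered)},
        carriers={lab: members for lab, (_, members) in zip(labels, ordered)},
    )


def mutational_steps(a: str, b: str, indel_mode: IndelMode = "exclude") -> int:
    """Number of mutational steps separating two aligned sequences.

    Counts columns where the two sequences carry different unambiguous
    nucleotides.  Columns gapped or missing in either sequence never count
    as substitutions; with ``indel_mode="fifth-state-event"`` each
    simple-coded indel event (maximal gap run with identical start and
    end) present in exactly one of the two sequences adds one step.
    """
    if len(a) != len(b):
        raise ValueError(f"sequence length mismatch: {len(a)} vs {len(b)}")
    steps = 0
    for x, y in zip(a, b):
        if x != y and x in NUCLEOTIDES and y in NUCLEOTIDES:
            steps += 1
    if indel_mode == "fifth-state-event":
        steps += len(set(gap_runs(a)) ^ set(gap_runs(b)))
    elif indel_mode != "exclude":
        raise ValueError(f"unknown indel_mode {indel_mode!r}")
    return steps


@dataclass
class HaplotypeNetwork:
    """Haplotype graph: observed nodes (with counts) plus ghost nodes.

    Node attributes: ``kind`` ("observed"|"ghost"), ``count`` (gene
    copies; 0 for ghosts), ``sequence`` (empty for ghosts), ``species``
    and ``islands`` (";"-joined).  Edge attribute: ``weight`` (mutational
    steps; all 1 after ghost insertion).
    """

    graph: nx.Graph
    locus_name: str = ""

    def observed(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "observed"]

    def ghosts(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "ghost"]

    @property
    def n_observed(self) -> int:
        return len(self.observed())

    @property
    def n_ghost(self) -> int:
        return len(self.ghosts())

    def total_length(self) -> int:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    def components(self) -> list["HaplotypeNetwork"]:
        return [
            HaplotypeNetwork(self.graph.subgraph(c).copy(), self.locus_name)
            for c in sorted(nx.connected_components(self.graph), key=sorted)
        ]


def build_network(
    catalog: HaplotypeCatalog,
    parsimony_limit: int | None = None,
    epsilon: int = 0,
    indel_mode: IndelMode = "exclude",
) -> HaplotypeNetwork:
    """Build the minimum spanning network over a haplotype catalog.

    An edge (u, v, w) is retained iff w <= t(u, v) + epsilon, where
    t(u, v) is the smallest weight threshold at which u and v fall into
    the same connected component of the pairwise-distance graph.  With
    ``epsilon=0`` this is exactly the union of all minimum spanning trees
    (an edge belongs to some MST iff its endpoints are disconnected using
    strictly lighter edges), so equal-length alternative paths are kept
    as loops.  Edges heavier than ``parsimony_limit`` are forbidden; if
    that disconnects the graph the components are kept in one
    :class:`HaplotypeNetwork` and can be split via ``components()``.
    """
    ids = list(catalog.haplotypes)
    g = nx.Graph()
    for hap_id in ids:
        g.add_node(
            hap_id,
            kind="observed",
            count=catalog.counts[hap_id],
            sequence=catalog.haplotypes[hap_id],
            species=";".join(sorted(catalog.species_of(hap_id))),
            islands=";".join(sorted(catalog.islands_of(hap_id))),
        )
    candidate: list[tuple[int, str, str]] = []
    for a, b in itertools.combinations(ids, 2):
        w = mutational_steps(
            catalog.haplotypes[a], catalog.haplotypes[b], indel_mode=indel_mode
        )
        if parsimony_limit is None or w <= parsimony_limit:
            candidate.append((w, a, b))
    candidate.sort()  # (weight, nodeA, nodeB): deterministic tie-break

    # Kruskal-style sweep recording, for every candidate pair, the weight
    # threshold at which its endpoints first become connected.
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    threshold: dict[tuple[str, str], int] = {}
    unresolved = {tuple(sorted((a, b))) for _, a, b in candidate}
    for w, group in itertools.groupby(candidate, key=lambda e: e[0]):
        for _, a, b in group:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
        for pair in [p for p in unresolved if find(p[0]) == find(p[1])]:
            threshold[pair] = w
            unresolved.discard(pair)

    for w, a, b in candidate:
        t = threshold[tuple(sorted((a, b)))]
        if w <= t + epsilon:
            g.add_edge(a, b, weight=w)
    return HaplotypeNetwork(graph=g, locus_name=catalog.locus_name)


def insert_ghosts(net: HaplotypeNetwork) -> HaplotypeNetwork:
    """Subdivide every edge of weight m >= 2 into a chain of m-1 ghost
    nodes joined by unit edges.

    Observed-node geodesic distances and the total network length are
    unchanged.  Ghost chains on alternative equal-weight paths are not
    merged into shared median nodes.
    """
    g = net.graph.copy()
    for u, v, data in sorted(net.graph.edges(data=True)):
        m = data["weight"]
        if m < 2:
            continue
        g.remove_edge(u, v)
        prev = u
        for k in range(1, m):
            ghost = f"ghost.{u}-{v}.{k}"
            g.add_node(
                ghost, kind="ghost", count=0, sequence="", species="", islands=""
            )
            g.add_edge(prev, ghost, weight=1)
            prev = ghost
        g.add_edge(prev, v, weight=1)
    return HaplotypeNetwork(graph=g, locus_name=net.locus_name)


def write_graphml(net: HaplotypeNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))


def write_edgelist(net: HaplotypeNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for u, v, d in sorted(net.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['weight']}\n")
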