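"""Network and diagnosability statistics for haplotype barcoding.

Implements the summary statistics used to contrast plastid and nuclear
markers: the ramification index I = 1 - (longest geodesic between two
observed haplotypes / total network length), the percentage of ghost
(inferred, unsampled) haplotypes, species-diagnostic haplotypes
(haplotypes unique to a single species and found in all sampled
individuals of that species), interspecific barcoding gaps (diagnostic
haplotypes more than one substitution from every other species'
haplotype), and a Hudson-Kaplan four-gamete screen for recombination.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .network import (
    HaplotypeCatalog,
    HaplotypeNetwork,
    IndelMode,
    mutational_steps,
)
from .phasing import Genotype, PhasedSet, heterozygosity_percent, phased_alignment
from .seqio import (
    NUCLEOTIDES,
    Alignment,
    SiteSummary,
    SpecimenTable,
    round_half_up,
    site_summary,
)


@dataclass(frozen=True)
class NetworkStats:
    """Shape statistics of one (connected) haplotype network.

    ``longest_distance`` is the network diameter over observed nodes
    (maximum geodesic step count); ``I`` is the ramification index,
    undefined (None) for networks with fewer than two observed haplotypes
    or zero total length.
    """

    longest_distance: int
    total_length: int
    n_observed: int
    n_ghost: int
    ghost_percent: float
    I: Optional[float]


def network_stats(net: HaplotypeNetwork) -> NetworkStats:
    """Compute diameter, total length, ghost percentage and ramification
    index for a connected network (ghosts inserted or not: both the
    observed geodesics and the total length are invariant to ghost
    insertion)."""
    if net.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    if not net.is_connected():
        raise ValueError(
            "network is disconnected; compute statistics per component "
            "(HaplotypeNetwork.components())"
        )
    observed = net.observed()
    total = net.total_length()
    longest = 0
    if len(observed) >= 2:
        lengths = dict(nx.all_pairs_dijkstra_path_length(net.graph, weight="weight"))
        longest = max(
            int(lengths[a][b]) for a, b in itertools.combinations(observed, 2)
        )
    n_ghost = net.n_ghost
    index: Optional[float] = None
    if len(observed) >= 2 and total > 0:
        index = 1.0 - longest / total
    return NetworkStats(
        longest_distance=longest,
        total_length=total,
        n_observed=len(observed),
        n_ghost=n_ghost,
        ghost_percent=round_half_up(100.0 * n_ghost / len(observed), 1),
        I=index,
    )


def ramification_index(net: HaplotypeNetwork) -> Optional[float]:
    return network_stats(net).I


def ghost_percent(net: HaplotypeNetwork) -> float:
    """100 * ghosts / observed haplotypes, one decimal."""
    n_obs = net.n_observed
    if n_obs == 0:
        raise ValueError("network has no observed haplotypes")
    return round_half_up(100.0 * net.n_ghost / n_obs, 1)


@dataclass(frozen=True)
class DiagnosticHaplotype:
    species: str
    haplotype_id: str
    locus: str
    gap: bool


@dataclass
class DiagnosticReport:
    entries: list[DiagnosticHaplotype]
    n_diagnostic_species: int
    n_sampled_taxa: int
    percent_diagnostic: int

    @property
    def diagnostic_species(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.species, None)
        return list(seen)

    @property
    def gap_species(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            if e.gap:
                seen.setdefault(e.species, None)
        return list(seen)


def interspecific_gap(
    hap_id: str, catalog: HaplotypeCatalog, indel_mode: IndelMode = "exclude"
) -> bool:
    """True iff this haplotype is >= 2 substitutions from every haplotype
    carried by any other species (the barcoding gap)."""
    own_species = catalog.species_of(hap_id)
    seq = catalog.haplotypes[hap_id]
    for other_id, other_seq in catalog.haplotypes.items():
        if other_id == hap_id:
            continue
        if catalog.species_of(other_id) - own_species:
            if mutational_steps(seq, other_seq, indel_mode=indel_mode) < 2:
                return False
    return True


def diagnostic_haplotypes(
    catalog: HaplotypeCatalog,
    specimens: SpecimenTable | None = None,
    n_sampled_taxa: int | None = None,
    indel_mode: IndelMode = "exclude",
) -> DiagnosticReport:
    """Find species-diagnostic haplotypes.

    A haplotype is diagnostic for a species iff (a) no other species
    carries it and (b) every sampled individual of that species carries at
    least one copy of it (heterozygotes count for diploid loci).  Species
    membership comes from the carrier metadata; ``specimens`` is used only
    for validation when given.  ``percent_diagnostic`` is over
    ``n_sampled_taxa`` (default: number of species sampled at this locus),
    rounded to the nearest integer.
    """
    individuals_by_species: dict[str, set[str]] = {}
    for hap_id, carriers in catalog.carriers.items():
        for c in carriers:
            if not c.species:
                raise ValueError(f"gene copy of specimen {c.specimen!r} lacks a species")
            if specimens is not None and c.specimen not in specimens:
                raise ValueError(
                    f"specimen {c.specimen!r} missing from the specimen table"
                )
            individuals_by_species.setdefault(c.species, set()).add(c.specimen)

    entries: list[DiagnosticHaplotype] = []
    for hap_id in catalog.haplotypes:
        species = catalog.species_of(hap_id)
        if len(species) != 1:
            continue
        (sp,) = species
        carriers = {c.specimen for c in catalog.carriers[hap_id]}
        if carriers == individuals_by_species[sp]:
            entries.append(
                DiagnosticHaplotype(
                    species=sp,
                    haplotype_id=hap_id,
                    locus=catalog.locus_name,
                    gap=interspecific_gap(hap_id, catalog, indel_mode=indel_mode),
                )
            )
    diagnostic_species = {e.species for e in entries}
    if n_sampled_taxa is None:
        n_sampled_taxa = len(individuals_by_species)
    if n_sampled_taxa <= 0:
        raise ValueError("n_sampled_taxa must be positive")
    return DiagnosticReport(
        entries=entries,
        n_diagnostic_species=len(diagnostic_species),
        n_sampled_taxa=n_sampled_taxa,
        percent_diagnostic=int(round_half_up(100.0 * len(diagnostic_species) / n_sampled_taxa)),
    )


def four_gamete_screen(catalog: HaplotypeCatalog) -> list[tuple[int, int]]:
    """Hudson-Kaplan four-gamete test over the haplotype sequences.

    Returns all site pairs (i < j, 0-based columns) at which all four
    two-site gamete combinations of the segregating alleles occur — a
    signal of recombination (or recurrent mutation).  Only biallelic
    unambiguous columns are considered, matching the infinite-sites
    regime in which the test is exact.
    """
    seqs = list(catalog.haplotypes.values())
    if not seqs:
        return []
    length = len(seqs[0])
    biallelic: list[int] = []
    for i in range(length):
        states = {s[i] for s in seqs if s[i] in NUCLEOTIDES}
        if len(states) == 2:
            biallelic.append(i)
    violations: list[tuple[int, int]] = []
    for i, j in itertools.combinations(biallelic, 2):
        gametes = {
            (s[i], s[j])
            for s in seqs
            if s[i] in NUCLEOTIDES and s[j] in NUCLEOTIDES
        }
        if len(gametes) == 4:
            violations.append((i, j))
    return violations


@dataclass
class GeneReport:
    """One marker-table row: variability, network shape, diagnosability."""

    locus: str
    mode: str  # "plastid" | "nuclear"
    length: int
    n_variable_sites: int
    n_indel_events: int
    percent_variable: float
    n_haplotypes: int
    n_ghosts: int
    ghost_percent: float
    longest_distance: int
    total_length: int
    ramification_index: Optional[float]
    heterozygosity_percent: float
    n_unresolved: int
    n_diagnostic_species: int
    n_sampled_taxa: int
    percent_diagnostic: int
    diagnostic_species: list[str]
    gap_species: list[str]
    n_four_gamete_violations: int
    n_components: int

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["diagnostic_species"] = ";".join(self.diagnostic_species)
        d["gap_species"] = ";".join(self.gap_species)
        return d


def gene_report(
    aln: Alignment,
    phased: PhasedSet | None,
    catalog: HaplotypeCatalog,
    net: HaplotypeNetwork,
    specimens: SpecimenTable,
    mode: str,
    n_sampled_taxa: int | None = None,
    indel_mode: IndelMode = "exclude",
) -> GeneReport:
    """Assemble the per-locus report row from the pipeline stages.

    ``aln`` holds the input rows (IUPAC genotypes for a nuclear locus,
    haploid sequences for a plastid one); site variability is computed on
    haplotype rows (phased copies for nuclear loci).  All inputs must
    refer to the same locus.
    """
    for other, label in ((catalog.locus_name, "catalog"), (net.locus_name, "network")):
        if other and other != aln.locus_name:
            raise ValueError(
                f"cross-locus mixing: alignment {aln.locus_name!r} vs "
                f"{label} {other!r}"
            )
    if mode == "nuclear":
        if phased is None:
            raise ValueError("nuclear locus requires a PhasedSet")
        hap_rows = phased_alignment(phased, aln.locus_name)
        genotypes = [Genotype(name, seq) for name, seq in aln.rows.items()]
        het = heterozygosity_percent(genotypes)
        n_unresolved = len(phased.unresolved)
    elif mode == "plastid":
        hap_rows = aln
        het = 0.0
        n_unresolved = 0
    else:
        raise ValueError(f"unknown locus mode {mode!r}")

    sites = site_summary(hap_rows)
    components = net.components()
    if len(components) == 1:
        stats = network_stats(net)
    else:
        # Parsimony limit split the network: report totals over components
        # and leave the ramification index undefined.
        stats = NetworkStats(
            longest_distance=max(network_stats(c).longest_distance for c in components),
            total_length=net.total_length(),
            n_observed=net.n_observed,
            n_ghost=net.n_ghost,
            ghost_percent=round_half_up(100.0 * net.n_ghost / net.n_observed, 1),
            I=None,
        )
    diag = diagnostic_haplotypes(
        catalog, specimens, n_sampled_taxa=n_sampled_taxa, indel_mode=indel_mode
    )
    return GeneReport(
        locus=aln.locus_name,
        mode=mode,
        length=sites.length,
        n_variable_sites=sites.n_variable_substitution_sites,
        n_indel_events=sites.n_indel_events,
        percent_variable=sites.percent_variable,
        n_haplotypes=catalog.n_haplotypes,
        n_ghosts=stats.n_ghost,
        ghost_percent=stats.ghost_percent,
        longest_distance=stats.longest_distance,
        total_length=stats.total_length,
        ramification_index=stats.I,
        heterozygosity_percent=het,
        n_unresolved=n_unresolved,
        n_diagnostic_species=diag.n_diagnostic_species,
        n_sampled_taxa=diag.n_sampled_taxa,
        percent_diagnostic=diag.percent_diagnostic,
        diagnostic_species=diag.diagnostic_species,
        gap_species=diag.gap_species,
        n_four_gamete_violations=len(four_gamete_screen(catalog)),
        n_components=len(components),
    )


def report_to_json(report: GeneReport) -> str:
    return json.dumps(report.to_dict(), sort_keys=True)
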