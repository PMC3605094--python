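"""Synthetic island-radiation datasets with known truth.

Emulates the sampling design of a Hawaiian-style radiation surveyed with
plastid and low-copy nuclear barcodes: a chain of islands of staggered
ages colonized oldest-to-youngest (progression rule), island-restricted
species arising by within-island bifurcation, one sampled gene copy per
individual for plastid loci versus two for nuclear loci, and a larger
effective gene-copy number for nuclear loci (``coalescence_scale``, 2.0
by default for biparental diploid vs uniparental haploid inheritance).
Genealogies are drawn with msprime and mutations placed under the
infinite-sites model, so simulated haplotypes are homoplasy-free and
recombination-free — the regime assumed by parsimony networks and the
four-gamete screen downstream.

Every dataset carries a :class:`TruthTable` (true phased haplotypes and
the true species-diagnostic sets), giving downstream phasing, network
and diagnosability code a ground truth to be scored against.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import msprime
import numpy as np

from . import netstats
from .network import GeneCopy, collapse_haplotypes
from .phasing import collapse_pair
from .seqio import (
    Alignment,
    SpecimenRecord,
    SpecimenTable,
    write_alignment,
    write_specimen_table,
)

DEFAULT_ISLANDS = ("Kauai", "Oahu", "MauiNui", "Hawaii")
DEFAULT_AGES_MY = (4.7, 3.0, 2.2, 0.5)


@dataclass(frozen=True)
class LocusSpec:
    """One simulated marker.

    ``theta`` is the population-scaled mutation rate of the whole locus
    on the plastid (base) effective-size scale: the expected pairwise
    diversity of a panmictic plastid population equals ``theta``; nuclear
    loci inherit the same per-generation rate but coalesce in a
    population ``coalescence_scale`` times larger.
    """

    name: str
    length: int
    mode: str  # "plastid" | "nuclear"
    theta: float

    @property
    def copies_per_individual(self) -> int:
        return 2 if self.mode == "nuclear" else 1


#: Default marker panel: two plastid barcodes and two short nuclear exons
#: with lengths typical of direct-sequenced barcoding loci, and thetas
#: giving a handful of variable sites per plastid locus versus several
#: fold more in the nuclear loci.
DEFAULT_LOCI = (
    LocusSpec("ptA", 533, "plastid", 0.5),
    LocusSpec("ptB", 439, "plastid", 0.5),
    LocusSpec("nucA", 556, "nuclear", 0.5),
    LocusSpec("nucB", 314, "nuclear", 0.5),
)


@dataclass(frozen=True)
class SimulationConfig:
    island_names: tuple[str, ...] = DEFAULT_ISLANDS
    island_ages_my: tuple[float, ...] = DEFAULT_AGES_MY
    #: species per island, oldest first; radiations of this kind are
    #: richest on the young islands (a single old-island endemic versus
    #: many recent segregates), which is what concentrates diagnosable
    #: species on the old, species-poor islands.
    n_species_per_island: int | tuple[int, ...] = (1, 3, 5, 7)
    n_individuals_per_species: int = 3
    locus_specs: tuple[LocusSpec, ...] = DEFAULT_LOCI
    #: nuclear / plastid effective gene-copy ratio.  Two gene copies per
    #: individual versus one, with uniparental plastid transmission,
    #: put organellar fixation roughly three times faster than nuclear.
    coalescence_scale: float = 3.0
    pop_size: float = 10_000.0  # plastid-scale effective gene-copy number
    generations_per_my: float = 10_000.0
    colonization_founders: float = 100.0  # propagule size at island colonization
    colonization_duration_gen: float = 50.0  # establishment phase at small size
    speciation_founders: float = 15.0  # isolate size at peripatric speciation
    speciation_duration_gen: float = 60.0  # isolation phase at small size
    peripatric_speciation: bool = True  # one daughter of each split is a founder isolate
    #: symmetric pollen-mediated migration among extant species (per
    #: lineage per generation); biparentally inherited nuclear loci move
    #: with pollen and seed, the maternal plastid only with seed, so by
    #: default only nuclear loci migrate — the mechanism that spreads
    #: nuclear alleles across species and islands while plastid variation
    #: stays geographically sorted.
    nuclear_migration_rate: float = 3e-5
    plastid_migration_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.island_names) != len(self.island_ages_my):
            raise ValueError("island_names and island_ages_my lengths differ")
        ages = list(self.island_ages_my)
        if any(a <= b for a, b in zip(ages, ages[1:])):
            raise ValueError("island ages must be strictly decreasing along the chain")
        if self.coalescence_scale <= 0 or self.pop_size <= 0:
            raise ValueError("coalescence_scale and pop_size must be positive")
        for spec in self.locus_specs:
            if spec.theta <= 0:
                raise ValueError(f"theta must be positive (locus {spec.name})")
            if spec.mode not in ("plastid", "nuclear"):
                raise ValueError(f"unknown locus mode {spec.mode!r}")
        if min(self.species_counts) < 1 or self.n_individuals_per_species < 1:
            raise ValueError("need at least one species and one individual")
        if len(self.species_counts) != len(self.island_names):
            raise ValueError("n_species_per_island tuple must match island count")

    @property
    def species_counts(self) -> tuple[int, ...]:
        if isinstance(self.n_species_per_island, int):
            return tuple([self.n_species_per_island] * len(self.island_names))
        return tuple(self.n_species_per_island)


@dataclass
class _Node:
    """Node of the species/colonization tree; time in generations
    (0 for extant species)."""

    pop_name: str
    time: float
    children: list["_Node"] = field(default_factory=list)
    parent: Optional["_Node"] = None


@dataclass
class SpeciesInfo:
    name: str
    island: str
    island_age_my: float


@dataclass
class LocusData:
    spec: LocusSpec
    phased: Alignment  # true haplotype rows (one per gene copy)
    genotypes: Optional[Alignment]  # IUPAC-collapsed rows (nuclear only)
    copies: list[GeneCopy]
    n_sites: int
    tree_newick: str


@dataclass
class TruthTable:
    phased: dict[str, dict[str, tuple[str, ...]]]  # locus -> specimen -> copies
    diagnostic: dict[str, list[str]]  # locus -> species with diagnostic haplotype
    n_sites: dict[str, int]
    tree_newick: dict[str, str]


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    species: list[SpeciesInfo]
    specimen_table: SpecimenTable
    loci: dict[str, LocusData]
    truth: TruthTable


def make_unphased(hap_a: str, hap_b: str) -> str:
    """Collapse a phased pair into the IUPAC consensus genotype (inverse
    of phasing)."""
    return collapse_pair(hap_a, hap_b)


def _yule_island(
    k: int, t_max: float, rng: np.random.Generator, island: str
) -> tuple[_Node, list[_Node]]:
    """Random within-island species tree with k tips.

    Topology follows a pure-birth (Yule) process: each split divides a
    uniformly chosen extant lineage.  The k-1 split times are uniform
    order statistics on (0, 0.9 * t_max) generations — the small-rate
    limit of a Yule process conditioned on k tips — keeping every split
    strictly younger than the island's colonization.
    """
    root = _Node(pop_name="", time=0.0)
    if k == 1:
        return root, [root]
    times = np.sort(rng.uniform(0.0, 0.9 * t_max, size=k - 1))[::-1]
    active = [root]
    n_anc = 0
    for t in times:
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        node.time = float(t)
        n_anc += 1
        if not node.pop_name:
            node.pop_name = f"{island}_anc{n_anc}"
        left = _Node(pop_name="", time=0.0, parent=node)
        right = _Node(pop_name="", time=0.0, parent=node)
        node.children = [left, right]
        active.extend([left, right])
    return root, active


def _build_species_tree(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[list[SpeciesInfo], list[_Node], list[tuple[float, str, str]]]:
    """Lay out the archipelago: per-island Yule trees plus colonization
    splits chaining each island's root to a lineage of the previous one.

    Returns (species list, all tree nodes, colonization events) where a
    colonization event is (time_gen, derived_root_pop, source_pop).
    """
    gpm = cfg.generations_per_my
    species: list[SpeciesInfo] = []
    all_nodes: list[_Node] = []
    colonizations: list[tuple[float, str, str]] = []
    prev_root: Optional[_Node] = None
    prev_first_leaf: Optional[_Node] = None
    for island, age, n_species in zip(
        cfg.island_names, cfg.island_ages_my, cfg.species_counts
    ):
        t_col = age * gpm
        root, leaves = _yule_island(n_species, t_col, rng, island)
        for j, leaf in enumerate(leaves, start=1):
            leaf.pop_name = f"{island}_sp{j}"
            species.append(SpeciesInfo(name=leaf.pop_name, island=island, island_age_my=age))

        def collect(node: _Node) -> None:
            all_nodes.append(node)
            for c in node.children:
                collect(c)

        collect(root)
        if prev_root is not None:
            source = _lineage_at(prev_first_leaf, t_col)
            colonizations.append((t_col, root.pop_name, source.pop_name))
        prev_root, prev_first_leaf = root, leaves[0]
    return species, all_nodes, colonizations


def _lineage_at(leaf: _Node, t: float) -> _Node:
    """The ancestor of ``leaf`` whose population is extant at backward
    time ``t`` (intervals: leaf [0, parent.time), internal
    [own split time, parent.time), island root unbounded above)."""
    node = leaf
    while node.parent is not None and node.parent.time <= t:
        node = node.parent
    return node


def _demography(
    cfg: SimulationConfig,
    nodes: Sequence[_Node],
    colonizations: Sequence[tuple[float, str, str]],
    copies_per_individual: float,
    migration_rate: float = 0.0,
) -> msprime.Demography:
    """Per-mode demography: population sizes are in gene copies, so a
    nuclear locus lives in a population ``coalescence_scale`` times the
    plastid one and each colonization propagule carries twice as many
    nuclear as plastid copies.  Every colonized island's root population
    starts as a founder propagule (``founder_individuals``) for
    ``founder_duration_gen`` generations — the drift pulse that sorts
    low-copy organellar variation island by island much faster than
    nuclear variation."""
    gene_copy_size = cfg.pop_size * copies_per_individual / 1.0
    dem = msprime.Demography()
    for node in nodes:
        # Extant species (tree leaves) must be explicitly active from the
        # present even when they also serve as the ancestral source of a
        # colonization split.
        dem.add_population(
            name=node.pop_name,
            initial_size=gene_copy_size,
            initially_active=True if not node.children else None,
        )
    for node in nodes:
        if node.children:
            dem.add_population_split(
                time=node.time,
                derived=[c.pop_name for c in node.children],
                ancestral=node.pop_name,
            )
    def founder_phase(
        pop_name: str, t_founding: float, founders: float, duration: float
    ) -> None:
        # Backward in time the newly founded population is at propagule
        # size during (t - duration, t), i.e. just after its founding.
        if duration > 0:
            dem.add_population_parameters_change(
                time=max(t_founding - duration, 0.0),
                population=pop_name,
                initial_size=founders * copies_per_individual,
            )

    if cfg.peripatric_speciation:
        # Within-island speciation is peripatric: the second daughter of
        # each split starts as a small, persistent founder isolate, so
        # standing variation is stochastically fixed at speciation — much
        # faster for the low-copy plastid pool than for the nuclear one.
        for node in nodes:
            if node.children:
                founder_phase(
                    node.children[1].pop_name,
                    node.time,
                    cfg.speciation_founders,
                    cfg.speciation_duration_gen,
                )
    for t, derived, source in colonizations:
        dem.add_population_split(time=t, derived=[derived], ancestral=source)
        founder_phase(derived, t, cfg.colonization_founders, cfg.colonization_duration_gen)
    if migration_rate > 0:
        leaves = [n for n in nodes if not n.children]
        if len(leaves) > 1:
            dem.set_symmetric_migration_rate(
                [n.pop_name for n in leaves], migration_rate
            )
            # Migration only applies while both species exist: shut each
            # pair off at the moment (pastward) the first of the two is
            # absorbed by its parent split.
            import itertools as _it

            for a, b in _it.combinations(leaves, 2):
                ends = [n.parent.time for n in (a, b) if n.parent is not None]
                if ends:
                    dem.add_symmetric_migration_rate_change(
                        time=min(ends), populations=[a.pop_name, b.pop_name], rate=0
                    )
    dem.sort_events()
    return dem


def _render_sequences(
    genotypes: np.ndarray, length: int, rng: np.random.Generator
) -> tuple[list[str], int]:
    """Place infinite-sites mutations (rows of a 0/1 sites-by-samples
    matrix) onto distinct integer columns of a random reference sequence
    and return one string per sample."""
    n_sites, n_samples = genotypes.shape
    if n_sites > length:
        raise ValueError(
            f"{n_sites} segregating sites exceed locus length {length}; "
            "lower theta or increase the locus length"
        )
    bases = np.array(list("ACGT"))
    reference = rng.choice(bases, size=length)
    columns = np.sort(rng.choice(length, size=n_sites, replace=False))
    derived = np.empty(n_sites, dtype="<U1")
    for s in range(n_sites):
        alternatives = [b for b in "ACGT" if b != reference[columns[s]]]
        derived[s] = alternatives[int(rng.integers(3))]
    sequences: list[str] = []
    for sample in range(n_samples):
        seq = reference.copy()
        carried = genotypes[:, sample] == 1
        seq[columns[carried]] = derived[carried]
        sequences.append("".join(seq))
    return sequences, n_sites


def simulate_radiation(cfg: SimulationConfig) -> SimulatedDataset:
    """Simulate all loci of an island-radiation dataset.

    For each locus a single-tree coalescent genealogy of all sampled gene
    copies is generated under the progression-rule species history, with
    the nuclear effective gene-copy number ``coalescence_scale`` times
    the plastid one; infinite-sites mutations are dropped onto the locus.
    Nuclear copies are paired within individuals and emitted both phased
    (truth) and as IUPAC-collapsed unphased genotypes.  Identical seed
    and config give byte-identical output.
    """
    root_ss = np.random.SeedSequence(cfg.seed)
    tree_ss, render_ss, msprime_ss = root_ss.spawn(3)
    tree_rng = np.random.default_rng(tree_ss)
    species, nodes, colonizations = _build_species_tree(cfg, tree_rng)

    specimen_records: dict[str, SpecimenRecord] = {}
    for sp in species:
        for k in range(1, cfg.n_individuals_per_species + 1):
            specimen_records[f"{sp.name}_{k:02d}"] = SpecimenRecord(
                species=sp.name, island=sp.island, population=f"{sp.name}_pop1"
            )
    specimen_table = SpecimenTable(records=specimen_records)

    seed_rng = np.random.default_rng(msprime_ss)
    render_rng = np.random.default_rng(render_ss)
    loci: dict[str, LocusData] = {}
    truth_phased: dict[str, dict[str, tuple[str, ...]]] = {}
    truth_diag: dict[str, list[str]] = {}
    truth_sites: dict[str, int] = {}
    truth_trees: dict[str, str] = {}

    # The plastid genome is a single non-recombining molecule: all plastid
    # loci share one genealogy per dataset, simulated jointly and then
    # sliced back into per-locus alignments.  Nuclear loci are unlinked and
    # each gets its own genealogy.
    plastid_specs = tuple(s for s in cfg.locus_specs if s.mode == "plastid")
    rendered: dict[str, tuple[list[str], int, str]] = {}
    if plastid_specs:
        dem = _demography(
            cfg, nodes, colonizations, 1.0, migration_rate=cfg.plastid_migration_rate
        )
        samples = [
            msprime.SampleSet(cfg.n_individuals_per_species, population=sp.name, ploidy=1)
            for sp in species
        ]
        total_length = sum(s.length for s in plastid_specs)
        anc_seed = int(seed_rng.integers(1, 2**31 - 1))
        mut_seed = int(seed_rng.integers(1, 2**31 - 1))
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=dem,
            ploidy=1,
            sequence_length=total_length,
            recombination_rate=0.0,
            random_seed=anc_seed,
        )
        boundaries = np.cumsum([0] + [s.length for s in plastid_specs])
        rate_map = msprime.RateMap(
            position=boundaries.astype(float),
            rate=[s.theta / (2.0 * cfg.pop_size * s.length) for s in plastid_specs],
        )
        mts = msprime.sim_mutations(
            ts,
            rate=rate_map,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
            random_seed=mut_seed,
        )
        genotypes = mts.genotype_matrix()
        positions = np.array([site.position for site in mts.sites()])
        newick = mts.first().as_newick()
        for i, spec in enumerate(plastid_specs):
            in_locus = (positions >= boundaries[i]) & (positions < boundaries[i + 1])
            seqs, n_sites = _render_sequences(
                genotypes[in_locus, :], spec.length, render_rng
            )
            rendered[spec.name] = (seqs, n_sites, newick)

    for spec in cfg.locus_specs:
        copies = spec.copies_per_individual
        if spec.mode == "plastid":
            sequences, n_sites, newick = rendered[spec.name]
        else:
            dem = _demography(
                cfg,
                nodes,
                colonizations,
                cfg.coalescence_scale,
                migration_rate=cfg.nuclear_migration_rate,
            )
            samples = [
                msprime.SampleSet(
                    cfg.n_individuals_per_species * copies, population=sp.name, ploidy=1
                )
                for sp in species
            ]
            anc_seed = int(seed_rng.integers(1, 2**31 - 1))
            mut_seed = int(seed_rng.integers(1, 2**31 - 1))
            ts = msprime.sim_ancestry(
                samples=samples,
                demography=dem,
                ploidy=1,
                sequence_length=spec.length,
                recombination_rate=0.0,
                random_seed=anc_seed,
            )
            mts = msprime.sim_mutations(
                ts,
                rate=spec.theta / (2.0 * cfg.pop_size * spec.length),
                model=msprime.BinaryMutationModel(),
                discrete_genome=False,
                random_seed=mut_seed,
            )
            sequences, n_sites = _render_sequences(
                mts.genotype_matrix(), spec.length, render_rng
            )
            newick = mts.first().as_newick()

        phased_rows: dict[str, str] = {}
        genotype_rows: dict[str, str] = {}
        gene_copies: list[GeneCopy] = []
        per_specimen: dict[str, tuple[str, ...]] = {}
        cursor = 0
        for sp in species:
            for k in range(1, cfg.n_individuals_per_species + 1):
                specimen = f"{sp.name}_{k:02d}"
                haps = tuple(sequences[cursor : cursor + copies])
                cursor += copies
                per_specimen[specimen] = haps
                for hap in haps:
                    gene_copies.append(
                        GeneCopy(
                            specimen=specimen,
                            species=sp.name,
                            island=sp.island,
                            sequence=hap,
                        )
                    )
                if copies == 2:
                    phased_rows[f"{specimen}_a"] = haps[0]
                    phased_rows[f"{specimen}_b"] = haps[1]
                    genotype_rows[specimen] = make_unphased(*haps)
                else:
                    phased_rows[specimen] = haps[0]

        phased_aln = Alignment(locus_name=spec.name, rows=phased_rows)
        genotype_aln = (
            Alignment(locus_name=spec.name, rows=genotype_rows)
            if spec.mode == "nuclear"
            else None
        )
        catalog = collapse_haplotypes(gene_copies, locus_name=spec.name)
        diag = netstats.diagnostic_haplotypes(catalog, specimen_table)
        loci[spec.name] = LocusData(
            spec=spec,
            phased=phased_aln,
            genotypes=genotype_aln,
            copies=gene_copies,
            n_sites=n_sites,
            tree_newick=newick,
        )
        truth_phased[spec.name] = per_specimen
        truth_diag[spec.name] = sorted(diag.diagnostic_species)
        truth_sites[spec.name] = n_sites
        truth_trees[spec.name] = newick

    return SimulatedDataset(
        config=cfg,
        species=species,
        specimen_table=specimen_table,
        loci=loci,
        truth=TruthTable(
            phased=truth_phased,
            diagnostic=truth_diag,
            n_sites=truth_sites,
            tree_newick=truth_trees,
        ),
    )


def within_species_diversity(ds: SimulatedDataset, locus: str) -> float:
    """Mean within-species pairwise diversity (mutational steps per
    locus), averaged over species, from the true haplotype copies."""
    from .diversity import mean_pairwise_diversity

    data = ds.loci[locus]
    by_species: dict[str, list[str]] = {}
    for copy in data.copies:
        by_species.setdefault(copy.species, []).append(copy.sequence)
    values = [mean_pairwise_diversity(seqs) for seqs in by_species.values()]
    return float(np.mean(values))


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> Path:
    """Write FASTA/TSV/JSON artifacts of a simulated dataset."""
    outdir = Path(outdir)
    loci_dir = outdir / "loci"
    loci_dir.mkdir(parents=True, exist_ok=True)
    write_specimen_table(ds.specimen_table, outdir / "specimens.tsv")
    manifest = {"seed": ds.config.seed, "loci": []}
    for name, data in ds.loci.items():
        phased_path = loci_dir / f"{name}.phased.fasta"
        write_alignment(data.phased, phased_path)
        entry = {
            "name": name,
            "mode": data.spec.mode,
            "phased_fasta": str(phased_path.relative_to(outdir)),
        }
        if data.genotypes is not None:
            gpath = loci_dir / f"{name}.genotypes.fasta"
            write_alignment(data.genotypes, gpath)
            entry["input_fasta"] = str(gpath.relative_to(outdir))
        else:
            entry["input_fasta"] = entry["phased_fasta"]
        manifest["loci"].append(entry)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(ds.config), fh, indent=2, sort_keys=True)
    truth = {
        "phased": {
            locus: {spec: list(haps) for spec, haps in per.items()}
            for locus, per in ds.truth.phased.items()
        },
        "diagnostic_species": ds.truth.diagnostic,
        "n_segregating_sites": ds.truth.n_sites,
        "tree_newick": ds.truth.tree_newick,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return outdir
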