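# Methods

`hapbarcode` compares the DNA-barcoding utility of plastid and low-copy
nuclear markers in young island radiations. This note documents the
statistical procedures, the simulator that generates ground-truth
datasets, the parameters that matter, and the limits of what the tests
demonstrate.

## Site summaries

A column of an aligned locus is a *variable substitution site* iff at
least two distinct unambiguous nucleotides (A/C/G/T) occur in it; gaps
(`-`), missing data (`N`) and unphased IUPAC codes never contribute.
Indels are counted by simple indel coding: one event per distinct maximal
gap run (identical start and end columns), shared runs counting once.
`percent_variable = 100 x substitution sites / aligned length`, with
indels excluded from the numerator. Percentages are rounded half-up
(56.25 → 56.3), matching how such tables are conventionally printed.
For loci whose raw sequences vary in length, the denominator is the
aligned matrix length; raw-sequence length ranges are not modelled.

## Clark parsimony phasing

Direct sequencing of a diploid locus yields one consensus per individual
with heterozygous positions as two-fold IUPAC codes. `clark_phase`
resolves these by the homozygote-subtraction procedure:

1. Homozygotes contribute their sequence twice to the known-haplotype
   pool; single-heterozygotes are forced into their two haplotypes.
2. Unresolved genotypes are scanned in input order for up to
   `max_passes` (default 10) passes. A known haplotype is a *template*
   for a genotype iff it matches at all unambiguous columns and carries
   one of the two encoded nucleotides at each heterozygous column; the
   complement (other encoded nucleotide at heterozygous columns) is then
   recorded and both haplotypes join the pool immediately.
3. Genotypes never matching a template are reported unresolved, the
   situation that in practice requires cloning.

The template search order (descending pool frequency, then
lexicographic) and the genotype scan order are the two places where the
procedure is genuinely underdetermined; both are configurable
(`tie_break`), the defaults favouring common haplotypes in the spirit of
parsimony, and an optional reversed-order rerun flags specimens whose
resolution is order-dependent. Phasing is *sound* by construction
(recombining any resolved pair reproduces the genotype) but not always
*correct*: a genotype whose heterozygous mutations can be bipartitioned
two ways over observed haplotypes may be resolved to the wrong pair, and
such mis-phased haplotypes can mimic recombination in downstream
four-gamete screens. On simulated data accuracy is therefore measured
against the truth table, not assumed: recovery is 100% when every true
haplotype occurs in a homozygote and no genotype admits an alternative
template-compatible resolution, and degrades with heterozygosity
otherwise. Gaps are treated as fixed characters shared by both
haplotypes; length-variant heterozygotes are out of scope.

## Haplotype networks

Identical sequences are collapsed into haplotypes labelled A, B, C, … by
descending copy count. Pairwise distances are mutational steps:
differing unambiguous columns, with columns gapped in either sequence
excluded by default (`indel_mode="exclude"`), or augmented by one step
per differing simple-coded indel event (`"fifth-state-event"`).

The retained graph is the *union of all minimum spanning trees* of the
pairwise-distance graph: an edge belongs to some MST iff its endpoints
are disconnected using strictly lighter edges, so alternative
equal-length connections survive as loops — the behaviour of classic
statistical-parsimony (TCS-style) networks for closely related
sequences. An `epsilon` parameter admits edges up to `epsilon` steps
above each pair's connection threshold; `epsilon=0` (default) is exactly
the union-of-MSTs graph, verified in the tests against exhaustive
spanning-tree enumeration for up to seven haplotypes. The classical 95%
connection probability is replaced by an explicit integer
`parsimony_limit` (default unlimited, since the empirical networks being
emulated are fully connected); a finite limit may split the graph into
components, which are then reported separately.

Every edge of weight m ≥ 2 is finally subdivided into m−1 *ghost* nodes
joined by unit edges: inferred intermediate haplotypes never recovered
in any accession. Ghost insertion preserves all observed-pair geodesics
and the total edge length. Ghost chains on alternative equal-weight
paths are deliberately not merged into shared median nodes; where an
empirical network's intermediate placement on loops is ambiguous, the
chain construction is the documented convention, so ghost counts on
loopy networks are a convention-dependent approximation.

## Network and diagnosability statistics

* **Ramification index** `I = 1 − longest_distance / total_length`,
  where `longest_distance` is the network diameter over observed nodes
  (maximum geodesic step count — not the longest simple path, which
  loops would inflate past the defining bound I ≤ 1) and `total_length`
  the sum of edge weights. `I = 0` for a simple path between observed
  endpoints, approaching 1 for star-like or reticulate networks;
  undefined for fewer than two observed haplotypes or zero length.
* **Ghost percentage** = 100 x ghosts / *observed* haplotypes. The
  observed-only denominator is the one consistent with the values such
  tables print (1 ghost among 9 observed → 11.1%; 9/16 → 56.3%).
* **Species-diagnostic haplotype**: carried by no other species *and*
  carried by every sampled individual of its species, where a diploid
  individual "carries" a haplotype if at least one of its two copies is
  that exact sequence (heterozygotes count). The diagnostic percentage
  is over the number of sampled taxa, rounded to the nearest integer.
  Both clauses are sample-relative: removing individuals can only
  preserve or enlarge a species' diagnostic set.
* **Interspecific (barcoding) gap**: a diagnostic haplotype at least two
  substitutions from every haplotype carried by any other species.
* **Four-gamete screen** (Hudson–Kaplan): all biallelic site pairs at
  which all four gamete combinations occur. Under infinite sites without
  recombination the result is empty, so any hit on phased empirical data
  flags recombination, recurrent mutation or mis-phasing.

## Accumulation curves and rarefaction

Accumulation curves are Monte Carlo: for each n, the mean and SD of the
distinct-haplotype count over `replicates` (default 1000) uniform draws
of n accessions without replacement, an accession contributing all its
gene copies. The final point equals observed richness exactly. A
copy-based sampling unit is also provided; in that mode the curve agrees
with exact hypergeometric rarefaction within Monte Carlo error (tested
at three standard errors), which is the cross-check between the two
estimators. Rarefied richness uses the classical closed form
`E[S_n] = Σ_h [1 − C(N−N_h, n) / C(N, n)]` evaluated with exact integer
combinatorics (no floating overflow). Island incidence tables count
carriers per island (islands ordered oldest first) and report each
island's rarefied richness at a common depth, by default the smallest
per-island copy count ≥ 2. The `terminal_slope` of a curve (mean gain
over its last k points, default plateau threshold 0.05 haplotypes per
accession) quantifies "plateau reached" versus "no inflexion".

## The island-radiation simulator

`simulate_radiation` emulates the sampling design of a Hawaiian-style
radiation surveyed with both genomes, with msprime generating a
single-tree coalescent genealogy per locus and infinite-sites mutations
placed on distinct columns of a random reference (at most two states per
column, no homoplasy, no recombination — the regime parsimony networks
assume).

**Geography and species.** Four islands with ages 4.7, 3.0, 2.2 and
0.5 My are colonized in order of formation (progression rule): each
island's founding population splits from the lineage occupying the
previous island at the island's age. Within an island, species arise by
a pure-birth (Yule) process — each split divides a uniformly chosen
extant lineage — with split times placed as uniform order statistics on
(0, 0.9 x colonization time), the small-rate limit of a Yule process
conditioned on the species count. Species counts default to (1, 3, 5, 7)
oldest→youngest: radiations of this kind are poorest on the old islands
(a single old-island endemic) and richest on the young ones, and this
asymmetry is what concentrates diagnosable species on old, species-poor
islands. Time is converted at 10,000 generations/My with a base
(plastid) effective gene-copy number of 10,000, so island ages span
roughly 0.5–4.7 plastid coalescent units — deep enough for plastid
sorting, shallow enough that nuclear sorting is incomplete.

**Genome asymmetries.** Three mechanisms, each configurable:

1. *Effective size*: population sizes are in gene copies; nuclear loci
   live in populations `coalescence_scale` (default 3.0) times the
   plastid ones — two biparentally inherited copies per individual
   versus one maternal copy, with uniparental transmission pushing the
   organellar effective number below its census copy number; fixation in
   nuclear genes is correspondingly about three times slower.
2. *Founder events*: colonization starts each island at propagule size
   (100 individuals for 50 generations), and speciation is peripatric —
   the second daughter of each split passes through a smaller, longer
   isolate phase (15 individuals, 60 generations). A founder of F
   individuals carries F plastid but 3F nuclear copies, so these drift
   pulses sort plastid variation (island chains, lost intermediates,
   hence ghost haplotypes) far faster than nuclear variation.
3. *Pollen flow*: symmetric migration among coexisting species (rate
   3x10⁻⁵ per lineage per generation, ≈ 4Nm of 3.6) applies to nuclear
   loci only — pollen moves nuclear genes between hybridizing species
   and across islands, while the maternal plastid moves only with seed
   (plastid migration defaults to 0). This is what keeps nuclear alleles
   shared across species and islands and suppresses nuclear
   diagnosability.

**Linkage.** All plastid loci of a dataset share one genealogy (the
plastid genome is a single non-recombining molecule), simulated jointly
with a per-locus mutation-rate map and sliced back into per-locus
alignments; nuclear loci are unlinked, each with its own genealogy.

**Mutation scale.** Each locus has a population-scaled `theta` defined
on the plastid base size (expected pairwise diversity of a panmictic
plastid population equals theta). The default panel — two plastid loci
(533 and 439 bp) and two nuclear loci (556 and 314 bp), all at
theta = 0.5 — was calibrated so the emitted datasets show a handful of
variable plastid sites, several-fold more variable nuclear sites, and
nuclear haplotype richness about twice plastid richness, the ranges
reported for real plastid barcodes versus short variable nuclear exons
in such radiations.

**Outputs and truth.** Each dataset comprises per-locus phased FASTA
(truth), IUPAC-collapsed unphased genotype FASTA for nuclear loci, a
specimen table (specimen, species, island, population; three individuals
per species by default), and a truth table with every true haplotype
pair, the per-locus true diagnostic species sets and tree summaries.
Identical seed and configuration give byte-identical output; all
randomness derives from the single config seed.

**Calibration check.** The effective-size machinery is validated in the
unstructured base case (one island, one species, where founder events
and migration cannot act): there the neutral expectation E[pi] ∝ theta x
gene-copy number is exact, and the measured nuclear/plastid ratio of
theta-scaled pairwise diversity matches `coalescence_scale` within
Monte Carlo error. The structured radiation is *not* a valid estimator
of this ratio — founder bottlenecks and finite species ages truncate
within-species coalescence — which is why the calibration uses the base
case.

**What the simulator does not capture.** No selection, no recombination,
no indel mutation, no hybrid speciation or chloroplast capture, no
intraspecific population structure, and species sampling is balanced
rather than opportunistic. Passing the simulation-recovery tests shows
the pipeline recovers the qualitative nuclear/plastid contrasts from
data generated under these mechanisms; it does not show the mechanisms
are the only ones operating in real radiations, nor calibrate absolute
diagnosability rates for field data.

## Replicate experiment

`replicate_contrasts` / `dataset_mode_summary` compute, per simulated
dataset and genome: mean per-locus haplotype richness and ramification
index, theta-scaled within-species pairwise diversity, and the
genome-level diagnosable-species fraction (a species counts if
diagnostic at any locus of that genome, the way marker panels are
reported). Over 100 seeded replicates of the default configuration,
nuclear richness exceeds plastid, plastid diagnosability exceeds
nuclear, and nuclear networks are more ramified, each in at least 80% of
replicates; the probability that a species is diagnosable rises with its
island age. These are the package's acceptance properties and are
recomputed from scratch by `scripts/acceptance.py`.

## Numerical conventions

Deterministic tie-breaks throughout: haplotype ids by (count, sequence);
candidate edges sorted by (weight, node a, node b); ghost chains named
by their parent edge; template order by (frequency, sequence). Seeds are
threaded from a single integer through `numpy.random.SeedSequence`, and
msprime seeds are drawn below 2³¹. Reported percentages round half-up;
the ramification index is kept at full precision internally. Degenerate
inputs (empty alignments, single-haplotype networks, zero-length loci,
out-of-range rarefaction depths) raise informative errors rather than
returning sentinel values, except that the ramification index of a
single-haplotype or zero-length network is reported as missing.
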