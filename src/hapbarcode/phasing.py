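"""Clark parsimony phasing of heterozygous nuclear genotypes.

Direct sequencing of a diploid nuclear locus yields a single consensus
sequence per individual in which heterozygous positions appear as IUPAC
two-fold ambiguity codes.  Clark's subtraction procedure resolves these
genotypes into haplotype pairs: haplotypes known with certainty (from
homozygotes and single-site heterozygotes) are used as templates to peel
one haplotype off each multi-site heterozygote, and every newly inferred
haplotype immediately joins the template pool.  Genotypes that never match
a template remain unresolved, mirroring field datasets in which "in a few
cases" phase cannot be determined without cloning.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .seqio import AMBIGUITY_CODES, Alignment, round_half_up

#: IUPAC two-fold ambiguity code -> unordered nucleotide pair.
AMBIGUITY_TO_PAIR: dict[str, frozenset[str]] = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}

#: Unordered nucleotide pair -> IUPAC code (inverse of the above).
PAIR_TO_AMBIGUITY: dict[frozenset[str], str] = {
    pair: code for code, pair in AMBIGUITY_TO_PAIR.items()
}

TieBreak = Literal["frequency", "lexicographic"]


def expand_ambiguity(code: str) -> frozenset[str]:
    """Return the unordered nucleotide pair encoded by a two-fold IUPAC code."""
    try:
        return AMBIGUITY_TO_PAIR[code]
    except KeyError:
        raise ValueError(
            f"{code!r} is not a two-fold IUPAC ambiguity code (R,Y,S,W,K,M)"
        ) from None


@dataclass
class Genotype:
    """One individual's consensus sequence, possibly with ambiguity codes."""

    specimen: str
    sequence: str
    het_sites: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.het_sites = tuple(
            i for i, ch in enumerate(self.sequence) if ch in AMBIGUITY_CODES
        )

    @property
    def n_het_sites(self) -> int:
        return len(self.het_sites)


@dataclass
class PhasedSet:
    """Result of phasing one locus."""

    resolved: dict[str, tuple[str, str]]
    unresolved: list[str]
    known_haplotypes: Counter
    resolution_log: list[tuple[str, str]]  # (specimen, template used)
    ambiguous: list[str] = field(default_factory=list)

    @property
    def haplotype_copies(self) -> list[tuple[str, str]]:
        """Flat list of (specimen, haplotype sequence), two per resolved
        specimen."""
        out = []
        for specimen, (a, b) in self.resolved.items():
            out.append((specimen, a))
            out.append((specimen, b))
        return out


def genotypes_from_alignment(aln: Alignment) -> list[Genotype]:
    return [Genotype(name, seq) for name, seq in aln.rows.items()]


def collapse_pair(hap_a: str, hap_b: str) -> str:
    """Collapse two haplotypes into the IUPAC consensus genotype sequence
    (inverse of phasing)."""
    if len(hap_a) != len(hap_b):
        raise ValueError("haplotypes differ in length")
    out = []
    for x, y in zip(hap_a, hap_b):
        if x == y:
            out.append(x)
        else:
            pair = frozenset((x, y))
            code = PAIR_TO_AMBIGUITY.get(pair)
            if code is None:
                raise ValueError(
                    f"cannot encode heterozygous pair {sorted(pair)} as a "
                    "two-fold IUPAC code"
                )
            out.append(code)
    return "".join(out)


def _forced_pair(g: Genotype) -> tuple[str, str]:
    """Resolve a genotype with exactly one heterozygous site."""
    (site,) = g.het_sites
    n1, n2 = sorted(expand_ambiguity(g.sequence[site]))
    seq = list(g.sequence)
    seq[site] = n1
    hap_a = "".join(seq)
    seq[site] = n2
    hap_b = "".join(seq)
    return tuple(sorted((hap_a, hap_b)))  # type: ignore[return-value]


def _complement_against(g: Genotype, template: str) -> str | None:
    """If ``template`` is compatible with genotype ``g``, return the
    complementary haplotype, else None.

    Compatibility: the template equals the genotype at every non-het
    column, and at every het column carries one of the two encoded
    nucleotides.  The complement takes the other encoded nucleotide at het
    columns and the genotype character elsewhere.
    """
    het = set(g.het_sites)
    comp = []
    for i, (gc, tc) in enumerate(zip(g.sequence, template)):
        if i in het:
            pair = AMBIGUITY_TO_PAIR[gc]
            if tc not in pair:
                return None
            (other,) = pair - {tc}
            comp.append(other)
        else:
            if tc != gc:
                return None
            comp.append(gc)
    return "".join(comp)


def _template_order(known: Counter, tie_break: TieBreak) -> list[str]:
    if tie_break == "frequency":
        return sorted(known, key=lambda h: (-known[h], h))
    if tie_break == "lexicographic":
        return sorted(known)
    raise ValueError(f"unknown tie_break policy {tie_break!r}")


def clark_phase(
    genotypes: Sequence[Genotype],
    max_passes: int = 10,
    tie_break: TieBreak = "frequency",
    check_order_dependence: bool = False,
) -> PhasedSet:
    """Phase genotypes by Clark's homozygote-comparison procedure.

    Stage 1 seeds the known-haplotype pool: homozygotes contribute their
    sequence twice; single-het genotypes are forced into their two
    haplotypes.  Stage 2 scans still-unresolved genotypes in input order
    for up to ``max_passes`` passes; templates are tried in descending
    frequency (then lexicographic) order by default.  Stage 3 lists
    genotypes that never matched a template as unresolved.

    With ``check_order_dependence`` the procedure is rerun on the reversed
    genotype order and specimens whose resolved pair differs are flagged
    in ``PhasedSet.ambiguous``.
    """
    if max_passes < 1:
        raise ValueError("max_passes must be >= 1")
    lengths = {len(g.sequence) for g in genotypes}
    if len(lengths) > 1:
        raise ValueError(f"genotype length mismatch: {sorted(lengths)}")
    result = _clark_phase_once(genotypes, max_passes, tie_break)
    if check_order_dependence:
        reversed_result = _clark_phase_once(
            list(reversed(genotypes)), max_passes, tie_break
        )
        for specimen, pair in result.resolved.items():
            other = reversed_result.resolved.get(specimen)
            if other is not None and frozenset(other) != frozenset(pair):
                result.ambiguous.append(specimen)
    return result


def _clark_phase_once(
    genotypes: Sequence[Genotype], max_passes: int, tie_break: TieBreak
) -> PhasedSet:
    resolved: dict[str, tuple[str, str]] = {}
    known: Counter = Counter()
    log: list[tuple[str, str]] = []
    pending: list[Genotype] = []

    for g in genotypes:
        if g.sequence and g.n_het_sites > len(g.sequence) / 2:
            warnings.warn(
                f"genotype {g.specimen!r} is heterozygous at more than half "
                "of its columns; possible paralog amplification or "
                "contamination",
                stacklevel=3,
            )
        if g.n_het_sites == 0:
            resolved[g.specimen] = (g.sequence, g.sequence)
            known[g.sequence] += 2
            log.append((g.specimen, "<homozygote>"))
        elif g.n_het_sites == 1:
            pair = _forced_pair(g)
            resolved[g.specimen] = pair
            known[pair[0]] += 1
            known[pair[1]] += 1
            log.append((g.specimen, "<single-het>"))
        else:
            pending.append(g)

    for _ in range(max_passes):
        progressed = False
        still_pending: list[Genotype] = []
        for g in pending:
            match = None
            for template in _template_order(known, tie_break):
                comp = _complement_against(g, template)
                if comp is not None:
                    match = (template, comp)
                    break
            if match is None:
                still_pending.append(g)
                continue
            template, comp = match
            resolved[g.specimen] = (template, comp)
            known[template] += 1
            known[comp] += 1
            log.append((g.specimen, template))
            progressed = True
        pending = still_pending
        if not pending or not progressed:
            break

    return PhasedSet(
        resolved=resolved,
        unresolved=[g.specimen for g in pending],
        known_haplotypes=known,
        resolution_log=log,
    )


def heterozygosity_percent(genotypes: Sequence[Genotype]) -> float:
    """Percentage of individuals with at least one heterozygous site,
    to one decimal."""
    if not genotypes:
        raise ValueError("empty genotype list")
    n_het = sum(1 for g in genotypes if g.n_het_sites > 0)
    return round_half_up(100.0 * n_het / len(genotypes), 1)


def phased_alignment(phased: PhasedSet, locus_name: str) -> Alignment:
    """Alignment of resolved haplotype copies, rows ``<specimen>_a/_b``."""
    rows: dict[str, str] = {}
    for specimen, (a, b) in phased.resolved.items():
        rows[f"{specimen}_a"] = a
        rows[f"{specimen}_b"] = b
    return Alignment(locus_name=locus_name, rows=rows)
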