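"""Alignment and specimen-table I/O, and per-locus site summaries.

Inputs are per-locus aligned FASTA files (one alignment per marker;
nuclear loci may carry IUPAC two-fold ambiguity codes for heterozygous
positions) and a tab-separated specimen table mapping each accession to
its species, island and population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as percentages are printed in
    marker tables (56.25 -> 56.3), unlike Python's banker's rounding."""
    import math

    scale = 10**ndigits
    return math.floor(abs(value) * scale + 0.5) / scale * (1 if value >= 0 else -1)


NUCLEOTIDES = frozenset("ACGT")
AMBIGUITY_CODES = frozenset("RYSWKM")
GAP = "-"
MISSING = "N"
ALPHABET = NUCLEOTIDES | AMBIGUITY_CODES | frozenset({GAP, MISSING})


class RaggedAlignmentError(ValueError):
    """Rows of an alignment do not all have the same length."""


class AlphabetError(ValueError):
    """A sequence contains a character outside the supported alphabet."""


class SchemaError(ValueError):
    """A specimen table is missing one of the required columns."""


class DuplicateSpecimenError(ValueError):
    """The same specimen id occurs more than once."""


@dataclass
class Alignment:
    """An aligned matrix of sequences keyed by specimen id.

    Rows are uppercase strings over ``{A,C,G,T,R,Y,S,W,K,M,-,N}`` and all
    have the same length.  Row order is preserved (insertion order of the
    mapping) and is the deterministic processing order downstream.
    """

    locus_name: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"alignment {self.locus_name!r} has no rows")
        normalized: dict[str, str] = {}
        length = None
        for name, seq in self.rows.items():
            seq = str(seq).upper()
            bad = set(seq) - ALPHABET
            if bad:
                raise AlphabetError(
                    f"record {name!r} in locus {self.locus_name!r} contains "
                    f"unsupported characters: {sorted(bad)}"
                )
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise RaggedAlignmentError(
                    f"ragged alignment in locus {self.locus_name!r}: record "
                    f"{name!r} has length {len(seq)}, expected {length}"
                )
            normalized[name] = seq
        self.rows = normalized

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def specimens(self) -> list[str]:
        return list(self.rows)

    def column(self, i: int) -> list[str]:
        return [seq[i] for seq in self.rows.values()]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class SpecimenRecord:
    species: str
    island: str
    population: str


@dataclass
class SpecimenTable:
    """specimen id -> (species, island, population), shared across loci."""

    records: dict[str, SpecimenRecord]

    def species_of(self, specimen: str) -> str:
        return self.records[specimen].species

    def island_of(self, specimen: str) -> str:
        return self.records[specimen].island

    @property
    def specimens(self) -> list[str]:
        return list(self.records)

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records.values():
            seen.setdefault(rec.species, None)
        return list(seen)

    def __contains__(self, specimen: str) -> bool:
        return specimen in self.records

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SiteSummary:
    """Per-locus variability summary (substitutions and indel events)."""

    locus_name: str
    length: int
    n_variable_substitution_sites: int
    n_indel_events: int
    percent_variable: float


def read_alignment(path: str | Path, locus_name: str | None = None) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Sequences are uppercased; the record description after the first
    whitespace is ignored; wrapped lines are allowed.  Records of unequal
    length raise :class:`RaggedAlignmentError` naming the offender.
    """
    path = Path(path)
    if locus_name is None:
        locus_name = path.stem
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise DuplicateSpecimenError(
                f"duplicate record id {rec.id!r} in {path}"
            )
        rows[rec.id] = str(rec.seq)
    if not rows:
        raise ValueError(f"no FASTA records found in {path}")
    return Alignment(locus_name=locus_name, rows=rows)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in aln.rows.items():
            fh.write(f">{name}\n{seq}\n")


REQUIRED_COLUMNS = ("specimen", "species", "island", "population")


def read_specimen_table(path: str | Path) -> SpecimenTable:
    """Read the specimen TSV (columns: specimen, species, island, population)."""
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise SchemaError(f"empty specimen table: {path}")
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise SchemaError(
                f"specimen table {path} lacks required column(s): {missing}"
            )
        idx = {c: header.index(c) for c in REQUIRED_COLUMNS}
        records: dict[str, SpecimenRecord] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                raise SchemaError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            specimen = fields[idx["specimen"]]
            if specimen in records:
                raise DuplicateSpecimenError(
                    f"{path}:{lineno}: duplicate specimen id {specimen!r}"
                )
            records[specimen] = SpecimenRecord(
                species=fields[idx["species"]],
                island=fields[idx["island"]],
                population=fields[idx["population"]],
            )
    return SpecimenTable(records=records)


def write_specimen_table(table: SpecimenTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(REQUIRED_COLUMNS) + "\n")
        for specimen, rec in table.records.items():
            fh.write(f"{specimen}\t{rec.species}\t{rec.island}\t{rec.population}\n")


def gap_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal runs of consecutive gap columns in one row, as (start, end)
    inclusive 0-based column intervals."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, ch in enumerate(seq):
        if ch == GAP:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(seq) - 1))
    return runs


def indel_events(rows: Iterable[str]) -> set[tuple[int, int]]:
    """Simple indel coding: one event per distinct maximal gap run (same
    start and end columns), no matter how many rows share it."""
    events: set[tuple[int, int]] = set()
    for seq in rows:
        events.update(gap_runs(seq))
    return events


def site_summary(aln: Alignment) -> SiteSummary:
    """Count variable substitution sites and indel events for one locus.

    A column is a variable substitution site iff at least two distinct
    unambiguous nucleotides (A/C/G/T) occur in it; gap-only variation and
    missing data never count.  Ambiguity codes are expected to have been
    phased away beforehand and are ignored here (treated as missing).
    percent_variable = 100 * variable sites / alignment length, indels
    excluded from the numerator, reported to 2 decimals.
    """
    if aln.length == 0:
        raise ValueError(f"zero-length alignment for locus {aln.locus_name!r}")
    n_var = 0
    for i in range(aln.length):
        states = {ch for ch in aln.column(i) if ch in NUCLEOTIDES}
        if len(states) >= 2:
            n_var += 1
    events = indel_events(aln.rows.values())
    return SiteSummary(
        locus_name=aln.locus_name,
        length=aln.length,
        n_variable_substitution_sites=n_var,
        n_indel_events=len(events),
        percent_variable=round_half_up(100.0 * n_var / aln.length, 2),
    )


def site_summary_to_json(summary: SiteSummary) -> str:
    return json.dumps(
        {
            "locus": summary.locus_name,
            "length": summary.length,
            "n_variable_substitution_sites": summary.n_variable_substitution_sites,
            "n_indel_events": summary.n_indel_events,
            "percent_variable": summary.percent_variable,
        }
    )
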