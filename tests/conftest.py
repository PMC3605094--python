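import numpy as np
import pytest

from hapbarcode.network import GeneCopy, collapse_haplotypes
from hapbarcode.seqio import SpecimenRecord, SpecimenTable


def write_fasta(path, rows):
    with open(path, "w") as fh:
        for name, seq in rows.items():
            fh.write(f">{name}\n{seq}\n")
    return path


def make_catalog(copies, locus_name="locus1"):
    """copies: iterable of (specimen, species, island, sequence)."""
    return collapse_haplotypes(
        [GeneCopy(*c) for c in copies], locus_name=locus_name
    )


def make_specimens(copies):
    records = {}
    for specimen, species, island, _ in copies:
        records.setdefault(specimen, SpecimenRecord(species, island, f"{species}_p1"))
    return SpecimenTable(records=records)


def path_sequences(n, length=40, step_positions=None):
    """Sequences forming a linear haplotype chain: sequence i differs from
    i-1 at one new site (or at the sites listed in step_positions[i-1])."""
    base = ["A"] * length
    seqs = ["".join(base)]
    cursor = 0
    for i in range(1, n):
        k = 1 if step_positions is None else step_positions[i - 1]
        seq = list(seqs[-1])
        for _ in range(k):
            seq[cursor] = "T"
            cursor += 1
        seqs.append("".join(seq))
    return seqs


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def random_catalog(rng, n_haplotypes, length=12):
    """Random distinct sequences as a single-species catalog (for network
    topology tests where carriers are irrelevant)."""
    seqs = set()
    while len(seqs) < n_haplotypes:
        seqs.add("".join(rng.choice(list("ACGT"), size=length)))
    copies = [(f"s{i}", "sp1", "isl1", seq) for i, seq in enumerate(sorted(seqs))]
    return make_catalog(copies)
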