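"""Haplotype accumulation curves, rarefaction and island incidence.

Accumulation curves describe how many distinct haplotypes are recovered
as accessions are added: a plateau indicates that sampling captured most
of the standing diversity, an uninflected slope that many haplotypes
remain unsampled.  Rarefied richness compares diversity across islands
with unequal sample sizes by computing the expected number of distinct
haplotypes in an equal-sized subsample (classical hypergeometric
rarefaction, computed exactly).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import HaplotypeCatalog, mutational_steps
from .seqio import SpecimenTable


@dataclass
class AccumulationCurve:
    locus: str
    points: list[tuple[int, float, float]]  # (n drawn, mean richness, sd)
    replicates: int
    seed: int
    method: str  # "montecarlo" | "hypergeometric"
    unit: str  # "accession" | "copy"

    @property
    def means(self) -> list[float]:
        return [m for _, m, _ in self.points]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["n", "mean_haplotypes", "sd"])


def accumulation_curve(
    assignments: Mapping[str, Sequence[str]],
    replicates: int = 1000,
    seed: int = 0,
    unit: str = "accession",
    locus: str = "",
) -> AccumulationCurve:
    """Monte-Carlo haplotype accumulation curve.

    ``assignments`` maps each accession to the multiset of haplotype ids
    it carries (two for a phased diploid, one for a plastid copy).  The
    sampling unit is the accession (each draw brings all its gene
    copies); ``unit="copy"`` instead samples individual gene copies,
    which makes the curve directly comparable to hypergeometric
    rarefaction.  For each n the mean and sd of distinct-haplotype counts
    over ``replicates`` uniform draws without replacement are returned;
    the final point (n = total units) is exact by construction.
    """
    if not assignments:
        raise ValueError("empty assignment map")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if unit == "accession":
        units: list[tuple[str, ...]] = [tuple(v) for v in assignments.values()]
    elif unit == "copy":
        units = [(h,) for v in assignments.values() for h in v]
    else:
        raise ValueError(f"unknown sampling unit {unit!r}")
    rng = np.random.default_rng(seed)
    n_units = len(units)
    total_richness = len({h for u in units for h in u})
    points: list[tuple[int, float, float]] = []
    for n in range(1, n_units + 1):
        if n == n_units:
            points.append((n, float(total_richness), 0.0))
            continue
        richness = np.empty(replicates)
        for r in range(replicates):
            draw = rng.choice(n_units, size=n, replace=False)
            richness[r] = len({h for i in draw for h in units[i]})
        points.append((n, float(richness.mean()), float(richness.std())))
    return AccumulationCurve(
        locus=locus,
        points=points,
        replicates=replicates,
        seed=seed,
        method="montecarlo",
        unit=unit,
    )


def rarefied_richness(counts: Sequence[int], n: int) -> float:
    """Expected number of distinct haplotypes in a subsample of n copies.

    E[S_n] = sum_h [1 - C(N - N_h, n) / C(N, n)] over haplotype copy
    counts N_h, evaluated with exact integer combinatorics.
    """
    counts = [c for c in counts if c > 0]
    total = sum(counts)
    if not counts:
        raise ValueError("no nonzero haplotype counts")
    if not 1 <= n <= total:
        raise ValueError(f"subsample size {n} out of range 1..{total}")
    denom = comb(total, n)
    expected = Fraction(0)
    for c in counts:
        expected += 1 - Fraction(comb(total - c, n), denom)
    return float(expected)


def hypergeometric_curve(
    counts: Sequence[int], locus: str = ""
) -> AccumulationCurve:
    """Exact copy-based rarefaction curve over all subsample sizes."""
    total = sum(c for c in counts if c > 0)
    points = [(n, rarefied_richness(counts, n), 0.0) for n in range(1, total + 1)]
    return AccumulationCurve(
        locus=locus, points=points, replicates=0, seed=0,
        method="hypergeometric", unit="copy",
    )


@dataclass
class IslandIncidence:
    """Haplotype-by-island carrier-count matrix with occupancy spans."""

    table: pd.DataFrame  # rows: haplotype ids, columns: islands (by age)
    span: dict[str, int]  # haplotype -> number of islands occupied
    rarefaction_depth: int | None
    rarefied_richness: dict[str, float]  # island -> E[S] at the common depth


def island_incidence(
    catalog: HaplotypeCatalog,
    specimens: SpecimenTable,
    island_order: Sequence[str],
    rarefaction_depth: int | None = None,
) -> IslandIncidence:
    """Tabulate haplotype incidence across islands (ordered oldest first)
    and rarefy each island's richness to a common depth.

    The default depth is the smallest per-island copy count that is at
    least 2; islands with fewer copies than the depth are left out of the
    rarefied comparison.
    """
    known = set(island_order)
    table = pd.DataFrame(
        0, index=list(catalog.haplotypes), columns=list(island_order), dtype=int
    )
    for hap_id, carriers in catalog.carriers.items():
        for c in carriers:
            island = c.island or specimens.island_of(c.specimen)
            if island not in known:
                raise ValueError(f"unknown island {island!r} for specimen {c.specimen!r}")
            table.loc[hap_id, island] += 1
    span = {hap_id: int((table.loc[hap_id] > 0).sum()) for hap_id in table.index}
    island_totals = table.sum(axis=0)
    eligible = island_totals[island_totals >= 2]
    depth = rarefaction_depth
    if depth is None and not eligible.empty:
        depth = int(eligible.min())
    rarefied: dict[str, float] = {}
    if depth is not None:
        for island in island_order:
            if island_totals[island] >= depth:
                rarefied[island] = rarefied_richness(
                    list(table[island]), depth
                )
    return IslandIncidence(
        table=table,
        span=span,
        rarefaction_depth=depth,
        rarefied_richness=rarefied,
    )


def terminal_slope(curve: AccumulationCurve, k: int = 5) -> float:
    """Mean slope of the curve over its last k points (haplotypes gained
    per additional sampling unit); ~0 indicates a plateau."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(curve.points):
        raise ValueError(f"curve has only {len(curve.points)} points, need {k}")
    means = curve.means
    return (means[-1] - means[-k]) / (k - 1)


def mean_pairwise_diversity(sequences: Sequence[str]) -> float:
    """Mean pairwise mutational steps among a set of aligned sequences."""
    if len(sequences) < 2:
        return 0.0
    pairs = list(itertools.combinations(sequences, 2))
    return sum(mutational_steps(a, b) for a, b in pairs) / len(pairs)
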