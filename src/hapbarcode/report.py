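"""End-to-end analysis: phase -> collapse -> network -> ghosts -> stats
-> diversity, with consolidated per-locus reporting, plus the replicate
experiment contrasting nuclear and plastid marker behaviour on simulated
radiations."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diversity import AccumulationCurve, IslandIncidence, accumulation_curve, island_incidence
from .netstats import DiagnosticReport, GeneReport, diagnostic_haplotypes, gene_report, network_stats
from .network import (
    GeneCopy,
    HaplotypeCatalog,
    HaplotypeNetwork,
    IndelMode,
    build_network,
    collapse_haplotypes,
    insert_ghosts,
    write_edgelist,
    write_graphml,
)
from .phasing import PhasedSet, clark_phase, genotypes_from_alignment
from .seqio import Alignment, SpecimenTable, read_alignment, read_specimen_table
from .synthetic import SimulatedDataset, SimulationConfig, simulate_radiation, within_species_diversity


@dataclass
class LocusInput:
    name: str
    mode: str  # "plastid" | "nuclear"
    alignment: Alignment  # IUPAC genotypes (nuclear) or haploid rows (plastid)


@dataclass
class LocusAnalysis:
    report: GeneReport
    catalog: HaplotypeCatalog
    network: HaplotypeNetwork  # ghost-inserted
    phased: Optional[PhasedSet]
    diagnostics: DiagnosticReport
    curve: AccumulationCurve
    incidence: Optional[IslandIncidence]


@dataclass
class AnalysisBundle:
    analyses: dict[str, LocusAnalysis]
    settings: dict

    def report_frame(self) -> pd.DataFrame:
        return pd.DataFrame([a.report.to_dict() for a in self.analyses.values()])


def copies_from_alignment(
    aln: Alignment, specimens: SpecimenTable, phased: Optional[PhasedSet]
) -> list[GeneCopy]:
    """Gene copies with carrier metadata: two per resolved specimen for a
    phased nuclear locus, one per row for a plastid locus."""
    copies: list[GeneCopy] = []
    if phased is not None:
        for specimen, pair in phased.resolved.items():
            rec = specimens.records[specimen]
            for hap in pair:
                copies.append(GeneCopy(specimen, rec.species, rec.island, hap))
    else:
        for specimen, seq in aln.rows.items():
            rec = specimens.records[specimen]
            copies.append(GeneCopy(specimen, rec.species, rec.island, seq))
    return copies


def analyze_locus(
    locus: LocusInput,
    specimens: SpecimenTable,
    parsimony_limit: int | None = None,
    indel_mode: IndelMode = "exclude",
    n_sampled_taxa: int | None = None,
    island_order: Sequence[str] | None = None,
    replicates: int = 1000,
    seed: int = 0,
    max_passes: int = 10,
) -> LocusAnalysis:
    """Run the full per-locus pipeline and assemble its report row."""
    phased = None
    if locus.mode == "nuclear":
        phased = clark_phase(genotypes_from_alignment(locus.alignment), max_passes=max_passes)
    copies = copies_from_alignment(locus.alignment, specimens, phased)
    catalog = collapse_haplotypes(copies, locus_name=locus.name)
    net = build_network(catalog, parsimony_limit=parsimony_limit, indel_mode=indel_mode)
    ghosted = insert_ghosts(net)
    row = gene_report(
        locus.alignment,
        phased,
        catalog,
        ghosted,
        specimens,
        mode=locus.mode,
        n_sampled_taxa=n_sampled_taxa,
        indel_mode=indel_mode,
    )
    diag = diagnostic_haplotypes(
        catalog, specimens, n_sampled_taxa=n_sampled_taxa, indel_mode=indel_mode
    )
    assignments: dict[str, list[str]] = {}
    for hap_id, carriers in catalog.carriers.items():
        for c in carriers:
            assignments.setdefault(c.specimen, []).append(hap_id)
    curve = accumulation_curve(
        assignments, replicates=replicates, seed=seed, locus=locus.name
    )
    incidence = None
    if island_order:
        incidence = island_incidence(catalog, specimens, island_order)
    return LocusAnalysis(
        report=row,
        catalog=catalog,
        network=ghosted,
        phased=phased,
        diagnostics=diag,
        curve=curve,
        incidence=incidence,
    )


def analyze_dataset(
    loci: Sequence[LocusInput],
    specimens: SpecimenTable,
    parsimony_limit: int | None = None,
    indel_mode: IndelMode = "exclude",
    n_sampled_taxa: int | None = None,
    island_order: Sequence[str] | None = None,
    replicates: int = 1000,
    seed: int = 0,
) -> AnalysisBundle:
    analyses: dict[str, LocusAnalysis] = {}
    for i, locus in enumerate(loci):
        try:
            analyses[locus.name] = analyze_locus(
                locus,
                specimens,
                parsimony_limit=parsimony_limit,
                indel_mode=indel_mode,
                n_sampled_taxa=n_sampled_taxa,
                island_order=island_order,
                replicates=replicates,
                seed=seed + i,
            )
        except Exception as exc:  # annotate failures with stage context
            raise RuntimeError(f"analysis failed for locus {locus.name!r}: {exc}") from exc
    settings = {
        "parsimony_limit": parsimony_limit,
        "indel_mode": indel_mode,
        "n_sampled_taxa": n_sampled_taxa,
        "island_order": list(island_order) if island_order else None,
        "replicates": replicates,
        "seed": seed,
        "ghost_percent_denominator": "observed_haplotypes",
        "accumulation_sampling_unit": "accession",
    }
    return AnalysisBundle(analyses=analyses, settings=settings)


def load_dataset_inputs(data_dir: str | Path) -> tuple[list[LocusInput], SpecimenTable]:
    """Load a simulated (or identically laid out) dataset directory:
    manifest.json naming per-locus FASTA inputs plus specimens.tsv."""
    data_dir = Path(data_dir)
    with open(data_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    specimens = read_specimen_table(data_dir / "specimens.tsv")
    loci = []
    for entry in manifest["loci"]:
        aln = read_alignment(data_dir / entry["input_fasta"], locus_name=entry["name"])
        loci.append(LocusInput(name=entry["name"], mode=entry["mode"], alignment=aln))
    return loci, specimens


def write_bundle(bundle: AnalysisBundle, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = bundle.report_frame()
    frame.to_csv(outdir / "gene_report.tsv", sep="\t", index=False)
    diag_rows = []
    for name, a in bundle.analyses.items():
        for e in a.diagnostics.entries:
            diag_rows.append(
                {"locus": name, "species": e.species, "haplotype": e.haplotype_id, "gap": e.gap}
            )
    pd.DataFrame(diag_rows, columns=["locus", "species", "haplotype", "gap"]).to_csv(
        outdir / "diagnostic_haplotypes.tsv", sep="\t", index=False
    )
    net_dir = outdir / "networks"
    net_dir.mkdir(exist_ok=True)
    for name, a in bundle.analyses.items():
        write_graphml(a.network, net_dir / f"{name}.graphml")
        write_edgelist(a.network, net_dir / f"{name}.edges.tsv")
        a.curve.to_frame().to_csv(outdir / f"{name}.accumulation.tsv", sep="\t", index=False)
        if a.incidence is not None:
            a.incidence.table.to_csv(outdir / f"{name}.island_incidence.tsv", sep="\t")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(
            {
                "settings": bundle.settings,
                "loci": {name: a.report.to_dict() for name, a in bundle.analyses.items()},
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return outdir


# ---------------------------------------------------------------------------
# Replicate experiment: the nuclear-versus-plastid contrast on simulation


def dataset_mode_summary(ds: SimulatedDataset) -> dict[str, dict[str, float]]:
    """Per-mode (plastid/nuclear) marker statistics of one simulated
    dataset, computed from the true haplotype copies: mean per-locus
    haplotype richness and ramification index, mean within-species
    diversity scaled by theta, and the genome-level diagnostic-species
    fraction (species diagnostic at any locus of that genome, as marker
    panels are reported in barcoding surveys)."""
    per_mode: dict[str, dict[str, list[float]]] = {
        "plastid": {"richness": [], "I": [], "pi_theta": []},
        "nuclear": {"richness": [], "I": [], "pi_theta": []},
    }
    diagnosed: dict[str, set[str]] = {"plastid": set(), "nuclear": set()}
    n_species = len(ds.species)
    for name, data in ds.loci.items():
        catalog = collapse_haplotypes(data.copies, locus_name=name)
        stats = network_stats(build_network(catalog))
        bucket = per_mode[data.spec.mode]
        bucket["richness"].append(catalog.n_haplotypes)
        diagnosed[data.spec.mode].update(ds.truth.diagnostic[name])
        if stats.I is not None:
            bucket["I"].append(stats.I)
        bucket["pi_theta"].append(within_species_diversity(ds, name) / data.spec.theta)
    out: dict[str, dict[str, float]] = {}
    for mode, bucket in per_mode.items():
        out[mode] = {
            key: float(np.mean(vals)) if vals else float("nan")
            for key, vals in bucket.items()
        }
        out[mode]["diag"] = len(diagnosed[mode]) / n_species
    return out


def island_diagnostic_rows(ds: SimulatedDataset) -> list[dict]:
    """One row per species: island, island age and whether the species
    has a diagnostic haplotype at any locus."""
    diagnosed = set()
    for species_list in ds.truth.diagnostic.values():
        diagnosed.update(species_list)
    return [
        {
            "species": sp.name,
            "island": sp.island,
            "island_age_my": sp.island_age_my,
            "diagnostic": sp.name in diagnosed,
        }
        for sp in ds.species
    ]


def replicate_contrasts(
    cfg: SimulationConfig | None = None,
    n_replicates: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run seeded replicate simulations and tabulate the per-replicate
    nuclear-versus-plastid contrasts plus the per-species island-age
    diagnosability table.

    Returns (contrasts, island_rows): ``contrasts`` has one row per
    replicate with per-mode richness, diagnostic fraction, ramification
    index and theta-scaled within-species diversity; ``island_rows`` has
    one row per species per replicate.
    """
    base = cfg or SimulationConfig()
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31 - 1)
    rows = []
    island_rows = []
    for r in range(n_replicates):
        ds = simulate_radiation(dataclasses.replace(base, seed=int(rep_seeds[r])))
        summary = dataset_mode_summary(ds)
        rows.append(
            {
                "replicate": r,
                "richness_nuclear": summary["nuclear"]["richness"],
                "richness_plastid": summary["plastid"]["richness"],
                "diag_nuclear": summary["nuclear"]["diag"],
                "diag_plastid": summary["plastid"]["diag"],
                "I_nuclear": summary["nuclear"]["I"],
                "I_plastid": summary["plastid"]["I"],
                "pi_theta_nuclear": summary["nuclear"]["pi_theta"],
                "pi_theta_plastid": summary["plastid"]["pi_theta"],
            }
        )
        for row in island_diagnostic_rows(ds):
            island_rows.append({"replicate": r, **row})
    return pd.DataFrame(rows), pd.DataFrame(island_rows)
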