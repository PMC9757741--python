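"""End-to-end orchestration over an on-disk world directory.

Glue between the analysis modules and the file layout produced by
``synthetic_data.generate_world`` (also usable with real data laid out the
same way). Each stage is importable on its own; this module only wires
them together.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import accessibility, conservation, enrichment, motifs, promoters, targets
from .core_genomics import (
    ChromSizes,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    read_bed,
    read_bed_names,
    read_coverage,
    read_fasta,
    read_gff3,
)


@dataclass
class SpeciesResult:
    species: str
    genome: Dict[str, str]
    chrom_sizes: ChromSizes
    genes: List[GeneModel]
    sites: List[GenomicInterval]
    site_names: List[str]
    accessibility_calls: List[accessibility.AccessibilityCall]
    promoter_calls: List[promoters.PromoterCall]  # co-option flags applied
    occurrences: Dict[str, List[motifs.MotifOccurrence]]
    pairs: List[motifs.MotifPair]

    @property
    def active_promoters(self) -> List[promoters.PromoterCall]:
        return [c for c in self.promoter_calls if c.is_promoter]

    def germline_promoter_sites(self) -> List[GenomicInterval]:
        seen = {}
        for c in self.active_promoters:
            if c.is_germline_specific:
                seen[(c.site.chrom, c.site.start, c.site.end)] = c.site
        return list(seen.values())


def read_manifest(world_dir: str | Path) -> dict:
    path = Path(world_dir) / "manifest.yaml"
    if not path.exists():
        return {}
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def run_species(
    world_dir: str | Path,
    species: str,
    scan_p_threshold: Optional[float] = None,
) -> SpeciesResult:
    """Accessibility -> promoter annotation -> motif scan -> pairing -> co-option."""
    world = Path(world_dir)
    sp = world / species
    genome = read_fasta(sp / "genome.fa")
    chrom_sizes = ChromSizes.from_sequences(genome)
    genes = read_gff3(sp / "genes.gff3")
    sites = read_bed(sp / "peaks.bed")
    site_names = read_bed_names(sp / "peaks.bed")

    matrix = accessibility.PeakCountMatrix.from_tsv(sp / "atac_counts.tsv")
    acc_calls = accessibility.classify_germline_specific(matrix)

    rna = read_coverage(
        chrom_sizes,
        plus_path=sp / "rna.plus.bedgraph",
        minus_path=sp / "rna.minus.bedgraph",
    )
    calls = promoters.annotate_promoters(sites, rna, genes, acc_calls)

    if scan_p_threshold is None:
        manifest = read_manifest(world)
        scan_p_threshold = (
            manifest.get("config", {}).get("scan_p_threshold", 0.0005)
        )
    pwms = {p.name: p for p in motifs.read_meme(world / "motifs.meme")}
    background = motifs.symmetrized_composition(genome.values())
    occs = {
        name: motifs.scan_genome(genome, pwm, scan_p_threshold, background=background)
        for name, pwm in pwms.items()
    }
    pairs = motifs.pair_and_classify(occs.get("m1", []), occs.get("m2", []))
    calls = motifs.flag_coopted(calls, pairs)
    return SpeciesResult(
        species=species,
        genome=genome,
        chrom_sizes=chrom_sizes,
        genes=genes,
        sites=sites,
        site_names=site_names,
        accessibility_calls=acc_calls,
        promoter_calls=calls,
        occurrences=occs,
        pairs=pairs,
    )


def run_enrichment(
    world_dir: str | Path,
    result: SpeciesResult,
    n: int = 1000,
    seed: int = 0,
) -> enrichment.PermutationResult:
    sp = Path(world_dir) / result.species
    repeats = read_bed(sp / "repeats.bed")
    gene_bodies = [g.body for g in result.genes]
    return enrichment.permutation_enrichment(
        repeats,
        result.germline_promoter_sites(),
        gene_bodies,
        result.chrom_sizes,
        n=n,
        seed=seed,
    )


def run_targets(
    world_dir: str | Path, result: SpeciesResult, mode: str = "down_only"
) -> List[targets.DirectTargetCall]:
    sp = Path(world_dir) / result.species
    de = targets.read_de_table(sp / "de.tsv")
    chip = read_bed(sp / "chip_peaks.bed")
    return targets.call_direct_targets(de, chip, result.promoter_calls, mode=mode)


def run_conservation(
    world_dir: str | Path, result_a: SpeciesResult, result_b: SpeciesResult
) -> List[conservation.ConservationCall]:
    pairs = conservation.read_ortholog_pairs(Path(world_dir) / "ortholog_pairs.tsv")
    singles_a = result_a.occurrences.get("m1", []) + result_a.occurrences.get("m2", [])
    singles_b = result_b.occurrences.get("m1", []) + result_b.occurrences.get("m2", [])
    return conservation.classify_conservation(
        pairs,
        result_a.promoter_calls,
        result_b.promoter_calls,
        result_a.pairs,
        result_b.pairs,
        singles_a,
        singles_b,
        result_a.genes,
        result_b.genes,
    )


def run_all(
    world_dir: str | Path,
    out_dir: str | Path,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Run both species, enrichment, targets and conservation; write TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res_a = run_species(world_dir, "spA")
    res_b = run_species(world_dir, "spB")
    for res in (res_a, res_b):
        promoters.promoter_calls_to_frame(res.promoter_calls).to_csv(
            out / f"promoters_{res.species}.tsv", sep="\t", index=False
        )
        accessibility.calls_to_frame(res.accessibility_calls).to_csv(
            out / f"accessibility_{res.species}.tsv", sep="\t", index=False
        )
        motifs.pairs_to_frame(res.pairs).to_csv(
            out / f"pairs_{res.species}.tsv", sep="\t", index=False
        )
    perm = run_enrichment(world_dir, res_a, n=n_permutations, seed=seed)
    pd.DataFrame(
        {
            "observed": [perm.observed],
            "null_mean": [perm.null_mean],
            "null_sd": [perm.null_sd],
            "fold": [perm.fold],
            "pvalue": [perm.pvalue],
            "n": [perm.n],
            "seed": [perm.seed],
        }
    ).to_csv(out / "enrichment_spA.tsv", sep="\t", index=False)
    target_calls = run_targets(world_dir, res_a)
    targets.target_calls_to_frame(target_calls).to_csv(
        out / "direct_targets_spA.tsv", sep="\t", index=False
    )
    targets.summarize_fractions(target_calls, res_a.promoter_calls).to_csv(
        out / "summary_spA.tsv", sep="\t", index=False
    )
    cons_calls = run_conservation(world_dir, res_a, res_b)
    conservation.calls_to_frame(cons_calls).to_csv(
        out / "conservation.tsv", sep="\t", index=False
    )
    return {
        "spA": res_a,
        "spB": res_b,
        "enrichment": perm,
        "targets": target_calls,
        "conservation": cons_calls,
    }
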