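"""Self-contained two-species benchmark with planted MITE-like elements.

``generate_world`` emits, for two synthetic species (spA, spB): a genome
FASTA, gene models (GFF3), accessible sites (BED), per-replicate ATAC
counts and coverage, stranded nuclear RNA coverage with outron signal, a DE
table and ChIP peaks (spA only), an ortholog table, and full ground truth
for every planted feature. All randomness flows from a single seed through
spawned child generators recorded in ``manifest.yaml``.

Planted motif pairs are the *only* motif instances in the emitted genomes:
after planting, the background is re-drawn wherever a spurious hit of the
m1/m2 matrices would otherwise occur at the configured scan threshold.
This makes downstream recovery exactly checkable against the truth table
(precision = recall = 1 when mutation and noise rates are zero).

Signal heights, element counts and class proportions are free parameters of
the benchmark, not literature-derived quantities.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .core_genomics import (
    ChromSizes,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    write_bed,
    write_coverage,
    write_fasta,
    write_gff3,
    write_table,
)
from .motifs import PWM, scan_genome, symmetrized_composition, write_meme

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class CapacityError(RuntimeError):
    """Raised when the requested features cannot be placed without overlap."""


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic world. Defaults define the benchmark used by
    the acceptance suite: a ~5 Mb two-chromosome genome with >= 200
    promoter-associated planted elements among >= 500 repeats."""

    chrom_sizes: Dict[str, int] = field(
        default_factory=lambda: {"chrI": 2_600_000, "chrII": 2_400_000}
    )
    n_genes: int = 320
    n_cerp2_promoters: int = 190
    n_cele2_promoters: int = 60
    germline_fraction: float = 0.8  # of co-opted promoters that are germline-specific
    n_noncoopted_germline: int = 20
    n_cerp2_background: int = 220
    n_cele2_background: int = 80
    n_bidirectional_pairs: int = 2
    n_nonpromoter_sites: int = 12
    cerp2_spacing: Tuple[int, int] = (12, 16)
    cele2_spacing: Tuple[int, int] = (23, 28)
    m1_consensus: str = "TGACCGTTAGCA"
    m2_consensus: str = "CATGGCTCAC"
    motif_major_prob: float = 0.94
    mutation_rate: float = 0.0
    base_composition: Tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    atac_high: int = 400
    atac_low: int = 2
    atac_noise: float = 0.0  # > 0 switches counts to Poisson draws
    rna_height: float = 6.0
    rna_noise: float = 0.0
    rna_gap_rate: float = 0.02
    rna_max_gap: int = 150  # < 200 so linking succeeds for true promoters
    n_replicates: int = 2
    scan_p_threshold: float = 0.0005
    n_direct_targets: int = 120
    n_down_indirect: int = 20
    n_up: int = 40
    n_chip_false: int = 20
    n_conserved: int = 95
    n_potentially_conserved: int = 48
    n_b_only_coopted: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.germline_fraction, self.mutation_rate, self.rna_gap_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        coopt = self.n_cerp2_promoters + self.n_cele2_promoters
        reserved = coopt + self.n_noncoopted_germline + 2 * self.n_bidirectional_pairs
        if reserved > self.n_genes:
            raise ValueError("gene roles exceed n_genes")
        if self.n_direct_targets > coopt:
            raise ValueError("n_direct_targets exceeds co-opted gene count")
        if self.n_conserved + self.n_potentially_conserved > self.n_cerp2_promoters:
            raise ValueError("conservation classes exceed CERP2 promoter count")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")

    @classmethod
    def tiny(cls, seed: int = 0) -> "SyntheticConfig":
        """A small world for fast tests (~0.8 Mb, 44 genes)."""
        return cls(
            chrom_sizes={"chrI": 450_000, "chrII": 350_000},
            n_genes=44,
            n_cerp2_promoters=14,
            n_cele2_promoters=6,
            germline_fraction=0.8,
            n_noncoopted_germline=4,
            n_cerp2_background=20,
            n_cele2_background=10,
            n_bidirectional_pairs=1,
            n_nonpromoter_sites=6,
            n_direct_targets=8,
            n_down_indirect=3,
            n_up=5,
            n_chip_false=5,
            n_conserved=4,
            n_potentially_conserved=3,
            n_b_only_coopted=2,
            seed=seed,
        )

    def pwms(self) -> Tuple[PWM, PWM]:
        return (
            PWM.from_consensus("m1", self.m1_consensus, self.motif_major_prob),
            PWM.from_consensus("m2", self.m2_consensus, self.motif_major_prob),
        )


@dataclass
class TruthTable:
    """Ground truth: planted elements, accessible sites, genes, orthologs."""

    elements: pd.DataFrame
    sites: pd.DataFrame
    genes: pd.DataFrame
    orthologs: pd.DataFrame

    @classmethod
    def read(cls, out_dir: str | Path) -> "TruthTable":
        d = Path(out_dir)

        def load(name):
            # keep empty strings as "" (not NaN) so written tables round-trip
            return pd.read_csv(d / name, sep="\t", keep_default_na=False, na_values=[])

        return cls(
            elements=load("truth.tsv"),
            sites=load("truth_sites.tsv"),
            genes=load("truth_genes.tsv"),
            orthologs=load("truth_orthologs.tsv"),
        )


# ---------------------------------------------------------------------------
# role assignment (shared gene scaffold for both species)
# ---------------------------------------------------------------------------


def _assign_roles(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    n_coopt = cfg.n_cerp2_promoters + cfg.n_cele2_promoters
    n_bid = 2 * cfg.n_bidirectional_pairs
    family = (
        ["CERP2_like"] * cfg.n_cerp2_promoters
        + ["CELE2_like"] * cfg.n_cele2_promoters
        + ["none"] * (n - n_coopt)
    )
    gs = np.zeros(n, dtype=bool)
    k = int(round(cfg.germline_fraction * n_coopt))
    if n_coopt:
        gs[rng.choice(n_coopt, size=k, replace=False)] = True
    gs[n_coopt : n_coopt + cfg.n_noncoopted_germline] = True
    partner = np.full(n, -1, dtype=np.int64)
    for i in range(cfg.n_bidirectional_pairs):
        a = n - n_bid + 2 * i
        partner[a], partner[a + 1] = a + 1, a

    de = np.array(["ns"] * n, dtype=object)
    if cfg.n_direct_targets:
        de[rng.choice(n_coopt, size=cfg.n_direct_targets, replace=False)] = "down"
    plain = [i for i in range(n_coopt, n - n_bid)]
    plain_pick = rng.permutation(plain)
    de[plain_pick[: cfg.n_down_indirect]] = "down"
    ns_pool = np.array([i for i in range(n - n_bid) if de[i] == "ns"])
    if cfg.n_up:
        de[rng.choice(ns_pool, size=cfg.n_up, replace=False)] = "up"
    chip = np.array([f != "none" for f in family])
    direct = (de == "down") & chip

    # conservation: classes only ever apply to CERP2-co-opted sides
    b_plant = np.array(["none"] * n, dtype=object)
    cons = np.array([""] * n, dtype=object)
    perm = rng.permutation(cfg.n_cerp2_promoters)
    for i in perm[: cfg.n_conserved]:
        b_plant[i], cons[i] = "coopted", "conserved"
    evid_cycle = ("single_m1", "single_m2", "pair_near_tss")
    for j, i in enumerate(perm[cfg.n_conserved : cfg.n_conserved + cfg.n_potentially_conserved]):
        b_plant[i] = evid_cycle[j % 3]
        cons[i] = "potentially_conserved"
    for i in perm[cfg.n_conserved + cfg.n_potentially_conserved :]:
        cons[i] = "species_specific"
    b_only_pool = np.array(
        [i for i in range(n_coopt, n - n_bid) if de[i] == "ns"], dtype=np.int64
    )
    if cfg.n_b_only_coopted:
        if len(b_only_pool) < cfg.n_b_only_coopted:
            raise ValueError("not enough plain genes for n_b_only_coopted")
        for i in rng.choice(b_only_pool, size=cfg.n_b_only_coopted, replace=False):
            b_plant[i], cons[i] = "coopted", "species_specific"

    return pd.DataFrame(
        {
            "idx": np.arange(n),
            "family": family,
            "is_germline_specific": gs,
            "partner": partner,
            "de_status": de,
            "chip": chip,
            "is_direct_target": direct,
            "b_plant": b_plant,
            "cons_class": cons,
        }
    )


# ---------------------------------------------------------------------------
# placement and planting
# ---------------------------------------------------------------------------


class _Occupancy:
    def __init__(self, chrom_sizes: ChromSizes):
        self.sizes = chrom_sizes
        self.masks = {c: np.zeros(l, dtype=bool) for c, l in chrom_sizes.items()}
        names = list(chrom_sizes)
        lengths = np.array([chrom_sizes[c] for c in names], dtype=np.float64)
        self._names = names
        self._weights = lengths / lengths.sum()

    def place(
        self, rng: np.random.Generator, width: int, margin: int = 2000, attempts: int = 4000
    ) -> Tuple[str, int]:
        for _ in range(attempts):
            chrom = self._names[int(rng.choice(len(self._names), p=self._weights))]
            length = self.sizes[chrom]
            if length - width - 2 * margin <= 0:
                continue
            start = int(rng.integers(margin, length - width - margin))
            if not self.masks[chrom][start : start + width].any():
                self.masks[chrom][start : start + width] = True
                return chrom, start
        raise CapacityError(
            f"could not place a feature of width {width} after {attempts} attempts; "
            "reduce feature counts or enlarge the genome"
        )


def _write_motif(
    codes: np.ndarray, start: int, seq: str, rng: np.random.Generator, mutation_rate: float
) -> None:
    enc = np.array([BASES.index(b) for b in seq], dtype=np.int8)
    if mutation_rate > 0:
        hit = rng.random(len(enc)) < mutation_rate
        shift = rng.integers(1, 4, size=len(enc))
        enc = np.where(hit, (enc + shift) % 4, enc).astype(np.int8)
    codes[start : start + len(enc)] = enc


def _plant_pair(
    codes: Dict[str, np.ndarray],
    chrom: str,
    left_start: int,
    family: str,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> Dict:
    """Write one m1m2 pair into the genome; return its truth record.

    CERP2-like pairs are divergent (left motif on '-', right on '+');
    CELE2-like pairs are tandem m2+m1+ on a random strand.
    """
    m1, m2 = cfg.m1_consensus, cfg.m2_consensus
    if family == "CERP2_like":
        spacing = int(rng.integers(cfg.cerp2_spacing[0], cfg.cerp2_spacing[1] + 1))
        arrangement = "divergent"
        if rng.random() < 0.5:
            left = ("m1", _revcomp(m1), "-", len(m1))
            right = ("m2", m2, "+", len(m2))
        else:
            left = ("m2", _revcomp(m2), "-", len(m2))
            right = ("m1", m1, "+", len(m1))
    elif family == "CELE2_like":
        spacing = int(rng.integers(cfg.cele2_spacing[0], cfg.cele2_spacing[1] + 1))
        arrangement = "tandem_m2_m1"
        if rng.random() < 0.5:
            left = ("m2", m2, "+", len(m2))
            right = ("m1", m1, "+", len(m1))
        else:  # on '-', m2 must be 3'-ward i.e. leftmost in 5'->3' along '-'
            left = ("m1", _revcomp(m1), "-", len(m1))
            right = ("m2", _revcomp(m2), "-", len(m2))
    else:  # pragma: no cover - guarded by callers
        raise ValueError(family)
    lname, lseq, lstrand, lwidth = left
    rname, rseq, rstrand, rwidth = right
    right_start = left_start + lwidth + spacing
    _write_motif(codes[chrom], left_start, lseq, rng, cfg.mutation_rate)
    _write_motif(codes[chrom], right_start, rseq, rng, cfg.mutation_rate)
    rec = {
        "chrom": chrom,
        "start": left_start - 10,
        "end": right_start + rwidth + 10,
        "family": family,
        "arrangement": arrangement,
        "spacing": spacing,
    }
    for name, start_, width_, strand_ in (
        (lname, left_start, lwidth, lstrand),
        (rname, right_start, rwidth, rstrand),
    ):
        rec[f"{name}_start"] = start_
        rec[f"{name}_end"] = start_ + width_
        rec[f"{name}_strand"] = strand_
    return rec


def _plant_single(
    codes: Dict[str, np.ndarray],
    chrom: str,
    start: int,
    which: str,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> Dict:
    seq = cfg.m1_consensus if which == "m1" else cfg.m2_consensus
    strand = "+" if rng.random() < 0.5 else "-"
    _write_motif(
        codes[chrom], start, seq if strand == "+" else _revcomp(seq), rng, cfg.mutation_rate
    )
    rec = {
        "chrom": chrom,
        "start": start,
        "end": start + len(seq),
        "family": f"single_{which}",
        "arrangement": "",
        "spacing": -1,
        f"{which}_start": start,
        f"{which}_end": start + len(seq),
        f"{which}_strand": strand,
    }
    return rec


def _scrub_background(
    codes: Dict[str, np.ndarray],
    protected: Dict[str, np.ndarray],
    planted: set,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    max_rounds: int = 40,
) -> None:
    """Redraw background bases until the only motif hits at the configured
    scan threshold are the exact planted windows.

    Hits partially overlapping a planted motif ("shadow" hits) have their
    non-protected bases redrawn; a spurious hit lying entirely inside
    protected bases cannot be fixed and indicates a self-similar consensus.
    """
    pwms = cfg.pwms()
    comp = np.array(cfg.base_composition)
    for _ in range(max_rounds):
        genome = {c: "".join(BASES[i] for i in codes[c]) for c in codes}
        bg = symmetrized_composition(genome.values())
        spurious: List[GenomicInterval] = []
        for pwm in pwms:
            for occ in scan_genome(genome, pwm, cfg.scan_p_threshold, background=bg):
                iv = occ.interval
                if (iv.chrom, iv.start, iv.end, occ.motif, iv.strand) in planted:
                    continue
                if protected[iv.chrom][iv.start : iv.end].all():
                    raise RuntimeError(
                        f"unfixable spurious {occ.motif} hit at {iv}: planted "
                        "motifs are mutually too similar; change the consensus"
                    )
                spurious.append(iv)
        if not spurious:
            return
        for iv in spurious:
            span = slice(iv.start, iv.end)
            keep = protected[iv.chrom][span]
            fresh = rng.choice(4, size=iv.length, p=comp).astype(np.int8)
            codes[iv.chrom][span] = np.where(keep, codes[iv.chrom][span], fresh)
    raise RuntimeError("background scrub did not converge; change motif consensus")


# ---------------------------------------------------------------------------
# RNA outron simulation
# ---------------------------------------------------------------------------


def simulate_rna_outron(
    gene: GeneModel,
    promoter: GenomicInterval,
    height: float,
    gap_rate: float,
    seed: int | np.random.Generator,
    max_gap: int = 150,
) -> Tuple[str, int, np.ndarray]:
    """Continuous strand-matched signal from the promoter midpoint through
    the first exon, with zero-coverage gaps each <= ``max_gap``.

    Returns ``(chrom, start, values)``; the segment lies on the gene strand.
    Gap runs never merge (each gap is followed by at least one covered
    base), so no zero run can exceed ``max_gap``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mid = promoter.midpoint
    fe = gene.first_exon
    if gene.strand == "+":
        if mid >= fe.end:
            raise ValueError("promoter downstream of first exon")
        start, end = mid, fe.end
    else:
        if mid < fe.start:
            raise ValueError("promoter downstream of first exon")
        start, end = fe.start, mid + 1
    values = np.full(end - start, float(height))
    if height > 0 and gap_rate > 0:
        i = 0
        n = len(values)
        while i < n:
            if rng.random() < gap_rate:
                glen = int(rng.integers(10, max_gap + 1))
                values[i : i + glen] = 0.0
                i += glen + 1
            else:
                i += 1
    return gene.chrom, start, values


# ---------------------------------------------------------------------------
# world generation
# ---------------------------------------------------------------------------


def _build_species(
    cfg: SyntheticConfig,
    species: str,
    roles: pd.DataFrame,
    seed_seq: np.random.SeedSequence,
) -> Dict:
    rng = np.random.default_rng(seed_seq)
    chrom_sizes = ChromSizes(cfg.chrom_sizes)
    comp = np.array(cfg.base_composition)
    codes = {
        c: rng.choice(4, size=l, p=comp).astype(np.int8) for c, l in chrom_sizes.items()
    }
    protected = {c: np.zeros(l, dtype=bool) for c, l in chrom_sizes.items()}
    occ = _Occupancy(chrom_sizes)
    is_a = species == "spA"

    genes: List[GeneModel] = []
    gene_rows: List[Dict] = []
    site_rows: List[Dict] = []
    element_rows: List[Dict] = []
    sites_by_id: Dict[str, GenomicInterval] = {}
    site_of_gene: Dict[str, str] = {}

    def gene_id(idx: int) -> str:
        return f"g{'A' if is_a else 'B'}{idx:04d}"

    def make_gene(idx: int, chrom: str, anchor: int, strand: str, glen: int) -> GeneModel:
        d = int(rng.integers(300, 701))
        elen = int(rng.integers(150, 301))
        if strand == "+":
            tss = anchor
            body = GenomicInterval(chrom, tss, tss + glen, strand)
            fe = GenomicInterval(chrom, tss + d, tss + d + elen, strand)
        else:
            tss = anchor
            body = GenomicInterval(chrom, tss - glen + 1, tss + 1, strand)
            fe = GenomicInterval(chrom, tss - d - elen + 1, tss - d + 1, strand)
        return GeneModel(gene_id(idx), chrom, strand, tss, fe, body)

    def plant_in_site(site: GenomicInterval, family: str) -> Dict:
        offset = int(rng.integers(12, 121))
        rec = _plant_pair(codes, site.chrom, site.start + offset, family, cfg, rng)
        for mname in ("m1", "m2"):
            protected[site.chrom][rec[f"{mname}_start"] : rec[f"{mname}_end"]] = True
        return rec

    # --- genes (bidirectional pairs placed jointly) ---
    skip: set = set()
    for idx in range(cfg.n_genes):
        if idx in skip:
            continue
        row = roles.iloc[idx]
        partner = int(row.partner)
        if partner >= 0:
            skip.add(partner)
            glen_l = int(rng.integers(2200, 3501))
            glen_r = int(rng.integers(2200, 3501))
            width = glen_l + glen_r + 3800
            chrom, rstart = occ.place(rng, width)
            mid = rstart + glen_l + 1900
            gene_l = make_gene(idx, chrom, mid - 60, "-", glen_l)
            gene_r = make_gene(partner, chrom, mid + 60, "+", glen_r)
            site = GenomicInterval(chrom, mid - 100, mid + 100)
            sid = f"site_{species}_{idx:04d}"
            for g, i in ((gene_l, idx), (gene_r, partner)):
                genes.append(g)
                site_of_gene[g.gene_id] = sid
                gene_rows.append(
                    {
                        "species": species,
                        "gene_id": g.gene_id,
                        "idx": i,
                        "site_id": sid,
                        "chrom": chrom,
                        "strand": g.strand,
                        "tss": g.tss,
                        "family": "none",
                        "is_germline_specific": False,
                        "lone_motif": "none",
                        "near_tss_pair": False,
                    }
                )
            sites_by_id[sid] = site
            site_rows.append(
                {
                    "species": species,
                    "site_id": sid,
                    "chrom": chrom,
                    "start": site.start,
                    "end": site.end,
                    "is_germline_specific": False,
                    "is_promoter": True,
                    "gene_ids": f"{gene_l.gene_id},{gene_r.gene_id}",
                }
            )
            continue

        glen = int(rng.integers(2200, 3501))
        width = glen + 1900
        chrom, rstart = occ.place(rng, width)
        strand = "+" if rng.random() < 0.5 else "-"
        anchor = rstart + 1700 if strand == "+" else rstart + width - 1701
        gene = make_gene(idx, chrom, anchor, strand, glen)
        genes.append(gene)
        tss = gene.tss
        site = (
            GenomicInterval(chrom, tss - 150, tss + 50)
            if strand == "+"
            else GenomicInterval(chrom, tss - 49, tss + 151)
        )
        sid = f"site_{species}_{idx:04d}"
        sites_by_id[sid] = site
        site_of_gene[gene.gene_id] = sid

        family = row.family if is_a else (
            "CERP2_like" if row.b_plant == "coopted" else "none"
        )
        gs = bool(row.is_germline_specific)
        lone = "none"
        near_tss = False
        if family in ("CERP2_like", "CELE2_like"):
            rec = plant_in_site(site, family)
            rec.update(
                {
                    "species": species,
                    "element_id": f"el_{species}_{len(element_rows):04d}",
                    "is_promoter": True,
                    "is_germline_specific": gs,
                    "gene_id": gene.gene_id,
                    "in_tss_window": False,
                }
            )
            element_rows.append(rec)
        elif not is_a and row.b_plant in ("single_m1", "single_m2"):
            lone = row.b_plant.split("_")[1]
            start = site.start + int(rng.integers(20, 100))
            rec = _plant_single(codes, chrom, start, lone, cfg, rng)
            protected[chrom][rec["start"] : rec["end"]] = True
            rec.update(
                {
                    "species": species,
                    "element_id": f"el_{species}_{len(element_rows):04d}",
                    "is_promoter": True,
                    "is_germline_specific": gs,
                    "gene_id": gene.gene_id,
                    "in_tss_window": False,
                }
            )
            element_rows.append(rec)
        elif not is_a and row.b_plant == "pair_near_tss":
            near_tss = True
            left_start = tss - 650 if strand == "+" else tss + 560
            rec = _plant_pair(codes, chrom, left_start, "CERP2_like", cfg, rng)
            for mname in ("m1", "m2"):
                protected[chrom][rec[f"{mname}_start"] : rec[f"{mname}_end"]] = True
            rec.update(
                {
                    "species": species,
                    "element_id": f"el_{species}_{len(element_rows):04d}",
                    "is_promoter": False,
                    "is_germline_specific": False,
                    "gene_id": gene.gene_id,
                    "in_tss_window": True,
                }
            )
            element_rows.append(rec)

        gene_rows.append(
            {
                "species": species,
                "gene_id": gene.gene_id,
                "idx": idx,
                "site_id": sid,
                "chrom": chrom,
                "strand": strand,
                "tss": tss,
                "family": family,
                "is_germline_specific": gs,
                "lone_motif": lone,
                "near_tss_pair": near_tss,
            }
        )
        site_rows.append(
            {
                "species": species,
                "site_id": sid,
                "chrom": chrom,
                "start": site.start,
                "end": site.end,
                "is_germline_specific": gs,
                "is_promoter": True,
                "gene_ids": gene.gene_id,
            }
        )

    # --- background (non-promoter) elements ---
    bg_plan = [("CERP2_like", cfg.n_cerp2_background), ("CELE2_like", cfg.n_cele2_background)]
    for family, count in bg_plan:
        for _ in range(count):
            fp = (
                len(cfg.m1_consensus)
                + len(cfg.m2_consensus)
                + (cfg.cerp2_spacing[1] if family == "CERP2_like" else cfg.cele2_spacing[1])
            )
            chrom, rstart = occ.place(rng, fp + 160, margin=2000)
            rec = _plant_pair(codes, chrom, rstart + 80, family, cfg, rng)
            for mname in ("m1", "m2"):
                protected[chrom][rec[f"{mname}_start"] : rec[f"{mname}_end"]] = True
            rec.update(
                {
                    "species": species,
                    "element_id": f"el_{species}_{len(element_rows):04d}",
                    "is_promoter": False,
                    "is_germline_specific": False,
                    "gene_id": "",
                    "in_tss_window": False,
                }
            )
            element_rows.append(rec)

    # --- accessible sites that are not promoters (no RNA, no gene link) ---
    for i in range(cfg.n_nonpromoter_sites):
        chrom, rstart = occ.place(rng, 5200, margin=2000)
        site = GenomicInterval(chrom, rstart + 2500, rstart + 2700)
        sid = f"xsite_{species}_{i:04d}"
        sites_by_id[sid] = site
        site_rows.append(
            {
                "species": species,
                "site_id": sid,
                "chrom": chrom,
                "start": site.start,
                "end": site.end,
                "is_germline_specific": i % 2 == 0,
                "is_promoter": False,
                "gene_ids": "",
            }
        )

    planted_keys = set()
    for rec in element_rows:
        for m in ("m1", "m2"):
            if f"{m}_start" in rec:
                planted_keys.add(
                    (rec["chrom"], rec[f"{m}_start"], rec[f"{m}_end"], m, rec[f"{m}_strand"])
                )
    _scrub_background(codes, protected, planted_keys, cfg, rng)
    genome = {c: "".join(BASES[i] for i in codes[c]) for c in codes}

    # --- ATAC counts and coverage ---
    site_ids = [r["site_id"] for r in site_rows]
    n_sites = len(site_ids)
    wt = np.zeros((n_sites, cfg.n_replicates), dtype=np.int64)
    gld = np.zeros((n_sites, cfg.n_replicates), dtype=np.int64)
    for i, r in enumerate(site_rows):
        hi, lo = cfg.atac_high, cfg.atac_low
        wt_base = hi
        gld_base = lo if r["is_germline_specific"] else hi
        if cfg.atac_noise > 0:
            wt[i] = rng.poisson(wt_base, size=cfg.n_replicates)
            gld[i] = rng.poisson(gld_base, size=cfg.n_replicates)
        else:
            wt[i] = wt_base
            gld[i] = gld_base
    atac_tracks: Dict[str, CoverageTrack] = {}
    for cond, counts in (("wt", wt), ("gld", gld)):
        for rep in range(cfg.n_replicates):
            track = CoverageTrack(chrom_sizes, stranded=False)
            for i, r in enumerate(site_rows):
                width = r["end"] - r["start"]
                track.get(r["chrom"])[r["start"] : r["end"]] = counts[i, rep] / width
            atac_tracks[f"atac_{cond}_rep{rep + 1}"] = track

    # --- RNA coverage with outron signal for every active promoter ---
    rna = CoverageTrack(chrom_sizes, stranded=True)
    for g in genes:
        site = sites_by_id[site_of_gene[g.gene_id]]
        chrom, start, values = simulate_rna_outron(
            g, site, cfg.rna_height, cfg.rna_gap_rate, rng, cfg.rna_max_gap
        )
        seg = rna.get(chrom, g.strand)[start : start + len(values)]
        np.maximum(seg, values, out=seg)
    if cfg.rna_noise > 0:
        for c in chrom_sizes:
            for s in "+-":
                rna.get(c, s)[:] += rng.poisson(cfg.rna_noise, size=chrom_sizes[c])

    out = {
        "species": species,
        "genome": genome,
        "chrom_sizes": chrom_sizes,
        "genes": genes,
        "gene_rows": gene_rows,
        "site_rows": site_rows,
        "element_rows": element_rows,
        "sites_by_id": sites_by_id,
        "atac_counts": (wt, gld),
        "atac_tracks": atac_tracks,
        "rna": rna,
    }

    # --- expression / binding layer (species A only) ---
    if is_a:
        de_rows = []
        for idx in range(cfg.n_genes):
            row = roles.iloc[idx]
            status = row.de_status
            if status == "down":
                lfc = -float(rng.uniform(1.0, 6.0))
                padj = float(10.0 ** -rng.uniform(4.0, 10.0))
            elif status == "up":
                lfc = float(rng.uniform(1.0, 6.0))
                padj = float(10.0 ** -rng.uniform(4.0, 10.0))
            else:
                lfc = float(rng.normal(0.0, 0.3))
                padj = float(rng.uniform(0.05, 1.0))
            de_rows.append({"gene_id": gene_id(idx), "lfc": lfc, "padj": padj})
        chip: List[GenomicInterval] = []
        for r in gene_rows:
            if r["family"] != "none":
                site = sites_by_id[r["site_id"]]
                chip.append(GenomicInterval(site.chrom, site.start - 25, site.end + 25))
        for _ in range(cfg.n_chip_false):
            chrom, rstart = occ.place(rng, 400, margin=2000)
            chip.append(GenomicInterval(chrom, rstart + 100, rstart + 300))
        chip.sort(key=lambda iv: (iv.chrom, iv.start))
        out["de_rows"] = de_rows
        out["chip_peaks"] = chip
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_species(build: Dict, cfg: SyntheticConfig, sp_dir: Path) -> List[Path]:
    sp_dir.mkdir(parents=True, exist_ok=True)
    files: List[Path] = []

    def reg(p: Path) -> Path:
        files.append(p)
        return p

    write_fasta(build["genome"], reg(sp_dir / "genome.fa"))
    write_gff3(build["genes"], reg(sp_dir / "genes.gff3"))
    site_rows = build["site_rows"]
    sites = [
        GenomicInterval(r["chrom"], r["start"], r["end"]) for r in site_rows
    ]
    write_bed(sites, reg(sp_dir / "peaks.bed"), names=[r["site_id"] for r in site_rows])
    elements = build["element_rows"]
    repeats = [
        GenomicInterval(r["chrom"], r["start"], r["end"])
        for r in elements
        if r["family"] in ("CERP2_like", "CELE2_like")
    ]
    repeat_names = [
        r["element_id"] for r in elements if r["family"] in ("CERP2_like", "CELE2_like")
    ]
    write_bed(repeats, reg(sp_dir / "repeats.bed"), names=repeat_names)
    for name, track in build["atac_tracks"].items():
        write_coverage(track, reg(sp_dir / f"{name}.bedgraph"))
    plus, minus = write_coverage(build["rna"], sp_dir / "rna")
    reg(plus)
    reg(minus)
    wt, gld = build["atac_counts"]
    counts = pd.DataFrame(
        {
            "site_id": [r["site_id"] for r in site_rows],
            "chrom": [r["chrom"] for r in site_rows],
            "start": [r["start"] for r in site_rows],
            "end": [r["end"] for r in site_rows],
        }
    )
    for i in range(cfg.n_replicates):
        counts[f"wt_{i + 1}"] = wt[:, i]
    for i in range(cfg.n_replicates):
        counts[f"gld_{i + 1}"] = gld[:, i]
    write_table(counts, reg(sp_dir / "atac_counts.tsv"))
    if "de_rows" in build:
        write_table(pd.DataFrame(build["de_rows"]), reg(sp_dir / "de.tsv"))
        write_bed(build["chip_peaks"], reg(sp_dir / "chip_peaks.bed"))
    return files


_ELEMENT_COLUMNS = [
    "species", "element_id", "chrom", "start", "end", "family", "arrangement",
    "spacing", "m1_start", "m1_end", "m1_strand", "m2_start", "m2_end",
    "m2_strand", "is_promoter", "is_germline_specific", "gene_id", "in_tss_window",
]


def generate_world(cfg: SyntheticConfig, out_dir: str | Path) -> TruthTable:
    """Generate the two-species benchmark under ``out_dir``.

    Identical config (including seed) produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(cfg.seed)
    ss_roles, ss_a, ss_b = root.spawn(3)
    roles = _assign_roles(cfg, np.random.default_rng(ss_roles))
    build_a = _build_species(cfg, "spA", roles, ss_a)
    build_b = _build_species(cfg, "spB", roles, ss_b)

    files = _write_species(build_a, cfg, out / "spA")
    files += _write_species(build_b, cfg, out / "spB")

    write_meme(list(cfg.pwms()), out / "motifs.meme")
    files.append(out / "motifs.meme")

    # ortholog table: positional pairing of the shared gene scaffold
    orth = pd.DataFrame(
        {
            "gene_a": [f"gA{i:04d}" for i in range(cfg.n_genes)],
            "gene_b": [f"gB{i:04d}" for i in range(cfg.n_genes)],
        }
    )
    write_table(orth, out / "ortholog_pairs.tsv")
    files.append(out / "ortholog_pairs.tsv")

    # truth tables
    elements = pd.DataFrame(
        build_a["element_rows"] + build_b["element_rows"]
    )
    for col in _ELEMENT_COLUMNS:
        if col not in elements.columns:
            elements[col] = -1
    elements = elements.fillna(-1)[_ELEMENT_COLUMNS]
    sites = pd.DataFrame(build_a["site_rows"] + build_b["site_rows"])
    gene_extra = roles[["idx", "de_status", "chip", "is_direct_target", "cons_class"]]
    genes = pd.DataFrame(build_a["gene_rows"] + build_b["gene_rows"]).merge(
        gene_extra, on="idx"
    )
    genes.loc[genes.species == "spB", ["de_status"]] = ""
    genes.loc[genes.species == "spB", ["chip", "is_direct_target"]] = False
    evid_a = []
    evid_b = []
    for r in roles.itertuples():
        evid_a.append("coopted" if r.family != "none" else "none")
        if r.b_plant == "coopted":
            evid_b.append("coopted")
        elif r.b_plant in ("single_m1", "single_m2"):
            evid_b.append("promoter_with_single_motif")
        elif r.b_plant == "pair_near_tss":
            evid_b.append("pair_near_tss")
        else:
            evid_b.append("none")
    orthtruth = pd.DataFrame(
        {
            "gene_a": orth.gene_a,
            "gene_b": orth.gene_b,
            "eligible": roles.cons_class != "",
            "class": roles.cons_class,
            "evidence_a": evid_a,
            "evidence_b": evid_b,
        }
    )
    truth = TruthTable(elements, sites, genes, orthtruth)
    write_table(truth.elements, out / "truth.tsv")
    write_table(truth.sites, out / "truth_sites.tsv")
    write_table(truth.genes, out / "truth_genes.tsv")
    write_table(truth.orthologs, out / "truth_orthologs.tsv")
    files += [
        out / "truth.tsv",
        out / "truth_sites.tsv",
        out / "truth_genes.tsv",
        out / "truth_orthologs.tsv",
    ]

    manifest = {
        "config": _config_dict(cfg),
        "seed": cfg.seed,
        "child_seeds": {
            "roles": list(ss_roles.spawn_key),
            "spA": list(ss_a.spawn_key),
            "spB": list(ss_b.spawn_key),
        },
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in sorted(files)},
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return truth


def _config_dict(cfg: SyntheticConfig) -> Dict:
    d = asdict(cfg)
    d["cerp2_spacing"] = list(cfg.cerp2_spacing)
    d["cele2_spacing"] = list(cfg.cele2_spacing)
    d["base_composition"] = list(cfg.base_composition)
    return d


def config_from_yaml(path: str | Path) -> SyntheticConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("cerp2_spacing", "cele2_spacing", "base_composition"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SyntheticConfig(**raw)
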