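"""Cross-species conservation classes for co-opted promoters.

A 1:1 ortholog pair is eligible when at least one side has a CERP2-like
co-opted promoter (divergent m1m2 pair, 12-16 bp spacing). Eligible pairs
get exactly one class, assigned by the first matching rule:

conserved              both orthologs have a co-opted promoter
potentially_conserved  the non-co-opted ortholog has a promoter containing
                       a lone m1 or m2, OR a divergent m1m2 pair lies in
                       [TSS-1000, TSS+200] (strand-oriented) outside any
                       annotated promoter
species_specific       otherwise
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set

import pandas as pd

from .core_genomics import GeneModel, GenomicInterval, IntervalIndex
from .motifs import MotifOccurrence, MotifPair
from .promoters import PromoterCall

CLASSES = ("conserved", "potentially_conserved", "species_specific")


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str


@dataclass(frozen=True)
class ConservationCall:
    pair: OrthologPair
    klass: str
    evidence_a: str
    evidence_b: str


class _SpeciesEvidence:
    """Per-gene co-option / motif evidence for one species."""

    def __init__(
        self,
        promoters: Sequence[PromoterCall],
        pairs: Sequence[MotifPair],
        singles: Sequence[MotifOccurrence],
        genes: Sequence[GeneModel],
        upstream: int,
        downstream: int,
    ):
        self.genes: Dict[str, GeneModel] = {g.gene_id: g for g in genes}
        pair_index = IntervalIndex(p.footprint for p in pairs)
        cerp2_index = IntervalIndex(
            p.footprint for p in pairs if p.family == "CERP2_like"
        )
        single_index = IntervalIndex(o.interval for o in singles)
        promoter_index = IntervalIndex(
            c.site for c in promoters if c.is_promoter
        )
        self.coopted: Set[str] = set()
        self.cerp2_coopted: Set[str] = set()
        self.single_motif_promoter: Set[str] = set()
        for c in promoters:
            if not c.is_promoter:
                continue
            if pair_index.overlaps_any(c.site):
                self.coopted.add(c.gene_id)
            if cerp2_index.overlaps_any(c.site):
                self.cerp2_coopted.add(c.gene_id)
            if single_index.overlaps_any(c.site):
                self.single_motif_promoter.add(c.gene_id)
        # divergent pairs in the oriented TSS window, outside any promoter
        self.pair_near_tss: Set[str] = set()
        free_divergent = [
            p.footprint
            for p in pairs
            if p.arrangement == "divergent" and not promoter_index.overlaps_any(p.footprint)
        ]
        free_index = sorted(free_divergent, key=lambda iv: (iv.chrom, iv.start))
        for g in genes:
            if g.strand == "+":
                lo, hi = g.tss - upstream, g.tss + downstream + 1
            else:
                lo, hi = g.tss - downstream, g.tss + upstream + 1
            for iv in free_index:
                if iv.chrom == g.chrom and iv.start >= lo and iv.end <= hi:
                    self.pair_near_tss.add(g.gene_id)
                    break

    def evidence(self, gene_id: str) -> str:
        if gene_id in self.coopted:
            return "coopted"
        if gene_id in self.single_motif_promoter:
            return "promoter_with_single_motif"
        if gene_id in self.pair_near_tss:
            return "pair_near_tss"
        return "none"


def classify_conservation(
    pairs: Sequence[OrthologPair],
    promoters_a: Sequence[PromoterCall],
    promoters_b: Sequence[PromoterCall],
    motif_pairs_a: Sequence[MotifPair],
    motif_pairs_b: Sequence[MotifPair],
    singles_a: Sequence[MotifOccurrence],
    singles_b: Sequence[MotifOccurrence],
    genes_a: Sequence[GeneModel],
    genes_b: Sequence[GeneModel],
    upstream: int = 1000,
    downstream: int = 200,
) -> List[ConservationCall]:
    """Classify every eligible ortholog pair (see module docstring).

    Ineligible pairs (no CERP2-like co-opted promoter on either side) are
    skipped. Unknown gene ids raise with the offending ids listed.
    """
    ev_a = _SpeciesEvidence(promoters_a, motif_pairs_a, singles_a, genes_a, upstream, downstream)
    ev_b = _SpeciesEvidence(promoters_b, motif_pairs_b, singles_b, genes_b, upstream, downstream)
    missing = [p.gene_a for p in pairs if p.gene_a not in ev_a.genes]
    missing += [p.gene_b for p in pairs if p.gene_b not in ev_b.genes]
    if missing:
        raise ValueError(f"gene ids absent from gene models: {sorted(set(missing))}")
    seen_a: Set[str] = set()
    seen_b: Set[str] = set()
    for p in pairs:
        if p.gene_a in seen_a or p.gene_b in seen_b:
            raise ValueError("ortholog mapping is not 1:1")
        seen_a.add(p.gene_a)
        seen_b.add(p.gene_b)
    calls: List[ConservationCall] = []
    for p in pairs:
        eligible = p.gene_a in ev_a.cerp2_coopted or p.gene_b in ev_b.cerp2_coopted
        if not eligible:
            continue
        a_co = p.gene_a in ev_a.coopted
        b_co = p.gene_b in ev_b.coopted
        if a_co and b_co:
            klass = "conserved"
        else:
            other_ev = ev_b.evidence(p.gene_b) if a_co else ev_a.evidence(p.gene_a)
            if other_ev in ("promoter_with_single_motif", "pair_near_tss"):
                klass = "potentially_conserved"
            else:
                klass = "species_specific"
        calls.append(
            ConservationCall(p, klass, ev_a.evidence(p.gene_a), ev_b.evidence(p.gene_b))
        )
    return calls


def calls_to_frame(calls: Sequence[ConservationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_a": [c.pair.gene_a for c in calls],
            "gene_b": [c.pair.gene_b for c in calls],
            "class": [c.klass for c in calls],
            "evidence_a": [c.evidence_a for c in calls],
            "evidence_b": [c.evidence_b for c in calls],
        }
    )


def read_ortholog_pairs(path) -> List[OrthologPair]:
    df = pd.read_csv(path, sep="\t")
    return [OrthologPair(r.gene_a, r.gene_b) for r in df.itertuples()]
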