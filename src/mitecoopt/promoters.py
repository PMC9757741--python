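"""Promoter annotation from accessible sites and stranded nuclear RNA signal.

An accessible site is called a promoter of a gene when (i) strand-matched
RNA coverage connects the site midpoint to the gene's annotated first exon,
tolerating zero-coverage gaps of up to 200 bp, and (ii) coverage summed over
the window +75..+350 bp from the site midpoint (toward the gene) is
significantly higher than in -350..-75 bp (one-sided binomial test on the
integerized window sums, requiring a minimum total).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .accessibility import AccessibilityCall
from .core_genomics import CoverageTrack, GeneModel, GenomicInterval


@dataclass(frozen=True)
class LinkResult:
    reached: bool
    path_length: int
    max_gap: int
    trivial: bool = False  # site midpoint already inside the first exon


@dataclass(frozen=True)
class DirectionalResult:
    statistic: float  # downstream fraction of the two-window total
    pvalue: float
    passed: bool
    truncated: bool = False


@dataclass(frozen=True)
class PromoterCall:
    site: GenomicInterval
    gene_id: str
    gene_strand: str
    linked: bool
    path_length: int
    max_gap: int
    statistic: float
    pvalue: float
    directional_pass: bool
    is_promoter: bool
    crosses_gene: bool = False
    is_germline_specific: bool = False
    is_coopted: bool = False


def _zero_runs(values: np.ndarray) -> int:
    """Length of the longest run of zeros (0 if none)."""
    if len(values) == 0:
        return 0
    zero = values <= 0
    if not zero.any():
        return 0
    padded = np.concatenate(([False], zero, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return int((edges[1::2] - edges[::2]).max())


def link_site_to_first_exon(
    site: GenomicInterval,
    rna: CoverageTrack,
    gene: GeneModel,
    max_gap: int = 200,
) -> LinkResult:
    """Walk from the site midpoint toward the gene's first exon over
    positions with coverage on the gene strand.

    The link holds iff no maximal zero-coverage run on the path exceeds
    ``max_gap``. A midpoint already inside the first exon links trivially
    (path length 0). A midpoint past the first exon (downstream of it on
    the gene strand) never links.
    """
    if site.chrom != gene.chrom:
        raise ValueError("site and gene on different chromosomes")
    mid = site.midpoint
    fe = gene.first_exon
    if fe.start <= mid < fe.end:
        return LinkResult(True, 0, 0, trivial=True)
    cov = rna.get(gene.chrom, gene.strand)
    if gene.strand == "+":
        if mid >= fe.end:
            return LinkResult(False, 0, 0)
        path = cov[mid : fe.start]
    else:
        if mid < fe.start:
            return LinkResult(False, 0, 0)
        path = cov[fe.end : mid + 1]
    gap = _zero_runs(path)
    return LinkResult(gap <= max_gap, int(len(path)), gap)


def directional_signal_test(
    site: GenomicInterval,
    gene_strand: str,
    rna: CoverageTrack,
    near: int = 75,
    far: int = 350,
    alpha: float = 0.05,
    min_total: int = 10,
) -> DirectionalResult:
    """One-sided test that coverage downstream of the site midpoint (toward
    the gene) exceeds upstream coverage.

    Both windows must lie fully on the chromosome; otherwise the test fails
    with the truncation flag set. Zero signal in both windows fails (no
    evidence), it is not an error.
    """
    mid = site.midpoint
    length = rna.chrom_sizes[site.chrom]
    if mid - far < 0 or mid + far + 1 > length:
        return DirectionalResult(0.0, 1.0, False, truncated=True)
    cov = rna.get(site.chrom, gene_strand)
    left = float(cov[mid - far : mid - near + 1].sum())
    right = float(cov[mid + near : mid + far + 1].sum())
    down, up = (right, left) if gene_strand == "+" else (left, right)
    k = int(np.rint(down))
    n = int(np.rint(down + up))
    if n < min_total:
        return DirectionalResult(0.0, 1.0, False)
    pvalue = float(stats.binomtest(k, n, 0.5, alternative="greater").pvalue)
    return DirectionalResult(k / n, pvalue, pvalue < alpha)


def _candidate_genes(
    site: GenomicInterval, genes: Sequence[GeneModel], search_radius: int
) -> List[GeneModel]:
    """First exons within ``search_radius`` downstream of the site midpoint
    on either strand. If a gene id appears with several first exons, the
    exon nearest the site wins."""
    mid = site.midpoint
    best: Dict[str, Tuple[int, GeneModel]] = {}
    for g in genes:
        if g.chrom != site.chrom:
            continue
        fe = g.first_exon
        if fe.start <= mid < fe.end:
            dist = 0
        elif g.strand == "+" and mid <= fe.start <= mid + search_radius:
            dist = fe.start - mid
        elif g.strand == "-" and mid - search_radius <= fe.end - 1 <= mid:
            dist = mid - (fe.end - 1)
        else:
            continue
        if g.gene_id not in best or dist < best[g.gene_id][0]:
            best[g.gene_id] = (dist, g)
    return [g for _, g in sorted(best.values(), key=lambda t: (t[0], t[1].gene_id))]


def _path_crosses_other_gene(
    site: GenomicInterval, gene: GeneModel, genes: Sequence[GeneModel]
) -> bool:
    mid = site.midpoint
    fe = gene.first_exon
    lo, hi = min(mid, fe.start), max(mid + 1, fe.end)
    for other in genes:
        if other.gene_id == gene.gene_id or other.chrom != gene.chrom:
            continue
        if other.body.start < hi and lo < other.body.end:
            return True
    return False


def annotate_promoters(
    sites: Sequence[GenomicInterval],
    rna: CoverageTrack,
    genes: Sequence[GeneModel],
    accessibility_calls: Optional[Sequence[AccessibilityCall]] = None,
    max_gap: int = 200,
    search_radius: int = 5000,
    near: int = 75,
    far: int = 350,
    alpha: float = 0.05,
    min_total: int = 10,
) -> List[PromoterCall]:
    """Evaluate every (site, candidate gene) link and directional test.

    Returns one PromoterCall per evaluated candidate; ``is_promoter`` is
    True iff both criteria passed. A site linking to genes on both strands
    can yield two promoter calls (bidirectional promoter). The
    germline-specific flag is copied from accessibility calls matched by
    peak coordinates; the co-option flag is left False (set later by
    ``motifs.flag_coopted``).
    """
    germline: Dict[Tuple[str, int, int], bool] = {}
    if accessibility_calls is not None:
        for c in accessibility_calls:
            germline[(c.peak.chrom, c.peak.start, c.peak.end)] = (
                c.label == "germline_specific"
            )
    calls: List[PromoterCall] = []
    for site in sites:
        gs = germline.get((site.chrom, site.start, site.end), False)
        for gene in _candidate_genes(site, genes, search_radius):
            link = link_site_to_first_exon(site, rna, gene, max_gap=max_gap)
            direction = directional_signal_test(
                site, gene.strand, rna, near=near, far=far, alpha=alpha, min_total=min_total
            )
            is_promoter = link.reached and direction.passed
            crosses = (
                _path_crosses_other_gene(site, gene, genes) if link.reached else False
            )
            calls.append(
                PromoterCall(
                    site=site,
                    gene_id=gene.gene_id,
                    gene_strand=gene.strand,
                    linked=link.reached,
                    path_length=link.path_length,
                    max_gap=link.max_gap,
                    statistic=direction.statistic,
                    pvalue=direction.pvalue,
                    directional_pass=direction.passed,
                    is_promoter=is_promoter,
                    crosses_gene=crosses,
                    is_germline_specific=gs,
                )
            )
    calls.sort(key=lambda c: (c.site.chrom, c.site.start, c.gene_id))
    return calls


def promoter_calls_to_frame(calls: Sequence[PromoterCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.site.chrom for c in calls],
            "start": [c.site.start for c in calls],
            "end": [c.site.end for c in calls],
            "gene_id": [c.gene_id for c in calls],
            "gene_strand": [c.gene_strand for c in calls],
            "linked": [c.linked for c in calls],
            "path_length": [c.path_length for c in calls],
            "max_gap": [c.max_gap for c in calls],
            "statistic": [c.statistic for c in calls],
            "pvalue": [c.pvalue for c in calls],
            "directional_pass": [c.directional_pass for c in calls],
            "is_promoter": [c.is_promoter for c in calls],
            "crosses_gene": [c.crosses_gene for c in calls],
            "is_germline_specific": [c.is_germline_specific for c in calls],
            "is_coopted": [c.is_coopted for c in calls],
        }
    )


def promoter_calls_from_frame(df: pd.DataFrame) -> List[PromoterCall]:
    return [
        PromoterCall(
            site=GenomicInterval(r.chrom, int(r.start), int(r.end)),
            gene_id=r.gene_id,
            gene_strand=r.gene_strand,
            linked=bool(r.linked),
            path_length=int(r.path_length),
            max_gap=int(r.max_gap),
            statistic=float(r.statistic),
            pvalue=float(r.pvalue),
            directional_pass=bool(r.directional_pass),
            is_promoter=bool(r.is_promoter),
            crosses_gene=bool(r.crosses_gene),
            is_germline_specific=bool(r.is_germline_specific),
            is_coopted=bool(r.is_coopted),
        )
        for r in df.itertuples()
    ]
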