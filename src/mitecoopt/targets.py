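"""Direct-target calls from a DE table plus ChIP peaks on promoters, and the
headline summary fractions."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import pandas as pd
from scipy import stats

from .core_genomics import GenomicInterval, IntervalIndex
from .promoters import PromoterCall

PADJ_CUT = 0.001  # DE direction thresholds: |LFC| sign with p.adj below this


@dataclass(frozen=True)
class DERecord:
    gene_id: str
    lfc: float
    padj: float

    @property
    def direction(self) -> str:
        if self.padj < PADJ_CUT and self.lfc > 0:
            return "up"
        if self.padj < PADJ_CUT and self.lfc < 0:
            return "down"
        return "ns"


@dataclass(frozen=True)
class DirectTargetCall:
    gene_id: str
    direction: str
    is_bound: bool  # >= 1 ChIP peak on a promoter linked to the gene
    is_direct_target: bool
    has_coopted_promoter: bool


def read_de_table(path) -> List[DERecord]:
    df = pd.read_csv(path, sep="\t")
    return [DERecord(r.gene_id, float(r.lfc), float(r.padj)) for r in df.itertuples()]


def call_direct_targets(
    de: Sequence[DERecord],
    chip_peaks: Sequence[GenomicInterval],
    promoters: Sequence[PromoterCall],
    mode: str = "down_only",
) -> List[DirectTargetCall]:
    """A direct target is a down-regulated gene (mode=down_only, the default)
    with a ChIP peak overlapping a promoter linked to the gene;
    mode=misregulated additionally admits up-regulated genes."""
    if mode not in ("down_only", "misregulated"):
        raise ValueError(f"unknown mode {mode!r}")
    ids = [d.gene_id for d in de]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate gene ids in DE table: {dupes}")
    peak_index = IntervalIndex(chip_peaks)
    bound_genes: Set[str] = set()
    coopted_genes: Set[str] = set()
    for c in promoters:
        if not c.is_promoter:
            continue
        if peak_index.overlaps_any(c.site):
            bound_genes.add(c.gene_id)
        if c.is_coopted:
            coopted_genes.add(c.gene_id)
    admitted = ("down",) if mode == "down_only" else ("down", "up")
    calls = []
    for d in de:
        bound = d.gene_id in bound_genes
        calls.append(
            DirectTargetCall(
                gene_id=d.gene_id,
                direction=d.direction,
                is_bound=bound,
                is_direct_target=bound and d.direction in admitted,
                has_coopted_promoter=d.gene_id in coopted_genes,
            )
        )
    return calls


def _percent(count: int, total: int) -> float:
    # truncated (not rounded) at one decimal: 193/304 reports as 63.4
    return int(1000.0 * count / total) / 10.0 if total else 0.0


def summarize_fractions(
    calls: Sequence[DirectTargetCall], promoters: Sequence[PromoterCall]
) -> pd.DataFrame:
    """Headline counts and percentages.

    Rows: direct targets with a co-opted promoter; germline-specific
    promoters carrying an m1m2 pair; germline-specific co-opted promoters
    that are their gene's only promoter. Percentages are truncated at one
    decimal; ``percent_int`` additionally gives the nearest-integer value.
    """
    if not calls:
        raise ValueError("empty direct-target call list")
    directs = [c for c in calls if c.is_direct_target]
    n_direct = len(directs)
    n_direct_coopted = sum(c.has_coopted_promoter for c in directs)

    active = [c for c in promoters if c.is_promoter]
    gs = [c for c in active if c.is_germline_specific]
    n_gs = len(gs)
    n_gs_coopted = sum(c.is_coopted for c in gs)

    per_gene: Dict[str, int] = {}
    for c in active:
        per_gene[c.gene_id] = per_gene.get(c.gene_id, 0) + 1
    gs_coopted = [c for c in gs if c.is_coopted]
    n_sole = sum(per_gene[c.gene_id] == 1 for c in gs_coopted)

    rows = [
        ("direct_targets_with_coopted_promoter", n_direct_coopted, n_direct),
        ("germline_specific_promoters_with_pair", n_gs_coopted, n_gs),
        ("coopted_promoters_sole_for_gene", n_sole, len(gs_coopted)),
    ]
    return pd.DataFrame(
        {
            "metric": [r[0] for r in rows],
            "count": [r[1] for r in rows],
            "total": [r[2] for r in rows],
            "percent": [_percent(r[1], r[2]) for r in rows],
            "percent_int": [int(round(_percent(r[1], r[2]))) for r in rows],
        }
    )


def peak_promoter_overlap_fraction(
    peaks: Sequence[GenomicInterval], promoters: Sequence[GenomicInterval]
) -> float:
    """|{promoters overlapping >= 1 peak}| / |promoters|."""
    promoters = list(promoters)
    if not promoters:
        raise ValueError("empty promoter set")
    return IntervalIndex(peaks).count_overlapping(promoters) / len(promoters)


def fisher_direction_test(
    de: Sequence[DERecord], bound_genes: Set[str]
) -> Tuple[float, float]:
    """Fisher's exact test for down- vs up-regulation skew among bound genes.

    2x2 table of direction (down/up) x bound (yes/no) over significantly
    misregulated genes; one-sided for enrichment of down among bound.
    """
    table = [[0, 0], [0, 0]]
    for d in de:
        direction = d.direction
        if direction == "ns":
            continue
        i = 0 if direction == "down" else 1
        j = 0 if d.gene_id in bound_genes else 1
        table[i][j] += 1
    odds, p = stats.fisher_exact(table, alternative="greater")
    return float(odds), float(p)


def target_calls_to_frame(calls: Sequence[DirectTargetCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "direction": [c.direction for c in calls],
            "is_bound": [c.is_bound for c in calls],
            "is_direct_target": [c.is_direct_target for c in calls],
            "has_coopted_promoter": [c.has_coopted_promoter for c in calls],
        }
    )
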