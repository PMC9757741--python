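"""Core genomic data types, interval arithmetic and plain-text format I/O.

All coordinates are 0-based half-open (BED convention). GFF3 input/output
(1-based inclusive) is converted at the boundary. Coverage is stored densely
per chromosome as float64 vectors, which is affordable for the desk-scale
genomes this package targets (a few Mb).
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located, optionally stranded span on a named chromosome.

    ``start`` is 0-based inclusive, ``end`` is exclusive. Strand ``"."``
    means unstranded.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        s = f"{self.chrom}:{self.start}-{self.end}"
        return s if self.strand == "." else f"{s}({self.strand})"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``a`` and ``b`` share >= 1 bp under half-open semantics.

    Strand is ignored; intervals on different chromosomes never overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


class ChromSizes:
    """Mapping of chromosome name -> length (bp)."""

    def __init__(self, sizes: Mapping[str, int]):
        for name, length in sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self._sizes: Dict[str, int] = dict(sizes)

    @classmethod
    def from_sequences(cls, genome: Mapping[str, str]) -> "ChromSizes":
        return cls({name: len(seq) for name, seq in genome.items()})

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def items(self):
        return self._sizes.items()

    def validate(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self._sizes:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self._sizes[iv.chrom]:
            raise ValueError(f"interval {iv} extends past chromosome end ({self._sizes[iv.chrom]})")

    def __eq__(self, other) -> bool:
        return isinstance(other, ChromSizes) and self._sizes == other._sizes


class IntervalIndex:
    """Merged, per-chromosome sorted interval index for fast overlap queries.

    Intervals are merged on construction, so the index answers "does X
    overlap anything in the set" / "how many of these queries hit the set"
    questions; it does not preserve identity of individual subject intervals.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: Dict[str, List[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda x: (x.start, x.end))
            merged_s: List[int] = []
            merged_e: List[int] = []
            for iv in ivs:
                if merged_e and iv.start <= merged_e[-1]:
                    merged_e[-1] = max(merged_e[-1], iv.end)
                else:
                    merged_s.append(iv.start)
                    merged_e.append(iv.end)
            self._starts[chrom] = np.asarray(merged_s, dtype=np.int64)
            self._ends[chrom] = np.asarray(merged_e, dtype=np.int64)

    def overlaps_any(self, iv: GenomicInterval) -> bool:
        if iv.chrom not in self._starts:
            return False
        return bool(
            self.overlap_flags(iv.chrom, np.array([iv.start]), np.array([iv.end]))[0]
        )

    def overlap_flags(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorized: flag[i] is True iff [starts[i], ends[i]) hits the set."""
        if chrom not in self._starts or len(self._starts[chrom]) == 0:
            return np.zeros(len(starts), dtype=bool)
        s, e = self._starts[chrom], self._ends[chrom]
        # candidate: first merged interval whose end is > query start
        idx = np.searchsorted(e, starts, side="right")
        flags = np.zeros(len(starts), dtype=bool)
        inside = idx < len(s)
        flags[inside] = s[idx[inside]] < ends[inside]
        return flags

    def count_overlapping(self, queries: Iterable[GenomicInterval]) -> int:
        total = 0
        by_chrom: Dict[str, List[GenomicInterval]] = {}
        for q in queries:
            by_chrom.setdefault(q.chrom, []).append(q)
        for chrom, qs in by_chrom.items():
            starts = np.fromiter((q.start for q in qs), dtype=np.int64, count=len(qs))
            ends = np.fromiter((q.end for q in qs), dtype=np.int64, count=len(qs))
            total += int(self.overlap_flags(chrom, starts, ends).sum())
        return total


def count_overlapping(
    query: Iterable[GenomicInterval], subject: Iterable[GenomicInterval]
) -> int:
    """Number of query intervals overlapping >= 1 subject interval.

    Each query is counted at most once regardless of how many subjects it
    hits.
    """
    return IntervalIndex(subject).count_overlapping(query)


class CoverageTrack:
    """Dense per-base signal, optionally stranded.

    Unstranded data lives in ``data[chrom]``; stranded data in
    ``data[chrom]["+"]`` / ``data[chrom]["-"]``. All values must be finite
    and >= 0 and each vector must span its whole chromosome.
    """

    def __init__(self, chrom_sizes: ChromSizes, stranded: bool = False):
        self.chrom_sizes = chrom_sizes
        self.stranded = stranded
        if stranded:
            self.data = {
                c: {s: np.zeros(l, dtype=np.float64) for s in "+-"}
                for c, l in chrom_sizes.items()
            }
        else:
            self.data = {c: np.zeros(l, dtype=np.float64) for c, l in chrom_sizes.items()}

    def get(self, chrom: str, strand: Optional[str] = None) -> np.ndarray:
        if self.stranded:
            if strand not in ("+", "-"):
                raise ValueError("stranded track requires strand '+' or '-'")
            return self.data[chrom][strand]
        return self.data[chrom]

    def add_segment(
        self, chrom: str, start: int, values: np.ndarray, strand: Optional[str] = None
    ) -> None:
        arr = self.get(chrom, strand)
        arr[start : start + len(values)] += values

    def validate(self) -> None:
        for chrom, length in self.chrom_sizes.items():
            vecs = self.data[chrom].values() if self.stranded else [self.data[chrom]]
            for v in vecs:
                if len(v) != length:
                    raise ValueError(f"coverage vector length mismatch on {chrom}")
                if not np.all(np.isfinite(v)) or np.any(v < 0):
                    raise ValueError(f"coverage on {chrom} has negative or non-finite values")

    def __eq__(self, other) -> bool:
        if not isinstance(other, CoverageTrack) or self.stranded != other.stranded:
            return False
        if set(self.data) != set(other.data):
            return False
        for chrom in self.data:
            if self.stranded:
                for s in "+-":
                    if not np.array_equal(self.data[chrom][s], other.data[chrom][s]):
                        return False
            elif not np.array_equal(self.data[chrom], other.data[chrom]):
                return False
        return True


@dataclass(frozen=True)
class GeneModel:
    """A gene with a TSS, a first exon and a gene body.

    The TSS must coincide with the strand-appropriate edge of the gene body
    (start for '+', end - 1 for '-'), and the first exon must be contained
    in the body.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    first_exon: GenomicInterval
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not (
            self.body.start <= self.first_exon.start
            and self.first_exon.end <= self.body.end
        ):
            raise ValueError(f"gene {self.gene_id}: first exon not contained in gene body")
        expected_tss = self.body.start if self.strand == "+" else self.body.end - 1
        if self.tss != expected_tss:
            raise ValueError(
                f"gene {self.gene_id}: TSS {self.tss} is not the {self.strand}-strand "
                f"edge of the gene body ({expected_tss})"
            )


# ---------------------------------------------------------------------------
# I/O: FASTA, BED, bedGraph, GFF3
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for line in textwrap.wrap(seq, width):
                fh.write(line + "\n")


def read_bed(path: str | Path) -> List[GenomicInterval]:
    ivs: List[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            strand = parts[5] if len(parts) >= 6 else "."
            ivs.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return ivs


def read_bed_names(path: str | Path) -> List[str]:
    """Name column (4th field) of a BED file; '.' when absent."""
    names: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            names.append(parts[3] if len(parts) >= 4 else ".")
    return names


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Optional[Sequence[str]] = None,
    scores: Optional[Sequence] = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_bedgraph(path: str | Path, chrom_sizes: ChromSizes) -> Dict[str, np.ndarray]:
    """Read one bedGraph file into dense per-chromosome vectors (missing = 0)."""
    vecs = {c: np.zeros(l, dtype=np.float64) for c, l in chrom_sizes.items()}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split("\t")
            vecs[chrom][int(start) : int(end)] = float(value)
    return vecs


def write_bedgraph(vecs: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Run-length encode dense vectors to bedGraph; zero runs are omitted.

    Values are written with ``repr`` so that float64 round-trips exactly.
    """
    with open(path, "w") as fh:
        for chrom in vecs:
            arr = np.asarray(vecs[chrom], dtype=np.float64)
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            bounds = np.concatenate(([0], change, [len(arr)]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                v = float(arr[s])
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v!r}\n")


def read_coverage(
    chrom_sizes: ChromSizes,
    path: Optional[str | Path] = None,
    plus_path: Optional[str | Path] = None,
    minus_path: Optional[str | Path] = None,
) -> CoverageTrack:
    """Build a CoverageTrack from one (unstranded) or two (stranded) bedGraphs."""
    if path is not None:
        track = CoverageTrack(chrom_sizes, stranded=False)
        track.data = read_bedgraph(path, chrom_sizes)
    else:
        if plus_path is None or minus_path is None:
            raise ValueError("stranded coverage needs both plus_path and minus_path")
        track = CoverageTrack(chrom_sizes, stranded=True)
        plus = read_bedgraph(plus_path, chrom_sizes)
        minus = read_bedgraph(minus_path, chrom_sizes)
        track.data = {c: {"+": plus[c], "-": minus[c]} for c in chrom_sizes}
    track.validate()
    return track


def write_coverage(track: CoverageTrack, path_or_prefix: str | Path) -> List[Path]:
    """Write a track as bedGraph(s); stranded tracks get .plus/.minus files."""
    if not track.stranded:
        p = Path(path_or_prefix)
        write_bedgraph(track.data, p)
        return [p]
    prefix = str(path_or_prefix)
    plus = Path(prefix + ".plus.bedgraph")
    minus = Path(prefix + ".minus.bedgraph")
    write_bedgraph({c: track.data[c]["+"] for c in track.data}, plus)
    write_bedgraph({c: track.data[c]["-"] for c in track.data}, minus)
    return [plus, minus]


def read_gff3(path: str | Path) -> List[GeneModel]:
    """Read gene models from GFF3 (gene features with child exons).

    The first exon is the 5'-most exon on the gene strand. Coordinates are
    converted from 1-based inclusive to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    genes: List[GeneModel] = []
    for feat in db.features_of_type("gene"):
        exons = list(db.children(feat, featuretype="exon"))
        if not exons:
            raise ValueError(f"gene {feat.id} has no exons")
        if feat.strand == "+":
            first = min(exons, key=lambda e: e.start)
        else:
            first = max(exons, key=lambda e: e.end)
        body = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        fe = GenomicInterval(first.seqid, first.start - 1, first.end, feat.strand)
        tss = body.start if feat.strand == "+" else body.end - 1
        genes.append(GeneModel(feat.id, feat.seqid, feat.strand, tss, fe, body))
    genes.sort(key=lambda g: (g.chrom, g.body.start, g.gene_id))
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path, source: str = "mitecoopt") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.body.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.body.start + 1}\t{g.body.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            fe = g.first_exon
            fh.write(
                f"{g.chrom}\t{source}\texon\t{fe.start + 1}\t{fe.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}.e1;Parent={g.gene_id}\n"
            )


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
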