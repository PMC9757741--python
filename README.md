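# mitecoopt

Detection and evolutionary classification of MITE-derived germline promoters
from chromatin accessibility, nascent-RNA coverage, and motif evidence.

The package implements, as a reusable and fully tested pipeline:

1. **Differential accessibility** (`accessibility`) — classify accessible
   sites as germline-specific by comparing wild-type vs germline-less ATAC
   replicate counts (LFC < −2 and BH-adjusted p < 0.01; pooled-variance
   t-test on log2(CPM+1) as a desk-scale stand-in for DiffBind).
2. **Promoter annotation** (`promoters`) — link accessible sites to a gene's
   annotated first exon through stranded nuclear RNA coverage (zero-coverage
   gaps up to 200 bp), plus a directional signal-asymmetry test on the
   ±75–350 bp windows around the site midpoint.
3. **Motif machinery** (`motifs`) — PWM scanning on both strands with exact
   p-values by dynamic programming over the discretized score distribution
   (hits at p ≤ 5e-4), m1/m2 pair annotation at 10–30 bp gap spacing with
   four arrangement classes (convergent, divergent, tandem m1+m2+, tandem
   m2+m1+), family hints (divergent/12–16 bp → CERP2-like; tandem
   m2+m1+/23–28 bp → CELE2-like), promoter co-option flagging, and a TT
   dinucleotide 10-bp periodicity profile.
4. **Permutation enrichment** (`enrichment`) — shuffleBed-style interval
   shuffles (length- and chromosome-preserving, gene bodies excluded) with
   add-one empirical p-values.
5. **Direct targets** (`targets`) — DE table + ChIP peaks on promoters →
   direct-target calls and the headline summary fractions.
6. **Conservation** (`conservation`) — classify each 1:1 ortholog pair as
   conserved / potentially conserved / species-specific from per-species
   promoter, pair and single-motif evidence.
7. **Synthetic benchmark** (`synthetic_data`) — a deterministic two-species
   world (~5 Mb) with planted CERP2-like and CELE2-like elements, simulated
   ATAC/RNA coverage, DE table, ChIP peaks, ortholog map, and a complete
   truth table. Planted motif instances are the only instances in the
   emitted genomes (the background is scrubbed of spurious hits at the scan
   threshold), so recovery is exactly checkable.

Shared interval/coverage types and plain-text format I/O (FASTA, GFF3,
BED, bedGraph, TSV) live in `core_genomics`. Internally all coordinates are
0-based half-open.

## CLI

```sh
mitecoopt simulate --out world --seed 1          # synthetic benchmark
mitecoopt classify-accessibility --counts world/spA/atac_counts.tsv --out acc.tsv
mitecoopt scan --genome world/spA/genome.fa --motifs world/motifs.meme --out occ.tsv
mitecoopt pair --occurrences occ.tsv --out pairs.tsv
mitecoopt enrich --repeats world/spA/repeats.bed --promoters gs.bed \
    --genes world/spA/genes.gff3 --genome world/spA/genome.fa --out enr.tsv
mitecoopt pipeline --world world --out results   # everything, both species
```

`mitecoopt simulate --config cfg.yaml` accepts a YAML file overriding any
field of `synthetic_data.SyntheticConfig`.

## Notes on free parameters

Synthetic signal heights, element counts, class proportions and the m1/m2
consensus sequences are benchmark parameters declared in
`SyntheticConfig`; they are not literature-derived quantities. Pair spacing
is the gap between motif intervals (bases strictly between the two
occurrences), not center-to-center.
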