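# mxescan

Prediction of **mutually exclusive exons (MXEs)** in annotated genomes.

Mutually exclusive splicing includes exactly one exon out of a cluster of
neighbouring exons in each mature transcript — the mechanism behind the
enormous isoform diversity of genes like arthropod *DSCAM* and *muscle myosin
heavy chain*. Because the exons of a cluster encode the same region of the
protein, they obey four testable preconditions: **similar length**,
**conserved splice-site patterns** (`AG` acceptor immediately 5', `GT`/`GC`
donor immediately 3'), **preservation of the reading frame**, and **sequence
homology**. `mxescan` turns those preconditions into a search: given a genome
(FASTA) and a coding-gene annotation (GFF3), it enumerates candidate exons in
introns and gene flanks, scores them, filters them, groups them into clusters
and classifies the clusters.

The similarity score of a candidate exon is self-normalized and given in
percent:

```
score(orig, cand) = 100 · S(orig, cand) / S(orig, orig)
```

where `S` is the global (end-gap-penalized) alignment score of the encoded
peptides under BLOSUM62 with affine gaps (open 11, extend 1; all
configurable). Identical peptides score exactly 100; unrelated peptides may
score negative.

A candidate survives enumeration if it is bounded by canonical splice sites,
its length differs from the original exon by a multiple of three nucleotides
(frame preservation) and by at most `max_len_diff` codons, its reading frame
contains no stop codon, and its score reaches `min_score`. Prediction runs
with deliberately **relaxed** thresholds (score ≥ 10 %, original exon ≥ 10 aa,
all introns, 20 kb flanks) and stores everything in a lossless YAML master
file; the **display** defaults (score ≥ 15 %, exon ≥ 15 aa, flanking introns
only) are applied as a pure re-filtering step, so thresholds can be explored
without repeating the genome scan.

Clusters containing a first coding exon are classified *initial* (alternative
promoters), those containing a last coding exon *terminal* (alternative
poly(A) sites), the rest *internal* — the class regulated at the level of
splicing proper. The package also detects MXE clusters already present in an
annotation (every isoform includes exactly one member), flags constitutive or
cassette exons that meet the MXE criteria, and recognizes ordered exon copies
in gene flanks as tandem-duplication/trans-splicing signatures.

A deterministic synthetic-genome generator (`mxescan.simulate`) plants MXE
clusters, decoy introns, multi-isoform genes and flank duplications with full
ground truth, so every stage is testable without downloading a genome.

## Worked example

`examples/02_filter_algebra.py` builds a three-exon gene carrying a planted
cluster of four MXEs (annotated exon 2b, 18 aa, plus alternatives 2a, 2c, 2d)
and shows what each filter does:

```
stored candidates (relaxed scan, score >= 10 %):
  2a: score 77.5 %, length diff 13 aa, upstream_intron
  2c: score 13.7 %, length diff 0 aa, downstream_intron
  2d: score 78.4 %, length diff 12 aa, downstream_intron
default filters (score>=15, diff<=20, exon>=15): ['2a', '2d']
length difference capped at 11 aa:         ['2c']
minimal original exon length 19 aa:        []
assembled cluster: 4 members, type 'internal'
```

The default score threshold removes only the divergent 2c; capping the length
difference below 12 codons instead removes the two long alternatives; raising
the minimal original exon length above 18 aa removes every candidate seeded
from the 18-aa exon 2b. The surviving exons plus their source form one
internal cluster of four.

The other example scripts cover prediction plus re-filtering on a planted
genome (`01`), annotated-MXE detection with sensitivity (`03`) and the
tandem-duplication flank signature (`04`).

## Command line

```
mxescan simulate --out-dir sim --seed 3 --genes 10        # synthetic genome
mxescan predict  --genome sim/genome.fasta --annotation sim/annotation.gff3 \
                 --out-dir pred                           # relaxed store scan
mxescan filter   --master pred/mxe.yaml --out-dir filt    # display filtering
mxescan stats    --master pred/mxe.yaml                   # summary table
```

Outputs: YAML master (lossless, re-filterable), TSV, GFF3 (1-based
inclusive) and BED (0-based half-open), with the similarity percent in the
score column.

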