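# Methods

## The prediction model

`mxescan` predicts mutually exclusive exons (MXEs) from four preconditions
that follow from the assumption that all exons of a cluster encode the same
region of the protein:

1. **Conserved splice sites.** A candidate exon must be immediately preceded
   by an `AG` acceptor dinucleotide and immediately followed by a `GT` or
   `GC` donor on the coding strand. Non-canonical (e.g. U12-type) introns are
   out of scope.
2. **Reading-frame preservation.** The candidate's length must differ from
   the original exon's length by a multiple of 3 nt, so that splicing in the
   alternative leaves downstream exons in frame.
3. **Similar length.** The length difference, in whole codons, is capped
   (`max_len_diff`, default 20 aa) — secondary-structure elements fix the
   length of the encoded region up to loop flexibility.
4. **Sequence homology.** The candidate peptide must reach a minimal
   similarity score against the original exon's peptide.

The similarity score is `100 · S(orig, cand) / S(orig, orig)` where `S` is a
global pairwise alignment score. Self-normalization makes 100 an exact fixed
point for identical peptides and makes thresholds comparable across exons of
different lengths and compositions. Scores can be negative for unrelated
peptides and cannot exceed 100 under a substitution matrix whose diagonal
dominates.

### Alignment settings

Global (end-gap-penalized) alignment is used because an exon replacement must
cover the same region end to end; local alignment would reward partial
matches that break the equal-region premise. Defaults: BLOSUM62, gap open 11,
gap extend 1, where a gap of length L costs `open + (L−1)·extend`. All four
settings are configurable (`PredictionParams`). The scorer is backed by
Biopython's `PairwiseAligner`; the test suite pins its semantics against an
independently written Gotoh dynamic-programming implementation to 1e-9.

### Enumeration

For each original exon of at least `min_exon_len` amino acids (floor of
nt/3; partial codons never count), the search walks the regions implied by
the scope: the two introns surrounding the exon (`flanking`, display
default), every intron of the isoform (`all`, store default), plus
`flank_nt` nucleotides up- and downstream of the gene locus when enabled.
Within a region, every (acceptor, donor) position pair with a
frame-compatible length inside the codon cap is considered; candidates
whose complete codons (in the frame imposed by the original exon's start
phase) contain a stop are rejected, as are candidates closer than
`min_candidate_margin` (default 20 nt) to a region edge — a residual intron
must remain on both sides. Regions are processed on the coding strand and
mapped back to forward-strand coordinates, which makes predictions exactly
mirror-symmetric between a gene and its reverse complement.

Mutually overlapping candidates within one region are reduced to the
highest-scoring one (ties: smaller length difference, then 5'-most start).
Stop codons split across the splice junction are not checked: a replacement
exon changes the junction codon only through its own sequence, which the
score already captures.

Multi-isoform genes are searched independently per isoform. Candidates are
then reconciled: exact interval matches to an exon of another isoform count
as confirmation, mere overlaps are flagged as potential false positives
(excluded by default, retainable with `--keep-isoform-overlaps`), and
overlaps with exons of the adjacent genes on the same contig are flagged
separately.

### Store vs display parameters

The pipeline scans once with relaxed values (score ≥ 10 %, original exon
≥ 10 aa, all introns, 20 kb flanks) and stores every hit in the YAML master
output together with the gene structures and parameters. Display filtering
(score ≥ 15 %, exon ≥ 15 aa, surrounding introns only, flanks off) is a pure
predicate pass over stored candidates: idempotent, order-invariant, and
monotone (relaxing any threshold can only grow the surviving set). The
master file alone reproduces filtered sets and summaries bit-identically.

### Clusters and classification

Each source exon plus its surviving candidates forms a cluster; clusters
sharing a member interval, or whose source exons predict each other, are
merged by union-find on intervals. Members are ordered genomically; should
merged members overlap, the lower-scoring predicted member is dropped with a
warning (annotated exons are never dropped). A cluster containing any
isoform's first coding exon is *initial*, any last coding exon *terminal*,
otherwise *internal*; a cluster qualifying as both (two-exon isoforms) is
labeled initial — an arbitrary but deterministic, logged tie-break.

Annotated MXE clusters are groups of ≥ 2 neighbouring, mutually
non-overlapping exons such that **every** isoform of the gene includes
exactly one member. "Neighbouring" means no annotated exon of any isoform
lies strictly between members — the weakest adjacency notion that keeps
alternatives in one genomic stretch. An isoform containing two members
(cassette pattern) or none disqualifies the group; tolerating
cluster-skipping isoforms would admit groups that are not mutually exclusive
in every transcript.

Constitutive/cassette neighbours that meet the MXE criteria pairwise are
flagged `constitutive_mxe_like`; because the score is asymmetric under
self-normalization, the larger of the two directions is compared against the
threshold.

Sensitivity against annotated MXEs counts an exon as reconstructed iff a
candidate sourced from a *different* exon of its cluster matches its genomic
interval exactly (both boundaries, ±0 nt — the strictest reading). By
default only internal clusters enter the computation, since initial and
terminal clusters can arise from alternative transcription starts or
poly(A) sites rather than splicing.

## Gene models

Internal coordinates are 0-based half-open on the forward strand everywhere;
GFF3's 1-based inclusive convention is converted only at the format
boundary. Phases follow GFF3 semantics (bases to skip to the first complete
codon) and are propagated through the exon chain when absent. Each exon's
peptide is the translation of its complete internal codons; junction codons
belong to no exon's scoring peptide. Validation labels — never exceptions —
mark non-canonical introns (anything but `GT..AG`/`GC..AG` on the coding
strand), in-frame internal stops, missing terminal stops, phase-chain
inconsistencies and, when a reference protein is supplied, translation
mismatches; any label makes the isoform `incomplete`. Incomplete isoforms
are still searched: flank extension exists precisely to find candidates for
genes with missing ends. Only the standard nuclear genetic code is
supported. Candidate regions containing `N` are skipped with a warning
rather than scored as wildcards.

## The synthetic-data generator

`mxescan.simulate` emulates the preconditions the predictor relies on, not
real genome statistics. Genes have an ATG start, one terminal stop, no
internal stops and canonical introns; planted alternatives are codon-level
mutated copies of their source exon (substitutions replace whole codons with
a codon of a different residue, so the realized amino-acid identity equals
the target exactly up to rounding; indels move whole codons, keeping frame
compatibility by construction) installed between `AG`/`GT` contexts with
margins. Decoy introns and decoy stretches of planted introns are
rejection-sampled until candidate enumeration against the flanking exons
finds nothing above the store-stage bar (10 %), so spurious hits on
negative-control genomes are excluded by construction, not by luck; the
rare sequence still dirty after 60 resamples is kept with a logged warning.
Background sequence is i.i.d. uniform over ACGT — no codon-usage, GC-content
or splice-site-strength realism, and intron/intergenic lengths are uniform
in a configurable range. Genes that gain or lose a whole exon between
isoforms (annotated-MXE, cassette and duplicate patterns) use codon-aligned
exon boundaries so the exon swap preserves the frame; plain genes use
jittered boundaries to exercise non-zero phases.

Passing tests on these genomes therefore demonstrates the correctness of
the search algebra — enumeration, scoring, filtering, clustering,
classification, sensitivity — under the stated preconditions. They do not
demonstrate performance on real genomes, where splice-site strength,
repeats, pseudogenes and annotation errors dominate the false-positive rate.

The worked fixture (`filter_demo_fixture`) pins a three-exon gene whose planted
cluster makes each filter's action visible: source exon 2b is exactly 18 aa;
2a and 2d differ by 13 and 12 codons with scores ≥ 15 %; 2c matches 2b's
length with a score engineered into [10, 15). The construction is
deterministic and self-verifying: it re-runs the store-stage scan and
requires exactly the three planted candidates before returning.

## Numerical and policy choices

* `aa_len := floor(nt_len / 3)` — conservative, integer-stable length for
  thresholds stated in amino acids.
* Candidate margin 20 nt: prevents zero-length residual introns; no
  biological splice-site-proximity model is implied.
* Determinism: identical inputs and parameters give byte-identical outputs;
  candidate order is (source exon, location, start), and every random
  process in the generator is driven by one seed.
* Scores are compared exactly where the contract is exact (self-score 100.0,
  identity-1.0 plants) and to 1e-9 against the DP oracle elsewhere.

## Problem sizes used in tests and the acceptance script

Recovery and negative-control experiments run on 100-gene genomes (3–5
exons of 18–40 aa per gene, introns 120–300 nt) and 100 three-gene control
genomes; the enumeration oracle is checked on 50 random introns of up to
2 kb. These sizes give stable 0/1 outcomes for the planted constructions at
interactive runtimes; the algebraic properties they certify are
size-independent.

## Known limitations

* No splice-site strength model (MaxEnt and the like), no branch points,
  no U12 introns, no RNA-secondary-structure evidence for cluster pairing.
* Specificity on real genomes is not estimable from these fixtures; only
  sensitivity against planted/annotated truth is computed.
* One genetic code; trans-spliced multi-locus gene reconstruction is out of
  scope (only the flank-copy *signature* is flagged).
* The YAML master schema is original to this package and versioned
  (`schema_version: 1`).
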