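# Methods

This note documents the models and procedures implemented in amplitax,
the parameters that matter, the synthetic-data generators used for
validation, and the design decisions taken where the problem was
genuinely open.

## Quality filtering and binning

Reads are processed in a fixed cascade: barcode match → forward-primer
match → adapter clip → sliding-window tail trim → structural filters →
quality bands.

- **Barcodes** are anchored at the 5′ read start and matched by Hamming
  distance within `BarcodeErrors` (default 0). A tie between two
  barcodes at the same minimal distance leaves the read *unassigned*
  rather than picking a winner: silent cross-sample bleed is worse than
  a lost read.
- **Primers** may contain IUPAC degeneracy codes; a degenerate position
  matches any base of its set at zero cost (`PrimerErrors` default 1).
- **Window trim** slides a `QualWindowWidth` (50 bp) window inward from
  the preserved end and cuts at the start of the first window whose
  mean quality drops below `QualWindowThreshold` (25). The default
  removes the 3′ tail, where base quality degrades on both 454 and
  Illumina instruments; a 5′ mode exists for unusual chemistry.
- **Structural filters**: `MinReadLength` 250, `MaxReadLength`
  unlimited, `MaxAmbiguousNT` 0, `MaxHomopolymer` 8 (homopolymer runs
  are the dominant 454 artifact). Rejection reports the first failing
  criterion in a fixed precedence (too_short, too_long, ambiguous,
  homopolymer, avg_qual, expected_error) so reports are deterministic.
- **Quality bands.** Expected error `E = Σ 10^(−Q/10)` is length-aware:
  a long mediocre read accumulates more expected errors than a short
  one at equal mean quality. High requires mean quality ≥ 27 and
  `E ≤ 1.0`; mid relaxes these by `MidQualRelax` (4×) on `E` and 5
  Phred on the mean. The mid band exists so that noisy reads can still
  be *counted* against established OTUs without being allowed to *found*
  OTUs. The high bin is additionally emitted truncated to
  `TruncateLength` (250 bp) as clustering input, keeping the
  high-quality 5′ region and a uniform length.

Tightening any single quality threshold can only shrink the high bin
(monotonicity), and identical inputs yield byte-identical bins — both
are tested properties.

## Identity

One definition is used everywhere identity appears: matches divided by
alignment columns. Alignments come from edlib; when one sequence is
shorter than the other (truncated read vs full-length seed) the shorter
is aligned end-gap-free within the longer, so missing tail sequence is
not penalised. Percent identity is 100× this fraction.

## OTU clustering and abundance

The built-in clusterer is deliberately simple: exact dereplication
(size-sorted, ties broken lexicographically) followed by greedy
centroid clustering in abundance order at 97% identity. It is a
transparent stand-in that keeps the pipeline free of external
dependencies; serious denoising clusterers plug in through the
seeds-FASTA + membership-TSV adapter. Abundance mapping assigns each
high- or mid-quality read to its *best*-identity seed at ≥ 97% (best-hit
rather than first-hit, so the matrix is independent of seed order; ties
go to the lexicographically smallest OTU id). An overlap check reports
seed pairs within the OTU radius of each other and can merge the
smaller member into the larger until no pair overlaps (idempotent).

## Seed extension

Clustering representatives are truncated reads; annotation wants long,
accurate ones. For each OTU the full-length high-quality member reads
aligning to the representative at ≥ 97% are ranked lexicographically
by (1) |identity − median identity| (closeness to the OTU centre),
(2) per-base expected error, (3) length (descending), (4) read id
(determinism). "Centre of the OTU" is read as closeness of alignment
identity to the candidates' median identity; the alternative reading
(median *length*) is rejected because length already appears as its own
criterion. Mid-quality reads never become seeds. Clusters whose members
have no surviving full-length high-quality read keep their
representative and are flagged in the log.

Paired reads are overlap-merged in-package: overlap lengths are scanned
longest-first and the first with mismatch fraction ≤ 0.25 (minimum
overlap 10 bp) is accepted; at overlap columns the higher-quality base
wins, with merged quality max(Qf,Qr) on agreement and max−min (floor 2)
on disagreement. This max-based formula was chosen over a probabilistic
posterior for simplicity and is pluggable. Note that repetitive
templates are fundamentally ambiguous for any overlap merger; the
reconstruction guarantee is stated for non-periodic templates.

## Windowed LCA taxonomy

Given BLAST-style tabular hits for a seed:

1. Multiple HSPs to one subject collapse to the best one — one
   reference, one vote (the hit format is per-HSP; without dedup a
   repetitive reference would dominate the vote).
2. Hits within 1.5 percentage points of the best percent identity are
   retained, then capped at 200 by (identity desc, bitscore desc,
   subject id asc). Applying the cap *after* the window avoids
   arbitrarily discarding in-window hits.
3. Ranks are walked domain → species. At each rank, references
   unannotated there abstain; the majority name wins iff its share of
   the remaining voters is strictly greater than the consensus fraction
   (0.9). Strict inequality means 9-of-10 fails; it also lets a single
   annotated reference carry a rank when all others abstain.
4. The best hit's identity caps the assignable depth: species 97,
   genus 95, family 93, order 91, class 88, phylum 78 (percent).
   Identity below the phylum cap leaves only the domain assignable.
   The published cap list pairs 91 with class and 88 with order, which
   is inconsistent with the standard rank order (order lies between
   family and class); the default here keeps the printed numbers but
   assigns them to hierarchy-consistent ranks so the caps are monotone
   in depth. `LcaSpec.printed_caps()` provides the literal pairing.
5. The first rank that fails the vote or exceeds the cap truncates the
   lineage; deeper ranks stay `?`.

The vote at each rank is recounted over the full retained hit set, not
conditioned on agreement with the already-assigned parent; in 16S
reference taxonomies rank names essentially never repeat across
parents, and the unconditioned recount matches the exhaustive oracle
the implementation is tested against.

## Synthetic data

Two generators produce all test and validation inputs; no downloads.

**`make_reference_set`** emulates a labelled 16S database. Lineages are
a balanced tree (default branching 4·2·2·2·2·2 under one domain = 128
species). Sequences are 600 bp with alternating conserved (120 bp) and
hypervariable (50 bp) blocks, mirroring the conserved-stretch /
V-region architecture of the real gene. Each lineage split substitutes
a fixed number of sites per variable block (rates 0.50 phylum → 0.08
species of variable sites) plus low-rate leakage (8% of the block rate)
on conserved sites; references within a species diverge i.i.d. at 2% of
variable sites. The fixed per-block count guarantees that sister taxa
differ within every variable block, so the noiseless-recovery property
(below) is structural rather than probabilistic. What this generator
does **not** emulate: indels, chimeras, copy-number variation,
rank-specific naming collisions, and realistic database imbalance —
conclusions from passing tests are about the algorithms, not about
classification accuracy on real databases.

**`make_multiplexed_run`** emulates a multiplexed sequencing run:
reads from 3 unrelated 300 bp templates, 4 sample barcodes (8 bp,
pairwise Hamming ≥ 4), per-read substitutions capped at 2 (so any two
reads of one template stay within the 97% OTU radius by construction),
and a mildly declining Q38→Q31 quality profile. It produces clean
high-bin reads by design; filter edge cases are exercised by dedicated
unit fixtures instead.

**Read simulation** for classifier validation takes the 5′ prefix of a
sampled reference at the requested length and applies i.i.d. uniform
substitutions (no indels; an honest simplification of "random
mutation" — edlib-based classification is indel-capable regardless).
`exclude_self` removes each read's source from the searchable database;
`exclude_relatives_identity` additionally hides all hits at or above a
given identity, emulating a taxon absent from the database. With
relatives ≥ 97% hidden, species-level assignment is structurally
impossible (the depth cap cannot be reached) — tested as an invariant.

## Evaluation

Per rank: TP = assigned and equal to the truth name, FP = assigned and
different, unassigned predictions are TN when the truth itself lacks
the rank and FN otherwise. Precision TP/(TP+FP) and specificity
TN/(TN+FP) are reported as absent when their denominator is zero.
The read-length trend (unassigned fraction at 250 bp ≤ at 100 bp) is a
statistical property and is asserted on means over 5 simulation seeds,
60 reads per run against a 200-reference database — sizes chosen to
make the seed-averaged trend stable while keeping the suite quick.

## Numerical and format notes

- FASTQ qualities are Phred+33 only; gzip is detected by magic bytes.
- BIOM output is the 1.0 JSON dialect (sparse), keeping tables plain
  text; taxonomy is per-observation metadata of exactly 7 strings.
- All randomness flows through explicitly seeded numpy generators;
  every pipeline stage is deterministic given its inputs.
- The phylogenetic-tree step is an external command hook (the extended
  seeds FASTA in, a tree file out); no alignment or inference is
  implemented in-package.
- Degenerate inputs: empty hit lists yield fully unassigned paths;
  empty read sets yield valid empty outputs; a window longer than the
  read leaves it untrimmed; quality-less FASTA input requires the
  quality criteria to be explicitly disabled.
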