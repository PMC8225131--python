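# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `mitochar`.

## Coordinate model

Genomes are circular; coordinates are 1-based closed intervals on the
majority (J) strand, the strand the sequence is written on. Features may
wrap the origin, in which case `end < start` and the feature carries an
explicit `wraps` flag — wrapping is never inferred from `end < start`
alone, so coordinate typos surface as errors instead of silently becoming
origin-spanning genes. N-strand features are read as the reverse
complement of their J-strand interval. The two leucine and two serine
tRNAs must carry disambiguating suffixes (trnL1 = CUN family, anticodon
TAG; trnL2 = UUR, TAA; trnS1 = AGN, GCT; trnS2 = UCN, TGA), giving every
gene a unique key for ordering and concatenation.

## Organization metrics

The spacer between adjacent features is `start(next) − end(prev) − 1`, so
abutting genes score 0 and an 8-bp overlap −8; the circular closure pair
(last feature back to the first) is included. Gene-order comparison finds
the genes outside a longest common circular subsequence of the two orders.
Because each gene name occurs exactly once, any cyclic common subsequence
can be cut immediately before one of its genes, and that gene fixes the
rotation of both orders — so taking the best linear LCS over all same-gene
cuts is exhaustive, not heuristic. This is deliberately weaker than
breakpoint/DCJ event inference (a non-goal): it exactly isolates
single-cluster translocations such as the derived lepidopteran
trnM–trnI–trnQ order versus the ancestral trnI–trnQ–trnM, which is the
rearrangement of interest here.

Start codons are the first 3 nt of the coding sequence. When the CDS
length is not a multiple of 3, the trailing 1–2 nt are reported as a
truncated stop (completed to UAA by post-transcriptional polyadenylation
in vivo); a truncated stop that is not a prefix of TAA, or a final codon
that is not a stop, is reported with a warning rather than an error —
annotations disagree with their own sequences often enough that refusing
to report would hide exactly the rows a curator needs to see.

## Composition and skew conventions

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C); both are `None` (never NaN
or 0) when their denominator is empty. Non-ACGT symbols are preserved in
sequence but tallied as `other` and excluded from fractions. Per-class
summaries concatenate each gene's coding strand (N-strand genes
reverse-complemented) — the convention under which rRNA skews are
biologically interpretable — while the whole-genome summary stays on the
J-strand, which is what makes the slightly negative whole-genome AT skew
of lepidopteran mitogenomes reproducible. Printed AT% is rounded to one
decimal; underlying values are full precision.

## Codon usage and translation

The invertebrate mitochondrial code (NCBI table 5) has 62 sense codons
(AGA/AGG = Ser, ATA = Met, TGA = Trp) and stops TAA/TAG. RSCU families
split leucine and serine into their two codon boxes (Leu1/Leu2,
Ser1/Ser2); every other amino acid is one family. Start codons are
included in usage counts; stop codons are tallied separately and excluded
from families (standard RSCU practice, and required for the family-mean-1
normalization). Unused families get RSCU 0 with a `used=False` flag.
Nonstandard starts are counted as their literal codons but rendered M in
translation by default, mirroring mitochondrial annotation convention
without corrupting usage counts.

## tRNA cloverleaf assignment

Folding is template-constrained, not thermodynamic. The template fixes the
conserved elements (acceptor stem 7 bp, anticodon stem 5 bp, anticodon
loop 7 nt) and bounds the variable ones (DHU stem 3–4 bp, DHU loop 4–9 nt,
variable loop 3–6 nt, TψC stem 4–5 bp, TψC loop 3–8 nt). The stem lengths
are the conserved values reported for these genomes; the loop ranges are
not printed in structure figures and are therefore configuration defaults,
not asserted facts. Arms tile the sequence without spacer nucleotides —
a simplification relative to canonical tRNA numbering (which has 1–2
linker nucleotides between arms); the template absorbs linkers into the
adjacent loops.

Every admissible boundary layout is enumerated (≤ a few hundred per
sequence) and scored per stem position: Watson–Crick = 2, wobble
(G·T, T·T, G·A — the pair classes conventionally drawn as dots in
mitogenome structure figures) = 1, mismatch = 0. Ties break toward more
Watson–Crick pairs, then the lexicographically smallest layout tuple, so
results are deterministic. A structure is rejected (`None`) when its score
is below 70% of its own maximum (2 × its stem positions) — configurable.

DHU-arm loss (the trnS1-AGN condition) is modeled as a layout whose DHU
arm is replaced by a plain 4–9-nt loop, accepted only when it *strictly*
out-scores every full-cloverleaf layout. Because the smallest full DHU arm
is 10 nt (2×3 stem + 4 loop), a replacement loop ≤ 9 nt cannot be imitated
by a full layout with identical downstream boundaries, which is what makes
the distinction decidable under a no-negative-score scheme.

## Control region

The region is derived from the annotation as (end(rrnS)+1 … start(trnM)−1)
on the circle — the text rule, which for the packaged study tables yields
335/347/280 bp — rather than trusting control-region table rows, whose
printed coordinates extend past the stated genome sizes and are flagged by
validation. Motif scanning reports 1-based positions within the scanned
sequence: all (possibly overlapping) ATAG and ATTTA occurrences, maximal
poly-T runs (≥7), poly-A runs (≥5) and (AT)n runs (n ≥ 3), each ATAG
paired with the nearest downstream poly-T starting within 20 nt of the
motif's end. The run minima encode the papers' qualitative "large"
stretches and are configurable; maximality means non-extendable (for (AT)n,
by a full AT unit).

## Supermatrices

Per-gene aligned coding sequences (equal lengths, divisible by 3, stops
removed) are an input contract enforced by a validator; alignment itself is
out of scope. Genes concatenate in the canonical mitochondrial positional
order (ND2, COX1, COX2, ATP8, ATP6, COX3, ND3, ND5, ND4, ND4L, ND6, CYTB,
ND1) — the source studies do not state their concatenation order, so it is
fixed here and config-exposed. PCG12 removes columns 3, 6, 9, … of each
gene (gap columns count toward the codon frame). In the AA dataset a codon
containing any gap becomes the gap character rather than X, preserving
missing-data semantics for downstream inference tools. Widths obey
3·W12 = 2·W123 and 3·Waa = W123 on gap-free input; partition intervals
tile the columns exactly.

## Synthetic-data generator

The generator emits the architecture the analyses assume: 37 genes + CR in
the derived lepidopteran order with trnM at position 1, PCG lengths/starts/
stops typical of pyraloid genomes (including the 682-bp COX2 with a
truncated single-T stop), tRNAs emitted from known template layouts with
all-reverse-complement stems plus a 5% wobble rate, trnS1 with the DHU arm
replaced by a loop, exact-composition rRNA blocks, and a control region
assembled as filler | ATAG | poly-T | filler | ATTTA | (AT)n | filler |
poly-A | filler with guard bases (placed by composition-preserving swaps)
keeping every planted run maximal at its planted coordinate. The truth
record stores every planted observable plus realized per-class base counts,
so each module's output can be scored exactly.

Numerical choices worth knowing:

* **Class A+T levels.** PCGs 0.78, control region 0.96 and whole genome
  0.81 are the study conditions; the tRNA (0.91) and rRNA (0.885) sampling
  levels are free parameters set by solving the class-mixture expectation
  so the realized whole-genome A+T centers on 0.81 (verified mean 0.810
  over 30 seeds). Two biases needed explicit correction: rejecting stop
  codons during PCG emission preferentially discards A/T-rich codons, so
  the per-base sampling level is raised by inverting the conditional
  expectation (bisection); and fixed anticodons plus wobble pairs pull
  realized tRNA composition a few points below its sampling level, which
  the tRNA/rRNA levels absorb.
* **Planted-fold uniqueness.** tRNAs are re-emitted (fresh randomness,
  capped attempts) until the planted layout is the unique fold optimum.
  This matters most for trnS1: on ~90% A+T sequence a random full-cloverleaf
  layout scores ~1.2 per stem position, and the best of ~80 such layouts
  beats a planted DHU-loss structure in most single draws, so the expected
  number of draws for trnS1 is ~5.
* **Divergence.** Genome sets substitute only mid-codon PCG sites (start
  and stop codons fixed, internal stops resampled), so substitution counts
  are exactly binomial and per-gene "alignments" are the identity — indels
  are deliberately excluded so supermatrix preconditions are testable
  without an aligner.
* **Determinism.** All randomness flows from one NumPy PCG64 generator
  seeded by `params.seed`; identical seeds give byte-identical genomes,
  annotations and truth records.

What the generator does *not* emulate: real codon-usage structure (codons
are i.i.d. given composition), rRNA secondary structure, indels, sequencing
error, and between-gene compositional heterogeneity beyond the class
means. Passing recovery tests therefore demonstrates the correctness of
the measurement code under the stated architecture, not robustness to
messy real annotations.

## Flagged inconsistencies in the packaged study tables

The printed organization tables are ingested as-is and compared against
their own coordinates; the validators flag rather than correct:

* the *D. latiterminalis* control-region row prints length 334 where its
  coordinates give 335;
* all three control-region rows end past the stated genome sizes (the rows
  appear to predate the final sequence rotation), which is why the region
  is derived from the rrnS→trnM rule instead;
* the printed rrnS-row spacers (0) ignore the unannotated gap before the
  control-region row (88/166/86 bp by coordinates);
* the *P. nigropunctalis* tRNA total is printed as 1452 in the text but
  sums to 1451 from the printed coordinates; the coordinate-derived value
  is reported.

## Scale of the shipped analyses

Synthetic-recovery checks run on 15-kb genomes; pooled fold-recovery
statistics use 10 genomes (220 planted tRNA structures), oracle
equivalence checks use 100 random sequences (folding) and 100 × 10 kb
strings (motif scanning), and skew antisymmetry is checked on 1,000 random
sequences. Whole-genome AT%/skew values of the deposited genomes
themselves, and all tree inference, require the GenBank sequences or
external tools and are intentionally outside the package's scope.
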