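# Methods

This note documents the models, rules and numerical choices behind
`srnanc`, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Read cleanup

Reads are fixed-length sequencer output carrying a ligated 3′ adapter.  The
insert is everything before the **leftmost** occurrence of an adapter prefix
of at least `min_overlap = 5` nt that either reaches the read's 3′ end or is
the full adapter.  Leftmost-wins yields the shortest credible insert, the
standard behaviour of adapter trimmers; requiring the prefix to be terminal
(or complete) is what distinguishes a ligated adapter from a chance internal
match.  Reads with no qualifying match are discarded as `no-adapter`.

Filters applied to the trimmed insert, each with a reason code:

* `contains-N` — exact-match mapping cannot place ambiguous bases, so these
  are dropped before trimming;
* `poly-A` — insert with ≥ 90 % adenine.  The threshold is a config value,
  not a community standard: 90 % tolerates a single miscalled base in a
  true poly-A artifact of the shortest retained length (16 nt);
* `5p-adapter` — insert beginning with ≥ 10 nt of the 5′ adapter's 3′ end.
  Anchoring at the insert start matches how adapter–adapter ligation
  chimeras arise; 10 nt makes a chance match (4⁻¹⁰) negligible at library
  scale;
* `too-short` / `too-long` — outside the 16–30-nt analysis window.

Quality scores are ignored throughout: every rule is sequence-only, so
FASTA input is sufficient.  Collapsing preserves counts per library and
orders unique sequences lexicographically for determinism.

## Mapping

`GenomeIndex` implements exact, all-occurrences, both-strand matching — the
contract of an `-n 0 -a` aligner run — as a 16-mer hash seed with full
verification.  k = 16 equals the minimum retained read length, so every
query has a seed.  Minus-strand hits are forward occurrences of the
reverse-complemented query; hits are ordered by (chromosome, position,
strand).  The implementation is deliberately simple enough to be checked
exhaustively against a naive sliding-window scan, which the test suite and
the acceptance script both do on seeded genomes up to 50 kb.

Unmapped sequences pass through four rescue stages **in order**: rRNA
repeat unit, exon–exon junction, CCA-tailed tRNA, tRNA with exactly one
substitution.  The order among rescues is a design choice (the stages are
almost disjoint in practice; rRNA first mirrors the dominant source of
rescueable reads).  The junction library uses a 29-nt flank — the maximum
read length minus one — so any junction-spanning retained read is an exact
substring.  One-mismatch rescue accepts exactly one substitution (zero
would have mapped or been caught earlier; two is rejected) and pre-labels
the sequence as tRNA-derived; ties among tRNA references fall to file
order, which only affects the reported reference id, never the class.

Sequences still unplaced are tested for 3′ untemplated additions: the
**longest** prefix with an exact genomic occurrence is found, and if it is
at least `min_prefix = 17` nt (and shorter than the read) the remainder is
recorded as the untemplated tail and the prefix re-enters the mapped set.
Searching the longest prefix (rather than any ≥ 17) makes the recorded tail
minimal, which is the conservative reading of an untemplated addition.
Because prefix matching is monotone, the implementation walks lengths
downward and stops at the first hit.

## Annotation cascade

Each mapped sequence gets exactly one label.  Classes are tried in a fixed
priority order (miRNA → mitochondrial RNA → rRNA → ITS → ETS → box H/ACA
snoRNA → box C/D snoRNA → scaRNA → tRNA → snRNA → RNaseP → SRP RNA → Xist →
7SK → H19 → vRNA → hY RNA → RNaseMRP → mRNA → tRNA 3′ trailer), and a
sequence leaves the pool at its first match, so earlier classes always win
deliberate overlaps.  A sequence matches a class when it is an exact
sense-strand substring of any reference of that class; tRNA additionally
matches through its CCA-tailed form.  After the ordered list, sequences
with a genomic hit overlapping a repeat locus by ≥ 1 nt become `genomic
repeat` (repeats are loci, not transcripts), and the remainder `unknown`.
For tail-trimmed sequences the retained genomic prefix is what is matched.

Composition tables report raw counts and percentages per library;
the 7SK/vRNA/RNaseMRP/RNaseP/Xist/H19 classes are rolled up into a single
`miscRNA` row for presentation only.  Percentages print at one decimal,
two decimals below 1 %.  Per-class totals are guaranteed to sum exactly to
each library's mapped total (conservation is asserted in tests).

## tRNA 3′ trailers

The trailer region of a gene is the 40 genomic nt immediately 3′ of the
annotated tRNA end, read on the gene strand (minus-strand regions
reverse-complemented; chromosome-end truncation is flagged, not fatal).
A sequence is a trailer of gene *g* iff it perfectly matches region(*g*)
starting at position 1 or 2 — position 2 absorbs the one-base uncertainty
of RNase Z cleavage.  A sequence matching several genes' regions joins
every matching gene's isotrailer set but is counted once in the class
composition; gene-level and class-level views double-count by construction,
which is the only consistent way to report both.

A trailer's abundance is the sum over its isotrailers; trailers are kept
when that sum **exceeds** 10 raw reads in at least one library (strict,
configurable).  The reported sequence is the most abundant isotrailer in
the cytoplasmic library (ties: lexicographic).  A U-tail is a terminal run
of ≥ 2 uridines — the templated remnant of the Pol III oligo-U terminator.
End heterogeneity is summarized per gene as the count-weighted Shannon
entropy of start offsets (support {1, 2}) and of end positions.

## Quantification

RPM normalizes to each library's mapped total: `raw / total × 10⁶`; the
per-library RPM values of all mapped sequences therefore sum to exactly
10⁶.  N/C is the ratio of nuclear to cytoplasmic RPM and is scale-invariant
in sequencing depth.  Sequences observed in one compartment only carry a
categorical flag (`nuclear-only` / `cytoplasmic-only`) rather than 0 or ∞,
and are reported as separate fractions.  Eligibility for N/C analyses is
raw count > 10 in at least one library — raw, not RPM, because the
threshold models counting noise, which normalization does not change.

isomiR families are keyed by mature miRNA: a miRNA-labelled sequence is
assigned to the mature arm it overlaps the most within its matched hairpin.
Representatives are per-library argmax by raw count (ties: lexicographically
smallest sequence — ties are theoretically possible, so the rule must be
explicit, but they essentially never occur in real counts).  Families whose
representatives differ between libraries are flagged discordant and
excluded from representative-level analyses.  The cross-compartment
correlation is squared Pearson on representative RPM, computed on the
linear scale by default with a log10(x+1) option; two-point inputs are
legal but flagged degenerate.

3′-end motif analysis extracts the terminal hexanucleotide and compares
N/C between carriers and non-carriers of a terminal motif (suffix match,
3–7 nt) by medians plus a two-sided Mann–Whitney test; the test is skipped
(reported as None) when either group has fewer than two members.

Report rounding is decimal half-up: 2 dp for miRNA N/C, 5 dp for trailer
N/C, 1 dp for RPM.

## Synthetic data

`srnanc.simulate` builds a 120-kb chromosome plus a 12-kb mitochondrial
contig with planted, non-overlapping features: 25 miRNA hairpins (22-nt
mature arms), 15 tRNA genes each followed by an engineered 40-nt trailer
region whose planted trailer ends in a 3–5-nt templated U-run with
probability 0.8, 8 box C/D and 5 box H/ACA snoRNAs, 3 scaRNAs (one
ACA45-like, given a miRNA-like compartment ratio), 5 multi-exon mRNAs,
3 repeat families at 3 loci each, and an off-genome rRNA repeat unit
(5′ETS–18S–ITS1–28S–3′ETS) so rRNA reads exercise the rescue path.
Feature placement rejects overlaps so cascade priority is tested only with
deliberately constructed overlap fixtures.

Every source fragment receives a log-uniform abundance (20–2000) and a
compartment ratio equal to its class ratio times log-normal jitter
(σ = 0.5 in log2).  Class ratios point the same directions fractionation
studies report: snoRNAs strongly nuclear (C/D 40, H/ACA 8, ETS 10),
mitochondrial fragments and tRNA trailers strongly cytoplasmic (0.1 and
0.06), tRNA 0.25, miRNA near parity (1.2).  Read counts are Poisson at the
configured depths (default 100,000 reads per library), so the planted
ratio of library shares is the exact expectation of the pipeline's N/C
estimator and its sampling error is analytic (≈ √(1/E[n_N] + 1/E[n_C])/ln 2
in log2).  Error channels, each individually switchable: miRNA 3′-end
jitter (−2..+2, templated from the hairpin), trailer 3′ jitter and
offset-2 starts, untemplated 1–3-nt tails over {U, A} whose first base is
forced to differ from the templated continuation, CCA-tailed tRNA 3′
fragments (rate 0.2), single-substitution tRNA reads (rate 0.1), and
poly-A / 5′-adapter / adapter-less contaminants (1 %, 1 %, 2 %).

What the generator does **not** emulate: general sequencing error (only
the tRNA substitution channel), quality scores, PCR duplication bias,
ligation sequence bias, 5′-end heterogeneity of miRNAs, antisense
transcription, and genuine sequence homology between features (features
are random, so cross-class ambiguity is rare rather than realistic).
Passing recovery tests therefore demonstrates the pipeline's logic is
correct under its own assumptions, not that real libraries are free of
mapping ambiguity or annotation overlap — on real genomes the cascade
order materially shapes class totals, which is exactly why the order is
fixed and documented.

## Numerical and degenerate-input choices

* Internal coordinates are 1-based closed; BED (0-based half-open) and
  GFF3 (1-based closed) are converted at the parse boundary.
* N/C with both compartments zero, empty eligible sets, zero library
  totals, correlations with < 2 points or zero variance, and hexamers of
  sequences < 6 nt all raise `ValueError`; chromosome-end trailer
  truncation and empty length histograms warn instead.
* Determinism: unique sequences are processed in lexicographic order, all
  randomness flows from a single integer seed through
  `numpy.random.default_rng`, and the run manifest checksums every input
  and output so identical configs reproduce identical bytes.
* Mapping, trailer calling and trimming are each validated against an
  independent brute-force oracle in the test suite; oracle code never
  shares logic with the implementation it checks.

## Problem sizes

The test suite and the acceptance script run the full pipeline at 100,000
reads per library (the end-to-end recovery condition), mapper-oracle
genomes of 5–50 kb, and 1,000 planted-tail reads for the trimming oracle.
These sizes make every statistical check well-powered (per-source expected
counts reach the hundreds) while a complete run stays in the tens of
seconds on one CPU.

## Known limitations

* The mapper is exact-match only: no gaps, no quality-aware mismatches;
  the single permitted mismatch lives in the tRNA rescue stage alone.
* Sense-strand substring matching cannot annotate antisense-derived sRNAs.
* The trailer caller assumes RNase Z cleavage within one base of the
  annotated gene end; trailers of mis-annotated tRNA genes are missed.
* mRNA matching uses spliced transcripts; reads from retained introns
  land in `genomic repeat`/`unknown`.
* Multi-gene trailer assignments double-count at the gene level by design
  (see above); consumers needing strictly additive gene counts should
  deduplicate on sequence.
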