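# Methods

## Scope and model

`exotsrna` implements a complete desk-scale analysis of exosomal
tRNA-derived small RNAs (tsRNAs) from single-end small-RNA-seq reads:
adapter trimming and tag collapsing, hierarchical small-RNA class
annotation against per-class references, positional classification of
tRNA-derived tags, descriptive profiling (class / type / isoacceptor /
length), replicate concordance, and two-group differential expression.
A paired synthetic-data generator emits libraries with known per-read
ground truth so that every stage can be validated end to end.

### tRNA reference model

Mature tRNAs are modeled as the spliced gene body plus the
non-templated 3' CCA; precursors as 5' leader + unspliced body + 3'
trailer (default 50 nt flanks, truncated at contig edges with the
actual lengths recorded). The trailer carries the genomic poly-T tract
transcribed as the poly-U tail that defines precursor-derived 3'U tRFs.
All coordinates are 0-based half-open; mature coordinates include the
CCA, so the mature 3' end equals the sequence length. Genes with
identical mature sequences (multicopy families) are collapsed to one
representative so read counts are not split across exact duplicates;
copy suffixes (`tRNA-GlyGCC-1`, `-2`, ...) disambiguate distinct
sequences within an isoacceptor. The anticodon locus is taken from the
annotation when present, with mature positions (33,36) as the canonical
fallback. Histidine −1 G addition and other non-templated edits beyond
CCA are not modeled.

### Preprocessing

Reads are kept when mean Phred ≥ 20, no base < 5 and no N ("high
quality" is operationalized here; the thresholds are flags). The 3'
adapter is mandatory — with 16–40 nt inserts on ≥ 50 nt reads every
genuine insert reads through into it — so reads without a detectable 3'
adapter are discarded; the 5' adapter is optional and absent reads pass
unmodified. Matching requires overlap ≥ 6 nt with mismatch fraction
≤ 0.1; for the 3' adapter the leftmost qualifying position wins (keeps
the shortest insert, the conservative anti-chimera choice); for the 5'
adapter exact overlaps beat longer mismatched ones. Inserts of 16–40 nt
(bounds inclusive) are collapsed into unique sequence tags with counts.
A conservation report guarantees
`reads_in = discarded_quality + discarded_no_adapter + discarded_length
+ retained` on every run.

### Alignment and class annotation

Whole-genome mapping is replaced by ungapped, full-length alignment of
tags to curated per-class references (miRNA, tRNA, rRNA, snoRNA, snRNA,
piRNA), with at most one mismatch by default — 16–40 nt tags rarely
tolerate indels, while modification-induced substitutions motivate
allowing one. Reporting is best-stratum: exact hits suppress mismatched
ones (prevents paralog bleed). Candidates come from an 8-mer seed index
with pigeonhole seeding (a hit with ≤ k mismatches contains at least
one exact chunk among k+1); a brute-force Hamming scan backstops
settings the seed length cannot cover, and the two paths are tested for
exact agreement against an independent all-offsets oracle. Each tag is
assigned the highest-priority class with ≥ 1 alignment (default
priority miRNA > tRNA > rRNA > snoRNA > snRNA > piRNA > other);
multi-mapping within the winning class gets uniform 1/n weights.
Within the tRNA class, mature hits take precedence over precursor hits
(the mature body is a substring of its precursor) *except* that
precursor alignments crossing the mature-3' boundary are retained —
they carry the only signal distinguishing 3'U tRFs.

### tsRNA classification

For an alignment at (start, end) on a mature of length L:

* `tRNA-5` iff start ≤ δ5 (default 1);
* `tRNA-3` iff end ≥ L − δ3 (default 2, absorbing partial CCA);
* both conditions → `unclassified` (near-full-length tRNA carryover is
  not a fragment);
* otherwise `tRNA-i`.

tRNA-5/tRNA-3 fragments are subtyped as halves (tRH) when they are
≥ 28 nt *and* the internal breakpoint falls within the anticodon
interval padded by 2 nt — the signature of angiogenin cleavage in the
anticodon loop — else fragments (tRF); internal fragments are tRFs by
definition. Precursor alignments crossing the mature-3' boundary whose
last 2 bases are T are `3pU-tRF`. The tolerances are this package's
operationalization (declared, configurable), not literature constants.
Multi-mapping tags are resolved by majority class by weight with ties →
`unclassified`; isoacceptor weight is split fractionally across the
winning alignments. Species are keyed as
`tRNA-<isoacceptor>-<5|i|3|3pU>|<tag sequence>` (field naming style,
e.g. `tRNA-GlyTCC-5`).

### Profiles and statistics

All fractions are over weighted read counts (the convention behind
"percentage of small RNAs" statements), respecting fractional
multi-mapping weights; each fraction vector sums to 1 within 1e-9.
Length histograms are integer-binned over the retained 16–40 nt range.
CPM uses the total annotated (non-"other") weighted count as library
size. Replicate concordance is Pearson r of log2(CPM+1) over the union
of species present in either replicate (absent = 0; an intersection
would inflate r). At modest depth the per-tag tsRNA species universe
contains a long tail of sub-Poisson species (rare 5'-end positions,
interior fragments, error-derived tags), so the replicate scatter is
computed at the aggregation replicate-QC scatters use — weighted counts
per annotated reference (each miRNA/rRNA/... reference; collapsed
mature tRNA), where the multinomial resampling argument actually holds;
`replicate_correlation` itself is agnostic to the species vector it is
given. The ΔΔCt utility implements
2^−((CtT,case − CtR,case) − (CtT,ctrl − CtR,ctrl)) for RT-qPCR relative
quantification against a reference RNA (e.g. miR-16).

### Differential expression

Species with CPM ≥ 5 in at least min(group sizes) samples are tested
with a two-sided Welch t-test on log2(CPM+1); Benjamini–Hochberg
adjustment runs across the post-filter species; calls require q ≤ 0.05
and |log2FC| ≥ 1 (all flags). A simple transparent test is preferred
over a count model: group sizes are small (5 vs 5 in the emulated
design) and the dispersion structure of exosomal tsRNA libraries is
unknown; negative-binomial GLMs are a non-goal. Degenerate species
(zero variance in both groups) get p = 1 when means agree, else p = 0
with a `degenerate` flag. BH is delegated to
`statsmodels.multipletests(fdr_bh)` behind `bh_adjust` and is tested
against an independent quadratic step-up oracle.

## Synthetic data: what it emulates, and what it does not

The generator's defaults encode the study conditions the analysis
expects:

* class mixture with tRNA-derived reads at 5% of the library (miRNA
  0.70, rRNA 0.15, snoRNA 0.04, snRNA 0.03, piRNA 0.03);
* tsRNA type mixture 90 / 1 / 9 % for tRNA-5 / tRNA-i / tRNA-3; the
  precursor 3'U channel defaults to 0 (precursor-derived tsRNAs are a
  minor exosomal component) and is switched on explicitly where
  exercised;
* 97% of tsRNA mass on Gly/Glu/Lys/Val isoacceptors (two anticodons
  per amino acid for the major four);
* tRNA-5 5' fragments starting at the mature 5' end with endpoints
  from a discretized Normal(32.5, 1) — a 32–33 nt mode; tRNA-3 lengths
  peaked at 16–18 nt; tRNA-i bimodal (16–17 and 28–32 nt) with strictly
  interior placement; 3'U tRFs crossing 2–5 nt into the poly-T trailer;
* substitution errors at 0.001/base (no indels — internally consistent
  with the ungapped aligner), reads of 50 nt as insert + 3' adapter,
  constant high base qualities (Q37);
* two-group designs spike selected isoacceptor channels by stated log2
  effects (control N1..Nn vs case T1..Tn, default 5 vs 5); per-sample
  RNG streams derive from `default_rng([master_seed, sample_index])`
  so any sample regenerates alone.

For differential-expression calibration at realistic species counts, a
count-matrix generator draws species baselines 2^U(6, 12) and
negative-binomial counts with dispersion 0.05 (CV ≈ 0.22 for abundant
species): well-expressed, reliably quantified species for which a
4-fold spike is the strong effect the emulated design intends. These
two knobs are deliberate: at markedly higher dispersion a 4-fold change
is not reliably detectable by any two-sample test at n = 5, which is a
statement about the design, not the implementation.

The generator does *not* emulate: realistic quality-score profiles,
PCR duplicates, ligation bias, indels, 5'-adapter read-through,
Histidine −1 G, mitochondrial tRNAs, or genomic multi-mapping outside
the curated references. Passing tests therefore demonstrate internal
correctness of the algorithms under the stated statistical structure,
not robustness to every artifact of real libraries.

## Numerical and procedural choices

* Deterministic everywhere: profiles and pipeline outputs are
  byte-identical across reruns with the same config and seed; a
  manifest records inputs (SHA-256 prefixes), parameters and stage
  conservation counts.
* Tie-breaks: leftmost 3' adapter occurrence; majority-by-weight class
  resolution with ties → unclassified; alignments sorted by
  (reference, start) before weighting.
* Degenerate inputs are errors, not silent zeros: empty record sets,
  empty replicates, non-positive library sizes, < 2 samples per group
  for DE, malformed sample sheets and FASTQ records (reported with
  their record number) all raise with distinct messages.
* Problem sizes in the validation suite: 50,000-read libraries for
  composition/length recovery, 2 × 100,000 reads for replicate
  concordance, 20 × (1,000 species, 5 vs 5) null matrices for type-I
  control, and one spiked 1,000-species matrix for recovery — sizes at
  which the binomial/multinomial error bounds quoted in the tests hold.

## Known limitations

* Class annotation is only as good as the supplied per-class
  references; absent classes are reported as "other".
* The positional tolerances (δ5, δ3, half length, anticodon window)
  are declared operational choices; against databases drawing different
  breakpoint windows the class boundaries may shift by 1–2 nt.
* Uniform multi-mapping weights do not attempt EM-style reassignment.
* The Welch/log-CPM DE stage is a pragmatic small-n choice, not a
  dispersion-modeling method; counts near zero rely on the +1
  pseudocount.
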