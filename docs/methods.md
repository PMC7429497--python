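# Methods

## The screen and its statistics

A randomized-promoter 5′RACE-Seq screen measures how the initially
transcribed region (ITR) of a phage promoter modulates transcriptional
output. A dsDNA template carries the core promoter (−17..−1; +1 fixed at G)
followed by a randomized +2..+16 segment. In vitro transcription converts
each template molecule into RNA in proportion to its promoter strength;
5′RACE-Seq then reads each transcript's exact 5′ terminus (Read1, antisense)
together with a unique molecular identifier (Read2). Direct sequencing of
the untranscribed template provides a *background library* that absorbs
synthesis bias.

The central statistic is the background-normalized relative abundance of a
motif m over a position span (typically +2..+8 or +4..+8):

    rel(m) = ( c(m) / N ) / ( c_bg(m) / N_bg )

where c and c_bg are pooled read counts in the RACE and background
libraries and N, N_bg their totals. Under a null screen (no sequence
preference) rel(m) = 1 for every motif; promoter effects appear as
departures on the log₂ scale. Ranks over rel define "better" ITRs; the
activity fold between two quantiles of rel summarizes the dynamic range of
the effect.

Both library totals enter as frequencies, so rel is invariant to the
background sequencing depth; this is the scale-invariant reading of
"divide by the corresponding background counts" and is asserted by a
property test.

## Generative model (`synthetic_screen`)

The simulator is first-class, tested code; its defaults are the screen's
study conditions.

**Template library.** `n` molecules with i.i.d. per-position bases drawn
from a synthesis bias (default A/C/G/T = 0.28/0.22/0.26/0.24 at every
position — randomized oligo pools are never perfectly equimolar, and the
background-normalization step exists precisely to cancel this). A (15, 4)
matrix allows position-specific bias, including degenerate positions used
to restrict a run to one +2/+3 class.

**Activity model.** The transcription weight of a molecule factorizes as
`class_factor(+2/+3) × itr_factor(+4..+8)` (+1 is fixed):

- `t7_like` — the 1024 ITR factors are exactly log-uniform over a
  `fold_range` (default 5): random scores with an additive AT-content tilt
  are rank-transformed to evenly spaced values on [0, 1] and exponentiated,
  so max/min = fold_range holds exactly and AT-rich motifs tend to rank
  high while remaining sequence-specific (two motifs of equal AT content
  can sit at opposite ends, as observed for real ITRs). The 16 class
  factors span 4-fold with the G triplet on top.
- `sp6_like` — activity depends on +2/+3 only (16 levels spanning
  `fold_range`, AA on top); the ITR has no effect.
- `uniform` — all weights 1 (null screen for calibration).

**5′-end events.** On G-triplet starts the polymerase slips and adds one
extra G with probability 0.79, two with 0.02 (zero for other classes);
reverse transcription appends one non-templated C with probability 0.05
regardless of class. Both events are visible in Read1 as extra Cs after
the +1 complement, and are *indistinguishable per read* — exactly as in
the real assay. The filter's AA/CA/CC whitelist records 0/1/2 visible
extras; a read with three extras (two slips + RT C) still shows the CC
pattern and, with the default poly(A) rule, passes with its third C inside
the window (9/10 A = 0.9 ≥ 0.9). The compound probabilities among accepted
reads are therefore

    P(≥1 extra C) = 1 − (1 − p₁ − p₂)(1 − r)
    P(extra_c = 2) = p₂ + p₁·r

with p₁, p₂ the sliding probabilities and r the RT rate; recovery tests
and the deconvolution in `experiments` use these forms. The RT baseline is
directly estimable from classes where sliding cannot occur, which is why
the extra-G report is laid out per +1..+3 class.

**Sequencing.** Read1 = [15 nt antisense 15mer][C][0–3 extra Cs][poly(A)
fill] at 35 nt; Read2 = [5 nt UMI][constant fill]. Substitution errors are
i.i.d. at 0.001/base (no indels, no quality model — qualities are written
as constant 'I' and ignored downstream). PCR duplication re-emits a
molecule's reads verbatim (same 15mer, UMI and error pattern) at rate 0.1,
matching an exact-match deduplication contract. Optional dark-cycle loss
drops reads carrying a long G run with a set probability (off by default);
it models two-channel sequencers in which G is the dark state.

**What the generator does not emulate** — and hence what green tests do
not show about real data: PCR amplification bias beyond duplication,
indels, quality-dependent errors, abortive transcripts shorter than the
read, template-switching artifacts, and real oligo synthesis error modes
(deletions dominate in practice). The homopolymer under-calling of real
dark-cycle sequencers is modeled only as an optional uniform loss.

## Filter cascade (`read_processing`)

Stage order: contaminant removal → 15mer–UMI dedup → structural filter →
reverse-complement → constant filter. Read positions are 1-based;
promoter positions are TSS coordinates (+1 first transcribed base, no 0).

- **Contaminant filter**: exact k-mer index (default k = 21, both strands)
  over supplied contaminant sequences; a read is discarded at ≥ 1 hit.
  This replaces an external aligner with the contract it implements: a
  random 35-mer false-positives against a 5 kb contaminant with
  probability < 5000/4²¹.
- **Dedup**: first occurrence of each (Read1 15mer, UMI) key survives,
  order preserved. Dedup precedes the structural filter; a
  `dedup_after_structure` switch exposes the alternative order.
- **Structural filter**: accept iff base 16 = C, bases 17–18 ∈ {AA, CA,
  CC} (extra_c = 0/1/2), and ≥ 90% of the 10 bases after the extra-C block
  are A. Window (10) and fraction (0.9) are config keys: the underlying
  protocol only guarantees "a poly(A) tail", so the rule is a repo
  decision, chosen to tolerate one sequencing error in the tail.
  Note the whitelist is over positions 17–18 given C at 16, so the
  triplet CCC (= C + "CC") is accepted with extra_c = 2.
- **Constant filter**: the +2..+11 10mer is discarded if it lies within
  Hamming distance 1 of any 10-window of any configured constant sequence
  (both strands), via a precomputed 4¹⁰ lookup table. The shipped
  constants are synthetic stand-ins for a real library's backbone and
  adapters (arbitrary fixed sequences; the real ones are run-specific
  inputs).

All filters are vectorized over uint8 code matrices; FASTQ files and the
in-memory simulator output run through the same code path (a round-trip
test asserts identical results), which is what keeps 2×10⁷-read runs
around two minutes on one CPU.

## Motif statistics (`motif_stats`)

- `min_bg = 10` background reads admit a motif into ranking; below that
  the denominator variance is unbounded and the motif is flagged
  `low_background` (configurable).
- **Homopolymer rule**: a motif is flagged when its +1-prefixed sequence
  (e.g. GGG + the +4..+8 motif in the G-triplet context) contains a run of
  ≥ 4 identical bases (any base by default). The exact rule a given
  sequencer/pipeline needs is not recoverable from first principles, so
  run length and base set are config keys; flagged motifs keep their
  counts but lose rank and are excluded from group summaries and fold
  ranges.
- **Ranks** are dense, 1-based, by descending rel with lexicographic
  tie-break — a deterministic permutation of the unflagged motifs.
- **Quantiles** everywhere are linear-interpolation (type 7, numpy
  default); group whisker bounds are q1 − 1.5·IQR and q3 + 1.5·IQR.
- **Wilson 95% intervals** (statsmodels) accompany the extra-G fractions;
  they behave at fractions near 0 (the two-extra case) where normal
  intervals fail.
- **Composition**: per position, the RNA/background frequency ratio
  renormalized to sum to 1 across bases, so "no preference" reads 0.25.

## Design layer (`promoter_design`)

Scoring locates the configured core promoter (default: canonical T7
consensus TAATACGACTCACTATA; overridable — SP6 ships as a preset),
extracts the motif on the supplied table's span, and reports
rel/rank; a non-GGG +1..+3 context draws a warning because most tables
are computed within the G-triplet context. The optimizer enumerates *all*
insertion/substitution combinations within the budget inside the editable
window (complete enumeration, duplicates collapsed to minimal edit count)
and orders candidates by rank, then fewest edits, then sequence. Budgets
≤ 3+3 stay well under a second. The upstream element of `assemble_primer`
is a required user input (its exact sequence is construct-specific); an AT
fraction < 0.75 draws a warning since only AT-rich elements improve
polymerase recruitment at low template concentrations.

## Problem sizes and acceptance conditions

The recovery experiments (`racescreen.experiments`, used by the test suite
and `scripts/acceptance.py`) run at these scales, chosen so each statistic
is measured with comfortable precision while a full run stays within a few
minutes on one CPU:

- ITR recovery: one T7-like screen per seed at 2×10⁷ reads (library and
  background at the same depth), fold recovered between the 2.5%/97.5%
  quantiles of rel over the G-triplet context (~2.4×10⁶ reads over 1024
  motifs). The true log-uniform 5-fold effect has a 4.61-fold
  inter-quantile range; the band [4, 6] allows estimation noise.
- Extra-G coverage: 50 replicates of 1.3×10⁵ GGG-restricted reads
  (degenerate +2/+3 bias), sequencing errors off so the per-replicate
  estimate is a clean binomial against the compound probabilities above.
- Null calibration: uniform activity at 1.2×10⁷ foreground and background
  reads; per-motif z = log₂rel / SE with SE = √(1/c + 1/c_bg)/ln 2. The
  nominal |z| > 3 rate is 0.27%; the asymmetry of the constant filter
  (applied to RACE reads, not background) inflates it mildly, and the
  acceptance bound is 1%. The 1%–99% fold under the null at this coverage
  is ≈ 1.3, bounded at 1.5.
- Replicate agreement: two independent screens of one model at 10⁷ reads;
  Pearson of log₂rel ≥ 0.9 over shared unflagged +2..+8 motifs.

## Known limitations

- The simulator samples transcripts with replacement from the library
  (molecules are not consumed); fine at the simulated copy numbers.
- Dedup keys are exact; UMI sequencing errors create false uniques at
  ~umi_len × error_rate per read and are not collapsed.
- The constant filter's false-positive rate on genuinely random 15mers is
  ~1% at the default constants (12 k of 4¹⁰ 10mers are within one
  mismatch of a constant window); it is motif-specific and slightly
  widens the null distribution, visible in the calibration numbers.
- `activity_range` between extreme quantiles (0, 1) is noise-inflated;
  use interior quantiles for fold estimates.
- SP6 mode reuses the T7 read structure (+1 G, same filter); polymerases
  with different initiation chemistry would need a different structural
  rule.
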