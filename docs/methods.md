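# Methods

## Problem and model

A microsatellite (MS) is a tandem repeat of a 1–6 bp motif; copies may be
exact (perfect MS) or mutated (approximate MS). `ssrscan` locates both in
DNA sequences via three stages: a scoring transform, a two-state HMM, and
a logistic filter. The design premise is that all parameters are fixed by
supervised learning on an annotated chromosome, so end users never tune
anything.

### Scoring transform

Each position `i` starts a query word of length `n`. The word is compared,
without gaps, to every candidate word lying fully inside the two flanking
windows; the score of `i` is the maximum identity score (count of
positions with equal bases). Conventions that the underlying idea leaves
open, fixed here once:

- The left window is the `m` positions immediately preceding `i`; the
  right window is the `m` positions immediately following the *end* of the
  query word. The query word is therefore never compared against a
  candidate overlapping itself, which would guarantee a meaningless
  self-match. A consequence: a repeat whose period `p` is smaller than `n`
  is still detected through copies at offsets ≥ `n` (a repeat tract of
  span ≥ `n + p` contains one), but an isolated tract shorter than `2n`
  cannot achieve a perfect score.
- Candidate words must lie fully inside window ∩ sequence; words
  straddling a window edge are not considered. Windows are truncated at
  sequence boundaries.
- `N` matches nothing, including another `N`. A query word containing `N`
  scores 0; candidate words containing `N` are skipped. N runs therefore
  sit firmly in the background state.
- Positions within `n − 1` of the sequence end have no complete query word
  and score 0.

The implementation runs one vectorized pass per candidate offset
(`2(m − n + 1)` passes), giving `O(m·h)` time and `O(h)` memory; the same
shifted-match array serves the left and right windows by symmetry. A
quadratic brute-force implementation in the test suite checks equality
position-by-position.

Defaults: `n = 6` bp (the longest MS motif; shorter motifs tile into 6-bp
words) and `m = 24` bp. Larger windows raise background scores — the
probability that a random flank contains a good match grows with window
size — while repeat scores are already saturated, so enlarging `m` blurs
the two states; `m = 24` keeps the two emission distributions well
separated and the runtime low.

### Detection component

The HMM has two states, background (non-MS) and repeat (MS), with discrete
emissions over scores `0..n`. Supervised training counts, from score
series paired with per-position truth labels:

- priors: state frequencies at the starts of 500-bp non-overlapping
  training segments (the last partial segment is kept);
- transitions: within-segment state bigrams (not counted across joins);
- emissions: per-state score frequencies.

All tables receive add-one smoothing before normalization, so no emission
is zero and decoding never underflows on unseen scores. Decoding runs on
the whole unsegmented sequence in log space; segmentation affects only the
training counts. Viterbi ties break toward the background state, making
decoding deterministic and conservative. Maximal MS-state runs become
candidate intervals; a candidate overlapping an N run is clipped to its
non-N parts (N positions carry score 0 and would never be honest repeat
calls) and dropped if nothing remains.

### Filtering component

Candidates are summarized by length (bp) and average score. Both are
z-scored with the mean and standard deviation of the *pooled*
positive-plus-negative training detections (population SD, ddof = 0), and
a logistic GLM on the z-scores produces the final confidence. Training
labels follow the shuffled-null protocol: candidates on the training
sequence that overlap the truth annotation by ≥ 1 bp are positives (+1);
candidates found in the zero-order shuffle of that sequence are negatives
(−1); unannotated real-sequence candidates are *discarded*, since an
annotation may simply have missed a genuine repeat. The fit is
maximum-likelihood logistic regression by iteratively reweighted least
squares with an L2 ridge of 1e-6 (so the Hessian stays invertible on
separable data), convergence at max |Δparameter| < 1e-8, at most 100
iterations. The ±1 labels map to {0, 1} internally for the Bernoulli
likelihood. A detection exactly on the decision boundary is kept (≥ θ).
Threshold θ = 0.5 by default; θ = 0.99 is the strict preset for AT-rich
genomes, where a zero-order shuffle is itself accidentally repetitive and
the null-based filter must demand near-certainty.

### Evaluation measures

All measures work on merged interval sets, so splitting or reordering
calls never changes them. Sensitivity of tool *a* to reference *b* is
`100·O_ab/L_b` (bp of overlap over bp of reference). FPR is
`10⁶·L_a/S` for detections on a zero-order shuffled sequence of length
`S`, optionally excluding detections inside supplied intervals (for
genomes whose shuffles contain real low-complexity tracts). Modified
precision is `100·O_ref,a/(O_ref,a + L_a^shuffled)`: false positives are
counted on the shuffle, because unannotated real-sequence detections are
not necessarily wrong. Percentage predicted is `100·L_a/T`. `S` and `T`
are whole-sequence lengths, N runs included — only non-N positions are
permuted by the shuffle, but the denominators use the full length.

### Training pipeline

`train_full` splits the chromosome into three contiguous spans of
near-equal length (boundaries at `⌊L/3⌋` and `⌊2L/3⌋`); annotation
intervals crossing a boundary are clipped there. The HMM is trained on the
first (training) span, the GLM on labeled candidates from the training
span and its shuffle, and all three spans are then evaluated
(sensitivity, FPR, precision, PP), so over-fitting is visible as a
train/test gap. All randomness (shuffles) derives from a single seed;
retraining with the same seed reproduces the model file byte for byte.
Circular chromosomes are treated as linear. Multi-record FASTA input is
processed record by record.

## Synthetic data

The generator stands in for a repeat-annotated real chromosome, producing
a sequence plus an exact truth annotation:

- Background: i.i.d. bases with configurable composition. Defaults to
  uniform; the `AT_RICH` preset (0.40/0.10/0.10/0.40) emulates a strongly
  AT-biased genome (~80% A+T), the regime where shuffled nulls break down.
- Planted loci: motif length uniform in 1–6 bp, copy number uniform in
  5–50, per-locus substitution rate drawn uniformly from [0, 0.20]
  (mixing perfect repeats with degenerate ones up to the 20% divergence
  where annotations conventionally stop calling a tract a microsatellite).
  Substituted bases are drawn uniformly from the other three. Degradation
  is substitution-only because the scoring transform is gapless;
  indel-degraded repeats are a stress case, not a training regime.
- Placement: uniform, non-overlapping, with ≥ 48 bp (2m) between loci so
  the flanking windows of distinct loci never interact; loci are planted
  until the target density is reached. Default density 0.011 — the
  genome-scale rarity of microsatellites that the background-state prior
  (≈ 0.989 vs 0.011) encodes.
- Optional N runs (geometric lengths) are placed outside loci; the default
  is none, i.e. a gapless contig. N handling is exercised separately in
  the tests.

What the generator does *not* emulate: transposable elements, low-
complexity tracts below the MS definition, composition heterogeneity along
the chromosome, and indel-mutated repeats. Real background is more
repetitive than i.i.d. sequence, so results on synthetic data bound the
easy direction: passing the planted-repeat benchmark shows the machinery
is correct and calibrated for its stated conditions, not that real-genome
FPRs will be equally low.

## Problem sizes and numerical choices

The end-to-end benchmark in the acceptance suite trains on a 2-Mb
synthetic chromosome (fixed seed), a size at which every span statistic is
stable while the full protocol (simulate, score, decode, shuffle, label,
fit, evaluate three spans) completes in seconds. Oracle-equivalence checks
use exhaustive enumeration at small sizes (all `2^L` paths for `L ≤ 12`;
quadratic scoring up to 2 kb); parameter-recovery checks use 10⁶ HMM
symbols and 10⁵ logistic draws.

Other numerical details: Viterbi and path probabilities in natural-log
space with `log 0 = −inf`; model files store floats in shortest-repr form
so write→read round-trips are exact; probability rows are validated to sum
to 1 within 1e-9; GLM training warns (but proceeds) below 10 examples per
class and refuses single-class input.

## Known limitations

- Gapless matching: an indel inside a repeat tract splits its score run;
  gapped word alignment is a possible extension.
- Tracts shorter than `2n` with period < `n` cannot reach the maximum
  score (see window placement above) and are often filtered; very short
  loci (e.g. five copies of a mononucleotide) are generally undetectable
  by design.
- The filter uses only length and average score; per-motif thresholds and
  richer features are out of scope.
- Training needs the shuffled training span to yield at least one (ideally
  ≥ 10) HMM detections; on very small or extremely clean sequences the
  pipeline stops with an explicit error instead of fitting a degenerate
  filter.
- With small training pools the two GLM weights are noisy and their
  ordering (length vs average score) can fluctuate; the ordering
  stabilizes, with length dominating, at the benchmark's 2-Mb scale.
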