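# ssrscan

Detection of perfect and approximate DNA microsatellites — tandem repeats
of 1–6 bp motifs — in FASTA sequences, with no per-run parameter tuning,
no motif list and no repeat library.

Microsatellites matter: their copy-number polymorphism is tied to pathogen
virulence, gene regulation and triplet-expansion diseases, and masking them
improves sequence alignment. Most detectors ask the user to pick scoring
and filtering parameters, so two labs scanning the same sequence can get
different answers. `ssrscan` instead fixes all parameters by supervised
learning, and ships an automated pipeline to retrain them on any annotated
chromosome (real or simulated).

## Method

Three components run in sequence, each linear in sequence length `h`:

1. **Scoring.** Each position `i` starts a word of length `n` (default 6,
   the longest microsatellite motif; shorter motifs tile into 6-bp words).
   The word is aligned gaplessly against every word inside the two `m`-bp
   flanking windows (default `m` = 24): the `m` positions before `i` and
   the `m` positions after the word. The score of `i` is the best identity
   score — the count of matching positions, in `[0, n]` — over all
   candidates. Inside a tandem repeat the flanks contain copies of the
   word, so scores saturate at `n`. At most `2·m·h` word comparisons are
   performed.
2. **Detection.** A two-state hidden Markov model over the score series:
   state `q_0` (non-MS) emits low scores, state `q_1` (MS) emits high
   ones. Priors π, transition matrix A and emission matrix B are estimated
   by supervised counting (with add-one smoothing) from labeled training
   sequence cut into 500-bp segments. Viterbi decoding of the series
   yields maximal MS-state runs as candidate detections.
3. **Filtering.** Each candidate is summarized by two features — length
   `x_1` and average score `x_2` — z-scored with training-pool constants
   (`z_i = (x_i − μ_i)/σ_i`) and passed through a logistic GLM
   `σ(w_1 z_1 + w_2 z_2 + b)`. Candidates with logistic value ≥ θ
   (default 0.5; 0.99 for AT-rich genomes whose shuffles are themselves
   repetitive) are reported. Positives for training the GLM are HMM
   detections overlapping the reference annotation; negatives are HMM
   detections in a zero-order shuffle of the same sequence.

Evaluation uses four base-pair measures: sensitivity to a reference
annotation (`100·O_ab/L_b`), false-positive rate on a shuffled sequence
(`10⁶·L_a/S` bp/Mbp), modified precision (`100·O_ref,a/(O_ref,a + L_a^shuf)`)
and percentage predicted (`100·L_a/T`).

Because training labels traditionally come from a repeat-annotated real
chromosome, the package includes a synthetic-genome generator that plants
perfect and degenerate microsatellites (with an exact truth annotation)
into background sequence of configurable composition, so the entire
train–validate–test protocol runs from scratch in seconds.

## Worked example

```sh
python examples/simulate_and_train.py
```

simulates a 400-kb chromosome with 38 planted loci (1.11% of the sequence),
trains the detector on the first third, and evaluates all thirds:

```
simulated 400,000 bp with 38 planted loci (4,441 bp, 1.11%)
filter weights: length 6.59, average score 6.90
GLM training pool: 16 positives, 105 negatives

span      sensitivity%  FPR(bp/Mbp)  precision%  PP%
train            89.9          0.0       100.0  0.74
validate         90.6          0.0       100.0  1.08
test             92.3        315.0        97.5  1.27
```

Sensitivity is the percentage of planted base pairs recovered; FPR is
detected bp per Mbp of shuffled (repeat-free) sequence; similar numbers
across the three spans show the model is not over-fit. The other examples
(`score_series.py`, `detect_and_mask.py`, `shuffled_null_fpr.py`,
`evaluate_detections.py`) each demonstrate one capability and print what
the numbers mean.

The same workflow is available from the shell:

```sh
ssrscan simulate --length 400000 --seed 0 --out-fasta sim.fa --out-bed truth.bed
ssrscan train sim.fa --annotation truth.bed --seed 0 --out-model model.txt
ssrscan detect genome.fa --model model.txt --out-fasta masked.fa --out-bed hits.tsv
```

`detect` writes two formats: masked FASTA (detected microsatellites in
lower case, everything else upper case) and a tab-separated table of
locations (1-based inclusive) with their logistic values.

## Documentation

`docs/methods.md` describes the model, its assumptions, all tunable
parameters, the synthetic-data generator and known limitations.
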