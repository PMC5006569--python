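# Methods

## Problem and model

piwe predicts whether a short DNA sequence (16–35 nt) is a transposon-derived
piRNA or a "pseudo piRNA" (a transposon-matched fragment of some other
non-coding RNA). Each sequence x is encoded into 22 fixed-length feature
vectors; one probabilistic base learner f_i is trained per feature family, and
the final score is the weighted ensemble

    F(x) = Σ_{i=1}^{N} w_i f_i(x),    w_i ≥ 0, Σ w_i = 1,

with the weight vector found by an adaptive genetic algorithm (GA) whose
fitness is the AUC of F on a held-out validation fold. Constraining w to the
probability simplex makes F a convex combination of probabilities, so
F(x) ∈ [0, 1] without any post hoc clipping.

## Feature families

All occurrence profiles are frequency-normalized (they sum to 1), which makes
sequences of different lengths comparable; k-mers are indexed
lexicographically with A<C<G<T.

- **k-spectrum** (k = 1..5): frequencies of the L−k+1 contiguous k-mers.
- **(k, m)-mismatch** (k = 3, 4, 5; m = 1): every window also credits each
  k-mer within Hamming distance ≤ m. The raw count total obeys the closed
  form (L−k+1)·Σ_{j≤m} C(k,j)·3^j, which the tests use as a combinatorial
  oracle. m = 1 keeps the mismatch budget under a third of the word length.
- **(k, w)-subsequence** (k = 3, 4, 5; w = 1): every index tuple
  i₁ < … < i_k contributes w^g to its k-mer, with g = (i_k − i₁ + 1) − k the
  total gap and 0⁰ ≡ 1, so w = 0 reduces exactly to the contiguous spectrum.
  Computed by a prefix-sum dynamic programme (the gap weight factorizes over
  consecutive picks), O(k·L·4^k) instead of enumerating C(L, k) tuples.
- **k-RevcKmer** (k = 1..5): spectrum counts pooled over
  {kmer, reverse complement} classes; the class representative is the
  lexicographic minimum. The class count is (4^k + 4^{k/2})/2 for even k and
  4^k/2 for odd k, i.e. 2, 10, 32, 136, 512. (A published table gives 528 for
  k = 5; the equivalence-class count is 512 — odd-length k-mers have no
  self-complements — and piwe follows the mathematics.)
- **Pseudo nucleotide composition** (parallel/series, di-/trinucleotide,
  λ = 1, weight 0.1): the first 4^t entries are tuple frequencies
  f_u/(1 + wΣθ); the tail is w·θ/(1 + wΣθ). Parallel correlation:
  θ_j = mean over positions and properties of the squared difference of
  standardized property values at lag j (always ≥ 0). Series correlation:
  one θ per (lag, property) pair, the lag-j mean *product* of that property's
  standardized values — these can be negative, so series-correlation vectors
  sum to 1 but are not guaranteed nonnegative. λ must satisfy
  λ ≤ L_min − 2 (dinucleotide) or L_min − 3 (trinucleotide).
- **Sparse profile** (d = 35): sequences are truncated to their first d
  residues or padded with the null letter E, then one-hot encoded per
  position over (A, C, G, T, E) → 5·d entries, exactly d of them 1.
- **PSSM** (d = 35): per column c and base R,
  m(R) = log₂(((count_c(R) + 0.25)/(n_c + 1))/0.25), where n_c counts non-E
  letters in column c of the fixed-length *positive training* sequences
  (pseudocount 0.25 per base against a uniform background). A sequence scores
  m(R_k) at each position, and 0 wherever the padded letter E stands. The
  PSSM is rebuilt inside every cross-validation round from that round's
  positive training sequences only, so no validation/test information leaks
  into the encoding.

Tuned defaults m = 1, w = 1, λ = 1, d = 35 are the package-wide defaults.

### Physicochemical property tables

The pseudo compositions need 6 dinucleotide properties (Twist, Tilt, Roll,
Shift, Slide, Rise) and 12 trinucleotide properties, z-scored over the 16/64
tuples. The bundled tables
(`data/*_properties_synthetic.tsv`) are deterministic synthetic stand-ins:
values drawn once (fixed seed) from plausible physical ranges per named
property, except trinucleotide GC content and molecular weight, which are
computed exactly. Since every property is standardized before use and the
encoders only require a fixed table, downstream behavior is insensitive to
the specific scale values; users with licensed property compilations can load
them via `PropertyTable.from_tsv`.

## Base learners

One random forest per feature family (100 trees — pinned for
reproducibility; scikit-learn defaults otherwise), emitting the positive-class
probability. Engine seeds are derived per (fold, feature) from the master
seed via `numpy.random.SeedSequence`, so runs are deterministic. Any
estimator with `fit`/`predict_proba` can be swapped in through the
`engine_factory` hook.

## Adaptive GA

Real-coded chromosomes g ∈ [0,1]^N are normalized to the simplex when
evaluated (an all-zero chromosome maps to uniform weights). Per generation:
roulette-wheel selection on fitness, uniform crossover, per-gene uniform
redraw mutation, one elite preserved. Crossover/mutation probabilities follow
the classic fitness-adaptive scheme: chromosomes at or above the population
average get p_c = k1·(f_max − f)/(f_max − f_avg) (resp. k2 for mutation),
below-average chromosomes get the constants k3 (resp. k4); a converged
population (f_max = f_avg) gets (k1, k2). Defaults k1 = k3 = 1.0,
k2 = k4 = 0.5, all configurable.

Two deliberate choices:

- The initial population contains the N one-hot corner vectors and the
  uniform vector besides random chromosomes. With elitism this guarantees the
  returned fitness is at least that of the best single base learner — the
  ensemble can never do worse than falling back on its best member.
- Validation scores of the base learners are computed once per round and
  cached; a GA generation only recombines weight vectors, evaluating AUC via
  a vectorized rank statistic. This is what makes the full-size profile
  (population 1000, 500 generations) tractable and small profiles instant.

Full-size defaults are population 1000 / 500 generations; tests and the
acceptance script use a reduced profile (50, 30), which already matches an
exhaustive simplex-grid search to within 0.01 fitness on small instances.

## Evaluation protocol

10-fold cross-validation with 8/1/1 roles: stratified, seeded fold
assignment; round r tests on fold r, validates (GA weight search) on the
cyclically following fold, and trains on the remaining eight. AUC (rank
statistic, ties count ½) is the primary metric; ACC, SN = TP/(TP+FN) and
SP = TN/(TN+FP) are reported at threshold 0.5 (predict positive iff
F(x) ≥ 0.5). Per-round metrics and their mean are both reported, along with
the 10 optimal weight vectors (rounds × features table, exportable as TSV).

## Dataset construction

Pseudo piRNAs are built from candidate ncRNAs: drop sequences < 16 nt, keep
16–35 nt whole, and replace longer sequences by one fragment whose length is
drawn from the empirical length distribution of the (transposon-matched)
positives and whose start offset is uniform — one fragment per source keeps
source diversity. Fragments are kept only if they match a transposon within
the mismatch budget (default 3), using an exhaustive sliding-window Hamming
scan over both strands (adequate at desk scale; no gapped alignment). Exact
duplicate sequences are removed within each class before assembly to prevent
train/test contamination by identical strings. Balanced assembly samples
|positives| negatives without replacement (seeded); imbalanced keeps all.

## Synthetic data generator

The generator emulates the gross statistics of piRNA collections so the
whole pipeline runs without downloads: lengths on [16, 35] from a
discretized Gaussian peaked at 30 (sd 3); a 5′-uridine bias (P(first base
= T) 0.8 for positives, 0.25 for negatives); one motif (TGCAT) inserted in
70 % of positives at a uniform interior position; and a first-order Markov
composition shift in positives (self-transition excess +0.18 over the
uniform background — the compositional-autocorrelation analogue of real
piRNA U/A-richness). The three channels load on different feature families
(positional one-hot/PSSM, 5-mer spectra, di-/trinucleotide statistics), which
makes GA weight recovery a meaningful test. The Markov strength is set so the
default condition is genuinely strongly separable: a single 5-spectrum random
forest reaches cross-validated AUC ≥ 0.9 on its own, and the full ensemble
reaches mean test AUC ≥ 0.95. A toy transposon library containing every
generated sequence as an exact substring is emitted alongside, so the
dataset-builder's filters pass by construction. `null_spec()` switches all
three channels off for chance-level controls.

What the generator does **not** emulate: real piRNA biogenesis (ping-pong
signatures, phasing), genomic context, species-specific composition, or
sequencing noise. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that the ensemble recovers planted signal — not that
the reported synthetic AUCs transfer to real piRNA collections.

## Numerical choices and degenerate inputs

- Profile normalization tolerance 1e-9; property tables z-scored to the same
  tolerance.
- Sequences shorter than a spec's minimum (k, or λ+2/λ+3 for pseudo
  compositions) encode to a zero vector with a logged warning; this cannot
  occur at the defaults since the minimum length 16 exceeds every requirement.
- AUC on a single-class fold, SN with no positives, SP with no negatives:
  errors, never silent zeros.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` / `SeedSequence`; identical seeds give
  byte-identical FASTA output and identical CV results.

## Problem sizes

Tests and the acceptance script run the end-to-end protocol at 500+500
synthetic instances with the reduced GA profile (population 50, 30
generations) — chosen as the desk-scale configuration at which the ensemble's
behavior is already stable; the full-size GA profile is the library default
for real runs.

## Known limitations

- The transposon matcher is an exhaustive scanner: fine for thousands of
  short queries against megabase-scale libraries, not for genome-scale work.
- Series-correlation pseudo compositions can produce signed entries (see
  above); consumers assuming nonnegative features should use the parallel
  variants.
- Per-round metric averaging (mean over rounds) is reported alongside
  per-round values; pooled-score aggregation is not implemented.
- No per-feature hyperparameter tuning; the forest uses library defaults
  beyond the pinned tree count.
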