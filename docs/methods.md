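# Methods

## Problem and model

Given a 9–11-mer peptide known (or predicted) to be presented on MHC class
I, the package estimates the probability that it elicits a CD8⁺ T-cell
response. Because both training classes are MHC-presented, the classifier
cannot fall back on binding-affinity signal; it must learn TCR-facing
physicochemical differences. The model is a random forest —
1000 trees, minimum samples-split 3, Gini impurity, **no bootstrap** (every
tree sees the full training set; diversity comes only from per-split
feature subsampling), unbounded depth. The score of a peptide is the mean
class-1 fraction of the leaves it falls into, in [0, 1].

`features_per_split` defaults to ⌊√118⌋ = 10, the conventional
classification default; the tree-diversity mechanism is otherwise
unspecified in this design, so feature subsampling carries all of it.
Class weights are left at 1 — the 1:3.5 imbalance is deliberately kept and
PR AUC is reported as the imbalance-aware metric. Cross-validation is
stratified 10-fold with a fixed seed; fold assignment, training and scoring
are deterministic given that seed (single-threaded fits).

## Peptide encoding

1. AAindex1 property scales are parsed (H/D/I record blocks, `NA` for
   missing values) into a 20 × P matrix over the canonical residue order
   `ACDEFGHIKLMNPQRSTVWY`.
2. Properties with any missing value are dropped; the rest are z-scaled
   across the 20 amino acids using the population variance (ddof = 0, a
   PCA convention fixed for reproducibility). A property constant across
   residues (relative sd ≤ 1e−10) is an error.
3. PCA retains the first 10 components ordered by decreasing explained
   variance. Sign convention: each component is oriented so its
   largest-magnitude loading is positive, making embeddings identical
   across linear-algebra backends. Each amino acid's embedding is its
   projection (z-scaled row × loadings, consistency asserted to 1e−8).
4. A peptide of length L fills position slots 1..L with its residue
   embeddings; slots L+1..11 are zero. **Padding is N-terminally
   anchored**: the two trailing slots are only populated by 10/11-mers.
   The alternative C-terminal anchoring (padding before the C-terminal
   anchor residue) was considered and rejected as the more complex reading
   of "positions −1/−2 relevant only for longer peptides"; the choice only
   relabels slots and does not change what the forest can learn.
5. Eight global descriptors are appended, computed with
   Bio.SeqUtils.ProtParam in this fixed order: molecular weight (Da),
   aromaticity (F/W/Y fraction), instability index, isoelectric point,
   GRAVY (mean Kyte–Doolittle hydropathy), helix/turn/sheet fractions.
   Using Biopython directly (rather than private copies of its constant
   tables) keeps the descriptors identical to the reference
   implementations; the tests pin the conventions with an independent
   hand-summed mass oracle.

Total: 11 × 10 + 8 = 118 ordered features. Nonstandard residues
(B, J, O, U, X, Z) and lengths outside 9–11 are rejected, not coerced.

## Dataset assembly

Non-self status is defined by the minimum Hamming distance between the
peptide and every equal-length window of the reference proteome — pure
substitutions, no gaps, because near-self neoantigens arise from point
mutations. Positives (T-cell-confirmed) require distance ≥ 1; negatives
(presented-only) must lie in {1, 2, 3} — far enough to be non-self, close
enough to be mutation-derived — and must not equal any positive (exact
identity, not substring overlap). The production search uses pigeonhole
seeding (a window within distance 3 shares one of the peptide's four exact
chunks, found via a position index) with a vectorized full scan as
fallback for larger distances; an exhaustive per-window scan is kept in
the tests as the independent oracle.

Subsampling to the 1:3.5 ratio retains ⌊3.5 · n_pos⌋ negatives. Strata are
peptide lengths; quotas follow largest-remainder apportionment of the
positive set's length distribution; within a stratum the draw is seeded,
without replacement, tie-broken by input order. A stratum that cannot meet
its quota raises an error naming the length.

## Diagnostics

Composition comparisons default to 9-mers (the dominant length class) with
length as a parameter. The frequency-difference logo is the signed matrix
freqA − freqB (rows sum to 0); per-position chi-square tests use the
2 × 20 contingency table with zero-total residue columns dropped (avoiding
zero expected counts) and no continuity correction, BH-adjusted across
positions. Entropy is the plug-in Shannon estimator in nats with
0·log 0 = 0 and no small-sample bias correction; its ceiling ln 20 ≈ 3 is
reached only under uniform usage of all 20 residues. Logo rendering is a
plain matplotlib signed bar chart; publication aesthetics are out of scope.

## Metrics

ROC AUC equals the Mann–Whitney concordance probability with ties counted
1/2 (asserted against a brute-force pair-counting oracle); average
precision is the step-sum, interpolation-free estimator. Top-k lift counts
positives among the top ⌈fraction·n⌉ scores with ties broken by stable
input order. The Kruskal–Wallis bias test uses the tie-corrected H with
the rank effect size η² = (H − k + 1)/(n − k) clipped to [0, 1]; the
bias-test driver takes the peptide sample as an input table (presentation
ranks come from an external predictor) and its size as a parameter. The
benchmark exclusion filter removes recorded negatives that have a positive
immunogenicity assay elsewhere, since their negative status is
contradicted; positives are kept unconditionally.

## Clinical analyses

*Max–mean biomarker.* For each mutation, all unique 9–11-mer windows of
the mutant protein context containing ≥ 1 altered residue are enumerated
(for one interior substitution with full flanks: 9 + 10 + 11 = 30
windows); the biomarker is the maximum over mutations of the mean window
score. All covering windows are scored; restricting to MHC-presented
windows is possible upstream by filtering the mutation table. Enumeration
is at the protein level — translating DNA variants is upstream of this
package; frameshifts/fusions enter as a multi-residue altered span.

*Survival.* Patients are first cut at a configurable mutation-burden
threshold (default 100 mutations/exome, the melanoma convention), then
median-split on the biomarker; ties at the median go to the low group (a
deterministic rule). Kaplan–Meier estimation and the two-sample logrank
test come from lifelines; a hand-computed observed-minus-expected oracle
checks the statistic in the tests.

*Vaccine comparison.* Per-patient hit rate = responding epitopes /
selected epitopes. The paired z-test is a one-sample z on the per-patient
differences: z = mean(d)/(sd(d)/√n) with the sample sd and a two-sided
normal p. All-equal nonzero differences (sd = 0) are reported as
degenerate rather than given an infinite z.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *formats* and the *statistical skeleton* of
the real inputs, not immunological content:

- peptides: positives draw signal-position residues from the hydrophobic
  set {A, C, F, I, L, M, V} (positive Kyte–Doolittle hydropathy) with
  probability `effect_size`, all else uniform. Defaults — 2000 positives,
  length mix 69/21/10% for 9/10/11-mers, signal at positions 1, 5 and 7,
  effect size 0.9 — mirror the length composition and the
  position/hydrophobicity structure reported for real immunogenicity
  data. Under these defaults the Bayes-optimal ROC AUC is ≈ 0.95
  (three near-binary position signals), so the forest's ≥ 0.90 out-of-fold
  requirement leaves honest headroom without being trivial;
- proteomes: i.i.d. uniform residues with planted exact substrings and
  recorded 1/2/3-mismatch variants whose true distances are computed by
  brute force at generation time, giving self-validating oracles;
- survival: exponential event times (baseline hazard ln 2/365 per day,
  i.e. one-year median), hazard multiplied by `hazard_ratio` for the
  upper biomarker half, uniform sub-time censoring at rate 0.2,
  negative-binomial mutation counts around 120.

Real peptide data has correlated positions, allele-specific anchor
constraints and assay noise; real proteomes have composition bias and
repeats; real cohorts have non-exponential hazards. Passing tests
therefore demonstrate that the *machinery* is correct and calibrated
(oracle equivalence, parameter recovery, type-I error ≈ 5%, power ≥ 90%
at hazard ratio 4 with 50 patients/arm), not that any particular clinical
performance level transfers to real data.

## Problem sizes and numerical choices

The default test and acceptance runs use: 2000 + 7000 peptides for the
planted-signal cross-validation (10-fold, 1000 trees), 500 + 1750 with a
200-tree forest for the no-signal control (chance AUC does not depend on
forest size), a 5 kaa proteome with 100 random queries for the mismatch
oracle, and 200 replicates × 100 patients for the logrank calibration.
These sizes were chosen so the full pipeline demonstrates every claim on
one CPU in minutes while keeping all statistical margins wide.

Other fixed choices: encoder serialization is a single `.npz` archive
(lossless round-trip); model persistence embeds the residue encoder so a
saved model is self-contained; seeds propagate explicitly to every random
draw; AUC/AP tie handling follows the threshold-between-distinct-values
convention.

## Known limitations

- Only 9–11-mers are supported; 8-mers and 12–15-mers are rejected by
  design (the dominant MHC-I ligandome classes are covered, minority
  length classes would add noise).
- The packaged AAindex handling is format-faithful, but no AAindex1
  snapshot ships with the package; the encoder's "~89% variance in 10
  components" behavior on the full 540-property set depends on the
  database release and is not asserted.
- The model predicts a general CD8 response, not TCR-level specificity,
  and ignores indication-specific features.
- SNP-overlap screening of negatives (dbSNP-style) is not implemented; an
  exclusion list can be applied upstream.
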