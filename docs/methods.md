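# Methods

## Problem and model

Predicting whether a plant protein is imported into mitochondria is treated
as binary classification. Two import routes motivate the feature design:
proteins with a cleavable N-terminal pre-sequence (detectable from local
composition and profile structure) and proteins with internal signals only
(detectable, if at all, from whole-sequence conservation patterns and from
the tendency of mitochondrial genes to co-express). Four feature blocks are
concatenated in a fixed order with a recorded layout:

| block | length | content |
|---|---|---|
| AAFreq.NT | 20 | residue frequencies over the first L residues |
| PSSM.NT | 20·L | scaled profile rows for positions 1..L, position-major |
| PSSM | 400 | scaled profile rows averaged per residue type (20x20) |
| Coexpr | 5 | KNN co-expression scores at K ∈ {0.25, 0.5, 1, 2, 4}% |

Defaults: L = 22 (valid 5–50), all blocks enabled, total length 865.
A model stores the layout fingerprint it was trained with and refuses
differently laid-out vectors.

## Sequence handling

Sequences are uppercased on input; the residue alphabet is the 20 standard
amino acids plus X/B/Z/U/O. Ambiguity codes contribute zero profile rows
and are excluded from frequency numerators and denominators. Sequences
shorter than 50 residues are excluded by the default length filter; the
initiator methionine is never trimmed. Redundancy reduction is greedy
longest-first clustering on a k-mer containment estimate of identity
(k = 5, threshold 0.40 by default) — a fast proxy adequate for
train/test-leakage control, not bit-compatible with alignment-based
clustering tools; a precomputed cluster table can be supplied instead, in
which case only the longest-member representative selection is applied.

## Profiles

PSI-BLAST ASCII PSSM files are parsed with the file's own column alphabet
remapped to the fixed order ACDEFGHIKLMNPQRSTVWY, and the residue column is
cross-checked against the sequence. Scaling is per-protein linear min–max
to [-1, 1]; a constant matrix maps to zeros. Per-protein scaling is the
simplest faithful choice where a single global affine would also be
defensible; both behaviors are reachable (scale any matrix you like before
injection), but per-protein is the default and the only path used
internally. When no profile file is available, a substitution-matrix
fallback (one BLOSUM62 row per residue) keeps the pipeline operational;
its use is flagged in the profile source and surfaces in prediction
output, because predictions made without an evolutionary profile are
systematically weaker.

## Co-expression

Each expression dataset is log2-transformed (x → log2(x + 1)) unless
flagged as already logged. Per-dataset Pearson matrices are combined by
Fisher z with inverse-variance weights (n − 3); |r| is clamped at
1 − 1e-6 to avoid infinite z. Zero-variance genes and pairs with no
covering dataset are missing rather than imputed, and missing pairs rank
below all covered pairs in neighbor search. Neighbor counts are
k = max(1, round-half-up(K/100 · N_train)); correlation ties break
lexicographically by gene id; a query never counts itself. Proteins
without a best-hit mapping into the reference expression space receive
five zeros — the same convention the unmapped-protein path uses at
prediction time.

The exact weighting scheme of the meta-analysis is an assumption (the
inverse-variance Fisher-z combination is the textbook default); it
satisfies two anchoring identities used in tests: a single dataset returns
its own r, and equal r with equal n returns r exactly.

## Classifiers

**SVM.** RBF kernel via scikit-learn with a tight KKT tolerance (1e-6) so
decision values are reproducible. Grid search maximizes mean stratified
10-fold CV AUC over cost {1e-3..1e3} × gamma {1e-5..1e5} (7 × 11 decades),
ties breaking toward smaller cost then smaller gamma. The default
operating point is cost 10 with the dimension-adaptive bandwidth
gamma = 1/(d·Var[X]) ("scale"): a fixed numeric gamma degenerates as the
feature dimension changes (e.g. across the window-length sweep, where d
runs from 120 to 1020), while the adaptive form keeps the kernel informative
at every layout. Raw decision values feed ROC analysis and calibration; no
probability calibration is applied.

**Maxout network.** A NumPy feed-forward network: hidden layers of maxout
units (max over 5 affine pieces), inverted dropout 0.5 on hidden outputs,
2-way softmax, cross-entropy loss, minibatch SGD (batch 100) with learning
rate 0.01 and momentum rising linearly from 0.5 to 0.7 across the epoch
cap (250). After each epoch the validation AUC is computed; the
best-validation snapshot is returned (validation AUC is the model-selection
criterion; the minibatch size and this criterion are package choices).
Default hidden sizes are (500, 500, 300); tests and the synthetic
benchmarks use (32, 32, 16), which trains in seconds at n = 800. All
stochastic elements (initialization, shuffling, dropout masks) derive from
one seed; training is bit-reproducible.

**Ensemble.** Ten members are trained by rotating the validation fold over
stratified folds (each rotation: 9 folds train, 1 validates); the ensemble
score is the members' mean positive-class probability, hence bounded by
the member extremes and lying in [0, 1].

## Cross-validation protocols

Stratified 10-fold throughout; per-fold class counts differ by at most one
from the exact quota. SVM protocol: rotation i trains on 9 folds, tests on
fold i. Network protocol: rotation i tests on fold i, validates on fold
(i+1) mod 10 and trains on the remaining 8, so each fold serves once as
test and once as validation.

Because the co-expression KNN block is computed **from training labels**,
assembling it once and then cross-validating leaks label information
transductively: chance correlation clusters give members scores that
correlate with their own labels, inflating null CV AUC by about +0.02 at
n = 800 with three 20-sample datasets. `pipeline.cross_validate` therefore
recomputes the Coexpr block in every rotation from the training folds'
labels only; the label-free sequence blocks are assembled once. This
fold-safe protocol is the package's default for internal validation and
for the recovery benchmarks. `models.run_cv` on a fixed feature matrix is
retained for feature sets without label-dependent blocks and for
externally supplied features.

## Calibration

The calibration table stores the raw, sorted scores of a held-out
negative-only set (an empirical distribution, not a parametric fit; no
interpolation between quantiles). The threshold at level s is the
*smallest* score value t such that the number of calibration negatives
scoring ≥ t is at most floor((1 − s)·n) — minimal so no sensitivity is
sacrificed, conservative at ties (every score equal to t counts as a
positive call, rule: score ≥ t ⇒ positive). If no value qualifies the
threshold lies strictly above the maximum negative score. Consequences
asserted as properties: empirical specificity on the calibration set is
≥ s for every s, thresholds are non-decreasing in s, and positive-call
counts are non-increasing in s on any fixed score set. Standard reporting
levels are 0.90 (default), 0.95 and 0.99. Below 100 negatives the table is
flagged as coarse.

## Evaluation

ROC and precision-recall points are produced one per distinct score
threshold (ties grouped; call rule score ≥ t), with AUC by the trapezoidal
rule — equal to the Mann–Whitney concordance probability for tie-free
scores, which the tests verify against a pair-counting oracle. MCC uses
the full confusion matrix and falls back to 0 (flagged) on zero
denominators; other metrics report NaN with a flag when undefined.
`counts_from_rates` reconstructs integer confusion counts from printed
sensitivity/specificity at known class sizes with round-half-up — the rule
under which all checked published table rows reproduce exactly.

The bootstrap AUC comparison resamples example indices with replacement
within each class (paired, stratified — both scorers see the same
replicate, and both classes stay represented), with ties between replicate
AUCs counted one-half; it is one-sided for "scorer a ranks better than
scorer b".

The window-length sweep rebuilds the N-terminal blocks at every L in 5..50
and reports mean CV AUC per window using the SVM (fast enough for 46 × 10
fits at desk scale).

## Synthetic data

The generator emulates the statistical structure the predictor assumes,
with defaults chosen once as the package's study conditions:

- 400 proteins per class; lengths uniform in 60–300 (≥ 50 by construction);
  background composition uniform over the 20 residues (a deliberate
  simplification — real proteomes are non-uniform, but uniformity isolates
  the planted effects);
- 70% of positives carry a 22-residue N-terminal signal window sampled
  from the background reweighted ×2 for R/W/H/L/K/A/Y/I and ×0.5 for
  D/E/V/N/G/P/M (direction fixed by the known pre-sequence bias; the
  magnitudes are free parameters). The remaining positives model
  internal-signal proteins and are background at the sequence level;
- profiles are the substitution fallback plus integer-rounded Gaussian
  noise (sd 1.0), and positives additionally receive a whole-sequence
  shift of +0.2 on the enriched-residue columns — the conservation
  signature that makes the global-profile block informative for positives
  with and without pre-sequences. The shift is deliberately small per
  position (a fifth of the noise sd) and becomes detectable only by
  averaging along the chain;
- three expression datasets of 20 samples; positives load on one shared
  latent factor with strength 0.7 (within-positive correlation ≈ 0.49 per
  dataset), negatives are independent noise; 10% of proteins are withheld
  from the gene mapping to exercise the five-zero path.

What passing on this data shows — and does not show: the pipeline recovers
planted signals of realistic direction and separability (full-feature CV
AUC ≥ 0.9; positives lacking pre-sequences recovered from global-profile +
co-expression blocks alone) and stays at chance when all effects are off.
It does not demonstrate performance on real proteomes, where profiles come
from iterative database search, expression noise is structured, classes
are imbalanced, and homology leaks between splits unless redundancy is
reduced.

## Numerical choices and degenerate inputs

Per-protein min–max profile scaling maps constant matrices to zeros;
Fisher-z clamps |r| at 1 − 1e-6; the calibration quantile adds 1e-9 to the
false-positive budget before flooring to absorb binary-float artifacts
(e.g. (1 − 0.9)·10 evaluating just below 1); neighbor-count rounding is
half-up with a floor of 1; grid-search and ranking ties break
deterministically (smaller parameters; lexicographic gene ids). Empty
inputs, single-class training sets, mismatched profile/sequence pairs,
conflicting mapping rows and layout-fingerprint mismatches raise typed
errors rather than propagating silently.

## Problem sizes used in the automated benchmarks

Recovery benchmarks run at 400 proteins per class with the reduced
(32, 32, 16) network and a 100-epoch cap; the signal-free null is averaged
over five generated studies (single-study CV AUC has sd ≈ 0.03 under the
null, dominated by chance correlation structure in the small expression
sample, so a multi-study mean is the meaningful statistic); the
window-length sweep uses 150 proteins per class. These sizes are the
package's desk-scale study conditions; all of them are plain parameters,
and nothing prevents running the same code at larger n.

## Known limitations

- The built-in redundancy reducer approximates alignment identity with
  k-mer containment; for publication-grade non-redundancy use an external
  clustering tool and import its cluster table.
- The best-hit protein→gene mapping is an external input; the package does
  not run sequence search.
- Co-expression covers only genes present in the supplied expression
  datasets; everything else falls back to five zeros, degrading gracefully
  but measurably.
- The specificity estimate is calibrated on the supplied negative set and
  transfers to new data only insofar as that set represents the negative
  score distribution there.
- Single-label output: dual-targeted proteins (mitochondria and
  chloroplast) are outside the model.
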