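# Methods

## Problem framing

The unit of classification is a fixed-length DNA window (41 nt by
default, always odd) over the alphabet {A, C, G, T, N} with an adenine
at the central position; label 1 means that adenine carries N6-methyl
(6mA). N denotes an unidentified nucleotide and is a first-class symbol
throughout: it is counted by the frequency encoders and has its own
one-hot bit.

## Dataset preparation

`read_fasta` uppercases sequences and maps every non-ACGT character
(ambiguity codes, U, gaps) to N; the map is idempotent and the number of
replacements is logged. `clean_datasets` applies, in order: (1) removal
of windows whose length differs from the target (longer *and* shorter —
every downstream encoder assumes fixed length); (2) exact-string
deduplication within each label, keeping the first occurrence in file
order (deterministic, independent of hashing); (3) removal of any
sequence present in both label sets from both. Duplication is exact
string equality only — reverse complements are not treated as
duplicates, since a window and its reverse complement center different
strands. A missing central A is a warning at cleaning time but a hard
error at prediction time: curated benchmark files guarantee the center,
arbitrary user FASTA may not.

The train/test split is random, seeded, and stratified by label
(fraction 0.8 by default). Stratification is a package choice for
variance reduction on near-balanced data; disable it with
`SplitSpec(stratified=False)`.

## Encoders

All encoders are pure functions; dimensionalities for window length L:

| encoder | dimension | notes |
|---|---|---|
| ONEHOT1 | 5L | symbol order A,C,G,T,N |
| ONEHOT2 | 25(L−1) | codebook lexicographic, AA=0 … NN=24 |
| AMNF | L | element t = freq. of dₜ in d₁..dₜ; first element always 1 |
| ADNF | L−1 | same over overlapping dinucleotides |
| DPCP | 25·P_d | count × property, flattened token-major |
| TPCP | 125·P_t | same for trinucleotides |
| FUSED | sum | plain concatenation, no rescaling |

Two interpretation choices in the count×property encoding are worth
recording. First, the output keeps one cell per (token, property) pair
rather than summing over properties per token; a per-token-only output
would discard the property index entirely. Second, N is the raw token
count, not a relative frequency; `encode_pcp(..., normalize=True)`
divides by the number of k-mers for users who want
composition-normalized values. Values are kept at full float precision;
two-decimal renderings like 0.33 in the docs are displays of 1/3.

### Bundled property tables — a synthetic stand-in

DPCP/TPCP need a token × property value matrix, which is an explicit,
swappable input (TSV schema: header `token<TAB>prop1<TAB>…`, one row per
k-mer; omitted N-containing rows default to zero). The bundled defaults
carry 15 dinucleotide and 11 trinucleotide properties. The thermodynamic
columns are standard nearest-neighbor parameters; geometric and
flexibility columns are representative values assembled from the DNA
physicochemical-property literature rather than a byte-exact copy of any
single published compilation, and trinucleotide values are derived by
averaging the two constituent dinucleotide steps. Tests that depend on
exact table content construct their own toy tables; the bundled numbers
only need to be a plausible, fixed, documented default.

## Classifier

Five scikit-learn base estimators behind one fit/predict contract:

| key | estimator | defaults that matter |
|---|---|---|
| RF | RandomForestClassifier | 100 trees, single-threaded for determinism |
| LDA | LinearDiscriminantAnalysis | svd solver; deterministic, no seed |
| MLP | MLPClassifier | one hidden layer (64,), max_iter 200 |
| SGD | SGDClassifier | hinge loss — a linear SVM fit by SGD |
| XGB | HistGradientBoostingClassifier | sklearn's gradient-boosted trees |

The gradient-boosting member is scikit-learn's histogram implementation
rather than the xgboost package (not available in the supported
environment); it plays the identical role — regression-tree boosting —
behind the same `"XGB"` key.

Votes are hard 0/1 labels, never probabilities or scores; the ensemble
labels a window 1 iff at least `vote_threshold` (default 3 of 5) base
votes are 1. With five voters and threshold 3 no tie is possible;
user-configured even ensembles map ties to 0 (the conservative non-6mA
call) with a warning. The MLP hidden-layer width is a hyperparameter,
not a constant, since only the one-hidden-layer architecture is fixed.

Grid search is exhaustive over the Cartesian product of a per-algorithm
grid, scored by stratified k-fold CV accuracy with deterministic
tie-breaking (first combination in enumeration order); failing
combinations are recorded as NaN and skipped. Grid search runs inside
the training set only — when `pipeline.train` holds out an internal
validation split, the grids never see it, avoiding the optimistic-CV
ambiguity that arises when tuning and evaluation share data. Default
grids ship in `default_grids()` and in the documented JSON config; they
are inputs, not constants.

Model persistence is a joblib archive bundling the five fitted
estimators, the encoder specification (including any property tables, so
prediction re-encodes identically), the vote threshold, provenance
metadata and a format version stamp. Save→load→predict round-trips
bit-identically; loading rejects unknown format versions.

## Metrics

ACC, MCC, SN, SP from the confusion counts (TP = correctly predicted
6mA). Conventions for degenerate inputs: MCC returns 0 when its
denominator vanishes (the uninformative-classifier value, standard
practice); SN/SP return NaN when their class is absent; an all-zero
confusion matrix is an error. Cross-validation is stratified and seeded;
sweeps reuse one seed and fold structure across every encoder ×
classifier cell so cells are comparable. Text reports round to 3
decimals; stored values are full precision.

## Synthetic data

The generator emulates the empirical signature of plant 6mA windows:
position-specific nucleotide enrichment flanking the methylated adenine,
as seen in two-sample sequence logos. The default profile plants A at
positions −6, −4, −3, +4, +7, +8, +10, +11, +12; C at −7, −2, +2, +6,
+9; G at −8, −1, +2, +3, +5, +8; and T at +3 (21 pairs, positions
relative to the center). Published logos are qualitative, so no numeric
enrichment magnitude is taken from them: each pair carries a strength
s ∈ [0,1], default 0.5, with the semantics "with probability s force the
enriched base, else draw from background". Under uniform background the
expected enriched-base frequency is s + (1−s)/4. Where two bases are
enriched at one position (e.g. C and G at +2) the rules apply
sequentially in profile order, mirroring logos in which several bases
are jointly over-represented.

Negatives are i.i.d. background with a forced central A. Real negatives
come from chromosomes with no detected 6mA and carry genome-scale
composition, CG skew and chromosomal context that i.i.d. background does
not emulate. Consequently a green end-to-end test establishes that the
pipeline recovers planted positional composition — not that it matches
real-genome performance. Duplicates are possible by chance and are left
to the standard cleaning step, mirroring the real data flow. An optional
`n_rate` masks flank positions to N to emulate unidentified nucleotides;
the center is never masked.

## Numerical and design choices

- All randomness flows through explicit integer seeds (numpy Generator,
  sklearn random_state); identical seeds give byte-identical datasets,
  splits, fits and votes.
- The strength-0 chance-level check uses a 99% binomial confidence
  interval around 0.5 on the held-out set.
- The ensemble-gain comparison (median ensemble accuracy ≥ median
  base-learner accuracy over 5 seeds) is run at strength 0.5: at
  strength 1.0 every learner saturates at ~1.0 and the comparison is
  vacuous.
- The benchmark sweep in the acceptance suite uses n=800 windows and
  3-fold CV to keep the default test run inside a desk-scale time
  budget; the sweep API itself takes arbitrary sizes and fold counts.

## Known limitations

- The bundled property tables are representative, not authoritative;
  supply your own TSV for publication-grade DPCP/TPCP features.
- LDA in the n ≪ p regime (e.g. 1000-dim One-hot2 with a few hundred
  training windows) is noticeably weaker than the other learners; this
  is a property of the model class, visible in small-sweep tables.
- The generator does not emulate genome-scale base composition, strand
  effects, or chromosomal context, and the package has no genome-scanning
  (sliding-window) mode.
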