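# Methods

## Problem and model

`labkg` predicts a binary disease label (the motivating application is
diabetes screening) from a routine laboratory panel, while making the
clinical knowledge the prediction rests on explicit.  The knowledge is the
set of published reference ranges: for each indicator, the interval a
healthy measurement should fall in.  The pipeline has three stages.

**1. Severity-band knowledge graph.**  Each indicator's measurement axis
is discretized into a grid of *value entities* and linked to its
*indicator entity* by one of seven ordered severity relations — severely
low, generally low, slightly low, normal, slightly high, generally high,
severely high — e.g. `(triglycerides, normal, 0.45 mmol/L)`.  The normal
interval `[low, high]` is closed on both ends.  The outer band boundaries
are not clinically standardized, so they are parametric: with
`W = high − low`, a value deviating by less than `alpha1·W` beyond the
range is a *slight* deviation, up to `alpha2·W` a *general* one, and
beyond that *severe*; the outer bands are half-open so every value has
exactly one band.  Defaults `alpha1 = 0.25`, `alpha2 = 0.75` reproduce
the usual clinical cue that a fasting glucose above 7.0 mmol/L (normal
range 3.9–6.1) is generally rather than slightly elevated; both are
overridable per run.  The default grid step is `W/100` rounded to one
decimal beyond the printed precision of the bounds, the grid extends one
range-width beyond the interval on each side (`span_factor = 1`), and
grids of concentration-like analytes are clamped at zero.

**2. Translational embeddings.**  Entities and relations are embedded so
that `l_h + l_r ≈ l_t` for true facts.  Three scoring geometries are
implemented: TransE (plain translation), TransH (entities projected onto
a relation-specific hyperplane, `e − (wᵀe)w`, before translation; this is
the default, as the indicator→value relations are strongly one-to-many),
and TransR (a relation-specific projection matrix; source and target
dimensions are taken equal).  The score is the L1 or L2 length of the
residual (L2 default).  Training minimizes the margin-ranking loss
`Σ max(0, s(pos) + γ − s(neg))` with uniform negative sampling (head
replaced by a random indicator entity or tail by a random value entity,
probability ½ each, never the relation), Adam (lr 1e-3), margin γ = 1,
batch 128.  After every batch the hyperplane normals are renormalized to
unit length and entity norms clipped to ≤ 1.  Embedding quality is
reported as Mean Rank and Hit@10 under exhaustive raw-setting corruption
of one side (head by default), with optimistic tie handling (rank = 1 +
number of strictly better candidates).  Both metrics are always reported
together; neither is treated as the single selection criterion.

**3. Patient encoding and SAC classifier.**  A patient's measurement for
indicator j is matched to the nearest grid value (ties at exact midpoints
round up); values beyond the grid collapse to `<HIGHEST>`/`<LOWEST>` and
missing cells to `<UNK>`.  These three sentinels are ordinary entities of
the embedding table; no triples mention them, so they keep their
(trainable-stage) initialization — they act as learned "out of
vocabulary" codes.  The relation vector of indicator j is the embedding
difference `e_value − e_indicator`, and stacking the m columns in the
declared panel order gives the k × m relation matrix fed to the
classifier: two stacked single-head self-attention layers
(`V softmax(KᵀQ/√D_k)`, softmax per column; no residuals or
normalization layers — the topology is deliberately minimal), then 1-D
convolutions with window
sizes {2, 3, 4}, 100 filters each, relu, max-over-positions pooling to a
300-vector Z, dropout 0.5 on Z, and an affine layer to two class scores
with softmax.  Training minimizes mean binary cross-entropy (probability
clamp 1e-7) with Adam, lr 2e-4, batch 32; parameters initialize
uniform(−0.1, 0.1) under the run seed.  The decision threshold is 0.5 on
the diseased-class probability.  The entire network and its
backpropagation are hand-written in NumPy; analytic gradients are checked
against central differences to 1e-4 in the test suite.

An ablation encoder replaces the knowledge representation with a plain
entity-embedding table (row lookup of the matched value entity,
equivalent to one-hot × weight matrix) trained jointly with the
classifier; it shares the downstream interface so the two representations
are directly comparable.

## Evaluation protocol

Experiments report accuracy, recall and F1 with the diseased class
positive (F1 defined as 0 when there are no true positives), on a
stratified 80/20 split or stratified five-fold cross-validation;
aggregate CV metrics are sample-weighted fold means.  Class imbalance is
handled by SMOTE: the minority class is oversampled to exact parity,
each synthetic row `x + u(x_nn − x)` with `u ~ U(0,1)` and `x_nn` one of
the k = 5 nearest minority neighbors.  SMOTE runs in raw measurement
space *before* encoding, so synthetic patients pass through the normal
entity-matching path; NaN (missing) cells are ignored in the neighbor
distance and propagate into synthetic rows.  By default only the
training portion is resampled; a flag also resamples the held-out
portion for protocols that balance both sides.

## Synthetic cohorts

Real exam panels cannot be redistributed, so cohorts are generated with
a known mechanism shaped like the motivating dataset: m = 11 indicators,
latent disease prevalence 0.10 (≈1:9 positives), 5% missing cells.
Healthy values are Gaussian around the range midpoint (sd = W/5, so a
small fraction drifts slightly out of range, as real healthy values do);
in latently diseased patients the causal indicators are shifted
0.25–1.125 range-widths above the upper bound.  Each cell's integer
severity s ∈ {−3..+3} comes from the same seven-band rule the graph
uses, and the label is Bernoulli(sigmoid(β₀ + Σ βⱼ sⱼ)) — so the signal
is exactly the structure the knowledge encoding is designed to expose.
The generator returns the full latent truth (values before masking,
severities, probabilities, latent states) for oracle checks, and
`expected_bayes_accuracy` scores the optimal rule (threshold the true
probability at 0.5) as the recovery ceiling.

The canonical recovery cohort (`strong_signal_spec`) uses n = 4000,
three causal indicators (indices 1, 4, 8 of 11), saturated effects
(β₀ = −30, βⱼ = 20) so labels are deterministic given the values and the
Bayes ceiling is 1.0, balanced classes, and no missingness.  What these
cohorts do **not** emulate: realistic marginal shapes (skew, heavy
tails), correlated indicators, age/sex-dependent ranges, and
measurement error — so passing recovery tests demonstrates that the
pipeline can extract band-structured signal, not that it matches
hospital-data performance.

**Permutation control.**  The no-signal control follows the standard
permutation-test protocol: the cohort's label vector is permuted once,
the identical train/evaluate pipeline is rerun, and accuracy is scored
against the permuted held-out labels, which sits at chance (0.5) for any
model.  Scoring a permuted-trained model against the *original* labels
is deliberately not used as the control: with well-separated classes the
hard 0.5 threshold amplifies tiny systematic drifts of an otherwise
uninformative predictor (probabilities within ±0.02 of 0.5) into
cluster-level decisions correlated with the truth, which misrepresents
how much signal the control actually learned.

## Problem sizes and numerical choices

The recovery experiments use embedding dimension 64, 200 embedding
epochs and 30 classifier epochs — the package's CPU-scale defaults for
a cohort of 4000; the constructor defaults (dimension 256, 100 epochs)
remain available for larger studies.  Other choices:
optimistic rank ties; the true triple's score is read out of the same
vectorized candidate computation during ranking so comparisons are
rounding-exact; max-pool backward routes gradient to the first argmax;
relation-matrix columns follow the ranges-file row order, which is
recorded in all outputs; the cross-entropy probability clamp is 1e-7;
`value_grid` rounds to the step's decimal precision and normalizes −0.0.

## Known limitations

Band boundaries beyond the normal range are parametric stand-ins, not
published clinical thresholds.  Reference ranges are age- and
sex-independent.  The NumPy network trains on one CPU core; dimension
256 at tens of thousands of patients is substantially slower than the
framework implementations it mirrors.  `<UNK>`-encoded missingness is
the only imputation mechanism.  Only binary outcomes are supported.
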