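# Methods

## Model

hdscreen implements classification and ranking over bipolar
hypervectors h ∈ {−1, +1}ᴰ. The algebra has three primitives: binding
(element-wise product; self-inverse on bipolar input), bundling
(element-wise integer sum) and cyclic permutation (exposed for
completeness; none of the molecular encoders uses it). Similarity is
the cosine, which is invariant to positive scaling, so bundled
prototypes are kept as exact integers and never renormalised or
re-binarised — renormalisation would change no prediction and would
lose exactness.

The statistical basis is quasi-orthogonality: two independent uniform
bipolar vectors have cosine with mean |cos| = √(2/(πD)) + O(D⁻¹)
(≈ 0.008 at D = 10,000), so class prototypes built from even modest
numbers of samples are far more similar to their own class's encodings
than random interference would predict. D = 10,000 is the default
dimension; larger D buys little and costs linearly.

### Encoders

All four encoders are deterministic given their configuration
(scheme, D, fingerprint length n, radius r, seed); re-encoding a
dataset is bit-identical.

* **DECFP**: ECFP/Morgan fingerprint with `nBits = D`, bits mapped
  {0,1} → {−1,+1}. By construction the Manhattan distance between two
  DECFP hypervectors is exactly twice the Hamming distance of the
  underlying fingerprints. Fingerprints come from RDKit's Morgan
  generator; chemically identical SMILES spellings give identical
  vectors.
* **RPFP**: h = σ(W · fp) with W ∈ ℝᴰˣⁿ, rows uniform on the unit
  sphere, realised as row-normalised standard-normal draws (the
  rotation-invariant construction). σ maps z ≤ 0 → −1, z > 0 → +1; the
  tie at exactly zero goes to −1, so an all-zero input maps to the
  all-(−1) vector. n is independent of D (default n = 1024, r = 1).
* **Feature projection**: the same σ(W·x) map applied to precomputed
  real embeddings read from file, one row per molecule, row order
  contractually matching the molecule table (a row-count mismatch is a
  hard error, never a truncation). Sign quantisation makes the encoder
  invariant to positive rescaling of the features and approximately
  order-preserving on pairwise cosine similarities for large D.
* **Combo**: binding (Hadamard product) of the DECFP hypervector with
  the feature-projection hypervector. Both operands are already
  bipolar; we bind the quantised vectors, not pre-quantisation reals.

Each encoder instance draws its projection matrix from one parent seed
and can be serialised to a single `.npz` file so that training and
screening share W exactly.

### Classifier

Single-pass build: prototype_k = Σ encodings with label k. Retraining
(default 10 epochs, early-stopped on a zero-update epoch, unit step by
default with an optional integer learning rate) re-predicts each
training sample against the *current* memory and on error adds the
sample to the true prototype and subtracts it from the predicted one.
Correct samples never touch the memory, so a perfectly classified
training set is a fixed point and `epochs=0` is the identity. The
update magnitude and schedule are design choices of this package; the
unit add/subtract step is the standard error-driven HDC rule, and the
epoch budget is configurable because no principled stopping rule
exists short of convergence.

Prediction is argmax of cosine against the prototypes, ties broken
toward the lowest prototype index for cross-platform determinism. Dot
products and squared norms are computed in exact integer arithmetic
before a single float division, so scoring is bit-identical whether
compounds are scored one at a time or in batches (default batch 128 —
purely a throughput knob).

### Confidence and ranking

For binary screens, η = 1/2 + (cos(h_q, h₁) − cos(h_q, h₀))/4, where
h₁ is the positive (active) prototype. η ∈ [0, 1] because each cosine
is in [−1, 1]; η = 1/2 at equal similarity; η > 0.5 exactly when the
query is closer to the active prototype, which makes η and the argmax
prediction consistent (exact ties predict class 0 and score 0.5).
The orientation — positive-minus-negative in the numerator — is the
one under which high η means predicted-active; ranking by descending η
(stable on ties) is what the enrichment metrics consume. This
orientation is deliberate and documented here because the transposed
form, with h₀ and h₁ swapped, silently inverts every ranking while
leaving accuracy untouched.

### Screening metrics

ROC curves and AUC delegate to scikit-learn (tied scores collapse to a
single step; AUC equals the tie-corrected pairwise probability).
EF-x% uses the cutoff n_s = round(x·n_b) with ties at the cutoff
resolved by stable sort order. ER-x% reads TPR off the empirical ROC
curve at FPR = x/100 with **linear interpolation** between adjacent
vertices — the empirical curve rarely has a vertex exactly at 1% FPR;
the interpolation convention is recorded in every metrics report
(`er_interpolation: linear`) so numbers are reproducible bit-for-bit.
EF requires at least one active and a non-empty cutoff; all ROC-based
metrics require both classes.

## Splits

Scaffold splits group molecules by Bemis–Murcko framework (RDKit) and
assign whole groups greedily, largest group first, to the partition
with the largest remaining deficit relative to its target fraction
(default 80/10/10), so no scaffold spans partitions and partition
sizes land within one largest-group size of their targets. Group-size
ties are ordered by a seeded shuffle, making the split a pure function
of (input order, seed). Stratified splits preserve the class ratio
(default 75/25 train/test) via scikit-learn. External precomputed
splits are consumed as id-list files.

## Synthetic data

The generators define the test conditions for every stage:

* **Gaussian features** — two unit-variance normal clusters whose
  means sit at ±separation/2 along a random unit direction. The
  symmetric placement matters: sign quantisation is origin-sensitive,
  and a cluster centered exactly at the origin would contribute no
  systematic sign signal regardless of separability. Defaults:
  200/class, 64 features, separation 4 (a cleanly separable regime,
  Bayes error ≈ Φ(−2) ≈ 2%), with a `class_ratio` knob down to the
  1:50 active:inactive skew typical of real screening decks.
* **Prototype-noise data** — two hidden uniform bipolar generators;
  samples copy their generator with independent sign flips (default
  probability 0.2). The flip rate directly controls the expected
  sample–generator cosine (1 − 2p), giving a closed-form
  parameter-recovery target for the associative memory.
* **Toy molecules** — enumerated scaffold–substituent SMILES
  (alkanes/cycloalkanes vs. five- and six-membered aromatics),
  labelled active iff an aromatic ring is present. The label is a pure
  substructure rule, so fingerprint encoders face a noiseless,
  learnable signal and a scaffold split still leaves the rule
  learnable from held-in chemotypes.

What the synthetic fixtures do **not** emulate: real chemical-space
diversity, label noise from assay variability, activity cliffs, or
feature distributions of actual pretrained embedding models. Passing
tests therefore demonstrate correctness of the machinery and its
statistical behaviour under known structure, not screening performance
on real decks.

## Numerical conventions and degenerate inputs

* σ(0) = −1 everywhere (quantisation tie), so all-zero fingerprints or
  features encode to the all-(−1) hypervector rather than erroring.
* Cosine with an all-zero vector, an empty bundle, an empty class, an
  all-zero prototype at predict time, duplicate molecule ids, labels
  outside {0, 1}, and non-finite features are all hard errors.
* Invalid SMILES raise at single-molecule level and are
  skipped-with-logged-count at dataset level.
* Screen result files carry scores at 12 significant digits, enough to
  round-trip the ranking exactly.

## Problem sizes in the test suite

The suite exercises the full default dimension D = 10,000 where the
claim depends on concentration (quasi-orthogonality, parameter
recovery, the end-to-end screen on 500 toy molecules) and smaller
dimensions (D = 128–2048) for exact algebraic contracts, where
dimension is irrelevant. Monte-Carlo assertions (mean |cos|, chance
AUC over 5 seeds, flip-rate checks) use fixed seeds and 3-standard-
error or pre-measured-margin tolerances.

## Known limitations

* Multi-class memories are supported, but confidence/ranking is
  defined for binary screens only.
* No probability calibration beyond the linear η map; η is a ranking
  score, not a calibrated probability.
* Retraining is full-batch sequential; no online/streaming updates.
* SMILES-tokenizer (n-gram/permutation-based) encodings and learned
  projection matrices are out of scope.
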