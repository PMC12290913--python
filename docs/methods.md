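# Methods

## Problem and model

`vitseq` classifies a registered, skull-stripped 3D T1-weighted brain volume
into one of three diagnostic classes — normal control (NC), mild cognitive
impairment (MCI), Alzheimer's disease (AD) — by treating the volume as an
*ordered sequence of 2D slices*:

1. **Slice preparation.** The volume is sectioned along one anatomical plane
   (axial by default); the central 50 slices are kept; each slice is resized
   to 224 × 224 pixels and written as an 8-bit grayscale PNG into
   `prepared_data/<subject>/<plane>/slice_<idx>.png`.
2. **Per-slice encoding.** Each slice is cut into a 14 × 14 grid of
   16-pixel patches (the ViT-Base/16 geometry) and encoded to a feature
   vector. Two encoders exist: an optional frozen pretrained ViT (requires
   `timm`; the slice feature is its pooled/class-token output), and the
   default *stub projection encoder* — a seeded random linear map of the
   196 per-patch mean intensities. The stub is not a learned representation;
   it is a deterministic, order-sensitive encoder that preserves coarse
   spatial information, so the downstream machinery can be exercised and
   tested without pretrained weights.
3. **Sequence classification.** The ordered (50 × feature_dim) matrix is
   classified by a time-series transformer: sinusoidal positional encodings
   added to the inputs, `n_blocks` pre-layer-norm transformer blocks
   (multi-head scaled dot-product self-attention with residual, then a
   position-wise two-layer ReLU feed-forward with residual), a final layer
   norm, pooling over the sequence axis, and a dense softmax head.
   Training minimizes categorical cross-entropy with Adam and early
   stopping on validation loss; the best-validation parameters are restored.

Evaluation uses stratified 10-fold cross-validation at the *subject* level
and reports accuracy, balanced accuracy (mean per-class recall) and
macro-averaged precision/recall/F1 per fold, plus mean and sample standard
deviation across folds.

## Architecture and training defaults

| parameter | default | rationale |
|---|---|---|
| seq_len | 50 | central-slice window length |
| n_blocks | 2 | small but non-trivial depth for 50-step sequences |
| n_heads × head_dim | 4 × 32 | standard multi-head split; inner width 128 |
| ff_dim | 128 | 2× the typical 64-dim feature width |
| dropout | 0.1 | light regularization for small cohorts |
| pooling | global average | attention pooling available via config |
| optimizer | Adam, lr 1e-3 | robust default for small transformers |
| batch_size / max_epochs / patience | 16 / 100 / 10 | CPU-friendly; early stopping governs the effective length |

The block width equals the feature dimension; if `model_dim` is set, a
single linear map projects the inputs first (no other input embedding is
used). Argmax ties break toward the lower class index, and the label
encoding is fixed: NC = 0, MCI = 1, AD = 2.

The entire network — forward pass, analytic gradients, Adam — is
implemented directly on NumPy arrays. This keeps the model exactly
reproducible under a fixed seed (one config seed drives initialization,
minibatch shuffling and dropout) and lets the test suite verify the
backward pass against central finite differences (observed agreement
~1e-10 in scaled error). The uniform-key-bias gradient is analytically
zero (a constant shift of all keys cancels in the softmax), which the
implementation reproduces.

## Cross-validation protocol

Rather than delegating to a library splitter, the split is an explicit
algorithm: per class, subjects are shuffled once with the seed and dealt
round-robin into `n_folds` test buckets, so test sets are disjoint, cover
every subject exactly once, and per-subset class proportions deviate from
the global proportions by at most one subject. For each fold the non-test
subjects are divided per class into train/validation with
`round(val_frac · n)` validation members (at least 1 when two or more
remain, never emptying the training set); `val_frac` defaults to 0.2. Fold
files follow the `traindata_Fold<i>.npy` / `trainlbl_Fold<i>.npy` (and
valid/test) convention, with a JSON manifest recording per-fold subject ids
in row order.

Splitting is deliberately at subject level only — slice-level splitting
would leak a subject's anatomy between train and test.

## Synthetic data: what it emulates and what it does not

Cohort MRI cannot ship with the package, so two seeded generators stand in:

* **Phantom volumes** (`PhantomSpec`): a bright ellipsoidal "brain"
  (intensity 0.8, radius 0.85 of the half-extent) containing a dark cavity
  (intensity 0.05) whose radius is `ventricle_scale` × the brain radius,
  plus Gaussian noise, clipped to [0, 1], written as NIfTI with 1 mm
  isotropic spacing. Default scales NC = 0.15, MCI = 0.25, AD = 0.35 are
  ordered to mimic ventricular enlargement under atrophy; the values
  themselves are arbitrary. Phantoms exercise slicing, resizing, PNG
  round-trips and encoder geometry — not MRI physics: there are no bias
  fields, no Rician noise, no anatomy beyond two ellipsoids.
* **Feature sequences** (`SyntheticFeatureSpec`): class `c` sequences are
  `separation · e_c` (orthogonal coordinate directions) + a class-independent
  positional waveform `positional_signal · sin(2πt/seq_len)` added to every
  feature dimension + unit-variance Gaussian noise. `separation` is
  therefore the between-class mean distance in noise-sd units, and
  `positional_signal` injects slice-order information. Defaults
  (20 subjects/class, 50 × 64, separation 6, positional signal 1) define a
  clearly separable but non-degenerate task; real ViT features are
  correlated across dimensions and slices in ways this generator does not
  model.

One global seed expands to per-subject sub-seeds as `seed + subject_index`,
so any subject is reproducible in isolation.

Consequently, passing tests show that the pipeline *recovers class
structure it is known to contain*, propagates slice order end to end, and
is deterministic and leak-free — they do not certify accuracy on clinical
MRI, which depends on real pretrained features and real cohorts.

## Numerical and design choices

* **Central window**: with `N` slices and window `k`, the window starts at
  `⌊(N−k)/2⌋`; for odd `N−k` the extra discarded slice comes from the top.
* **Resizing**: bilinear interpolation without anti-aliasing, output
  clamped to the input range; a same-size resize is the identity.
* **PNG quantization**: per-slice min–max scaling to 0–255; a constant
  slice maps to 0. Filenames zero-pad the source index so lexicographic
  order equals anatomical order.
* **Orientation**: the plane-to-axis mapping comes from the NIfTI
  orientation codes; volumes without usable orientation are assumed RAS
  with a logged warning.
* **Pre-LN blocks and sinusoidal (not learned) positional encodings**:
  stabler at small scale and fully deterministic/testable.
* **Degenerate metrics**: any 0/0 ratio (e.g. precision of a never-predicted
  class) is defined as 0 with a logged warning, so degenerate folds still
  aggregate.
* **Macro averaging** for multiclass precision/recall/F1, consistent with
  reporting balanced accuracy.
* **Problem sizes**: the bundled demo and the reproduction script use
  3 × 20 subjects with 50 × 64 sequences and 10 folds — large enough that
  stratification, early stopping and aggregation are all non-trivially
  exercised, small enough to run on one CPU in a few minutes.

## Known limitations

* The stub encoder is linear in patch means; it cannot represent texture
  contrasts a pretrained ViT would capture.
* Registration, bias correction and skull-stripping are out of scope; input
  volumes are assumed already standardized.
* No hyperparameter search, repeated/nested cross-validation, or
  between-model significance testing.
* The pretrained-ViT backend is optional and untested in CI (it requires
  downloading weights); it shares the geometry and interface of the stub.
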