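# Methods

## Model

The classifier operates on spectral-spatial patches: for each labeled pixel
(i, j) of a hyperspectral cube X ∈ ℝ^(M×N)×B, the s×s neighborhood of
spectra (after band reduction to D bands) forms one sample x ∈ ℝ^(s×s)×D
labeled by the focal pixel's class alone. The default geometry is s = 3,
D = 3.

One SCS layer scores each kernel against each spatial window:

    SCS(w, x) = sign(c) · |c|^p,   c = (w·x) / ((‖w‖ + q)(‖x‖ + q))

* The stabilizer is added to the *norms*, not to the vector components:
  this keeps the q = 0, p = 1 limit exactly equal to cosine similarity and
  directly addresses the numerical purpose of q (a small-magnitude window
  cannot blow up the quotient). The component-wise reading
  c = w·x / (‖w+q‖‖x+q‖) is available via `q_mode="componentwise"` for
  comparison; it is not scale-invariant and does not reduce to cosine.
* |c| ≤ 1 for every q ≥ 0 because (‖w‖+q)(‖x‖+q) ≥ ‖w‖‖x‖ ≥ |w·x|, so the
  sharpening exponent p ≥ 1 only contracts scores toward 0 while preserving
  sign — it sharpens the contrast between well-aligned and weakly aligned
  windows.
* q and p are trainable per kernel (scalars). During optimization q is
  clamped at 1e-6 and p at 1.0; defaults q = 0.1, p = 1.0 — p = 1 keeps the
  default model exactly the printed similarity while leaving sharpening
  available.
* The layer has no bias and no activation; absolute max-pooling (keep the
  signed entry of largest magnitude; ties to the first element in row-major
  order, for determinism) follows when the SCS output retains spatial
  extent. With 3×3 patches and a 3×3 kernel the SCS output is 1×1, so
  pooling degrades to identity but remains in the graph for larger patches.
* Head: flatten → dense → softmax. Nothing in between.

Gradients of the score w.r.t. w, q and p are derived in closed form
(`scs_score_grad`, and batched inside `nn.SCSLayer.backward`) and verified
against central finite differences; the pooling gradient flows only to the
selected element.

### Width

The SCS layer defaults to 256 units. The architecture depth/width is an
open choice, and at desk scale it interacts with the fixed training budget:
a 64×64 scene with half its pixels labeled yields ~300 training samples, so
50 epochs at batch 256 is only ~100 Adam steps at lr 0.001 — far too few to
reshape a narrow random feature bank. A wide bank of unit-sphere cosine
kernels makes the classes nearly linearly separable at initialization, so
the softmax head converges within the budget. Width is exposed in
`SCSLayerConfig`; 32 units behave identically once the step budget grows
(larger scenes or more labeled pixels).

### Baselines

`cnn2d`: Conv 3×3 (32 filters) + ReLU → max-pool → flatten → dense 100 +
batch-norm + ReLU → softmax. `lenet`: two 5×5 conv + ReLU + average-pool
stages (6 and 16 filters) → dense 120 → dense 84 → softmax. On patches
smaller than the kernels, convolutions switch to same-padding and pools
degrade to identity, with a logged note. All layers are numpy with exact
analytic backward passes (finite-difference-checked in the test suite), so
fixed-seed training histories are bit-reproducible on a given machine.

## Preprocessing

* **Band reduction.** Factor Analysis (scikit-learn) fitted on the
  (M·N)×B matrix of band-standardized spectra; pixels are mapped to D = 3
  factor scores, each re-standardized to zero mean / unit variance over the
  scene. "Most informative bands via FA" is read as projection to factor
  scores (dimension reduction), the standard FA output; a band-selection
  mode (original band with the largest absolute loading per factor) covers
  the alternative reading. Spectra are standardized before fitting so the
  factors reflect correlation structure rather than raw band scale — the
  output is then invariant to band-wise affine rescaling up to factor sign.
  Zero-variance bands are excluded with a warning.
* **Patches.** Zero padding by default at scene edges (mirror available);
  declared in the config so runs are reproducible. A full-scene mode
  extracts a patch at every pixel for map prediction.
* **Split.** Per-class 15/15/70 with largest-remainder rounding (ties
  resolve train → val → test; classes processed in ascending code order),
  giving per-class counts within one sample of the exact fractions. Classes
  with fewer than 3 samples go entirely to train with a warning (error in
  strict mode).

## Evaluation metrics

Rows of the confusion matrix are truth, columns prediction; per-class
TP/FP/TN/FN are one-vs-rest readings. Kappa uses the standard
marginal-product expected agreement A_e = Σ_c row_c·col_c / n²,
κ = (A_o − A_e)/(1 − A_e), returning 0 with a warning when A_e = 1. AA is
macro-averaged recall; F1 is reported per class, macro and
support-weighted (the two aggregations differ under class imbalance, so
both are always emitted). Two nonstandard printed variants that circulate
in the applied literature — a two-class expected-agreement formula missing
one marginal factor, and AA = (TP+TN)/(TP+TN+FN) — are implemented verbatim
behind `kappa_binary_literal` / `average_accuracy_literal` for inspection;
they are never used in reports because neither reduces to the definitions
the metric names promise. All report metrics are cross-checked in the tests
against label-level recounts and scikit-learn.

## Synthetic scenes

The generator emulates the structure of intraoperative tissue cubes, not
their optics: four classes with smooth non-negative mean spectra (baseline
plus 1–3 Gaussian bumps over band index), band-correlated Gaussian noise
(exponential correlation, length 5 bands, per-band std σ = 0.05), and a
contiguous layout — background frame (~M/10 wide), normal-tissue interior,
one elliptical tumor blob (radii ~0.12–0.18 of the scene), two sinusoidal
vessel tracks drawn 2 px thick (single-pixel tracks would be an unrealistic
vessel caliber at this ground resolution and are destroyed by 3×3
patching). Half of each class's pixels are labeled by default, emulating
partial annotation.

**Separation** is defined as the minimum pairwise *Mahalanobis* distance
between class means under the noise covariance σ²R, and the generator
rescales the drawn means so the realized value equals the request exactly
(a common non-negativity offset preserves all pairwise distances). Under
correlated noise this — not raw distance over σ — is what governs
attainable accuracy: at separation 10 the optimal per-pixel error rate is
negligible by construction, so pipeline accuracy measures the method, not
an accidental noise-geometry ceiling.

Default dims are 64×64×30 (not the ~400×500×826 of real acquisitions):
FA reduces to 3 factors either way and the pipeline is band-count-invariant
by design; 826-band generation works but is not the default problem size.
What passing on these scenes does **not** show: robustness to real tissue
optics (absorption/scattering signatures), illumination gradients,
specular glare, registration artifacts, or label noise from approximate
intraoperative annotation — none of which the generator models.

The layout and noise are drawn from a random stream independent of the
label-subsampling stream, so the cube is bit-identical across
`labeled_fraction` values; regenerating with fraction 1.0 yields the full
ground truth for map scoring.

## Numerical and design notes

* Cube intensities are promoted to float64 at load; the SCS quotient
  divides by potentially small norms and benefits from the headroom.
* Coordinates are 0-based (row, col), row-major, fixed once for patch
  extraction and map rendering to agree.
* ENVI (BSQ/BIL/BIP) and a JSON-headed `.npz` container are the cube
  dialects; masks are 16-bit PNG with a JSON sidecar naming classes;
  classification maps are palette-rendered PNGs that decode back to the
  exact predicted mask through the inverse palette.
* Training: Adam (β₁ = 0.9, β₂ = 0.999), softmax cross-entropy, defaults
  50 epochs / batch 256 / lr 0.001, random init (SCS kernels uniform on the
  unit sphere — only direction matters at q = 0; dense layers Glorot).
  Divergence (NaN loss) raises, naming the epoch. No early stopping.
* `compare_models` shares one patch set and split across all models and
  records the split's SHA-256, honoring a single-sample-set comparison
  protocol. Wall-times are reported but are hardware context, never part
  of any assertion.

## Known limitations

* CPU-only, desk-scale: the numpy layers are exact but not fast; very
  large scenes (e.g. 600×500×826) are feasible for I/O and FA but training
  a large patch set will be slow compared to framework implementations.
* Whether background pixels should enter training for every image is
  dataset policy; the pipeline trains on whatever classes the mask
  declares.
* The "RNN" and Xception baselines sometimes quoted alongside compact CNNs
  are out of scope: the former is architecturally a CNN duplicate, the
  latter is not desk-scale.
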