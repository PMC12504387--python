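# Methods

## The augmentation

`enhanced_ricap` builds each training sample from four sources: the batch
in its original order plus three independent shuffles of it, so every
position is paired with three random partners (self-pairing is allowed;
a batch of one degenerates gracefully).  Per source:

1. **CAM.** The adapter supplies the last convolutional layer's feature
   stack `F ∈ R^{d×h×w}` and the classifier weight vector of the source's
   *ground-truth* class; the CAM is their channel-weighted sum.  This
   requires a global-average-pool + linear head, the architecture family
   for which CAMs are defined.
2. **Peak.** The CAM argmax, ties broken first-in-row-major-order so the
   operator is deterministic.  The map-space coordinate `(ū, v̄)` maps to
   pixels as `u = round(ū·W/w)`, `v = round(v̄·H/h)`, clipped into bounds.
   This is the cell-origin convention; a half-cell offset `(ū+0.5)·W/w`
   would centre each map cell instead, but the difference (at most half an
   upsampling cell) is absorbed by the region size, and the plain form is
   kept.
3. **Region.** A crop ratio γ ~ Uniform(γ_min, γ_max) fixes the region at
   `round(W·γ) × round(H·γ)` (ties-to-even, never below one pixel).  The
   box is centred on the peak, then slid back inside the image with its
   size preserved.  Boxes are half-open `[u_l, u_r) × [v_t, v_b)` with
   0-based integer bounds and `v` increasing downward, which makes widths
   exact and tiling seam-free.
4. **Mass.** The CAM is bilinearly upsampled to image resolution
   (half-pixel-centre sampling; values never overshoot the input range),
   rectified by clamping negatives to zero, and summed inside the region
   and over the whole image.  Rectification is needed because raw CAMs can
   be negative, which would make mass ratios fall outside [0, 1].

The four label weights are `λ_i = patch_mass_i / total_mass_i`, normalised
to sum to one.  Two degenerate cases are defined explicitly: a source with
zero total mass (an untrained network) falls back to its patch's **area
fraction** — the classic RICAP weighting — and if all four raw weights are
zero the label splits equally.  The soft label is `ȳ = Σ λ_i·onehot(y_i)`
with duplicate classes accumulating.  Normalisation guarantees ȳ is a
probability vector; an unnormalised sum would rescale the loss arbitrarily.

**Tiling.**  Four independently sized patches cannot tile a canvas
exactly, so two layouts are provided.  `quadrant_resize` (default)
bilinearly resizes each patch to `(W/2)×(H/2)` and places them
top-left/top-right/bottom-left/bottom-right: no holes, deterministic
geometry, composite pixels are convex combinations of source pixels.
`anchored_overwrite` keeps native patch sizes, anchors each patch at its
quadrant's outer corner, lets later pastes overwrite earlier overlap, and
pre-fills the canvas with the first source's image.  Note that under
`anchored_overwrite` the label weights still reflect CAM mass, not visible
area, so heavily overlapping patches can credit occluded sources; the
resize layout avoids this and is the default.  Even canvas dimensions are
required and validated at configuration time.

`classic_ricap` is the reference baseline: a boundary point drawn from
`Beta(β, β)` on each axis splits the canvas into four rectangles, filled
by uniformly offset random crops and weighted purely by area fraction.
Zero-area rectangles are dropped from the label.

## Training integration

`train` runs epochs of mini-batch optimisation with soft-label
cross-entropy `−Σ_c ȳ_c log softmax(z)_c` (log-sum-exp stabilised) — the
standard loss for mixed-sample augmentation, where the target is a
distribution.  The first `cam_warmup_epochs` train on clean one-hot
batches so the network that supplies CAMs is not noise when mixing starts;
afterwards every batch is replaced by composites (no application
probability).  CAMs come from the model currently being trained, read in
inference mode; within one batch each source's CAM is computed once and
cached.  Shuffling and augmentation draw from two generator streams
spawned from one seed, so a warm-up-only run is bit-identical to an
unaugmented run at equal seeds — a property the tests assert.  Evaluation
always uses clean images and hard argmax predictions; precision, recall
and F1 are computed per class from the confusion matrix with zero (not
NaN) for empty rows or columns.

`TrainConfig` defaults mirror the reference fine-tuning recipe for large
pretrained backbones: Adam, learning rate 1e-4, weight decay 1e-5 (SGD is
selectable).  The *demo* runs in this repository train the tiny bundled
CNN from scratch and use learning rate 3e-3, batch 4, five epochs, two
warm-up epochs, γ ∈ (0.2, 0.9); these are run conditions, not library
defaults.

## The tiny CNN adapter

The bundled trainable model is a numpy CNN (im2col convolutions,
hand-written backward pass, Adam with L2 weight decay; the backward pass
is verified against finite differences in the tests).  Design choices that
matter at this scale:

- **Area-average downsampling to 16×16.**  Integrating each 14×14 pixel
  block preserves a small lesion's colour mass and suppresses pixel noise,
  where point sampling would alias it.
- **Median-colour subtraction.**  Leaf images are background-dominated;
  subtracting each image's median colour cancels the class-neutral
  background so localised symptom colour becomes the dominant signal.
- **Colour-basis stem.**  The first six 3×3 filters are fixed signed
  single-channel centre taps (+R, −R, +G, −G, +B, −B) at initialisation
  (they remain trainable).  Channel-opponent detectors therefore exist
  from step 0; without them, gradient descent at tiny step budgets
  reliably stalled in a symmetric optimum that merges two lesion colours.
- **Pointwise later layers.**  The second and third convolutions are 1×1,
  keeping the final features spatially local so the CAM stays aligned with
  the evidence; leaky ReLU (slope 0.1) avoids dead units in so small a
  network.
- GAP over the resulting 4×4×32 stack feeds a bias-free linear head, the
  CAM-compatible architecture.

## The synthetic fixture family

Each image is a green background (`(0.18, 0.42, 0.16)`) plus smoothed
Gaussian noise texture (σ = 12 px, amplitude 0.06, green-weighted), one
lesion blob with a Gaussian alpha profile (σ = 10 px, full amplitude at
the centre) whose colour encodes the class (brown / yellow / grey / rust /
pale for up to five classes), and additive pixel noise (sd 0.02).  Lesion
centres are drawn uniformly with a 3σ border margin and recorded in the
manifest, giving ground truth for localisation.  Defaults: 224×224 RGB,
three classes, stratified 80/10/10 split, PNG on disk for byte-exact
determinism.

What the family does and does not emulate: it reproduces the *structure*
of the problem — class identity carried by a small localised symptom on a
class-neutral background — but not the appearance statistics of real
leaves (shape, venation, lighting, multiple lesions, class imbalance).
Passing tests therefore demonstrate the mechanics of CAM-guided mixing
(localisation, weighting, label validity, trainability), not field
performance on real crops.

The analytic adapter closes the loop for testing: its feature map is a
single-channel Gaussian bump planted at the lesion's map-space coordinate
(σ scaled by `w/W`), so the CAM peak is the lesion by construction and
region-recovery claims become checkable against ground truth.

## Numerical and protocol choices

- Coordinates are `(u, v)` = (column, row); arrays are `(H, W, C)` floats
  in [0, 1].
- Bilinear resampling uses half-pixel-centre sampling and never
  overshoots; a 1×1 map broadcasts to a constant.
- `round` is ties-to-even throughout (numpy/Python semantics).
- All randomness flows through explicit `numpy.random.Generator` objects;
  training spawns separate shuffle/augmentation streams from one seed.
- The demo problem size is 300 images (100 per class), five epochs, CPU;
  the acceptance script uses 1000-trial Monte-Carlo checks for the
  stochastic properties.

## Known limitations

- With a concentrated, well-localised CAM and crop ratios ≳ 0.25, every
  patch captures essentially all of its source's mass, so λ ≈ ¼ each and
  the soft targets are maximally mixed.  Fitting such targets is a harder
  optimisation problem than clean classification; at the demo scale
  (5 epochs, 240 training images, a three-layer CNN) the augmented run's
  final accuracy varies considerably from seed to seed, which is why the
  smoke protocol averages three seeds.  At the scale the method is meant
  for (hundreds of epochs, deep pretrained backbones), the same mixing
  acts as regularisation rather than a fitting obstacle.
- CAM quality gates the method: early in training, or for architectures
  whose final features are spatially diffuse, peaks may sit off the
  evidence and the mixed labels inherit that noise.  The warm-up phase
  mitigates but does not eliminate this.
- `anchored_overwrite` can credit occluded sources (see above).
- The CNN adapter assumes square inputs and is deliberately small; it is a
  test vehicle, not a production classifier.
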