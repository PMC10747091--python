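# Methods

## Model

The enhancement stage models the first synaptic layer of the retina (the
outer plexiform layer) as a linear spatio-temporal low-pass filter followed
by a pointwise, luminance-driven nonlinearity.

**Filter.**  The photoreceptor transfer function is specified in the
frequency domain as

    F_ph(f_x, f_y, f_t) = 1 / (1 + β_ph + 2 α_ph (2 − cos 2πf_x − cos 2πf_y)
                               + j 2π τ_ph f_t).

The underlying one-dimensional form uses a single spatial frequency; its
two-dimensional extension is not uniquely determined.  We adopt the
separable-cosine term `2α(2 − cos 2πf_x − cos 2πf_y)`, the discrete-
Laplacian coupling conventional in OPL retina models, rather than an
isotropic radial variant.  The separable form has an exact inverse-DFT
kernel, so frequency-domain application is *exactly* a circular spatial
convolution; the test-suite exploits this as an independent oracle
(brute-force rolled-copy convolution, agreement < 1e-8, typically ~1e-13).

Frequencies are in cycles/pixel on [−0.5, 0.5) in standard unshifted DFT
order: DC sits at index (0, 0) and no `fftshift` is used anywhere.
Boundary handling is periodic — inherent to the DFT and required for the
convolution oracle to be exact.  The real part of the inverse transform is
taken (the imaginary residue of a Hermitian response is numerical noise),
and the filtered image — the local-luminance map `L` — is deliberately not
clipped: mild over/undershoot near sharp edges is harmless downstream and
clipping would break linearity.

For image sequences the temporal factor `1/(1 + j2πτf_t)` is discretized
as the exponential-smoothing recursion `y[t] = (x[t] + τ y[t−1])/(1 + τ)`,
which has unity DC gain and is initialized at the first frame.  Static
images drop the temporal term (`f_t = 0`).

**Adaptation.**  The pointwise light regulation is the Michaelis–Menten
response

    C = R (V_max + R0) / (R + R0),        R0 = V0 L + V_max (1 − V0).

The flattened source text of the response equation admits more than one
algebraic grouping; this grouping is the standard photoreceptor-adaptation
form and the only candidate satisfying both stated behaviours — dark
amplification (`C ≥ R` whenever `R0 ≤ V_max`) and the bright fixed point
(`C = V_max` at `R = R0 = V_max`).  The degenerate pixel `R + R0 = 0` is
assigned `C = 0`, the continuous limit from `R → 0`.  Output is clipped to
`[0, V_max]`; quantization (round half up) happens only on 8-bit file
write.  Colour images share one `R0` map computed from the channel-mean
luminance, preserving hue relations; an independent-per-channel mode exists
behind a flag.  Enhancement is intentionally not idempotent — applying it
twice brightens further.

**Parameters.**

| name  | default | units | role |
|-------|---------|-------|------|
| β_ph  | 0       | —     | gain control; DC gain is 1/(1+β) |
| α_ph  | 1       | —     | spatial cut-off of the low-pass |
| τ_ph  | 1       | frames| temporal smoothing for sequences |
| V0    | 0.7     | —     | strength of local adaptation, in [0, 1] |
| V_max | 255     | intensity | 8-bit ceiling |

The defaults are the heuristically tuned reference values; `V0 = 0`
disables local adaptation entirely (`R0 ≡ V_max`) and `V0 = 1` ties the
operating point to local luminance exactly.

## Dataset variants

V1 is grayscale (channel mean) + area-averaging resize (Pillow BOX) to the
classifier's 50×50 input.  V2 applies the enhancement first.  V3 applies
the enhancement, runs a landmark detector, and replaces the image by its
skeleton: 21 joints as filled discs (pixels at Euclidean distance strictly
below the radius) and 20 wrist-rooted bone chains as lines.  Lines use a
round-half-up DDA rule — `max(|Δr|, |Δc|) + 1` pixels with the minor
coordinate rounded at each major-axis step — chosen over a library
Bresenham because the rule is exactly specifiable, letting an independent
pure-Python enumeration reproduce the pixel set verbatim in tests.
Skeletons are rendered at the source resolution (radius 2 px and thickness
1 px at 200×200, scaled proportionally) and then resized.  Images where
the detector reports no hand are dropped and logged, so a "nothing in
view" class naturally vanishes from V3.

The bone topology is the five wrist-rooted digit chains (wrist→thumb,
…→pinky; 4 bones each).  Real landmark software typically adds palm edges
between finger bases instead of wrist spokes; the wrist-rooted variant is
visually equivalent for classification purposes and is fixed here.

## Classifier

A fixed small CNN on 50×50×1 inputs scaled to [0, 1]:
conv 16@2×2 (same) → maxpool 2×2/2 → conv 32@3×3 (same) → maxpool 3×3/3 →
conv 64@5×5 (same) → maxpool 8×8/8 → dense 128 → dense n_classes, ReLU
throughout and softmax output.  Same-padding convolutions with these pool
geometries are the unique conventional configuration reproducing the shape
chain 50→25→8→1 (the 3×3/3 pool drops the one-row remainder of 25).  The
dense width 128 is the unique width consistent with the 68,045-parameter
total given the convolutional structure.  Even kernels pad asymmetrically
(extra row/column bottom-right).  Max pooling is assumed (configurable in
principle); no dropout or weight decay is used.

The network is implemented directly on NumPy (im2col convolutions,
scatter-add col2im, Adam).  Backpropagation is validated by central-
difference gradient checks in float64 on sampled weights of every layer
(relative error < 1e-4).  Max-pool ties share gradient equally among
maxima; prediction ties break to the lowest class index.  Training
defaults — Adam, learning rate 1e-3, batch 32, 20 epochs — are package
choices, seeded end to end: identical seeds give identical runs
(single-threaded BLAS assumed for bit-identity).

## Synthetic data

The generators are first-class, tested code and define the study
conditions:

* **Dark scenes** emulate severe underexposure: exponential background
  (mass below intensity 30, the `dark_bias` fraction guaranteed by
  construction) with a few mid-gray discs inside the remaining pixel
  budget — structure an enhancement should recover.
* **Gesture glyphs** stand in for a photographic sign-alphabet set:
  29 classes, 200×200, each class a deterministic arrangement of four
  thick strokes and two discs (geometry drawn once per class from the
  seed), with per-sample jitter in position (±4 %), rotation (±0.12 rad)
  and stroke brightness (200–245) over a noisy dark background.  The
  NOTHING class is a near-blank dark frame.  20 samples per class is the
  default working size.
* **Dark corruption** rescales a bright image into [0, 30], adds Gaussian
  sensor noise (σ = 2) and requantizes — the same scene as captured by a
  badly underexposed camera.
* **Landmarks** jitter a fixed open-hand template; the synthetic detector
  gates on peak brightness *and* peak-to-median contrast (so blank frames
  fail even after global brightening) and derives the hand pose from
  bright-pixel moments, making detection a pure function of the image and
  approximately consistent within a class.

All generators are pure functions of their seed via NumPy's PCG64
(`default_rng`); fixed seeds give byte-identical files across machines.

What the synthetic experiments show — and do not.  Passing tests
demonstrate that the enhancement provably balances dark-biased histograms,
that the pipeline is wired correctly end to end, and that training on
enhanced inputs never trails training on raw inputs under dark corruption.
They do not measure performance on photographic hands: the glyphs are far
more separable than real gestures, so held-out accuracies saturate near
100 % for both raw and enhanced variants at these scales (the acceptance
script reports both numbers and their difference as computed).  Claims
about real-world accuracy gains would require real image data and a real
detector, both outside this package's scope.

## Problem sizes

The test-suite and acceptance script use 29 classes × 20 samples at
200×200 (580 images), an 80/20 held-out split, 20 training epochs, three
seeds for the raw-versus-enhanced comparison, and 100 seeded scenes at
100×100 for the histogram-balancing rate.  These sizes were chosen as the
smallest at which every effect of interest is comfortably resolved on a
single CPU.

## Known limitations

* Only the photoreceptor/OPL stage is modelled; contour-enhancing
  parvocellular and motion-sensitive magnocellular pathways are not.
* Periodic boundaries can leak opposite edges into `L` for images with
  strong edge-to-edge contrast; at the default α this is negligible past a
  few pixels from the border.
* The CNN is CPU-scale by design; no GPU path, no tiled processing of very
  large images.
* Bit-exact training reproducibility assumes a fixed BLAS thread
  configuration; results are otherwise statistically indistinguishable.
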