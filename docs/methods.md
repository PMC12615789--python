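# Methods

`forestmap` re-creates, at desk scale, a complete probabilistic
natural-forest mapping pipeline: fusing heterogeneous label sources into
training labels, training a multi-modal temporal-spatial vision transformer
on seasonal satellite composites, producing a stitched probability map from
overlapping inference windows, calibrating the probabilities, and assessing
the map against a stratified validation sample with design-based
estimators. Everything runs on synthetic scenes generated by the package
itself, so the pipeline is fully testable on one CPU with no data
downloads.

## Land-cover legend

Nine integer codes. Code 0 ("unknown") marks pixels whose label could not
be established and is never a prediction target; 1 = natural forest (the
class of interest), 2 = planted forest and 3 = tree crops (hard negatives —
tree cover that is not natural forest), 4 = other vegetation, 5 = built,
6 = water, 7 = permanent ice/snow, 8 = bare or sparse vegetation.

## Synthetic scenes (`forestmap.synthetic`)

A scene is a `SceneSample`: four seasonal 10-band surface-reflectance
composites (DJF/MAM/JJA/SON, bands B2–B12 at 10 m, reflectance in [0, 1]),
a topography stack (elevation m, slope°, aspect° clockwise from north), a
unit-sphere location vector, and a 0–8 label raster.

The generator emulates the statistical structure the method exploits, not
geography:

- **Layout.** Class regions are level sets of a smooth Gaussian random
  field partitioned at the target cumulative area fractions, giving
  contiguous blobs whose realized areas match the targets to within ties.
  Default fractions put natural forest at 34% of pixels and the hard
  negatives at ~38%, echoing the training-data composition the method was
  designed around.
- **Spectra.** Each class follows a fixed seasonal mean spectrum
  (broadleaf-like red edge and NIR for forests, dark NIR/SWIR for water,
  bright SWIR for bare ground, and so on). A `separation` dial moves every
  class spectrum towards or away from the all-class mean. South of the
  equator the seasonal curve is rolled by two composites, so phenology
  phase is latitude-dependent while the compositing calendar stays fixed.
- **Texture.** Planted forest carries an oriented sinusoidal row pattern,
  tree crops a sinusoidal grid, natural forest unstructured spatially
  correlated texture — the spatial cue that separates plantations from
  natural stands. Spatially correlated Gaussian noise (`noise_sigma`,
  default 0.02 reflectance) is added per band and season; reflectance is
  clipped to [0, 1] afterwards.
- **Topography.** Elevation is a smooth random field; slope and aspect are
  derived with a Horn 3×3 stencil on the 10 m grid. Flat pixels take
  aspect 0 by convention. The finite-difference oracle (a tilted plane) is
  exact on interior pixels; edges use clamped padding.
- **Label sources.** The `SourceStack` mimics the rasterized source
  datasets the fusion stage expects: two natural-forest layers, a
  forest-type layer, planted and tree-crop layers, per-class land-cover
  layers, canopy height, loss year, loss driver, a managed-forest-model
  natural probability, and year-2000 tree cover. Every boolean layer is
  the true class map flipped at configurable false-positive /
  false-negative rates (default 2%/2%).

What the generator does **not** emulate: clouds and compositing gaps,
mixed pixels, reprojection artifacts, inter-class spectral gradients,
realistic terrain–cover correlation, and real geographic layouts. Passing
tests therefore demonstrate that the pipeline's machinery is correct under
the assumed statistical structure, not that the model would reach any
particular accuracy on real imagery.

The `high_separation_layout` preset (separation 2.0, no reflectance noise,
noiseless sources) is used wherever a learning check must not be
bottlenecked by label quality; under it a nearest-centroid pixel classifier
on seasonal means exceeds 99% accuracy, so any competent model should
approach that ceiling.

## Label fusion (`forestmap.fusion`)

An ordered rule cascade produces one 0–8 label raster:

1. Candidate natural forest = union of the natural-forest sources, plus
   pixels where the managed-forest model gives p(natural) > 0.5, plus
   2001–2020 loss attributed to wildfire or other natural disturbance
   (assumed to regrow).
2. Remove pixels whose loss driver implies permanent conversion (permanent
   agriculture, hard commodities, settlements) and pixels with
   p(natural) < 0.3.
3. Intersect with the forest mask: canopy height strictly above 5 m, or
   natural-disturbance loss, or the forest-type layer.
4. Planted forest = union of planted sources ∩ forest mask (planted stands
   must meet the forest definition); tree crops = union of crop sources,
   *not* masked (crops need not).
5. Pixels claimed both by the natural candidate (evaluated on the raw
   claim of step 1, before the removals) and by planted/crops — and pixels
   claimed by planted and crops simultaneously — become unknown. Judging
   the overlap on the raw claim makes masking monotone: adding loss can
   demote a pixel to unknown but can never promote a competing forest
   class.
6. Water, ice, built and bare are assigned from their sources outside the
   forest mask, in that fixed priority order (spectrally most distinct
   first) when noisy sources overlap.
7. Other vegetation is conservative: assigned only where *all* its sources
   agree, year-2000 tree cover is ≤ 10%, and the forest mask is false.
8. Everything else stays unknown.

Thresholds 0.5/0.3 (natural-probability support/veto), 5 m (height) and
10% (tree cover) are fixed constants of the recipe.

## Model (`forestmap.model`)

A multi-modal temporal-spatial vision transformer. Full-scale
configuration: 8×8-pixel spatial patches (a 128-px scene → 256 tokens per
image), temporal patch 1, embedding 192, 6 heads, spatial encoder depth 2,
temporal encoder depth 2, decoder depth 4, MLP width 768, 8 output classes;
4.31 M parameters.

- Each modality (spectral stack, topography) is patch-embedded separately;
  learned spatial positional embeddings are shared across modalities and
  time; learned temporal embeddings of length 4 index the seasons
  (topography uses index 0).
- The **spatial encoder** (weights shared across modalities and time
  steps) self-attends over the patch sequence of every (modality, time)
  pair; the **temporal encoder** (also shared) attends over the time axis
  of every (modality, spatial token), length 4 for spectra and 1 for
  topography.
- Temporal-encoder outputs are mean-pooled over time — the "compressed"
  spatio-temporal embedding — giving one token per (modality, spatial
  position). The **decoder** then self-attends over the fused set: spectral
  tokens + topography tokens + one token from a linear projection of the
  location vector. Cross-attention from a query set would be an equally
  valid reading; plain self-attention over the fused set was chosen as the
  simpler mechanism.
- The head layer-norms the decoded spectral-token slots and maps each
  through an MLP to patch²·8 values, reshaped to per-pixel logits. No
  upsampling convolutions.
- Inputs are standardized per band with statistics computed on the
  training split and stored with the weights.
- Ensemble prediction is the arithmetic mean of member softmax outputs
  (probability averaging, not logit averaging).

Blocks are pre-norm transformer blocks with tanh-approximation GELU.
The implementation runs on a compact numpy reverse-mode autodiff core
(`forestmap.autodiff`, float32) with fused softmax/layernorm/GELU/
cross-entropy nodes; gradients were verified against directional finite
differences to the float32 noise floor (~0.2% relative).

## Training (`forestmap.training`)

Masked cross-entropy (unknown pixels carry no gradient; a batch with no
labelled pixel contributes exactly zero), Adam (β = 0.9/0.999, ε = 1e-8)
with learning rate 1e-3 and weight decay 3e-5, linear warmup over the first
10% of steps then cosine decay to zero, and global-gradient-norm clipping
at 1.0. Augmentation draws one of four right-angle rotations plus
independent horizontal/vertical flips, applied synchronously to every
modality, every time step and the labels; right angles avoid resampling.
The aspect band is moved geometrically but its angular values are not
recomputed — a known physical inconsistency of naive augmentation, accepted
here. Train/test splitting is block-wise: scenes are assigned to 100 km
blocks by their centre and whole blocks go to one side only, so spatial
autocorrelation cannot leak across the split.

**Desk scale.** The full-scale recipe (batch 512, 10 epochs over hundreds
of thousands of 128-px scenes, ensembles of five) is kept in the config
defaults but is not a single-CPU workload. The desk preset used by the
tests and the acceptance script trains three ensemble members on 48
high-separation 32-px scenes, spatial patch 4 (keeping 8×8 patches per
scene), embedding 48 with 4 heads, MLP width 192 (4× the embedding, the
same ratio as full scale), batch 8, 80 epochs — roughly ten minutes of
single-CPU time for the ensemble. Member seeds are derived from the run
seed, so the whole procedure is reproducible bit-for-bit at
initialization.

## Map construction (`forestmap.mapping`)

Inference windows are 1280 m squares planned on a regular grid of centres
(default stride 210 m; a final centre is clamped to the region edge when
the stride grid would leave a strip uncovered). Overlapping predictions
are averaged with inverse-distance weights w = 1 / max(d, 5 m), where d is
the distance from the pixel centre to the window centre; the 5 m floor
(half a pixel) removes the singularity at the central pixel. Distances are
in metres (the choice only matters through the floor). The weighted mean
is computed as deviations from the first covering window's value, which is
algebraically identical but exactly value-preserving for single-window
pixels and constant fields — inter-window seams on a constant scene are
exactly zero. Stitching is a convex combination, so the output is bounded
by the per-pixel min/max of the contributing windows.

Probabilities are quantized to integers 0–250 (q = round(250·p), half to
even; p = q/250), a probability resolution of 0.4% and a worst-case
round-trip error of 0.002. The recommended operating threshold 0.52 is
exactly representable (130/250). Tiles are written as tiled TIFFs (uint8,
nodata 255) carrying their affine transform and CRS in a JSON description
tag; the mosaic round trip is lossless. Only the natural-forest band is
exported by default; the model's full 8-class output is available in
memory.

## Calibration (`forestmap.calibrate`)

Calibration operates on the binary natural-vs-other probability through
the logit map: p' = σ(logit(p)/T). T is fitted by minimizing the binary
negative log-likelihood with bounded 1-D search on log T ∈ [log 0.1,
log 10] (deterministic; inputs clamped to [1e-6, 1 − 1e-6]; a flat
likelihood returns T = 1 by convention). Temperature scaling is strictly
monotone, so rankings and thresholded maps are preserved up to the
equivalent threshold — calibrating cannot change accuracy at a matched
operating point. Reliability is assessed with adaptive (equal-count)
binning, default 10 bins (the count is configurable; equal-count bins keep
per-bin variance comparable), optionally weighted by stratum inclusion
weights since validation data come from a stratified design; the expected
calibration error is the count-weighted mean absolute gap between mean
predicted probability and empirical positive fraction.

## Accuracy assessment (`forestmap.assess`)

Validation plots are 100 × 100 m (10 × 10 pixels, axis-aligned). A plot is
predicted natural when strictly more than 50% of its pixels meet p ≥ t
(exactly half → other; p ≥ t is closed on the left so t = 0 classifies
everything positive). Overall accuracy is a stratified mean of the
agreement indicator, OA = Σ N_h ȳ_h / Σ N_h with variance
(1/N²) Σ N_h²(1 − n_h/N_h) s²_h / n_h; user's and producer's accuracy are
combined ratio estimators R̂ = Ŷ/X̂ of the matching totals with
Taylor-linearized variance
(1/X̂²) Σ N_h²(1 − n_h/N_h)(s²_y + R̂²s²_x − 2R̂s_xy)/n_h. Confidence
intervals are ±1.96 SE, clipped to [0, 1]. The finite-population
correction is retained (it vanishes when N_h ≫ n_h and makes the census
limit exactly zero-variance); strata with a single plot contribute their
mean with a zero variance term and a logged warning. A threshold sweep
reports the full curve, the OA-optimal threshold (ties → smallest), the
balanced threshold minimizing |UA − PA|, and the near-optimal band of
thresholds with OA ≥ 99% of the maximum. High-confidence commission and
omission rates at extreme thresholds are raw (unweighted) counts; a
weighted variant is available through the estimator itself. The
validation-table reader accepts the released-style CSV schema (plot id,
lon/lat, binary label, stratum, optional region); per-stratum population
sizes can be supplied alongside, defaulting to the self-weighting
N_h = n_h when absent.

## Numerical and degenerate-input choices

- Float32 throughout the network; probability simplex holds to ~1e-7.
- Undefined ratios (no predicted or no reference positives) are reported
  as not-available rather than NaN.
- Quantization rejects inputs outside [0, 1]; dequantization rejects
  values above 250.
- Stitching validates that all window grids share one pixel lattice.
- `fit_temperature` requires n ≥ 100 and both label values present.
- All generators and the trainer are pure functions of (seed, config).

## Problem sizes used by the tests and the acceptance script

Unit tests run on 16–64-px scenes. The acceptance run uses: 60
high-separation 32-px scenes (48 train / 12 held out), a 3-member desk
ensemble, a 64-px region mapped with nine half-overlapping 32-px windows,
a stratified validation sample drawn from ~36 plot footprints at a 70%
sampling fraction, 10⁵-draw simulations for temperature recovery and
estimator-variance checks, and the printed worked examples (47/4 and
997/60 plots; 800 + 1,272 validation rows). These sizes were chosen so the
full pipeline demonstrates every stage in minutes on one CPU.

## Known limitations

- Desk-scale accuracy on synthetic scenes says nothing quantitative about
  full-scale accuracy on satellite imagery.
- The temporal encoder sees topography as a length-1 sequence (shared
  weights) rather than bypassing it; with temporal patch 1 this is a
  no-op architecturally but costs a few layer evaluations.
- The location token enters only at the decoder; alternative injection
  points (added to every token) were not explored.
- Gap masks for partially cloud-free composites are not implemented; the
  generator produces gap-free composites.
- No isotonic or Platt calibration alternatives; temperature scaling only.
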