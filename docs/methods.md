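# Methods

## Model

A scene is scored in three stages.

1. **Green-pixel classification.** The RGB planes (normalized to [0, 1]) are
   converted to hexcone HSV; a pixel is green iff its hue lies in
   [hue_min, hue_max] degrees, saturation ≥ saturation_min and value ≥
   value_min. Defaults: hue ∈ [60°, 180°], saturation_min = 0.15,
   value_min = 0.10 — a deliberately wide vegetation band in line with common
   green-extraction practice; all four numbers are parameters because the
   right band depends on camera, white balance and lighting. Achromatic
   pixels (R = G = B) are assigned hue 0 with saturation 0, so they can never
   pass a classifier with saturation_min > 0.

2. **Health index.** NDVI = (NIR − R)/(NIR + R) per pixel when a
   co-registered NIR band exists (values in [−1, 1] where defined), else
   VARI = (G − R)/(G + R − B) (unbounded). Pixels where the denominator
   vanishes are marked invalid and never aggregated: a 0/0 pixel carries no
   health information, and substituting 0 would silently dilute the mean.

3. **Scores.** GVI = 100·n_green/n_total. The mean health index is taken over
   pixels that are green *and* valid; EGVI = GVI · mean_index. By default
   each contributing index value is clipped to [0, 1] before averaging, so
   the mean acts as a health *weight* and 0 ≤ EGVI ≤ GVI is guaranteed;
   `clamp=False` keeps raw values (negative NDVI from water/shadow, or
   over-unity VARI, then flow through and EGVI may leave [0, GVI]). An empty
   green mask yields mean 0 and EGVI 0 rather than an error — no greenery is
   a valid observation. `n_aggregated` is always reported so the support of
   the mean is auditable.

Region sub-scoring crops all planes to a 0-based, half-open row/column
rectangle (row 0 at the top, raster convention) and reruns the same pipeline;
a full-frame region reproduces the whole-scene scores exactly.

## Synthetic scenes and what they do (not) show

The generator renders non-overlapping rectangles/ellipses of a green color on
a non-green background, each with a target health index v, and *solves* the
NIR plane per pixel so that (NIR − R)/(NIR + R) = v exactly:
NIR = R(1 + v)/(1 − v). Where that exceeds 1, NIR and R are jointly rescaled
by 1/NIR, preserving v while keeping planes in [0, 1]. v = 1 with R > 0 is
unrepresentable (rejected), as is R = 0 with v < 1.

Defaults emulate the two-location demonstration scene: a 15 × 11 canvas
(165 px) holding a 26-px tree (five crown rows of 3, 5, 7, 5, 3 px over a
3-px trunk — only the counts matter, the shape is arbitrary), tree index 0.9
at location 1 and 0.4 at location 2, gray background with index 0.05. The
palette sits on the 1/255 grid — green (12, 204, 12)/255 gives NIR exactly
228/255 (v = 0.9) and 28/255 (v = 0.4), background gray 95/255 gives
105/255 — so 8-bit file round trips are lossless and CLI scores equal
in-memory scores bit for bit.

Noise is additive Gaussian (`noise_sd`, intensity units, default 0) applied
to every plane after ground truth is frozen, then clipped to [0, 1], from a
single `numpy` generator stream seeded by `seed`; identical specs are
bit-reproducible.

Limits of the emulation: flat-colored regions have none of the texture,
shading, specularity or mixed pixels of street photography, and the gray
background is deliberately adversarial for noise studies — near-achromatic
pixels under noise acquire random hue and occasionally cross the saturation
threshold, so classifier contamination is visible at realistic noise levels.
Passing tests therefore validate the *arithmetic* of the pipeline and its
noise behaviour, not classifier accuracy on real imagery (for which the HSV
box must be tuned, or replaced by a learned segmenter).

## Numerical notes

- All intensity math is in [0, 1]: 8-bit sources are divided by 255, 16-bit
  by 65535, making the indices bit-depth independent.
- Index maps are written as float32 TIFF with NaN no-data (GDAL_NODATA tag),
  unclipped — clamping is an aggregation choice, not an I/O one.
  Georeferencing of input GeoTIFFs is not propagated to outputs.
- Under pixel noise σ the plug-in NDVI mean is a ratio estimator with a
  second-order bias ≈ 2σ²(NIR − R)/(NIR + R)³ that does not shrink with
  region area; the recovery tests budget this analytically alongside the
  3·SE sampling band. Recovery of a region's target index is measured over
  the ground-truth mask, separating index recovery from classification
  contamination.
- Reports round scores to 2 decimal places; the API keeps full precision.
  The exact worked-example values are GVI = 2600/165 = 15.7576%,
  EGVI = 14.1818% (v = 0.9) and 6.3030% (v = 0.4); published roundings of
  such figures (e.g. 15.7, 14.13, 6.28) differ from exact arithmetic by a
  few tenths of a percent.
- Test problem sizes: property and oracle checks use 10 × 10 random scenes
  (≥100 trials); noise-recovery uses a 10⁴-px region, where the 3·SE band is
  ≈ 0.001 in index units.

## Known limitations

- Co-registration of RGB and NIR is asserted (equal pixel grids), never
  solved; misaligned pairs must be registered upstream.
- VARI-based EGVI is computed per image only. Because VARI is relative, the
  batch command emits a calibration warning when VARI is selected;
  cross-image VARI calibration is out of scope.
- Wrap-around hue bands (e.g. for red targets) are unsupported; green never
  needs them.
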