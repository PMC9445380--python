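# greenview

Street-level greenery scoring from RGB and near-infrared imagery, for urban
planners and researchers quantifying how much — and how healthy — the
vegetation visible in a scene is.

## The indices

The classical **Green View Index** measures greenery *cover* only:

```
GVI = 100 · n_green / n_total
```

where `n_green` is the number of pixels classified as green vegetation (an
HSV-box threshold on hue, saturation and value) and `n_total` the pixel count
of the scene. Two streets with equally large but very differently healthy
trees get the same GVI.

The **Enhanced Green View Index** weights cover by vegetation health: the
mean per-pixel health index over the green pixels,

```
EGVI = 100 · n_green · (1/n Σᵢ NDVIᵢ) / n_total = GVI · mean(NDVI)
```

with `NDVI = (NIR − R)/(NIR + R)` when a co-registered near-infrared band is
available, or `VARI = (G − R)/(G + R − B)` from RGB alone. VARI measures
greenness relative to the scene rather than absolute health, so cross-scene
comparison of VARI-based scores requires calibration; NDVI is preferred.

`greenview` provides the classifier, per-pixel NDVI/VARI maps with validity
masks, whole-scene and region-of-interest scoring, raster I/O (PNG/JPEG/TIFF),
batch CSV reporting, and a synthetic scene generator with exact ground truth.

## Worked example

A 165-pixel scene holds a 26-pixel tree. At location 1 the tree is healthy
(uniform NDVI 0.9), at location 2 unhealthy (0.4):

```python
from greenview import make_worked_example, score_scene

for loc in (1, 2):
    bundle, _ = make_worked_example(loc)
    s = score_scene(bundle.rgb, bundle.nir, index_kind="NDVI")
    print(loc, s.to_dict())
```

prints

```
1 {'n_total': 165, 'n_green': 26, 'gvi': 15.76, 'index_kind': 'NDVI', 'mean_index': 0.9, 'n_aggregated': 26, 'egvi': 14.18}
2 {'n_total': 165, 'n_green': 26, 'gvi': 15.76, 'index_kind': 'NDVI', 'mean_index': 0.4, 'n_aggregated': 26, 'egvi': 6.3}
```

Both locations have identical cover (GVI 15.76%), but EGVI separates the
healthy tree (14.18%) from the unhealthy one (6.30%) — EGVI values scale in
the ratio of the health indices, 0.9/0.4.

The same from the shell:

```
greenview synth --location 1 --output-dir scenes
greenview score scenes/location1_rgb.png --nir scenes/location1_nir.tif
# location1_rgb [full] n_green=26/165 GVI=15.76 mean_NDVI=0.90 EGVI=14.18
```

`greenview batch manifest.csv --out report.csv` scores a whole CSV manifest,
and `--roi r0:r1:c0:c1` sub-scores rectangular regions.

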