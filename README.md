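# habstruct

Habitat structural complexity metrics from heightmaps/DEMs and binary
rasters:

* **Fractal dimension** — box-counting with bias mitigations (random grid
  origins, edge-box exclusion, intermediate-scale fitting) and the
  variation (windowed-oscillation) method, with regression diagnostics and
  a fractality-range assessment.
* **Rugosity** — surface-area / planar-area ratio from dual-diagonal
  triangulation, 1D chain rugosity, plane-of-best-fit slope correction,
  multi-resolution analysis, and an area-decoupled richness regression
  (`log S = a log A + b log R + c`).
* **Terrain metrics** — height range, terrain ruggedness index, slope and
  aspect, vector dispersion of facet normals.
* **Information metrics** — Shannon entropy (bits) of habitat composition,
  with an adjacency-pair entropy extension.
* **Simulators** — midpoint-displacement (diamond-square) and spectral
  (Fourier synthesis) fractional Brownian surfaces and profiles with known
  dimension (`D = 3 − H` for surfaces, `2 − H` for curves/excursion-set
  boundaries), Koch-curve rasters, and analytic fixtures (planes,
  sawtooths, hemispheres) that serve as exact oracles.
* **Bias study** — a reproducible pipeline that simulates maps of known D,
  runs naive and intermediate-scale protocols of both estimators, and
  tabulates estimator bias.

Everything is seeded and deterministic; no external data are required.

## CLI

One executable, `habstruct`, with subcommands:

```bash
# simulate a 513x513 fBm surface (H = 0.5) and write ESRI ASCII
habstruct simulate --kind mpd --hurst 0.5 --level 9 --seed 1 --out surf.asc

# box-count a binary raster over the intermediate scale window
habstruct boxcount --input koch.asc --eps auto --origins 32 --range intermediate --out d.csv

# variation-method dimension of a DEM (or a distance,height CSV profile)
habstruct variation --input surf.asc --range naive --out v.csv

# rugosity across grains, with optional slope correction
habstruct rugosity --input surf.asc --grains 1,2,4,8 --out r.csv

# terrain metrics / composition entropy
habstruct metrics --input surf.asc --metrics range,tri,slope,dispersion --out m.csv
habstruct entropy --input composition.csv --out h.csv

# the estimator-bias study from a YAML config
habstruct bias-study --config study.yaml --out bias.csv --plot bias.png
```

Raster formats: ESRI ASCII grid (`.asc`), single-band TIFF (`.tif`),
16-bit PNG with a JSON scaling sidecar (`.png`). Scales (box sizes,
grains, windows) are given in cells; cell size converts them to physical
units.

## Notes & limitations

* Heightmaps are 2.5D: overhangs and interstitial spaces cannot be
  represented, so all surface metrics describe the draped surface.
* Box counting excludes boxes that straddle the raster edge; give
  rasterized objects an empty margin at least as large as the biggest box
  (see `koch_curve_raster(..., margin=...)`) so the exclusion never drops
  foreground.
* The plain diamond-square generator has a known increment-scaling bias at
  high H; the spectral generator follows the target power spectrum closely
  and is preferred when exact scaling matters.
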