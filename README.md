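# palmage

Oil-palm plantation **extent and stand-age mapping** from SAR annual
mosaics and optical bare-soil-index time series — the full mapping chain
behind published 30 m oil-palm detection-year products for Southeast
Asia, implemented as a tested, reusable Python pipeline and exercised
end-to-end on synthetic satellite scenes with known ground truth.

It is written for remote-sensing researchers and methods developers who
want to study, stress-test or extend this family of mapping algorithms
without continent-scale imagery archives: every stage is a library
function or scikit-learn-style estimator, and a synthetic-scene generator
provides inputs with the statistical structure the pipeline assumes plus
per-pixel truth for recovery experiments.

## The method

**Extent.** An annual C-band mosaic is built from all scenes of the map
year: incidence-angle normalization (cosine law, reference 37.5°), a
trimmed temporal mean per polarization that discards the lowest 20% of
values per pixel, the VH−VV contrast (in dB the "VH/VV ratio" up to
sign), byte scaling, and the GLCM summed-average texture
SAVG = Σₖ k·p₍x+y₎(k) of each byte band over a radius-3 window. The study
area is cut into 12 equal grid tiles; in each tile 50,000 training pixels
are drawn and k-means models fitted for every cluster count k ∈ [10, 16],
keeping the k that maximizes the Calinski–Harabasz variance ratio.
Clusters are labelled oil palm from labelled reference points (the
stand-in for visual very-high-resolution checks), each tile's model
classifies the whole extent, and the 12 competing maps are reconciled by
majority: a pixel is oil palm iff **≥ 7 of 12** members vote palm.
Rule-based post-processing removes mapped palm with NDVI < 0.5
(settlements, roads), palm inside a given mangrove mask, fills SAR gaps
with a 3×3 modal filter (900 m² minimum mapping unit), and re-applies the
NDVI rule.

**Age.** Per palm pixel, a bare-soil-index series
BSI = ((SWIR+Red) − (NIR+Blue)) / ((SWIR+Red) + (NIR+Blue)) is computed
from cloud-masked observations starting 1984, smoothed with a
monthly-stepped trailing 12-month median (windows with < 3 observations
omitted). A threshold τ is calibrated as the **95th percentile** of the
map-year median BSI over all mapped palm pixels — it coincides with the
small share of still-open very young stands — and the series is scanned
backwards: the detection year is the year the smoothed BSI first drops
below τ after its last bare window (canopy closure, at a stand age of
2–3 years). Years are stored as 16-bit codes: 0 = NoData, 4 = 1984 (also
the left-censored bucket), …, 37 = 2017; codes 1–3 never occur.

**Accuracy.** Validation points are allocated 25% / 25% / 50% to three
strata (all reference maps agree on presence / on absence / any
disagreement), each labelled by 5–8 simulated raters with consensus kept
at ≥ 80% agreement, and accuracy is estimated design-based:
p̂ᵢⱼ = Wᵢ·nᵢⱼ/nᵢ, OA = Σⱼ p̂ⱼⱼ, UA/PA as row/column ratios, and
V(OA) = Σᵢ Wᵢ²·aᵢ(1−aᵢ)/(nᵢ−1) with a 95% normal CI.

## Worked example

```bash
palmage run-all --seed 1 --out palmage_run
```

runs the whole chain (simulate → mosaic → classify → postprocess → age →
validate → summarize) on the 256×256 reference scene and prints
`completed 7 stages; artifacts in palmage_run`. The manifest written by
this run records, per stage (seed 1):

```
simulate     palm_pixels: 18662, sar_scenes: 31, optical_observations: 816
classify     palm_pixels_raw: 16971, selected_k: [10, 11, 11, 12, 10, ...]
postprocess  palm_pixels_final: 16163  (ndvi_mask removed 1181 px, ...)
age          dated_pixels: 16163, bsi_threshold: -0.2859
validate     n_points: 1000, n_retained: 837, overall_accuracy: 0.9602
summarize    palm_area_ha: 1454.67
```

Reading the numbers: the ensemble maps 16,971 palm pixels against 18,662
in truth; the NDVI rule removes 1,181 of them (mostly still-bare young
stands and settlement confusion); the reconciled, cleaned extent agrees
with truth on 96.2% of pixels. The age stage dates every mapped palm
pixel with the BSI threshold calibrated at −0.286, and the stratified
design estimates 96.0% overall accuracy from the 837 consensus-labelled
validation points. `extent_by_period.csv` summarizes the mapped area by
detection period (before 2000 / 2000–2009 / 2010–2017), mirroring the
published per-region tables.

The same artifacts are available programmatically:

```python
from palmage.pipeline import PipelineConfig, run_pipeline
manifest = run_pipeline(PipelineConfig().with_seed(1), "palmage_run")
```

## Layout

| module | contents |
| --- | --- |
| `palmage.synthetic` | scenario config, landscape/SAR/optical generators, ground truth |
| `palmage.mosaic` | trimmed mean, incidence normalization, byte scaling, GLCM SAVG |
| `palmage.ensemble` | grid partition, `KSelectKMeans`, `GridClusterEnsemble`, majority vote |
| `palmage.postprocess` | NDVI/mangrove/slope rules, gap-fill filter, `MapPostProcessor` |
| `palmage.age` | BSI, 12-month median smoothing, threshold calibration, `BsiAgeModel`, year codes |
| `palmage.validation` | agreement strata, stratified design, rater consensus, accuracy estimators |
| `palmage.raster_io`, `palmage.pipeline`, `palmage.cli` | TIFF+metadata I/O, the stage driver, the `palmage` CLI |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
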