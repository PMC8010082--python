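# Methods

This note documents the models, parameter choices and numerical
conventions behind `palmage`, and what the synthetic-scene experiments do
and do not demonstrate about real data.

## 1. The synthetic scene

The generator emulates the *statistical structure* the mapping chain
relies on, not radiometry.

**Landscape.** Land cover (oil palm, forest, settlement, mangrove, water,
road) is a Voronoi tessellation of seeded points (~250 px per patch at
the default), with seed classes allocated by largest-remainder quota so
realized proportions track the configured fractions (default 30% oil
palm, 40% forest). Patch-based generation — rather than i.i.d. pixels —
makes texture features spatially meaningful, mirroring plantation block
geometry. "Road" is an ordinary patch class here, not a thin network; its
role is only to provide a low-NDVI, low-backscatter confuser.

**Planting campaigns.** Palm pixels are cut into ~100-px planting blocks
(estates plant holdings in phases). Each block gets a planting year from
an accelerating distribution — 30% / 40% / 30% of palm pixels over the
periods up to 1999, 2000–2009 and 2010–2016 for a 2017 map — allocated by
remaining-pixel-quota matching (period first, then year within period) so
the realized age structure is stable in any scene, plus a uniform
within-year planting date and a bare-phase duration drawn uniformly from
[2, 3] years. The recorded closure date is exactly planting date +
duration; the truth rasters carry class, planting year and closure date
per pixel. Planting acceleration is a documented property of the mapped
region (per-period extent summaries of the published product); it also
keeps a few percent of palm pixels still open-canopied at the map year,
which is the regime in which a 95th-percentile bare-soil threshold is
meaningful (§4).

**SAR.** Per scene and pixel, backscatter (dB) = class mean + incidence
term + Gaussian speckle. Class means/speckle (e.g. palm VV −9.0, VH
−13.5, sd 1.0 dB; forest −6.8/−11.8; settlement −3.0/−9.0 with sd 3 dB)
are package defaults chosen for class separability — the real study
publishes none — and are configuration, not ground truth. The incidence
term is linear in cos θ with slope 10/(ln10·cos 37.5°) ≈ 5.47 dB per unit
cos θ and zero at the 37.5° reference, i.e. the local linearization of
the cosine law that the mosaic module inverts; θ ramps 32°→43° across the
scene with ±1.5° per-scene jitter. One scene every 12 days (the paper
does not state Sentinel-1 scene counts; this is an assumption recorded
here) gives 31 scenes in the map year.

**Optics.** Two observations per month from 1984 (emulating the combined
Landsat 5+7 revisit), four bands (blue, red, NIR, SWIR). Every pixel has
a class template; palm pixels switch from a forest-like template before
planting to a bare-soil template (BSI ≈ +0.21) at planting, then ramp
*linearly* to the closed-canopy palm template (BSI ≈ −0.34) over the
final `canopy_transition_years` (default 1.0 y), reaching it exactly at
the closure date. The ramp reflects progressive canopy development; a
step trajectory would make the percentile threshold calibration (§4) a
knife edge with no stable answer. Noise: per-observation band noise sd
0.016 (≈ 0.05 in BSI units at the canopy denominator) plus a static
per-pixel band offset sd 0.008 (spatial variability); clouds are flagged
independently per observation with probability 0.30 (CFMASK emulation);
flagged pixels carry no usable signal.

All randomness flows through `SeedSequence` streams keyed by (seed,
stream, index), so outputs are bit-identical for identical (config,
seed) and independent of evaluation order. The optical archive is
generated lazily per observation: a dense 4-band, 816-observation stack
does not fit in memory at useful raster sizes.

**What passing tests show — and do not.** Recovery results demonstrate
the *internal consistency* of the chain under its own assumptions:
Gaussian class-conditional backscatter, piecewise reflectance templates,
independent clouds, no mixed pixels, no atmosphere, no terrain
radiometry, no class confusion beyond what noise induces. Real scenes
violate all of these; numbers obtained here do not transfer to real
archives.

## 2. Annual mosaic

* Trimmed temporal mean: per pixel, the floor(0.2·n) smallest valid dB
  values are dropped, the rest averaged. The floor rule is a convention
  (no rounding rule is published). Note the trim biases a symmetric noise
  distribution upward by σ·φ(Φ⁻¹(q))/(1−q) (≈ +0.35σ at q = 0.2); tests
  compare mosaic class means against this analytic trimmed-Gaussian
  expectation, and the bias is class-wise constant so clustering is
  unaffected.
* Incidence normalization: σ_norm = σ − 10·log10(cos θ / cos 37.5°);
  angles outside [20°, 50°] are masked. The published text names the step
  but not the law; the cosine law and the 37.5° reference (mid-swath) are
  package choices.
* Temporal means are computed in dB. Whether the original mosaic averaged
  in linear power or dB is unstated; dB averaging is the package choice,
  flagged for sensitivity analysis.
* Byte scaling: linear, round-half-up, clipped; default ranges VV
  [−25, 0], VH [−32, −5], VH−VV [−15, 5] dB (package defaults, none are
  published).
* SAVG texture: symmetric GLCM over a (2r+1)² window (default r = 3),
  distance-1 pairs **pooled over the four directions into one matrix**
  before normalization; SAVG = Σ k·p₍x+y₎(k) = the mean grey-level sum
  over all window pairs. Pooling (rather than averaging per-direction
  normalized matrices) is the package convention; the two differ only
  through unequal directional pair counts (42/42/36/36 in a 7×7 window).
  The implementation computes integer pair sums by convolution and is
  bit-exact against literal pair enumeration. Texture is defined only
  where the window is fully inside the raster and fully valid.

## 3. Classification ensemble

Features are the three byte bands plus their three SAVG textures,
z-scored per band over each tile's training sample before clustering —
unscaled byte and texture ranges would otherwise dominate Euclidean
distances. Defaults follow the published design: 12 tiles (raster-space
near-square factorization; the real study tiled five-degree geography),
50,000 training points per tile (drawn within-tile; with replacement and
a logged warning when a tile holds fewer valid pixels), k ∈ [10, 16]
selected by the Calinski–Harabasz criterion (the original unsupervised
routine implies an internal model selection but names no criterion), and
the strict 7-of-12 reconciliation.

Cluster labelling replaces visual high-resolution inspection with
labelled reference points: a cluster is oil palm iff its reference share
is strictly above 0.5, with at least 10 points (clusters below the
minimum are conservatively non-palm). Member-map gap pixels (e.g.
texture borders) count as 0-votes in the reconciliation; a config switch
(`renormalize_votes`) instead rescales the threshold to the valid vote
count.

## 4. Detection-year model

BSI uses the standard four-band bare-soil index (the source text names
BSI but never writes a formula). Smoothing is a trailing 12-calendar-
month median stepped monthly (the step size is not published), keeping
windows with ≥ 3 cloud-free observations. The threshold τ is the 95th
percentile — linear interpolation between order statistics — of the
map-year December-window median BSI over all mapped palm pixels.

The per-pixel scan: with A the set of valid windows with median ≥ τ,

* map-year December window in A → still bare → map-year code;
* A empty (never bare in the archive, or no valid windows) → the
  left-censored archive-start code 4;
* otherwise, the detection year is the calendar year of the first valid
  below-τ window after max(A) (or of max(A) itself if nothing valid
  follows).

The published description scans "pixels above the threshold in 2017"
backwards, which cannot by itself date long-closed stands; the semantics
above — both branches, with explicit censoring — is this package's
reading and is applied uniformly.

Why the calibration works here: the map-year median-BSI distribution has
a closed-canopy mode, a thin continuum from stands mid-transition, and a
bare plateau mode from the youngest stands. With the default planting
distribution the plateau holds under 5% of palm pixels and plateau +
transition over 5%, so the 95th percentile lands inside the wide
inter-mode interval; any τ there intersects each pixel's closure ramp
within its final year, giving detection within ±1 year of truth. If the
still-bare share is made to exceed ~5% (or young stands are removed
entirely), the percentile lands inside a mode and dating degrades — a
genuine property of percentile calibration, not an implementation
artifact.

## 5. Post-processing

Rules run in the published order ndvi → mangrove → fill → ndvi-recheck,
and each mask rule only ever removes palm. The NDVI source is the
map-year median composite (the source sensor is not named). The fill
filter is gap-restricted — it fills flagged gaps with the modal class of
valid neighbours, ties to non-palm — rather than a global smoother, so a
single unmasked 30 m palm pixel (900 m², the minimum mapping unit)
survives. Slope handling is reduced to a gap-mask heuristic: Horn slope
> 20° on aspects facing away from the radar look direction; the exact
correction applied in the original processing ("with respect to
hillshades") is not recoverable from its description, so this stands in
and is entirely config-driven. Note the NDVI rule removes genuinely
young (still-bare) plantations along with settlements; the published
product shares this behaviour.

## 6. Accuracy estimation

Strata come from three-map agreement; in the pipeline the "three other
maps" are synthetic degradations of the generator truth (5/8/10% flipped
pixels). Allocation 25/25/50 uses largest-remainder rounding (ties to
the earlier stratum) so totals are exact. Rater consensus: "maybe" votes
are excluded from the agreement denominator by default (a config switch
counts them as disagreement); 80% is inclusive; fewer than 5 raters
discards the point.

Estimators are design-based for stratified random sampling **where the
strata differ from the map classes**: cell proportions p̂ᵢⱼ = Wᵢnᵢⱼ/nᵢ,
OA = Σp̂ⱼⱼ, UA/PA as ratios, with Taylor-series ratio-estimator variances
per stratum; for OA this reduces exactly to
V = Σ Wᵢ²aᵢ(1−aᵢ)/(nᵢ−1). CIs are normal 95%. Whether the published CIs
were design-based or binomial is not stated; the design-based choice is
recorded in the report metadata. Strata with fewer than two retained
points are dropped with weight renormalization. Calibration tests
confirm unbiasedness (≤ 0.5 points over 500 draws) and 93–97% CI
coverage over 1,000 replicates on scenes of this size.

## 7. Numerical and I/O conventions

* Round-half-up for byte scaling (`floor(x + 0.5)`), avoiding banker's
  rounding surprises at the midpoint.
* Invalid pixels propagate as explicit masks; data gaps never raise.
* Problem sizes: the reference scene is 256×256 at 30 m (≈ 59 km²), 31
  SAR scenes, 816 optical observations; tests use 96×96 and smaller.
  These sizes keep every experiment a desk-scale computation while
  leaving all per-tile sample sizes at their published values.
* Rasters are TIFFs with grid, NoData, band names and provenance stored
  as JSON in the ImageDescription tag (round-trip exact). The
  detection-year map is unsigned 16-bit, NoData 0, codes 4..37 — the
  published product's convention. Validation points are written as
  GeoJSON and CSV; reports as JSON and plain text.

## 8. Known limitations

* No radiometric realism (orbit geometry, terrain radiometry,
  atmosphere); separability is a configured property, so classification
  scores here are upper bounds of a structural kind, not forecasts.
* The slope/hillshade correction is a stand-in heuristic (§5).
* Ages are detection years (stand age ≈ detection − 2 to 3 years);
  converting to exact age or yield is out of scope, as is validating age
  against imagery.
* The planting-block quota assignment makes small scenes slightly less
  random in their age structure than a fully i.i.d. draw; the year
  *distribution* is as configured.
* Left-censoring: stands closed before ~1985 cannot be dated and share
  code 4 with 1984 plantings.
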