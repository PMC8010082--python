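"""Synthetic landscapes, SAR stacks and optical time series with ground truth.

The generator produces the statistical structure the mapping pipeline
assumes, not radiometric realism:

* a patch-based land-cover map (oil palm, forest, settlement, mangrove,
  water, road) built by seeded Voronoi growth, so that texture features are
  spatially informative the way plantation blocks are;
* class-conditional C-band backscatter (VV/VH, dB) with Gaussian speckle
  and a linear-in-cos(theta) incidence-angle term;
* per-pixel optical reflectance trajectories in which an oil-palm pixel is
  forest-like before planting, soil-like (high bare-soil index) for the
  2-3 year open-canopy phase, and palm-canopy-like after closure;
* independent per-observation cloud gaps emulating CFMASK flags.

Every draw is routed through :class:`numpy.random.SeedSequence` streams
derived from the scenario seed, so all outputs are bit-identical for an
identical (config, seed) pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .grid import RasterGrid

__all__ = [
    "CLASS_NAMES",
    "CLASS_CODES",
    "OIL_PALM",
    "ClassSarParams",
    "ClassOpticalParams",
    "ScenarioConfig",
    "ConfigurationError",
    "LandscapeTruth",
    "SarScene",
    "OpticalObservation",
    "OpticalSeries",
    "generate_landscape",
    "simulate_sar_stack",
    "simulate_optical_series",
    "synthetic_dem",
]

CLASS_NAMES = ("oil_palm", "forest", "settlement", "mangrove", "water", "road")
CLASS_CODES = {name: i + 1 for i, name in enumerate(CLASS_NAMES)}
OIL_PALM = CLASS_CODES["oil_palm"]

# Seed-stream tags: keep sub-generators independent of each other.
_STREAM_LANDSCAPE = 1
_STREAM_SAR = 2
_STREAM_OPTICAL = 3
_STREAM_DEM = 4

# Slope of the incidence-angle term, matched to the local slope of the
# 10*log10(cos theta) law at the 37.5 deg reference so that the cosine-law
# normalization in the mosaic module removes it almost exactly.
_COS_LAW_SLOPE_DB = 10.0 / (math.log(10.0) * math.cos(math.radians(37.5)))


class ConfigurationError(ValueError):
    """Invalid scenario or pipeline configuration."""


@dataclass(frozen=True)
class ClassSarParams:
    vv_db: float
    vh_db: float
    speckle_sd_db: float = 1.0


@dataclass(frozen=True)
class ClassOpticalParams:
    """Mean surface reflectance per band plus per-observation noise sd."""

    blue: float
    red: float
    nir: float
    swir: float
    noise_sd: float = 0.016

    def as_array(self) -> np.ndarray:
        return np.array([self.blue, self.red, self.nir, self.swir])


def _default_fractions() -> dict:
    return {
        "oil_palm": 0.30,
        "forest": 0.40,
        "settlement": 0.08,
        "mangrove": 0.10,
        "water": 0.07,
        "road": 0.05,
    }


def _default_sar() -> dict:
    # Synthetic defaults chosen for class separability; the real study
    # publishes no class-conditional backscatter statistics.
    return {
        "oil_palm": ClassSarParams(-9.0, -13.5, 1.0),
        "forest": ClassSarParams(-6.8, -11.8, 1.0),
        "settlement": ClassSarParams(-3.0, -9.0, 3.0),
        "mangrove": ClassSarParams(-6.0, -11.0, 1.0),
        "water": ClassSarParams(-18.0, -26.0, 1.5),
        "road": ClassSarParams(-14.0, -22.0, 1.5),
    }


def _default_optical() -> dict:
    # "bare_soil" is the open-canopy phase template for young oil palm.
    return {
        "oil_palm": ClassOpticalParams(0.03, 0.05, 0.40, 0.16),
        "bare_soil": ClassOpticalParams(0.08, 0.20, 0.28, 0.35),
        "forest": ClassOpticalParams(0.03, 0.04, 0.45, 0.18),
        "settlement": ClassOpticalParams(0.10, 0.18, 0.22, 0.25),
        "mangrove": ClassOpticalParams(0.03, 0.04, 0.35, 0.12),
        "water": ClassOpticalParams(0.05, 0.04, 0.02, 0.01),
        "road": ClassOpticalParams(0.09, 0.15, 0.20, 0.22),
    }


@dataclass(frozen=True)
class ScenarioConfig:
    """Scenario parameters for one synthetic scene.

    The defaults define the package's reference scene: a 256x256 raster at
    30 m with ~30% oil palm, speckled SAR scenes every 12 days of the map
    year, two optical observations per month from 1984, 30% cloud
    probability per observation, and a planting-year distribution that
    leaves a few percent of palm pixels still in the bare phase at the map
    year (so the 95th-percentile BSI threshold falls between the
    closed-canopy and bare modes, as in the real calibration).
    """

    rows: int = 256
    cols: int = 256
    class_fractions: dict = field(default_factory=_default_fractions)
    sar_params: dict = field(default_factory=_default_sar)
    optical_params: dict = field(default_factory=_default_optical)
    pixel_offset_sd: float = 0.008      # per-pixel, per-band reflectance offset
    bare_phase_range: tuple = (2.0, 3.0)   # years of open canopy after planting
    canopy_transition_years: float = 1.0   # final ramp from bare to closed canopy
    planting_year_span: int = 35        # planting years: [map_year-span, map_year-1]
    # Planting accelerates over time, as in the published per-period extent
    # summaries: shares for the spans [start, map-18], (map-18, map-8] and
    # (map-8, map-1] (for a 2017 map: before 2000 / 2000-2009 / 2010-2016).
    planting_period_fractions: tuple = (0.30, 0.40, 0.30)
    cloud_prob: float = 0.30
    optical_per_month: int = 2          # combined Landsat 5+7 revisit
    sar_revisit_days: int = 12
    archive_start: int = 1984
    map_year: int = 2017
    patch_pixels: int = 250             # mean patch size for Voronoi growth
    planting_block_pixels: int = 100    # planting-campaign block size within palm
    incidence_ref_deg: float = 37.5
    incidence_span_deg: tuple = (32.0, 43.0)
    incidence_jitter_deg: float = 1.5   # per-scene angle wobble
    seed: int = 0

    def __post_init__(self) -> None:
        fr = self.class_fractions
        unknown = set(fr) - set(CLASS_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown classes in fractions: {sorted(unknown)}")
        vals = np.array([fr.get(c, 0.0) for c in CLASS_NAMES], dtype=float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise ConfigurationError("class fractions must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"class fractions sum to {vals.sum()!r}, expected 1")
        lo, hi = self.bare_phase_range
        if not (0.5 <= lo <= hi <= 5.0):
            raise ConfigurationError("bare_phase_range must lie within [0.5, 5] years")
        if not (0.0 <= self.cloud_prob < 1.0):
            raise ConfigurationError("cloud_prob must lie in [0, 1)")
        if self.map_year <= self.archive_start:
            raise ConfigurationError("map_year must follow archive_start")

    @property
    def grid(self) -> RasterGrid:
        return RasterGrid(self.rows, self.cols)

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=int(seed))


@dataclass
class LandscapeTruth:
    """Ground truth for one synthetic scene.

    ``planting_year`` is 0 (undefined) everywhere except oil-palm pixels;
    ``closure_date`` is the exact fractional-year date at which the canopy
    closes (planting date + drawn bare-phase duration) and NaN elsewhere.
    """

    class_raster: np.ndarray          # uint8, codes 1..6
    planting_year_raster: np.ndarray  # int16, calendar year, 0 = undefined
    planting_date_raster: np.ndarray  # float64 fractional year, NaN off-palm
    closure_date_raster: np.ndarray   # float64 fractional year, NaN off-palm
    grid: RasterGrid

    def __post_init__(self) -> None:
        palm = self.class_raster == OIL_PALM
        if not np.array_equal(palm, self.planting_year_raster > 0):
            raise ValueError("planting year must be defined exactly on oil-palm pixels")
        for r in (self.planting_year_raster, self.planting_date_raster,
                  self.closure_date_raster):
            if r.shape != self.grid.shape:
                raise ValueError("all truth rasters must share the grid")

    @property
    def palm_mask(self) -> np.ndarray:
        return self.class_raster == OIL_PALM

    def class_mask(self, name: str) -> np.ndarray:
        return self.class_raster == CLASS_CODES[name]

    @property
    def closure_year_raster(self) -> np.ndarray:
        """Calendar year of canopy closure (int), -1 off-palm."""
        out = np.full(self.grid.shape, -1, dtype=np.int32)
        m = self.palm_mask
        out[m] = np.floor(self.closure_date_raster[m]).astype(np.int32)
        return out


@dataclass
class SarScene:
    """One SAR acquisition: VV/VH backscatter (dB) and incidence angle."""

    vv_db: np.ndarray
    vh_db: np.ndarray
    incidence_angle: np.ndarray  # degrees
    date: np.datetime64
    valid: np.ndarray            # bool
    grid: RasterGrid


@dataclass
class OpticalObservation:
    """One cloud-flagged multispectral observation of the whole scene."""

    date: np.datetime64
    time_years: float            # fractional calendar year
    blue: np.ndarray
    red: np.ndarray
    nir: np.ndarray
    swir: np.ndarray
    cloud: np.ndarray            # bool; flagged pixels carry no usable signal

    @property
    def valid(self) -> np.ndarray:
        return ~self.cloud

    def bands(self) -> np.ndarray:
        return np.stack([self.blue, self.red, self.nir, self.swir])


def _largest_remainder_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total`` with largest-remainder rounding."""
    quotas = fractions * total
    counts = np.floor(quotas).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def generate_landscape(config: ScenarioConfig) -> LandscapeTruth:
    """Grow a patchy class map and assign planting years to palm patches.

    Patches are Voronoi cells of seeded points; seed classes are allocated
    by largest-remainder quota so realized class proportions track the
    configured fractions. Oil-palm pixels are further cut into planting
    blocks that each receive one planting campaign (year, within-year date
    and bare-phase duration); see :func:`_assign_planting`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_LANDSCAPE]))
    rows, cols = config.rows, config.cols
    n_pix = rows * cols
    fractions = np.array([config.class_fractions.get(c, 0.0) for c in CLASS_NAMES])

    n_seeds = max(int(round(n_pix / config.patch_pixels)), int((fractions > 0).sum()))
    seed_classes = np.repeat(
        np.arange(1, len(CLASS_NAMES) + 1),
        _largest_remainder_counts(fractions, n_seeds),
    )
    rng.shuffle(seed_classes)
    seed_idx = rng.choice(n_pix, size=n_seeds, replace=False)
    seed_xy = np.column_stack(np.unravel_index(seed_idx, (rows, cols))).astype(float)

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    pix_xy = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    _, patch_of_pixel = cKDTree(seed_xy).query(pix_xy, k=1)
    class_raster = seed_classes[patch_of_pixel].reshape(rows, cols).astype(np.uint8)

    planting_year = np.zeros((rows, cols), dtype=np.int16)
    planting_date = np.full((rows, cols), np.nan)
    closure_date = np.full((rows, cols), np.nan)
    palm = class_raster == OIL_PALM
    if palm.any():
        _assign_planting(config, palm, planting_year, planting_date,
                         closure_date, rng)

    return LandscapeTruth(class_raster, planting_year, planting_date,
                          closure_date, config.grid)


def _planting_year_weights(config: ScenarioConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-year pixel weights over the planting span.

    Planting accelerates over time as in the published per-period extent
    summaries; within each period years are weighted uniformly.
    """
    span = config.planting_year_span
    years = np.arange(config.map_year - span, config.map_year)
    f_old, f_mid, f_new = config.planting_period_fractions
    n_old = max(span - 17, 1)
    n_mid = min(10, span - n_old)
    n_new = span - n_old - n_mid
    weights = np.concatenate([
        np.full(n_old, f_old / n_old),
        np.full(n_mid, f_mid / n_mid) if n_mid else np.empty(0),
        np.full(n_new, f_new / n_new) if n_new else np.empty(0),
    ])
    return years, weights / weights.sum()


def _assign_planting(config: ScenarioConfig, palm: np.ndarray,
                     planting_year: np.ndarray, planting_date: np.ndarray,
                     closure_date: np.ndarray, rng) -> None:
    """Assign planting campaigns to palm pixels.

    Estates plant large holdings in phases, so palm pixels are cut into
    planting blocks (a denser Voronoi partition, ~``planting_block_pixels``
    each) that each receive one campaign: a planting year, a uniform
    within-year date and a bare-phase duration. Years are allocated to
    blocks by remaining-pixel-quota greedy matching — first at the period
    level, then per year inside the chosen period — so the realized
    pixel-weighted age structure tracks the configured distribution even
    in scenes with few, unequal patches.
    """
    rows, cols = palm.shape
    palm_rc = np.column_stack(np.nonzero(palm)).astype(float)
    n_palm = palm_rc.shape[0]
    n_blocks = max(1, int(round(n_palm / config.planting_block_pixels)))
    seed_rows = rng.choice(n_palm, size=min(n_blocks, n_palm), replace=False)
    _, block_of_px = cKDTree(palm_rc[seed_rows]).query(palm_rc, k=1)
    n_blocks = len(seed_rows)
    block_sizes = np.bincount(block_of_px, minlength=n_blocks)

    years, weights = _planting_year_weights(config)
    span = years.size
    n_old = max(span - 17, 1)
    n_mid = min(10, span - n_old)
    period_of_year = np.repeat([0, 1, 2], [n_old, n_mid, span - n_old - n_mid])
    period_quota = np.array([w * n_palm for w in
                             (np.add.reduceat(weights, [0, n_old, n_old + n_mid]))])
    year_quota = weights * n_palm
    p_jit = rng.random(3) * 1e-6
    y_jit = rng.random(span) * 1e-6

    block_year = np.zeros(n_blocks, np.int64)
    for b in np.argsort(-block_sizes, kind="stable"):
        period = int(np.argmax(period_quota + p_jit))
        in_period = period_of_year == period
        masked = np.where(in_period, year_quota + y_jit, -np.inf)
        pick = int(np.argmax(masked))
        block_year[b] = years[pick]
        period_quota[period] -= block_sizes[b]
        year_quota[pick] -= block_sizes[b]

    lo, hi = config.bare_phase_range
    frac = rng.random(n_blocks)
    durations = rng.uniform(lo, hi, size=n_blocks)
    px_year = block_year[block_of_px]
    px_date = px_year + frac[block_of_px]
    px_close = px_date + durations[block_of_px]
    planting_year[palm] = px_year.astype(np.int16)
    planting_date[palm] = px_date
    closure_date[palm] = px_close


def _incidence_field(config: ScenarioConfig, jitter: float) -> np.ndarray:
    lo, hi = config.incidence_span_deg
    ramp = np.linspace(lo, hi, config.cols)
    theta = np.broadcast_to(ramp, (config.rows, config.cols)) + jitter
    return np.clip(theta, 20.0, 50.0)


def simulate_sar_stack(truth: LandscapeTruth, config: ScenarioConfig,
                       year: int | None = None) -> list[SarScene]:
    """Simulate one year of SAR acquisitions over the truth landscape.

    Per scene and pixel: backscatter = class mean + linear-in-cos(theta)
    incidence term (zero at the reference angle) + Gaussian speckle in dB.
    """
    present = np.unique(truth.class_raster)
    missing = [CLASS_NAMES[c - 1] for c in present if CLASS_NAMES[c - 1] not in config.sar_params]
    if missing:
        raise ConfigurationError(f"missing SAR parameters for classes: {missing}")

    year = config.map_year if year is None else year
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_SAR, year]))
    codes = truth.class_raster
    vv_mean = np.zeros(codes.shape)
    vh_mean = np.zeros(codes.shape)
    speckle = np.zeros(codes.shape)
    for name, code in CLASS_CODES.items():
        m = codes == code
        if not m.any():
            continue
        p = config.sar_params[name]
        vv_mean[m], vh_mean[m], speckle[m] = p.vv_db, p.vh_db, p.speckle_sd_db

    cos_ref = math.cos(math.radians(config.incidence_ref_deg))
    dates = np.arange(np.datetime64(f"{year}-01-03"),
                      np.datetime64(f"{year + 1}-01-01"),
                      np.timedelta64(config.sar_revisit_days, "D"))
    scenes = []
    for d in dates:
        j = config.incidence_jitter_deg
        theta = _incidence_field(config, jitter=rng.uniform(-j, j))
        angle_term = _COS_LAW_SLOPE_DB * (np.cos(np.radians(theta)) - cos_ref)
        vv = vv_mean + angle_term + rng.standard_normal(codes.shape) * speckle
        vh = vh_mean + angle_term + rng.standard_normal(codes.shape) * speckle
        scenes.append(SarScene(vv, vh, theta, d, np.ones(codes.shape, bool), truth.grid))
    return scenes


class OpticalSeries:
    """Lazy, reproducible optical time series for a whole scene.

    Observations are generated on demand (an archive of 30+ years at two
    observations per month does not fit in memory as a dense 4-band stack
    at useful raster sizes); ``observation(i)`` is deterministic in
    (config, seed, i) and independent of access order.
    """

    def __init__(self, truth: LandscapeTruth, config: ScenarioConfig):
        self.truth = truth
        self.config = config
        self.grid = truth.grid
        months = []
        times = []
        dates = []
        per = config.optical_per_month
        day_of_month = np.linspace(1, 28, per, dtype=int) if per > 1 else np.array([15])
        for year in range(config.archive_start, config.map_year + 1):
            for month in range(1, 13):
                for k, day in enumerate(day_of_month):
                    months.append((year - config.archive_start) * 12 + (month - 1))
                    times.append(year + (month - 1 + (day - 0.5) / 28.0) / 12.0)
                    dates.append(np.datetime64(f"{year:04d}-{month:02d}-{day:02d}"))
        self.month_index = np.asarray(months)
        self.times = np.asarray(times)
        self.dates = np.asarray(dates)

        # Static per-pixel reflectance offsets (spatial variability).
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_OPTICAL, 0]))
        self._offsets = rng.standard_normal((4,) + self.grid.shape) * config.pixel_offset_sd

        # Per-class template means and noise, palm handled per phase.
        self._mean = {}
        self._sd = {}
        for key, p in config.optical_params.items():
            self._mean[key] = p.as_array()
            self._sd[key] = p.noise_sd

    def __len__(self) -> int:
        return len(self.times)

    def _phase_masks(self, t: float):
        """Forest-like / open-canopy / closed masks for palm pixels at t."""
        palm = self.truth.palm_mask
        planted = palm & (self.truth.planting_date_raster <= t)
        closed = palm & (self.truth.closure_date_raster <= t)
        bare = planted & ~closed
        pre = palm & ~planted
        return pre, bare, closed

    def _bare_weight(self, t: float, bare: np.ndarray) -> np.ndarray:
        """Bare-soil template weight for open-canopy pixels at time t.

        The canopy develops progressively: reflectance sits at the bare
        template through most of the open phase, then ramps linearly to
        the closed-canopy template over the final ``canopy_transition_years``,
        reaching it exactly at the recorded closure date.
        """
        trans = self.config.canopy_transition_years
        if trans <= 0:
            return np.ones(int(bare.sum()))
        remain = self.truth.closure_date_raster[bare] - t
        return np.clip(remain / trans, 0.0, 1.0)

    def observation(self, i: int) -> OpticalObservation:
        cfg = self.config
        t = float(self.times[i])
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, _STREAM_OPTICAL, 1, int(i)]))
        shape = self.grid.shape
        mean = np.zeros((4,) + shape)
        sd = np.zeros(shape)
        codes = self.truth.class_raster
        for name, code in CLASS_CODES.items():
            m = codes == code
            if not m.any() or name == "oil_palm":
                continue
            mean[:, m] = self._mean[name][:, None]
            sd[m] = self._sd[name]
        pre, bare, closed = self._phase_masks(t)
        for m, key in ((pre, "forest"), (closed, "oil_palm")):
            if m.any():
                mean[:, m] = self._mean[key][:, None]
                sd[m] = self._sd[key]
        if bare.any():
            w = self._bare_weight(t, bare)
            mean[:, bare] = (self._mean["bare_soil"][:, None] * w
                             + self._mean["oil_palm"][:, None] * (1.0 - w))
            sd[bare] = self._sd["bare_soil"] * w + self._sd["oil_palm"] * (1.0 - w)
        bands = mean + self._offsets + rng.standard_normal((4,) + shape) * sd
        np.clip(bands, 0.0, 1.0, out=bands)
        cloud = rng.random(shape) < cfg.cloud_prob
        return OpticalObservation(self.dates[i], t, bands[0], bands[1],
                                  bands[2], bands[3], cloud)

    def __iter__(self):
        for i in range(len(self)):
            yield self.observation(i)


def simulate_optical_series(truth: LandscapeTruth, config: ScenarioConfig) -> OpticalSeries:
    """Build the (lazy) cloud-flagged optical archive for a scene."""
    return OpticalSeries(truth, config)


def synthetic_dem(grid: RasterGrid, seed: int = 0, relief_m: float = 60.0,
                  ramp_m: float = 30.0) -> np.ndarray:
    """A smooth synthetic elevation field: low-frequency noise plus a ramp."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(np.random.SeedSequence([seed, _STREAM_DEM]))
    noise = gaussian_filter(rng.standard_normal(grid.shape), sigma=8.0)
    span = noise.max() - noise.min()
    if span > 0:
        noise = (noise - noise.min()) / span
    ramp = np.linspace(0.0, 1.0, grid.cols)[None, :]
    return noise * relief_m + ramp * ramp_m
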