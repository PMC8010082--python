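"""Plantation detection-year estimation from bare-soil-index time series.

A young oil-palm stand exposes soil for its first 2-3 years; the bare
soil index BSI = ((SWIR + Red) - (NIR + Blue)) / ((SWIR + Red) + (NIR +
Blue)) is high in that phase and drops as the canopy closes. Per pixel:

1. cloud-flagged observations are removed;
2. the BSI series (archive start 1984 onwards) is smoothed with a
   monthly-stepped trailing 12-month median, omitting windows with fewer
   than three observations;
3. a threshold tau is calibrated as the 95th percentile of the map-year
   median BSI over all mapped palm pixels (it coincides with the small
   share of still-open very young plantations);
4. scanning the smoothed series, the detection year is the year the
   series first drops below tau after its last bare (>= tau) window —
   canopy closure, reached at a stand age of two to three years.

Detection years are stored as 16-bit codes: 0 = no data (non-palm),
4 = the archive start year (1984; also the left-censored bucket for
stands already closed at archive start), ..., 37 = 2017. Codes 1-3 never
occur.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .synthetic import ConfigurationError, OpticalObservation, OpticalSeries

__all__ = [
    "BsiSeries",
    "SmoothedBsiSeries",
    "AgeModelParams",
    "BsiAgeModel",
    "compute_bsi",
    "mask_clouds",
    "build_bsi_series",
    "smooth_median_12mo",
    "calibrate_threshold",
    "detect_year",
    "encode_year",
    "decode_year",
]

logger = logging.getLogger(__name__)

NO_DATA_CODE = 0
FIRST_YEAR_CODE = 4


def compute_bsi(blue, red, nir, swir) -> tuple[np.ndarray, np.ndarray]:
    """Bare soil index; zero-denominator pixels are masked invalid."""
    blue, red = np.asarray(blue, float), np.asarray(red, float)
    nir, swir = np.asarray(nir, float), np.asarray(swir, float)
    num = (swir + red) - (nir + blue)
    den = (swir + red) + (nir + blue)
    valid = np.isfinite(den) & (den > 0)
    bsi = np.full(np.shape(den), np.nan)
    np.divide(num, den, out=bsi, where=valid)
    return bsi, valid


def mask_clouds(observations: list[OpticalObservation]) -> list[OpticalObservation]:
    """Drop observations that are entirely cloud-flagged; within partially
    clouded observations the flags stay attached and are honoured by the
    series builder."""
    return [o for o in observations if not o.cloud.all()]


@dataclass
class BsiSeries:
    """Cloud-masked BSI observations for a set of pixels.

    ``values[t, p]`` is NaN where pixel p was cloud-flagged at time t.
    ``month_index`` counts calendar months from January of
    ``archive_start``; observations are in strictly increasing date order.
    """

    month_index: np.ndarray      # (n_obs,)
    times: np.ndarray            # (n_obs,) fractional years
    values: np.ndarray           # (n_obs, n_pixels) float32, NaN = masked
    archive_start: int
    map_year: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) < 0):
            raise ValueError("observation dates must be increasing")


@dataclass
class SmoothedBsiSeries:
    """Monthly-stepped trailing 12-month median BSI.

    One row per window-end month from January of archive_start + 1 through
    December of map_year; ``values`` is NaN where the window held fewer
    than ``min_obs`` cloud-free observations.
    """

    window_month: np.ndarray     # (n_windows,) absolute month index of window end
    window_year: np.ndarray      # (n_windows,) calendar year of window end
    values: np.ndarray           # (n_windows, n_pixels)
    n_obs: np.ndarray            # (n_windows, n_pixels) int16
    min_obs: int
    archive_start: int
    map_year: int

    @property
    def valid(self) -> np.ndarray:
        return self.n_obs >= self.min_obs


def build_bsi_series(optical: OpticalSeries,
                     pixel_mask: np.ndarray | None = None) -> BsiSeries:
    """Stream the optical archive into a cloud-masked BSI series.

    ``pixel_mask`` restricts the series to a subset of pixels (row-major
    order within the mask); by default all pixels are kept.
    """
    cfg = optical.config
    shape = optical.grid.shape
    if pixel_mask is None:
        pixel_mask = np.ones(shape, bool)
    n_px = int(pixel_mask.sum())
    n_obs = len(optical)
    values = np.full((n_obs, n_px), np.nan, np.float32)
    for i in range(n_obs):
        obs = optical.observation(i)
        bsi, ok = compute_bsi(obs.blue, obs.red, obs.nir, obs.swir)
        bsi[~(ok & obs.valid)] = np.nan
        values[i] = bsi[pixel_mask]
    return BsiSeries(optical.month_index.copy(), optical.times.copy(), values,
                     cfg.archive_start, cfg.map_year)


def smooth_median_12mo(series: BsiSeries, min_obs: int = 3) -> SmoothedBsiSeries:
    """Trailing 12-calendar-month median, stepped monthly.

    For each window-end month m (from one year after archive start to the
    December of the map year) the window spans months m-11..m; the median
    is reported only where at least ``min_obs`` observations survive cloud
    masking.
    """
    if min_obs < 1:
        raise ConfigurationError("min_obs must be >= 1")
    n_months = (series.map_year - series.archive_start + 1) * 12
    ends = np.arange(12, n_months)
    # Observations are date-sorted, so each window is a contiguous slice.
    starts_idx = np.searchsorted(series.month_index, ends - 11, side="left")
    stops_idx = np.searchsorted(series.month_index, ends, side="right")
    n_px = series.values.shape[1]
    med = np.full((ends.size, n_px), np.nan, np.float32)
    cnt = np.zeros((ends.size, n_px), np.int16)
    for w, (a, b) in enumerate(zip(starts_idx, stops_idx)):
        if b <= a:
            continue
        chunk = series.values[a:b]
        cnt[w] = (~np.isnan(chunk)).sum(axis=0)
        enough = cnt[w] >= min_obs
        if enough.any():
            with np.errstate(all="ignore"):
                med[w, enough] = np.nanmedian(chunk[:, enough], axis=0)
    med[cnt < min_obs] = np.nan
    years = series.archive_start + ends // 12
    return SmoothedBsiSeries(ends, years, med, cnt, min_obs,
                             series.archive_start, series.map_year)


@dataclass(frozen=True)
class AgeModelParams:
    threshold: float
    percentile: float = 95.0
    min_obs: int = 3
    archive_start: int = 1984
    map_year: int = 2017

    def __post_init__(self) -> None:
        if not (-1.0 <= self.threshold <= 1.0):
            raise ConfigurationError("BSI threshold must lie in [-1, 1]")
        if not (0.0 < self.percentile < 100.0):
            raise ConfigurationError("percentile must lie in (0, 100)")


def calibrate_threshold(smoothed: SmoothedBsiSeries, is_palm: np.ndarray,
                        percentile: float = 95.0,
                        min_pixels: int = 100) -> AgeModelParams:
    """Threshold from established plantations in the map year.

    tau is the given percentile (linear interpolation between order
    statistics) of the December-map-year median BSI over all mapped palm
    pixels with a valid final window.
    """
    is_palm = np.asarray(is_palm, bool)
    final = smoothed.values[-1]
    vals = final[is_palm & ~np.isnan(final)]
    if vals.size < min_pixels:
        raise ConfigurationError(
            f"only {vals.size} palm pixels with a valid map-year window "
            f"(need >= {min_pixels}) for threshold calibration")
    tau = float(np.percentile(vals, percentile))
    return AgeModelParams(tau, percentile, smoothed.min_obs,
                          smoothed.archive_start, smoothed.map_year)


def encode_year(year: int, archive_start: int = 1984, map_year: int = 2017):
    """Detection year -> stored code (archive start -> 4, each later year
    +1; 1984..2017 -> 4..37)."""
    year = np.asarray(year)
    if np.any(year < archive_start) or np.any(year > map_year):
        raise ValueError(f"year outside [{archive_start}, {map_year}]")
    code = year - (archive_start - FIRST_YEAR_CODE)
    return int(code) if code.ndim == 0 else code.astype(np.uint16)


def decode_year(code: int, archive_start: int = 1984, map_year: int = 2017):
    """Stored code -> detection year; 0 decodes to None (no data) and the
    never-used codes 1-3 are rejected."""
    code_arr = np.asarray(code)
    if code_arr.ndim == 0:
        c = int(code_arr)
        if c == NO_DATA_CODE:
            return None
        if 1 <= c <= 3:
            raise ValueError("codes 1 to 3 are not present in the encoding")
        year = c + archive_start - FIRST_YEAR_CODE
        if year > map_year:
            raise ValueError(f"code {c} beyond map year {map_year}")
        return year
    if np.any((code_arr >= 1) & (code_arr <= 3)):
        raise ValueError("codes 1 to 3 are not present in the encoding")
    if np.any(code_arr > map_year - (archive_start - FIRST_YEAR_CODE)):
        raise ValueError("code beyond map year")
    year = code_arr + archive_start - FIRST_YEAR_CODE
    return np.where(code_arr == NO_DATA_CODE, 0, year)


def detect_year(smoothed: SmoothedBsiSeries, params: AgeModelParams,
                is_palm: np.ndarray) -> np.ndarray:
    """Detection-year codes for every pixel of a smoothed series.

    Non-palm pixels get 0. For a palm pixel, with A the set of valid
    windows whose median BSI >= tau: still bare in the map-year December
    window -> map-year code; A empty (never bare in the archive, or no
    valid windows at all) -> the left-censored archive-start code 4;
    otherwise the detection year is the year of the first valid
    below-threshold window after the last bare window (or of the last
    bare window itself if nothing valid follows).
    """
    is_palm = np.asarray(is_palm, bool).ravel()
    vals = smoothed.values
    valid = smoothed.valid
    n_win, n_px = vals.shape
    if is_palm.size != n_px:
        raise ValueError("is_palm length does not match the series pixels")
    tau = params.threshold

    with np.errstate(invalid="ignore"):
        bare = valid & (vals >= tau)
        below = valid & (vals < tau)

    codes = np.zeros(n_px, np.uint16)
    palm = is_palm
    if not palm.any():
        return codes

    any_bare = bare.any(axis=0)
    # Branch 1: still bare at the end of the map year.
    still_bare = palm & bare[-1]
    codes[still_bare] = encode_year(params.map_year, params.archive_start,
                                    params.map_year)
    # Branch 2: never bare (incl. all-invalid series) -> left-censored.
    censored = palm & ~any_bare & ~still_bare
    codes[censored] = FIRST_YEAR_CODE
    # Branch 3: closure after the last bare window.
    scan = palm & any_bare & ~still_bare
    if scan.any():
        last_bare = n_win - 1 - np.argmax(bare[::-1], axis=0)
        after = np.arange(n_win)[:, None] > last_bare[None, :]
        below_after = below & after
        has_close = below_after.any(axis=0)
        first_below = np.argmax(below_after, axis=0)
        year = np.where(has_close, smoothed.window_year[first_below],
                        smoothed.window_year[last_bare])
        codes[scan] = encode_year(year[scan], params.archive_start,
                                  params.map_year)
    return codes


class BsiAgeModel(BaseEstimator):
    """Sklearn-style estimator for the detection-year model.

    ``fit`` calibrates the BSI threshold on the mapped palm pixels of a
    smoothed series; ``predict`` turns a smoothed series plus palm flags
    into detection-year codes.
    """

    def __init__(self, percentile: float = 95.0, min_obs: int = 3,
                 min_calibration_pixels: int = 100):
        self.percentile = percentile
        self.min_obs = min_obs
        self.min_calibration_pixels = min_calibration_pixels

    def fit(self, smoothed: SmoothedBsiSeries, is_palm: np.ndarray):
        params = calibrate_threshold(smoothed, is_palm, self.percentile,
                                     self.min_calibration_pixels)
        self.threshold_ = params.threshold
        self.params_ = params
        return self

    def predict(self, smoothed: SmoothedBsiSeries, is_palm: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "params_")
        return detect_year(smoothed, self.params_, is_palm)
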