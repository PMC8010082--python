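"""Rule-based corrections to the reconciled oil-palm map.

Order of the published rules, kept as the pipeline default: (1) remove
mapped palm with NDVI below 0.5 (settlements and other built surfaces are
radar-bright and heterogeneous enough to land in palm clusters); (2)
remove mapped palm inside a given mangrove mask; (3) fill SAR gaps (e.g.
radar shadow on slopes facing away from the look direction) with the
modal class of a 3x3 window — the de facto 900 m2 minimum mapping unit;
(4) re-apply the NDVI rule, since filling can introduce palm onto roads
and other thin non-palm features.

Every mask rule only ever removes palm (palm area is monotone
non-increasing); the fill step only touches flagged gap pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .grid import GridMismatchError
from .synthetic import ConfigurationError

__all__ = [
    "PostprocessConfig",
    "MapPostProcessor",
    "compute_ndvi",
    "ndvi_mask",
    "mangrove_mask",
    "slope_gap_mask",
    "horn_slope_aspect",
    "fill_gaps_majority",
    "post_fill_ndvi_recheck",
]


@dataclass(frozen=True)
class PostprocessConfig:
    ndvi_min: float = 0.5
    fill_window: int = 3
    slope_max: float = 20.0
    look_direction: float = 90.0   # azimuth the radar looks toward, degrees
    apply_fill_only_to_gaps: bool = True

    def __post_init__(self) -> None:
        if not (-1.0 <= self.ndvi_min <= 1.0):
            raise ConfigurationError("ndvi_min must lie in [-1, 1]")
        if self.fill_window < 3 or self.fill_window % 2 == 0:
            raise ConfigurationError("fill_window must be odd and >= 3")


def _check_same_shape(*arrays) -> None:
    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise GridMismatchError(f"raster shapes differ: {a.shape} vs {shape}")


def compute_ndvi(red: np.ndarray, nir: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(NIR - Red) / (NIR + Red); zero-denominator pixels are masked."""
    red = np.asarray(red, float)
    nir = np.asarray(nir, float)
    _check_same_shape(red, nir)
    denom = nir + red
    valid = np.isfinite(denom) & (denom > 0)
    ndvi = np.full(red.shape, np.nan)
    np.divide(nir - red, denom, out=ndvi, where=valid)
    return ndvi, valid


def ndvi_mask(palm_map: np.ndarray, ndvi: np.ndarray,
              ndvi_min: float = 0.5) -> np.ndarray:
    """Remove mapped palm where NDVI < ndvi_min (the minimum is inclusive:
    a pixel at exactly ndvi_min is kept)."""
    palm_map = np.asarray(palm_map)
    _check_same_shape(palm_map, ndvi)
    out = palm_map.copy()
    with np.errstate(invalid="ignore"):
        out[(palm_map == 1) & (ndvi < ndvi_min)] = 0
    return out


def mangrove_mask(palm_map: np.ndarray, mangrove: np.ndarray) -> np.ndarray:
    """Remove mapped palm inside the (given) binary mangrove raster."""
    palm_map = np.asarray(palm_map)
    mangrove = np.asarray(mangrove)
    _check_same_shape(palm_map, mangrove)
    out = palm_map.copy()
    out[(palm_map == 1) & (mangrove != 0)] = 0
    return out


def horn_slope_aspect(dem: np.ndarray, pixel_size: float = 30.0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Slope (degrees) and downhill aspect (degrees from north, clockwise)
    by Horn's 3x3 finite differences; edges use replicated borders."""
    dem = np.asarray(dem, float)
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float)  # d/dx (east)
    ky = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], float)  # d/dy (north)
    dzdx = ndimage.correlate(dem, kx, mode="nearest") / (8.0 * pixel_size)
    dzdy = ndimage.correlate(dem, ky, mode="nearest") / (8.0 * pixel_size)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    # Downhill direction: azimuth of -grad, measured clockwise from north.
    aspect = np.degrees(np.arctan2(-dzdx, dzdy))
    aspect = (180.0 - aspect) % 360.0
    return slope, aspect


def slope_gap_mask(dem: np.ndarray, look_direction: float = 90.0,
                   slope_max: float = 20.0, pixel_size: float = 30.0) -> np.ndarray:
    """Flag probable SAR gaps: steep slopes facing away from the radar.

    A pixel is flagged when its Horn slope exceeds ``slope_max`` degrees
    and its downhill aspect is within 90 degrees of the away-from-sensor
    azimuth. A flat DEM yields an empty mask.
    """
    slope, aspect = horn_slope_aspect(dem, pixel_size)
    away = (look_direction + 180.0) % 360.0
    diff = np.abs((aspect - away + 180.0) % 360.0 - 180.0)
    return (slope > slope_max) & (diff < 90.0)


def fill_gaps_majority(palm_map: np.ndarray, gap_mask: np.ndarray,
                       window: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Fill gap pixels with the modal class of their valid neighbours.

    Only pixels in ``gap_mask`` are modified; the modal palm/non-palm
    class is taken over non-gap neighbours in the window (centre pixel is
    a gap, hence never counted). Ties go to non-palm; gaps with no valid
    neighbour stay non-palm and remain flagged. Returns
    ``(filled_map, still_gap)``.
    """
    if window < 3 or window % 2 == 0:
        raise ConfigurationError("fill window must be odd and >= 3")
    palm_map = np.asarray(palm_map)
    gap_mask = np.asarray(gap_mask, bool)
    _check_same_shape(palm_map, gap_mask)
    valid = ~gap_mask
    k = np.ones((window, window), np.int64)
    palm_votes = ndimage.correlate((palm_map == 1) & valid, k,
                                   mode="constant", cval=0, output=np.int64)
    valid_votes = ndimage.correlate(valid.astype(np.int64), k,
                                    mode="constant", cval=0)
    out = palm_map.copy()
    fill_palm = gap_mask & (valid_votes > 0) & (2 * palm_votes > valid_votes)
    fill_non = gap_mask & (valid_votes > 0) & ~fill_palm
    out[fill_palm] = 1
    out[fill_non] = 0
    still_gap = gap_mask & (valid_votes == 0)
    out[still_gap] = 0
    return out, still_gap


def post_fill_ndvi_recheck(palm_map: np.ndarray, ndvi: np.ndarray,
                           ndvi_min: float = 0.5) -> np.ndarray:
    """Re-apply the NDVI rule after gap filling (same contract as
    :func:`ndvi_mask`; idempotent)."""
    return ndvi_mask(palm_map, ndvi, ndvi_min)


class MapPostProcessor(BaseEstimator):
    """Sklearn-style wrapper applying the full rule sequence.

    ``transform`` takes the reconciled binary map plus the auxiliary
    rasters and returns ``(clean_map, provenance)`` where provenance
    records parameters and pixels changed per rule (written to the output
    sidecar by the pipeline).
    """

    def __init__(self, ndvi_min: float = 0.5, fill_window: int = 3,
                 slope_max: float = 20.0, look_direction: float = 90.0):
        self.ndvi_min = ndvi_min
        self.fill_window = fill_window
        self.slope_max = slope_max
        self.look_direction = look_direction

    def fit(self, X=None, y=None):
        PostprocessConfig(self.ndvi_min, self.fill_window, self.slope_max,
                          self.look_direction)  # validate
        self.is_fitted_ = True
        return self

    def transform(self, palm_map: np.ndarray, ndvi: np.ndarray,
                  mangrove: np.ndarray | None = None,
                  gap_mask: np.ndarray | None = None,
                  dem: np.ndarray | None = None,
                  pixel_size: float = 30.0) -> tuple[np.ndarray, dict]:
        self.fit()
        steps = []
        current = np.asarray(palm_map).copy()

        stage = ndvi_mask(current, ndvi, self.ndvi_min)
        steps.append(("ndvi_mask", int((current != stage).sum())))
        current = stage

        if mangrove is not None:
            stage = mangrove_mask(current, mangrove)
            steps.append(("mangrove_mask", int((current != stage).sum())))
            current = stage

        gaps = np.zeros(current.shape, bool) if gap_mask is None else np.asarray(gap_mask, bool).copy()
        if dem is not None:
            gaps |= slope_gap_mask(dem, self.look_direction, self.slope_max,
                                   pixel_size)
        stage, still_gap = fill_gaps_majority(current, gaps, self.fill_window)
        steps.append(("fill_gaps_majority", int((current != stage).sum())))
        current = stage

        stage = post_fill_ndvi_recheck(current, ndvi, self.ndvi_min)
        steps.append(("post_fill_ndvi_recheck", int((current != stage).sum())))
        current = stage

        provenance = {
            "rules": [{"rule": name, "pixels_changed": n} for name, n in steps],
            "parameters": self.get_params(),
            "still_gap_pixels": int(still_gap.sum()),
        }
        return current, provenance
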