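"""Annual SAR feature mosaic.

Builds the per-year feature stack used by the unsupervised classifier:

1. incidence-angle normalization of every scene (cosine law, reference
   angle 37.5 deg);
2. trimmed temporal mean per polarization, dropping the lowest 20% of the
   valid values per pixel (outlier / low-backscatter removal);
3. the VH-VV contrast band — in the dB domain the "VH/VV ratio" and the
   VH-VV difference coincide up to sign, so the difference is stored;
4. byte scaling of each band to 0..255;
5. the GLCM summed-average (SAVG) texture of each byte band over a
   radius-3 (7x7) window.

Bands carry explicit validity masks; texture is defined only where the
full window lies inside the raster and every window pixel is valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import RasterGrid
from .synthetic import ConfigurationError, SarScene

__all__ = [
    "MosaicConfig",
    "AnnualMosaic",
    "trimmed_temporal_mean",
    "normalize_incidence",
    "scale_to_byte",
    "glcm_savg",
    "build_annual_mosaic",
]

FEATURE_NAMES = ("vv", "vh", "diff", "savg_vv", "savg_vh", "savg_diff")

#: GLCM offsets for the four standard directions at distance 1.
_GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def _default_byte_ranges() -> dict:
    return {"vv": (-25.0, 0.0), "vh": (-32.0, -5.0), "diff": (-15.0, 5.0)}


@dataclass(frozen=True)
class MosaicConfig:
    trim_fraction: float = 0.2
    reference_angle: float = 37.5
    byte_ranges: dict = field(default_factory=_default_byte_ranges)
    texture_radius: int = 3

    def __post_init__(self) -> None:
        if not (0.0 <= self.trim_fraction < 0.5):
            raise ConfigurationError("trim_fraction must lie in [0, 0.5)")
        if self.texture_radius < 1:
            raise ConfigurationError("texture_radius must be >= 1")


@dataclass
class AnnualMosaic:
    """Per-pixel annual SAR features plus SAVG textures on a shared grid."""

    vv_mean: np.ndarray
    vh_mean: np.ndarray
    vhvv_diff: np.ndarray
    vv_byte: np.ndarray
    vh_byte: np.ndarray
    diff_byte: np.ndarray
    savg_vv: np.ndarray
    savg_vh: np.ndarray
    savg_diff: np.ndarray
    valid: np.ndarray          # temporal-mean validity
    texture_valid: np.ndarray  # full-window validity for the SAVG bands
    grid: RasterGrid

    @property
    def feature_valid(self) -> np.ndarray:
        """Pixels with all six clustering features defined."""
        return self.valid & self.texture_valid

    def feature_stack(self) -> np.ndarray:
        """(rows, cols, 6) float feature array in FEATURE_NAMES order."""
        return np.stack(
            [self.vv_byte.astype(float), self.vh_byte.astype(float),
             self.diff_byte.astype(float), self.savg_vv, self.savg_vh,
             self.savg_diff], axis=-1)


def trimmed_temporal_mean(stack: np.ndarray, trim_fraction: float,
                          valid: np.ndarray | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Temporal mean after dropping the lowest values per pixel.

    Per pixel, of the n valid values the floor(trim_fraction * n) smallest
    are discarded and the rest averaged. Returns ``(mean, valid_out)``;
    pixels with zero valid observations are flagged invalid, never raised.
    """
    if not (0.0 <= trim_fraction < 0.5):
        raise ConfigurationError("trim_fraction must lie in [0, 0.5)")
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 1:
        stack = stack[:, None]
        squeeze = True
    else:
        squeeze = False
    n = stack.shape[0]
    if valid is None:
        valid = np.isfinite(stack)
    else:
        valid = np.asarray(valid, bool) & np.isfinite(stack)
        if squeeze and valid.ndim == 1:
            valid = valid[:, None]

    work = np.where(valid, stack, np.inf)  # invalid sorts to the top
    work = np.sort(work, axis=0)
    n_valid = valid.sum(axis=0)
    k = np.floor(trim_fraction * n_valid).astype(np.int64)

    csum = np.cumsum(np.where(np.isfinite(work), work, 0.0), axis=0)
    total = np.take_along_axis(csum, np.maximum(n_valid - 1, 0)[None], axis=0)[0]
    below = np.take_along_axis(csum, np.maximum(k - 1, 0)[None], axis=0)[0]
    below = np.where(k > 0, below, 0.0)
    kept = n_valid - k
    valid_out = n_valid > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(valid_out, (total - below) / np.maximum(kept, 1), np.nan)
    if squeeze:
        return mean[0], valid_out[0]
    return mean, valid_out


def normalize_incidence(scene: SarScene, reference_angle: float = 37.5) -> SarScene:
    """Cosine-law incidence normalization of one scene.

    sigma_norm = sigma - 10 log10(cos theta / cos theta_ref). Pixels whose
    incidence angle falls outside [20, 50] degrees are masked invalid.
    """
    theta = np.asarray(scene.incidence_angle, float)
    in_range = (theta >= 20.0) & (theta <= 50.0)
    with np.errstate(invalid="ignore"):
        adj = 10.0 * np.log10(np.cos(np.radians(theta)) /
                              np.cos(np.radians(reference_angle)))
    valid = scene.valid & in_range
    vv = np.where(valid, scene.vv_db - adj, np.nan)
    vh = np.where(valid, scene.vh_db - adj, np.nan)
    return SarScene(vv, vh, theta, scene.date, valid, scene.grid)


def scale_to_byte(band: np.ndarray, lo: float, hi: float,
                  valid: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Linear map lo->0, hi->255 with round-half-up and clipping.

    Returns ``(byte_band, valid_out)``; invalid pixels are set to 0 in the
    byte band and stay flagged invalid.
    """
    if lo >= hi:
        raise ConfigurationError(f"byte scaling needs lo < hi, got [{lo}, {hi}]")
    band = np.asarray(band, float)
    if valid is None:
        valid = np.isfinite(band)
    else:
        valid = np.asarray(valid, bool) & np.isfinite(band)
    scaled = (band - lo) / (hi - lo) * 255.0
    byte = np.clip(np.floor(scaled + 0.5), 0, 255)  # round half up, then clip
    byte = np.where(valid, byte, 0).astype(np.uint8)
    return byte, valid


def _glcm_kernels(radius: int) -> list[tuple[tuple[int, int], np.ndarray]]:
    """7x7-style indicator kernels of pair-anchor offsets per direction."""
    size = 2 * radius + 1
    kernels = []
    for dr, dc in _GLCM_OFFSETS:
        k = np.zeros((size, size), dtype=np.int64)
        for orow in range(-radius, radius + 1):
            for ocol in range(-radius, radius + 1):
                if (-radius <= orow + dr <= radius) and (-radius <= ocol + dc <= radius):
                    k[radius + orow, radius + ocol] = 1
        kernels.append(((dr, dc), k))
    return kernels


def glcm_savg(byte_band: np.ndarray, radius: int = 3,
              valid: np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """GLCM summed-average texture over a (2*radius+1)^2 moving window.

    The co-occurrence matrix pools distance-1 pixel pairs from the four
    directions (0, 45, 90, 135 deg, symmetric); SAVG is sum_k k*p_{x+y}(k)
    with k = i + j, i.e. the mean grey-level sum over all window pairs.
    Computed exactly (integer pair sums via convolution), so it matches a
    literal pair-enumeration oracle bit for bit. Pixels whose window
    leaves the raster or contains any invalid pixel are masked.
    """
    byte_band = np.asarray(byte_band)
    if byte_band.dtype != np.uint8:
        raise TypeError(f"glcm_savg expects a byte (uint8) band, got {byte_band.dtype}")
    if valid is None:
        valid = np.ones(byte_band.shape, bool)
    valid = np.asarray(valid, bool)
    img = byte_band.astype(np.int64)
    rows, cols = img.shape

    pair_sum = np.zeros((rows, cols), dtype=np.int64)
    pair_cnt = np.zeros((rows, cols), dtype=np.int64)
    for (dr, dc), kernel in _glcm_kernels(radius):
        shifted = np.full_like(img, 0)
        r0, r1 = max(dr, 0), rows + min(dr, 0)
        c0, c1 = max(dc, 0), cols + min(dc, 0)
        shifted[r0 - dr:r1 - dr, c0 - dc:c1 - dc] = img[r0:r1, c0:c1]
        psum = img + shifted
        pair_sum += ndimage.correlate(psum, kernel, mode="constant", cval=0)
        pair_cnt += ndimage.correlate(np.ones_like(img), kernel, mode="constant", cval=0)

    size = 2 * radius + 1
    window_valid = ndimage.correlate(valid.astype(np.int64), np.ones((size, size), np.int64),
                                     mode="constant", cval=0) == size * size
    inside = np.zeros((rows, cols), bool)
    if rows > 2 * radius and cols > 2 * radius:
        inside[radius:rows - radius, radius:cols - radius] = True
    valid_out = window_valid & inside

    savg = np.full((rows, cols), np.nan)
    np.divide(pair_sum, pair_cnt, out=savg, where=valid_out & (pair_cnt > 0))
    savg[~valid_out] = np.nan
    return savg, valid_out


def build_annual_mosaic(scenes: list[SarScene],
                        config: MosaicConfig | None = None) -> AnnualMosaic:
    """Assemble the annual feature mosaic from a year of SAR scenes."""
    if not scenes:
        raise ConfigurationError("build_annual_mosaic needs at least one scene")
    config = config or MosaicConfig()
    grid = scenes[0].grid

    normed = [normalize_incidence(s, config.reference_angle) for s in scenes]
    vv_stack = np.stack([s.vv_db for s in normed])
    vh_stack = np.stack([s.vh_db for s in normed])
    valid_stack = np.stack([s.valid for s in normed])

    vv_mean, vv_ok = trimmed_temporal_mean(vv_stack, config.trim_fraction, valid_stack)
    vh_mean, vh_ok = trimmed_temporal_mean(vh_stack, config.trim_fraction, valid_stack)
    valid = vv_ok & vh_ok
    diff = np.where(valid, vh_mean - vv_mean, np.nan)

    vv_byte, _ = scale_to_byte(vv_mean, *config.byte_ranges["vv"], valid=valid)
    vh_byte, _ = scale_to_byte(vh_mean, *config.byte_ranges["vh"], valid=valid)
    diff_byte, _ = scale_to_byte(diff, *config.byte_ranges["diff"], valid=valid)

    savg_vv, t_vv = glcm_savg(vv_byte, config.texture_radius, valid)
    savg_vh, t_vh = glcm_savg(vh_byte, config.texture_radius, valid)
    savg_diff, t_diff = glcm_savg(diff_byte, config.texture_radius, valid)
    texture_valid = t_vv & t_vh & t_diff

    return AnnualMosaic(vv_mean, vh_mean, diff, vv_byte, vh_byte, diff_byte,
                        savg_vv, savg_vh, savg_diff, valid, texture_valid, grid)
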