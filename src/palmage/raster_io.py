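"""Raster and tabular I/O with the published product's conventions.

Rasters are written as single- or multi-band TIFF via :mod:`tifffile`;
the grid/georeference, NoData value, band names and provenance are stored
as a JSON document in the TIFF ImageDescription tag and round-trip
exactly. The detection-year map follows the published convention:
unsigned 16-bit, NoData = 0, valid codes 4..(map_year - 1980).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .grid import RasterGrid

__all__ = ["Raster", "read_raster", "write_raster", "write_age_map",
           "validate_age_codes", "write_points_geojson"]


@dataclass
class Raster:
    data: np.ndarray
    grid: RasterGrid
    nodata: float | int | None = None
    band_names: tuple | None = None
    provenance: dict | None = None


def validate_age_codes(codes: np.ndarray, archive_start: int = 1984,
                       map_year: int = 2017) -> None:
    """Reject arrays that violate the year-code range {0} | [4, max]."""
    codes = np.asarray(codes)
    max_code = map_year - (archive_start - 4)
    bad_low = (codes >= 1) & (codes <= 3)
    if bad_low.any():
        raise ValueError("age codes 1 to 3 are not present in the encoding")
    if (codes > max_code).any():
        raise ValueError(f"age codes above {max_code} exceed the map year {map_year}")


def write_raster(path, data: np.ndarray, grid: RasterGrid,
                 nodata=None, dtype=None, band_names=None,
                 provenance: dict | None = None) -> Path:
    """Write a raster with its grid + provenance embedded as JSON tags."""
    path = Path(path)
    data = np.asarray(data)
    if dtype is not None:
        data = data.astype(dtype)
    if data.ndim == 2 and data.shape != grid.shape:
        raise ValueError(f"data shape {data.shape} != grid shape {grid.shape}")
    meta = {
        "grid": grid.to_dict(),
        "nodata": None if nodata is None else float(nodata),
        "band_names": list(band_names) if band_names else None,
        "provenance": provenance or {},
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, data, description=json.dumps(meta))
    return path


def read_raster(path) -> Raster:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc) if desc else {}
    grid = RasterGrid.from_dict(meta["grid"]) if "grid" in meta else \
        RasterGrid(*data.shape[-2:])
    nodata = meta.get("nodata")
    names = meta.get("band_names")
    return Raster(data, grid, nodata, tuple(names) if names else None,
                  meta.get("provenance") or {})


def write_age_map(path, codes: np.ndarray, grid: RasterGrid,
                  archive_start: int = 1984, map_year: int = 2017,
                  provenance: dict | None = None) -> Path:
    """Write a detection-year map: uint16, NoData = 0, validated codes."""
    validate_age_codes(codes, archive_start, map_year)
    prov = dict(provenance or {})
    prov.setdefault("encoding", {"nodata": 0, "first_code": 4,
                                 "first_year": archive_start,
                                 "last_year": map_year})
    return write_raster(path, codes, grid, nodata=0, dtype=np.uint16,
                        provenance=prov)


def write_points_geojson(path, points, grid: RasterGrid) -> Path:
    """Validation points as GeoJSON (pixel centres in grid coordinates)."""
    feats = []
    for p in points:
        x = grid.x_origin + (p.col + 0.5) * grid.pixel_size
        y = grid.y_origin - (p.row + 0.5) * grid.pixel_size
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [x, y]},
            "properties": {
                "row": p.row, "col": p.col, "stratum": int(p.stratum),
                "map_label": int(p.map_label),
                "votes": list(p.votes),
                "consensus": None if p.consensus is None else int(p.consensus),
            },
        })
    doc = {"type": "FeatureCollection", "crs_name": grid.crs, "features": feats}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc))
    return path
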