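"""Raster and table I/O.

Rasters are written as plain (multi-band) TIFF via :mod:`tifffile`,
with the geotransform, CRS, nodata value and band names carried in a
JSON sidecar (``<file>.meta.json``) so round-trips are bit-exact.
Tables are CSV with a header row; scenario and coefficient files are
YAML/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["write_raster", "read_raster", "write_class_map", "read_class_map"]

_DEFAULT_TRANSFORM = (0.0, 1.0, 0.0, 0.0, 0.0, -1.0)


def write_raster(
    path,
    data: np.ndarray,
    transform=_DEFAULT_TRANSFORM,
    crs: str = "EPSG:4326",
    nodata=None,
    band_names=None,
) -> None:
    """Write a (rows, cols) or (bands, rows, cols) array as TIFF + sidecar."""
    path = Path(path)
    data = np.asarray(data)
    if data.ndim not in (2, 3):
        raise ValueError("raster must be 2-D or 3-D (bands first)")
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "transform": list(transform),
        "crs": crs,
        "nodata": nodata,
        "band_names": list(band_names) if band_names is not None else None,
        "dtype": str(data.dtype),
        "shape": list(data.shape),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_raster(path) -> tuple[np.ndarray, dict]:
    """Read a TIFF raster and its sidecar metadata (empty if absent)."""
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return data, meta


def write_class_map(path, class_map: np.ndarray, transform=_DEFAULT_TRANSFORM, crs="EPSG:4326") -> None:
    """Integer class raster with the documented code legend in the sidecar."""
    from .containers import CLASS_NAMES, NODATA_CODE

    legend = {str(NODATA_CODE): "nodata", **{str(k): v for k, v in CLASS_NAMES.items()}}
    path = Path(path)
    tifffile.imwrite(path, np.asarray(class_map, dtype=np.int16))
    meta = {
        "transform": list(transform),
        "crs": crs,
        "nodata": NODATA_CODE,
        "legend": legend,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_class_map(path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=np.int16)
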