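"""Single-band GeoTIFF input/output.

Layers are stored as plain single-band TIFFs carrying the standard GeoTIFF
georeferencing tags (ModelPixelScale, ModelTiepoint) plus the GDAL nodata tag,
written and parsed directly through :mod:`tifffile`. Continuous layers are
float64 bands with NaN nodata; categorical layers and masks are integer bands
with nodata 0 (states are 1-based, mask members are 1).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import tifffile

from .grid import CategoricalRaster, Grid, Raster, RegionMask

TAG_PIXEL_SCALE = 33550
TAG_TIEPOINT = 33922
TAG_GEO_ASCII = 34737
TAG_GDAL_NODATA = 42113


class RasterIOError(IOError):
    """Base class for raster file problems."""


class MultiBandError(RasterIOError):
    """The file holds more than one band; the pipeline is single-band only."""


class MissingGeoreferenceError(RasterIOError):
    """The file carries no pixel-scale / tiepoint georeferencing."""


def _geo_tags(grid: Grid, nodata: str) -> list[tuple]:
    cs = float(grid.cell_size)
    ox, oy = grid.origin
    tags = [
        (TAG_PIXEL_SCALE, "d", 3, (cs, cs, 0.0), True),
        (TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(ox), float(oy), 0.0), True),
        (TAG_GDAL_NODATA, "s", 0, nodata, True),
    ]
    if grid.crs_label:
        tags.append((TAG_GEO_ASCII, "s", 0, grid.crs_label, True))
    return tags


def write_raster(r: Raster | CategoricalRaster | RegionMask, path: str | os.PathLike) -> Path:
    """Write a layer as a single-band GeoTIFF; returns the path written.

    Float layers keep their values bit-for-bit at valid cells (float64 band,
    NaN nodata). Categorical layers and masks are written as int32 bands.
    """
    path = Path(path)
    if isinstance(r, RegionMask):
        data = r.member.astype(np.int32)
        nodata = "-1"
    elif isinstance(r, CategoricalRaster):
        data = np.where(r.valid, r.levels, 0).astype(np.int32)
        nodata = "0"
    else:
        data = np.where(r.valid, r.values, np.nan).astype(np.float64)
        nodata = "nan"
    try:
        tifffile.imwrite(path, data, extratags=_geo_tags(r.grid, nodata))
    except (OSError, PermissionError) as exc:
        raise RasterIOError(f"cannot write raster to {path}: {exc}") from exc
    return path


def _read_band(path: Path) -> tuple[np.ndarray, Grid, float | None]:
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise MultiBandError(f"{path}: expected a single band, found {len(tif.pages)} pages")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise MultiBandError(
                f"{path}: expected a single band, found {page.samplesperpixel} samples/pixel"
            )
        data = page.asarray()
        scale = page.tags.get(TAG_PIXEL_SCALE)
        tie = page.tags.get(TAG_TIEPOINT)
        if scale is None or tie is None:
            raise MissingGeoreferenceError(f"{path}: no GeoTIFF georeferencing tags")
        sx, sy = float(scale.value[0]), float(scale.value[1])
        if not np.isclose(sx, sy):
            raise MissingGeoreferenceError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
        i, j, _k, x, y, _z = (float(v) for v in tie.value[:6])
        origin = (x - i * sx, y + j * sy)
        crs = page.tags.get(TAG_GEO_ASCII)
        crs_label = str(crs.value).rstrip("\x00|") if crs is not None else ""
        nod = page.tags.get(TAG_GDAL_NODATA)
        nodata = None
        if nod is not None:
            try:
                nodata = float(str(nod.value))
            except ValueError:
                nodata = None
    grid = Grid(data.shape[0], data.shape[1], sx, origin, crs_label)
    return data, grid, nodata


def read_raster(path: str | os.PathLike) -> Raster:
    """Read a continuous single-band GeoTIFF; nodata cells become invalid."""
    data, grid, nodata = _read_band(Path(path))
    values = data.astype(np.float64)
    valid = np.isfinite(values)
    if nodata is not None and np.isfinite(nodata):
        valid &= values != nodata
    return Raster(grid, values, valid)


def read_categorical(path: str | os.PathLike, n_states: int | None = None) -> CategoricalRaster:
    """Read an integer-band GeoTIFF as a categorical layer.

    ``n_states`` defaults to the largest level present in the file.
    """
    data, grid, nodata = _read_band(Path(path))
    levels = np.asarray(data)
    if not np.issubdtype(levels.dtype, np.integer):
        levels = np.rint(levels).astype(np.int32)
    valid = np.ones(grid.shape, dtype=bool)
    if nodata is not None:
        valid &= levels != int(nodata)
    valid &= levels >= 1
    if n_states is None:
        n_states = int(levels[valid].max()) if valid.any() else 2
    n_states = max(int(n_states), 2)
    levels = np.where(valid, levels, 1)
    return CategoricalRaster(grid, levels, n_states, valid)


def read_mask(path: str | os.PathLike) -> RegionMask:
    """Read a 0/1 integer GeoTIFF as a membership mask."""
    data, grid, _ = _read_band(Path(path))
    return RegionMask(grid, np.asarray(data) == 1)
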