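"""Georeferenced grid, raster, and mask types shared by every analysis stage.

All layers in an assessment live on a single common grid; cross-layer
operations require exact alignment and never resample implicitly (an explicit
nearest-neighbour resample is available for pre-processing). The coordinate
convention is row-major with cell (0, 0) at the top-left corner of the grid;
``origin`` is the outer corner of that cell, x increasing with columns and y
decreasing with rows. All distances are Euclidean between cell centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class AlignmentError(ValueError):
    """Two layers do not share the same grid."""


@dataclass(frozen=True)
class Grid:
    """Spatial support of a raster layer.

    Parameters
    ----------
    n_rows, n_cols
        Shape of the layer; at least 1 each.
    cell_size
        Edge length of a (square) cell in meters; strictly positive.
    origin
        ``(x, y)`` map coordinates of the outer top-left corner of cell (0, 0).
    crs_label
        Free-text spatial-reference tag; may be empty. Compared verbatim.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_label: str = ""

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def aligned_with(self, other: "Grid", rtol: float = 1e-9) -> bool:
        """True iff the two grids coincide (shape, cell size, origin, CRS tag)."""
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and math.isclose(self.cell_size, other.cell_size, rel_tol=rtol)
            and math.isclose(self.origin[0], other.origin[0], rel_tol=rtol, abs_tol=1e-6)
            and math.isclose(self.origin[1], other.origin[1], rel_tol=rtol, abs_tol=1e-6)
            and self.crs_label == other.crs_label
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) map coordinates of every cell center, each shaped (n_rows, n_cols)."""
        cols = np.arange(self.n_cols) + 0.5
        rows = np.arange(self.n_rows) + 0.5
        x = self.origin[0] + cols * self.cell_size
        y = self.origin[1] - rows * self.cell_size
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(y[:, None], self.shape).copy()


def require_aligned(*grids: Grid) -> None:
    """Raise :class:`AlignmentError` unless all grids coincide."""
    first = grids[0]
    for g in grids[1:]:
        if not first.aligned_with(g):
            raise AlignmentError(f"grids are not aligned: {first} vs {g}")


@dataclass
class Raster:
    """A real-valued layer with a validity mask (``valid=False`` means nodata)."""

    grid: Grid
    values: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.grid.shape or self.valid.shape != self.grid.shape:
            raise ValueError(
                f"layer shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_values(self) -> np.ndarray:
        """1-D array of the values at valid cells."""
        return self.values[self.valid]

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy(), self.valid.copy())


@dataclass
class CategoricalRaster:
    """An integer-state layer: every valid cell holds a level in {1, ..., n_states}."""

    grid: Grid
    levels: np.ndarray
    n_states: int
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int32)
        if self.valid is None:
            self.valid = np.ones(self.grid.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.levels.shape != self.grid.shape or self.valid.shape != self.grid.shape:
            raise ValueError("layer shape does not match grid")
        if self.n_states < 2:
            raise ValueError("a categorical layer needs at least 2 states")
        lv = self.levels[self.valid]
        if lv.size and (lv.min() < 1 or lv.max() > self.n_states):
            raise ValueError(
                f"levels outside 1..{self.n_states} at valid cells "
                f"(saw {int(lv.min())}..{int(lv.max())})"
            )

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class RegionMask:
    """A boolean membership layer (e.g., island land, the study area, a subset match)."""

    grid: Grid
    member: np.ndarray

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=bool)
        if self.member.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")

    @property
    def n_member(self) -> int:
        return int(self.member.sum())

    def intersect(self, other: "RegionMask") -> "RegionMask":
        require_aligned(self.grid, other.grid)
        return RegionMask(self.grid, self.member & other.member)


def buffer_mask(land: RegionMask, distance: float) -> RegionMask:
    """Dilate ``land`` by ``distance`` meters (Euclidean, between cell centers).

    Returns the cells whose center lies within ``distance`` of the center of
    any member cell, including the members themselves. With the 1000 m default
    of the assessment convention this produces the study-area mask (island land
    plus its surrounding sea ring).
    """
    if distance < 0:
        raise ValueError("buffer distance must be nonnegative")
    if land.n_member == 0:
        raise ValueError("cannot buffer an empty mask")
    if distance == 0:
        return RegionMask(land.grid, land.member.copy())
    # Exact Euclidean center-to-center distances on a regular grid.
    dist = ndimage.distance_transform_edt(
        ~land.member, sampling=land.grid.cell_size
    )
    return RegionMask(land.grid, dist <= distance + 1e-9)


def resample_nearest(r: Raster | CategoricalRaster, target: Grid) -> Raster | CategoricalRaster:
    """Nearest-neighbour resample onto ``target``; explicit pre-processing only.

    Target cells whose center falls outside the source extent come back invalid.
    """
    src = r.grid
    tx, ty = target.cell_centers()
    col = np.floor((tx - src.origin[0]) / src.cell_size).astype(int)
    row = np.floor((src.origin[1] - ty) / src.cell_size).astype(int)
    inside = (row >= 0) & (row < src.n_rows) & (col >= 0) & (col < src.n_cols)
    rr = np.clip(row, 0, src.n_rows - 1)
    cc = np.clip(col, 0, src.n_cols - 1)
    valid = inside & r.valid[rr, cc]
    if isinstance(r, CategoricalRaster):
        levels = np.where(valid, r.levels[rr, cc], 1)
        return CategoricalRaster(target, levels, r.n_states, valid, labels=r.labels)
    values = np.where(valid, r.values[rr, cc], np.nan)
    return Raster(target, values, valid)
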