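"""Perimetric pattern, OCT superpixel grids and unit maps.

Coordinate conventions
----------------------
All coordinates are degrees of visual angle in *right-eye* format.

* **Visual-field (VF) frame**: ``x > 0`` is the temporal field, ``y > 0``
  the superior field.
* **Retinal frame**: the VF flipped along the horizontal midline
  (``y -> -y``); superior retina has ``y > 0`` and corresponds to the
  inferior hemifield.  ``x`` is carried through unchanged, so the nasal
  retina sits at ``x > 0``.

Superpixel grids are squares of side ``n * cell_size = 24`` degrees centred
on the fovea.  Superpixels are numbered S1..S(n^2) row-major from the
superior-temporal corner of the retina: columns run temporal-to-nasal
(increasing ``x``), rows run superior-to-inferior (decreasing ``y``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

Scheme = Literal["CMA", "LMA"]

#: Radius-squared bound (deg^2) selecting the 68 stimuli of the 10-2 pattern
#: on the odd-integer lattice.
_PATTERN_R2 = 82
_BOUNDARY_TOL = 1e-9


class OutsideGridError(ValueError):
    """A point falls outside the superpixel grid extent."""


@dataclass(frozen=True)
class VFLocation:
    """A single perimetric stimulus location.

    ``x`` and ``y`` are odd integers (degrees, right-eye VF convention).
    """

    id: int
    x: float
    y: float


@dataclass(frozen=True)
class VFPattern:
    """An ordered set of perimetric stimulus locations."""

    locations: tuple[VFLocation, ...]
    spacing: float = 2.0

    def __len__(self) -> int:
        return len(self.locations)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (x, y) in degrees."""
        return np.array([(l.x, l.y) for l in self.locations], dtype=float)

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(l.id for l in self.locations)

    def location(self, loc_id: int) -> VFLocation:
        for l in self.locations:
            if l.id == loc_id:
                return l
        raise KeyError(f"no location with id {loc_id}")


def make_10_2_pattern() -> VFPattern:
    """Generate the 68-point 10-2 perimetric pattern.

    Stimuli lie on the odd-integer lattice, 2 degrees apart, within the
    central 10 degrees: all (x, y) with x, y odd, |x|, |y| <= 9 and
    x^2 + y^2 <= 82.  Locations are numbered in reading order (superior
    row first, temporal to nasal within a row), as printed on perimetric
    charts.
    """
    pts = [
        (x, y)
        for y in range(9, -10, -2)
        for x in range(-9, 10, 2)
        if x * x + y * y <= _PATTERN_R2
    ]
    locs = tuple(
        VFLocation(id=i + 1, x=float(x), y=float(y)) for i, (x, y) in enumerate(pts)
    )
    return VFPattern(locations=locs)


def flip_vertical(pattern: VFPattern) -> VFPattern:
    """Flip a pattern along the horizontal midline (``y -> -y``).

    Maps VF coordinates to the corresponding retinal locations (and back:
    the operation is an involution).  Location ids are preserved.
    """
    locs = tuple(replace(l, y=-l.y) for l in pattern.locations)
    return replace(pattern, locations=locs)


def to_right_eye_format(coords, laterality: str):
    """Convert coordinates to right-eye format.

    Right eyes are returned unchanged; left-eye coordinates are mirrored
    horizontally (``x -> -x``).  Accepts a ``VFPattern`` or an array of
    shape (..., 2).
    """
    if laterality not in ("left", "right"):
        raise ValueError(f"unknown laterality: {laterality!r}")
    if isinstance(coords, VFPattern):
        if laterality == "right":
            return coords
        locs = tuple(replace(l, x=-l.x) for l in coords.locations)
        return replace(coords, locations=locs)
    arr = np.asarray(coords, dtype=float)
    if laterality == "right":
        return arr
    out = arr.copy()
    out[..., 0] = -out[..., 0]
    return out


def _axis_index(w: float, half: float, cell: float, n: int) -> int:
    """Index of the cell interval containing ``w`` along one axis.

    Intervals are half-open with the closed edge on the peripheral side:
    a coordinate exactly on an interior boundary joins the cell farther
    from fixation.  The two outer edges are closed inward.
    """
    if w < -half - _BOUNDARY_TOL or w > half + _BOUNDARY_TOL:
        raise OutsideGridError(f"coordinate {w} outside grid half-width {half}")
    u = (w + half) / cell
    i = int(np.floor(u + _BOUNDARY_TOL))
    on_boundary = abs(u - round(u)) < _BOUNDARY_TOL
    if on_boundary and w < -_BOUNDARY_TOL:
        i -= 1
    return min(max(i, 0), n - 1)


@dataclass(frozen=True)
class SuperpixelGrid:
    """Square lattice of thickness-averaging cells, optionally rotated.

    ``rotation`` is the fovea-to-Bruch's-membrane-opening (FoBMO) angle in
    degrees; the grid is conceptually acquired along that axis and rotated
    back so its rows read horizontal.  Membership tests counter-rotate the
    query point about the fovea, which leaves all center-to-center
    distances unchanged.
    """

    n: int
    cell_size: float
    center: tuple[float, float] = (0.0, 0.0)
    rotation: float = 0.0
    excluded: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        bad = {i for i in self.excluded if not 1 <= i <= self.n_cells}
        if bad:
            raise ValueError(f"excluded ids out of range: {sorted(bad)}")

    @property
    def n_cells(self) -> int:
        return self.n * self.n

    @property
    def half_extent(self) -> float:
        return self.n * self.cell_size / 2.0

    @property
    def superpixel_ids(self) -> range:
        return range(1, self.n_cells + 1)

    def _rot(self, invert: bool = False) -> np.ndarray:
        a = np.deg2rad(-self.rotation if invert else self.rotation)
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s], [s, c]])

    def _to_grid_frame(self, xy: np.ndarray) -> np.ndarray:
        return (xy - np.asarray(self.center)) @ self._rot(invert=True).T

    def _to_world(self, xy: np.ndarray) -> np.ndarray:
        return xy @ self._rot().T + np.asarray(self.center)

    def cell_of(self, x: float, y: float) -> int:
        """Superpixel id containing the point (peripheral tie-break)."""
        gx, gy = self._to_grid_frame(np.array([x, y], dtype=float))
        col = _axis_index(gx, self.half_extent, self.cell_size, self.n)
        iy = _axis_index(gy, self.half_extent, self.cell_size, self.n)
        row = self.n - 1 - iy
        return row * self.n + col + 1

    def _check_id(self, sp_id: int) -> None:
        if not 1 <= sp_id <= self.n_cells:
            raise KeyError(f"superpixel id {sp_id} not in 1..{self.n_cells}")

    def cell_center(self, sp_id: int) -> tuple[float, float]:
        """Center of a superpixel in world (retinal) coordinates."""
        self._check_id(sp_id)
        row, col = divmod(sp_id - 1, self.n)
        gx = -self.half_extent + (col + 0.5) * self.cell_size
        gy = self.half_extent - (row + 0.5) * self.cell_size
        x, y = self._to_world(np.array([gx, gy]))
        return float(x), float(y)

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of world-frame centers, id order."""
        return np.array([self.cell_center(i) for i in self.superpixel_ids])

    def cell_sample_points(self, sp_id: int, k: int = 5) -> np.ndarray:
        """A deterministic k x k quadrature lattice inside a cell (world frame)."""
        self._check_id(sp_id)
        return self.all_sample_points(k)[sp_id - 1]

    def all_sample_points(self, k: int = 5) -> np.ndarray:
        """(n_cells, k*k, 2) quadrature lattices for every cell, id order."""
        off = (np.arange(k) + 0.5) / k * self.cell_size
        rows, cols = np.divmod(np.arange(self.n_cells), self.n)
        gx = -self.half_extent + cols[:, None] * self.cell_size + off[None, :]
        gy = self.half_extent - (rows[:, None] + 1) * self.cell_size + off[None, :]
        gxx = np.repeat(gx[:, None, :], k, axis=1)  # (cells, ky, kx)
        gyy = np.repeat(gy[:, :, None], k, axis=2)
        pts = np.stack([gxx, gyy], axis=-1).reshape(self.n_cells, k * k, 2)
        return self._to_world(pts)


def make_grid(scheme: Scheme) -> SuperpixelGrid:
    """Build the fovea-centred superpixel grid for a mapping scheme.

    CMA uses 8 x 8 cells of 3 degrees (boundaries at -12, -9, ..., 12);
    LMA uses 12 x 12 cells of 2 degrees (boundaries at -12, -10, ..., 12),
    whose cell centers coincide with the 10-2 stimulus lattice.
    """
    if scheme == "CMA":
        return SuperpixelGrid(n=8, cell_size=3.0)
    if scheme == "LMA":
        return SuperpixelGrid(n=12, cell_size=2.0)
    raise ValueError(f"unknown scheme: {scheme!r}")


def rotate_grid(grid: SuperpixelGrid, fobmo_angle_deg: float) -> SuperpixelGrid:
    """Return a copy of the grid rotated about the fovea by the FoBMO angle."""
    if not np.isfinite(fobmo_angle_deg):
        raise ValueError("FoBMO angle must be finite")
    return replace(grid, rotation=float(fobmo_angle_deg))


def superpixel_center(grid: SuperpixelGrid, sp_id: int) -> tuple[float, float]:
    """World-frame center of a superpixel, degrees."""
    return grid.cell_center(sp_id)


def distance_deg(grid: SuperpixelGrid, id_a: int, id_b: int) -> float:
    """Euclidean distance between two superpixel centers, degrees."""
    a = np.array(grid.cell_center(id_a))
    b = np.array(grid.cell_center(id_b))
    return float(np.hypot(*(a - b)))


def apply_onh_exclusion(
    grid: SuperpixelGrid,
    disc_center: tuple[float, float],
    disc_radius: float,
) -> SuperpixelGrid:
    """Exclude superpixels overlying the optic nerve head.

    A superpixel is excluded when its center falls within the disc circle
    (center and radius in degrees, right-eye retinal frame).  Excluded
    cells are masked out of every downstream atlas and vector map.
    """
    centers = grid.cell_centers()
    d = np.hypot(centers[:, 0] - disc_center[0], centers[:, 1] - disc_center[1])
    hit = {int(i) + 1 for i in np.nonzero(d <= disc_radius)[0]}
    return replace(grid, excluded=grid.excluded | frozenset(hit))


@dataclass(frozen=True)
class VFUnit:
    """A group of VF locations correlated against one mapped superpixel."""

    id: str
    member_location_ids: tuple[int, ...]
    mapped_superpixel: int


@dataclass(frozen=True)
class VFUnitMap:
    """Partition of the 68 locations into units, with mapped superpixels."""

    units: tuple[VFUnit, ...]
    scheme: Scheme
    grid: SuperpixelGrid
    pattern: VFPattern

    def __len__(self) -> int:
        return len(self.units)

    @property
    def unit_ids(self) -> tuple[str, ...]:
        return tuple(u.id for u in self.units)

    @property
    def mapped_superpixels(self) -> np.ndarray:
        return np.array([u.mapped_superpixel for u in self.units])

    def unit(self, unit_id: str) -> VFUnit:
        for u in self.units:
            if u.id == unit_id:
                return u
        raise KeyError(f"no unit {unit_id}")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (unit, member location)."""
        rows = []
        for u in self.units:
            for lid in u.member_location_ids:
                loc = self.pattern.location(lid)
                rows.append(
                    dict(
                        unit_id=u.id,
                        scheme=self.scheme,
                        location_id=lid,
                        x_deg=loc.x,
                        y_deg=loc.y,
                        superpixel_id=u.mapped_superpixel,
                    )
                )
        return pd.DataFrame(rows)


def assign_units(
    pattern: VFPattern, grid: SuperpixelGrid, scheme: Scheme
) -> VFUnitMap:
    """Group pattern locations into VF units mapped to grid superpixels.

    The pattern must already be in retinal orientation (vertically
    flipped).  Under CMA each location joins the superpixel containing it,
    with boundary ties broken toward the peripheral cell; non-empty cells
    become units C1..C40 (ordered by superpixel id).  Under LMA every
    location is its own unit L1..L68, mapped to the cell centred on it.
    """
    if scheme == "CMA":
        by_cell: dict[int, list[int]] = {}
        for loc in pattern.locations:
            sp = grid.cell_of(loc.x, loc.y)
            by_cell.setdefault(sp, []).append(loc.id)
        units = tuple(
            VFUnit(
                id=f"C{i + 1}",
                member_location_ids=tuple(sorted(by_cell[sp])),
                mapped_superpixel=sp,
            )
            for i, sp in enumerate(sorted(by_cell))
        )
    elif scheme == "LMA":
        units = tuple(
            VFUnit(
                id=f"L{i + 1}",
                member_location_ids=(loc.id,),
                mapped_superpixel=grid.cell_of(loc.x, loc.y),
            )
            for i, loc in enumerate(pattern.locations)
        )
    else:
        raise ValueError(f"unknown scheme: {scheme!r}")
    return VFUnitMap(units=units, scheme=scheme, grid=grid, pattern=pattern)
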