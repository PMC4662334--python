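"""Trap arrays, survey designs and habitat masks.

All coordinates are planar metres. Density surfaces are expressed in animals
per hectare, so spatial integrals divide mask cell areas (m^2) by 1e4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint
from shapely.geometry.base import BaseGeometry

#: square metres per density unit (densities are per hectare)
M2_PER_HA = 1.0e4

RegionTag = Literal["full_integration", "full_report", "reduced_report"]


@dataclass(frozen=True)
class TrapArray:
    """An array of K traps at fixed planar locations."""

    trap_id: np.ndarray  # shape (K,), str or int identifiers
    x: np.ndarray  # metres, shape (K,)
    y: np.ndarray  # metres, shape (K,)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        ids = np.asarray(self.trap_id)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "trap_id", ids)
        if x.ndim != 1 or x.shape != y.shape or ids.shape != x.shape:
            raise ValueError("trap_id, x, y must be equal-length 1-d arrays")
        if x.size < 1:
            raise ValueError("need at least one trap")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("trap coordinates must be finite")
        if len(set(ids.tolist())) != ids.size:
            raise ValueError("trap_ids must be unique")

    @property
    def n_traps(self) -> int:
        return int(self.x.size)

    @property
    def coords(self) -> np.ndarray:
        """(K, 2) array of trap coordinates."""
        return np.column_stack([self.x, self.y])

    def convex_hull(self) -> BaseGeometry:
        return MultiPoint([(xi, yi) for xi, yi in self.coords]).convex_hull

    def distances_to(self, points: np.ndarray) -> np.ndarray:
        """Euclidean distances, shape (n_points, K)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.hypot(
            pts[:, 0:1] - self.x[None, :], pts[:, 1:2] - self.y[None, :]
        )


def build_grid_array(n_cols: int, n_rows: int, spacing: float) -> TrapArray:
    """Rectangular trap grid; columns run east-west (x), westernmost at x = 0.

    ``build_grid_array(5, 4, 100)`` is the study design: 20 traps spanning
    400 m east-west by 300 m north-south.
    """
    if n_cols < 1 or n_rows < 1:
        raise ValueError("grid dimensions must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    xs, ys = np.meshgrid(
        np.arange(n_cols) * spacing, np.arange(n_rows) * spacing
    )
    ids = np.array([f"T{i + 1}" for i in range(n_cols * n_rows)])
    return TrapArray(trap_id=ids, x=xs.ravel(), y=ys.ravel())


@dataclass(frozen=True)
class SurveyDesign:
    """Survey geometry and occasion/reset schedule.

    Time is measured in days from the survey origin, which coincides with the
    first trap check/reset (08:00 by convention); occasions are whole days, so
    occasion boundaries sit at integer multiples of T / L.
    """

    traps: TrapArray
    duration_T: float  # days
    num_occasions_L: int
    reset_time_of_day: float = 8.0  # clock hours, metadata only
    start_time: float = 0.0  # days

    def __post_init__(self) -> None:
        if self.duration_T <= 0:
            raise ValueError("duration_T must be positive")
        if self.num_occasions_L < 1:
            raise ValueError("need at least one occasion")

    @property
    def occasion_length(self) -> float:
        return self.duration_T / self.num_occasions_L


def occasion_boundaries(design: SurveyDesign) -> np.ndarray:
    """L+1 strictly increasing times from 0 to T; resets at internal boundaries."""
    return np.linspace(0.0, design.duration_T, design.num_occasions_L + 1)


@dataclass(frozen=True)
class Mask:
    """Regular grid of candidate activity-centre locations over a region."""

    points: np.ndarray  # (M, 2), metres
    cell_area: float  # m^2 per point
    region_tag: RegionTag
    region: BaseGeometry = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        object.__setattr__(self, "points", pts)
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        if pts.shape[0] == 0:
            raise ValueError("mask region is empty")

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    @property
    def area(self) -> float:
        """Approximate region area in m^2 (points x cell_area)."""
        return self.n_points * self.cell_area

    @property
    def cell_area_ha(self) -> float:
        return self.cell_area / M2_PER_HA


def _region_geometry(traps: TrapArray, buffer: float, region_tag: RegionTag) -> BaseGeometry:
    if region_tag == "full_integration":
        # bounding box of the array buffered on all sides
        xmin, ymin = traps.coords.min(axis=0)
        xmax, ymax = traps.coords.max(axis=0)
        from shapely.geometry import box

        return box(xmin - buffer, ymin - buffer, xmax + buffer, ymax + buffer)
    hull = traps.convex_hull()
    if buffer > 0:
        # mitre join keeps rectangular arrays rectangular after buffering
        return hull.buffer(buffer, join_style="mitre")
    return hull


def build_mask(
    traps: TrapArray,
    buffer: float,
    spacing: float,
    region_tag: RegionTag = "full_integration",
) -> Mask:
    """Regular grid mask over the tagged region, endpoint-inclusive.

    full_integration: trap bounding box buffered (4 sigma in the study design).
    full_report: convex hull of the traps buffered (2 sigma).
    reduced_report: the convex hull itself (buffer ignored unless > 0).
    """
    if buffer < 0:
        raise ValueError("buffer must be >= 0")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    region = _region_geometry(traps, buffer, region_tag)
    xmin, ymin, xmax, ymax = region.bounds
    eps = 1e-9 * max(1.0, abs(xmax), abs(ymax))
    xs = np.arange(xmin, xmax + spacing / 2, spacing)
    ys = np.arange(ymin, ymax + spacing / 2, spacing)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    import shapely

    inside = shapely.contains_xy(region.buffer(eps), pts[:, 0], pts[:, 1])
    return Mask(
        points=pts[inside],
        cell_area=spacing**2,
        region_tag=region_tag,
        region=region,
    )


def read_traps(path) -> TrapArray:
    """Read a trap layout file (CSV with header trap_id, x, y)."""
    df = pd.read_csv(path)
    required = {"trap_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"trap file must have columns {sorted(required)}")
    return TrapArray(
        trap_id=df["trap_id"].to_numpy(),
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
    )


def write_traps(traps: TrapArray, path) -> None:
    pd.DataFrame(
        {"trap_id": traps.trap_id, "x": traps.x, "y": traps.y}
    ).to_csv(path, index=False)


def write_mask(mask: Mask, path) -> None:
    pd.DataFrame(
        {
            "x": mask.points[:, 0],
            "y": mask.points[:, 1],
            "region_tag": mask.region_tag,
        }
    ).to_csv(path, index=False)
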