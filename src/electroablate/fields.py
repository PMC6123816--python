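"""Reconstruction of continuous 2D fields from scattered probe measurements.

Probe measurements (pH or voltage) are taken at a fixed set of sites in the
dish; each site may be sampled several times.  This module aggregates the
replicates, linearly interpolates the per-site means on the Delaunay
triangulation of the sites, rasterizes the interpolant onto a regular grid
(cells outside the convex hull are masked invalid), and extracts iso-contours
by marching squares.  Linear interpolation on the triangulation reproduces
affine fields exactly and never overshoots the vertex values of a triangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.ndimage import map_coordinates
from scipy.spatial import QhullError, distance
from skimage import measure

from .errors import ValidationError

__all__ = [
    "MeasurementGrid",
    "FieldSamples",
    "RasterField",
    "aggregate_replicates",
    "recenter_voltage",
    "linear_interpolator",
    "interpolate_scattered",
    "extract_contours",
    "rasterize",
]

#: default raster cell size, mm.  Much finer than the >=2 mm inter-site
#: spacing of the measurement template, much coarser than a cell diameter.
DEFAULT_SPACING = 0.1


@dataclass(frozen=True)
class MeasurementGrid:
    """Scattered measurement sites: parallel tuples of ids and (x, y) in mm."""

    site_ids: tuple
    xy: np.ndarray

    def __post_init__(self):
        xy = np.asarray(self.xy, dtype=float)
        object.__setattr__(self, "xy", xy)
        object.__setattr__(self, "site_ids", tuple(str(s) for s in self.site_ids))
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValidationError("site coordinates must be an (n, 2) array")
        if len(self.site_ids) != len(xy):
            raise ValidationError("site_ids and xy must have the same length")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValidationError("site_ids must be unique")

    def __len__(self) -> int:
        return len(self.site_ids)

    def index_of(self, site_id: str) -> int:
        return self.site_ids.index(site_id)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"site_id": self.site_ids, "x_mm": self.xy[:, 0], "y_mm": self.xy[:, 1]}
        )


@dataclass(frozen=True)
class FieldSamples:
    """Replicate measurements of one scalar quantity on a MeasurementGrid.

    ``data`` has columns ``site_id``, ``replicate``, ``value``; every site_id
    must exist in the grid.  pH values are checked against [0, 14].
    """

    grid: MeasurementGrid
    quantity: str
    data: pd.DataFrame

    def __post_init__(self):
        required = {"site_id", "replicate", "value"}
        if not required.issubset(self.data.columns):
            raise ValidationError(f"samples need columns {sorted(required)}")
        known = set(self.grid.site_ids)
        unknown = set(self.data["site_id"]) - known
        if unknown:
            raise ValidationError(f"values reference unknown sites: {sorted(unknown)}")
        vals = self.data["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("sample values must be finite")
        if self.quantity == "pH" and (vals.min() < 0.0 or vals.max() > 14.0):
            raise ValidationError("pH values must lie in [0, 14]")

    def replicate_counts(self) -> pd.Series:
        counts = self.data.groupby("site_id").size()
        return counts.reindex(self.grid.site_ids, fill_value=0)

    def per_site_means(self) -> np.ndarray:
        """Per-site arithmetic means aligned with the grid's site order."""
        means = self.data.groupby("site_id")["value"].mean()
        return means.reindex(self.grid.site_ids).to_numpy(dtype=float)


@dataclass
class RasterField:
    """A gridded field in world coordinates.

    ``values[row, col]`` lives at ``(origin[0] + col*spacing,
    origin[1] + row*spacing)``; ``valid_mask`` marks cells inside the convex
    hull of the source sites (or everywhere, for rasterized analytic fields).
    """

    origin: tuple
    spacing: float
    values: np.ndarray
    valid_mask: np.ndarray
    quantity: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.spacing <= 0:
            raise ValidationError("raster spacing must be positive")
        if self.values.shape != self.valid_mask.shape:
            raise ValidationError("values and valid_mask shapes differ")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValidationError("values must be finite wherever valid")

    @property
    def x_coords(self) -> np.ndarray:
        return self.origin[0] + self.spacing * np.arange(self.values.shape[1])

    @property
    def y_coords(self) -> np.ndarray:
        return self.origin[1] + self.spacing * np.arange(self.values.shape[0])

    def masked(self) -> np.ndarray:
        """Values with invalid cells set to NaN."""
        out = self.values.copy()
        out[~self.valid_mask] = np.nan
        return out

    def sample_bilinear(self, x, y) -> np.ndarray:
        """Bilinear sample at world points; NaN outside the valid region."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rows = (y - self.origin[1]) / self.spacing
        cols = (x - self.origin[0]) / self.spacing
        return map_coordinates(
            self.masked(), [rows, cols], order=1, mode="constant", cval=np.nan
        )


def aggregate_replicates(samples: FieldSamples, min_replicates: int = 1) -> FieldSamples:
    """Collapse replicate measurements to one mean value per site.

    Raises ValidationError naming the first offending site if any site has
    fewer than ``min_replicates`` values.  Site order is preserved.
    """
    counts = samples.replicate_counts()
    short = counts[counts < min_replicates]
    if len(short):
        raise ValidationError(
            f"site '{short.index[0]}' has {int(short.iloc[0])} replicates, "
            f"fewer than the required {min_replicates}"
        )
    means = samples.per_site_means()
    data = pd.DataFrame(
        {"site_id": samples.grid.site_ids, "replicate": 0, "value": means}
    )
    return FieldSamples(grid=samples.grid, quantity=samples.quantity, data=data)


def linear_interpolator(samples: FieldSamples) -> Callable:
    """Delaunay barycentric-linear interpolant of the per-site means.

    Returns a callable (x, y) -> value (NaN outside the convex hull).
    """
    xy = samples.grid.xy
    if len(xy) < 3:
        raise ValidationError("interpolation needs at least 3 sites")
    d = distance.pdist(xy)
    if d.size and d.min() < 1e-9:
        raise ValidationError("duplicate sites (within 1e-9 mm) cannot be triangulated")
    values = samples.per_site_means()
    try:
        return LinearNDInterpolator(xy, values)
    except QhullError as exc:  # collinear sites
        raise ValidationError(f"sites cannot be triangulated: {exc}") from exc


def recenter_voltage(samples: FieldSamples, midpoint) -> tuple:
    """Re-center voltage samples around the interpolated value at ``midpoint``.

    Returns ``(signed, magnitude)`` FieldSamples: the signed field (used for
    gradient computation) and its absolute-value view (the reported potential
    relative to the midpoint between the electrodes).
    """
    interp = linear_interpolator(samples)
    v0 = float(interp(midpoint[0], midpoint[1]))
    if not np.isfinite(v0):
        raise ValidationError(
            f"midpoint {tuple(midpoint)} lies outside the convex hull of the sites"
        )
    signed_data = samples.data.copy()
    signed_data["value"] = signed_data["value"].astype(float) - v0
    signed = FieldSamples(grid=samples.grid, quantity=samples.quantity, data=signed_data)
    mag_data = signed_data.copy()
    mag_data["value"] = mag_data["value"].abs()
    magnitude = FieldSamples(grid=samples.grid, quantity=samples.quantity, data=mag_data)
    return signed, magnitude


def interpolate_scattered(
    samples: FieldSamples,
    spacing: float = DEFAULT_SPACING,
    bounds=None,
) -> RasterField:
    """Rasterize scattered per-site values by Delaunay linear interpolation.

    ``samples`` must carry exactly one value per site (aggregate first).
    ``bounds = (x_min, x_max, y_min, y_max)`` defaults to the site bounding
    box.  Cells outside the convex hull are masked invalid.
    """
    counts = samples.replicate_counts()
    if (counts > 1).any():
        raise ValidationError(
            "interpolate_scattered expects one value per site; "
            "call aggregate_replicates first"
        )
    interp = linear_interpolator(samples)
    xy = samples.grid.xy
    if bounds is None:
        bounds = (xy[:, 0].min(), xy[:, 0].max(), xy[:, 1].min(), xy[:, 1].max())
    x_min, x_max, y_min, y_max = map(float, bounds)
    # snap the origin to the spacing lattice so refined rasters share nodes
    x0 = np.floor(x_min / spacing) * spacing
    y0 = np.floor(y_min / spacing) * spacing
    nx = int(np.ceil((x_max - x0) / spacing)) + 1
    ny = int(np.ceil((y_max - y0) / spacing)) + 1
    xs = x0 + spacing * np.arange(nx)
    ys = y0 + spacing * np.arange(ny)
    X, Y = np.meshgrid(xs, ys)
    values = interp(X, Y)
    mask = np.isfinite(values)
    values = np.where(mask, values, 0.0)
    return RasterField(
        origin=(x0, y0), spacing=spacing, values=values, valid_mask=mask,
        quantity=samples.quantity,
    )


def rasterize(
    func: Callable,
    bounds,
    spacing: float = DEFAULT_SPACING,
    quantity: str = "",
) -> RasterField:
    """Rasterize an analytic field ``func(x, y)`` over ``bounds`` (fully valid)."""
    x_min, x_max, y_min, y_max = map(float, bounds)
    x0 = np.floor(x_min / spacing) * spacing
    y0 = np.floor(y_min / spacing) * spacing
    nx = int(np.ceil((x_max - x0) / spacing)) + 1
    ny = int(np.ceil((y_max - y0) / spacing)) + 1
    X, Y = np.meshgrid(x0 + spacing * np.arange(nx), y0 + spacing * np.arange(ny))
    values = np.asarray(func(X, Y), dtype=float)
    return RasterField(
        origin=(x0, y0), spacing=spacing, values=values,
        valid_mask=np.ones_like(values, dtype=bool), quantity=quantity,
    )


def extract_contours(raster: RasterField, levels: Sequence[float]) -> dict:
    """Marching-squares iso-lines of a raster, per level, in world mm.

    Returns ``{level: [polyline (n, 2) arrays of (x, y)]}``.  Levels outside
    the raster's range simply yield empty lists.  Invalid cells are excluded.
    """
    out = {}
    masked = raster.masked()
    for level in levels:
        if not np.isfinite(level):
            raise ValidationError("contour levels must be finite")
        lines = []
        for rc in measure.find_contours(masked, float(level)):
            xy = np.column_stack(
                (
                    raster.origin[0] + rc[:, 1] * raster.spacing,
                    raster.origin[1] + rc[:, 0] * raster.spacing,
                )
            )
            lines.append(xy)
        out[float(level)] = lines
    return out
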