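"""Height extraction: terrain/surface rasters and tube-length strips.

Tree height comes from a raster chain: a digital terrain model (per-cell
minimum elevation), a digital surface model (per-cell maximum), and their
difference, the normalised DSM, whose value in the cell containing a stem
centroid is that tree's height above ground.  For laboratory tubes, length
is instead measured from the vertical extent of two narrow diametrically
opposed strips on the tube surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .simulate import PointCloud, TubeSpec

__all__ = [
    "RasterGrid",
    "TerrainModels",
    "rasterize",
    "ndsm",
    "sample_height_at",
    "tube_length_from_segments",
    "write_ascii_grid",
]


@dataclass
class RasterGrid:
    """2D raster over half-open cells [x0+i*cs, x0+(i+1)*cs).

    ``values`` is indexed [row, col] = [iy, ix]; NaN marks empty cells.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray
    aggregation: str = "none"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_index(self, x, y):
        ix = np.floor((np.asarray(x) - self.origin[0]) / self.cell_size).astype(int)
        iy = np.floor((np.asarray(y) - self.origin[1]) / self.cell_size).astype(int)
        return iy, ix

    def sample(self, x, y):
        """Value of the cell containing each (x, y); NaN outside the grid."""
        iy, ix = self.cell_index(x, y)
        ny, nx = self.values.shape
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        out = np.full(np.shape(inside), np.nan)
        out[inside] = self.values[iy[inside], ix[inside]]
        return out

    def congruent_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) < 1e-12
            and abs(self.origin[0] - other.origin[0]) < 1e-9
            and abs(self.origin[1] - other.origin[1]) < 1e-9
        )


def rasterize(cloud: PointCloud, cell_size: float, aggregation: str) -> RasterGrid:
    """Per-cell min or max of point elevation over a regular XY grid.

    The grid origin snaps to a multiple of ``cell_size`` at the floor of
    the cloud bounds, and the extent covers all points; cells are
    half-open, so a point exactly on a boundary belongs to the
    higher-index cell.  Empty cells are NaN.
    """
    if len(cloud) == 0:
        raise ValueError("cloud is empty")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if aggregation not in ("min", "max"):
        raise ValueError("aggregation must be 'min' or 'max'")
    lo, hi = cloud.bounds
    x0 = np.floor(lo[0] / cell_size) * cell_size
    y0 = np.floor(lo[1] / cell_size) * cell_size
    nx = int(np.floor((hi[0] - x0) / cell_size)) + 1
    ny = int(np.floor((hi[1] - y0) / cell_size)) + 1
    ix = np.floor((cloud.points[:, 0] - x0) / cell_size).astype(int)
    iy = np.floor((cloud.points[:, 1] - y0) / cell_size).astype(int)
    flat = iy * nx + ix
    init = np.inf if aggregation == "min" else -np.inf
    vals = np.full(ny * nx, init)
    op = np.minimum if aggregation == "min" else np.maximum
    op.at(vals, flat, cloud.points[:, 2])
    vals[~np.isfinite(vals)] = np.nan
    return RasterGrid(
        origin=(x0, y0),
        cell_size=cell_size,
        values=vals.reshape(ny, nx),
        aggregation=aggregation,
    )


def _nn_fill(values: np.ndarray) -> np.ndarray:
    """Fill NaN cells with the value of the nearest non-NaN cell."""
    mask = np.isnan(values)
    if not mask.any():
        return values
    if mask.all():
        raise ValueError("cannot fill a raster with no defined cells")
    _, (iy, ix) = ndimage.distance_transform_edt(mask, return_indices=True)
    return values[iy, ix]


def ndsm(dtm: RasterGrid, dsm: RasterGrid, fill: bool = True) -> RasterGrid:
    """Cellwise DSM minus DTM: heights above ground.

    With ``fill=True`` (the default, appropriate on flat sites) terrain
    cells hidden under dense crowns are filled from the nearest defined
    ground cell before subtracting; otherwise nodata propagates.
    """
    if not dtm.congruent_with(dsm):
        raise ValueError("DTM and DSM grids are not congruent")
    ground = _nn_fill(dtm.values.copy()) if fill else dtm.values
    return RasterGrid(
        origin=dtm.origin,
        cell_size=dtm.cell_size,
        values=dsm.values - ground,
        aggregation="ndsm",
    )


@dataclass
class TerrainModels:
    """DTM (min), DSM (max) and nDSM (= DSM - DTM) on one grid."""

    dtm: RasterGrid
    dsm: RasterGrid
    ndsm: RasterGrid

    @classmethod
    def from_cloud(
        cls, cloud: PointCloud, cell_size: float = 0.5, fill: bool = True
    ) -> "TerrainModels":
        dtm = rasterize(cloud, cell_size, "min")
        dsm = rasterize(cloud, cell_size, "max")
        return cls(dtm=dtm, dsm=dsm, ndsm=ndsm(dtm, dsm, fill=fill))


def sample_height_at(
    grid: RasterGrid, stem_xy, stem_ids: list[str] | None = None
) -> np.ndarray:
    """Height value of the cell containing each stem centroid.

    Stems outside the raster extent are an error (named); stems over a
    nodata cell come back NaN (missing, not an error).
    """
    stem_xy = np.asarray(stem_xy, dtype=float).reshape(-1, 2)
    iy, ix = grid.cell_index(stem_xy[:, 0], stem_xy[:, 1])
    ny, nx = grid.shape
    outside = (ix < 0) | (ix >= nx) | (iy < 0) | (iy >= ny)
    if outside.any():
        k = int(np.argmax(outside))
        name = stem_ids[k] if stem_ids else f"#{k}"
        raise ValueError(f"stem {name} lies outside the raster extent")
    return grid.values[iy, ix].astype(float)


def tube_length_from_segments(
    cloud: PointCloud,
    tube: TubeSpec,
    segment_width: float = 0.03,
    margin: float = 0.1,
) -> float | None:
    """Tube length (cm) from the z-extent of two opposed vertical strips.

    Two diametrically opposed strips of width ``segment_width`` are cut
    from the tube's surface points (either side of the centre along x);
    the reported length is the mean over strips of (max z - min z).  If
    one strip is empty the other alone is used; if both are empty the
    tube is undetected and ``None`` is returned.
    """
    if segment_width <= 0:
        raise ValueError("segment_width must be positive")
    cx, cy = tube.center_xy
    pts = cloud.points
    near = (
        np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) <= tube.radius_m + margin
    )
    pts = pts[near]
    in_band = np.abs(pts[:, 1] - cy) <= segment_width / 2
    east = pts[in_band & (pts[:, 0] >= cx)]
    west = pts[in_band & (pts[:, 0] < cx)]
    extents = [
        float(strip[:, 2].max() - strip[:, 2].min())
        for strip in (east, west)
        if len(strip) >= 2
    ]
    if not extents:
        return None
    return float(np.mean(extents) * 100.0)


def write_ascii_grid(grid: RasterGrid, path, nodata: float = -9999.0) -> None:
    """Export a raster as an ESRI ASCII grid (north-up row order)."""
    ny, nx = grid.shape
    vals = np.where(np.isnan(grid.values), nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write(f"xllcorner {grid.origin[0]:.6f}\n")
        fh.write(f"yllcorner {grid.origin[1]:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, vals[::-1], fmt="%.4f")
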