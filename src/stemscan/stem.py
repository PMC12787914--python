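"""Stem cross-section analysis: DBH and contour-noise quantification.

The chain implemented here mirrors how stem diameter is read off a
terrestrial point cloud: a thin horizontal slice at breast height is cut
from the cloud and clustered into individual stems; each stem section gets
a reference circle by an algebraic (Taubin) fit; the section is unwrapped
into azimuth-versus-radial-deviation form; a truncated Fourier series
models the systematic contour (ovality, lobes) while staying periodic over
0-360 degrees; and the width of the central interval holding 95% of the
residuals is the device's per-section noise figure, in millimetres.

Diameter itself is taken from the length of a polygon outlining the outer
perimeter of the section (an automated surrogate for manual digitisation):
points are grouped into angular bins about the fitted centre, the outer
radius of each bin is a high quantile of the bin's radii, and the diameter
is the closed polygon's perimeter divided by pi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .simulate import PointCloud

__all__ = [
    "CrossSection",
    "FittedCircle",
    "UnwrappedProfile",
    "FourierModel",
    "NoiseBand",
    "PerimeterPolygon",
    "extract_dbh_slice",
    "fit_circle",
    "unwrap_to_polar",
    "fit_fourier",
    "residual_band95",
    "perimeter_polygon",
    "dbh_from_perimeter",
    "estimate_dbh",
    "section_noise_band",
]

#: Default breast-height band: a 5 cm slice [1.30, 1.35) m above ground.
DEFAULT_CENTER_HEIGHT = 1.325
DEFAULT_THICKNESS = 0.05


@dataclass
class CrossSection:
    """XY points of one stem inside a horizontal height band."""

    points: np.ndarray
    band: tuple[float, float]
    stem_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    @property
    def detected(self) -> bool:
        return len(self.points) >= 3

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass(frozen=True)
class FittedCircle:
    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class UnwrappedProfile:
    """Azimuth (deg, sorted ascending in [0, 360)) vs radial deviation (mm)."""

    theta: np.ndarray
    deviation: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.deviation = np.asarray(self.deviation, dtype=float)
        if self.theta.shape != self.deviation.shape:
            raise ValueError("theta and deviation must have equal length")


@dataclass
class FourierModel:
    """Truncated Fourier series dev(theta) = a0 + sum a_k cos + b_k sin, mm."""

    a0: float
    harmonics: list[tuple[float, float]]

    @property
    def K(self) -> int:
        return len(self.harmonics)

    def __call__(self, theta_deg: np.ndarray) -> np.ndarray:
        th = np.radians(np.asarray(theta_deg, dtype=float))
        out = np.full_like(th, self.a0, dtype=float)
        for k, (a, b) in enumerate(self.harmonics, start=1):
            out += a * np.cos(k * th) + b * np.sin(k * th)
        return out


@dataclass(frozen=True)
class NoiseBand:
    """Width of the central interval containing 95% of contour residuals."""

    width95: float
    n_points: int
    bounds: tuple[float, float]


@dataclass
class PerimeterPolygon:
    """Closed simple polygon outlining a section's outer contour."""

    vertices: np.ndarray
    perimeter: float = field(init=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        poly = Polygon(self.vertices)
        if not poly.is_simple:
            raise ValueError("perimeter polygon is self-intersecting")
        self.perimeter = poly.length


# ---------------------------------------------------------------------------

def _height_above_ground(cloud: PointCloud, ground) -> np.ndarray:
    if ground is None:
        raise ValueError("ground reference is required (constant or TerrainModels)")
    if np.isscalar(ground):
        return cloud.points[:, 2] - float(ground)
    # TerrainModels-like: sample the DTM under each point
    dtm = ground.dtm if hasattr(ground, "dtm") else ground
    return cloud.points[:, 2] - dtm.sample(cloud.points[:, 0], cloud.points[:, 1])


def extract_dbh_slice(
    cloud: PointCloud,
    ground=0.0,
    center_height: float = DEFAULT_CENTER_HEIGHT,
    thickness: float = DEFAULT_THICKNESS,
    cluster_distance: float = 0.3,
) -> list[CrossSection]:
    """Cut the breast-height band and split it into per-stem sections.

    Points whose height above ground falls in
    ``[center_height - thickness/2, center_height + thickness/2)`` are kept,
    projected to XY and partitioned into stems by single-linkage clustering
    at ``cluster_distance`` (safe for plantation spacing well above it).
    Clusters with fewer than 3 points are returned with ``detected=False``.
    An empty band yields an empty list.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    if len(cloud) == 0:
        raise ValueError("cloud is empty")
    h = _height_above_ground(cloud, ground)
    lo = center_height - thickness / 2
    hi = center_height + thickness / 2
    mask = (h >= lo) & (h < hi)
    xy = cloud.points[mask][:, :2]
    if len(xy) == 0:
        return []
    tree = cKDTree(xy)
    pairs = tree.query_pairs(cluster_distance, output_type="ndarray")
    n = len(xy)
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    sections = []
    for c in range(n_comp):
        pts = xy[labels == c]
        sections.append(CrossSection(pts, band=(lo, hi), stem_id=f"S{c:03d}"))
    # stable ordering: by centroid (y, x)
    sections.sort(key=lambda s: (round(s.centroid[1], 6), round(s.centroid[0], 6)))
    for i, s in enumerate(sections):
        s.stem_id = f"S{i:03d}"
    return sections


def fit_circle(section: CrossSection | np.ndarray) -> FittedCircle:
    """Algebraic (Taubin) circle fit; exact on noiseless circular data.

    Minimises the Taubin-normalised algebraic distance, a non-iterative
    eigenvector solution with near-geometric accuracy for small noise.
    Requires at least 3 non-collinear points.
    """
    pts = section.points if isinstance(section, CrossSection) else np.asarray(section)
    pts = pts.reshape(-1, 2)
    if len(pts) < 3:
        raise ValueError("circle fit needs at least 3 points")
    x0, y0 = pts[:, 0].mean(), pts[:, 1].mean()
    x = pts[:, 0] - x0
    y = pts[:, 1] - y0
    cov = np.cov(np.stack([x, y]), bias=True)
    scale = max(cov[0, 0] + cov[1, 1], 1e-300)
    if np.linalg.det(cov) < 1e-12 * scale**2:
        raise ValueError("points are collinear; circle is undefined")
    z = x * x + y * y
    zm = z.mean()
    # Taubin constraint absorbed by rescaling the quadratic column; the
    # null-space vector of [Z0 | x | y] gives A(x^2+y^2)+Bx+Cy+D = 0
    Z0 = (z - zm) / (2.0 * np.sqrt(zm))
    _, _, Vt = np.linalg.svd(np.column_stack([Z0, x, y]), full_matrices=False)
    v = Vt[-1]
    A = v[0] / (2.0 * np.sqrt(zm))
    B, C = v[1], v[2]
    D = -zm * A
    if abs(A) < 1e-15:
        raise ValueError("degenerate circle fit (infinite radius)")
    cx = -B / (2 * A)
    cy = -C / (2 * A)
    r2 = cx * cx + cy * cy - D / A
    if r2 <= 0:
        raise ValueError("degenerate circle fit (non-positive radius)")
    return FittedCircle(
        center=(float(cx + x0), float(cy + y0)), radius=float(np.sqrt(r2))
    )


def unwrap_to_polar(
    section: CrossSection | np.ndarray, circle: FittedCircle
) -> UnwrappedProfile:
    """Express a section as azimuth about the fitted centre vs deviation (mm).

    theta is the atan2 azimuth mapped to [0, 360); deviation is the point's
    radius minus the reference radius, in millimetres.  Output is sorted by
    theta.  A point exactly at the centre has no azimuth and is an error.
    """
    pts = section.points if isinstance(section, CrossSection) else np.asarray(section)
    pts = pts.reshape(-1, 2)
    dx = pts[:, 0] - circle.center[0]
    dy = pts[:, 1] - circle.center[1]
    r = np.hypot(dx, dy)
    if np.any(r < 1e-12):
        raise ValueError("point coincides with the circle centre")
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0
    dev = (r - circle.radius) * 1000.0
    order = np.argsort(theta, kind="stable")
    return UnwrappedProfile(theta[order], dev[order])


def fit_fourier(profile: UnwrappedProfile, K: int = 8) -> FourierModel:
    """Least-squares truncated Fourier fit of the deviation profile.

    The fitted model is periodic over [0, 360) by construction, so the
    contour estimate has no discontinuity at the angular wrap-around —
    the reason a global harmonic model is preferred over local smoothers.
    Needs at least ``2K + 1`` points.
    """
    n = len(profile.theta)
    if K < 0:
        raise ValueError("K must be non-negative")
    if n < 2 * K + 1:
        raise ValueError(f"need at least {2 * K + 1} points for K={K}")
    th = np.radians(profile.theta)
    cols = [np.ones(n)]
    for k in range(1, K + 1):
        cols.append(np.cos(k * th))
        cols.append(np.sin(k * th))
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, profile.deviation, rcond=None)
    harmonics = [(float(coef[2 * k - 1]), float(coef[2 * k])) for k in range(1, K + 1)]
    return FourierModel(a0=float(coef[0]), harmonics=harmonics)


def residual_band95(
    profile: UnwrappedProfile, model: FourierModel, shortest: bool = False
) -> NoiseBand:
    """Width of the interval containing 95% of the contour residuals (mm).

    Residuals are deviations minus the Fourier contour.  By default the
    central (equal-tail) interval between the 2.5th and 97.5th percentiles
    is used; ``shortest=True`` instead finds the narrowest window covering
    95% of the sorted residuals.  A small residual count makes the
    quantiles unstable; below 40 a warning is issued but the band is
    still computed.
    """
    res = profile.deviation - model(profile.theta)
    n = len(res)
    if n == 0:
        raise ValueError("no residuals")
    if n < 40:
        warnings.warn(
            f"only {n} residuals; 95% band quantiles are unstable", stacklevel=2
        )
    if shortest:
        srt = np.sort(res)
        k = max(1, int(np.ceil(0.95 * n)))
        widths = srt[k - 1 :] - srt[: n - k + 1]
        i = int(np.argmin(widths))
        lo, hi = float(srt[i]), float(srt[i + k - 1])
    else:
        lo, hi = (float(q) for q in np.percentile(res, [2.5, 97.5]))
    return NoiseBand(width95=hi - lo, n_points=n, bounds=(lo, hi))


def perimeter_polygon(
    section: CrossSection | np.ndarray,
    circle: FittedCircle,
    n_bins: int = 72,
    quantile: float = 0.9,
    interpolate: bool = True,
    smooth_harmonics: int | None = None,
) -> PerimeterPolygon:
    """Outline the outer contour of a section as a closed polygon.

    Points are grouped into ``n_bins`` equal angular bins about the fitted
    centre; each occupied bin contributes a vertex at the bin-centre angle
    with radius equal to the ``quantile`` upper quantile of the bin's radii
    (the outer contour, robust to interior noise).  Empty bins are filled
    by periodic linear interpolation of radius over angle; with
    ``interpolate=False`` any empty bin is an error.  Vertices are ordered
    by angle and closed.

    With ``smooth_harmonics`` set, the bin radii are replaced by their
    truncated-Fourier reconstruction with that many harmonics before the
    polygon is built.  This emulates a human outlining a smooth closed
    contour: without it, per-bin quantile jitter makes the polygon
    zig-zag and systematically inflates its perimeter on noisy sections.
    """
    pts = section.points if isinstance(section, CrossSection) else np.asarray(section)
    pts = pts.reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("empty section")
    if n_bins < 3:
        raise ValueError("need at least 3 angular bins")
    dx = pts[:, 0] - circle.center[0]
    dy = pts[:, 1] - circle.center[1]
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0
    r = np.hypot(dx, dy)
    # anchor the bin phase to the outermost point so the estimate is
    # exactly covariant under rigid motions of the section
    anchor = theta[int(np.argmax(r))]
    theta = (theta - anchor) % 360.0
    width = 360.0 / n_bins
    idx = np.minimum((theta // width).astype(int), n_bins - 1)
    radii = np.full(n_bins, np.nan)
    for b in np.unique(idx):
        radii[b] = np.quantile(r[idx == b], quantile)
    occupied = np.isfinite(radii)
    n_occ = int(occupied.sum())
    if n_occ <= 1:
        raise ValueError("all points fall in a single angular bin")
    if not interpolate and n_occ < n_bins:
        raise ValueError(
            f"{n_bins - n_occ} empty angular bins and interpolation disabled"
        )
    if n_occ < n_bins:
        centers = (np.arange(n_bins) + 0.5) * width
        occ_c = centers[occupied]
        # periodic linear interpolation over angle
        radii = np.interp(
            centers,
            np.concatenate([occ_c - 360.0, occ_c, occ_c + 360.0]),
            np.tile(radii[occupied], 3),
        )
    if smooth_harmonics is not None and smooth_harmonics >= 0:
        K = min(smooth_harmonics, (n_bins - 1) // 2)
        prof = UnwrappedProfile((np.arange(n_bins) + 0.5) * width, radii)
        radii = fit_fourier(prof, K=K)(prof.theta)
    ang = np.radians((np.arange(n_bins) + 0.5) * width + anchor)
    verts = np.column_stack(
        (
            circle.center[0] + radii * np.cos(ang),
            circle.center[1] + radii * np.sin(ang),
        )
    )
    return PerimeterPolygon(verts)


def dbh_from_perimeter(poly: PerimeterPolygon) -> float:
    """Diameter (cm) of the circle with the polygon's perimeter."""
    if poly.perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return poly.perimeter / np.pi * 100.0


# ---------------------------------------------------------------------------
# convenience chains

def estimate_dbh(
    section: CrossSection,
    n_bins: int = 72,
    quantile: float = 0.9,
    smooth_harmonics: int | None = 8,
) -> float:
    """Section -> circle fit -> smooth perimeter polygon -> diameter in cm."""
    circle = fit_circle(section)
    poly = perimeter_polygon(
        section, circle, n_bins=n_bins, quantile=quantile,
        smooth_harmonics=smooth_harmonics,
    )
    return dbh_from_perimeter(poly)


def section_noise_band(
    section: CrossSection, K: int = 8, shortest: bool = False
) -> NoiseBand:
    """Section -> circle fit -> unwrap -> Fourier contour -> 95% band."""
    circle = fit_circle(section)
    profile = unwrap_to_polar(section, circle)
    model = fit_fourier(profile, K=K)
    return residual_band95(profile, model, shortest=shortest)
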