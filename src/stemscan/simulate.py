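"""Synthetic scenes and device-specific scan simulation.

The simulator produces registered point clouds of two kinds of scene — a
laboratory arrangement of upright cylindrical tubes on a flat floor, and a
plantation of regularly spaced trees — as seen by four classes of scanner:
a survey-grade tripod TLS, a handheld mobile scanner, a low-cost
rosette-pattern prototype, and a smartphone depth sensor.  Devices differ in
point rate, angular field of view, ranging noise, maximum range and their
ability to detect thin objects.

Geometry is deliberately simple: tubes are vertical cylinders, tree stems
are vertical conic frustums with linear taper, crowns are cones carrying the
apex.  Rays are cast from the scanner origin; the first surface hit within
range is returned, perturbed by Gaussian ranging noise along the ray.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "DeviceProfile",
    "TubeSpec",
    "TreeSpec",
    "ScanPose",
    "PointCloud",
    "Scene",
    "DEFAULT_PROFILES",
    "rosette_directions",
    "pattern_directions",
    "simulate_scan",
    "make_lab_scene",
    "make_plantation_scene",
    "plantation_from_extent",
    "merge_scans",
    "synthetic_section_points",
]

_EPS = 1e-9


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class DeviceProfile:
    """Static description of a scanning device.

    Parameters
    ----------
    points_per_second
        Pulse emission rate.
    fov_h, fov_v
        Horizontal / vertical angular field of view in degrees (full width).
    range_sigma
        1-sigma Gaussian ranging noise along the beam, in metres.
    max_range
        Returns beyond this distance are discarded, in metres.
    pattern
        Beam steering pattern: ``rosette`` (non-repetitive two-frequency
        Lissajous-like sweep), ``raster_lines`` (line scanning), or
        ``uniform`` (pseudo-random angular sampling).
    detection_floor_diameter
        Objects thinner than this (metres) produce no returns at all,
        modelling the failure of low-resolution sensors to register
        very thin targets.
    dropout_rate
        Per-pulse Bernoulli probability of losing a return.
    sigma_reference_range
        If set (metres), ranging noise grows linearly with range and
        ``range_sigma`` is the 1-sigma value at this reference range —
        the form in which prism-scanner datasheets quote precision
        (e.g. "2 cm, 1 sigma at 20 m").  If ``None``, noise is
        range-independent.
    fov_v_offset
        Centre elevation (degrees) of the vertical FOV window at every
        azimuth; panoramic survey scanners look further above the horizon
        than below (e.g. -40..+60 for a 100-degree window, offset +10).
    """

    name: str
    points_per_second: float
    fov_h: float
    fov_v: float
    range_sigma: float
    max_range: float
    pattern: str = "uniform"
    detection_floor_diameter: float = 0.0
    dropout_rate: float = 0.0
    sigma_reference_range: float | None = None
    fov_v_offset: float = 0.0

    def sigma_at(self, r: np.ndarray | float) -> np.ndarray | float:
        """Ranging noise sigma at range r (metres)."""
        if self.sigma_reference_range is None:
            return np.broadcast_to(self.range_sigma, np.shape(r)) if np.ndim(r) else self.range_sigma
        return self.range_sigma * np.asarray(r) / self.sigma_reference_range

    def __post_init__(self) -> None:
        if self.points_per_second <= 0:
            raise ValueError("points_per_second must be positive")
        if not (0 < self.fov_h <= 360 and 0 < self.fov_v <= 360):
            raise ValueError("fov_h/fov_v must lie in (0, 360]")
        if self.range_sigma < 0:
            raise ValueError("range_sigma must be non-negative")
        if self.max_range <= 0:
            raise ValueError("max_range must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.pattern not in ("rosette", "raster_lines", "uniform"):
            raise ValueError(f"unknown pattern {self.pattern!r}")


#: Default device profiles.  Rates and fields of view follow the
#: manufacturers' published figures; ranging sigmas are calibration choices
#: except for the rosette prototype's sensor, specified at 2 cm (1σ @ 20 m).
DEFAULT_PROFILES: dict[str, DeviceProfile] = {
    "riegl": DeviceProfile(
        name="riegl", points_per_second=122_000, fov_h=360.0, fov_v=100.0,
        range_sigma=0.005, max_range=1400.0, pattern="raster_lines",
        fov_v_offset=10.0,
    ),
    "stonex": DeviceProfile(
        name="stonex", points_per_second=976_000, fov_h=360.0, fov_v=270.0,
        range_sigma=0.012, max_range=120.0, pattern="uniform",
    ),
    "lca_tls": DeviceProfile(
        name="lca_tls", points_per_second=240_000, fov_h=70.4, fov_v=77.2,
        range_sigma=0.020, max_range=190.0, pattern="rosette",
        sigma_reference_range=20.0,
    ),
    "iphone": DeviceProfile(
        name="iphone", points_per_second=30_000, fov_h=60.0, fov_v=45.0,
        range_sigma=0.008, max_range=5.0, pattern="uniform",
        detection_floor_diameter=0.05,
    ),
}


@dataclass(frozen=True)
class TubeSpec:
    """An upright cylinder: diameter and length in cm, position in m."""

    id: str
    diameter: float
    length: float
    center_xy: tuple[float, float]
    base_z: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError("tube diameter and length must be positive")

    @property
    def radius_m(self) -> float:
        return self.diameter / 200.0

    @property
    def top_z(self) -> float:
        return self.base_z + self.length / 100.0


@dataclass(frozen=True)
class TreeSpec:
    """A simple tree: tapered conic stem plus a conic crown.

    ``dbh`` is the stem diameter (cm) at 1.3 m above ground; ``taper`` is
    the relative diameter shrink per metre of height, so the stem diameter
    at height z is ``dbh * (1 + taper * (1.3 - z))``.  The crown is a cone
    of base radius ``crown_radius`` at ``crown_base``, apex at ``height``.
    ``crown_porosity`` is the probability that a beam passes through the
    crown envelope unreturned — leaf-off crowns are mostly branches, so
    most pulses fly straight through.
    """

    id: str
    dbh: float
    height: float
    stem_xy: tuple[float, float]
    taper: float = 0.2 / 1.3
    crown_radius: float = 1.5
    crown_base: float = 0.0
    crown_porosity: float = 0.5

    def __post_init__(self) -> None:
        if self.dbh <= 0:
            raise ValueError("dbh must be positive")
        if not (self.height > self.crown_base >= 0):
            raise ValueError("need height > crown_base >= 0")
        if not 0 <= self.crown_porosity < 1:
            raise ValueError("crown_porosity must lie in [0, 1)")

    def stem_radius_at(self, z: float) -> float:
        return max(0.0, (self.dbh / 200.0) * (1 + self.taper * (1.3 - z)))


@dataclass(frozen=True)
class ScanPose:
    """Scanner placement for one scan, plus optional registration jitter.

    ``registration_jitter`` is (translation sigma m, rotation sigma deg):
    a random rigid perturbation applied to the whole scan, emulating
    imperfect multi-scan registration.
    """

    position: tuple[float, float, float]
    yaw: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0
    duration: float = 1.0
    registration_jitter: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.registration_jitter[0] < 0 or self.registration_jitter[1] < 0:
            raise ValueError("jitter sigmas must be non-negative")

    def rotation(self) -> Rotation:
        return Rotation.from_euler(
            "zyx", [self.yaw, self.pitch, self.roll], degrees=True
        )


@dataclass
class PointCloud:
    """Registered 3D points (m, Z up) with a device tag.

    ``scan_id`` optionally records which scan each point came from.
    """

    points: np.ndarray
    device: str = ""
    scan_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        if self.scan_id is not None:
            self.scan_id = np.asarray(self.scan_id)
            if len(self.scan_id) != len(self.points):
                raise ValueError("scan_id length mismatch")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        if len(self.points) == 0:
            z = np.zeros(3)
            return z, z
        return self.points.min(axis=0), self.points.max(axis=0)


@dataclass
class Scene:
    """Objects standing on a flat ground plane z = 0."""

    objects: list = field(default_factory=list)
    floor_size: float | None = None
    ground_z: float = 0.0


# ---------------------------------------------------------------------------
# beam patterns

#: Base angular frequency of the rosette sweep (rad/s) and the irrational
#: ratio of the second frequency; the incommensurate pair guarantees the
#: pattern never retraces, so angular coverage grows with dwell time.
_ROSETTE_OMEGA1 = 2 * math.pi * 997.0
_ROSETTE_RATIO = math.sqrt(2.0)


def rosette_directions(
    profile: DeviceProfile, duration: float, seed: int
) -> np.ndarray:
    """Unit direction vectors of a non-repetitive rosette sweep.

    The deflection angle on each axis is a sum of two cosines with an
    irrational frequency ratio, scaled to fill the field of view.  This is
    a qualitative stand-in for prism-based non-repetitive scanners: its
    defining property — spatial coverage strictly grows with dwell time —
    is what downstream code relies on.

    Returns an (n, 3) array, x forward, for n = floor(rate * duration).
    """
    if profile.pattern != "rosette":
        raise ValueError("rosette_directions requires a rosette-pattern profile")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    n = int(math.floor(profile.points_per_second * duration))
    if n == 0:
        return np.empty((0, 3))
    t = np.arange(n) / profile.points_per_second
    rng = np.random.default_rng(seed)
    ph = rng.uniform(0, 2 * math.pi, size=4)
    w1, w2 = _ROSETTE_OMEGA1, _ROSETTE_OMEGA1 * _ROSETTE_RATIO
    az = (profile.fov_h / 4.0) * (np.cos(w1 * t + ph[0]) + np.cos(w2 * t + ph[1]))
    el = profile.fov_v_offset + (profile.fov_v / 4.0) * (
        np.cos(w1 * t + ph[2]) + np.cos(w2 * t + ph[3])
    )
    return _angles_to_dirs(az, el)


def _angles_to_dirs(az_deg: np.ndarray, el_deg: np.ndarray) -> np.ndarray:
    az = np.radians(az_deg)
    el = np.radians(el_deg)
    ce = np.cos(el)
    return np.column_stack((ce * np.cos(az), ce * np.sin(az), np.sin(el)))


_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def _raster_directions(profile: DeviceProfile, duration: float) -> np.ndarray:
    # line scanning: azimuth sweeps line by line; line elevations follow a
    # golden-ratio interleave, so lines fill the vertical FOV
    # quasi-uniformly as dwell time grows instead of retracing frames.
    # Points per line are chosen so the azimuth and elevation resolutions
    # match, as survey scanners are configured.
    n = int(math.floor(profile.points_per_second * duration))
    if n == 0:
        return np.empty((0, 3))
    ppl = max(16, int(round(math.sqrt(n * profile.fov_h / profile.fov_v))))
    idx = np.arange(n)
    line = idx // ppl
    # each line's azimuth comb is phase-shifted (plastic-number sequence)
    # so successive lines interleave rather than resample the same azimuths
    phase = np.mod((line + 1) * 0.7548776662466927, 1.0)
    az = -profile.fov_h / 2 + profile.fov_h * ((idx % ppl) + phase) / ppl
    el = (profile.fov_v_offset - profile.fov_v / 2
          + profile.fov_v * np.mod((line + 1) * _GOLDEN, 1.0))
    return _angles_to_dirs(az, el)


def _uniform_directions(
    profile: DeviceProfile, duration: float, seed: int
) -> np.ndarray:
    n = int(math.floor(profile.points_per_second * duration))
    rng = np.random.default_rng(seed)
    az = rng.uniform(-profile.fov_h / 2, profile.fov_h / 2, size=n)
    el = profile.fov_v_offset + rng.uniform(
        -profile.fov_v / 2, profile.fov_v / 2, size=n
    )
    return _angles_to_dirs(az, el)


def pattern_directions(
    profile: DeviceProfile, duration: float, seed: int
) -> np.ndarray:
    """Dispatch to the profile's beam pattern; device frame, x forward."""
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if profile.pattern == "rosette":
        return rosette_directions(profile, duration, seed)
    if profile.pattern == "raster_lines":
        return _raster_directions(profile, duration)
    return _uniform_directions(profile, duration, seed)


# ---------------------------------------------------------------------------
# ray casting

def _frustum_surfaces(obj) -> list[tuple]:
    """Decompose an object into vertical conic frustums, each a tuple
    ((cx, cy, r0, s, zlo, zhi), porosity) with radius(z) = r0 + s*z."""
    if isinstance(obj, TubeSpec):
        cx, cy = obj.center_xy
        return [((cx, cy, obj.radius_m, 0.0, obj.base_z, obj.top_z), 0.0)]
    if isinstance(obj, TreeSpec):
        cx, cy = obj.stem_xy
        r_half = obj.dbh / 200.0
        s = -r_half * obj.taper
        r0 = r_half * (1 + 1.3 * obj.taper)
        stem_top = obj.height if s >= 0 else min(obj.height, -r0 / s)
        out = [((cx, cy, r0, s, 0.0, stem_top), 0.0)]
        if obj.crown_base > 0 and obj.crown_radius > 0:
            sc = -obj.crown_radius / (obj.height - obj.crown_base)
            r0c = obj.crown_radius * obj.height / (obj.height - obj.crown_base)
            out.append(((cx, cy, r0c, sc, obj.crown_base, obj.height), obj.crown_porosity))
        return out
    raise TypeError(f"unsupported scene object {type(obj).__name__}")


def _ray_frustum_t(o, d, cx, cy, r0, s, zlo, zhi) -> np.ndarray:
    """Smallest positive ray parameter hitting the frustum, inf if none."""
    ox, oy, oz = o
    dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
    px, py = ox - cx, oy - cy
    R0 = r0 + s * oz  # frustum radius at the origin's height, along the ray
    A = dx * dx + dy * dy - (s * dz) ** 2
    B = 2 * (px * dx + py * dy - s * dz * R0)
    C = px * px + py * py - R0 * R0

    t_best = np.full(len(d), np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = B * B - 4 * A * C
        quad = (np.abs(A) > 1e-15) & (disc >= 0)
        sq = np.sqrt(np.where(quad, disc, 0.0))
        for sign in (-1.0, 1.0):
            t = np.where(quad, (-B + sign * sq) / (2 * A), np.inf)
            t_best = np.minimum(t_best, _valid_t(t, oz, dz, r0, s, zlo, zhi))
        lin = (np.abs(A) <= 1e-15) & (np.abs(B) > 1e-15)
        t = np.where(lin, -C / B, np.inf)
        t_best = np.minimum(t_best, _valid_t(t, oz, dz, r0, s, zlo, zhi))
    return t_best


def _valid_t(t, oz, dz, r0, s, zlo, zhi) -> np.ndarray:
    z = oz + t * dz
    ok = (t > _EPS) & (z >= zlo) & (z <= zhi) & (r0 + s * z >= 0)
    return np.where(ok, t, np.inf)


def simulate_scan(
    scene: Scene,
    pose: ScanPose,
    profile: DeviceProfile,
    seed: int,
) -> PointCloud:
    """Ray-cast one scan of a scene and return the resulting point cloud.

    Every emitted beam direction is intersected with the ground plane and
    all object surfaces; the first hit within ``max_range`` is kept, its
    range perturbed by Gaussian noise of sigma ``range_sigma`` along the
    beam.  Objects thinner than the profile's detection floor yield no
    returns.  Dropout removes returns at the profile's Bernoulli rate, and
    the pose's registration jitter applies a random rigid perturbation to
    the finished scan.  Deterministic given (scene, pose, profile, seed).
    """
    if not scene.objects:
        raise ValueError("scene must contain at least one object")
    ss = np.random.SeedSequence(seed)
    seed_dirs, seed_noise, seed_porosity = ss.spawn(3)
    dirs = pattern_directions(
        profile, pose.duration, int(seed_dirs.generate_state(1)[0] % 2**31)
    )
    if len(dirs) == 0:
        return PointCloud(np.empty((0, 3)), device=profile.name)
    dirs = pose.rotation().apply(dirs)
    o = np.asarray(pose.position, dtype=float)

    t_best = np.full(len(dirs), np.inf)
    # ground plane
    dz = dirs[:, 2]
    below = dz < -1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ground = np.where(below, (scene.ground_z - o[2]) / dz, np.inf)
    t_best = np.minimum(t_best, np.where(t_ground > _EPS, t_ground, np.inf))

    rng_por = np.random.default_rng(seed_porosity)
    for obj in scene.objects:
        diam_m = (
            obj.diameter / 100.0 if isinstance(obj, TubeSpec) else obj.dbh / 100.0
        )
        if diam_m < profile.detection_floor_diameter:
            continue
        for surf, porosity in _frustum_surfaces(obj):
            t_surf = _ray_frustum_t(o, dirs, *surf)
            if porosity > 0:
                # beams pass through a porous (leaf-off) crown unreturned
                t_surf = np.where(
                    rng_por.random(len(dirs)) < porosity, np.inf, t_surf
                )
            t_best = np.minimum(t_best, t_surf)

    rng = np.random.default_rng(seed_noise)
    hit = np.isfinite(t_best)
    t = t_best[hit]
    if profile.range_sigma > 0:
        t = t + rng.standard_normal(len(t)) * profile.sigma_at(t)
    keep = t <= profile.max_range
    pts = o + t[keep, None] * dirs[hit][keep]
    if profile.dropout_rate > 0:
        pts = pts[rng.random(len(pts)) >= profile.dropout_rate]

    sig_t, sig_r = pose.registration_jitter
    if sig_t > 0 or sig_r > 0:
        shift = rng.normal(0.0, sig_t, size=3) if sig_t > 0 else np.zeros(3)
        if sig_r > 0:
            rot = Rotation.from_euler(
                "zyx", rng.normal(0.0, sig_r, size=3), degrees=True
            )
            pts = rot.apply(pts - o) + o
        pts = pts + shift
    return PointCloud(pts, device=profile.name)


# ---------------------------------------------------------------------------
# scenes

def make_lab_scene(tubes: list[TubeSpec] | None = None) -> Scene:
    """Lab scene: upright tubes on a flat floor within a 7 x 7 m area.

    With no argument, the twelve reference tubes of the laboratory
    benchmark are laid out on a regular grid (diameters 2.6-50.5 cm,
    lengths 100-290 cm).  Tubes with overlapping footprints are rejected.
    """
    if tubes is None:
        from .io import lab_reference_tubes

        tubes = lab_reference_tubes()
    if not tubes:
        raise ValueError("lab scene needs at least one tube")
    for i, a in enumerate(tubes):
        for b in tubes[i + 1 :]:
            dx = a.center_xy[0] - b.center_xy[0]
            dy = a.center_xy[1] - b.center_xy[1]
            if math.hypot(dx, dy) <= a.radius_m + b.radius_m:
                raise ValueError(
                    f"tubes {a.id} and {b.id} have overlapping footprints"
                )
    return Scene(objects=list(tubes), floor_size=7.0)


def make_plantation_scene(
    n_rows: int,
    n_cols: int,
    spacing: float = 4.0,
    dbh_mean: float = 25.6,
    dbh_sd: float = 5.0,
    th_mean: float = 15.7,
    th_sd: float = 0.5,
    seed: int = 0,
    taper: float = 0.2 / 1.3,
    crown_radius: float = 1.5,
    crown_base_frac: float = 0.6,
    allometry_slope: float = 7.5,
    position_jitter: float = 0.1,
) -> Scene:
    """Regular plantation grid with lognormal DBH and allometric height.

    Stems sit on a ``n_rows x n_cols`` grid at ``spacing`` metres, each
    displaced by isotropic Gaussian planting scatter of sigma
    ``position_jitter`` (real rows are straight only to within a couple
    of decimetres).  DBH is lognormal with the requested mean and SD
    (cm); tree height follows the standard allometric form
    ``TH = a + b * ln(DBH) + eps`` with slope ``b`` and intercept chosen
    so the expected height equals ``th_mean``.
    """
    if n_rows < 1 or n_cols < 1 or n_rows * n_cols < 1:
        raise ValueError("grid dimensions must be positive")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(seed)
    n = n_rows * n_cols
    if dbh_sd > 0:
        s2 = math.log(1 + (dbh_sd / dbh_mean) ** 2)
        mu = math.log(dbh_mean) - s2 / 2
        dbh = rng.lognormal(mu, math.sqrt(s2), size=n)
    else:
        mu = math.log(dbh_mean)
        dbh = np.full(n, dbh_mean)
    a = th_mean - allometry_slope * mu
    th = a + allometry_slope * np.log(dbh)
    if th_sd > 0:
        th = th + rng.normal(0.0, th_sd, size=n)
    th = np.maximum(th, 2.0)
    scatter = (
        rng.normal(0.0, position_jitter, size=(n, 2))
        if position_jitter > 0
        else np.zeros((n, 2))
    )

    trees = []
    k = 0
    for i in range(n_rows):
        for j in range(n_cols):
            trees.append(
                TreeSpec(
                    id=f"T{k + 1:03d}",
                    dbh=float(dbh[k]),
                    height=float(th[k]),
                    stem_xy=(
                        j * spacing + float(scatter[k, 0]),
                        i * spacing + float(scatter[k, 1]),
                    ),
                    taper=taper,
                    crown_radius=crown_radius,
                    crown_base=float(crown_base_frac * th[k]),
                )
            )
            k += 1
    return Scene(objects=trees)


def plantation_from_extent(
    width: float, depth: float, spacing: float = 4.0, **kwargs
) -> Scene:
    """Plantation covering a width x depth plot: floor(w/s)+1 stems per axis."""
    n_cols = int(math.floor(width / spacing)) + 1
    n_rows = int(math.floor(depth / spacing)) + 1
    return make_plantation_scene(n_rows, n_cols, spacing, **kwargs)


def merge_scans(clouds: list[PointCloud]) -> PointCloud:
    """Concatenate co-registered scans of one device, tagging scan ids."""
    if not clouds:
        raise ValueError("no clouds to merge")
    devices = {c.device for c in clouds}
    if len(devices) > 1:
        raise ValueError(f"cannot merge clouds from different devices: {devices}")
    pts = np.vstack([c.points for c in clouds])
    ids = np.concatenate(
        [
            c.scan_id if c.scan_id is not None else np.full(len(c), i)
            for i, c in enumerate(clouds)
        ]
    )
    return PointCloud(pts, device=clouds[0].device, scan_id=ids)


# ---------------------------------------------------------------------------
# direct cross-section sampler (bypasses ray casting)

def synthetic_section_points(
    radius: float,
    n: int,
    sigma_radial: float = 0.0,
    center: tuple[float, float] = (0.0, 0.0),
    arc: tuple[float, float] = (0.0, 360.0),
    seed: int = 0,
) -> np.ndarray:
    """Sample a stem cross-section directly: circle plus radial Gaussian noise.

    Useful for studying the contour quality statistic in isolation, where
    the noise is radial by construction rather than along a beam.
    Returns (n, 2) XY points in metres.
    """
    rng = np.random.default_rng(seed)
    theta = np.radians(rng.uniform(arc[0], arc[1], size=n))
    r = radius + (rng.normal(0.0, sigma_radial, size=n) if sigma_radial > 0 else 0.0)
    return np.column_stack(
        (center[0] + r * np.cos(theta), center[1] + r * np.sin(theta))
    )
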