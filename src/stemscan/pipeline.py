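"""End-to-end chains: scan protocols, measurement, device benchmarking.

Each device class scans a scene according to its field protocol: tripod
scanners from a few fixed positions around (and inside) the plot, the
narrow-FOV rosette prototype from more positions with aimed orientations,
the handheld scanner along a walked perimeter-and-through path, and the
phone along the planting rows, close to each stem because of its short
range.  The handheld trajectories carry a small per-scan rigid
registration jitter, reflecting that their clouds are assembled by SLAM
rather than tripod-and-target registration; the phone's jitter is larger
(drift of vision-based tracking), which is what limits it in practice far
more than its low ranging noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import canopy, evaluate, stem
from .io import ReferenceTable, read_reference_table
from .simulate import (
    DEFAULT_PROFILES,
    DeviceProfile,
    PointCloud,
    ScanPose,
    Scene,
    TubeSpec,
    make_plantation_scene,
    merge_scans,
    simulate_scan,
)

__all__ = [
    "standard_poses",
    "scan_scene",
    "measure_lab_diameters",
    "measure_lab_lengths",
    "measure_plantation_dbh",
    "measure_plantation_th",
    "estimates_to_reference_table",
    "benchmark_plantation_dbh",
]

#: Registration jitter (translation sigma m, rotation sigma deg) by protocol:
#: tripod multi-scan registration is treated as exact; handheld SLAM drifts
#: at the millimetre level, phone visual-inertial tracking at the centimetre
#: level.
_JITTER = {"riegl": (0.0, 0.0), "lca_tls": (0.0, 0.0),
           "stonex": (0.005, 0.05), "iphone": (0.015, 0.2)}

#: Relative pulse budgets: point rate x published per-plot collection time
#: (21 min tripod TLS, ~4.5 min handheld walk, 13 min rosette prototype,
#: 8 min phone), normalised to the tripod TLS.
_BUDGET_SCALE = {"riegl": 1.0, "stonex": 1.71, "lca_tls": 1.22, "iphone": 0.094}


def _scene_extent(scene: Scene) -> tuple[float, float, float, float]:
    xs = [o.center_xy[0] if isinstance(o, TubeSpec) else o.stem_xy[0] for o in scene.objects]
    ys = [o.center_xy[1] if isinstance(o, TubeSpec) else o.stem_xy[1] for o in scene.objects]
    return min(xs), max(xs), min(ys), max(ys)


def _aim(position, target) -> tuple[float, float]:
    """Yaw and pitch (deg) pointing the beam axis from position at target."""
    dx = target[0] - position[0]
    dy = target[1] - position[1]
    dz = target[2] - position[2]
    yaw = math.degrees(math.atan2(dy, dx))
    pitch = -math.degrees(math.atan2(dz, math.hypot(dx, dy)))
    return yaw, pitch


def standard_poses(
    profile: DeviceProfile,
    scene: Scene,
    total_points: int = 1_200_000,
) -> list[ScanPose]:
    """Scan poses following each device's field protocol for the scene.

    ``total_points`` is the approximate pulse budget for the whole scan
    set; it is split evenly over the poses to fix per-pose dwell time.
    """
    x0, x1, y0, y1 = _scene_extent(scene)
    cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
    is_lab = any(isinstance(o, TubeSpec) for o in scene.objects)
    jit = _JITTER.get(profile.name, (0.0, 0.0))
    poses: list[ScanPose] = []

    if profile.name == "iphone":
        if is_lab:
            # walk around every tube at close range
            for tube in scene.objects:
                tx, ty = tube.center_xy
                d = tube.radius_m + 1.0
                for ang in (0, 90, 180, 270):
                    px = tx + d * math.cos(math.radians(ang))
                    py = ty + d * math.sin(math.radians(ang))
                    yaw, pitch = _aim((px, py, 1.0), (tx, ty, 1.0))
                    poses.append(ScanPose((px, py, 1.0), yaw, pitch,
                                          registration_jitter=jit, duration=1.0))
        else:
            # walk the aisles flanking every row, facing the nearer row;
            # rows are recovered by gap-clustering stem y (planting
            # scatter keeps stems within decimetres of the row line)
            ys = np.sort([o.stem_xy[1] for o in scene.objects])
            splits = np.where(np.diff(ys) > 1.0)[0]
            rows = [float(g.mean()) for g in np.split(ys, splits + 1)]
            spacing = float(np.median(np.diff(rows))) if len(rows) > 1 else 4.0
            aisles = [rows[0] - spacing / 2] + [r + spacing / 2 for r in rows]
            xs = np.arange(x0 - 1.0, x1 + 1.0 + 1e-9, spacing / 2)
            for ai, ay in enumerate(aisles):
                face = 90.0 if ai == 0 else -90.0  # face the row walked past
                for k, px in enumerate(xs):
                    yaw = face if ai in (0, len(aisles) - 1) else (90.0 if k % 2 else -90.0)
                    poses.append(ScanPose((float(px), float(ay), 1.4), yaw, 0.0,
                                          registration_jitter=jit, duration=1.0))
    elif profile.name == "lca_tls":
        # narrow FOV: ring of positions, each aimed at the scene, two
        # orientations per position (stem band and upper canopy)
        margin = 2.0 if is_lab else 3.0
        n_pos = 4 if is_lab else 8
        ring = np.linspace(0, 360, n_pos, endpoint=False) + (45 if n_pos == 4 else 22.5)
        rad = math.hypot(x1 - x0, y1 - y0) / 2 + margin
        top = 2.0 if is_lab else 10.0
        for ang in ring:
            px = cx + rad * math.cos(math.radians(ang))
            py = cy + rad * math.sin(math.radians(ang))
            for tz in (1.3, top):
                yaw, pitch = _aim((px, py, 1.5), (cx, cy, tz))
                poses.append(ScanPose((px, py, 1.5), yaw, pitch,
                                      registration_jitter=jit, duration=1.0))
    elif profile.name == "stonex":
        # walked loop around the plot plus a pass through the middle;
        # waypoints sit off the row/column lines to avoid sighting straight
        # down a planting row
        margin = 1.5
        loop = [
            (x0 - margin, y0 - margin + 0.4), (cx + 1.3, y0 - margin),
            (x1 + margin, y0 - margin - 0.4), (x1 + margin + 0.4, cy + 0.9),
            (x1 + margin, y1 + margin - 0.4), (cx - 1.1, y1 + margin),
            (x0 - margin, y1 + margin + 0.4), (x0 - margin - 0.4, cy - 1.3),
        ]
        through = (
            []
            if is_lab
            else [(x0 + (x1 - x0) * f + 0.5, cy + 1.3) for f in (0.2, 0.5, 0.8)]
        )
        for px, py in loop + through:
            poses.append(ScanPose((px, py, 1.8), 0.0, 0.0,
                                  registration_jitter=jit, duration=1.0))
    else:
        # wide-FOV tripod TLS: corners for the lab, a de-aligned 3x3 grid
        # for plots (scanners stand between rows, never on a row line)
        if is_lab:
            margin = 1.5
            positions = [(x0 - margin, y0 - margin), (x1 + margin, y0 - margin),
                         (x1 + margin, y1 + margin), (x0 - margin, y1 + margin)]
        else:
            positions = [
                (x, y)
                for x in (x0 - 2.1, cx + 1.9, x1 + 2.3)
                for y in (y0 - 1.7, cy + 1.3, y1 + 1.9)
            ]
        for px, py in positions:
            poses.append(ScanPose((px, py, 1.5), 0.0, 0.0,
                                  registration_jitter=jit, duration=1.0))

    per_pose = max(1, int(total_points / len(poses)))
    duration = per_pose / profile.points_per_second
    return [
        ScanPose(p.position, p.yaw, p.pitch, p.roll, duration, p.registration_jitter)
        for p in poses
    ]


def scan_scene(
    scene: Scene,
    profile: DeviceProfile,
    poses: list[ScanPose] | None = None,
    seed: int = 0,
    total_points: int = 1_200_000,
) -> PointCloud:
    """Scan a scene from every pose and merge into one registered cloud."""
    if poses is None:
        poses = standard_poses(profile, scene, total_points=total_points)
    seeds = np.random.SeedSequence(seed).spawn(len(poses))
    clouds = [
        simulate_scan(scene, pose, profile, int(s.generate_state(1)[0] % 2**31))
        for pose, s in zip(poses, seeds)
    ]
    return merge_scans(clouds)


# ---------------------------------------------------------------------------
# measurement chains

def _match_section(sections, xy, tol):
    best, best_d = None, tol
    for s in sections:
        if len(s.points) == 0:
            continue
        d = float(np.hypot(*(s.centroid - xy)))
        if d < best_d:
            best, best_d = s, d
    return best


def measure_lab_diameters(
    cloud: PointCloud,
    scene: Scene,
    slice_height: float = 0.8,
    thickness: float = stem.DEFAULT_THICKNESS,
    n_bins: int = 72,
) -> pd.DataFrame:
    """Per-tube diameter estimates (cm) from a lab scan.

    The measurement slice sits at 0.8 m by default so that even the
    shortest (1 m) tubes intersect it; reference diameters were taped at
    a comparable height and the tubes are prisms, so the slice height
    does not bias the comparison.
    """
    sections = stem.extract_dbh_slice(
        cloud, ground=scene.ground_z, center_height=slice_height, thickness=thickness
    )
    rows = []
    for tube in scene.objects:
        sec = _match_section(sections, np.asarray(tube.center_xy), tube.radius_m + 0.3)
        est = np.nan
        if sec is not None and sec.detected:
            try:
                est = stem.estimate_dbh(sec, n_bins=n_bins)
            except ValueError:
                pass
        rows.append({"id": tube.id, "detected": np.isfinite(est), "est": est})
    return pd.DataFrame(rows)


def measure_lab_lengths(
    cloud: PointCloud, scene: Scene, segment_width: float = 0.03
) -> pd.DataFrame:
    """Per-tube length estimates (cm) from vertical surface strips."""
    rows = []
    for tube in scene.objects:
        est = canopy.tube_length_from_segments(cloud, tube, segment_width)
        rows.append(
            {"id": tube.id, "detected": est is not None,
             "est": est if est is not None else np.nan}
        )
    return pd.DataFrame(rows)


def measure_plantation_dbh(
    cloud: PointCloud,
    scene: Scene,
    n_bins: int = 72,
    min_section_points: int = 20,
) -> pd.DataFrame:
    """Per-tree DBH estimates (cm) from the breast-height slice."""
    sections = stem.extract_dbh_slice(cloud, ground=scene.ground_z)
    rows = []
    for tree in scene.objects:
        sec = _match_section(
            sections, np.asarray(tree.stem_xy), tree.dbh / 200.0 + 0.3
        )
        est = np.nan
        if sec is not None and len(sec.points) >= min_section_points:
            try:
                est = stem.estimate_dbh(sec, n_bins=n_bins)
            except ValueError:
                pass
        rows.append({"id": tree.id, "detected": np.isfinite(est), "est": est})
    return pd.DataFrame(rows)


def measure_plantation_th(
    cloud: PointCloud, scene: Scene, cell_size: float = 0.5
) -> pd.DataFrame:
    """Per-tree height estimates (m) from the nDSM cell at each stem."""
    models = canopy.TerrainModels.from_cloud(cloud, cell_size=cell_size)
    xy = np.array([t.stem_xy for t in scene.objects])
    th = canopy.sample_height_at(models.ndsm, xy, [t.id for t in scene.objects])
    return pd.DataFrame(
        {"id": [t.id for t in scene.objects], "detected": np.isfinite(th), "est": th}
    )


def estimates_to_reference_table(
    reference: dict[str, float], per_device: dict[str, pd.DataFrame]
) -> ReferenceTable:
    """Assemble measurement DataFrames into a validated reference table."""
    ids = list(reference)
    data = {"id": ids, "reference": [reference[i] for i in ids]}
    for dev, df in per_device.items():
        d = df.set_index("id")
        det = [bool(d.loc[i, "detected"]) for i in ids]
        data[f"{dev}_detected"] = det
        data[f"{dev}_est"] = [
            d.loc[i, "est"] if det_i else np.nan for i, det_i in zip(ids, det)
        ]
    return read_reference_table(pd.DataFrame(data))


@dataclass
class PlantationBenchmark:
    """Per-device DBH accuracy on replicated simulated plots."""

    per_replicate: pd.DataFrame  # columns: replicate, device, rmse, bias, n
    mean_rmse: dict[str, float]


def benchmark_plantation_dbh(
    devices: list[str] | None = None,
    n_rows: int = 3,
    n_cols: int = 3,
    n_replicates: int = 20,
    seed: int = 0,
    total_points: int = 800_000,
    **scene_kwargs,
) -> PlantationBenchmark:
    """Replicate simulated plots and summarise DBH RMSE per device."""
    devices = devices or list(DEFAULT_PROFILES)
    records = []
    root = np.random.SeedSequence(seed)
    for rep, rep_seed in enumerate(root.spawn(n_replicates)):
        s_scene, s_scan = (int(s.generate_state(1)[0] % 2**31) for s in rep_seed.spawn(2))
        scene = make_plantation_scene(n_rows, n_cols, seed=s_scene, **scene_kwargs)
        ref = {t.id: t.dbh for t in scene.objects}
        for dev in devices:
            profile = DEFAULT_PROFILES[dev]
            budget = int(total_points * _BUDGET_SCALE.get(dev, 1.0))
            cloud = scan_scene(scene, profile, seed=s_scan, total_points=budget)
            est = measure_plantation_dbh(cloud, scene)
            table = estimates_to_reference_table(ref, {dev: est})
            det = est[est["detected"]]
            if len(det) == 0:
                continue
            err = det["est"].to_numpy() - np.array([ref[i] for i in det["id"]])
            records.append(
                {
                    "replicate": rep,
                    "device": dev,
                    "rmse": evaluate.rmse(err),
                    "bias": evaluate.bias(err),
                    "n": len(det),
                    "tdr": evaluate.detection_rate(table, dev),
                }
            )
    df = pd.DataFrame(records)
    mean_rmse = df.groupby("device")["rmse"].mean().to_dict()
    return PlantationBenchmark(per_replicate=df, mean_rmse=mean_rmse)
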