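"""Point-cloud and reference-table input/output.

Supported formats:

* LAS 1.2, point format 0 (uncompressed), written with a 1 mm coordinate
  scale — round-trips preserve coordinates to the 0.5 mm quantum.
* Whitespace-delimited XYZ text (CloudCompare style, ``#`` comments).
* CSV reference tables pairing per-object reference measurements with
  per-device detection flags and estimates; the two laboratory benchmark
  tables (tube diameters and tube lengths) ship with the package.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import PointCloud, TubeSpec

__all__ = [
    "read_las",
    "write_las",
    "read_xyz",
    "write_xyz",
    "ReferenceTable",
    "read_reference_table",
    "lab_reference_diameters",
    "lab_reference_heights",
    "lab_reference_tubes",
    "load_profile",
    "load_scene",
]

_LAS_HEADER_SIZE = 227
_LAS_POINT_SIZE = 20
_LAS_SCALE = 0.001

_POINT_DTYPE = np.dtype(
    [
        ("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"),
        ("intensity", "<u2"), ("flags", "u1"), ("classification", "u1"),
        ("scan_angle", "i1"), ("user_data", "u1"), ("point_source", "<u2"),
    ]
)


def write_las(cloud: PointCloud, path: str | Path) -> None:
    """Write a cloud as LAS 1.2, point format 0, 1 mm scale."""
    path = Path(path)
    pts = cloud.points
    if len(pts):
        lo, hi = cloud.bounds
        offset = np.floor(lo)
    else:
        lo = hi = offset = np.zeros(3)
    header = bytearray(_LAS_HEADER_SIZE)
    struct.pack_into("<4sHH", header, 0, b"LASF", 0, 0)
    # 16-byte project GUID left zero
    struct.pack_into("<BB", header, 24, 1, 2)
    struct.pack_into("<32s", header, 26, b"stemscan")
    struct.pack_into("<32s", header, 58, b"stemscan")
    struct.pack_into("<HH", header, 90, 1, 2000)  # file day/year, nominal
    struct.pack_into("<HII", header, 94, _LAS_HEADER_SIZE, _LAS_HEADER_SIZE, 0)
    struct.pack_into("<BHI", header, 104, 0, _LAS_POINT_SIZE, len(pts))
    struct.pack_into("<5I", header, 111, len(pts), 0, 0, 0, 0)
    struct.pack_into(
        "<3d3d", header, 131, _LAS_SCALE, _LAS_SCALE, _LAS_SCALE, *offset
    )
    struct.pack_into(
        "<6d", header, 179, hi[0], lo[0], hi[1], lo[1], hi[2], lo[2]
    )
    rec = np.zeros(len(pts), dtype=_POINT_DTYPE)
    if len(pts):
        scaled = np.round((pts - offset) / _LAS_SCALE).astype("<i4")
        rec["X"], rec["Y"], rec["Z"] = scaled[:, 0], scaled[:, 1], scaled[:, 2]
        if cloud.scan_id is not None:
            rec["point_source"] = np.asarray(cloud.scan_id, dtype=np.int64) % 65536
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(rec.tobytes())


def read_las(path: str | Path, device: str = "") -> PointCloud:
    """Read a LAS 1.2 point-format-0 file back into a cloud."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _LAS_HEADER_SIZE:
        raise ValueError(f"{path}: truncated LAS header at offset {len(raw)}")
    if raw[:4] != b"LASF":
        raise ValueError(f"{path}: bad LAS signature at offset 0")
    (data_offset,) = struct.unpack_from("<I", raw, 96)
    fmt, rec_len, n = struct.unpack_from("<BHI", raw, 104)
    if fmt != 0 or rec_len != _LAS_POINT_SIZE:
        raise ValueError(
            f"{path}: unsupported point format {fmt} (record length {rec_len}) "
            f"at offset 104"
        )
    scales = struct.unpack_from("<3d", raw, 131)
    offsets = struct.unpack_from("<3d", raw, 155)
    end = data_offset + n * rec_len
    if len(raw) < end:
        raise ValueError(
            f"{path}: truncated point data, expected {end} bytes got {len(raw)} "
            f"(error at offset {len(raw)})"
        )
    rec = np.frombuffer(raw, dtype=_POINT_DTYPE, count=n, offset=data_offset)
    pts = np.column_stack(
        [rec[ax] * sc + off for ax, sc, off in zip("XYZ", scales, offsets)]
    )
    sid = rec["point_source"].astype(int) if n else None
    return PointCloud(pts, device=device, scan_id=sid)


def write_xyz(cloud: PointCloud, path: str | Path, header: bool = False) -> None:
    """Write whitespace-delimited ``x y z`` text at micro-metre precision."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write("# x y z\n")
        np.savetxt(fh, cloud.points, fmt="%.6f")


def read_xyz(path: str | Path, device: str = "", header: bool = False) -> PointCloud:
    """Read whitespace-delimited XYZ text; ``#`` lines are comments."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if header:
                header = False
                continue
            tokens = stripped.split()
            if len(tokens) < 3:
                raise ValueError(
                    f"{path}: expected 3 columns at line {lineno}, got {len(tokens)}"
                )
            try:
                rows.append([float(t) for t in tokens[:3]])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric token at line {lineno}: {exc}"
                ) from None
    return PointCloud(np.array(rows).reshape(-1, 3), device=device)


# ---------------------------------------------------------------------------
# reference tables

@dataclass
class ReferenceTable:
    """Per-object reference measurements and per-device estimates.

    Backed by a DataFrame with columns ``id``, ``reference`` and, for each
    device, ``<device>_detected`` (bool) and ``<device>_est`` (NaN where
    undetected).  Undetected objects carry no estimate by construction.
    """

    df: pd.DataFrame

    @property
    def devices(self) -> list[str]:
        return [c[: -len("_detected")] for c in self.df.columns if c.endswith("_detected")]

    @property
    def ids(self) -> list[str]:
        return list(self.df["id"])

    @property
    def reference(self) -> np.ndarray:
        return self.df["reference"].to_numpy(dtype=float)

    def detected(self, device: str) -> np.ndarray:
        self._check(device)
        return self.df[f"{device}_detected"].to_numpy(dtype=bool)

    def estimates(self, device: str) -> np.ndarray:
        self._check(device)
        return self.df[f"{device}_est"].to_numpy(dtype=float)

    def _check(self, device: str) -> None:
        if f"{device}_detected" not in self.df.columns:
            raise KeyError(f"unknown device {device!r}; have {self.devices}")


def read_reference_table(path) -> ReferenceTable:
    """Read and validate a reference-measurement CSV."""
    df = pd.read_csv(path) if not isinstance(path, pd.DataFrame) else path.copy()
    if df.empty:
        raise ValueError("reference table is empty")
    missing = [c for c in ("id", "reference") if c not in df.columns]
    devices = [c[: -len("_detected")] for c in df.columns if c.endswith("_detected")]
    for dev in devices:
        if f"{dev}_est" not in df.columns:
            missing.append(f"{dev}_est")
    if missing:
        raise ValueError(f"reference table missing columns: {missing}")
    if (df["reference"] <= 0).any():
        raise ValueError("reference values must be positive")
    for dev in devices:
        det = df[f"{dev}_detected"]
        if det.dtype == object:
            det = det.str.strip().str.lower().isin(("yes", "true", "1"))
            df[f"{dev}_detected"] = det
        if df.loc[~det, f"{dev}_est"].notna().any():
            raise ValueError(f"device {dev}: undetected rows must have no estimate")
    return ReferenceTable(df)


def _packaged(name: str) -> ReferenceTable:
    with resources.files("stemscan.data").joinpath(name).open() as fh:
        return read_reference_table(pd.read_csv(fh))


def lab_reference_diameters() -> ReferenceTable:
    """The packaged laboratory tube-diameter benchmark table (cm)."""
    return _packaged("lab_diameters.csv")


def lab_reference_heights() -> ReferenceTable:
    """The packaged laboratory tube-length benchmark table (cm)."""
    return _packaged("lab_heights.csv")


# ---------------------------------------------------------------------------
# YAML/JSON configs

def _load_mapping(path: str | Path) -> dict:
    import json

    import yaml

    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def load_profile(path: str | Path):
    """Device profile from a YAML/JSON mapping of DeviceProfile fields."""
    from .simulate import DeviceProfile

    return DeviceProfile(**_load_mapping(path))


def load_scene(path: str | Path):
    """Scene from a YAML/JSON config.

    The mapping either describes a plantation (``plantation:`` with the
    generator's keyword arguments) or a tube scene (``tubes:`` listing
    TubeSpec fields, ``center_xy`` as a two-element list).
    """
    from .simulate import Scene, TubeSpec, make_lab_scene, make_plantation_scene

    data = _load_mapping(path)
    if "plantation" in data:
        return make_plantation_scene(**data["plantation"])
    if "tubes" in data:
        tubes = [
            TubeSpec(**{**t, "center_xy": tuple(t["center_xy"])})
            for t in data["tubes"]
        ]
        return make_lab_scene(tubes)
    raise ValueError(f"{path}: config needs a 'plantation' or 'tubes' section")


def lab_reference_tubes() -> list[TubeSpec]:
    """The twelve benchmark tubes, laid out on a grid inside 7 x 7 m."""
    dia = lab_reference_diameters()
    length = {r.id: r.reference for r in lab_reference_heights().df.itertuples()}
    tubes = []
    for k, row in enumerate(dia.df.itertuples()):
        i, j = divmod(k, 4)
        tubes.append(
            TubeSpec(
                id=row.id,
                diameter=row.reference,
                length=length[row.id],
                center_xy=(0.8 + 1.8 * j, 1.2 + 2.3 * i),
            )
        )
    return tubes
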