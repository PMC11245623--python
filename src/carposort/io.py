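"""Plain-text serialization of clouds, scans, and fitted curves."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh

from .synthetic_seeds import IntrinsicParams, PointCloud, SeedScan

__all__ = [
    "save_cloud",
    "load_cloud",
    "save_scan",
    "load_scan",
    "save_intrinsics",
    "load_intrinsics",
]


def save_cloud(path: str | Path, cloud: PointCloud) -> None:
    """Write a cloud as ASCII PLY (``.ply``) or whitespace XYZ (``.xyz``)."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        data = trimesh.PointCloud(cloud.points).export(file_type="ply", encoding="ascii")
        path.write_bytes(data)
    elif path.suffix.lower() == ".xyz":
        np.savetxt(path, cloud.points, fmt="%.6f")
    else:
        raise ValueError(f"unsupported cloud format: {path.suffix!r}")


def load_cloud(path: str | Path) -> PointCloud:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        pc = trimesh.load(path)
        return PointCloud(np.asarray(pc.vertices, dtype=float))
    if path.suffix.lower() == ".xyz":
        return PointCloud(np.loadtxt(path, ndmin=2))
    raise ValueError(f"unsupported cloud format: {path.suffix!r}")


def save_scan(path: str | Path, scan: SeedScan) -> None:
    """Write a height map as a row-major plain-text matrix (mm values)."""
    np.savetxt(path, scan.height_map, fmt="%.6f")


def load_scan(path: str | Path) -> SeedScan:
    return SeedScan(np.loadtxt(path, ndmin=2))


def save_intrinsics(path: str | Path, intrinsics: IntrinsicParams) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "mm_per_pixel_x": intrinsics.mm_per_pixel_x,
                "mm_per_pixel_y": intrinsics.mm_per_pixel_y,
                "principal_point": list(intrinsics.principal_point),
            },
            indent=2,
        )
    )


def load_intrinsics(path: str | Path) -> IntrinsicParams:
    raw = json.loads(Path(path).read_text())
    return IntrinsicParams(
        raw["mm_per_pixel_x"],
        raw["mm_per_pixel_y"],
        tuple(raw["principal_point"]),
    )
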