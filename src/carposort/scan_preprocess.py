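"""Scan-to-cloud conversion, pose canonicalization, and length normalization.

A stereoscopic pip scan is a rectangular height map; multiplying pixel
indices and heights by the scanner's intrinsic parameters turns each
foreground pixel into a metric 3D point.  Downstream measurement and
registration assume a canonical pose (x = length, y = breadth, ventral face
toward +z, centroid at the origin), established here from the principal axes
of the point scatter.  Finally, clouds are rescaled to a common length while
preserving their proportions, so registration-based similarity reflects
shape rather than physical size.
"""

from __future__ import annotations

import numpy as np

from . import morphometry
from .synthetic_seeds import IntrinsicParams, PointCloud, SeedScan

__all__ = [
    "EmptyScanError",
    "scan_to_cloud",
    "canonicalize_pose",
    "normalize_length",
    "preprocess_scan",
]


class EmptyScanError(ValueError):
    """Scan contains no foreground pixels."""


def scan_to_cloud(
    scan: SeedScan, intrinsics: IntrinsicParams, background: float = 0.0
) -> PointCloud:
    """Convert a height map to a point cloud via the intrinsic parameters.

    Each pixel (row, col) with height above ``background`` yields one point
    (x, y, z) = ((col - cx) * sx, (row - cy) * sy, height).
    """
    hm = scan.height_map
    rows, cols = np.nonzero(hm > background)
    if rows.size == 0:
        raise EmptyScanError("scan has no foreground pixels")
    cx, cy = intrinsics.principal_point
    x = (cols - cx) * intrinsics.mm_per_pixel_x
    y = (rows - cy) * intrinsics.mm_per_pixel_y
    z = hm[rows, cols]
    return PointCloud(np.column_stack([x, y, z]))


def _principal_axes(pts: np.ndarray) -> np.ndarray:
    cov = np.cov(pts.T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if eigvals[1] <= 1e-12 * max(eigvals[0], 1e-30):
        raise morphometry.DegenerateCloudError("rank-deficient point scatter")
    if np.linalg.det(eigvecs) < 0:
        eigvecs[:, 2] *= -1.0
    return eigvecs


def canonicalize_pose(cloud: PointCloud) -> PointCloud:
    """Center a cloud and align its principal axes to (x, y, z).

    Axes are ordered by decreasing scatter variance (length, breadth,
    height).  Sign conventions: the beak end — identified as the x-end
    quartile with the smaller mean transverse cross-section — points toward
    negative x; the ventral face — identified by detectable infold grooves,
    falling back to the side with the larger z extent — points toward +z;
    the y sign then completes a right-handed frame.  Invariant to rigid
    motion of the input up to these conventions, and idempotent.
    """
    pts = np.asarray(cloud.points, dtype=float)
    if pts.shape[0] < 3:
        raise morphometry.DegenerateCloudError("need at least 3 points")
    centered = pts - pts.mean(axis=0)
    axes = _principal_axes(centered)
    t = centered @ axes

    # beak (narrower cross-section) toward negative x
    x = t[:, 0]
    lo, hi = np.quantile(x, [0.25, 0.75])
    r2 = t[:, 1] ** 2 + t[:, 2] ** 2
    sx = 1.0
    mean_low, mean_high = r2[x <= lo].mean(), r2[x >= hi].mean()
    if mean_high < mean_low:
        sx = -1.0

    # ventral grooves toward +z
    up = t * np.array([sx, 1.0, 1.0])
    down = t * np.array([sx, 1.0, -1.0])
    prom_up = morphometry.groove_prominence(up)
    prom_down = morphometry.groove_prominence(down)
    if prom_up > prom_down:
        sz = 1.0
    elif prom_down > prom_up:
        sz = -1.0
    else:
        sz = 1.0 if (t[:, 2].max() + t[:, 2].min()) >= 0 else -1.0

    sy = sx * sz  # right-handed frame
    out = t * np.array([sx, sy, sz])
    return cloud.with_points(out)


def normalize_length(cloud: PointCloud, target_length: float = 1.0) -> PointCloud:
    """Uniformly rescale a canonical cloud to a common length.

    All coordinates are multiplied by the single factor
    ``target_length / length``, so every shape ratio (L/W, W/DVI) is
    preserved exactly; idempotent once applied.
    """
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    length = float(np.ptp(cloud.points[:, 0]))
    if length <= 0:
        raise morphometry.DegenerateCloudError("zero-length cloud")
    factor = target_length / length
    return cloud.with_points(cloud.points * factor)


def preprocess_scan(
    scan: SeedScan,
    intrinsics: IntrinsicParams,
    target_length: float | None = 1.0,
    background: float = 0.0,
) -> PointCloud:
    """Scan → cloud → canonical pose → (optional) equal-length normalization."""
    cloud = canonicalize_pose(scan_to_cloud(scan, intrinsics, background))
    if target_length is not None:
        cloud = normalize_length(cloud, target_length)
    return cloud
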