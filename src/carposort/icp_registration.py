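"""Rigid point-cloud registration by Iterative Closest Point (ICP).

Classic point-to-point ICP: alternate (1) nearest-neighbor correspondence
from source to target via a k-d tree and (2) the least-squares rigid
transform for those correspondences (Kabsch/SVD with reflection correction).
The residual mean squared nearest-neighbor distance (MSE, mm²) after the
final alignment is the pairwise shape-dissimilarity used as a feature by the
similarity classifier.  With exact correspondence and transform steps the
MSE sequence is non-increasing, which is asserted throughout the test suite.

Clouds are expected to arrive canonicalized and length-normalized, so ICP
starts from the identity; no random restarts are needed and no scale is
estimated here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .synthetic_seeds import PointCloud

__all__ = [
    "RigidTransform",
    "IcpResult",
    "DegenerateGeometryError",
    "nearest_correspondences",
    "best_rigid_transform",
    "icp",
]


class DegenerateGeometryError(ValueError):
    """Input geometry insufficient for a unique rigid alignment."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion p ↦ R p + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def as_matrix(self) -> np.ndarray:
        """The 3x4 [R | t] matrix."""
        return np.hstack([self.rotation, self.translation[:, None]])


@dataclass(frozen=True)
class IcpResult:
    transform: RigidTransform
    mse: float
    n_iterations: int
    converged: bool
    mse_history: tuple[float, ...] = ()


def nearest_correspondences(source: PointCloud, target: PointCloud) -> np.ndarray:
    """Index of the nearest target point for every source point."""
    if target.n_points == 0 or source.n_points == 0:
        raise ValueError("clouds must be non-empty")
    tree = cKDTree(target.points)
    _, idx = tree.query(source.points, k=1)
    return np.asarray(idx, dtype=int)


def best_rigid_transform(source_pts: np.ndarray, target_pts: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping paired source onto target points.

    Kabsch/SVD solution minimizing the mean squared pair distance over all
    rotations and translations; a reflection in the SVD solution is
    corrected so the returned rotation is proper.
    """
    src = np.asarray(source_pts, dtype=float)
    tgt = np.asarray(target_pts, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays required")
    if src.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 point pairs")
    cs, ct = src.mean(axis=0), tgt.mean(axis=0)
    H = (src - cs).T @ (tgt - ct)
    U, S, Vt = np.linalg.svd(H)
    if S[1] <= 1e-12 * max(S[0], 1e-30):
        raise DegenerateGeometryError("collinear or degenerate point pairs")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ct - R @ cs
    return RigidTransform(R, t)


def icp(
    source: PointCloud,
    target: PointCloud,
    max_iterations: int = 50,
    tolerance: float = 1e-6,
    trim_fraction: float = 0.0,
) -> IcpResult:
    """Register source onto target, returning the final transform and MSE.

    Stops when the relative MSE change drops below ``tolerance`` or after
    ``max_iterations``.  ``trim_fraction`` optionally discards that fraction
    of worst correspondences in the transform update (useful for
    crack-damaged clouds; off by default, and the monotone-MSE guarantee is
    only strict without trimming).
    """
    if source.n_points == 0 or target.n_points == 0:
        raise ValueError("clouds must be non-empty")
    if not 0.0 <= trim_fraction < 1.0:
        raise ValueError("trim_fraction must lie in [0, 1)")
    src0 = source.points
    tree = cKDTree(target.points)
    transform = RigidTransform.identity()
    history: list[float] = []
    converged = False
    n_done = 0
    for _ in range(max_iterations):
        moved = transform.apply(src0)
        dists, idx = tree.query(moved, k=1)
        mse = float(np.mean(dists**2))
        history.append(mse)
        n_done += 1
        if len(history) > 1:
            prev = history[-2]
            if abs(prev - mse) <= tolerance * max(mse, 1e-30):
                converged = True
                break
        keep = np.arange(src0.shape[0])
        if trim_fraction > 0.0:
            n_keep = max(3, int(np.ceil((1.0 - trim_fraction) * src0.shape[0])))
            keep = np.argsort(dists)[:n_keep]
        try:
            transform = best_rigid_transform(src0[keep], target.points[idx[keep]])
        except DegenerateGeometryError:
            break
    final = transform.apply(src0)
    dists, _ = tree.query(final, k=1)
    final_mse = float(np.mean(dists**2))
    if not history or final_mse < history[-1]:
        history.append(final_mse)
    return IcpResult(
        transform=transform,
        mse=min(final_mse, history[-1]),
        n_iterations=n_done,
        converged=converged,
        mse_history=tuple(history),
    )
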