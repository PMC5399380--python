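"""Binary mask to physically scaled point cloud, and spheroid isolation.

Each foreground voxel becomes one point at the voxel centre in
micrometres, so the point count times the voxel volume equals the
foreground volume exactly.  The cloud is then cleaned by DBSCAN in
physical (µm) space: the spheroid of interest is the largest density-
connected cluster; stray cells and detector noise fall into smaller
clusters or the noise label and are discarded.

Points are stored (x, y, z) in µm.  A voxel at index (iz, iy, ix) with
pitch (dz, dy, dx) maps to ((ix+0.5)·dx, (iy+0.5)·dy, (iz+0.5)·dz).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

import numpy as np
from sklearn.cluster import DBSCAN

from .segmentation import BinaryMask

__all__ = [
    "PointCloud",
    "ClusterLabeling",
    "mask_to_points",
    "subsample",
    "cluster_points",
    "extract_main_cluster",
    "default_eps_um",
]


@dataclass
class PointCloud:
    """Points (x, y, z) in µm plus the pitch they were derived from."""

    points: np.ndarray  # (n, 3) float, columns x, y, z
    source_pitch: Tuple[float, float, float]  # (dz, dy, dx) µm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {self.points.shape}")
        if not np.isfinite(self.points).all():
            raise ValueError("point coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class ClusterLabeling:
    """DBSCAN labels per point; -1 marks noise."""

    labels: np.ndarray
    eps_um: float
    min_points: int


def default_eps_um(pitch: Tuple[float, float, float], factor: float = 2.0) -> float:
    """DBSCAN eps as a multiple of the largest voxel pitch.

    eps must bridge the largest inter-slice gap of an anisotropic stack,
    so it scales with max(dz, dy, dx); factor 2 is the default.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    return factor * max(pitch)


def mask_to_points(mask: BinaryMask, pitch: Tuple[float, float, float]) -> PointCloud:
    """One point per foreground voxel, at the voxel centre in µm."""
    idx = np.argwhere(mask.mask)  # (n, 3) in (z, y, x) order
    if len(idx) == 0:
        raise ValueError("empty mask: no cells detected")
    dz, dy, dx = pitch
    pts = np.empty((len(idx), 3), dtype=np.float64)
    pts[:, 0] = (idx[:, 2] + 0.5) * dx
    pts[:, 1] = (idx[:, 1] + 0.5) * dy
    pts[:, 2] = (idx[:, 0] + 0.5) * dz
    return PointCloud(points=pts, source_pitch=tuple(pitch))


def subsample(cloud: PointCloud, max_points: int, seed: int = 0) -> PointCloud:
    """Uniform subsample without replacement when the cloud is too large.

    Keeps Delaunay triangulation and neighbour search tractable on dense
    masks.  Identity when the cloud already fits; deterministic given
    the seed.
    """
    if max_points < 4:
        raise ValueError("max_points must be >= 4")
    if len(cloud) <= max_points:
        return cloud
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(cloud), size=max_points, replace=False)
    keep.sort()  # preserve index order so border-point assignment stays deterministic
    return PointCloud(points=cloud.points[keep], source_pitch=cloud.source_pitch)


def cluster_points(cloud: PointCloud, eps_um: float, min_points: int) -> ClusterLabeling:
    """DBSCAN in physical µm space (Euclidean metric).

    Core points have at least ``min_points`` neighbours (self included)
    within ``eps_um``; clusters are maximal density-connected sets;
    border points join the cluster of the first core point reaching them
    in index order; everything else is labelled -1.
    """
    if eps_um <= 0:
        raise ValueError("eps_um must be > 0")
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    labels = DBSCAN(eps=eps_um, min_samples=min_points).fit_predict(cloud.points)
    return ClusterLabeling(labels=labels, eps_um=float(eps_um), min_points=int(min_points))


def extract_main_cluster(cloud: PointCloud, labeling: ClusterLabeling) -> PointCloud:
    """Points of the largest cluster — the spheroid of interest.

    Cardinality ties break toward the lowest label.  Raises if DBSCAN
    marked every point as noise (clustering parameters failed).
    """
    labels = labeling.labels
    valid = labels[labels >= 0]
    if valid.size == 0:
        raise ValueError("all points labelled noise; check eps_um / min_points")
    counts = np.bincount(valid)
    main = int(np.argmax(counts))  # argmax takes the lowest label on ties
    return PointCloud(points=cloud.points[labels == main], source_pitch=cloud.source_pitch)


def write_xyz(cloud: PointCloud, path: str | Path) -> Path:
    """Export as whitespace-separated XYZ text for external inspection."""
    path = Path(path)
    np.savetxt(path, cloud.points, fmt="%.6f", header="x_um y_um z_um")
    return path
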