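"""Alpha-shape volumetrics: cell body, spheroid body, and their ratio.

The alpha shape (alpha complex, in the circumradius formulation of
Edelsbrunner and Muecke) of a point cloud is the union of Delaunay
tetrahedra whose circumsphere radius does not exceed alpha.  As alpha
grows the shape grows monotonically toward the convex hull; small alpha
carves out cavities larger than alpha — which is exactly what separates
a hollow spheroid's cell volume from its enclosing body volume:

* cell volume  — alpha small enough not to span the lumen, so the
  central cavity is excluded;
* body volume  — alpha effectively infinite (convex hull), spanning the
  lumen.

Both alphas are set as multiples of the largest voxel pitch, mirroring
an acquisition-resolution-driven choice, and the cell/body volume ratio
is the luminal-filling statistic: about the shell fraction for a hollow
bilayer, approaching 1 for a filled lumen.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .pointcloud import PointCloud

__all__ = [
    "AlphaParameters",
    "TriangulatedBody",
    "default_alpha",
    "alpha_shape",
    "compute_volumes",
    "VolumeResult",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlphaParameters:
    """The two alpha radii, and the pitch multipliers that produced them."""

    alpha_cell_um: float
    alpha_body_um: float
    cell_factor: float = 3.0
    body_factor: float = 1e6

    def __post_init__(self) -> None:
        if not (0 < self.alpha_cell_um < self.alpha_body_um):
            raise ValueError("require 0 < alpha_cell_um < alpha_body_um")

    @classmethod
    def from_pitch(cls, pitch: Tuple[float, float, float],
                   cell_factor: float = 3.0, body_factor: float = 1e6) -> "AlphaParameters":
        return cls(
            alpha_cell_um=default_alpha(pitch, cell_factor),
            alpha_body_um=default_alpha(pitch, body_factor),
            cell_factor=cell_factor,
            body_factor=body_factor,
        )


@dataclass
class TriangulatedBody:
    """Alpha-shape tetrahedralisation with a well-defined volume."""

    vertices: np.ndarray  # (n, 3) µm
    tetrahedra: np.ndarray  # (m, 4) vertex indices
    volume_um3: float
    alpha_um: float


@dataclass(frozen=True)
class VolumeResult:
    """Cell volume, spheroid body volume and their ratio for one spheroid."""

    spheroid_id: str
    cell_volume_um3: float
    body_volume_um3: float
    ratio: float

    def __post_init__(self) -> None:
        if self.body_volume_um3 > 0:
            expected = self.cell_volume_um3 / self.body_volume_um3
            if abs(self.ratio - expected) > 1e-9 * max(1.0, expected):
                raise ValueError("ratio inconsistent with cell/body volumes")


def default_alpha(pitch: Tuple[float, float, float], factor: float) -> float:
    """Alpha radius as a function of the acquisition resolution.

    Returns ``factor * max(dz, dy, dx)``: the coarsest pitch is the
    largest gap between adjacent foreground voxel centres, so alpha must
    scale with it for tetrahedra between neighbouring voxels to survive.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    return factor * max(pitch)


def _tet_volumes(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """|det| / 6 per tetrahedron, vectorised."""
    a = pts[simplices[:, 0]]
    edges = pts[simplices[:, 1:]] - a[:, None, :]  # (m, 3, 3)
    return np.abs(np.linalg.det(edges)) / 6.0


def _circumradii(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumsphere radius per tetrahedron; inf for degenerate ones.

    The circumcentre c satisfies 2 (v_i - v_0) · (c - v_0) = |v_i - v_0|²
    for i = 1..3; solved per-simplex as a batched 3x3 linear system.
    """
    a = pts[simplices[:, 0]]
    m = pts[simplices[:, 1:]] - a[:, None, :]  # (n, 3, 3) rows v_i - v_0
    rhs = 0.5 * np.einsum("nij,nij->ni", m, m)  # (n, 3)
    det = np.linalg.det(m)
    radii = np.full(len(simplices), np.inf)
    ok = np.abs(det) > np.finfo(np.float64).tiny
    if ok.any():
        sol = np.linalg.solve(m[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(sol, axis=1)
    return radii


def alpha_shape(cloud: PointCloud, alpha_um: float) -> TriangulatedBody:
    """Alpha complex of the cloud: Delaunay tetrahedra with circumradius <= alpha.

    Degenerate (coplanar / collinear) clouds trigger one retry with a
    deterministic jitter of 1e-9 x max pitch; if Qhull still fails, a
    zero-volume body is returned with a warning, matching the geometric
    fact that such a cloud encloses no volume.
    """
    if alpha_um <= 0:
        raise ValueError("alpha_um must be > 0")
    pts = cloud.points
    if len(pts) < 4:
        raise ValueError(f"alpha shape needs >= 4 points, got {len(pts)}")
    try:
        tri = Delaunay(pts)
    except QhullError:
        centred = pts - pts.mean(axis=0)
        rank = np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(centred).max()))
        if rank < 3:
            warnings.warn("degenerate (coplanar/collinear) cloud: volume set to 0",
                          stacklevel=2)
            return TriangulatedBody(vertices=pts, tetrahedra=np.empty((0, 4), dtype=int),
                                    volume_um3=0.0, alpha_um=float(alpha_um))
        # full-rank but numerically awkward: one deterministic jitter retry
        jitter_scale = 1e-9 * max(cloud.source_pitch)
        rng = np.random.default_rng(0)  # fixed: jitter must not vary between runs
        logger.warning("qhull failed on full-rank cloud; retrying with %.1e um jitter",
                       jitter_scale)
        tri = Delaunay(pts + rng.normal(0.0, jitter_scale, pts.shape))
    radii = _circumradii(pts, tri.simplices)
    keep = tri.simplices[radii <= alpha_um]
    volume = float(_tet_volumes(pts, keep).sum()) if len(keep) else 0.0
    return TriangulatedBody(vertices=pts, tetrahedra=keep, volume_um3=volume,
                            alpha_um=float(alpha_um))


def compute_volumes(cloud: PointCloud, params: AlphaParameters,
                    spheroid_id: str = "") -> VolumeResult:
    """Cell and body volumes of the extracted main cluster, and their ratio.

    The cell body uses the small alpha, the spheroid body the large one;
    monotonicity of the alpha complex in alpha guarantees ratio <= 1.
    """
    cell = alpha_shape(cloud, params.alpha_cell_um)
    body = alpha_shape(cloud, params.alpha_body_um)
    if body.volume_um3 <= 0:
        raise ValueError("degenerate cloud: spheroid body volume is zero")
    return VolumeResult(
        spheroid_id=spheroid_id,
        cell_volume_um3=cell.volume_um3,
        body_volume_um3=body.volume_um3,
        ratio=cell.volume_um3 / body.volume_um3,
    )


def write_ply(body: TriangulatedBody, path: str | Path) -> Path:
    """Export the tetrahedral body as ASCII PLY (vertices + tetra faces)."""
    path = Path(path)
    faces = set()
    for tet in body.tetrahedra:
        for f in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
            faces.add(tuple(sorted(int(tet[i]) for i in f)))
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {len(body.vertices)}",
        "property float x", "property float y", "property float z",
        f"element face {len(faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    lines += [f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in body.vertices]
    lines += [f"3 {a} {b} {c}" for a, b, c in sorted(faces)]
    path.write_text("\n".join(lines) + "\n")
    return path
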