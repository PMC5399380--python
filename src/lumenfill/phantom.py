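"""Synthetic spheroid phantoms with known geometry.

The phantoms emulate confocal z-stacks of DAPI-labelled breast-duct
spheroids grown in collagen gels: a shell of nuclei (the luminal/
myoepithelial bilayer) around a central cavity.  A hollow phantom
(``fill_fraction = 0``) stands for an intact bilayer with an open lumen;
``fill_fraction = 1`` stands for complete luminal filling, the DCIS-like
state.  Every phantom carries an analytic ground truth, so the whole
volumetric pipeline — thresholding, point-cloud extraction, clustering,
alpha-shape volumes — can be validated end to end without microscope data.

Nuclei are rendered as solid balls of uniform intensity rather than
Gaussian blobs so that occupancy has a well-defined volume; overlap is
permitted and the rendered occupied volume is measured by voxel-union
counting on the render grid (the same grid the pipeline sees).  The
optical model is an isotropic Gaussian PSF followed by additive Gaussian
read noise; Poisson shot noise is deliberately omitted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import tifffile
from pydantic import BaseModel, Field, model_validator

from .stackio import ImageStack

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "expected_ratio",
    "write_phantom",
    "hollow_control_spec",
    "filled_induced_spec",
]


class PhantomSpec(BaseModel):
    """Geometry, optics and noise of one synthetic spheroid stack.

    Lengths are micrometres, intensities arbitrary units.  Defaults
    describe a small bilayer spheroid (outer radius 20 µm, lumen 12 µm)
    imaged at typical confocal anisotropy (z-step 2 µm, 0.5 µm pixels).
    """

    outer_radius_um: float = 20.0
    lumen_radius_um: float = 12.0
    fill_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    nucleus_radius_um: float = 3.5
    shell_nucleus_count: int = 100
    voxel_pitch: Tuple[float, float, float] = (2.0, 0.5, 0.5)  # (dz, dy, dx)
    stack_shape: Tuple[int, int, int] = (32, 128, 128)  # (nz, ny, nx)
    fg_intensity: float = 200.0
    bg_intensity: float = 20.0
    psf_sigma_um: float = 0.5
    noise_sd: float = 10.0
    seed: int = 0

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_geometry(self) -> "PhantomSpec":
        if not (0.0 <= self.lumen_radius_um < self.outer_radius_um):
            raise ValueError("require 0 <= lumen_radius_um < outer_radius_um")
        if any(p <= 0 for p in self.voxel_pitch):
            raise ValueError("all voxel pitches must be > 0")
        if self.fg_intensity <= self.bg_intensity:
            raise ValueError("fg_intensity must exceed bg_intensity")
        if self.nucleus_radius_um <= 0:
            raise ValueError("nucleus_radius_um must be > 0")
        if self.shell_nucleus_count < 1:
            raise ValueError("shell_nucleus_count must be >= 1")
        # The sphere plus one nucleus diameter of margin must fit the stack.
        need = self.outer_radius_um + 2.0 * self.nucleus_radius_um
        half_extent = [n * p / 2.0 for n, p in zip(self.stack_shape, self.voxel_pitch)]
        if any(h < need for h in half_extent):
            raise ValueError(
                f"stack too small: sphere + margin needs {need:.1f} um half-extent, "
                f"stack provides {tuple(round(h, 1) for h in half_extent)} um (z, y, x)"
            )
        return self


@dataclass(frozen=True)
class GroundTruth:
    """Analytic volumes of a phantom, plus the rendered occupancy.

    ``true_cell_volume_um3`` and ``true_ratio`` are closed-form: the
    occupied volume of a ball of radius R with a lumen of radius r filled
    to fraction f is (4/3)pi (R^3 - (1 - f) r^3), so
    ``true_ratio = 1 - (1 - f) (r/R)^3``.  ``rendered_cell_volume_um3``
    is the voxel-union volume actually drawn on the render grid and
    differs from the analytic value by discretisation and the randomness
    of nucleus packing.
    """

    true_cell_volume_um3: float
    true_body_volume_um3: float
    true_ratio: float
    rendered_cell_volume_um3: float

    def __post_init__(self) -> None:
        assert 0.0 < self.true_ratio <= 1.0 + 1e-12


def expected_ratio(spec: PhantomSpec) -> float:
    """Closed-form expected cell/body volume ratio of a phantom.

    ``1 - (1 - fill_fraction) * (lumen_radius / outer_radius)**3``:
    the shell fraction of the ball plus the occupied fraction of the lumen.
    """
    r3 = (spec.lumen_radius_um / spec.outer_radius_um) ** 3
    return 1.0 - (1.0 - spec.fill_fraction) * r3


class PlacementError(RuntimeError):
    """Rejection sampling could not satisfy the phantom geometry."""


def _sample_in_ball(rng: np.random.Generator, radius: float, n: int) -> np.ndarray:
    """Uniform points in a ball of given radius, shape (n, 3)."""
    pts = np.empty((0, 3))
    while len(pts) < n:
        cand = rng.uniform(-radius, radius, size=(2 * (n - len(pts)) + 8, 3))
        cand = cand[np.einsum("ij,ij->i", cand, cand) <= radius * radius]
        pts = np.vstack([pts, cand])
    return pts[:n]


def _sample_in_shell(
    rng: np.random.Generator, r_in: float, r_out: float, n: int, max_attempts: int
) -> np.ndarray:
    """Uniform points in the spherical shell [r_in, r_out] by rejection."""
    out = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"placed {len(out)}/{n} shell nuclei in {max_attempts} attempts; "
                "shell too thin for the requested count"
            )
        batch = rng.uniform(-r_out, r_out, size=(64, 3))
        d = np.sqrt(np.einsum("ij,ij->i", batch, batch))
        keep = batch[(d >= r_in) & (d <= r_out)]
        out.extend(keep[: n - len(out)])
    return np.asarray(out[:n])


def _stamp_ball(occ: np.ndarray, centre_um: np.ndarray, radius_um: float,
                pitch: Tuple[float, float, float]) -> None:
    """Mark voxels whose centres lie within a ball (in-place, local box)."""
    dz, dy, dx = pitch
    lo = []
    hi = []
    for c, p, n in zip(centre_um, pitch, occ.shape):
        lo.append(max(int((c - radius_um) / p - 0.5), 0))
        hi.append(min(int((c + radius_um) / p - 0.5) + 2, n))
    if any(l >= h for l, h in zip(lo, hi)):
        return
    zz = (np.arange(lo[0], hi[0]) + 0.5) * dz - centre_um[0]
    yy = (np.arange(lo[1], hi[1]) + 0.5) * dy - centre_um[1]
    xx = (np.arange(lo[2], hi[2]) + 0.5) * dx - centre_um[2]
    d2 = (zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2)
    occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= radius_um * radius_um


def generate_phantom(spec: PhantomSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a phantom stack and return it with its ground truth.

    Shell nuclei centres are rejection-sampled in the spherical shell
    ``[lumen_radius, outer_radius - nucleus_radius]``.  When
    ``fill_fraction > 0``, additional nuclei are dropped uniformly into
    the lumen until the occupied lumen volume (voxel-counted) reaches
    ``fill_fraction`` times the lumen volume.  The occupancy map is
    rendered at fg/bg intensity, blurred with the Gaussian PSF, read
    noise is added and the result clipped at zero.  Output is a pure
    function of the spec (which includes the seed).

    Raises
    ------
    PlacementError
        If rejection sampling cannot place the requested nuclei within a
        bounded number of attempts (over-packed or inconsistent spec).
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.stack_shape
    pitch = spec.voxel_pitch
    centre = np.array([n * p / 2.0 for n, p in zip(spec.stack_shape, pitch)])

    R = spec.outer_radius_um
    r = spec.lumen_radius_um
    a = spec.nucleus_radius_um

    occ = np.zeros(spec.stack_shape, dtype=bool)

    shell_outer = R - a
    if shell_outer <= r and spec.shell_nucleus_count > 0:
        raise PlacementError("no room for shell nuclei: outer_radius - nucleus_radius <= lumen_radius")
    shell_centres = _sample_in_shell(
        rng, r, shell_outer, spec.shell_nucleus_count,
        max_attempts=1000 + 100 * spec.shell_nucleus_count,
    )
    for c in shell_centres:
        _stamp_ball(occ, centre + c, a, pitch)

    # Lumen voxel set, for measuring fill occupancy on the render grid.
    zz = (np.arange(nz) + 0.5) * pitch[0] - centre[0]
    yy = (np.arange(ny) + 0.5) * pitch[1] - centre[1]
    xx = (np.arange(nx) + 0.5) * pitch[2] - centre[2]
    d2 = zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    lumen_vox = d2 <= r * r

    if spec.fill_fraction > 0.0 and r > 0.0:
        n_lumen = int(lumen_vox.sum())
        target = spec.fill_fraction * n_lumen
        # Random covering needs ~log(1/eps) oversampling; bound generously.
        vox_per_nucleus = max((4.0 / 3.0) * math.pi * a**3 / np.prod(pitch), 1.0)
        max_attempts = int(200 + 40 * n_lumen / vox_per_nucleus * (1 + 10 * spec.fill_fraction))
        attempts = 0
        while (occ & lumen_vox).sum() < target:
            attempts += 1
            if attempts > max_attempts:
                raise PlacementError(
                    f"lumen fill stalled at "
                    f"{(occ & lumen_vox).sum() / n_lumen:.3f} of target "
                    f"{spec.fill_fraction} after {max_attempts} nuclei"
                )
            c = _sample_in_ball(rng, r, 1)[0]
            _stamp_ball(occ, centre + c, a, pitch)

    voxel_volume = float(np.prod(pitch))
    rendered_cell_volume = float(occ.sum()) * voxel_volume

    image = np.where(occ, spec.fg_intensity, spec.bg_intensity).astype(np.float64)
    if spec.psf_sigma_um > 0:
        from scipy.ndimage import gaussian_filter

        sigma_vox = [spec.psf_sigma_um / p for p in pitch]
        image = gaussian_filter(image, sigma=sigma_vox)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, None)

    body = (4.0 / 3.0) * math.pi * R**3
    cell = (4.0 / 3.0) * math.pi * (R**3 - (1.0 - spec.fill_fraction) * r**3)
    truth = GroundTruth(
        true_cell_volume_um3=cell,
        true_body_volume_um3=body,
        true_ratio=expected_ratio(spec),
        rendered_cell_volume_um3=rendered_cell_volume,
    )
    stack = ImageStack(voxels=image, pitch=pitch, bit_depth=16,
                       label=f"phantom(seed={spec.seed}, fill={spec.fill_fraction})")
    return stack, truth


def write_phantom(stack: ImageStack, truth: GroundTruth, spec: PhantomSpec,
                  path: str | Path) -> Path:
    """Write a phantom as multi-page TIFF plus a sidecar JSON.

    The sidecar carries the voxel pitch, the generating spec and the
    ground truth, so a written phantom remains fully self-describing.
    Returns the TIFF path.
    """
    path = Path(path)
    data = np.clip(np.round(stack.voxels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {
        "pitch_um": list(stack.pitch),
        "bit_depth": 16,
        "label": stack.label,
        "phantom_spec": spec.model_dump(),
        "ground_truth": {
            "true_cell_volume_um3": truth.true_cell_volume_um3,
            "true_body_volume_um3": truth.true_body_volume_um3,
            "true_ratio": truth.true_ratio,
            "rendered_cell_volume_um3": truth.rendered_cell_volume_um3,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def hollow_control_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Default hollow-bilayer phantom: intact lumen (control condition)."""
    return PhantomSpec(seed=seed, fill_fraction=0.0, **overrides)


def filled_induced_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Default filled-lumen phantom: complete luminal filling (induced)."""
    return PhantomSpec(seed=seed, fill_fraction=1.0, **overrides)
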