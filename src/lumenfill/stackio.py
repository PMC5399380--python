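"""Z-stack I/O with physical voxel metadata, and run configuration.

Axis order is (z, y, x) everywhere in this package, and the voxel pitch
is stored in the same order, (dz, dy, dx) in micrometres.  Physical
coordinates use the voxel-centre convention: index ``i`` along an axis
of pitch ``p`` sits at ``(i + 0.5) * p``.

A stack's pitch is resolved, in order of precedence, from an explicit
override, a sidecar JSON next to the file, or OME-XML metadata embedded
in the TIFF.  A stack without any pitch source is an error — volumes in
cubic micrometres cannot be inferred from pixel counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "ImageStack",
    "RunConfig",
    "read_stack",
    "write_stack",
    "load_config",
    "read_manifest",
]

Pitch = Tuple[float, float, float]


@dataclass
class ImageStack:
    """A 3D intensity volume plus its physical voxel pitch.

    ``voxels`` is indexed (z, y, x) for greyscale or (z, y, x, channel)
    for RGB pages; ``pitch`` is (dz, dy, dx) in µm.
    """

    voxels: np.ndarray
    pitch: Pitch
    bit_depth: int = 16
    label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim not in (3, 4):
            raise ValueError(f"expected a (z, y, x[, c]) array, got ndim={self.voxels.ndim}")
        if any(p <= 0 for p in self.pitch):
            raise ValueError(f"voxel pitch must be positive, got {self.pitch}")
        if np.issubdtype(self.voxels.dtype, np.floating) and (self.voxels < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def is_rgb(self) -> bool:
        return self.voxels.ndim == 4

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.pitch))


class RunConfig(BaseModel):
    """Validated configuration for a pipeline run.

    ``eps_um``/``min_points`` drive DBSCAN spheroid isolation;
    ``cell_factor``/``body_factor`` set the two alpha radii as multiples
    of the largest voxel pitch.  ``eps_factor`` likewise scales eps off
    the largest pitch when ``eps_um`` is not given explicitly, so
    defaults adapt to each stack's anisotropy.
    """

    manifest: str
    threshold_method: str = "otsu"
    pooled_histogram: bool = False
    eps_um: Optional[float] = Field(default=None, gt=0)
    eps_factor: float = Field(default=2.0, gt=0)
    min_points: int = Field(default=10, ge=1)
    max_points: int = Field(default=200_000, ge=4)
    cell_factor: float = Field(default=3.0, gt=0)
    body_factor: float = Field(default=1e6, gt=0)
    pitch_override: Optional[Pitch] = None
    out_dir: str = "lumenfill_run"
    save_intermediates: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.cell_factor >= self.body_factor:
            raise ValueError("cell_factor must be < body_factor")
        if self.threshold_method not in ("otsu", "mean", "percentile"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.pitch_override is not None and any(p <= 0 for p in self.pitch_override):
            raise ValueError("pitch_override entries must be > 0")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration, applying documented defaults."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig(**data)


def _pitch_from_sidecar(path: Path) -> Optional[Pitch]:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        return None
    meta = json.loads(sidecar.read_text())
    if "pitch_um" in meta:
        dz, dy, dx = meta["pitch_um"]
        return (float(dz), float(dy), float(dx))
    return None


def _pitch_from_ome(tif: tifffile.TiffFile) -> Optional[Pitch]:
    if not tif.ome_metadata:
        return None
    try:
        meta = tifffile.xml2dict(tif.ome_metadata)
        px = meta["OME"]["Image"]
        if isinstance(px, list):
            px = px[0]
        px = px["Pixels"]
        return (
            float(px["PhysicalSizeZ"]),
            float(px["PhysicalSizeY"]),
            float(px["PhysicalSizeX"]),
        )
    except (KeyError, TypeError, ValueError):
        return None


def read_stack(path: str | Path, pitch_override: Optional[Pitch] = None) -> ImageStack:
    """Read a multi-page TIFF / OME-TIFF z-stack with voxel pitch.

    RGB pages are retained as a trailing channel axis; the segmentation
    stage collapses them.  Pitch resolution order: ``pitch_override``,
    sidecar JSON (``<stem>.json``), OME-XML.  Missing pitch is an error,
    never a silent default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        ome_pitch = _pitch_from_ome(tif)
    if data.ndim == 2:
        data = data[None]
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: unsupported TIFF shape {data.shape}")
    if data.ndim == 4 and data.shape[-1] not in (3, 4):
        raise ValueError(f"{path}: trailing axis of size {data.shape[-1]} is not RGB(A)")
    if data.ndim == 4 and data.shape[-1] == 4:
        data = data[..., :3]  # drop alpha

    pitch = pitch_override or _pitch_from_sidecar(path) or ome_pitch
    if pitch is None:
        raise ValueError(
            f"{path}: no voxel pitch found (no override, sidecar JSON, or OME metadata)"
        )
    bit_depth = 8 if data.dtype == np.uint8 else 16
    return ImageStack(voxels=data, pitch=tuple(pitch), bit_depth=bit_depth, label=path.stem)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a greyscale stack as multi-page TIFF with a pitch sidecar.

    Round-trips bit-exactly for integer data via :func:`read_stack`.
    """
    path = Path(path)
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    data = np.clip(np.round(stack.voxels), 0, np.iinfo(dtype).max).astype(dtype)
    tifffile.imwrite(path, data, photometric="minisblack")
    path.with_suffix(".json").write_text(
        json.dumps({"pitch_um": list(stack.pitch), "bit_depth": stack.bit_depth,
                    "label": stack.label}, indent=2)
    )
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest CSV with columns (stack_path, group, spheroid_id).

    Relative stack paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"stack_path", "group", "spheroid_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    df["stack_path"] = [
        str((path.parent / p).resolve()) if not Path(p).is_absolute() else p
        for p in df["stack_path"]
    ]
    return df
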