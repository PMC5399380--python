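"""Greyscale conversion, intensity profile, thresholding, binarisation.

The cell-presence threshold is computed from the greyscale distribution
profile of a whole stack by Otsu's criterion: the threshold maximising
the between-class intensity variance of the histogram.  Ties are broken
toward the lowest maximising threshold so the result is deterministic.
A mean and a percentile rule are available as alternatives behind the
same interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stackio import ImageStack

__all__ = [
    "IntensityHistogram",
    "BinaryMask",
    "to_greyscale",
    "build_profile",
    "compute_threshold",
    "binarize",
]


@dataclass(frozen=True)
class IntensityHistogram:
    """Greyscale distribution profile of one stack (or a pooled set)."""

    bin_edges: np.ndarray  # len n_bins + 1
    counts: np.ndarray  # len n_bins, non-negative ints
    n_voxels: int

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.n_voxels:
            raise ValueError("histogram counts do not sum to n_voxels")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class BinaryMask:
    """Per-voxel cell-presence indicator plus the threshold that made it."""

    mask: np.ndarray  # 3D bool, (z, y, x)
    threshold_used: float


def to_greyscale(stack: ImageStack) -> ImageStack:
    """Collapse RGB stacks by per-voxel channel maximum.

    The DAPI signal may have been stored in any single channel of an RGB
    export; the channel maximum recovers it regardless.  Single-channel
    input is returned unchanged.
    """
    if not stack.is_rgb:
        return stack
    if stack.voxels.shape[-1] != 3:
        raise ValueError(f"unsupported channel count {stack.voxels.shape[-1]}")
    grey = stack.voxels.max(axis=-1)
    return ImageStack(voxels=grey, pitch=stack.pitch, bit_depth=stack.bit_depth,
                      label=stack.label)


def default_bin_count(stack: ImageStack) -> int:
    """256 bins for 8-bit data, 65,536 for 16-bit."""
    return 256 if stack.bit_depth == 8 else 65_536


def build_profile(stack: ImageStack, n_bins: int | None = None) -> IntensityHistogram:
    """Histogram of all voxels of all z-sections of one stack."""
    if stack.is_rgb:
        raise ValueError("build_profile requires a greyscale stack; call to_greyscale first")
    if stack.voxels.size == 0:
        raise ValueError("empty stack")
    if n_bins is None:
        n_bins = default_bin_count(stack)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vox = stack.voxels.ravel()
    lo, hi = float(vox.min()), float(vox.max())
    if hi == lo:
        hi = lo + 1.0  # single-valued stack still yields a valid (degenerate) profile
    counts, edges = np.histogram(vox, bins=n_bins, range=(lo, hi))
    return IntensityHistogram(bin_edges=edges, counts=counts, n_voxels=int(vox.size))


def pooled_profile(stacks: list[ImageStack], n_bins: int | None = None) -> IntensityHistogram:
    """One histogram over every voxel of several stacks (global-threshold mode)."""
    if not stacks:
        raise ValueError("no stacks to pool")
    if n_bins is None:
        n_bins = max(default_bin_count(s) for s in stacks)
    allv = np.concatenate([s.voxels.ravel() for s in stacks])
    lo, hi = float(allv.min()), float(allv.max())
    if hi == lo:
        hi = lo + 1.0
    counts, edges = np.histogram(allv, bins=n_bins, range=(lo, hi))
    return IntensityHistogram(bin_edges=edges, counts=counts, n_voxels=int(allv.size))


def _otsu_threshold(hist: IntensityHistogram) -> float:
    """Between-class-variance maximiser over histogram bin centres.

    Candidate thresholds are the bin centres; a threshold at centre t
    assigns bins with centre <= t to the background class.  Returns the
    lowest candidate achieving the maximal between-class variance.
    """
    counts = hist.counts.astype(np.float64)
    centers = hist.bin_centers
    total = counts.sum()
    w0 = np.cumsum(counts)  # background weight up to and including bin i
    w1 = total - w0
    mu_cum = np.cumsum(counts * centers)
    mu_total = mu_cum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_total - mu_cum) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    # exclude the last bin: thresholding there leaves no foreground class
    between[-1] = -np.inf
    best = int(np.argmax(between))  # argmax returns the first (lowest) maximiser
    return float(centers[best])


def compute_threshold(hist: IntensityHistogram, method: str = "otsu",
                      percentile: float = 50.0) -> float:
    """Cell-presence threshold from an intensity profile.

    ``otsu`` (default) maximises between-class variance; ``mean`` is the
    intensity-weighted histogram mean; ``percentile`` is the given
    histogram percentile.  Raises on a single-valued (blank or
    saturated) profile, which cannot be split into two classes.
    """
    if int((hist.counts > 0).sum()) < 2:
        raise ValueError("degenerate histogram: fewer than 2 occupied bins "
                         "(blank or saturated stack)")
    if method == "otsu":
        return _otsu_threshold(hist)
    if method == "mean":
        w = hist.counts.astype(float)
        return float((w * hist.bin_centers).sum() / w.sum())
    if method == "percentile":
        cum = np.cumsum(hist.counts) / hist.counts.sum()
        idx = int(np.searchsorted(cum, percentile / 100.0))
        return float(hist.bin_centers[min(idx, len(hist.bin_centers) - 1)])
    raise ValueError(f"unknown threshold method {method!r}")


def binarize(stack: ImageStack, threshold: float) -> BinaryMask:
    """Strictly-greater-than binarisation; records the threshold used."""
    if stack.is_rgb:
        raise ValueError("binarize requires a greyscale stack")
    return BinaryMask(mask=stack.voxels > threshold, threshold_used=float(threshold))
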