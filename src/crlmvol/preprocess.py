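"""Intensity normalization and slice extraction feeding the 2-D models.

Two steps, applied in a fixed order: (1) clip Hounsfield values to the
abdominal soft-tissue window [−100, 400] HU so all scans share a common
range around the liver; (2) histogram-equalize the clipped volume so each
scan uses that range evenly.  Equalization is the empirical CDF over
equal-width bins of the clipped window, computed per whole volume (not per
slice, so intensity keeps one meaning across the slices of a scan) and is
monotone non-decreasing in input HU with output in [0, 1].

The 2-D segmentation models consume axial slices; `extract_slices` /
`restack_slices` are an exact inverse pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ct_io import CTVolume, GeometryError, MaskVolume

__all__ = [
    "DEFAULT_CLIP_LO",
    "DEFAULT_CLIP_HI",
    "DEFAULT_BINS",
    "NormalizedVolume",
    "clip_hu",
    "equalize_histogram",
    "normalize",
    "extract_slices",
    "restack_slices",
]

DEFAULT_CLIP_LO = -100.0
DEFAULT_CLIP_HI = 400.0
DEFAULT_BINS = 256


@dataclass
class NormalizedVolume:
    """Unit-interval intensity grid plus the exact parameters that made it."""

    scan_id: str
    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    provenance: dict

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(f"normalized grid must be rank 3, got {self.values.ndim}")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("normalized values must lie in [0, 1]")


def clip_hu(
    volume: CTVolume,
    lo: float = DEFAULT_CLIP_LO,
    hi: float = DEFAULT_CLIP_HI,
) -> CTVolume:
    """Clamp HU values into [lo, hi]; idempotent, geometry unchanged."""
    if lo >= hi:
        raise ValueError(f"clip window requires lo < hi, got [{lo}, {hi}]")
    return CTVolume(
        scan_id=volume.scan_id,
        voxels=np.clip(volume.voxels, lo, hi),
        spacing_mm=volume.spacing_mm,
        patient_id=volume.patient_id,
    )


def equalize_histogram(
    volume: CTVolume,
    bins: int = DEFAULT_BINS,
    lo: float = DEFAULT_CLIP_LO,
    hi: float = DEFAULT_CLIP_HI,
) -> NormalizedVolume:
    """Map clipped HU through the volume's empirical CDF onto [0, 1].

    The CDF is taken over `bins` equal-width bins spanning [lo, hi]; the
    input is clipped to that window first (applying the default window if
    the caller has not already done so).  Voxels in the same bin map to the
    same output, so the mapping is monotone non-decreasing in HU.

    A constant-valued volume has a degenerate histogram; it maps to 0.5
    everywhere with a warning.
    """
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    clipped = np.clip(np.asarray(volume.voxels, dtype=np.float64), lo, hi)
    provenance = {"clip_lo": float(lo), "clip_hi": float(hi), "bins": int(bins)}
    if clipped.max() == clipped.min():
        warnings.warn(
            f"scan {volume.scan_id}: constant-valued volume, equalization is "
            "degenerate; returning 0.5 everywhere",
            stacklevel=2,
        )
        return NormalizedVolume(
            scan_id=volume.scan_id,
            values=np.full(clipped.shape, 0.5, dtype=np.float32),
            spacing_mm=volume.spacing_mm,
            provenance=provenance,
        )
    hist, edges = np.histogram(clipped, bins=bins, range=(lo, hi))
    cdf = np.cumsum(hist) / clipped.size
    # bin index of each voxel; right edge of the last bin belongs to it
    idx = np.minimum(((clipped - lo) / (hi - lo) * bins).astype(np.int64), bins - 1)
    out = cdf[idx].astype(np.float32)
    return NormalizedVolume(
        scan_id=volume.scan_id,
        values=out,
        spacing_mm=volume.spacing_mm,
        provenance=provenance,
    )


def normalize(
    volume: CTVolume,
    lo: float = DEFAULT_CLIP_LO,
    hi: float = DEFAULT_CLIP_HI,
    bins: int = DEFAULT_BINS,
) -> NormalizedVolume:
    """The full two-step normalization: clip then equalize."""
    return equalize_histogram(clip_hu(volume, lo, hi), bins=bins, lo=lo, hi=hi)


def _check_mask_alignment(values: np.ndarray, spacing, mask: MaskVolume) -> None:
    if mask.labels.shape != values.shape:
        raise GeometryError(
            f"mask shape {mask.labels.shape} does not match volume shape {values.shape}"
        )
    if not np.allclose(mask.spacing_mm, spacing, rtol=1e-4):
        raise GeometryError(
            f"mask spacing {mask.spacing_mm} does not match volume spacing {spacing}"
        )


def extract_slices(
    volume: NormalizedVolume,
    masks: list[MaskVolume] | None = None,
    axis: int = 2,
) -> list[tuple[np.ndarray, ...]]:
    """One (image, mask, ...) tuple per index along `axis`, order preserved.

    Axial slicing (axis=2, the z axis) is the default.  Restacking the
    image planes with `restack_slices` reproduces the volume exactly.
    """
    masks = masks or []
    for m in masks:
        _check_mask_alignment(volume.values, volume.spacing_mm, m)
    n = volume.values.shape[axis]
    out = []
    for k in range(n):
        img = np.take(volume.values, k, axis=axis)
        planes = tuple(np.take(m.labels, k, axis=axis) for m in masks)
        out.append((img, *planes))
    return out


def restack_slices(slices: list[np.ndarray], axis: int = 2) -> np.ndarray:
    """Inverse of `extract_slices` for one channel: stack planes along `axis`."""
    if not slices:
        raise ValueError("cannot restack an empty slice list")
    return np.stack(slices, axis=axis)
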