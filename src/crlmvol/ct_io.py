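"""CT volume and mask containers with NIfTI-backed I/O.

Conventions (fixed package-wide so the segmentation, metrics and volumetry
code can never disagree about geometry):

* voxel grids are rank-3 numpy arrays indexed ``[x, y, z]`` with axial
  slices along ``z``; indexing is 0-based;
* ``spacing_mm`` is the per-axis voxel size in millimetres and must be
  strictly positive — a missing or zero spacing is an error, never a
  silent default;
* nothing in this module resamples, reorients or rescales: any geometry
  mismatch between paired images is raised as an error.

Hounsfield volumes are written to disk as signed 16-bit integers, masks as
unsigned 8-bit {0, 1}.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "MaskVolume",
    "GeometryError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_report",
]


class GeometryError(ValueError):
    """Shape/spacing disagreement between images that must be aligned."""


def _validate_spacing(spacing_mm: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 or not np.isfinite(s) for s in spacing):
        raise ValueError(f"spacing must be 3 strictly positive values, got {spacing_mm}")
    return spacing  # type: ignore[return-value]


@dataclass
class CTVolume:
    """3-D grid of Hounsfield-unit values plus voxel spacing in mm."""

    scan_id: str
    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    patient_id: str | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"CT grid must be rank 3, got rank {self.voxels.ndim}")
        self.spacing_mm = _validate_spacing(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class MaskVolume:
    """Binary label grid aligned voxel-for-voxel with a CTVolume."""

    scan_id: str
    labels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"mask grid must be rank 3, got rank {self.labels.ndim}")
        values = np.unique(self.labels)
        if not np.isin(values, (0, 1)).all():
            raise ValueError(f"mask labels must be binary, found values {values.tolist()}")
        self.labels = self.labels.astype(np.uint8)
        self.spacing_mm = _validate_spacing(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.labels))


def _affine_from_spacing(spacing_mm: Sequence[float]) -> np.ndarray:
    return np.diag(list(spacing_mm) + [1.0])


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3-D image, got {data.ndim} dimensions {data.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel spacing {zooms} in header")
    return data, tuple(float(z) for z in zooms)  # type: ignore[return-value]


def read_volume(path: str | Path, scan_id: str | None = None) -> CTVolume:
    """Read a CT volume from NIfTI; spacing is taken from the header."""
    data, spacing = _load_nifti(path)
    sid = scan_id if scan_id is not None else Path(path).name.split(".")[0]
    return CTVolume(scan_id=sid, voxels=data, spacing_mm=spacing)


def write_volume(volume: CTVolume, path: str | Path) -> None:
    """Write HU values as int16 NIfTI with spacing in the header."""
    data = np.asarray(np.rint(volume.voxels), dtype=np.int16)
    img = nib.Nifti1Image(data, _affine_from_spacing(volume.spacing_mm))
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def read_mask(
    path: str | Path,
    reference: CTVolume | None = None,
    label: int | None = None,
    scan_id: str | None = None,
) -> MaskVolume:
    """Read a binary mask; optionally check alignment against a reference CT.

    Files containing labels other than {0, 1} are rejected unless `label`
    selects which value becomes foreground.
    """
    data, spacing = _load_nifti(path)
    present = np.unique(data)
    if label is not None:
        data = (data == label).astype(np.uint8)
    elif not np.isin(present, (0, 1)).all():
        raise ValueError(
            f"{path}: mask is not binary; labels present: "
            f"{{{', '.join(str(int(v)) for v in present)}}} — pass `label` to select one"
        )
    sid = scan_id if scan_id is not None else Path(path).name.split(".")[0]
    mask = MaskVolume(scan_id=sid, labels=data.astype(np.uint8), spacing_mm=spacing)
    if reference is not None:
        if mask.shape != reference.shape:
            raise GeometryError(
                f"{path}: mask shape {mask.shape} does not match reference CT "
                f"shape {reference.shape}"
            )
        if not np.allclose(mask.spacing_mm, reference.spacing_mm, rtol=1e-4):
            raise GeometryError(
                f"{path}: mask spacing {mask.spacing_mm} does not match reference "
                f"CT spacing {reference.spacing_mm}"
            )
    return mask


def write_mask(mask: MaskVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.uint8), _affine_from_spacing(mask.spacing_mm))
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))


def write_report(report: Any, path: str | Path, format: str = "json") -> None:
    """Serialize a report record (dict or list of dicts) as JSON or CSV.

    JSON keeps full float precision.  CSV writes one row per record; an
    empty record list still produces a valid file (header only when the
    columns are known).
    """
    path = Path(path)
    if format == "json":
        payload = report.to_dict() if hasattr(report, "to_dict") else report
        path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")
    elif format == "csv":
        rows = report if isinstance(report, list) else [report]
        rows = [r.to_dict() if hasattr(r, "to_dict") else dict(r) for r in rows]
        with open(path, "w", newline="") as fh:
            if not rows:
                fh.write("")
                return
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            for row in rows:
                writer.writerow({k: _csv_cell(v) for k, v in row.items()})
    else:
        raise ValueError(f"unknown report format {format!r}; use 'json' or 'csv'")


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _csv_cell(v: Any) -> Any:
    if isinstance(v, float):
        return repr(v)  # >= 10 significant digits
    if isinstance(v, (list, tuple)):
        return json.dumps(v)
    return v
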