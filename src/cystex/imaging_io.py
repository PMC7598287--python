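"""Volume / mask I/O and region-of-interest extraction.

Axis convention, fixed for the whole package: arrays are indexed
``(slice, row, column)``, 0-based.  "Horizontal" always means along the
column axis within a slice; "vertical" along the row axis.  Texture
matrices are computed per slice and accumulated over the slices a lesion
spans, so the ROI of a lesion is the full 3D set of in-mask voxels.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom

from .errors import DataError, EmptyROIError, FormatError, UnsupportedDataError

POSITIVE = "positive"  # endometrioma-like (heterogeneous) class
NEGATIVE = "negative"  # hemorrhagic-cyst-like (smooth) class


@dataclasses.dataclass
class LesionVolume:
    """One lesion: intensity grid, binary mask, geometry and label.

    ``intensities`` holds non-negative integers in arbitrary scanner
    units; ``mask`` is a boolean grid of the same shape with at least one
    true voxel.  ``voxel_spacing`` is mm per axis in (slice, row, column)
    order.
    """

    intensities: np.ndarray
    mask: np.ndarray
    voxel_spacing: tuple[float, float, float] = (4.4, 0.75, 0.75)
    lesion_id: str = "lesion"
    class_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.intensities.ndim != 3:
            raise FormatError("intensity grid must be 3D (slice, row, column)")
        if self.intensities.shape != self.mask.shape:
            raise FormatError(
                f"mask shape {self.mask.shape} != intensity shape "
                f"{self.intensities.shape}"
            )
        if not self.mask.any():
            raise EmptyROIError(f"lesion {self.lesion_id!r}: mask is empty")
        if self.class_label not in (None, POSITIVE, NEGATIVE):
            raise DataError(f"unknown class label {self.class_label!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclasses.dataclass
class SliceView:
    """One axial slice of the ROI, cropped to its in-slice bounding box."""

    index: int  # slice position in the parent volume
    image: np.ndarray  # 2D intensities, bounding-box crop
    mask: np.ndarray  # 2D booleans, same crop


@dataclasses.dataclass
class ROI:
    """In-mask voxel values plus per-slice cropped views of a lesion."""

    values: np.ndarray  # all in-mask intensities (1D, raw units)
    slices: list[SliceView]
    lesion_id: str = "lesion"

    @property
    def n_voxels(self) -> int:
        return int(self.values.size)


def read_volume(path, format: str = "nifti"):
    """Read an intensity grid from disk.

    Returns ``(grid, voxel_spacing)`` with the grid as integers in
    (slice, row, column) order.  ``format`` is ``"nifti"`` for .nii/.nii.gz
    files or ``"dicom_series"`` for a directory of single-frame grayscale
    DICOM slices sharing one orientation.
    """
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise FormatError(f"unknown volume format {format!r}")


def _read_nifti(path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D NIfTI volume, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if np.issubdtype(data.dtype, np.floating):
        data = np.rint(data).astype(np.int64)
    return data, spacing


def _read_dicom_series(path):
    files = sorted(p for p in Path(path).iterdir() if p.is_file())
    if not files:
        raise FormatError(f"{path}: no files in DICOM series directory")
    datasets = [pydicom.dcmread(str(f)) for f in files]

    orientations = []
    for ds in datasets:
        if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
            raise UnsupportedDataError(
                f"{path}: non-grayscale DICOM (SamplesPerPixel != 1)"
            )
        orientations.append(tuple(float(v) for v in ds.ImageOrientationPatient))
    if len(set(orientations)) > 1:
        raise FormatError(f"{path}: slices have mixed image orientations")

    # Sort along the slice normal; fall back to instance number.
    row_dir = np.array(orientations[0][:3])
    col_dir = np.array(orientations[0][3:])
    normal = np.cross(row_dir, col_dir)

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(np.dot(np.asarray(pos, dtype=float), normal))
        return float(ds.InstanceNumber)

    datasets.sort(key=sort_key)

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise FormatError(f"{path}: slices have mixed matrix sizes {shapes}")
    grid = np.rint(np.stack(slices, axis=0)).astype(np.int64)

    ds0 = datasets[0]
    pixel_spacing = getattr(ds0, "PixelSpacing", [1.0, 1.0])
    if len(datasets) > 1:
        z = [sort_key(ds) for ds in datasets]
        dz = float(np.mean(np.diff(z)))
        if dz == 0.0:
            dz = float(getattr(ds0, "SliceThickness", 1.0))
    else:
        dz = float(getattr(ds0, "SliceThickness", 1.0))
    spacing = (abs(dz), float(pixel_spacing[0]), float(pixel_spacing[1]))
    return grid, spacing


def read_mask(path) -> np.ndarray:
    """Read a binary lesion mask stored as NIfTI; nonzero means in-mask."""
    data, _ = _read_nifti(path)
    return data != 0


def extract_roi(volume: LesionVolume) -> ROI:
    """Collect in-mask voxels and per-slice bounding-box crops.

    The 1D value multiset feeds the first-order histogram features; the
    cropped 2D slice views feed the matrix, gradient and wavelet families.
    The total voxel count is conserved across the per-slice partition.
    """
    mask = volume.mask
    if not mask.any():
        raise EmptyROIError(f"lesion {volume.lesion_id!r}: empty ROI")
    values = volume.intensities[mask]
    slices: list[SliceView] = []
    for z in range(mask.shape[0]):
        m = mask[z]
        if not m.any():
            continue
        rows = np.flatnonzero(m.any(axis=1))
        cols = np.flatnonzero(m.any(axis=0))
        r0, r1 = rows[0], rows[-1] + 1
        c0, c1 = cols[0], cols[-1] + 1
        slices.append(
            SliceView(
                index=z,
                image=volume.intensities[z, r0:r1, c0:c1],
                mask=m[r0:r1, c0:c1],
            )
        )
    return ROI(values=values, slices=slices, lesion_id=volume.lesion_id)


def read_cohort(manifest_path) -> list[LesionVolume]:
    """Load every lesion listed in a cohort manifest CSV.

    The manifest has columns ``lesion_id, image, mask, class_label`` with
    file paths relative to the manifest's directory (as written by
    :func:`cystex.phantom.write_cohort`).
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    required = {"lesion_id", "image", "mask", "class_label"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"manifest is missing columns {sorted(missing)}")
    root = manifest_path.parent
    lesions = []
    for rec in table.itertuples(index=False):
        grid, spacing = read_volume(root / rec.image, "nifti")
        mask = read_mask(root / rec.mask)
        lesions.append(
            LesionVolume(
                intensities=grid,
                mask=mask,
                voxel_spacing=spacing,
                lesion_id=str(rec.lesion_id),
                class_label=str(rec.class_label),
            )
        )
    return lesions


def labels_from(lesions: Sequence[LesionVolume]) -> pd.Series:
    """Boolean positive-class labels indexed by lesion id."""
    idx = [les.lesion_id for les in lesions]
    vals = []
    for les in lesions:
        if les.class_label is None:
            raise DataError(f"lesion {les.lesion_id!r} has no class label")
        vals.append(les.class_label == POSITIVE)
    return pd.Series(vals, index=idx, name="label")
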