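"""Scalar volume container and medical-image I/O.

A :class:`ScalarVolume` is a 3D grid of scalar values (Hounsfield units,
normalized intensity, or probability) plus the voxel spacing in millimetres
and a world origin. World coordinates follow ``world = index * spacing +
origin`` with axes ordered (x, y, z), z being the through-plane axis, and
0-based indices.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ScalarVolume:
    """3D scalar grid with world metadata.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values. HU for CT data, [0, 1] for normalized/probability data.
    spacing : tuple of 3 floats
        Voxel edge length per axis, mm. Strictly positive.
    origin : tuple of 3 floats
        World position of voxel (0, 0, 0), mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def like(self, values: np.ndarray) -> "ScalarVolume":
        """New volume with the same grid metadata but different values."""
        return ScalarVolume(values, self.spacing, self.origin)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm coordinates."""
        return np.asarray(idx, dtype=float) * np.array(self.spacing) + np.array(self.origin)

    def congruent(self, other: "ScalarVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


def save_nifti(vol: ScalarVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI; spacing and origin go into the affine."""
    import nibabel as nib

    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), affine)
    nib.save(img, os.fspath(path))


def load_nifti(path: str | os.PathLike) -> ScalarVolume:
    """Read a NIfTI volume; only diagonal (axis-aligned) affines are supported."""
    import nibabel as nib

    img = nib.load(os.fspath(path))
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise ValueError("only axis-aligned NIfTI volumes are supported")
    spacing = tuple(np.abs(np.diag(rot)))
    origin = tuple(affine[:3, 3])
    return ScalarVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def load_dicom_series(directory: str | os.PathLike) -> ScalarVolume:
    """Read an axial DICOM series into a HU volume.

    Slices are sorted by ImagePositionPatient z (fallback: InstanceNumber) and
    the rescale slope/intercept is applied so values are Hounsfield units.
    """
    import pydicom

    directory = os.fspath(directory)
    datasets = []
    for name in sorted(os.listdir(directory)):
        path = os.path.join(directory, name)
        if not os.path.isfile(path):
            continue
        try:
            datasets.append(pydicom.dcmread(path))
        except Exception:
            continue
    if not datasets:
        raise ValueError(f"no readable DICOM files in {directory}")

    def sort_key(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return int(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    first = datasets[0]
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    # pixel_array is (row, col) = (y, x); stack on z then move to (x, y, z)
    values = np.transpose(np.stack(slices, axis=0), (2, 1, 0))
    py, px = (float(v) for v in getattr(first, "PixelSpacing", [1.0, 1.0]))
    if len(datasets) > 1:
        dz = abs(sort_key(datasets[1]) - sort_key(datasets[0])) or 1.0
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    origin = tuple(float(v) for v in getattr(first, "ImagePositionPatient", [0, 0, 0]))
    return ScalarVolume(values, (px, py, dz), origin)
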