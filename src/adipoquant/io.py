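"""Reading MR slice stacks and writing label volumes / quantification tables.

Conventions
-----------
Volumes are stored row-major as ``(rows, cols, slices)`` with 0-based indices;
the slice axis is last. ``in_plane_spacing`` is millimetres per pixel along
(row, col); ``slice_thickness`` is the inter-plane spacing in millimetres.

Label volumes are integer coded: 0 background, 1 SAT, 2 VAT, 3 skin/abdominal
wall, 4 organ. This coding is fixed so files interchange bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .errors import GeometryError, ValidationError

#: Fixed integer coding of depot labels in NIfTI output.
LABEL_CODES = {
    "background": 0,
    "sat": 1,
    "vat": 2,
    "skin_wall": 3,
    "organ": 4,
}

LABEL_NAMES = {v: k for k, v in LABEL_CODES.items()}


@dataclass
class ImageVolume:
    """A 3-D stack of transverse MR slices with acquisition geometry.

    Parameters
    ----------
    voxels : ndarray, shape (rows, cols, slices)
        Scalar intensities in arbitrary scanner units.
    in_plane_spacing : (float, float)
        Pixel size in mm along (row, col).
    slice_thickness : float
        Inter-plane spacing in mm.
    slice_labels : sequence of str, optional
        Ordered per-slice names (e.g. an anatomical range such as L1–L5).
    """

    voxels: np.ndarray
    in_plane_spacing: tuple[float, float]
    slice_thickness: float
    slice_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[:, :, None]
        if self.voxels.ndim != 3:
            raise GeometryError(
                f"expected a 2-D slice or 3-D stack, got ndim={self.voxels.ndim}"
            )
        if self.voxels.shape[2] < 1:
            raise GeometryError("volume must contain at least one slice")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("volume intensities must all be finite")
        self.in_plane_spacing = (
            float(self.in_plane_spacing[0]),
            float(self.in_plane_spacing[1]),
        )
        self.slice_thickness = float(self.slice_thickness)
        if min(self.in_plane_spacing) <= 0 or self.slice_thickness <= 0:
            raise GeometryError("voxel spacing must be strictly positive")
        if self.slice_labels is not None:
            self.slice_labels = list(self.slice_labels)
            if len(self.slice_labels) != self.n_slices:
                raise GeometryError(
                    "slice_labels length does not match the number of slices"
                )

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.voxels.shape[:2]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm³."""
        return (
            self.in_plane_spacing[0] * self.in_plane_spacing[1] * self.slice_thickness
        )

    def get_slice(self, index: int) -> np.ndarray:
        return self.voxels[:, :, index]


@dataclass
class DepotLabelVolume:
    """Per-voxel depot labels sharing the geometry of a source :class:`ImageVolume`."""

    labels: np.ndarray
    in_plane_spacing: tuple[float, float]
    slice_thickness: float
    slice_labels: Sequence[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim == 2:
            self.labels = self.labels[:, :, None]
        if self.labels.ndim != 3:
            raise GeometryError("label volume must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise ValidationError("labels must be integers")
            self.labels = self.labels.astype(np.uint8)
        valid = set(LABEL_CODES.values())
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise ValidationError(
                f"label volume contains values outside {sorted(valid)}: "
                f"{sorted(present - valid)}"
            )
        self.labels = self.labels.astype(np.uint8)
        self.in_plane_spacing = (
            float(self.in_plane_spacing[0]),
            float(self.in_plane_spacing[1]),
        )
        self.slice_thickness = float(self.slice_thickness)
        if min(self.in_plane_spacing) <= 0 or self.slice_thickness <= 0:
            raise GeometryError("voxel spacing must be strictly positive")

    @property
    def n_slices(self) -> int:
        return self.labels.shape[2]

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of one depot by name ('sat', 'vat', ...)."""
        return self.labels == LABEL_CODES[name]

    def count(self, name: str) -> int:
        return int(np.count_nonzero(self.mask(name)))


def _read_dicom_series(directory: Path) -> ImageVolume:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue  # skip non-DICOM files (e.g. DICOMDIR, sidecars)
        if not hasattr(ds, "pixel_array"):
            continue
        datasets.append((p.name, ds))
    if not datasets:
        raise GeometryError(f"no readable DICOM slices found in {directory}")

    def sort_key(item):
        name, ds = item
        pos = getattr(ds, "ImagePositionPatient", None)
        z = float(pos[2]) if pos is not None else 0.0
        inst = int(getattr(ds, "InstanceNumber", 0))
        return (z, inst)

    datasets.sort(key=sort_key)

    ref_name, ref = datasets[0]
    if not hasattr(ref, "PixelSpacing"):
        raise GeometryError(f"slice {ref_name} is missing the PixelSpacing tag")
    spacing = (float(ref.PixelSpacing[0]), float(ref.PixelSpacing[1]))
    thickness = getattr(ref, "SpacingBetweenSlices", None) or getattr(
        ref, "SliceThickness", None
    )
    if thickness is None:
        raise GeometryError(
            f"slice {ref_name} is missing SliceThickness/SpacingBetweenSlices"
        )
    thickness = float(thickness)
    shape = ref.pixel_array.shape

    slices = []
    for name, ds in datasets:
        arr = ds.pixel_array.astype(float)
        if arr.shape != shape:
            raise GeometryError(
                f"slice {name} has matrix size {arr.shape}, expected {shape}"
            )
        if not hasattr(ds, "PixelSpacing"):
            raise GeometryError(f"slice {name} is missing the PixelSpacing tag")
        sp = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
        if sp != spacing:
            raise GeometryError(
                f"slice {name} has pixel spacing {sp}, expected {spacing}"
            )
        slices.append(arr)

    return ImageVolume(
        voxels=np.stack(slices, axis=-1),
        in_plane_spacing=spacing,
        slice_thickness=thickness,
    )


def _read_array_with_metadata(path: Path) -> ImageVolume:
    """Read a ``.npy`` array with a JSON metadata sidecar (``<stem>.json``)."""
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise GeometryError(f"metadata sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    for key in ("in_plane_spacing", "slice_thickness"):
        if key not in meta:
            raise GeometryError(f"metadata sidecar is missing required key {key!r}")
    return ImageVolume(
        voxels=np.load(path),
        in_plane_spacing=tuple(meta["in_plane_spacing"]),
        slice_thickness=meta["slice_thickness"],
        slice_labels=meta.get("slice_labels"),
    )


def read_volume(source: str | Path) -> ImageVolume:
    """Read an MR slice stack from a DICOM series directory or an array file.

    A directory is treated as a DICOM series (slices ordered by slice
    position, ties broken by instance number). A ``.npy`` file is read with
    its JSON sidecar; ``.nii``/``.nii.gz`` files are read with nibabel, taking
    spacing from the affine.
    """
    source = Path(source)
    if source.is_dir():
        return _read_dicom_series(source)
    if not source.exists():
        raise GeometryError(f"input {source} does not exist")
    if source.suffix == ".npy":
        return _read_array_with_metadata(source)
    if source.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(source))
        zooms = img.header.get_zooms()
        return ImageVolume(
            voxels=np.asarray(img.dataobj, dtype=float),
            in_plane_spacing=(float(zooms[0]), float(zooms[1])),
            slice_thickness=float(zooms[2]) if len(zooms) > 2 else 1.0,
        )
    raise GeometryError(f"unrecognised input format: {source}")


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write an intensity volume as ``.npy`` + JSON metadata sidecar."""
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    np.save(path, volume.voxels)
    meta = {
        "in_plane_spacing": list(volume.in_plane_spacing),
        "slice_thickness": volume.slice_thickness,
    }
    if volume.slice_labels is not None:
        meta["slice_labels"] = list(volume.slice_labels)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def write_labels(labels: DepotLabelVolume, path: str | Path) -> Path:
    """Write a depot label volume as integer-coded NIfTI-1.

    The affine encodes voxel spacing on its diagonal; a read-back with
    :func:`read_labels` reproduces labels and spacing bit-exactly.
    """
    path = Path(path)
    affine = np.diag(
        [
            labels.in_plane_spacing[0],
            labels.in_plane_spacing[1],
            labels.slice_thickness,
            1.0,
        ]
    )
    img = nib.Nifti1Image(labels.labels.astype(np.uint8), affine)
    nib.save(img, str(path))
    return path


def read_labels(path: str | Path) -> DepotLabelVolume:
    """Read back a label volume written by :func:`write_labels`."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    return DepotLabelVolume(
        labels=np.asarray(img.dataobj).astype(np.uint8),
        in_plane_spacing=(float(zooms[0]), float(zooms[1])),
        slice_thickness=float(zooms[2]) if len(zooms) > 2 else 1.0,
    )
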