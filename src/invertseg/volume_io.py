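"""Reading, writing and geometric normalization of NIfTI volumes.

The two in-memory containers of the package live here:

``Volume``
    a 3-D scalar intensity grid with voxel spacing (mm), a 4x4
    voxel-to-world affine and a modality tag.
``LabelMap``
    a 3-D integer class-id grid on the same kind of grid, plus a
    vocabulary mapping ids to class names (0 is reserved for background).

All volumes are reoriented to the closest-to-RAS axis order on load so
that sided anatomy (left/right kidney, left/right lung) is well defined:
under the canonical affine the first array axis increases toward the
patient's right, i.e. patient-left structures sit at *low* first-axis
indices.

File handling is delegated to :mod:`nibabel`; resampling uses
``scipy.ndimage.map_coordinates`` (linear for intensities,
nearest-neighbor for labels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "LabelMap",
    "read_volume",
    "read_labelmap",
    "write_volume",
    "resample_isotropic",
]

MODALITY_TAGS = ("CT", "T1w", "T2wfs", "other")


class GeometryError(ValueError):
    """Raised when a grid/affine precondition is violated."""


def _check_grid(data: np.ndarray, spacing, affine) -> tuple[np.ndarray, np.ndarray]:
    if data.ndim != 3:
        raise GeometryError(f"expected a 3-D array, got {data.ndim}-D")
    if min(data.shape) < 1:
        raise GeometryError(f"every axis must have length >= 1, got {data.shape}")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or not np.all(spacing > 0):
        raise GeometryError(f"spacing must be 3 strictly positive values, got {spacing}")
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise GeometryError("affine must be 4x4")
    if abs(np.linalg.det(affine)) < 1e-12:
        raise GeometryError("affine must be invertible")
    return spacing, affine


@dataclass
class Volume:
    """3-D scalar intensity grid with physical geometry."""

    data: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray
    modality_tag: str = "other"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing, self.affine = _check_grid(self.data, self.spacing, self.affine)
        if self.modality_tag not in MODALITY_TAGS:
            raise ValueError(
                f"modality_tag must be one of {MODALITY_TAGS}, got {self.modality_tag!r}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same geometry, new intensities (shape must match)."""
        if np.shape(data) != self.data.shape:
            raise GeometryError("replacement data must keep the grid shape")
        return replace(self, data=np.asarray(data))


@dataclass
class LabelMap:
    """3-D integer class-id grid plus an id -> name vocabulary."""

    data: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray
    vocabulary: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.array_equal(self.data, np.round(self.data)):
                raise ValueError("label data must be integer-valued")
            self.data = self.data.astype(np.int32)
        self.spacing, self.affine = _check_grid(self.data, self.spacing, self.affine)
        if np.any(self.data < 0):
            raise ValueError("label ids must be non-negative")
        self.vocabulary = {int(k): str(v) for k, v in self.vocabulary.items()}
        present = set(np.unique(self.data).tolist()) - {0}
        missing = present - set(self.vocabulary)
        if missing:
            raise ValueError(f"ids present in data but absent from vocabulary: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def mask(self, class_id: int) -> np.ndarray:
        return self.data == class_id

    def class_volume_cm3(self, class_id: int) -> float:
        return float(np.count_nonzero(self.data == class_id)) * self.voxel_volume_mm3 / 1000.0

    def id_of(self, class_name: str) -> int:
        for cid, name in self.vocabulary.items():
            if name == class_name:
                return cid
        raise KeyError(f"class {class_name!r} not in vocabulary")


def _load_canonical(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise GeometryError(f"{path}: expected a 3-D NIfTI image, got shape {img.shape}")
    return nib.as_closest_canonical(img)


def read_volume(path, modality_tag: str = "other") -> Volume:
    """Read a NIfTI (.nii/.nii.gz) file as a :class:`Volume`.

    The image is reoriented to the closest-to-RAS axis order; intensities
    are not rescaled beyond the NIfTI header's own scl_slope/scl_inter.
    """
    img = _load_canonical(path)
    data = np.asarray(img.dataobj)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return Volume(data=data, spacing=spacing, affine=np.asarray(img.affine), modality_tag=modality_tag)


def read_labelmap(path, vocabulary: Mapping[int, str] | None = None) -> LabelMap:
    """Read a NIfTI label map; vocabulary from a JSON sidecar if present.

    The sidecar is ``<stem>.json`` next to the image, holding
    ``{"vocabulary": {"1": "kidney_left", ...}}`` (or a bare id->name map).
    """
    img = _load_canonical(path)
    data = np.asarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError(f"{path}: label map has non-integer voxel values")
        data = rounded.astype(np.int32)
    if vocabulary is None:
        vocabulary = _sidecar_vocabulary(path)
    if vocabulary is None:
        vocabulary = {int(i): f"class_{int(i)}" for i in np.unique(data) if i != 0}
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return LabelMap(data=data, spacing=spacing, affine=np.asarray(img.affine),
                    vocabulary=dict(vocabulary))


def _sidecar_path(path) -> Path:
    path = Path(path)
    stem = path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return path.parent / (stem + ".json")


def _sidecar_vocabulary(path) -> dict[int, str] | None:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        return None
    payload = json.loads(sidecar.read_text())
    vocab = payload.get("vocabulary", payload) if isinstance(payload, dict) else payload
    return {int(k): str(v) for k, v in vocab.items()}


def write_volume(v: Volume | LabelMap, path) -> None:
    """Write a Volume or LabelMap to NIfTI.

    Label maps are written with an integer on-disk dtype and a JSON
    vocabulary sidecar; intensity volumes keep their array dtype.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(v, LabelMap):
        max_id = int(v.data.max(initial=0))
        dtype = np.uint8 if max_id < 256 else np.int16 if max_id < 2**15 else np.int32
        img = nib.Nifti1Image(v.data.astype(dtype), v.affine)
        img.header.set_zooms(tuple(v.spacing))
        nib.save(img, str(path))
        if v.vocabulary:
            _sidecar_path(path).write_text(
                json.dumps({"vocabulary": {str(k): n for k, n in sorted(v.vocabulary.items())}},
                           indent=1)
            )
    else:
        img = nib.Nifti1Image(np.asarray(v.data), v.affine)
        img.header.set_zooms(tuple(v.spacing))
        nib.save(img, str(path))


def resample_isotropic(v: Volume | LabelMap, target_mm: float = 1.0):
    """Resample to an isotropic voxel size (default 1 x 1 x 1 mm).

    Intensity volumes are interpolated linearly, label maps by nearest
    neighbor so that no fractional/novel ids appear.  The new grid keeps
    the position of voxel (0,0,0) and covers the same physical extent to
    within one voxel per axis; output spacing is exactly ``target_mm``.
    """
    if not np.isscalar(target_mm) or target_mm <= 0:
        raise ValueError(f"target_mm must be a positive scalar, got {target_mm!r}")
    target_mm = float(target_mm)
    old_shape = np.asarray(v.data.shape)
    new_shape = np.maximum(1, np.rint(old_shape * v.spacing / target_mm).astype(int))
    # voxel-center aligned at index 0; new index i' samples old index i' * target/spacing
    scale = target_mm / v.spacing
    coords = np.meshgrid(*[np.arange(n) * s for n, s in zip(new_shape, scale)],
                         indexing="ij", sparse=False)
    coords = np.stack([c.astype(np.float64) for c in coords])

    new_affine = v.affine.copy()
    for axis in range(3):
        new_affine[:3, axis] = v.affine[:3, axis] * scale[axis]
    new_spacing = np.full(3, target_mm)

    if isinstance(v, LabelMap):
        out = ndimage.map_coordinates(v.data, coords, order=0, mode="nearest")
        return LabelMap(data=out, spacing=new_spacing, affine=new_affine,
                        vocabulary=dict(v.vocabulary))
    out = ndimage.map_coordinates(np.asarray(v.data, dtype=np.float32), coords,
                                  order=1, mode="nearest")
    return Volume(data=out, spacing=new_spacing, affine=new_affine,
                  modality_tag=v.modality_tag)
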