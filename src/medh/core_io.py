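"""Imaging data model and file round-tripping.

All images in the pipeline are axis-aligned 3D scalar grids with strictly
positive voxel spacing, stored on disk as NIfTI-1.  World coordinates follow
the RAS convention: the world position of voxel index ``i`` is
``origin + i * spacing`` on each axis.  Displacement fields hold one
millimetre-valued 3-vector per voxel and are warped with pull-back
semantics — the output voxel at ``x`` samples the input at ``x + u(x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

__all__ = [
    "GeometryError",
    "Volume3D",
    "LabelVolume",
    "DisplacementField",
    "TumorMask",
    "read_volume",
    "write_volume",
    "read_label_volume",
    "read_field",
    "write_field",
    "read_region_table",
    "write_region_table",
    "validate_region_table",
    "warp",
    "warp_labels",
    "resample_to_grid",
    "same_geometry",
]

#: axis orientation every volume is reoriented to on load
RAS = "RAS"

ATLAS_TO_SUBJECT = "atlas_to_subject"
SUBJECT_TO_ATLAS = "subject_to_atlas"

HEMISPHERES = ("left", "right", "non-hemispheric")


class GeometryError(ValueError):
    """Raised for invalid or mismatched image geometry."""


def _as_triple(x) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64).reshape(-1)
    if arr.size != 3:
        raise GeometryError(f"expected 3 components, got {arr.size}")
    return arr


@dataclass
class Volume3D:
    """Scalar 3D image with voxel spacing and world origin (mm)."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_orientation: str = RAS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(f"non-3D image (ndim={self.data.ndim})")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if np.any(self.spacing <= 0):
            raise GeometryError(f"non-positive spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "Volume3D":
        return replace(self, data=np.asarray(data))

    def world_coordinates(self) -> list[np.ndarray]:
        """Per-axis world coordinates on the full grid (broadcastable)."""
        return [
            self.origin[a] + np.arange(self.shape[a], dtype=np.float64)
            .reshape([-1 if i == a else 1 for i in range(3)]) * self.spacing[a]
            for a in range(3)
        ]


@dataclass
class LabelVolume:
    """Integer parcellation on the same grid contract as :class:`Volume3D`."""

    labels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise GeometryError(f"non-3D label image (ndim={self.labels.ndim})")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded, atol=1e-6):
                raise GeometryError("label volume contains non-integer values")
            self.labels = rounded.astype(np.int32)
        if self.labels.min() < 0:
            raise GeometryError("negative labels are not allowed")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if np.any(self.spacing <= 0):
            raise GeometryError(f"non-positive spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def present_labels(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def as_volume(self) -> Volume3D:
        return Volume3D(self.labels.astype(np.float64), self.spacing, self.origin)


@dataclass
class DisplacementField:
    """Per-voxel displacement 3-vectors in mm, plus direction semantics.

    ``direction`` is either ``atlas_to_subject`` (the forward transform T:
    warping the atlas with this field resamples it into subject space) or
    ``subject_to_atlas`` (the inverse T', carrying the subject's tissue
    displacement relative to the template).
    """

    vectors: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: str = ATLAS_TO_SUBJECT

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise GeometryError(
                f"displacement field must have shape (nx,ny,nz,3), got {self.vectors.shape}"
            )
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if np.any(self.spacing <= 0):
            raise GeometryError(f"non-positive spacing {self.spacing}")
        if self.direction not in (ATLAS_TO_SUBJECT, SUBJECT_TO_ATLAS):
            raise GeometryError(f"unknown field direction {self.direction!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.vectors**2, axis=-1))

    def jacobian_determinant(self) -> np.ndarray:
        """det(I + grad u), evaluated with central differences in mm units."""
        grads = np.empty(self.shape + (3, 3))
        for c in range(3):
            gx, gy, gz = np.gradient(self.vectors[..., c], *self.spacing)
            grads[..., c, 0] = gx
            grads[..., c, 1] = gy
            grads[..., c, 2] = gz
        grads[..., 0, 0] += 1.0
        grads[..., 1, 1] += 1.0
        grads[..., 2, 2] += 1.0
        return np.linalg.det(grads)


@dataclass
class TumorMask:
    """Three-compartment tumor segmentation: 1=necrotic core, 2=enhancing, 3=edema."""

    compartments: LabelVolume

    NECROTIC_CORE = 1
    ENHANCING = 2
    EDEMA = 3

    def __post_init__(self) -> None:
        extra = set(self.compartments.present_labels()) - {1, 2, 3}
        if extra:
            raise GeometryError(f"unexpected tumor compartment codes {sorted(extra)}")

    @property
    def combined(self) -> np.ndarray:
        return self.compartments.labels > 0

    @property
    def volume_ml(self) -> float:
        vox = float(np.prod(self.compartments.spacing))
        return float(np.count_nonzero(self.combined)) * vox / 1000.0


def same_geometry(a, b, atol: float = 1e-5) -> bool:
    return (
        tuple(a.shape) == tuple(b.shape)
        and np.allclose(a.spacing, b.spacing, atol=atol)
        and np.allclose(a.origin, b.origin, atol=atol)
    )


def _require_same_geometry(a, b) -> None:
    if not same_geometry(a, b):
        raise GeometryError(
            f"geometry mismatch: shape {tuple(a.shape)} spacing {a.spacing} origin {a.origin}"
            f" vs shape {tuple(b.shape)} spacing {b.spacing} origin {b.origin}"
        )


# ---------------------------------------------------------------------------
# NIfTI round-tripping
# ---------------------------------------------------------------------------

def _affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _geometry_from_nifti(img) -> tuple[np.ndarray, np.ndarray]:
    img = nib.as_closest_canonical(img)
    aff = img.affine
    rot = aff[:3, :3]
    spacing = np.sqrt(np.sum(rot**2, axis=0))
    off_diag = rot - np.diag(np.diag(rot))
    if np.any(np.abs(off_diag) > 1e-3 * max(spacing.max(), 1.0)):
        raise GeometryError("oblique (non-axis-aligned) affine headers are not supported")
    if np.any(np.diag(rot) <= 0):
        raise GeometryError("non-positive spacing in affine after RAS reorientation")
    return img, np.diag(rot).astype(np.float64), aff[:3, 3].astype(np.float64)


def read_volume(path) -> Volume3D:
    """Read a 3D NIfTI-1 scalar volume, reoriented to RAS."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    img, spacing, origin = _geometry_from_nifti(img)
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise GeometryError(f"non-3D image: {path.name} has shape {data.shape}")
    return Volume3D(data, spacing, origin)


def write_volume(vol: Volume3D, path, dtype=None) -> None:
    """Write a volume as NIfTI-1.  Integer-valued data round-trips bitwise."""
    path = Path(path)
    data = vol.data
    if dtype is not None:
        data = data.astype(dtype)
    img = nib.Nifti1Image(data, _affine(vol.spacing, vol.origin))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_label_volume(path) -> LabelVolume:
    vol = read_volume(path)
    return LabelVolume(np.rint(vol.data).astype(np.int32), vol.spacing, vol.origin)


def write_field(fld: DisplacementField, path) -> None:
    """Write a displacement field as a 4D (x,y,z,3) vector NIfTI."""
    img = nib.Nifti1Image(fld.vectors.astype(np.float64), _affine(fld.spacing, fld.origin))
    img.header.set_intent("vector")
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_field(path, direction: str = ATLAS_TO_SUBJECT) -> DisplacementField:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    img, spacing, origin = _geometry_from_nifti(img)
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector convention (x,y,z,1,3)
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise GeometryError(f"not a 3-component vector image: shape {data.shape}")
    return DisplacementField(data, spacing, origin, direction)


# ---------------------------------------------------------------------------
# Region tables
# ---------------------------------------------------------------------------

REGION_COLUMNS = ["region_id", "region_name", "hemisphere"]


def validate_region_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REGION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"region table missing columns {missing}")
    table = table[REGION_COLUMNS].copy()
    table["region_id"] = table["region_id"].astype(int)
    if (table["region_id"] <= 0).any():
        raise ValueError("region_id must be positive")
    if table["region_id"].duplicated().any():
        raise ValueError("region_id must be unique")
    bad = set(table["hemisphere"]) - set(HEMISPHERES)
    if bad:
        raise ValueError(f"unknown hemisphere values {sorted(bad)}")
    return table


def read_region_table(path) -> pd.DataFrame:
    return validate_region_table(pd.read_csv(path))


def write_region_table(table: pd.DataFrame, path) -> None:
    validate_region_table(table).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Warping and resampling
# ---------------------------------------------------------------------------

_ORDERS = {"linear": 1, "nearest": 0}


def _index_grid(shape) -> list[np.ndarray]:
    return np.meshgrid(
        *[np.arange(n, dtype=np.float64) for n in shape], indexing="ij", copy=False
    )


def sample_at_voxel_coords(data: np.ndarray, coords, order: int) -> np.ndarray:
    """Sample ``data`` at fractional voxel coordinates, zero outside."""
    return map_coordinates(
        np.asarray(data, dtype=np.float64), coords, order=order, mode="constant",
        cval=0.0, prefilter=False,
    )


def warp(vol: Volume3D, fld: DisplacementField, interpolation: str = "linear",
         return_valid: bool = False):
    """Pull-back warp: output voxel at x samples the input at x + u(x).

    Out-of-bounds samples are zero-filled; ``return_valid`` additionally
    returns the boolean mask of in-bounds samples.
    """
    if interpolation not in _ORDERS:
        raise ValueError(f"interpolation must be one of {sorted(_ORDERS)}")
    _require_same_geometry(vol, fld)
    idx = _index_grid(vol.shape)
    coords = [idx[a] + fld.vectors[..., a] / vol.spacing[a] for a in range(3)]
    out = sample_at_voxel_coords(vol.data, coords, _ORDERS[interpolation])
    result = vol.with_data(out)
    if return_valid:
        valid = np.ones(vol.shape, dtype=bool)
        for a in range(3):
            valid &= (coords[a] >= 0) & (coords[a] <= vol.shape[a] - 1)
        return result, valid
    return result


def warp_labels(labels: LabelVolume, fld: DisplacementField) -> LabelVolume:
    """Nearest-neighbour warp for parcellations and masks (no new labels)."""
    vol = warp(labels.as_volume(), fld, interpolation="nearest")
    return LabelVolume(np.rint(vol.data).astype(labels.labels.dtype),
                       labels.spacing, labels.origin)


def resample_to_grid(vol: Volume3D, reference: Volume3D,
                     interpolation: str = "linear") -> Volume3D:
    """Resample onto the reference grid by world-coordinate sampling."""
    if interpolation not in _ORDERS:
        raise ValueError(f"interpolation must be one of {sorted(_ORDERS)}")
    idx = _index_grid(reference.shape)
    coords = [
        (reference.origin[a] + idx[a] * reference.spacing[a] - vol.origin[a])
        / vol.spacing[a]
        for a in range(3)
    ]
    data = sample_at_voxel_coords(vol.data, coords, _ORDERS[interpolation])
    return Volume3D(data, reference.spacing, reference.origin)


def resample_field_to_grid(fld: DisplacementField, reference: Volume3D) -> DisplacementField:
    """Linearly resample each vector component onto the reference grid."""
    comps = [
        resample_to_grid(Volume3D(fld.vectors[..., c], fld.spacing, fld.origin),
                         reference).data
        for c in range(3)
    ]
    return DisplacementField(np.stack(comps, axis=-1), reference.spacing,
                             reference.origin, fld.direction)
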