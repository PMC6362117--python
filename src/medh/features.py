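"""Mass Effect Deformation Heterogeneity (MEDH) feature extraction.

MEDH for an anatomical region is the variance of per-voxel tissue
displacement magnitudes inside that region.  Displacements are taken from
the subject-to-template (inverse) deformation field sampled on the template
grid, where the parcellation is defined, so every subject contributes one
variance per parcellation region.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd

from .core_io import (
    DisplacementField,
    LabelVolume,
    TumorMask,
    Volume3D,
    GeometryError,
    same_geometry,
    validate_region_table,
)

__all__ = [
    "AtlasBundle",
    "SubjectBundle",
    "MEDH_COLUMNS",
    "magnitude_map",
    "hemisphere_of",
    "regional_variance",
    "tumor_overlap_fraction",
    "extract_medh",
    "medh_matrix",
]

MEDH_COLUMNS = [
    "subject_id", "region_id", "region_name", "hemisphere",
    "medh_mm2", "voxel_count", "tumor_overlap", "missing",
]


@dataclass
class AtlasBundle:
    """Healthy template: T1 image, brain mask, parcellation and region table."""

    t1: Volume3D
    labels: LabelVolume
    regions: pd.DataFrame
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        self.regions = validate_region_table(self.regions)


@dataclass
class SubjectBundle:
    """One subject: T1 image plus tumor segmentation (subject space)."""

    subject_id: str
    t1: Volume3D
    tumor: TumorMask
    true_field: Optional[DisplacementField] = None
    tumor_in_atlas: Optional[TumorMask] = None
    params: dict = dc_field(default_factory=dict)


def magnitude_map(fld: DisplacementField) -> Volume3D:
    """Per-voxel Euclidean norm sqrt(x^2 + y^2 + z^2) of the field, in mm."""
    return Volume3D(fld.magnitude(), fld.spacing, fld.origin)


_VERMIS_RE = re.compile(r"(vermis|midline)", re.IGNORECASE)


def hemisphere_of(region_name: str) -> str:
    """Hemisphere from the parcellation naming convention.

    ``_L``/``_R`` suffixes map to left/right; vermis and midline names are
    non-hemispheric; anything else is non-hemispheric with a warning.
    """
    name = region_name.strip()
    if name.endswith("_L"):
        return "left"
    if name.endswith("_R"):
        return "right"
    if _VERMIS_RE.search(name):
        return "non-hemispheric"
    warnings.warn(f"unrecognized hemisphere suffix in region name {name!r}; "
                  "treating as non-hemispheric", stacklevel=2)
    return "non-hemispheric"


def _region_sums(values: np.ndarray, labels: np.ndarray, n_labels: int):
    counts = np.bincount(labels.ravel(), minlength=n_labels)
    sums = np.bincount(labels.ravel(), weights=values.ravel(), minlength=n_labels)
    return counts, sums


def regional_variance(mag: Volume3D, labels: LabelVolume, region_table: pd.DataFrame,
                      min_voxels: int = 10, ddof: int = 1,
                      subject_id: str = "subject",
                      tumor_overlap: Optional[pd.Series] = None) -> pd.DataFrame:
    """Per-region variance of displacement magnitudes (mm^2).

    Sample variance (``ddof=1``) by default; regions with fewer than
    ``min_voxels`` voxels are flagged missing rather than reported as zero.
    """
    if not same_geometry(mag, labels):
        raise GeometryError("magnitude map and label volume are on different grids")
    region_table = validate_region_table(region_table)
    lab = labels.labels
    if lab.max() == 0:
        raise ValueError("empty label volume")
    n = int(lab.max()) + 1
    values = np.asarray(mag.data, dtype=np.float64)
    counts, sums = _region_sums(values, lab, n)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    # two-pass variance: stable against magnitude offsets
    centered_sq = np.zeros_like(values)
    valid = counts[lab] > 0
    centered_sq[valid] = (values[valid] - means[lab[valid]]) ** 2
    _, sq_sums = _region_sums(centered_sq, lab, n)

    rows = []
    for _, reg in region_table.iterrows():
        rid = int(reg.region_id)
        cnt = int(counts[rid]) if rid < n else 0
        missing = cnt < max(min_voxels, ddof + 1)
        if missing:
            var = np.nan
        else:
            var = float(sq_sums[rid] / (cnt - ddof))
        overlap = float(tumor_overlap.get(rid, 0.0)) if tumor_overlap is not None else 0.0
        rows.append({
            "subject_id": subject_id,
            "region_id": rid,
            "region_name": reg.region_name,
            "hemisphere": reg.hemisphere,
            "medh_mm2": var,
            "voxel_count": cnt,
            "tumor_overlap": overlap,
            "missing": bool(missing),
        })
    return pd.DataFrame(rows, columns=MEDH_COLUMNS)


def tumor_overlap_fraction(labels: LabelVolume, tumor_mask: np.ndarray) -> pd.Series:
    """Fraction of each region's voxels inside the combined tumor mask."""
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if tumor_mask.shape != tuple(labels.shape):
        raise GeometryError("tumor mask and labels are on different grids")
    lab = labels.labels
    n = int(lab.max()) + 1
    counts = np.bincount(lab.ravel(), minlength=n)
    inside = np.bincount(lab[tumor_mask].ravel(), minlength=n)
    ids = np.arange(n)
    keep = (ids > 0) & (counts > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = inside[keep] / counts[keep]
    return pd.Series(frac, index=ids[keep], name="tumor_overlap")


@dataclass
class MEDHQC:
    """Per-subject quality-control record emitted next to the MEDH row."""

    subject_id: str
    inverse_consistency_mm: float
    mean_magnitude_mm: float
    max_tumor_overlap: float
    mode: str


def extract_medh(subject: SubjectBundle, atlas: AtlasBundle,
                 registration_params=None, min_voxels: int = 10,
                 use_true_field: bool = False,
                 include_affine: bool = True,
                 run_preprocess: bool = True,
                 exclusion_dilate_voxels: int = 3) -> tuple[pd.DataFrame, MEDHQC]:
    """End-to-end extraction: preprocess, register, magnitudes, variances.

    With ``use_true_field`` the planted ground-truth field of a phantom
    subject bypasses preprocessing/registration entirely — the oracle path
    used to separate feature-extraction correctness from registration error.
    ``run_preprocess=False`` skips bias correction and standardization for
    inputs that are already intensity-faithful to the template.  The
    exclusion mask is dilated (default 3 voxels) so that bias-correction
    halos and interpolation bleed around the lesion cannot enter the
    similarity forces.
    """
    from . import preprocess, registration  # deferred: heavy deps

    overlap_atlas: Optional[pd.Series]
    if use_true_field:
        if subject.true_field is None:
            raise ValueError(f"subject {subject.subject_id} has no ground-truth field")
        fld = subject.true_field
        residual = 0.0
        # phantom true fields live on the atlas grid already
        atlas_mask = (subject.tumor_in_atlas.combined
                      if subject.tumor_in_atlas is not None
                      else subject.tumor.combined)
        overlap_atlas = tumor_overlap_fraction(atlas.labels, atlas_mask)
        mode = "ground_truth_bypass"
    else:
        from scipy.ndimage import binary_dilation

        params = registration_params or registration.RegistrationParams()
        if run_preprocess:
            pre = preprocess.preprocess_subject(subject, atlas)
            fixed, brain = pre.t1, pre.brain_mask
        else:
            fixed = subject.t1
            brain = preprocess.estimate_brain_mask(subject.t1)
        exclusion = subject.tumor.combined
        if exclusion_dilate_voxels:
            exclusion = binary_dilation(exclusion,
                                        iterations=exclusion_dilate_voxels)
        result = registration.register_pair(
            fixed=fixed, moving=atlas.t1,
            fixed_exclusion_mask=exclusion, params=params,
            include_affine=include_affine,
            fixed_domain_mask=brain,
        )
        fld = result.inverse_on_atlas
        residual = result.inverse_consistency_mm
        tumor_in_atlas = registration.map_mask_to_atlas(subject.tumor.combined, result)
        overlap_atlas = tumor_overlap_fraction(atlas.labels, tumor_in_atlas)
        mode = "registered"

    mag = magnitude_map(fld)
    table = regional_variance(
        mag, atlas.labels, atlas.regions, min_voxels=min_voxels,
        subject_id=subject.subject_id, tumor_overlap=overlap_atlas,
    )
    qc = MEDHQC(
        subject_id=subject.subject_id,
        inverse_consistency_mm=float(residual),
        mean_magnitude_mm=float(mag.data[atlas.brain_mask].mean()),
        max_tumor_overlap=float(table["tumor_overlap"].max()),
        mode=mode,
    )
    return table, qc


def medh_matrix(long_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long MEDH table to a subjects x region_id matrix."""
    return long_table.pivot(index="subject_id", columns="region_id",
                            values="medh_mm2")
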