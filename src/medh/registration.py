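"""Affine + diffeomorphic registration with cost-function masking.

The deformable engine is a symmetric, Gaussian-regularized demons-class
scheme: per iteration a masked force field is computed from the intensity
difference and the mean of fixed/warped gradients, smoothed (fluid
regularization), composed with the running field, and smoothed again
(elastic regularization).  Voxels inside the exclusion mask — the combined
tumor segmentation — contribute no force, so the transform there is the
smoothness-regularized extension of its surroundings, exactly the
cost-function-masking behaviour needed for pathological brains.

The affine stage is delegated to SimpleITK's registration framework with the
same metric mask.  Forward (atlas-to-subject) and inverse (subject-to-atlas)
fields are returned together; the inverse is obtained by fixed-point
iteration and checked against a consistency tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import binary_dilation, gaussian_filter, zoom

from .core_io import (
    ATLAS_TO_SUBJECT,
    SUBJECT_TO_ATLAS,
    DisplacementField,
    GeometryError,
    Volume3D,
    _index_grid,
    same_geometry,
    sample_at_voxel_coords,
    warp,
)

__all__ = [
    "RegistrationParams",
    "RegistrationError",
    "AffineTransform",
    "RegistrationResult",
    "affine_register",
    "diffeo_register",
    "invert_field",
    "compose",
    "register_pair",
    "map_mask_to_atlas",
    "masked_similarity",
]


class RegistrationError(RuntimeError):
    pass


@dataclass
class RegistrationParams:
    """Knobs of the multiresolution masked demons scheme (all sigmas in mm)."""

    levels: int = 3
    iterations: Sequence[int] = (100, 60, 30)
    similarity: str = "local_correlation"   # or "mutual_information"
    affine_similarity: str = "mutual_information"
    histogram_bins: int = 32
    update_smoothing_sigma: float = 2.0
    field_smoothing_sigma: float = 1.0
    step: float = 1.0
    inverse_tolerance: float = 0.5
    max_step_voxels: float = 0.8
    #: window (mm) of the local-correlation force model
    cc_sigma: float = 3.0
    #: no force where the local gradient is below this (intensity units/mm);
    #: flat areas are then filled in by regularization alone, which keeps
    #: residual intensity offsets from dragging textureless tissue around
    gradient_floor: float = 1.0

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.update_smoothing_sigma < 0 or self.field_smoothing_sigma < 0:
            raise ValueError("smoothing sigmas must be >= 0")
        if self.inverse_tolerance <= 0:
            raise ValueError("inverse_tolerance must be positive")
        for sim in (self.similarity, self.affine_similarity):
            if sim not in ("mutual_information", "local_correlation"):
                raise ValueError(f"unknown similarity {sim!r}")
        if len(self.iterations) != self.levels:
            raise ValueError("need one iteration count per level")


@dataclass
class AffineTransform:
    """World-coordinate affine x -> A x + t (fixed space to moving space)."""

    matrix: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation)

    def as_field(self, geometry) -> DisplacementField:
        xs = np.stack(np.broadcast_arrays(*geometry.world_coordinates()), axis=-1)
        vec = xs @ (self.matrix - np.eye(3)).T + self.translation
        return DisplacementField(vec, geometry.spacing, geometry.origin,
                                 ATLAS_TO_SUBJECT)


# ---------------------------------------------------------------------------
# Similarity metrics (reported / asserted, not differentiated)
# ---------------------------------------------------------------------------

def masked_similarity(fixed: np.ndarray, moving: np.ndarray, weight: np.ndarray,
                      kind: str = "local_correlation", bins: int = 32) -> float:
    """Similarity over weighted voxels; higher is better.

    ``local_correlation`` is the global normalized correlation of the masked
    voxels (the phantoms are mono-modal); ``mutual_information`` is a
    joint-histogram MI in nats.
    """
    sel = weight > 0
    a = fixed[sel].ravel()
    b = moving[sel].ravel()
    if a.size < 8:
        return 0.0
    if kind == "local_correlation":
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a**2).sum() * (b**2).sum())
        return float((a * b).sum() / denom) if denom > 0 else 0.0
    hist, _, _ = np.histogram2d(a, b, bins=bins)
    p = hist / hist.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


# ---------------------------------------------------------------------------
# Affine stage (SimpleITK)
# ---------------------------------------------------------------------------

def _to_sitk(vol: Volume3D) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T, dtype=np.float64))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    return img


def _mask_to_sitk(mask: np.ndarray, vol: Volume3D) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(mask.T.astype(np.uint8)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    return img


def affine_register(fixed: Volume3D, moving: Volume3D,
                    fixed_exclusion_mask: Optional[np.ndarray] = None,
                    similarity: str = "mutual_information",
                    histogram_bins: int = 32) -> AffineTransform:
    """12-parameter affine maximizing the masked similarity.

    Voxels inside ``fixed_exclusion_mask`` contribute nothing to the metric.
    Returns the world-coordinate transform mapping fixed points to the moving
    sample locations (so its displacement form plugs into :func:`warp`).
    """
    f_img = _to_sitk(fixed)
    m_img = _to_sitk(moving)
    reg = sitk.ImageRegistrationMethod()
    if similarity == "mutual_information":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=histogram_bins)
    else:
        reg.SetMetricAsCorrelation()
    include = fixed.data > -np.inf
    if fixed_exclusion_mask is not None:
        include = ~np.asarray(fixed_exclusion_mask, dtype=bool)
        reg.SetMetricFixedMask(_mask_to_sitk(include, fixed))
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=200,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    initial = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.AffineTransform(3),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg.SetInitialTransform(initial, inPlace=False)
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    try:
        tx = reg.Execute(f_img, m_img)
    except RuntimeError as exc:  # pragma: no cover - sitk failure path
        raise RegistrationError(f"affine registration failed: {exc}") from exc
    tx = tx.Downcast()
    if isinstance(tx, sitk.CompositeTransform):
        tx = tx.GetNthTransform(0).Downcast()
    if not isinstance(tx, sitk.AffineTransform):
        raise RegistrationError(f"unexpected transform type {type(tx).__name__}")
    a = np.asarray(tx.GetMatrix(), dtype=np.float64).reshape(3, 3)
    c = np.asarray(tx.GetCenter(), dtype=np.float64)
    t = np.asarray(tx.GetTranslation(), dtype=np.float64)
    # ITK applies x -> A (x - c) + c + t
    return AffineTransform(a, c + t - a @ c)


# ---------------------------------------------------------------------------
# Demons engine
# ---------------------------------------------------------------------------

def _smooth_vec(vec: np.ndarray, sigma_mm: float, spacing: np.ndarray) -> np.ndarray:
    if sigma_mm <= 0:
        return vec
    sig = sigma_mm / spacing
    out = np.empty_like(vec)
    for c in range(3):
        out[..., c] = gaussian_filter(vec[..., c], sigma=sig)
    return out


def _sample_field(vec: np.ndarray, coords) -> np.ndarray:
    out = np.empty(coords[0].shape + (3,))
    for c in range(3):
        out[..., c] = sample_at_voxel_coords(vec[..., c], coords, order=1)
    return out


def _compose_vec(outer: np.ndarray, inner: np.ndarray, spacing: np.ndarray,
                 idx=None) -> np.ndarray:
    """Field of (id+outer) o (id+inner): inner(x) + outer(x + inner(x))."""
    if idx is None:
        idx = _index_grid(inner.shape[:3])
    coords = [idx[a] + inner[..., a] / spacing[a] for a in range(3)]
    return inner + _sample_field(outer, coords)


def _downsample(data: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return data
    sm = gaussian_filter(data, sigma=factor / 2.0)
    return sm[::factor, ::factor, ::factor]


def _ssd_force(fixed, warped, gfix, spacing, params):
    """Thirion demons force from the intensity difference."""
    diff = fixed - warped
    gw = np.stack(np.gradient(warped, *spacing), axis=-1)
    g = 0.5 * (gfix + gw)
    g2 = np.sum(g**2, axis=-1)
    kappa2 = float(np.mean(spacing) ** 2)
    denom = g2 + diff**2 / kappa2
    active = g2 > params.gradient_floor**2
    coef = np.where(active & (denom > 1e-9), diff / np.maximum(denom, 1e-9), 0.0)
    return coef[..., None] * g


def _local_center(im, spacing, sigma_mm):
    """Subtract the local mean: cancels smooth additive/low-frequency
    intensity distortion (residual bias, imperfect standardization)."""
    return im - gaussian_filter(im, sigma=sigma_mm / spacing)


def _demons_level(fixed: np.ndarray, moving: np.ndarray, weight: np.ndarray,
                  spacing: np.ndarray, u: np.ndarray, iters: int,
                  params: RegistrationParams) -> np.ndarray:
    idx = _index_grid(fixed.shape)
    gfix = np.stack(np.gradient(fixed, *spacing), axis=-1)
    max_step_mm = params.max_step_voxels * float(spacing.min())
    use_lcc = params.similarity == "local_correlation"
    if use_lcc:
        fixed_c = _local_center(fixed, spacing, params.cc_sigma)
        gfix = np.stack(np.gradient(fixed_c, *spacing), axis=-1)
    for _ in range(iters):
        coords = [idx[a] + u[..., a] / spacing[a] for a in range(3)]
        warped = sample_at_voxel_coords(moving, coords, order=1)
        if use_lcc:
            warped = _local_center(warped, spacing, params.cc_sigma)
            force = _ssd_force(fixed_c, warped, gfix, spacing, params)
        else:
            force = _ssd_force(fixed, warped, gfix, spacing, params)
        delta = params.step * weight[..., None] * force
        delta = _smooth_vec(delta, params.update_smoothing_sigma, spacing)
        mags = np.sqrt(np.sum(delta**2, axis=-1))
        peak = mags.max()
        if peak > max_step_mm:
            delta *= max_step_mm / peak
        u = _compose_vec(u, delta, spacing, idx)
        u = _smooth_vec(u, params.field_smoothing_sigma, spacing)
    return u


def diffeo_register(fixed: Volume3D, moving: Volume3D,
                    fixed_exclusion_mask: Optional[np.ndarray] = None,
                    params: RegistrationParams = None,
                    fixed_domain_mask: Optional[np.ndarray] = None,
                    initial_moving: Optional[Volume3D] = None,
                    log: Optional[dict] = None,
                    ) -> tuple[DisplacementField, DisplacementField]:
    """Masked symmetric demons; returns (forward, inverse) fields.

    forward: warping ``moving`` with it reproduces ``fixed`` (atlas-to-subject
    when fixed is the subject).  inverse: its fixed-point inverse
    (subject-to-atlas).  Inside ``fixed_exclusion_mask`` the similarity force
    is zeroed, so the field there is purely the regularized extension of its
    surroundings.
    """
    params = params or RegistrationParams()
    if not same_geometry(fixed, moving):
        raise GeometryError("fixed and moving must share one grid")
    work_moving = initial_moving if initial_moving is not None else moving

    weight = np.ones(fixed.shape)
    if fixed_domain_mask is not None:
        weight *= np.asarray(fixed_domain_mask, dtype=np.float64)
    if fixed_exclusion_mask is not None:
        weight *= 1.0 - np.asarray(fixed_exclusion_mask, dtype=np.float64)

    factors = [2 ** (params.levels - 1 - i) for i in range(params.levels)]
    u = None
    metric_by_level = []
    idx_full = _index_grid(fixed.shape)
    for level, factor in enumerate(factors):
        f = _downsample(fixed.data, factor)
        m = _downsample(work_moving.data, factor)
        w = _downsample(weight, factor)
        # conservative masking under pyramid smoothing: a coarse voxel whose
        # support touches any excluded fine voxel is fully excluded, with one
        # extra coarse voxel of margin against intensity smear
        w = (np.clip(w, 0.0, 1.0) > 0.99).astype(np.float64)
        if factor > 1:
            from scipy.ndimage import binary_erosion as _berode
            w = _berode(w > 0, iterations=1).astype(np.float64)
        sp = fixed.spacing * factor
        if u is None:
            u = np.zeros(f.shape + (3,))
        else:
            u = np.stack(
                [zoom(u[..., c], np.asarray(f.shape) / np.asarray(u.shape[:3]),
                      order=1, mode="nearest") for c in range(3)], axis=-1)
        u = _demons_level(f, m, w, sp, u, int(params.iterations[level]), params)
        # full-resolution masked similarity after this level
        u_full = u if factor == 1 else np.stack(
            [zoom(u[..., c], np.asarray(fixed.shape) / np.asarray(u.shape[:3]),
                  order=1, mode="nearest") for c in range(3)], axis=-1)
        coords = [idx_full[a] + u_full[..., a] / fixed.spacing[a] for a in range(3)]
        warped = sample_at_voxel_coords(work_moving.data, coords, order=1)
        metric_by_level.append(masked_similarity(
            fixed.data, warped, weight, params.similarity, params.histogram_bins))

    if log is not None:
        log["metric_by_level"] = metric_by_level
    if any(b < a - 1e-3 for a, b in zip(metric_by_level, metric_by_level[1:])):
        warnings.warn("masked similarity decreased across pyramid levels; "
                      "registration may not have converged")

    forward = DisplacementField(u, fixed.spacing, fixed.origin, ATLAS_TO_SUBJECT)
    check_mask = fixed_domain_mask if fixed_domain_mask is not None else None
    jac = forward.jacobian_determinant()
    jmin = float(jac[check_mask].min()) if check_mask is not None else float(jac.min())
    if jmin <= 0:
        raise RegistrationError(
            f"non-positive Jacobian determinant (min {jmin:.4f}) after final level")
    inverse = invert_field(forward, tolerance=params.inverse_tolerance,
                           domain_mask=check_mask)
    return forward, inverse


def invert_field(fld: DisplacementField, tolerance: float = 0.1,
                 max_iters: int = 100, relaxation: float = 0.5,
                 domain_mask: Optional[np.ndarray] = None) -> DisplacementField:
    """Damped fixed-point inverse: v <- v + a(-u(x + v(x)) - v).

    Raises if more than 1% of (masked) voxels leave a residual |u(x+v)+v|
    above the tolerance.
    """
    u = fld.vectors
    spacing = fld.spacing
    idx = _index_grid(fld.shape)
    v = -u
    for it in range(max_iters):
        coords = [idx[a] + v[..., a] / spacing[a] for a in range(3)]
        target = -_sample_field(u, coords)
        step = relaxation * (target - v)
        v = v + step
        if np.max(np.abs(step)) < 1e-4:
            break
    coords = [idx[a] + v[..., a] / spacing[a] for a in range(3)]
    residual = np.sqrt(np.sum((_sample_field(u, coords) + v) ** 2, axis=-1))
    res = residual[domain_mask] if domain_mask is not None else residual
    frac_bad = float(np.mean(res > tolerance))
    if frac_bad > 0.01:
        raise RegistrationError(
            f"field inversion failed: {100 * frac_bad:.1f}% of voxels above "
            f"tolerance {tolerance} mm")
    direction = (SUBJECT_TO_ATLAS if fld.direction == ATLAS_TO_SUBJECT
                 else ATLAS_TO_SUBJECT)
    return DisplacementField(v, fld.spacing, fld.origin, direction)


def compose(outer, inner: DisplacementField) -> DisplacementField:
    """Displacement field of (outer o inner); outer may be affine or a field."""
    if isinstance(outer, AffineTransform):
        xs = np.stack(np.broadcast_arrays(
            *Volume3D(np.zeros(inner.shape), inner.spacing, inner.origin)
            .world_coordinates()), axis=-1)
        pts = xs + inner.vectors
        vec = outer.apply(pts.reshape(-1, 3)).reshape(pts.shape) - xs
        return DisplacementField(vec, inner.spacing, inner.origin, inner.direction)
    if not same_geometry(outer, inner):
        raise GeometryError("cannot compose fields on different grids")
    vec = _compose_vec(outer.vectors, inner.vectors, inner.spacing)
    return DisplacementField(vec, inner.spacing, inner.origin, inner.direction)


# ---------------------------------------------------------------------------
# Full pair registration (affine + diffeo, totals with affine folded in)
# ---------------------------------------------------------------------------

@dataclass
class RegistrationResult:
    affine: AffineTransform
    forward: DisplacementField          # total atlas->subject (affine included)
    inverse_on_atlas: DisplacementField  # total subject->atlas, on the atlas grid
    diffeo_forward: DisplacementField   # non-affine part only
    inverse_consistency_mm: float
    log: dict = dc_field(default_factory=dict)


def register_pair(fixed: Volume3D, moving: Volume3D,
                  fixed_exclusion_mask: Optional[np.ndarray] = None,
                  params: RegistrationParams = None,
                  include_affine: bool = True,
                  do_affine: bool = True,
                  fixed_domain_mask: Optional[np.ndarray] = None,
                  ) -> RegistrationResult:
    """Affine + masked diffeomorphic registration of a subject/template pair.

    ``fixed`` is the subject, ``moving`` the template.  The total forward
    field maps template into subject space; the inverse total field (the one
    feeding MEDH) carries the subject's displacement with respect to the
    template and is sampled on the template grid.  ``include_affine``
    controls whether the affine component is folded into the totals.
    """
    params = params or RegistrationParams()
    log: dict = {}
    if do_affine:
        affine = affine_register(fixed, moving, fixed_exclusion_mask,
                                 similarity=params.affine_similarity,
                                 histogram_bins=params.histogram_bins)
    else:
        affine = AffineTransform.identity()
    moving_aff = warp(moving, affine.as_field(fixed)) if do_affine else moving

    fwd_diffeo, inv_diffeo = diffeo_register(
        fixed, moving_aff, fixed_exclusion_mask, params,
        fixed_domain_mask=fixed_domain_mask, log=log,
    )

    if include_affine:
        # total forward: x -> A(x + u(x)); displacement = A(x+u) - x
        forward = compose(affine, fwd_diffeo)
        inv_affine = affine.inverse()
        inverse = compose(inv_diffeo, inv_affine.as_field(fixed))
        inverse = DisplacementField(inverse.vectors, fixed.spacing, fixed.origin,
                                    SUBJECT_TO_ATLAS)
    else:
        forward = fwd_diffeo
        inverse = inv_diffeo

    comp = compose(forward, DisplacementField(
        inverse.vectors, inverse.spacing, inverse.origin, ATLAS_TO_SUBJECT))
    mags = np.sqrt(np.sum(comp.vectors**2, axis=-1))
    mask = fixed_domain_mask if fixed_domain_mask is not None else fixed.data > 0
    residual = float(mags[mask].mean()) if mask.any() else float(mags.mean())
    log["inverse_consistency_mm"] = residual
    if residual > params.inverse_tolerance:
        warnings.warn(f"inverse consistency {residual:.3f} mm exceeds tolerance "
                      f"{params.inverse_tolerance} mm")
    return RegistrationResult(
        affine=affine, forward=forward, inverse_on_atlas=inverse,
        diffeo_forward=fwd_diffeo, inverse_consistency_mm=residual, log=log,
    )


def map_mask_to_atlas(subject_mask: np.ndarray, result: RegistrationResult,
                      dilate_voxels: int = 0) -> np.ndarray:
    """Carry a subject-space mask to the atlas grid.

    The inverse total field resamples subject-space data onto the atlas
    grid: atlas voxel y holds subject_mask(y + T'(y)) — nearest-neighbour.
    """
    mask = np.asarray(subject_mask, dtype=np.float64)
    fld = result.inverse_on_atlas
    vol = Volume3D(mask, fld.spacing, fld.origin)
    resample = DisplacementField(fld.vectors, fld.spacing, fld.origin,
                                 ATLAS_TO_SUBJECT)
    out = warp(vol, resample, interpolation="nearest").data > 0.5
    if dilate_voxels:
        out = binary_dilation(out, iterations=dilate_voxels)
    return out
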