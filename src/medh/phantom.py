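"""Synthetic phantoms: template, parcellation, tumors, fields and cohorts.

The generator stands in for a real template/parcellation pair and a glioma
cohort.  Its pieces:

* an ellipsoidal three-tissue "brain" parcellated into mirrored left/right
  region pairs plus midline regions (116 regions by default, matching the
  cardinality of whole-brain anatomical parcellations with non-hemispheric
  vermis entries);
* a radial, diffeomorphic-by-construction mass-effect displacement field
  around an inserted three-compartment tumor;
* a small smooth "anatomical variability" field modelling benign
  subject-to-template anatomical differences — without it every region's
  deformation would be a deterministic function of tumor size and no region
  would be statistically null;
* survival times negatively coupled to the mean true displacement-magnitude
  variance over a designated set of contralateral regions.

Everything is driven by one seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core_io import (
    ATLAS_TO_SUBJECT,
    DisplacementField,
    LabelVolume,
    TumorMask,
    Volume3D,
    warp,
    warp_labels,
)
from .features import AtlasBundle, SubjectBundle, hemisphere_of, magnitude_map, regional_variance

__all__ = [
    "MassEffectParams",
    "CohortConfig",
    "CohortTruth",
    "Cohort",
    "make_atlas",
    "mass_effect_field",
    "anatomical_variability_field",
    "insert_tumor",
    "corrupt",
    "simulate_cohort",
]

DAYS_PER_MONTH = 30.4375


@dataclass(frozen=True)
class MassEffectParams:
    """Radial mass-effect model: linear ramp inside the tumor, exponential decay outside."""

    center: tuple[float, float, float]  # world mm
    tumor_radius: float                 # r_t, mm
    peak_displacement: float            # D_max, mm
    decay_length: float                 # lambda, mm

    def __post_init__(self) -> None:
        if self.tumor_radius <= 0:
            raise ValueError("tumor_radius must be positive")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")
        if self.peak_displacement < 0:
            raise ValueError("peak_displacement must be non-negative")
        if self.peak_displacement / self.decay_length >= 1.0:
            raise ValueError(
                "peak_displacement/decay_length must be < 1 to guarantee a "
                "diffeomorphic field"
            )


# ---------------------------------------------------------------------------
# Atlas construction
# ---------------------------------------------------------------------------

def _three_factors(n: int) -> tuple[int, int, int]:
    """a*b*c = n with factors as equal as possible (a<=b<=c)."""
    best = (1, 1, n)
    for a in range(1, int(round(n ** (1 / 3))) + 2):
        if n % a:
            continue
        m = n // a
        for b in range(a, int(m ** 0.5) + 1):
            if m % b:
                continue
            c = m // b
            if c / a < best[2] / best[0]:
                best = (a, b, c)
    return best


def _quantile_partition(order_keys: list[np.ndarray], n_parts: tuple[int, int, int],
                        idx: np.ndarray) -> np.ndarray:
    """Assign region numbers 0..prod(n_parts)-1 to voxel list ``idx``.

    Recursive quantile splits along the given sort keys produce box-like
    regions of near-equal voxel counts.
    """
    assignment = np.zeros(idx.size, dtype=np.int32)

    def split(sel: np.ndarray, depth: int, base: int) -> None:
        if depth == len(order_keys):
            assignment[sel] = base
            return
        k = n_parts[depth]
        order = sel[np.argsort(order_keys[depth][sel], kind="stable")]
        bounds = np.linspace(0, order.size, k + 1).round().astype(int)
        stride = int(np.prod(n_parts[depth + 1:]))
        for j in range(k):
            split(order[bounds[j]:bounds[j + 1]], depth + 1, base + j * stride)

    split(np.arange(idx.size), 0, 0)
    return assignment


def make_atlas(grid_shape=(64, 64, 64), spacing=(2.0, 2.0, 2.0),
               n_region_pairs: int = 54, n_midline_regions: int = 8,
               seed: int = 0) -> AtlasBundle:
    """Ellipsoidal three-tissue template with a mirrored parcellation.

    Defaults emit 54 left/right pairs + 8 midline regions = 116 regions.
    Left regions are exact x-reflections of their right partners.  Small
    deterministic per-region intensity offsets give the template internal
    contrast so deformable registration has gradient information away from
    tissue boundaries.
    """
    shape = tuple(int(s) for s in grid_shape)
    if min(shape) < 32:
        raise ValueError("grid must be at least 32^3")
    if n_region_pairs < 1:
        raise ValueError("need at least one region pair")
    spacing = np.asarray(spacing, dtype=np.float64)
    rng = np.random.default_rng(seed)

    nx, ny, nz = shape
    ii, jj, kk = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape],
                             indexing="ij")
    center_vox = (np.asarray(shape, dtype=np.float64) - 1) / 2
    semi_axes = np.array([0.42 * nx, 0.36 * ny, 0.34 * nz]) * spacing
    x = (ii - center_vox[0]) * spacing[0]
    y = (jj - center_vox[1]) * spacing[1]
    z = (kk - center_vox[2]) * spacing[2]
    rho = np.sqrt((x / semi_axes[0]) ** 2 + (y / semi_axes[1]) ** 2
                  + (z / semi_axes[2]) ** 2)
    brain = rho <= 1.0

    # three tissue classes by normalized ellipsoidal radius
    t1 = np.zeros(shape)
    t1[brain & (rho > 0.88)] = 35.0    # CSF-like rim
    t1[brain & (rho <= 0.88)] = 80.0   # GM-like band
    t1[brain & (rho <= 0.60)] = 115.0  # WM-like core

    # parcellation: midline slab + mirrored left/right partitions
    mid = (nx - 1) / 2
    slab_halfwidth_vox = max(1.0, 3.0 / spacing[0])
    in_slab = np.abs(ii - mid) <= slab_halfwidth_vox
    right_half = (ii - mid) > slab_halfwidth_vox

    labels = np.zeros(shape, dtype=np.int32)
    right_idx = np.flatnonzero(brain & right_half)
    if right_idx.size < 20 * n_region_pairs:
        raise ValueError(
            f"{n_region_pairs} region pairs infeasible for grid {shape}: only "
            f"{right_idx.size} right-hemisphere voxels"
        )
    keys = [kk.ravel()[right_idx], jj.ravel()[right_idx], ii.ravel()[right_idx]]
    parts = _three_factors(n_region_pairs)[::-1]  # biggest factor on z
    assign = _quantile_partition(keys, parts, right_idx)
    # right region j -> id 2j+2 ; left mirror -> id 2j+1 (odd=left, even=right)
    flat = labels.ravel()
    flat[right_idx] = 2 * assign + 2
    labels = flat.reshape(shape)
    mirrored = labels[::-1, :, :]  # mirror across the x mid-plane
    left_sel = brain & ((mid - ii) > slab_halfwidth_vox) & (mirrored > 0)
    labels = np.where(left_sel, mirrored - 1, labels)

    rows = []
    for j in range(n_region_pairs):
        rows.append({"region_id": 2 * j + 1, "region_name": f"Region_{j + 1:02d}_L"})
        rows.append({"region_id": 2 * j + 2, "region_name": f"Region_{j + 1:02d}_R"})

    if n_midline_regions > 0:
        slab_idx = np.flatnonzero(brain & in_slab)
        if slab_idx.size < 10 * n_midline_regions:
            raise ValueError("midline region count infeasible for grid size")
        zkey = kk.ravel()[slab_idx]
        order = slab_idx[np.argsort(zkey, kind="stable")]
        bounds = np.linspace(0, order.size, n_midline_regions + 1).round().astype(int)
        base = 2 * n_region_pairs
        flat = labels.ravel()
        for m in range(n_midline_regions):
            flat[order[bounds[m]:bounds[m + 1]]] = base + m + 1
            rows.append({"region_id": base + m + 1,
                         "region_name": f"Midline_{m + 1}"})
        labels = flat.reshape(shape)

    regions = pd.DataFrame(rows)
    regions["hemisphere"] = [hemisphere_of(n) for n in regions["region_name"]]

    # per-region contrast: mirrored pairs share one offset, midline its own
    offsets = rng.uniform(-8.0, 8.0, size=n_region_pairs + n_midline_regions)
    offset_of_label = np.zeros(int(labels.max()) + 1)
    for j in range(n_region_pairs):
        offset_of_label[2 * j + 1] = offsets[j]
        offset_of_label[2 * j + 2] = offsets[j]
    for m in range(n_midline_regions):
        offset_of_label[2 * n_region_pairs + m + 1] = offsets[n_region_pairs + m]
    t1 = t1 + offset_of_label[labels] * (labels > 0)
    # smooth within-tissue texture: broadens the class histogram peaks the
    # way real T1 tissue does (continuous CDF -> stable quantile landmarks)
    # and gives deformable registration gradient information inside classes
    texture = gaussian_filter(rng.standard_normal(shape), sigma=4.0 / spacing)
    texture *= 5.0 / max(texture[brain].std(), 1e-9)
    t1 = t1 + texture * brain
    t1 = gaussian_filter(t1, sigma=0.6)
    t1[~brain] = 0.0

    vol = Volume3D(t1, spacing, np.zeros(3))
    return AtlasBundle(
        t1=vol,
        labels=LabelVolume(labels, spacing, np.zeros(3)),
        regions=regions,
        brain_mask=brain,
    )


# ---------------------------------------------------------------------------
# Displacement fields
# ---------------------------------------------------------------------------

def mass_effect_field(params: MassEffectParams, geometry: Volume3D) -> DisplacementField:
    """Radial outward field u(x) = m(d) (x - c)/d.

    m(d) = D_max * d/r_t inside the tumor and D_max * exp(-(d - r_t)/lambda)
    outside; D_max/lambda < 1 bounds |m'| below 1 on the decay branch, which
    makes id + u invertible (positive Jacobian everywhere).
    """
    c = np.asarray(params.center, dtype=np.float64)
    xs = geometry.world_coordinates()
    dx = xs[0] - c[0]
    dy = xs[1] - c[1]
    dz = xs[2] - c[2]
    d = np.sqrt(dx**2 + dy**2 + dz**2)
    m = np.where(
        d < params.tumor_radius,
        params.peak_displacement * d / params.tumor_radius,
        params.peak_displacement * np.exp(-(d - params.tumor_radius) / params.decay_length),
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(d > 0, m / d, 0.0)
    vec = np.stack(np.broadcast_arrays(scale * dx, scale * dy, scale * dz), axis=-1)
    return DisplacementField(vec, geometry.spacing, geometry.origin, ATLAS_TO_SUBJECT)


def anatomical_variability_field(geometry: Volume3D, brain_mask: np.ndarray,
                                 rms_mm: float = 0.35, smooth_mm: float = 8.0,
                                 seed: int = 0) -> DisplacementField:
    """Smooth random field emulating benign anatomical differences.

    White noise per component, Gaussian-smoothed at ``smooth_mm``, rescaled so
    the per-voxel vector magnitude has the requested RMS over the brain mask.
    """
    rng = np.random.default_rng(seed)
    shape = geometry.shape
    comps = []
    for _ in range(3):
        noise = rng.standard_normal(shape)
        comps.append(gaussian_filter(noise, sigma=smooth_mm / geometry.spacing))
    vec = np.stack(comps, axis=-1)
    mags = np.sqrt(np.sum(vec**2, axis=-1))
    rms = np.sqrt(np.mean(mags[brain_mask] ** 2))
    if rms > 0:
        vec *= rms_mm / rms
    return DisplacementField(vec, geometry.spacing, geometry.origin, ATLAS_TO_SUBJECT)


def _add_fields(a: DisplacementField, b: DisplacementField) -> DisplacementField:
    return DisplacementField(a.vectors + b.vectors, a.spacing, a.origin, a.direction)


# ---------------------------------------------------------------------------
# Tumor insertion and corruption
# ---------------------------------------------------------------------------

DEFAULT_COMPARTMENT_INTENSITIES = (25.0, 150.0, 60.0)  # core, enhancing, edema


def insert_tumor(atlas_img: Volume3D, params: MassEffectParams,
                 compartment_radii: Optional[tuple[float, float, float]] = None,
                 intensities: tuple[float, float, float] = DEFAULT_COMPARTMENT_INTENSITIES,
                 seed: int = 0) -> tuple[Volume3D, TumorMask]:
    """Paint concentric core/enhancing/edema spheres into the template.

    Radii must be nested; the edema sphere must stay inside the brain
    (nonzero template intensity), otherwise an error is raised.
    """
    if compartment_radii is None:
        r = params.tumor_radius
        compartment_radii = (0.4 * r, 0.7 * r, r)
    r_core, r_enh, r_edema = compartment_radii
    if not (0 <= r_core <= r_enh <= r_edema):
        raise ValueError("compartment radii must be nested: core <= enhancing <= edema")

    c = np.asarray(params.center, dtype=np.float64)
    xs = atlas_img.world_coordinates()
    d = np.sqrt((xs[0] - c[0]) ** 2 + (xs[1] - c[1]) ** 2 + (xs[2] - c[2]) ** 2)

    comp = np.zeros(atlas_img.shape, dtype=np.int32)
    if r_edema > 0:
        comp[d <= r_edema] = TumorMask.EDEMA
        comp[d <= r_enh] = TumorMask.ENHANCING
        comp[d <= r_core] = TumorMask.NECROTIC_CORE
        brain = atlas_img.data > 0
        if np.any((comp > 0) & ~brain):
            raise ValueError("tumor extends outside the brain mask")

    data = atlas_img.data.copy()
    if r_edema > 0:
        rng = np.random.default_rng(seed)
        texture = gaussian_filter(rng.standard_normal(atlas_img.shape), sigma=1.0) * 6.0
        for code, val in zip(
            (TumorMask.NECROTIC_CORE, TumorMask.ENHANCING, TumorMask.EDEMA),
            intensities,
        ):
            sel = comp == code
            data[sel] = val + texture[sel]
    mask = TumorMask(LabelVolume(comp, atlas_img.spacing, atlas_img.origin))
    return atlas_img.with_data(data), mask


def corrupt(vol: Volume3D, bias_order: int = 2, bias_amplitude: float = 0.2,
            noise_sigma: float = 2.0, seed: int = 0,
            brain_mask: Optional[np.ndarray] = None) -> Volume3D:
    """Multiplicative smooth polynomial bias (mean 1 over the brain) + noise."""
    if bias_amplitude < 0:
        raise ValueError("bias_amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    if brain_mask is None:
        brain_mask = vol.data > 0
    data = vol.data.astype(np.float64)
    if bias_amplitude > 0:
        coords = [
            2.0 * (np.arange(n, dtype=np.float64) / max(n - 1, 1)) - 1.0
            for n in vol.shape
        ]
        grid = np.meshgrid(*coords, indexing="ij")
        poly = np.zeros(vol.shape)
        for px in range(bias_order + 1):
            for py in range(bias_order + 1 - px):
                for pz in range(bias_order + 1 - px - py):
                    if px == py == pz == 0:
                        continue
                    coef = rng.uniform(-1.0, 1.0)
                    poly += coef * grid[0] ** px * grid[1] ** py * grid[2] ** pz
        peak = np.abs(poly[brain_mask]).max() if brain_mask.any() else np.abs(poly).max()
        if peak > 0:
            poly *= bias_amplitude / peak
        bias = 1.0 + poly
        bias /= bias[brain_mask].mean()
        data = data * bias
    if noise_sigma > 0:
        data = data + rng.normal(0.0, noise_sigma, size=vol.shape)
    return vol.with_data(data)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study conditions for the simulated cohort."""

    n_subjects: int = 40
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_region_pairs: int = 54
    n_midline_regions: int = 8
    hemisphere_assignment: str = "right"     # "right", "left" or "both"
    # mass-effect parameter ranges
    tumor_radius_range: tuple[float, float] = (8.0, 10.0)
    peak_displacement_max: float = 8.0
    peak_displacement_min: float = 1.0
    decay_length_range: tuple[float, float] = (9.0, 11.0)
    # anatomical variability
    anatomical_rms_mm: float = 0.35
    anatomical_smooth_mm: float = 8.0
    # survival model: days = s0 - beta * vbar + N(0, sigma), floored at 1
    survival_s0_days: float = 680.0
    survival_beta: float = 4500.0
    survival_sigma_days: float = 40.0
    n_designated_regions: int = 6
    # a region is "null" when the across-subject spread of its tumor-driven
    # variance is below this fraction of the spread of its total variance
    null_coupling_ratio: float = 0.1
    # image corruption
    bias_amplitude: float = 0.15
    noise_sigma: float = 2.0
    make_images: bool = True
    min_voxels: int = 10
    seed: int = 0


@dataclass
class CohortTruth:
    """Ground truth the estimators are later judged against."""

    params: list[MassEffectParams]
    true_variance: pd.DataFrame        # subjects x region_id, total field
    tumor_only_variance: pd.DataFrame  # subjects x region_id, mass-effect field only
    designated_region_ids: dict[str, list[int]]  # per tumor hemisphere
    null_region_ids: list[int]
    vbar: pd.Series                    # per-subject coupled quantity (mm^2)
    survival_s0_days: float
    survival_beta: float
    survival_sigma_days: float
    seed: int


@dataclass
class Cohort:
    atlas: AtlasBundle
    subjects: list[SubjectBundle]
    records: pd.DataFrame
    truth: CohortTruth


def _sample_center(rng: np.random.Generator, atlas: AtlasBundle, hemisphere: str,
                   r_edema: float) -> np.ndarray:
    """Tumor centre inside the requested hemisphere with the edema sphere in-brain."""
    shape = np.asarray(atlas.t1.shape, dtype=np.float64)
    spacing = atlas.t1.spacing
    c_mid = (shape - 1) / 2 * spacing
    semi = np.array([0.42 * shape[0], 0.36 * shape[1], 0.34 * shape[2]]) * spacing
    sign = 1.0 if hemisphere == "right" else -1.0
    for _ in range(200):
        cand = np.array([
            c_mid[0] + sign * rng.uniform(0.28, 0.36) * semi[0],
            c_mid[1] + rng.uniform(-0.10, 0.10) * semi[1],
            c_mid[2] + rng.uniform(-0.10, 0.10) * semi[2],
        ])
        rel = (cand - c_mid) / semi
        margin = (r_edema + 4.0) / semi.min()
        if np.sqrt(np.sum(rel**2)) <= 1.0 - margin:
            return cand
    raise RuntimeError("could not place tumor inside the brain")


def _regional_variance_of(fld: DisplacementField, atlas: AtlasBundle,
                          subject_id: str, min_voxels: int) -> pd.Series:
    table = regional_variance(magnitude_map(fld), atlas.labels, atlas.regions,
                              min_voxels=min_voxels, subject_id=subject_id)
    return table.set_index("region_id")["medh_mm2"]


def simulate_cohort(config: CohortConfig = CohortConfig()) -> Cohort:
    """Draw a full synthetic cohort with known truth.

    Per subject: mass-effect parameters with the tumor centre in the assigned
    hemisphere; subject image = corrupt(warp(insert_tumor(atlas))); survival
    = s0 - beta * vbar + noise (floored at one day), where vbar is the mean
    true magnitude-variance over the designated contralateral regions.
    """
    if config.n_subjects < 4:
        raise ValueError("need at least 4 subjects")
    if config.hemisphere_assignment not in ("left", "right", "both"):
        raise ValueError("hemisphere_assignment must be left, right or both")
    rng = np.random.default_rng(config.seed)
    atlas = make_atlas(config.grid_shape, config.spacing, config.n_region_pairs,
                       config.n_midline_regions, seed=config.seed)

    n = config.n_subjects
    if config.hemisphere_assignment == "both":
        hemis = ["right" if i < (n + 1) // 2 else "left" for i in range(n)]
    else:
        hemis = [config.hemisphere_assignment] * n

    subjects: list[SubjectBundle] = []
    params_list: list[MassEffectParams] = []
    total_var_rows, tumor_var_rows = [], []
    records = []

    for i in range(n):
        sid = f"sub-{i + 1:03d}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        r_t = sub_rng.uniform(*config.tumor_radius_range)
        lam = sub_rng.uniform(*config.decay_length_range)
        # D_max ~ D_hi * sqrt(U): makes D_max^2 (which regional variance tracks)
        # uniform, spreading subjects evenly across the survival range
        u = sub_rng.uniform()
        d_max = max(config.peak_displacement_min,
                    config.peak_displacement_max * np.sqrt(u))
        d_max = min(d_max, 0.9 * lam)
        center = _sample_center(sub_rng, atlas, hemis[i], r_t)
        params = MassEffectParams(tuple(center), r_t, d_max, lam)
        params_list.append(params)

        tumor_field = mass_effect_field(params, atlas.t1)
        anat_field = anatomical_variability_field(
            atlas.t1, atlas.brain_mask, config.anatomical_rms_mm,
            config.anatomical_smooth_mm, seed=sub_seed,
        )
        total_field = _add_fields(tumor_field, anat_field)

        total_var_rows.append(_regional_variance_of(total_field, atlas, sid,
                                                    config.min_voxels))
        tumor_var_rows.append(_regional_variance_of(tumor_field, atlas, sid,
                                                    config.min_voxels))

        tumor_img, tumor_mask_atlas = insert_tumor(atlas.t1, params, seed=sub_seed)
        if config.make_images:
            warped = warp(tumor_img, total_field)
            img = corrupt(warped, bias_amplitude=config.bias_amplitude,
                          noise_sigma=config.noise_sigma, seed=sub_seed,
                          brain_mask=warped.data > 0)
            mask_sub = TumorMask(warp_labels(tumor_mask_atlas.compartments,
                                             total_field))
        else:
            img = None
            mask_sub = tumor_mask_atlas

        subjects.append(SubjectBundle(
            subject_id=sid,
            t1=img if img is not None else tumor_img,
            tumor=mask_sub,
            true_field=total_field,
            tumor_in_atlas=tumor_mask_atlas,
            params={"tumor_radius": r_t, "peak_displacement": d_max,
                    "decay_length": lam, "center": tuple(center),
                    "seed": sub_seed, "hemisphere": hemis[i]},
        ))
        records.append({"subject_id": sid, "tumor_hemisphere": hemis[i],
                        "age_years": float(np.clip(sub_rng.normal(58.0, 10.0), 25, 85)),
                        "kps": int(np.clip(np.round(sub_rng.normal(80, 12) / 10) * 10,
                                           40, 100)),
                        "tumor_volume_ml": mask_sub.volume_ml,
                        "event": 1})

    total_var = pd.DataFrame(total_var_rows)
    tumor_var = pd.DataFrame(tumor_var_rows)
    total_var.index = [s.subject_id for s in subjects]
    tumor_var.index = [s.subject_id for s in subjects]

    region_hemi = atlas.regions.set_index("region_id")["hemisphere"]
    mean_tumor_var = tumor_var.mean(axis=0)
    designated: dict[str, list[int]] = {}
    for hemi in sorted(set(hemis)):
        contra = "left" if hemi == "right" else "right"
        contra_ids = region_hemi[region_hemi == contra].index
        ranked = mean_tumor_var.loc[contra_ids].sort_values(ascending=False)
        designated[hemi] = [int(r) for r in ranked.index[:config.n_designated_regions]]
    coupling = tumor_var.std(axis=0) / total_var.std(axis=0).replace(0.0, np.nan)
    null_ids = [int(r) for r in coupling.index
                if np.isfinite(coupling[r]) and coupling[r] < config.null_coupling_ratio]

    # survival: couple each subject to its own tumor-hemisphere designated set
    vbar = pd.Series({
        s.subject_id: float(total_var.loc[s.subject_id,
                                          designated[s.params["hemisphere"]]].mean())
        for s in subjects
    })
    noise = rng.normal(0.0, config.survival_sigma_days, size=n)
    survival = np.maximum(
        1.0, config.survival_s0_days - config.survival_beta * vbar.values + noise
    )

    records_df = pd.DataFrame(records)
    records_df["survival_days"] = survival
    records_df["survival_months"] = survival / DAYS_PER_MONTH

    truth = CohortTruth(
        params=params_list,
        true_variance=total_var,
        tumor_only_variance=tumor_var,
        designated_region_ids=designated,
        null_region_ids=null_ids,
        vbar=vbar,
        survival_s0_days=config.survival_s0_days,
        survival_beta=config.survival_beta,
        survival_sigma_days=config.survival_sigma_days,
        seed=config.seed,
    )
    return Cohort(atlas=atlas, subjects=subjects, records=records_df, truth=truth)
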