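"""Bias correction, tumor-excluding intensity standardization, skull-stripping.

Processing order is fixed: bias-correct, standardize intensities to the
template, then register.  Standardization is a monotone piecewise-linear
map between matched quantile landmarks of the source and template
histograms (255 bins, 64 landmark points by default); voxels under the
tumor exclusion mask never move the landmarks but are still mapped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .core_io import Volume3D, same_geometry

__all__ = [
    "IntensityMap",
    "estimate_brain_mask",
    "correct_bias",
    "learn_standardization",
    "apply_standardization",
    "skull_strip",
    "preprocess_subject",
    "PreprocessedSubject",
]

HISTOGRAM_BINS = 255
LANDMARK_POINTS = 64


def estimate_brain_mask(vol: Volume3D, noise_sigmas: float = 6.0) -> np.ndarray:
    """Foreground mask for images with noisy background.

    The background noise level is estimated robustly (MAD) from the corner
    blocks of the volume, which lie outside any head; voxels above
    ``noise_sigmas`` times that level, after morphological opening and hole
    filling, form the mask.  A class-separating threshold (e.g. Otsu) is
    deliberately avoided: with a dark CSF rim it tends to cut brain/CSF
    rather than brain/background.
    """
    from scipy.ndimage import binary_fill_holes, binary_opening

    data = vol.data
    k = max(2, min(8, min(data.shape) // 8))
    corners = []
    for sx in (slice(0, k), slice(-k, None)):
        for sy in (slice(0, k), slice(-k, None)):
            for sz in (slice(0, k), slice(-k, None)):
                corners.append(data[sx, sy, sz].ravel())
    bg = np.concatenate(corners)
    sigma = 1.4826 * np.median(np.abs(bg - np.median(bg)))
    # floor at a fraction of the bright-tissue level so noise-free images do
    # not degenerate to "everything above zero" (partial-volume rim included)
    bright = float(np.percentile(data, 99))
    thr = max(np.median(bg) + noise_sigmas * max(sigma, 1e-6), 0.05 * bright)
    mask = data > thr
    mask = binary_opening(mask, iterations=1)
    return binary_fill_holes(mask)


# ---------------------------------------------------------------------------
# Bias correction (N4)
# ---------------------------------------------------------------------------

def correct_bias(vol: Volume3D, brain_mask: Optional[np.ndarray] = None,
                 iterations: tuple[int, ...] = (40, 40, 30),
                 shrink_factor: int = 2) -> tuple[Volume3D, Volume3D]:
    """Remove a smooth multiplicative intensity inhomogeneity field.

    Returns ``(corrected, bias)`` with ``corrected = vol / bias``, the bias
    strictly positive and normalized to mean 1 over the brain mask.
    """
    if brain_mask is None:
        brain_mask = vol.data > 0
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    if float(np.ptp(vol.data[brain_mask])) <= 0:
        raise ValueError("degenerate (constant) input image")

    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.maximum(vol.data, 0.0).T, dtype=np.float32))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    msk = sitk.GetImageFromArray(np.ascontiguousarray(brain_mask.T.astype(np.uint8)))
    msk.SetSpacing(tuple(float(s) for s in vol.spacing))

    small = sitk.Shrink(img, [shrink_factor] * 3)
    small_mask = sitk.Shrink(msk, [shrink_factor] * 3)
    n4 = sitk.N4BiasFieldCorrectionImageFilter()
    n4.SetMaximumNumberOfIterations(list(iterations))
    n4.Execute(small, small_mask)
    log_bias = n4.GetLogBiasFieldAsImage(img)
    bias = np.exp(sitk.GetArrayFromImage(log_bias).T.astype(np.float64))
    bias /= bias[brain_mask].mean()
    corrected = np.maximum(vol.data / bias, 0.0)
    return vol.with_data(corrected), vol.with_data(bias)


# ---------------------------------------------------------------------------
# Intensity standardization
# ---------------------------------------------------------------------------

@dataclass
class IntensityMap:
    """Monotone piecewise-linear intensity transform from matched landmarks."""

    source_landmarks: np.ndarray
    template_landmarks: np.ndarray

    def __post_init__(self) -> None:
        self.source_landmarks = np.asarray(self.source_landmarks, dtype=np.float64)
        self.template_landmarks = np.asarray(self.template_landmarks, dtype=np.float64)
        if self.source_landmarks.shape != self.template_landmarks.shape:
            raise ValueError("landmark arrays must have equal length")
        if np.any(np.diff(self.source_landmarks) < 0):
            raise ValueError("source landmarks must be non-decreasing")

    @classmethod
    def identity(cls, lo: float = 0.0, hi: float = 1.0) -> "IntensityMap":
        pts = np.array([lo, hi])
        return cls(pts, pts.copy())

    def __call__(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=np.float64)
        src, tgt = self.source_landmarks, self.template_landmarks
        out = np.interp(values, src, tgt)
        # linear extrapolation from the end segments
        lo_slope = _end_slope(src, tgt, 0)
        hi_slope = _end_slope(src, tgt, -1)
        below = values < src[0]
        above = values > src[-1]
        out[below] = tgt[0] + (values[below] - src[0]) * lo_slope
        out[above] = tgt[-1] + (values[above] - src[-1]) * hi_slope
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"source_landmark": self.source_landmarks,
                             "template_landmark": self.template_landmarks})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "IntensityMap":
        return cls(frame["source_landmark"].to_numpy(),
                   frame["template_landmark"].to_numpy())


def _end_slope(src: np.ndarray, tgt: np.ndarray, which: int) -> float:
    if which == 0:
        i, j = 0, 1
    else:
        i, j = -2, -1
    ds = src[j] - src[i]
    return (tgt[j] - tgt[i]) / ds if ds > 0 else 1.0


def _histogram_landmarks(values: np.ndarray, bins: int, points: int) -> np.ndarray:
    """Uniformly spaced quantiles (incl. min/max) read off a binned CDF."""
    values = values[np.isfinite(values)]
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return np.full(points, lo)
    hist, edges = np.histogram(values, bins=bins, range=(lo, hi))
    cdf = np.concatenate([[0.0], np.cumsum(hist)]) / values.size
    probs = np.linspace(0.0, 1.0, points)
    # invert the CDF on bin edges; ties resolved by the leftmost edge
    landmarks = np.interp(probs, cdf, edges)
    landmarks[0], landmarks[-1] = lo, hi
    return np.maximum.accumulate(landmarks)


def learn_standardization(source: Volume3D, template: Volume3D,
                          exclude_mask: Optional[np.ndarray] = None,
                          source_brain_mask: Optional[np.ndarray] = None,
                          template_brain_mask: Optional[np.ndarray] = None,
                          template_exclude_mask: Optional[np.ndarray] = None,
                          bins: int = HISTOGRAM_BINS,
                          points: int = LANDMARK_POINTS,
                          threshold_at_mean: bool = False) -> IntensityMap:
    """Learn the piecewise-linear landmark map from source to template.

    Landmarks are matched quantiles of the two brain histograms; background
    (zero) voxels are excluded everywhere, and tumor voxels (``exclude_mask``)
    are excluded from the source histogram so lesion intensities cannot bend
    the map — they are still transformed when the map is applied.  Both brain
    masks are eroded by one voxel before the histograms are taken: the
    partial-volume rim dilutes the low quantiles differently on the two
    sides and would otherwise bend the low end of the map.
    """
    from scipy.ndimage import binary_erosion

    src_sel = (source.data > 0) if source_brain_mask is None \
        else np.asarray(source_brain_mask, dtype=bool) & (source.data > 0)
    src_sel = binary_erosion(src_sel, iterations=1)
    if exclude_mask is not None:
        src_sel = src_sel & ~np.asarray(exclude_mask, dtype=bool)
    tpl_sel = (template.data > 0) if template_brain_mask is None \
        else np.asarray(template_brain_mask, dtype=bool) & (template.data > 0)
    tpl_sel = binary_erosion(tpl_sel, iterations=1)
    if template_exclude_mask is not None:
        # drop the geometrically corresponding voxels from the template
        # histogram so both quantile sets cover comparable anatomy
        tpl_sel = tpl_sel & ~np.asarray(template_exclude_mask, dtype=bool)
    src_vals = source.data[src_sel]
    if src_vals.size < points:
        raise ValueError(
            f"only {src_vals.size} source voxels after exclusion; need >= {points}")
    tpl_vals = template.data[tpl_sel]
    if tpl_vals.size < points:
        raise ValueError("too few template voxels")
    if threshold_at_mean:
        # classic histogram-matching convention: landmarks from voxels above
        # each image's mean only, which keeps the unstable dark tail
        # (partial-volume rim, CSF mass changes) from bending the map
        src_hi = src_vals[src_vals > src_vals.mean()]
        tpl_hi = tpl_vals[tpl_vals > tpl_vals.mean()]
        if src_hi.size >= points and tpl_hi.size >= points:
            src_vals, tpl_vals = src_hi, tpl_hi
    return IntensityMap(
        _histogram_landmarks(src_vals, bins, points),
        _histogram_landmarks(tpl_vals, bins, points),
    )


def apply_standardization(vol: Volume3D, imap: IntensityMap) -> Volume3D:
    """Voxelwise application; background zeros stay zero."""
    out = imap(vol.data)
    out[vol.data == 0] = 0.0
    return vol.with_data(out)


# ---------------------------------------------------------------------------
# Skull stripping via atlas mask propagation
# ---------------------------------------------------------------------------

def skull_strip(subject: Volume3D, template: Volume3D,
                template_brain_mask: np.ndarray,
                registration_params=None) -> np.ndarray:
    """Subject-space brain mask from template-to-subject registration.

    Registers the template to the subject (the tumor is unknown at this
    stage, so no exclusion mask) and carries the template brain mask over
    with nearest-neighbour interpolation.
    """
    from . import registration

    template_brain_mask = np.asarray(template_brain_mask, dtype=bool)
    if not template_brain_mask.any():
        return np.zeros(subject.shape, dtype=bool)
    params = registration_params or registration.RegistrationParams(
        levels=2, iterations=(40, 20))
    result = registration.register_pair(fixed=subject, moving=template,
                                        params=params)
    mask_vol = Volume3D(template_brain_mask.astype(np.float64),
                        template.spacing, template.origin)
    from .core_io import warp
    stripped = warp(mask_vol, result.forward, interpolation="nearest")
    return stripped.data > 0.5


# ---------------------------------------------------------------------------
# Subject-level orchestration used by the extraction pipeline
# ---------------------------------------------------------------------------

@dataclass
class PreprocessedSubject:
    t1: Volume3D
    bias: Volume3D
    intensity_map: IntensityMap
    brain_mask: np.ndarray


def preprocess_subject(subject, atlas, bins: int = HISTOGRAM_BINS,
                       points: int = LANDMARK_POINTS,
                       skull_strip_subject: bool = False) -> PreprocessedSubject:
    """Bias-correct and standardize a subject against the template.

    The phantom subjects are already brain-only, so atlas-propagated
    skull-stripping is optional and off by default.
    """
    if skull_strip_subject:
        brain = skull_strip(subject.t1, atlas.t1, atlas.brain_mask)
    else:
        brain = estimate_brain_mask(subject.t1)
    corrected, bias = correct_bias(subject.t1, brain)
    imap = learn_standardization(
        corrected, atlas.t1, exclude_mask=subject.tumor.combined,
        source_brain_mask=brain, template_brain_mask=atlas.brain_mask,
        template_exclude_mask=subject.tumor.combined,
        bins=bins, points=points,
    )
    standardized = apply_standardization(corrected, imap)
    cleaned = standardized.data.copy()
    cleaned[~brain] = 0.0  # strip residual background noise
    return PreprocessedSubject(t1=standardized.with_data(cleaned), bias=bias,
                               intensity_map=imap, brain_mask=brain)
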