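# Methods

## The quantity being estimated

A growing brain tumor and its edema displace the surrounding tissue within
the fixed cranial vault (mass effect). Aligning a patient's T1-weighted MRI
to a healthy template with a diffeomorphic registration yields, at every
voxel, a displacement vector `u(x)` (mm) describing how far that tissue has
moved relative to normal anatomy. The headline feature of this package is
the **variance of the per-voxel displacement magnitudes
`|u| = sqrt(x² + y² + z²)` within each region of an anatomical
parcellation** — mass-effect deformation heterogeneity (MEDH, mm²). A region
that is uniformly translated has low MEDH; a region that is sheared or
differentially compressed has high MEDH. Regional MEDH values are then
associated with overall survival through Spearman rank correlation,
confounder-adjusted (partial) Spearman correlation, and Cox
proportional-hazards concordance.

The pipeline is, in order:

1. **Bias correction** — N4 (SimpleITK) removes the smooth multiplicative
   field induced by the scanner coil; the emitted field is strictly
   positive and normalized to mean 1 over the brain.
2. **Intensity standardization** — a monotone piecewise-linear map between
   matched quantile landmarks of the subject and template histograms
   (255 bins, 64 landmarks; background excluded; both brain masks eroded by
   one voxel so the partial-volume rim cannot bend the low landmarks).
   Voxels under the tumor segmentation are excluded from the source
   histogram — and their geometric counterparts from the template histogram,
   so that both quantile sets cover comparable anatomy — but they are still
   mapped when the transform is applied.
3. **Masked registration** — a 12-parameter affine (SimpleITK, Mattes mutual
   information, full sampling) followed by a symmetric, Gaussian-regularized
   demons-class diffeomorphic stage. The combined tumor segmentation
   (necrotic core + enhancing + edema), dilated by 3 voxels, is excluded
   from the similarity everywhere (cost-function masking): inside that zone
   the transform is purely the smoothness-regularized extension of its
   surroundings. Both forward (template-to-subject) and inverse
   (subject-to-template) fields are produced; the inverse — with the affine
   component composed in — is sampled on the template grid where the
   parcellation lives and is the field MEDH is computed from.
4. **Feature extraction** — per-voxel magnitude, then per-region sample
   variance (`n−1` denominator; a `ddof` switch exposes the population
   convention). Regions with fewer than `min_voxels = 10` voxels are flagged
   missing, not zero. The fraction of each region overlapped by the
   tumor is recorded so analyses can drop high-overlap regions; overlapped
   voxels are *not* excluded from the variance.
5. **Association battery** — per tumor-hemisphere group, per survival
   stratum (pooled long+short, and medium): plain and partial Spearman of
   regional MEDH against survival days; univariate Cox concordance for each
   region significant in the plain long+short analysis; one multivariate
   Cox model over those regions.

## Registration engine

The deformable stage iterates: warp the moving image through the running
field; compute a masked force field; smooth the update (fluid
regularization, `update_smoothing_sigma`, default 2 mm); compose with the
running field; smooth the total (elastic regularization,
`field_smoothing_sigma`, default 1 mm). Per-iteration updates are capped at
0.8 voxel, so each incremental map is invertible and the composition stays
diffeomorphic; the Jacobian determinant is checked numerically at the end
and non-positivity is an error. The inverse field comes from a damped
fixed-point iteration `v ← v + ½(−u(x + v) − v)`, with the residual
`|u(x+v)+v|` checked against a tolerance (default 0.5 mm; failure of more
than 1% of brain voxels is an error).

Two force models are available and matter in practice:

* `similarity="mutual_information"` — classic Thirion demons forces on the
  (standardized) intensities. Near-exact when subject and template
  intensities correspond faithfully: on a clean phantom pair the regional
  variance noise floor is ~10⁻³ mm².
* `similarity="local_correlation"` (default) — the same forces on locally
  mean-centered images (Gaussian window, `cc_sigma = 3 mm`). Smooth
  additive/low-frequency intensity distortion cancels, which is what
  survives N4 and histogram standardization on real data.

A gradient floor (default 1 intensity unit/mm) zeroes forces where the
image carries no edge information, leaving flat tissue to the regularizer:
residual intensity offsets in textureless areas would otherwise drag
tissue steadily. The multiresolution pyramid uses conservative masks: a
coarse voxel whose support touches any excluded fine voxel is fully
excluded, with one extra coarse voxel of margin, because downsampling
otherwise smears lesion intensity past the exclusion mask. The masked
similarity (global normalized correlation or 32-bin joint-histogram MI) is
recorded at full resolution after each pyramid level and must be
non-decreasing; a decrease produces a convergence warning.

The affine metric defaults to mutual information rather than global
correlation: on mass-effect subjects the masked correlation optimum is a
genuinely ~10% scaled affine (the brain is locally expanded), which the
MI profile does not reward.

## Synthetic phantom and cohort

The generator emulates the study design end to end so every stage is
testable without external data.

* **Template**: an ellipsoidal "brain" (semi-axes ~54 × 46 × 44 mm on the
  default 64³ × 2 mm grid) with three tissue classes (CSF-like rim 35,
  GM-like band 80, WM-like core 115), per-region-pair intensity offsets
  (±8) and smooth within-tissue texture (SD 5, 4 mm correlation). The
  texture makes the intensity histogram continuous — piecewise-constant
  classes give a steppy CDF whose quantile landmarks are unstable — and
  gives the registration gradient information away from class boundaries.
* **Parcellation**: 54 mirrored left/right region pairs (recursive quantile
  splits of each hemisphere into box-like cells of near-equal volume; left
  regions are exact x-reflections of their right partners) plus 8 midline
  regions — 116 regions, matching the cardinality of whole-brain anatomical
  parcellations with non-hemispheric vermis entries.
* **Mass effect**: radial field `u(x) = m(d)·(x−c)/d` with
  `m(d) = D_max·d/r_t` inside the tumor radius and
  `m(d) = D_max·exp(−(d−r_t)/λ)` outside. `D_max/λ < 1` bounds `|m′| < 1`,
  a sufficient condition for `id + u` to be a diffeomorphism; it is
  enforced at construction and verified numerically in tests.
* **Tumor**: concentric necrotic core / enhancing rim / edema spheres
  (default radii 0.4·r_t, 0.7·r_t, r_t) painted hypo/hyper/intermediate
  with mild texture; an error if the edema sphere leaves the brain.
* **Anatomical variability**: a smooth random vector field (white noise per
  component, 8 mm Gaussian smoothing, rescaled to 0.35 mm RMS magnitude
  over the brain) added to the tumor field. This models benign
  subject-to-template anatomical differences. It is load-bearing for
  statistical calibration: without it, every region's variance is a
  deterministic monotone function of tumor size, all 116 regions correlate
  with survival, and no region is truly null.
* **Cohort**: tumor centres are drawn in a mid-hemisphere box
  (x-offset 0.28–0.36 of the semi-axis from the midline, ±10% jitter in
  y/z), `r_t ∈ [8, 10]` mm, `λ ∈ [9, 11]` mm, and `D_max = 8·sqrt(U)` mm
  (floored at 1 mm) so that `D_max²` — which regional variance tracks — is
  uniformly distributed and the survival strata are realistically occupied.
  Survival is `S = S₀ − β·v̄ + ε`, floored at 1 day, with `v̄` the mean
  *true* total-field variance over the designated contralateral region set
  (the 6 contralateral regions with the highest mean tumor-only variance),
  `S₀ = 680` days, `β = 4500` days/mm², `ε ~ N(0, 40²)` days. With these
  constants a 40-subject cohort typically lands near 10 short / 20 medium /
  10 long survivors (7- and 18-month cutoffs, 30.4375 days/month). Truth
  tables record the per-region variance of both the total and the
  tumor-only field; "null" regions are those whose tumor-only variance
  spread across subjects is under 10% of their total spread — the set
  against which false-positive rates are calibrated. Subject images are
  `corrupt(warp(insert_tumor(template)))`: multiplicative polynomial bias
  (order 2, amplitude 0.15, mean 1 over the brain) plus Gaussian noise
  (SD 2). All randomness flows from one seed; cohorts are bit-reproducible.

### What the phantom does not capture

Real brains have convoluted cortical geometry, fine-grained tissue
interfaces, multi-modal intensity relationships and scanner-specific
artifacts that the three-class ellipsoid lacks. Passing tests therefore
demonstrate the *correctness of the machinery* — masked registration
recovering smooth planted fields, exact variance bookkeeping, calibrated
statistics — not clinical-grade registration accuracy on patient MRI.
The deformation range (D_max up to 8 mm) was chosen for registration
recoverability at the 2 mm working resolution, not for fidelity to any
particular tumor biology.

## Measured error budget and its consequences

On intensity-faithful inputs (no corruption, no preprocessing) the
registration recovers a planted field (D_max = 4 mm, λ = 12 mm) with
~0.2 mm mean magnitude error, a regional-variance noise floor of
10⁻³–10⁻² mm², and region ranking that matches the truth at Spearman
ρ ≈ 0.95.

With the full preprocessing chain in the loop the floor rises to roughly
0.2–0.6 mm² in the worst regions. The dominant cause is intrinsic to
histogram standardization: mass-effect compression genuinely changes the
subject's intensity histogram (class proportions shift), so quantile
matching against the template bends intensities even for a
perfectly-acquired image, and the registration converts that spatially
structured intensity error into spurious displacement. N4 contributes a
smaller, lesion-centred halo (hence the 3-voxel exclusion dilation).
Consequently, regions whose true variance sits below the floor are ranked
unreliably; full-pipeline rank recovery on default-corruption phantoms is
ρ ≈ 0.5–0.75. Cohort-level statistical tests therefore run on the
ground-truth-field bypass path, which separates feature/statistics
correctness from registration error by construction.

## Statistical conventions

* Spearman: average ranks; two-sided p via the t approximation, exact
  permutation over all `n!` orderings for `n ≤ 9` (config-selectable).
  Constant input is undefined and flagged.
* Partial Spearman: rank-transform x, y and each confounder; regress both
  rank vectors on the rank-confounders plus intercept; Pearson correlation
  of the residuals; p from t with `n − 2 − k` df. A variable fully
  explained by the confounders leaves zero residual variance; the partial
  association is then reported as null (r = 0, p = 1) with a warning.
  Constant confounder columns drop out, recovering the plain correlation.
* Concordance: Harrell's C over comparable pairs (the shorter-surviving
  member had the event); tied risks count ½.
* Cox: Breslow tie handling (scikit-survival); features are standardized
  internally for optimizer stability and coefficients returned on the
  original scale; under monotone likelihood (perfect separation) the fit
  falls back to a light ridge penalty, which leaves the risk ranking — and
  hence the concordance index — intact. All subjects are treated as events
  unless an event column is supplied.
* Significance markers: `**` for p < 0.05, `*` for p < 0.1; no
  multiple-testing correction across regions in the headline tables, but
  Benjamini–Hochberg q-values are emitted alongside.
* The multivariate Cox model uses the regions significant in the plain
  long+short analysis; when they outnumber what the sample size supports,
  the smallest-p regions up to `n − 3` are kept and the cap is noted in
  the report.
* Months-to-days conversion (stratification only): 30.4375 days/month.
  Correlations use survival days directly.

## Degenerate inputs and tie-breaks

Non-positive voxel spacing, oblique affine headers, 4D images, label
volumes with non-integer values, empty label volumes, empty or degenerate
brain masks, tumors leaving the brain, infeasible region counts,
nonpositive survival, collinear confounders and empty mask pairs (Dice)
are all rejected with specific errors. Out-of-bounds warp samples are
zero-filled and reported in a validity mask rather than extrapolated.
Quantile landmarks are made non-decreasing by cumulative max; ties in the
binned CDF resolve to the leftmost bin edge.

## Known limitations

* The demons-class engine recovers smooth fields well but underestimates
  deformation inside the exclusion zone by construction (no data term
  there) — measured at roughly half the planted magnitude. This mirrors
  the near-null behaviour reported for masked registration generally and
  is asserted as such in tests.
* Histogram standardization is the accuracy bottleneck of the full
  pipeline (see the error budget above); a contrast-adaptive force model
  only partly compensates.
* The working grid is configuration, not fixed; all defaults target
  64³ × 2 mm, where one full registration takes ~15 s on one CPU. Problem
  sizes in the test-suite (48³ unit phantoms, 20 × 40-subject bypass
  cohorts) were chosen so the whole suite and the acceptance benchmarks
  complete comfortably on a single CPU.
* Sample variance vs population variance is immaterial at realistic region
  sizes (hundreds of voxels) but pinned to `n−1` so tests are exact.
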