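# medh — mass-effect deformation heterogeneity

A growing brain tumor and its edema push the surrounding tissue around
inside the fixed cranial vault ("mass effect"). These deformations reach
far beyond the lesion — into the opposite hemisphere — and are mostly
sub-visual. `medh` quantifies them: it registers a tumor-bearing
T1-weighted MRI to a healthy template with a tumor-masked diffeomorphic
registration, takes the per-voxel displacement magnitude
`|u| = sqrt(x² + y² + z²)` (mm) from the subject-to-template field, and
summarizes each region `R` of an anatomical parcellation by

```
MEDH(R) = Var_{x ∈ R} |u(x)|        [mm²]
```

the *mass-effect deformation heterogeneity*. Regional MEDH values are then
tested for association with overall survival: per-region Spearman rank
correlation, partial Spearman adjusted for age and total tumor volume, and
Cox proportional-hazards concordance (univariate per region and
multivariate over the significant regions), run separately per tumor
hemisphere and survival stratum (short ≤ 7 months < medium ≤ 18 months <
long).

The package is aimed at neuro-imaging researchers who want to reproduce or
extend this class of displacement-field radiomics. Because the original
cohorts are external clinical data, `medh` ships a first-class synthetic
phantom module: a labeled template, tumors with analytically known
mass-effect fields, and cohorts whose survival is negatively coupled to
contralateral deformation heterogeneity — so every stage, from cost-function
masking to null calibration of the statistics, is testable on its own.

## Worked example

Simulate a 40-subject cohort (right-hemisphere tumors, survival coupled to
contralateral MEDH), then run the association battery on the
ground-truth-field features:

```python
from medh import phantom, survival

cohort = phantom.simulate_cohort(
    phantom.CohortConfig(n_subjects=40, make_images=False, seed=7))

long = (cohort.truth.true_variance.rename_axis("subject_id").reset_index()
        .melt(id_vars="subject_id", var_name="region_id", value_name="medh_mm2")
        .merge(cohort.atlas.regions, on="region_id"))
report = survival.run_association_analysis(long, cohort.records)

corr = report.correlations
plain = corr[(corr["group"] == "long+short") & (corr["analysis"] == "plain")]
print(plain.nsmallest(5, "p")[["region_name", "hemisphere", "r", "p", "marker"]])
```

prints

```
region_name      hemisphere         r            p marker
Region_22_L            left -0.918690 1.624556e-09     **
  Midline_5 non-hemispheric -0.875776 9.367775e-08     **
Region_31_L            left -0.852061 4.849837e-07     **
  Midline_4 non-hemispheric -0.852061 4.849837e-07     **
Region_13_L            left -0.850932 5.207309e-07     **
```

The strongest associations are *negative* correlations in left-hemisphere
(contralateral) and midline regions — more deformation heterogeneity,
shorter survival — exactly the planted coupling: this cohort's designated
contralateral regions include 43 (= `Region_22_L`) and 61 (= `Region_31_L`).
The Cox stage of the same report gives a best univariate concordance of
0.89 and a multivariate concordance of 0.94 over the 19 retained regions
(`report.concordance`, `report.multivariate`); 1.0 is perfect ranking,
0.5 chance.

For the imaging half of the pipeline:

```python
from medh import extract_medh
table, qc = extract_medh(subject_bundle, atlas_bundle)   # N4 → standardize →
# masked affine+diffeomorphic registration → |u| → per-region variance
```

returns one 116-row table per subject (`region_id, medh_mm2, voxel_count,
tumor_overlap, missing`) plus a QC record with the inverse-consistency
residual. `use_true_field=True` bypasses registration with a phantom's
planted field.

## Command line

```bash
medh phantom    --config cohort.yaml --out cohort/        # synthetic cohort
medh preprocess --subject t1.nii.gz --tumor seg.nii.gz --template mni.nii.gz --out pre/
medh register   --fixed sub.nii.gz --moving template.nii.gz --exclude tumor.nii.gz --out reg/
medh extract    --subject-dir cohort/subjects/sub-001 --atlas-dir cohort/atlas --out medh.csv
medh stats      --medh medh.csv --subjects subjects.csv --out report/
medh full-run   --config config.yaml --out run/           # all of the above
medh validate   --atlas-dir cohort/atlas --subjects subjects.csv
```

`full-run` requires a `seed` in the config and is bit-reproducible: the
global seed is fanned out to per-stage child seeds, and rerunning the same
config yields byte-identical `medh.csv`. All volumes are NIfTI-1
(RAS-reoriented on load; axis-aligned headers only); displacement fields
are 3-component vector NIfTIs; tables are CSV.

## Documentation

`docs/methods.md` describes the deformation model, the registration
engine and its force models, the phantom's design and what it does and
does not emulate, the statistical conventions, the measured error budget,
and known limitations.
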