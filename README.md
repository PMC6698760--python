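# dvhpredict

Knowledge-based dose-volume-histogram (DVH) prediction for radiotherapy
treatment-plan quality assurance.

A cohort of historical plans is reduced to paired samples *(t, x)* — the
signed minimal distance *t* (mm) from each organ-at-risk (OAR) voxel to the
target (PTV) boundary, and the dose *x* (Gy) that voxel received.  A Gaussian
product-kernel conditional density *p(x | t)* is fitted per OAR class.  For a
new patient, the organ's dose density is obtained by marginalizing the
conditional over the patient's own voxel-distance distribution,

```
p_D(x) = (1/M) Σ_j p(x | t_j),        DVH(D) = 1 − ∫₀^D p_D(x) dx,
```

and summarized into clinical metrics (mean dose, V*d* cut-points, near-max
dose).  Predicted curves serve as a benchmark against which an achieved plan
is compared: per-metric mean difference and RMSE across a cohort, plus a
per-plan linear fit (slope, R²) of predicted vs. achieved DVH points.

Because no clinical dataset ships with the method, a synthetic phantom module
generates cohorts of esophageal-like plans (central target, overlapping
heart-like organ, paired lungs, thin cord) whose dose follows a known
logistic falloff in *t* with per-plan variability — giving every statistic an
analytic ground truth.

## Layout

| module | contents |
| --- | --- |
| `dvhpredict.volumes` | voxel grids, contour rasterization (even-odd), mask algebra, trilinear dose resampling |
| `dvhpredict.distance` | signed Euclidean distance transform (anisotropic spacing), (t, x) sample extraction |
| `dvhpredict.kde_model` | bandwidth selection (Gaussian-reference / LSCV), conditional density with reflection at 0 Gy, marginalized dose density, JSON model files |
| `dvhpredict.dvh` | cumulative DVH curves from densities or samples, metric extraction |
| `dvhpredict.evaluation` | cohort mean/RMSE report, per-plan DVH linear fits |
| `dvhpredict.phantom` | synthetic cohort generator + analytic true DVH |
| `dvhpredict.io_cli` | NRRD volumes, portable plan bundles, minimal DICOM-RT codec, structure-name matching, YAML config, CLI |

## CLI

```sh
# 1. simulate a cohort of synthetic plans (portable format: plan.json + NRRD)
dvhpredict simulate --n-plans 20 --seed 42 --out cohort/train
dvhpredict simulate --n-plans 10 --seed 42 --start-index 100 --out cohort/test

# 2. train one KDE model per OAR class (JSON files)
dvhpredict train --plans cohort/train --out models/

# 3. predict one plan (DVH + metrics CSV)
dvhpredict predict --models models/ --plan cohort/test/plan_100 --out pred/

# 4. cohort evaluation (mean/RMSE table, linear fits, optional overlay plots)
dvhpredict evaluate --models models/ --plans cohort/test --out report/ --plots
```

Every pipeline default (0.1 Gy dose bin, 20 000-voxel per-structure
subsampling cap, bandwidth rule, per-class cut-points V30/V20/V5, near-max
fraction 0.1 %, structure-name match table) lives in one YAML-overridable
config; pass `--config cfg.yaml` to any command.

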