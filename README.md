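# dseg

Segmentation of the 2-D isotropic/anisotropic diffusion plane into 16
microstructural segments, per-scan spectrum summaries, a spectral-angle
score against a healthy reference, and the downstream cohort statistics
that turn that score into a biomarker: longitudinal mixed-effects change
models, two-stage slope regressions, Cox dementia-risk models and
leave-one-out cross-validated linear discriminant classification.

A synthetic-cohort generator (nested-ellipsoid eigenvalue phantoms with
severity-scaled lesion load, coupled cognition, and hazard-driven
conversion) makes every stage testable offline with known ground truth.

## Layout

| module | purpose |
| --- | --- |
| `dseg.pq` | tensor eigenvalues → isotropy `p = √3·MD` and anisotropy `q = ‖deviatoric‖` maps; OLS log-linear tensor fit for DWI input |
| `dseg.cluster` | pooled 2-D (p, q) histogram, k-medians segmentation (Euclidean Voronoi assignment, count-weighted coordinate-wise median update), per-voxel segment labels |
| `dseg.spectra` | 16-component percentage spectrum per scan; tissue-class summaries |
| `dseg.theta` | spectral angle `θ = arccos(⟨A,B⟩/(‖A‖‖B‖))`; fixed-point healthy-reference selection |
| `dseg.longitudinal` | mixed-effects change models (ML, random intercept + slope), empirical-Bayes subject slopes, slope-on-angle OLS regressions |
| `dseg.prediction` | z-scoring, Cox proportional hazards (Efron ties), pooled-covariance LDA, LOO-CV, sensitivity/specificity/accuracy/BCR/AUC |
| `dseg.synthetic` | phantom + cohort generator with recorded ground truth |
| `dseg.io`, `dseg.pipeline`, `dseg.cli` | NIfTI/TSV/JSON I/O, run manifest, stage orchestration, command-line interface |

## Command line

```sh
# (p, q) maps from a DWI volume or eigenvalue volume
pq compute --dwi X.nii.gz --bvals X.bval --bvecs X.bvec --mask M.nii.gz --out-p p.nii.gz --out-q q.nii.gz
pq from-eigenvalues --lambdas L.nii.gz --mask M.nii.gz --out-p p.nii.gz --out-q q.nii.gz

# pooled segment-model fit and per-scan assignment
dseg fit --pq-manifest scans.tsv --k 16 --out model.json
dseg assign --model model.json --p p.nii.gz --q q.nii.gz --mask M.nii.gz --out labels.nii.gz
dseg spectrum --labels labels.nii.gz --subject-id s01 --out spectra.tsv
dseg theta --spectra spectra.tsv --healthy-ids h01,h02 --out theta.tsv

# synthetic cohort + full pipeline
dseg-sim generate --out cohort_dir --seed 7
dseg run --out run_dir --seed 7            # generate → stats → predict → report
dseg-stats lme --cohort run_dir/cohort.csv --outcome EF --max-time 5
dseg-predict cox --subjects run_dir/subjects.csv --covariates theta_baseline
dseg-predict lda --subjects run_dir/subjects.csv --features theta_baseline,theta_slope --loo
```

`dseg run` accepts `--config cohort.yaml` (see `dseg.synthetic.SyntheticConfig`)
and `--stages` for partial re-runs with cached upstream outputs.

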