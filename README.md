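# mkldecode

Atlas-based multiple kernel learning (MKL) decoding of whole-brain fMRI
contrast images.

Whole-brain multivariate pattern analysis is sensitive but hard to
interpret: a single pattern spanning tens of thousands of voxels says
little about which brain regions carry the information. `mkldecode`
addresses this by modelling the whole-brain pattern as a sparse convex
combination of per-region patterns. Given an anatomical parcellation
that splits the masked brain into R regions, each region contributes a
linear kernel K_m over subjects, and the decoder is a kernel machine on

    K(d) = Σ_m d_m K_m,    d_m ≥ 0,  Σ_m d_m = 1,

with the kernel weights d learned jointly with the machine (SimpleMKL).
The L1 simplex constraint drives uninformative regions to weight
exactly zero, so the fitted model directly yields a ranking of regions
by their contribution — and, for linear kernels, explicit voxel-level
weights within each region.

The package implements the full analysis pipeline around that model:

* **synthetic** — generators for parcellations, per-condition contrast
  images, block-design BOLD sessions, subject ratings (the
  threat-perception index: the sum of four 1–9 threat ratings) and
  analytic stimulus pictures, so every stage is testable without data
  downloads;
* **glm** — first-level GLM: canonical double-gamma HRF, block
  regressors, discrete-cosine drift basis (128-s cut-off), motion
  covariates, voxelwise OLS, run-averaged condition-vs-baseline
  contrasts, common NaN masking;
* **kernels** — atlas parcellation into region feature blocks, linear
  kernels, feature-space mean-centring and trace normalisation with
  train/test hygiene;
* **mkl** — the SimpleMKL solver for binary classification (SVM) and
  ε-insensitive regression (SVR), plus back-projection of region and
  voxel weights;
* **evaluation** — subject-level LOSO and 10-fold nested
  cross-validation, pooled metrics (per-class/balanced accuracy,
  ROC/AUC; Pearson r, R² = r², MSE), and permutation tests with
  p = (1 + #{at least as good}) / (n_perm + 1);
* **reporting** — fold-averaged region rankings, per-lobe weight sums,
  NIfTI weight-map export;
* **stimuli** — picture standardisation metrics (brightness, contrast,
  spatial frequency) and rating aggregation;
* **cli** — a `mkldecode` console command tying the stages together
  from a YAML config.

See `docs/methods.md` for the model, conventions and numerical choices.

## Worked example

Decode threat vs. neutral conditions from a simulated 16-subject study
in which region 3 of an 8-region synthetic atlas carries a condition
effect twice the noise SD:

```yaml
# example_cfg.yaml
task: classify
synthetic_scenario:
  design: {n_subjects: 16}
  effect: {informative_region_ids: [3], delta: 1.0, sigma: 0.5}
atlas_regions: 8
grid_shape: [16, 16, 16]
scheme: kfold
k: 4
C_grid: [0.01, 1.0, 100.0]
n_permutations: 100
seed: 7
out_dir: example_run
```

```bash
mkldecode run --config example_cfg.yaml
```

prints

```
Cross-validated classification performance (pooled):
  balanced accuracy  96.88 (p = 0.01) %
  class 1 (threat)   93.75 (p = 0.01) %
  class 2 (neutral)  100.00 (p = 0.01) %
  ROC/AUC            1.00 (p = 0.01)
```

Balanced accuracy is the mean of the two per-class accuracies, pooled
over all outer-fold test subjects; p-values come from 100 reruns with
the class labels permuted within each subject's image pair, so 0.01 is
the smallest attainable value (the observed model beat every permuted
rerun). The run directory contains pooled predictions, permutation
null distributions, NIfTI weight maps and the region ranking; the top
of `example_run/region_ranking.csv`:

```
region_id,region_name,lobe_group,mean_pct,rank,selection_freq
3,region_3,temporal,72.26,1,1.00
6,region_6,cerebellum,18.98,2,0.75
1,region_1,frontal,7.57,3,0.75
```

The informative region (3) is ranked first with 72% of the kernel
weight and is selected in every fold — the model recovered both the
discrimination and its anatomical source. `lobe_summary.csv` sums the
percentages per lobe group, mirroring how region-level results are
summarised per cerebral lobe.

The same config with `task: regress` decodes each subject's
threat-perception index from the threat images and reports Pearson r,
R² and MSE instead.

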