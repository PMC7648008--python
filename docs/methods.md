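# Methods

`mkldecode` implements whole-brain decoding of fMRI contrast images in
which the multivariate pattern is modelled as a sparse convex
combination of anatomical-region patterns. This note documents the
model, the generative assumptions of the synthetic data, the numerical
choices, and what the test suite does and does not establish.

## Decoding model

Let x denote a subject's masked contrast image and let an atlas split
its voxels into R regions, giving regional feature vectors x^(1), …,
x^(R). Each region contributes a linear kernel
K_m(i, j) = ⟨x_i^(m), x_j^(m)⟩ over samples. The decoder is a kernel
machine on the combined kernel

    K(d) = Σ_m d_m K_m,   d_m ≥ 0,  Σ_m d_m = 1,

trained jointly over the kernel weights d and the machine's dual
variables (SimpleMKL). The L1 simplex constraint makes d sparse:
regions that do not help the prediction receive weight exactly zero.
The inner machine is a soft-margin SVM for classification (threat vs.
neutral condition labels, coded ±1) and an ε-insensitive support vector
regression for decoding the continuous threat-perception index. For
linear kernels both sets of weights can be made explicit: the region
weight is d_m and the voxel weights are w_m = d_m Σ_i u_i φ(x_i^(m)),
with u the signed dual vector and φ the centring/scaling transform the
kernels were built with.

### Kernel preprocessing

Kernels are mean-centred in feature space and then trace-normalised so
that the training submatrix has trace n_train. Centring first and
normalising second means the normalisation equalises each region's
*residual* scale rather than its raw one; the alternative order differs
only by a per-region constant and is not separately supported. Both
operations compute statistics on training rows only and apply them to
all rows; regions whose centred training kernel has zero trace (no
variance) are dropped with a warning, since a zero kernel cannot be
trace-normalised. Trace normalisation compensates for region size: the
trace of a linear kernel grows with voxel count, so without it large
regions dominate the combination for purely dimensional reasons.

### Optimisation

J(d) = max_u dual(u; K(d)) is convex in d with envelope gradient
∂J/∂d_m = −½ uᵀK_m u at the inner optimum. The solver minimises J on
the simplex in two phases:

1. **Reduced-gradient descent** (the SimpleMKL scheme): descent
   direction relative to the largest component, coordinates at zero
   with ascent pressure frozen, walk to the nearest simplex face while
   the objective decreases there (zeroing the blocking coordinate),
   then a quadratic-interpolation line search with an Armijo safeguard
   inside the last interval. Up to 12 passes.
2. **Sequential quadratic refinement** (SLSQP on the simplex with the
   same analytic gradient) when the duality gap is still above
   tolerance. First-order simplex descent is known to zigzag near the
   optimum once several regions' quadratic forms must equalise; the
   quasi-Newton model removes that tail at a fraction of the inner
   solves.

Both phases are deterministic: d starts uniform at 1/R, the inner QP is
solved by libsvm (via scikit-learn, tolerance 1e-6) which is
deterministic for a fixed problem, and no randomness enters the line
searches. Termination is at duality gap
max_m ½uᵀK_mu − ½uᵀK(d)u ≤ tol·max(1, |J|) with tol = 1e-4 (default),
or max_iter = 500 with the best iterate retained and a warning raised.
Weights below 1e-6 are reported as exactly zero and the simplex is
renormalised; the duals are re-solved once for the sparsified weights
so that model coefficients are mutually consistent.

Regression targets are mean-centred on the training fold (the mean is
restored at prediction) so the bias interacts cleanly with centred
kernels; ε defaults to 0.1 × SD of the training targets.

## Cross-validation and inference

Folds are always subject-level — both condition images of a subject
stay on one side of every split — under leave-one-subject-out (LOSO) or
k-fold (k = 10; fold sizes differ by at most one, assignment shuffled
by the seed). Hyperparameter C is selected per outer fold by an inner
cross-validation of the same scheme restricted to the outer-training
subjects, scored on pooled inner predictions (balanced accuracy for
classification, MSE for regression), with ties resolved toward the
smallest C. Kernel statistics and target means are recomputed from the
training side of every split, inner or outer, so held-out data never
influence fitting. The default C grid is {0.01, 0.1, 1, 10, 100}.

Test predictions are pooled across outer folds before computing
metrics. Per-class accuracy is the pooled fraction correct per class
and balanced accuracy their mean, which makes every LOSO accuracy an
integer multiple of 100/n_subjects. The ROC curve pools decision
values over all folds (with one test subject per LOSO fold a per-fold
ROC is undefined) and AUC is its trapezoidal area with midrank tie
handling. For regression: Pearson r, R² = r², and MSE.

Significance is by permutation: the pipeline is re-run n_perm times
(default 100) with permuted labels, holding fold plans and the C grid
fixed, and

    p = (1 + #{permutations at least as good}) / (n_perm + 1),

where "at least as good" compares absolute metric values and is
reversed for MSE. The add-one convention keeps p ≥ 1/(n_perm + 1), so
an observed metric beating all 100 permutations prints as p = 0.01.
Classification permutes the class labels within each subject's image
pair, preserving the paired design (a free across-sample permutation is
available behind a flag); regression permutes the target vector across
subjects. Re-running the full nested search for every permutation is
the conservative default; a fast mode fixes C (the modal selected
value) during permutations, which is also what the end-to-end runner
uses by default.

## Region reporting

Kernel weights are averaged across outer folds, renormalised to
percentages summing to 100 (a no-op unless folds dropped regions), and
ranked in descending order with ties broken by region id. A selection
frequency — the fraction of folds with d_m > 0 — is added as a
stability diagnostic; it is an extension, not part of the ranking
itself. Lobe summaries sum the percentages over each region's lobe
group. Voxel-weight volumes are the fold-average of the per-fold
primal weights assembled on the atlas grid.

## Synthetic data

The generator emulates the study design the pipeline assumes: 38
subjects, four conditions (threat/neutral × towards/away), 4 runs of
198 volumes at TR = 2 s, 56 blocks of 15 s (14 per condition, every
condition present in every run) separated by 12-s fixation baselines.

* **Atlas** — region centres drawn uniformly in an ellipsoidal
  brain-like mask, voxels assigned to the nearest centre (Voronoi), so
  regions are contiguous blobs; lobe groups assigned round-robin from
  six labels. Default test atlas: 8 regions on a 16³ grid of 4-mm
  voxels (a down-scaled stand-in for a 120-region parcellation, which
  the pipeline equally accepts).
* **Contrast images** — threat-condition images receive
  δ + γ·z(index) in the voxels of the informative regions, where
  z(index) is the subject's standardised threat-perception index;
  neutral conditions have zero mean. A per-subject offset
  (SD 0.2 by default) and iid Gaussian noise (σ = 0.5) are added inside
  the mask; an optional Gaussian-smoothed noise component approximates
  spatial correlation after smoothing. Outside the mask voxels are NaN.
  Optional NaN injection (off by default) punches holes in ~1% of
  mask-border voxels for a random half of subjects, to exercise the
  common-mask rule.
* **Ratings** — four per-subject ratings from a discretised truncated
  normal on 1–9 (mean 3, SD 2), summed into the threat-perception
  index (range 4–36). This puts the index mean/SD near the reported
  towards-context values (≈12.4 / 7.5); only the mean and SD of the
  real distribution are known, so the distributional form is a
  stand-in, not a claim.
* **BOLD** — per run, signal = baseline (100) + Σ_condition
  amplitude·(boxcar ⊛ canonical HRF) + a slow cosine drift
  (amplitude 0 by default, configurable) + AR(1) noise (ρ = 0.3).
  Amplitudes follow the same effect specification as the contrast
  generator. Six smooth sinusoidal nuisance series stand in for motion
  parameters.

Default effect sizes used by the recovery tests are δ = 1.0 against
σ = 0.5 (a voxelwise effect twice the noise SD) and γ = 1.0; null
scenarios set δ = γ = 0. What the generator does *not* model:
hemodynamic nonlinearity, physiological noise, motion artifacts,
inter-subject anatomical variability, realistic spatial covariance.
Passing recovery tests therefore demonstrate the pipeline's
correctness and sensitivity under its own assumptions, not expected
performance on real data.

## First-level GLM

The canonical HRF is the conventional double gamma (peak delay 6 s,
undershoot delay 16 s, unit dispersions, peak:undershoot ratio 6, 32-s
support), sampled per TR; regressors are built by convolving condition
boxcars with the HRF on a 16× oversampled microtime grid and sampling
at scan times. Low frequencies are modelled by a discrete-cosine basis
with a 128-s cut-off period (the number of drift terms is
⌊2·T/cutoff⌋); motion covariates enter as columns of no interest, plus
a per-run constant. The first 3 volumes of each run are dropped and
onsets shifted accordingly. Runs are modelled independently and
per-condition contrast estimates averaged across runs (averaging, not
summing, keeps units independent of run count; the alternative is a
constant factor). The baseline is the unmodelled inter-block fixation
interval, so the contrast vector selects the condition column alone.
Estimation is voxelwise OLS without autocorrelation prewhitening — a
deliberate simplification: OLS amplitude estimates are unbiased under
stationary noise, and nothing downstream consumes their standard
errors. Voxels that are NaN in any subject's image are excluded for
all subjects (common mask).

## Picture metrics

Brightness = mean over pixels of the per-pixel mean of R, G, B.
Contrast = sample SD across image columns of the per-column mean RGB
value. Spatial frequency = median FFT power (|FFT|², zero-frequency
term excluded) per row and per column, with row- and column-median
averages averaged. Excluding the DC term makes the metric invariant to
constant offsets (otherwise a uniform picture would have nonzero
"frequency"); "mean RGB value per pixel" is read as the mean of the
three channels. The footnote-style definitions admit other readings
(amplitude vs. power, exact median/averaging order); the implemented
choice is fixed and oracle-tested, not asserted to be bit-identical to
the original scripts.

## Problem sizes and tolerances in the test suite

The suite runs entirely on synthetic data at desk scale: recovery and
null pipelines use the full 38-subject design with an 8-region 16³
atlas, 10-fold nested CV and a reduced C grid {0.01, 1, 100}; the
permutation-calibration property uses a 12-subject, 3-region study at
4-fold CV with C fixed during permutations, 49 permutations and 100
pipeline seeds, testing the AUC p-values against U(0, 1) by
Kolmogorov–Smirnov at α = 0.01. Calibration is read on AUC rather
than balanced accuracy because accuracy is coarsely discrete at small
n and the "at least as good" tie rule then makes its p-values
conservative by construction. Key numeric tolerances: OLS recovery
1e-6 relative; kernel-trick consistency 1e-8 relative Frobenius;
MKL-vs-grid-oracle 1e-3 on the objective; single-kernel MKL vs. plain
kernel machine 1e-6 on decision values; duality-gap tolerance 1e-4.

## Known limitations

* The inner QP is libsvm's numerical solution (tolerance 1e-6), not an
  exact rational optimum; all oracle comparisons inherit that floor.
* Kernel centring/normalisation constants follow the explicit contract
  above and may differ from other toolboxes' conventions by an order
  of operations.
* The permutation fast mode fixes C during permutations; when the
  observed run's selected C varies strongly across folds the
  conservative full-nested mode is preferable.
* LOSO nested CV refits O(n²·|grid|) models and is substantially
  slower than 10-fold; both are supported, tests default to 10-fold.
* Only binary classification and scalar regression are implemented; no
  nonlinear kernels, no elastic-net kernel combinations.
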