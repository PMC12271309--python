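# Methods

This note documents the statistical and numerical choices behind
`bodycomp`: what each component computes, the assumptions it makes, the
defaults and why, and what the synthetic generators do and do not emulate.

## Label scheme and volumes

All segmentations use a fixed six-class scheme (0 background, 1
cavity-excluded, 2 SF, 3 VF, 4 PM, 5 EM).  Derived classes TF = SF+VF and
TM = PM+EM are always computed, never stored.  Volumes are voxel counts
times the voxel volume from the stored mm spacing, reported in mL, computed
on the native grid (no resampling).  NIfTI inputs are normalised to
canonical (RAS) axis order on read; voxel values outside 0–5 or non-integer
data are schema errors, not silently clipped.

## Accuracy metrics

DSC and IOU are plain voxel-count overlap measures and satisfy
IOU = DSC/(2−DSC) identically.  Boundary metrics use one consistent surface
definition: a surface voxel is a foreground voxel with at least one
face-adjacent (6-connected) background voxel, and distances are exact
Euclidean distances between surface-voxel *centres*, scaled by the spacing
(computed with a distance transform; verified exactly against an O(n²)
all-pairs oracle in the tests).  Conventions where the field has no single
standard:

* **HD95** pools the directed distance sets in both directions and takes
  the 95th percentile with linear interpolation between order statistics.
  The max-of-directed-percentiles dialect is available via
  `directed="max"`.
* **NSD tolerance** τ defaults to 2.0 mm (≈ 1.4 in-plane voxels at 1.46 mm),
  configurable everywhere it appears.
* **Degenerate masks**: both empty → DSC/IOU/NSD = 1, HD95 = 0, flagged;
  exactly one empty → DSC/IOU = 0 and the boundary metrics are NaN
  (undefined), flagged.  A number is never invented for an undefined
  quantity.
* **Weighted mean DSC** weights each foreground class (1–5) by its
  reference voxel count; background is excluded.  Aggregation across test
  subjects is an unweighted mean.

## STAPLE consensus

`staple_binary` is the classic EM estimator: per-voxel posterior foreground
weights given per-rater sensitivity/specificity (E-step, computed in log
space), then closed-form performance updates (M-step), iterated until
max |ΔW| < 1e-6 or 100 iterations.  The foreground prior π defaults to the
empirical foreground fraction of the rater average; initial p = q = 0.99999.
The observed-data log-likelihood is tracked every iteration and must be
non-decreasing.  All-foreground/all-background stacks degenerate to a
majority vote with a warning.

The six-class problem is handled **one-vs-rest**: a binary STAPLE per
foreground class, per-voxel argmax of the class weights, background where
every weight is below 0.5, ties to the lowest class index.  This is a
deliberate dialect — it matches the per-class evaluation the consensus
feeds — and is not the full multi-label confusion-matrix STAPLE.

A caution from testing: "consensus = majority vote for symmetric raters" is
exact for a *single E-step at fixed symmetric p = q with π = 0.5*, and is
verified exhaustively in that form.  The full EM does not guarantee it on
tiny degenerate stacks, where other likelihood fixed points exist (a lone
dissenting rater can be re-interpreted as the only sensitive one).

## Ensembles and post-processing

Averaging takes the argmax of the channel-wise mean probability; voting
takes the per-voxel modal label; both break ties to the lowest class index
for determinism.  The ensemble ladder from four base models enumerates
4 + 6 + 4 + 1 = 15 configurations in lexicographic block order.
Largest-component cleanup labels the union of foreground classes 1–5 with
26-connectivity and zeroes everything outside the largest component —
stray regions (e.g. arms) are removed whole, labels inside are untouched.

## Hierarchical area-bias model

Observations are per-slice area differences δ_nm = A_nm − a_n (cm²)
between segmentation model m and the consensus area a_n:

    δ_nm = α + β (a_n − ā) + u_m + ε_nm,
    u_m ~ N(0, σ²_inter),  ε_nm ~ N(0, σ²_intra).

The covariate is centred at ā so α is the bias at the mean area (also
reported as 100·α/ā %).  ICC = σ²_intra/(σ²_intra+σ²_inter) is defined so
that values well above 0.5 mean models behave like one another (inter-model
spread small relative to slice-level noise).  Priors are weakly informative
and scale-adaptive: α, β ~ N(0, (10·sd δ)²), half-Normal(5·sd δ) on both
SDs, with the non-centered parameterisation u_m = σ_inter·z_m.  Slices are
treated as independent; a shared per-patient effect across slices of the
same scan is a known omission.

**Sampler.**  Inference is a hand-written fixed-path-length Hamiltonian
Monte Carlo on the unconstrained vector (α, β, z, log σ_inter, log σ_intra)
with analytic gradients.  Warmup (default 500 iterations) adapts the step
size by dual averaging (target acceptance 0.9) and estimates a **dense mass
matrix** from an intermediate window, applied as a Cholesky change of
variables; sampling (default 3 chains × 1500 draws, no thinning) runs with
both frozen.  The dense mass is essential: α and the mean of the model
effects u_m form a correlated ridge that a diagonal mass leaves
slow-mixing.  Trajectory length defaults to 2.5 time units in whitened
coordinates, jittered ±30% against resonance; divergent (non-finite energy)
trajectories are rejected and counted.  Convergence is judged by the
classic split Gelman–Rubin statistic per scalar parameter (implementation
agrees with arviz to machine precision), with the conventional bar
r̂ < 1.1; non-convergence flags the result rather than raising.  At the
default settings on well-specified data, max split-r̂ rounds to 1.00.

Degenerate inputs: exactly-zero-variance differences are rejected at model
construction (the likelihood would be unbounded in σ_intra).  Near-zero
noise is handled, and the posterior mean of (α, β) then matches ordinary
least squares.

## Repeatability statistics

For paired double-baseline volumes (x_i1, x_i2):

* **wCV** (%) uses the squared-relative-difference estimator
  100·√(mean_i[(x_i1−x_i2)²/(2 m_i²)]).
* **σ_w,log** = √(Σ(ln x_i1 − ln x_i2)²/2n) feeds the repeatability
  coefficient RC_log = 1.96·√2·σ_w,log and the asymmetric limits
  100·(exp(±RC_log)−1), which satisfy (1+U/100)(1+L/100) = 1 exactly.
  The log scale is the natural one for volume measurements whose error is
  multiplicative; the two estimators agree to first order for small CV.
* **ICC** is the one-way random-effects form (MSB−MSW)/(MSB+MSW) for two
  interchangeable replicates; undefined (NaN) at zero total variance.

Stratification (e.g. by gender) recomputes all three per stratum; strata
with fewer than two complete pairs are skipped with a warning.

## Longitudinal classification

Percent change is measured against the *average* of the two baselines, and
a change counts as real only if it strictly exceeds the LOA limits
(boundary values are no_change).  Because the limits are built for a
difference of two single measurements (SD √2·σ) while the
change-vs-averaged-baseline statistic has SD √1.5·σ, the construction is
**conservative**: its theoretical false-positive rate on a no-change cohort
is 2·Φ(−1.96·√(4/3)) ≈ 2.4%, below the nominal 5%.  The tests assert both
facts — the averaged-baseline rate at its own theoretical value (and under
5%), and the exact 5% exceedance rate for a plain replicate pair.  Cohort
trend uses a two-sided paired t-test on raw volumes; gender comparisons use
Welch's test per tissue, including derived TF/TM.

## Synthetic generators

All generators are bit-reproducible given (spec, seed); one seed fans out
to per-component substreams via `numpy.random.SeedSequence`.

* **Phantom**: an elliptic-cylinder abdomen — SF ring outermost, EM ring
  inside it, then the cavity (class 1) holding deterministic VF blobs and
  two PM discs — at 1.46 × 1.46 × 4 mm spacing, 25 slices by default.  The
  SF ring volume has a closed form used as a geometry oracle (voxelisation
  agrees within 2% at this spacing).  No MRI intensities, no anatomical
  variability along z.
* **Corruption**: a smooth random displacement field with amplitude in mm
  (spacing-aware, correlation length 20 mm), signed per-class
  dilation/erosion margins in mm, and uniform label flips.  Defaults are
  tuned only to produce the DSC range (≈ 0.6–0.95) typical of
  inter-observer variation in this task; they are not claims about any
  specific dataset.
* **Cohort**: 49 patients, half female, with per-gender log-normal true
  volumes (females more SF, males more VF and muscle; log-SD 0.35) and
  multiplicative within-subject error with σ_w = 0.041/0.10/0.23/0.018 for
  SF/VF/PM/EM — the repeatability regime this kind of study reports (SF/EM
  tight, PM loose).  wCV relates to σ_w by wCV = √(exp(σ_w²)−1) ≈ σ_w.
  77.6% of patients (38/49) carry a day-180 visit.
* **Bias observations**: exactly the hierarchical model above, defaults
  N = 25 slices, M = 15 models, areas uniform on 50–200 cm², α = −5 cm²,
  β = −0.05, σ_inter = 1.5, σ_intra = 4.

What passing tests on these generators show: the estimators recover their
own estimands under the stated error models.  What they do not show:
robustness to real-MRI effects (intensity artefacts, slice malposition,
anatomy-correlated rater bias, non-log-normal error).

## Problem sizes used in the test suite

Worked examples and combinatorial checks run instantly.  The heavier
statistical suites use: STAPLE performance recovery at ~10⁵ voxels;
wCV recovery at n = 500 pairs; type-I classification at n = 1000 patients;
bias-model credible-interval coverage over 50 simulated datasets fitted at
3 chains × 500 draws / 250 warmup (the reporting configuration 3 × 1500/500
is exercised separately end to end).  These sizes give Monte-Carlo error
comfortably inside the asserted bounds while keeping the default suite
fast.
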