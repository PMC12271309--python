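# bodycomp

Validation toolkit for deep-learning **fat/muscle segmentation of abdominal
MRI**, aimed at quantitative-imaging researchers who need to know not just
how *accurate* a segmentation model is, but how *precise* its derived tissue
volumes are — and therefore when a change measured in an individual patient
is real rather than test–retest noise.

The package covers the technical-validation chain for multi-class abdominal
body-composition segmentation (subcutaneous fat SF, visceral fat VF, psoas
muscle PM, external muscle EM, plus derived totals TF = SF+VF and
TM = PM+EM, on the fixed 0–5 label scheme):

* **Accuracy metrics** — class-wise Dice (DSC), intersection-over-union
  (IOU = DSC/(2−DSC)), 95th-percentile Hausdorff distance (HD95, mm) and
  normalised surface Dice (NSD at tolerance τ mm), with reference-weighted
  averages, all cross-checked against brute-force surface-distance oracles.
* **STAPLE consensus** — the expectation-maximisation estimator of a hidden
  true segmentation from multiple raters, with per-rater sensitivity
  p<sub>j</sub> and specificity q<sub>j</sub>, extended one-vs-rest to the
  six-class scheme, plus reader-study ranking against the consensus.
* **Ensembling and post-processing** — probability averaging and hard-label
  voting, the 15-configuration ensemble ladder from four base models, and
  largest-connected-component cleanup.
* **Hierarchical Bayesian bias model** — per-slice area differences
  δ<sub>nm</sub> between model *m* and the consensus area a<sub>n</sub>:

      δ_nm = α + β·(a_n − ā) + u_m + ε_nm,   u_m ~ N(0, σ²_inter),  ε_nm ~ N(0, σ²_intra)

  fitted by Hamiltonian Monte Carlo (3 chains × 1500 draws, 500 warmup),
  with split Gelman–Rubin r̂ convergence diagnostics, bias at the mean area
  as a percentage (100·α/ā), ICC = σ²_intra/(σ²_intra+σ²_inter) and 95%
  posterior predictive bands.
* **Test–retest repeatability** — within-subject coefficient of variation
  (wCV), one-way random-effects ICC, and asymmetric 95% limits of agreement
  on the log scale, LOA = 100·(exp(±1.96·√2·σ<sub>w,log</sub>) − 1), which
  are reciprocal-symmetric by construction.
* **Longitudinal change classification** — percent change from the averaged
  double baseline, classified as a real increase/decrease only when it
  exceeds the repeatability-coefficient limits (95% confidence), with
  cohort-level paired t-tests and gender group comparisons (Welch).
* **Synthetic data** — a nested-ellipse abdominal phantom, imperfect-rater
  corruption (smooth boundary displacement in mm, per-class
  over/under-segmentation, label flips), log-normal test–retest volume
  cohorts and bias-model observations, all bit-reproducible from a seed, so
  the whole pipeline is exercised against known ground truth.

## Worked example

```python
from bodycomp import (AreaBiasModel, BiasSimSpec, CohortSpec,
                      simulate_bias_observations, simulate_cohort,
                      stratified_repeatability, cohort_change_analysis)

# hierarchical bias model on simulated observations (25 slices x 15 models)
obs = simulate_bias_observations(BiasSimSpec(seed=0))
res = AreaBiasModel.from_dataframe(obs).fit(seed=0)
print(res.summary().round(4))
```

```
            parameter    mean   ci2.5  ci97.5   rhat
                alpha -4.7293 -5.8598 -3.6321 0.9994
                 beta -0.0499 -0.0590 -0.0409 0.9995
          sigma_inter  2.0916  1.2939  3.2633 1.0017
          sigma_intra  3.9284  3.6534  4.2278 0.9996
bias_at_mean_area_pct -3.8762 -4.8027 -2.9769    NaN
                  icc  0.7779  0.5925  0.9045    NaN
             max_rhat  1.0017     NaN     NaN 1.0017
```

The generating truth was α = −5 cm², β = −0.05, σ_inter = 1.5, σ_intra = 4:
every 95% credible interval covers it, the segmentations under-estimate area
by ≈ 3.9% at the mean consensus area, the negative slope says larger regions
are more biased, and max split-r̂ = 1.00 confirms the sampler converged.

```python
# test-retest repeatability and change classification on a 49-patient cohort
vols = simulate_cohort(CohortSpec(seed=0))
rep = stratified_repeatability(vols)
limits = {r.tissue: (r.loa_lower_pct, r.loa_upper_pct) for r in rep}
print(cohort_change_analysis(vols, limits).round(3))
```

```
tissue stratum  n  wcv_pct   icc  loa_lower_pct  loa_upper_pct
    EM     all 49    2.046 0.998         -5.515          5.837
    PM     all 49   22.324 0.714        -46.784         87.912
    SF     all 49    4.172 0.991        -10.929         12.270
    VF     all 49    8.320 0.951        -20.666         26.050

tissue  n  pct_increase  pct_decrease  pct_no_change  p_paired_t
    EM 38           0.0           0.0          100.0       0.462
    PM 38           0.0           0.0          100.0       0.430
    SF 38           0.0           0.0          100.0       0.789
    VF 38           7.9           2.6           89.5       0.224
```

SF volumes repeat to ≈ 4% (limits of agreement −10.9%/+12.3% — note the
log-scale asymmetry: (1+0.123)(1−0.109) ≈ 1), PM is an order of magnitude
noisier, and in a no-true-change cohort almost every patient is correctly
left unflagged.

A `bodycomp` console script exposes the same steps
(`phantom`, `simulate`, `metrics`, `staple`, `ensemble`, `postprocess`,
`repeatability`, `biasfit`, `longitudinal`, `run-study`); see
`bodycomp --help`.

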