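# Methods

This note documents the statistical model the package implements, the
choices made where the procedure was genuinely open, and what the
synthetic cohorts do and do not establish.

## The prediction pipeline

The target is a continuous phenotype (FSIQ, mean 100 / SD 15) and the
features are Fisher-z functional-connectivity (FC) values for all
unordered ROI pairs under a fixed upper-triangle row-major edge order
(`edge_id(a, b) = i·n_roi − i(i+1)/2 + (j−i−1)`, i = min, j = max).
FC is stored z-transformed throughout: the unbounded support suits
linear modeling and the L1 deviation sums of the differentiability
statistic.

Per cross-validation fold:

1. **Edge screening.** Pearson correlation of each edge with the target
   over training subjects; two-sided p from the exact t transform with
   n−2 df; retain p < 0.05. Constant edge columns get r = 0 and are
   never retained (warned, never fatal). A fold whose screen retains
   nothing predicts the training mean.
2. **Penalty search.** λ grid: 50 log-spaced values from λ_max =
   max_j |⟨x̃_j, ỹ⟩|/n down to 10⁻³ λ_max, computed on the z-scored
   screened features. Inner 5-fold subject-grouped CV picks the λ with
   minimal mean held-out squared error; ties go to the largest
   (sparsest) λ. **Each inner fold re-runs the screen on its own
   training rows.** Without this, features screened on the full outer
   training set have already seen the inner validation rows, the
   validation error is biased optimistic for dense models, and the
   selected λ collapses toward the dense end (observed: CV r dropped
   from ~0.56 to ~0.35 on the default planted world). This is the one
   place the implementation goes beyond the minimal reading of "an
   inner-loop cross-validation was performed"; the selection criterion
   was otherwise unspecified.
3. **Fit.** LASSO minimizing (1/2n)‖y − b − Xw‖² + λ‖w‖₁ on z-scored
   features (training-fold statistics), weights back-transformed to
   original FC units so fold models share a scale. Solutions satisfy
   the KKT subgradient conditions to 1e-6 (tested). The solver is
   scikit-learn's coordinate descent; λ = 0 falls back to least
   squares.

### Run handling

Subjects may have one or two resting-state runs. Folds partition
*subjects*; a subject's runs are never split across the train/test
boundary. Training uses each subject's **run-averaged** connectome as
one row. This makes the screening t-test df honest (rows are
independent subjects), and makes duplicating a run an exact no-op —
with runs as separate rows, a duplicated run would change the
screening df and hence the retained edge set. At test time runs are
scored separately and the subject's prediction is their mean; for a
linear model this equals predicting the run-averaged connectome, so
the two conventions agree.

### Unified model

Weights are averaged over all fold models **with zeros for unselected
edges** (divide by 50, not by the number of selecting folds), the
intercept is the fold-intercept mean, and per-edge selection
frequencies are recorded. The in-sample r of this model exceeds the
out-of-fold CV r on every signal simulation seed — it is reported only
as a leakage-ordering check, never as a performance estimate.

### Evaluation

Pearson r with parametric two-sided p, and R² as the raw coefficient
of determination 1 − SS_res/SS_tot (not r²), so miscalibrated
predictions are penalized. Constant predictions leave r undefined
(flagged status), while R² is still returned.

## Permutation inference

The target is shuffled across subjects (runs keep their subject's
permuted value) and the **entire** pipeline — screening, λ search, fit
— is re-run per permutation; p = (1 + #{null ≥ observed})/(1 + n_perm),
one-sided for larger r. Re-running everything is the conservative
choice; reusing the observed screen would understate the null spread.
Transfer significance on an external cohort compares the real unified
model's transfer r against unified models built from permuted labels.

**Why permutation rather than "r ≈ 0" nulls:** cross-validated
correlation is *negatively biased* under the null. Near-null fold
models predict approximately the training-fold mean, and with the
grand mean fixed, the training mean anti-correlates with the held-out
fold's mean. On the default null world (h = 0, n = 600) the mean CV r
is ≈ −0.06 (SE 0.007), not 0. One acceptance test asserts the naive
"within 2 SE of 0" expectation and is deliberately left failing as
documentation of this artifact. The permutation null shares the bias,
so the permutation test is correctly calibrated (measured rejection
rate 1/20 at α = 0.05 on null worlds).

## Importance decompositions

"Edges involving a network/ROI" means incident to ≥ 1 ROI of it, so a
between-network edge is removed by either endpoint's removal. ROI
importance exposes both mean-|w| and sum-|w| aggregations (both appear
in standard displays). Leave-one-network-out zeroes the incident
weights in every *fold model* and regenerates out-of-fold predictions,
keeping the comparison honest; Δr pairs r_standard and r_removed on
exactly the same per-subject prediction set. The Fisher r-to-z
comparison uses the independent-samples formula with n₁ = n₂ = group
size even though the two correlations share subjects — a
dependent-correlations (Steiger) variant is provided as an option.
FDR is Benjamini–Hochberg across the seven networks within each group.

## Subdomain analysis

The "IQ-correlated" set is the top k = 500 edges by |unified weight|
(ties broken by edge id). Subdomain fits are in-sample multiple linear
regressions of each score on the k edges (minimum-norm solution if
rank-deficient, flagged). The controlled permutation refits on k edges
drawn from the uncorrelated pool per trial, so the null shares the
fit's dimensionality and in-sample R² inflation (≈ k/(n−1) under the
null) cancels out of the comparison. Pattern similarity is the inner
product of unit-L2-normalized weight vectors. ROI-level regressions
use per-subject scores: for ROI R, Σ over scope edges incident to R of
(unified weight × subject FC). A static per-ROI importance value is
constant across subjects and cannot regress anything, so this
subject-varying weighted-incidence reading is the only workable one;
it is flagged here because the verbal description ("ROI importances as
regressors") underdetermines it.

## Individual differentiability

ID_i = Σ_j |FC_ij − mean_j| over all edges, mean connectome over *all*
subjects regardless of diagnosis, no normalization by the edge count.
Multi-run subjects contribute their run-averaged connectome both to
the mean and to their own ID. Exact properties (tested): ID = 0 at the
mean connectome, invariance to adding a constant to every edge,
positive homogeneity under scaling.

## The synthetic cohort

Per subject i and edge j:

    FC_ij   = M_j + γ·s_j·1[j ∈ true]·g_i + group/site shifts + N(0, σ_e²)
    run r   : FC_ij + N(0, σ_r²)
    FSIQ_i  = 100 + 15(√h·g_i + √(1−h)·ε_i) + group/site shifts
    domain k: 100 + 15(a_k·g_i + √(1−a_k²)·u_ik)

Defaults: n = 600 subjects, 100 ROIs in 7 networks, 50 true edges with
random signs, γ = 0.15 FC-z per latent SD, σ_e = σ_r = 0.08, two runs,
h = 0.35, subdomain loadings (0.75, 0.80, 0.70, 0.72, 0.55) with PSI
weakest, within/between-network baseline FC 0.35/0.10 (z-scale, SD
0.05). Diagnosis mix approximates an ADHD-heavy pediatric
transdiagnostic cohort (HC 9%, ADHD 47%, ASD 5%, MDD 2%, anxiety 11%,
other 26%) with small FSIQ offsets (−4…+4 points) and small
within-network FC offsets for ADHD (DAN) and ASD (DMN); four sites
with uneven enrolment carry small edge-mean and FSIQ offsets. These
magnitudes are stand-ins chosen once for plausibility — they are *not*
estimates of any real cohort's parameters.

With these defaults the pooled oracle predictor β·FC correlates with
the latent trait at ≈ 0.996 (kγ² ≫ σ²), so its population correlation
with FSIQ is ≈ √h = 0.59; the pipeline's cross-validated r of ≈ 0.55
(10-seed mean 0.5504, SE 0.011) reflects estimation loss. The
generator emulates the *statistical skeleton* the pipeline assumes —
linear edge–trait coupling, block-structured mean connectome,
run-level noise, group/site shifts. It does **not** emulate BOLD
autocorrelation, motion artifacts, edge–edge correlation beyond the
shared latent trait, nonlinear or interaction effects, or realistic
site heterogeneity. A green recovery test therefore establishes
internal consistency of the pipeline, not performance on real data.

## Numerical choices

- Outer folds per round: a seeded permutation of subjects split into 5
  near-equal groups; inner folds: deterministic modulo assignment over
  the training subjects. A single pipeline seed reproduces every split
  bit-for-bit.
- LASSO tolerances: 1e-6 for reported fits (KKT-tested at 1e-6), 1e-4
  inside the λ search where paths are only ranked; solver
  non-convergence at the dense end of the path is suppressed there
  because that region never wins the selection.
- atanh guards: compute_fc rejects |r| ≥ 1 − 1e-12 naming the ROI
  pair; Fisher comparisons reject |r| = 1 and n ≤ 3.
- Tabular round-trips use `float_precision="round_trip"` so written
  cohorts reload bit-exactly.
- Permutation seeds spawn from a single `SeedSequence`, keeping every
  derived seed below 2³¹.

## Known limitations

- Screening retains a single signed edge set; the classic
  positive/negative split variant of CPM is not implemented.
- The subdomain analysis is in-sample by design; no cross-validated
  subdomain prediction is offered.
- ComBat-style site harmonization is out of scope; site effects in the
  simulator are additive shifts only.
- The negative null bias of CV r (above) means raw CV r values near
  zero must be interpreted against the permutation null, never against
  zero itself.
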