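# Methods

## Problem and data model

The package predicts cognitive scores (MMSE 0–30, ADAS-Cog 0–70, or
arbitrary continuous targets) at future time points M12–M48 from
longitudinal tabular MRI biomarkers: one row per (patient, visit) with a
visit code in {BL, M06, M12, M24}, an exam date, a diagnosis group
(AD / MCI / CN) and d FreeSurfer-style features in five categories —
cortical volume (CV, mm³), white-matter volume (SV, mm³), surface area
(SA, mm²), mean cortical thickness (TA, mm) and its standard deviation
(TS, mm).

Preprocessing follows fixed rules: features missing in **strictly more
than** half of the rows are dropped (a feature missing in exactly half is
kept); patients without both a BL and an M06 scan are excluded (for the
dynamic-prediction workflow, without any of the required follow-up
scans); remaining gaps are filled with the feature's mean over all
retained rows, pooled across visits and groups (per-visit stratification
is available but off by default — nothing in the data model requires
stratified imputation, and pooling is the simpler estimator); patients
with incomplete cognitive follow-up are dropped from the score table.
Scores outside their nominal range trigger a validation warning but are
never silently clamped.

## Similarity tensor

For a scan interval (early, late), each biomarker's variation trend is
the 2-vector (rate of change, velocity). The velocity denominator
converts the exact date difference to months using the mean Gregorian
month of 30.4375 days, since "per month" does not otherwise pin down a
unit. A zero value at the earlier visit makes the rate undefined; because
FreeSurfer features are positive, the default is a hard error, with an
opt-in fallback that marks the rate missing and computes that biomarker's
distances from the velocity component alone.

One patient's slice is the d×d matrix of pairwise Mahalanobis distances
among their d variation vectors, which is symmetric with a zero diagonal;
the strictly upper-triangular mask K = triu(1, k=1) removes the
duplicated half wherever the slice enters the model. The 2×2 covariance
S of the distance can be estimated per patient (default: each slice gets
its own metric, treating the patient's d biomarker vectors as the
observations; requires d ≥ 3) or pooled over all patients' vectors. S is
regularized as S + ε·(tr S/2)·I with ε = 1e−6 so it is always
invertible; a zero-trace S (all vectors identical) degenerates to the
identity, under which all distances are zero anyway. Under a fixed SPD S
the distance is a true metric (nonnegative, symmetric, triangle
inequality), which the tests assert on random triples.

Each slice is min–max scaled to [0, 1] by default, so slices are
comparable across patients regardless of their individual covariance
scale; the raw distances are available with `normalize=False`.

## Tensor multi-task regression

Per prediction time point t the model couples three ingredients
(see README for the formulas): a masked bilinear prediction
ŷ_n = Σ_ij [(A_t B_tᵀ) ⊙ K ⊙ W_t ⊙ X_n]_ij, a CP-factorization fit
(λ/2)‖X − [[A_t, B_t, C_t]]‖²_F that anchors the latent factors to the
tensor, and an ℓ1 penalty with a single shared β on W_t, A_t, B_t, C_t.
Across time points the unfolded weight stack W_f pays the generalized
temporal-smoothness penalty θ‖W_f P(α)‖²_F, where
P(α) = H·D_1(α_1)···D_{t−2}(α_{t−2}); with all α = 0 this reduces to the
plain first-difference penalty, and for t = 2 there are no α parameters
at all. The sample factors C_t appear only in the CP term, so predicting
unseen patients needs only A_t, B_t, W_t and the new slices.

Design choices that the formulation leaves open:

* **Per-time-point factors.** A_t, B_t, C_t are fitted per time point
  (they are subscripted by t in the objective); a `shared_factors` mode
  ties one factor set across all time points for ablation.
* **α as hyperparameters.** The mixing parameters are selected on the CV
  grid, not learned by gradient; the default grid shares one α value
  across stages to keep the grid small, with per-stage values available.
* **Missing targets.** A sample without a score at time point t is
  excluded from that time point's empirical loss but still informs the
  CP term through its tensor slice.

### Solver

Block proximal gradient descent: per outer iteration the blocks
A_t → B_t → C_t are updated for each time point, then the whole W stack
jointly (the smoothness term couples its columns). Each block takes one
gradient step on the smooth part followed by soft thresholding. Step
sizes start at 1/L̂ with L̂ estimated by power iteration on the block's
quadratic operator and are then adapted by backtracking: a step is
accepted only when the smooth part satisfies the quadratic majorization
bound, which guarantees the outer objective trace is non-increasing (the
tests allow 1e−10 relative slack for float arithmetic). Convergence is
declared when the relative objective change drops below `tol`
(default 1e−5, `max_iter` 500). With `max_iter=0` the returned model is
exactly the initialization and the trace has length 1.

Initialization: A, B, C from unregularized CP-ALS sweeps on X
(`init_sweeps`, default 10; the recovery experiments use 100–200), W = 0.
Everything is driven by a seeded generator, so identical seeds give
bitwise-identical fits.

CP-ALS itself runs 8 random restarts and keeps the lowest-error run.
On realistic similarity tensors single-start ALS lands in different local
basins depending on the seed, and the factor product A Bᵀ — which the
prediction rule consumes — differs materially between basins; best-of-8
reliably finds the same basin, making the factors reproducible. Factors
are normalized to unit-norm, sign-fixed A/B columns with the magnitudes
absorbed into C, which removes the CP scale/sign indeterminacy (component
permutation does not affect A Bᵀ).

## Gradient boosting over scan intervals

One stage per consecutive interval (BL→M06, M06→M12, M12→M24), in
chronological order. Stage 1 fits Y; stage s fits the residual of the
cumulative prediction after s−1 stages, computed in-sample (the
formulation describes sequential residual fitting without out-of-fold
machinery). Shrinkage ν ∈ (0, 1] scales each stage's contribution;
the default ν = 1 with the first stage unshrunk makes a one-stage
ensemble identical to the base model. Prediction with `upto_stage=k`
sums the first k stages — the dynamic-prediction path for a patient with
k scan intervals so far. Residuals are taken against the fixed target
matrix Y; intermediate-visit scores do not update the residuals.

## Evaluation protocol

Repeated patient-level 9:1 train/test splits (default 20 repeats; splits
are always over patients, never rows, to avoid leakage), k-fold CV
(default 5) on the training patients for hyperparameter selection by mean
validation rMSE (averaged over folds and time points; ties go to the
earlier grid entry), refit on the full training set, test evaluation.
Reported are per-time-point rMSE mean ± SD over repeats (sample SD,
ddof=1) and nMSE = Σ_i ‖Y_i − Ŷ_i‖²/σ(Y_i) / Σ_i n_i over observed
entries, with σ(Y_i) the (population, ddof=0) standard deviation of the
observed test targets at time point i.

Interpretability: the fitted W_t is masked to its upper triangle and the
top-k biomarker pairs are ranked by |weight| — magnitude, because impact
on the prediction is what the weight measures — with the signed value
reported and ties broken by (row, column) index for a stable order.
Rankings can be exported as BrainNet-Viewer-style `.node`/`.edge` text
files; without atlas coordinates the nodes are laid out on a unit circle.

## Synthetic cohorts

The generator emulates the statistical shape of a registration-gated
longitudinal MRI cohort:

* Trajectories x(v) = baseline·(1 + rate·months + noise) with
  per-(group, biomarker) monthly rates. Atrophy-sensitive categories
  (CV, TA, TS) decline with group means −0.004 (AD), −0.002 (MCI),
  −0.0005 (CN) per month — i.e. roughly 2.4% volume/thickness loss over
  six months for AD — while SA and SV drift at the CN rate for all
  groups. Biomarker-level spread of the group mean is 0.0015, patient-
  level spread 0.0008, relative measurement noise 0.005 per cell.
  Baselines are drawn per category at realistic scales (e.g. TA ≈
  2.5 ± 0.3 mm). Exam dates sit at the nominal month ± up to 15 days of
  uniform jitter.
* Targets come from the model's own forward rule: a sparse
  upper-triangular weight stack W* (5% of pairs, values ~N(0, 1) pushed
  0.5 away from zero, drifting mildly across time points so the
  smoothness prior is correct), combined with CP factors A*, B* of the
  actual generated tensor. Score noise is homoscedastic Gaussian with SD
  equal to `score_noise_frac` (default 10%) of the per-time-point signal
  SD — the data model itself specifies no noise distribution, so the
  simplest one is used and stated here. With several intervals,
  `interval_weights` sets each interval's contribution to the target.
* Optional feature-, visit- and score-level missingness at configurable
  rates.

What the generator does **not** emulate: real neuroanatomy or atlas
geometry, between-feature correlation structure beyond what the
trajectory model induces, heteroscedastic or floor/ceiling-censored
scores, visit dropout correlated with disease severity, and diagnosis
conversion over time. Passing tests on these cohorts therefore
demonstrate the estimator's correctness and its behaviour under the
model's own assumptions — not clinical performance on real data.

## Experiment sizes and known limitations

The bundled experiments run at desk scale, chosen so the full suite
completes in minutes: solver checks at n=60/d=15, weight recovery at
n=100/d=20/r=3/t=4 with 10% score noise, boosting on 3-interval cohorts
at n=80/d=12 with interval weights (1.0, 0.8, 0.6) and a 9:1 split.

Known limitations:

* **Support selection is optimistic-biased on these designs.** The
  distance-matrix features are correlated (pairs share rows and columns
  of the slice), and the effective regression coefficient is
  (A Bᵀ ⊙ K) ⊙ W, so true pairs whose factor-product entry is near zero
  carry almost no signal. Consequently the ℓ1 support contains genuine
  false positives at stationarity (verified via the KKT conditions) and
  misses weak-leverage true pairs; varying β trades precision against
  recall without resolving this. The weight *values* are recovered well
  (vectorized correlation ≈ 0.8 at the sizes above), but the exact
  nonzero pattern is not a reliable edge detector at n ≈ 100 — rankings
  of the largest weights are the robust interpretable output.
* The joint objective is nonconvex; the solver guarantees monotone
  descent to a stationary point, not a global optimum. Multi-start ALS
  initialization makes the reached point reproducible in practice.
* Per-patient covariance estimation of the variation vectors needs
  d ≥ 3 and is noisy for small d; the pooled scope is preferable when
  biomarker counts are low.
* The model has no intercept: targets are assumed centred the way the
  forward rule produces them. Real score scales may need centring
  upstream.
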