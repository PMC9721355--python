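# tensorcog

Tensor multi-task ensemble learning for predicting the progression of
cognitive decline (MMSE, ADAS-Cog scores) from longitudinal MRI-derived
brain biomarkers.

## Who this is for

Researchers modelling Alzheimer's disease progression from FreeSurfer-style
tabular features (regional volumes, surface areas, cortical thickness
statistics) measured at repeated visits (baseline, month 6, 12, 24), who
want to forecast a patient's cognitive scores at future time points
(M12–M48) and to read off which *pairs* of brain biomarkers drive the
forecast. Because each patient accumulates scans over time, the package
also supports dynamic prediction: the forecast sharpens as each new scan
interval arrives.

## The model

For each patient and scan interval, every biomarker gets a 2-vector
describing its morphological variation trend: the rate of change
(x_late − x_early)/x_early and the velocity (x_late − x_early)/Δmonths.
The pairwise Mahalanobis distances among a patient's d variation vectors
form one symmetric d×d slice; stacking n patients gives the similarity
tensor X ∈ ℝ^{d×d×n}. A strictly upper-triangular mask K removes the
duplicated half of each symmetric slice.

Per prediction time point t, the score of patient n is predicted by the
masked bilinear form

    ŷ_n = Σ_ij [ (A_t B_tᵀ) ⊙ K ⊙ W_t ⊙ X_n ]_ij

where A_t, B_t ∈ ℝ^{d×r} are CP latent factors of X, W_t ∈ ℝ^{d×d} is a
sparse weight matrix over biomarker pairs, and ⊙ is the elementwise
product. The joint training objective over all t time points is

    L = Σ_t [ ½‖ŷ_t − y_t‖² + (λ/2)‖X − [[A_t, B_t, C_t]]‖²_F
              + β(‖W_t‖₁ + ‖A_t‖₁ + ‖B_t‖₁ + ‖C_t‖₁) ]
        + θ‖W_f P(α)‖²_F

with [[A,B,C]] the rank-r CP reconstruction, W_f the (d²)×t unfolding of
the weight stack, and P(α) = H·D_1(α_1)···D_{t−2}(α_{t−2}) the generalized
temporal-smoothness operator that blends each time point's weight change
with all preceding changes. The objective is minimized by block proximal
gradient descent with backtracked step sizes (monotone descent), and the
ℓ1 terms are handled by soft thresholding.

Consecutive scan intervals (BL→M06, M06→M12, M12→M24) are combined by a
gradient-boosting ensemble: stage 1 fits the scores from the first
interval's tensor, every later stage fits the residual of the cumulative
prediction using its own interval's tensor. Predicting with the first k
stages uses exactly the scans a patient has so far.

## Worked example

Real cohorts of this kind are registration-gated, so the bundled generator
produces cohorts with the same statistical shape and known ground truth:

```python
import tensorcog as tc

spec = tc.SyntheticSpec(n=60, d=12, rank=2, seed=42)
cohort, tensors, Y, truth = tc.make_regression_problem(spec)

grid = [tc.TMTLHyperparameters(lam=1.0, beta=b, theta=1e-3, rank=2,
                               max_iter=60, init_sweeps=60)
        for b in (5e-3, 5e-2)]
report = tc.run_protocol(tensors[0], Y, grid, n_repeats=3, split_ratio=0.9,
                         cv_folds=3, seed=0,
                         time_points=("M12", "M24", "M36", "M48"))
print(report.summary())
```

```
time point  rMSE mean  rMSE SD
       M12     0.0618   0.0185
       M24     0.0528   0.0180
       M36     0.0528   0.0136
       M48     0.0563   0.0157
nMSE: 0.0239 +/- 0.0145 (3 repeats)
```

Per time point this is the test root-mean-square error of the predicted
score over 3 repeated 9:1 patient-level splits (hyperparameters chosen by
3-fold cross-validation inside each training set); nMSE is the
variance-normalized error pooled over time points. Scores here are in the
forward model's own units, and the per-time-point target SD is ≈0.08, so
an rMSE of ≈0.05–0.06 means the model explains most of the signal.

The fitted weights are directly interpretable as ranked biomarker pairs:

```python
model = tc.fit(tensors[0], Y, tc.TMTLHyperparameters(
    lam=1.0, beta=5e-3, theta=1e-3, rank=2, max_iter=200, seed=0))
top = tc.rank_relationships(model.W[0], tensors[0].biomarker_names, model.K,
                            k=3, time_point="M12")
for name_i, name_j, w in top:
    print(f"{name_i:>12} -- {name_j:<12} weight {w:+.4f}")
```

```
   TS_roi004 -- TS_roi009    weight -2.2275
   SA_roi002 -- TA_roi008    weight -0.5759
   TA_roi003 -- SV_roi006    weight +0.5204
```

`rank_relationships` can also be exported as BrainNet-Viewer-style
`.node`/`.edge` text files via `write_brainnet`.

A command-line interface mirrors the library
(`tensorcog simulate | preprocess | build-tensor | fit | fit-ensemble |
predict | evaluate`); every subcommand writes the resolved configuration
and seed next to its outputs.

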