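# Methods

`embryopt` models a three-factor plant-growth-regulator (PGR) experiment on
chrysanthemum somatic embryogenesis and optimizes the factor levels against
two objectives. This note records the models, the numerical choices, and
the limits of what the test suite can demonstrate.

## The data and its reconstruction

The bundled dataset is a 4 × 4 × 4 full factorial: 2,4-D (0, 4.54, 9.09,
13.63 μM) × kinetin (0, 4.65, 9.29, 13.94 μM) × sodium nitroprusside
(0, 10, 20, 40 μM), with three responses per treatment — callogenesis
rate (%), embryogenesis rate (%) and somatic embryos per explant — each
summarized as mean ± standard error over nine replications.

Model fitting operates on replicate-level rows (576 = 64 × 9). Since only
the summary statistics are published, replicates are reconstructed by exact
moment matching: draw nine standard-normal values, center them, rescale so
the sample SD equals SE·√9, and add the printed mean. The sample mean and
sample SE of each cell then reproduce the printed values to 1e-9.
Rates are clipped to [0, 100] and counts to ≥ 0 afterwards; where clipping
binds (cells whose mean sits within ~2 SD of a bound) exact moment matching
is impossible, and the deviation is logged rather than silently
re-projected — re-projection cannot in general satisfy both the moments and
the bounds. About half of the 89 positive-SE treatment/response cells are affected,
mostly high-rate cells near 100 %.

Two limitations of this reconstruction matter for interpretation. First,
the replicate noise is Gaussian and symmetric; the real rates come from
five-explant counts and are discrete and skewed near the bounds. Second,
each reconstructed cell has *exactly* the printed moments, so the
between-replicate variance carries no sampling error of its own. Passing
tests therefore show that the procedures behave correctly under the
published first- and second-moment structure, not that they would behave
identically on the raw explant-level data.

## Synthetic surfaces for recovery tests

`SurfaceConfig`/`generate_surface` produce full-factorial replicate tables
from separable Gaussian-peak response surfaces
`height · exp(−Σ_j ((x_j − peak_j)/width_j)²)` plus Gaussian noise, clipped
to the valid range. Defaults mirror the study conditions: the same factor
levels, nine replicates, peaks at the best observed treatment
(9.09, 4.65, 20), heights at the observed maxima (100, 100, 57.8) and
noise SDs (5 %, 5 %, 1 embryo) of the order of the published replicate
SDs. Setting a width to a huge value makes that input irrelevant, which is
how the sensitivity-recovery tests construct known ground truth. A single
shared peak across responses means the synthetic optimization problem has
no objective trade-off; it tests peak recovery, not front geometry.

## Scaling and splitting

Inputs and targets are min–max scaled to [0, 1] with parameters observed on
the training partition only; predictions are mapped back to natural units
before any metric, so RMSE/MAE are in percent or embryos. Splitting is a
seeded row-level permutation; replicates of one treatment may land in both
partitions, so the test partition is not independent of the training
treatments — it measures interpolation error at the replicate level, which
is what the published n = 432/144 split does too. The default
train fraction is 0.75, matching those published partition sizes; 0.70 is
available since the accompanying text says 70/30.

## ε-SVR

The regressor is the RBF-kernel expansion y(x) = Σ β_i k(x, x_i) + b with
k(x, z) = exp(−γ‖x−z‖²) on scaled data. Training solves the standard
ε-insensitive dual (box constraints [0, C], one equality constraint) with
a second-order maximal-violating-pair SMO, numba-compiled, with
LIBSVM-style shrinking of bounded variables and a full-gradient
verification pass before accepting convergence, so shrinking never changes
the solution. The default KKT-gap tolerance is 1e-6; the bias is the mean
of the free-support-vector KKT values, falling back to the midpoint of the
feasible bias interval (with a warning) when no free vector exists. `C` is
the conventional per-point penalty (no 1/n factor; the two
parameterizations differ only by rescaling C).

Hyperparameters are not published, so all three are tuned by exhaustive
5-fold cross-validated RMSE over C ∈ {1, 10, 100, 1000},
ε ∈ {0.001, 0.01, 0.05, 0.1} (scaled units), γ ∈ {0.1, 0.5, 1, 2, 5} —
a standard coarse log grid. Ties break toward smaller C, then larger ε,
then smaller γ, making the selection independent of candidate order. Three
numerical choices keep the 400-fit search affordable without touching the
final models: fold fits run at tolerance 1e-3 (scores only rank
candidates), fold solves warm-start along the increasing-C path (the
previous solution stays feasible when the box grows), and a candidate
whose fold solve exceeds 50 000 pair updates is dropped from the selection
— the model it would score is not the model a converged fit produces, and
such corners (large C with tiny ε on noisy percent data) are never
competitive. Final fits always run to full convergence at 1e-6.

## MLP

The comparison model is a three-layer perceptron (tanh hidden layer, linear
output) trained by Levenberg–Marquardt on the scaled sum of squared errors:
Δw = −(JᵀJ + μI)⁻¹Jᵀe with the analytic backpropagation Jacobian,
μ₀ = 1e-3, ×10 on rejected steps, ×0.1 on accepted ones, at most 1000
epochs, gradient tolerance 1e-7. A 15 % slice of the training rows is held
out for early stopping (patience 25); the best-validation weights are
returned. Hidden size is selected from {3, 5, 8, 12, 15} by validation
RMSE, and the winner is refit on the full training partition with a fresh
internal early-stopping split. Weights initialize uniformly in
[−0.5, 0.5]/√fan-in, seeded.

## Metrics

R² is the squared Pearson correlation between observed and predicted series
(undefined and rejected for constant series); MAE and RMSE are computed in
natural units. Squared correlation is used deliberately: it is the
quantity the published comparison behaves like (bounded by 1, affine
invariant), and the printed formula is not a valid statistic as typeset.

## Sensitivity (VSE / VSR)

Input importance is measured by remove-and-retrain: the baseline model is
tuned and fitted on all 576 rows with all inputs and scored by RMSE on
those rows; for each input, the model is re-tuned and refitted from
scratch without it and rescored on the same rows. VSR is the ratio of the
reduced model's RMSE to the baseline's; ranks follow descending VSR with
ties broken by input order. Removal means retraining without the variable
— substituting a constant for an input of the full model probes a
different question (that mode exists behind `mode="zero"` for comparison).
Because the reduced model is re-tuned, a VSR slightly below 1 can occur
when the baseline's extra dimension is pure nuisance.

## NSGA-II and ideal-point selection

The optimizer maximizes the two surrogate predictions (embryogenesis rate,
embryo count) over the experimental box (2,4-D ∈ [0, 13.63],
KIN ∈ [0, 13.94], SNP ∈ [0, 40] μM) — the surrogates are untrustworthy
outside the design region. Settings follow the published run: population
200, 1000 generations, crossover 0.7, per-gene mutation 0.5, roulette
parent selection on fitness 1/(1 + front rank); the canonical crowded
binary tournament is available by configuration. Variation operators are
the de-facto real-coded pair: simulated binary crossover and bounded
polynomial mutation, both with distribution index 20, children clipped to
the box. Survival is the standard elitist reduction of parents + children
by front rank then crowding distance. The surrogates return raw
(unclipped) predictions during the search — clipping flattens the
selection gradient near the boundary — and clipping is applied only to the
reported optimum.

From the final first front (near-duplicate decisions within 1e-6 removed),
the reported answer is the member minimizing the Euclidean distance, in raw
mixed units (% and count), to the ideal point: the best observed value of
each objective in the data, (100, 57.80) for the bundled dataset. Ties
break toward lower 2,4-D. A normalized-distance variant was considered and
rejected as the default for fidelity to the published rule.

The surrogates handed to the optimizer are refit on all 576 rows. In the
orchestrated study they reuse the hyperparameters tuned on the training
partition (`refit_on_full=True`, the split-trained variant is
configurable); the standalone optimization entry point in
`scripts/acceptance.py` tunes directly on the full table. Both choices are
defensible since the published account does not say which partition fed
the optimizer; they select nearly identical models here.

## Determinism

Every stochastic stage (replicate expansion, splitting, CV folds, weight
initialization, the GA) draws from a substream spawned from the single run
seed, so a run is reproducible end to end; repeated study runs differ only
through that seed.

## Known limitations

- Exact published model statistics are not recoverable: the original
  hyperparameters (C, ε, γ, hidden size, stopping epoch) are unreported.
  The pipeline reproduces the magnitudes and the SVR-vs-MLP ordering
  pattern, not the printed third decimals.
- The CV-tuned embryo-count surrogate is close to a treatment-mean
  interpolant (the printed SEs are tiny), and RBF interpolants overshoot
  between design points: its maximum over the box exceeds the best
  observed count and sits at a higher SNP level than the published
  optimum. The published surrogate evidently smoothed more; with its
  hyperparameters unavailable, this difference is inherent to re-tuning.
- The published importance ordering for embryogenesis rate (SNP ahead of
  KIN) is difficult to reconcile with the published data table, in which
  embryogenesis is almost entirely determined by 2,4-D and KIN and barely
  varies with SNP; remove-and-retrain sensitivity on the reconstructed
  data accordingly ranks KIN at or near the top for that response.
- Embryo counts are treated as continuous (printed means are non-integer);
  no count-model likelihood is used, matching the published regression
  treatment.
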