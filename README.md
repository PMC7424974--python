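# embryopt

Surrogate-model optimization of plant tissue-culture protocols, built
around a worked case: somatic embryogenesis of chrysanthemum under three
plant growth regulators — 2,4-D (a synthetic auxin), kinetin (a cytokinin)
and sodium nitroprusside (SNP, a nitric-oxide donor).

Wet-lab optimization of an embryogenesis protocol is slow and expensive:
even a modest 4 × 4 × 4 factorial with nine replications is 576 culture
units scored over weeks. `embryopt` is for tissue-culture researchers and
modelers who want to squeeze a validated optimum out of such a factorial
computationally:

1. **Response surrogates.** One model per response — callogenesis rate
   (%), embryogenesis rate (%), somatic embryos per explant — as a
   function of the three concentrations. The primary surrogate is
   ε-insensitive support vector regression with an RBF kernel,

   ŷ(x) = Σᵢ (αᵢ − αᵢ*) k(x, xᵢ) + b,  k(x, z) = exp(−γ‖x − z‖²),

   trained by solving the dual (box constraints [0, C], Σ(αᵢ − αᵢ*) = 0)
   with an SMO solver written for this package; a three-layer perceptron
   trained with Levenberg–Marquardt is the comparison family. Since none
   of C, ε, γ or the hidden size is canonical, all are tuned by
   cross-validation. Models are compared by R² (squared Pearson
   correlation), RMSE and MAE in natural units.
2. **Input importance.** Remove-and-retrain sensitivity: the variable
   sensitivity ratio VSRⱼ = RMSE(model without input j) / RMSE(full model)
   ranks the regulators per response.
3. **Multi-objective optimization.** NSGA-II maximizes the embryogenesis
   rate and embryo count surrogates jointly over the experimental
   concentration box, and the reported optimum is the Pareto-front member
   minimizing the Euclidean distance √((f₁ − x)² + (f₂ − y)²) to the ideal
   point (x, y) — the best observed value of each objective.

The 64-treatment factorial summary (mean ± SE, n = 9) ships with the
package; replicate-level rows are reconstructed by exact moment matching,
and a synthetic Gaussian-peak surface generator provides ground truth for
recovery tests. See `docs/methods.md` for the models, defaults and
limitations.

## Worked example

Fit and score the embryo-count surrogate (`examples/02_fit_svr.py`):

```
tuned: C=1000 epsilon=0.01 gamma=5 (cv rmse 0.0171 scaled)
support vectors: 171 of 432 rows
train: R2=0.995 RMSE=0.822 MAE=0.633 (embryos/explant)
test: R2=0.995 RMSE=0.807 MAE=0.645 (embryos/explant)
```

The tuned model explains ~99.5 % of the replicate-level variance in embryo
counts; errors below one embryo per explant are at the scale of the
replicate noise itself.

Optimize the medium (`examples/04_optimize.py`):

```
Pareto front: 98 distinct points
ideal point (best observed): (100, 57.8)
selected medium: 2,4-D 9.42 uM, KIN 4.99 uM, SNP 27.15 uM
predicted there: embryogenesis 100.00 % (raw 106.29), 66.45 embryos/explant
distance to ideal: 10.692
```

The selected medium sits near the best observed treatment
(9.09 μM 2,4-D, 4.65 μM KIN, 20 μM SNP, which yielded 100 % embryogenesis
and 57.8 embryos); the count surrogate's prediction between design points
exceeds the best observed count because a tightly tuned RBF interpolant
overshoots off-grid — a behavior discussed in `docs/methods.md`.

Other examples: `01_dataset.py` (load and reconstruct the factorial),
`03_sensitivity.py` (VSR ranking), `05_full_study.py` (the orchestrated
SVR-vs-MLP study via `run_study`), `06_synthetic_recovery.py` (recover a
known synthetic optimum end to end).

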