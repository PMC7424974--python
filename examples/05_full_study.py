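"""Run the orchestrated study end to end and compare the model families.

One seed drives every stochastic stage.  This example uses a reduced grid
and GA budget; drop the overrides to run at the published scale
(full default grid, population 200 x 1000 generations, plus the
remove-and-retrain sensitivity stage).
"""

import logging

logging.getLogger("embryopt").setLevel(logging.ERROR)

import embryopt as eo

config = eo.RunConfig(
    seed=0,
    svr_grid=eo.SVRHyperGrid(C=(1.0, 10.0, 100.0), epsilon=(0.01, 0.1), gamma=(0.5, 2.0), k=3),
    mlp_config=eo.LMConfig(max_epochs=200, hidden_sizes=(3, 5, 8)),
    nsga=eo.NSGAConfig(population_size=60, generations=100),
    run_sensitivity=False,
)
report = eo.run_study(config)

print(report.metrics.round(3).to_string(index=False))
comparison = eo.compare_models(report)
wins = comparison["winner"].value_counts()
print(f"\ncell winners: {wins.to_dict()}")

opt = report.optimization
d24, kin, snp = opt.selected_decision
print(
    f"\nselected medium: 2,4-D {d24:.2f} uM, KIN {kin:.2f} uM, SNP {snp:.2f} uM"
)
print(
    f"predicted: embryogenesis {min(opt.selected_objectives[0], 100):.2f} %, "
    f"{opt.selected_objectives[1]:.2f} embryos/explant"
)
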