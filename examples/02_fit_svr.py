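"""Tune and fit one epsilon-SVR response model and score it.

Grid-tunes (C, epsilon, gamma) by 5-fold cross-validated RMSE on the
training partition, fits the winner, and reports R2/RMSE/MAE in natural
units on both partitions.  R2 is the squared Pearson correlation; RMSE and
MAE are in embryos per explant for this response.
"""

import logging

logging.getLogger("embryopt").setLevel(logging.ERROR)

import embryopt as eo
from embryopt.preprocess import fit_scaler

replicates = eo.expand_replicates(eo.load_treatment_means(), 9, seed=0)
train, test = eo.split(replicates, train_fraction=0.75, seed=0)
scaler = fit_scaler(train, list(eo.FACTOR_NAMES) + ["num"])

X = scaler.apply_array(train[list(eo.FACTOR_NAMES)].to_numpy(), list(eo.FACTOR_NAMES))
y = scaler.apply_array(train[["num"]].to_numpy(), ["num"]).ravel()
C, eps, gamma, cv_rmse = eo.tune_svr(X, y, eo.SVRHyperGrid(seed=0))
print(f"tuned: C={C:g} epsilon={eps:g} gamma={gamma:g} (cv rmse {cv_rmse:.4f} scaled)")

model = eo.fit_response(train, "num", scaler, C, eps, gamma)
print(f"support vectors: {model.n_support} of {len(train)} rows")
for name, part in (("train", train), ("test", test)):
    pred = model.predict(part)
    print(
        f"{name}: R2={eo.r_squared(part['num'], pred):.3f} "
        f"RMSE={eo.rmse(part['num'], pred):.3f} "
        f"MAE={eo.mae(part['num'], pred):.3f} (embryos/explant)"
    )
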