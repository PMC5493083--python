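"""Stepwise MLR on one calibration set, with the full validation battery.

Selection is forward-entry / backward-removal on partial-F p-values (enter at
p < 0.05, remove at p > 0.10).  The fitted subset is then judged by
leave-one-out Q², external prediction R^2_p, and a 10-round Y-randomization.
"""

import numpy as np

from hsp90qsar import (
    fit_ols, generate, make_splits, q2_cv, r2_prediction, stepwise_select, y_randomization,
)

dataset, truth = generate(
    n=50, p=40, n_informative=4, seed=7, target_signal_r2=0.8,
)
split = make_splits(dataset, n_validation=9, n_repeats=1, seed=7)[0]
X, y = dataset.X(), dataset.y()
X_cal, y_cal = X.loc[list(split.calibration_ids)], y.loc[list(split.calibration_ids)].to_numpy()
X_val, y_val = X.loc[list(split.validation_ids)], y.loc[list(split.validation_ids)].to_numpy()

model = stepwise_select(X_cal, y_cal)
print(f"selected descriptors: {model.descriptor_names}")
print(f"planted descriptors : {truth.informative_names}")
print(f"R2c = {model.r2_c:.3f}, S.E. = {model.se:.3f} (N = {model.n_train})")

refit = lambda Xf, yv: fit_ols(Xf[model.descriptor_names], yv)  # noqa: E731
q2, rmse = q2_cv(refit, X_cal[model.descriptor_names], y_cal)
print(f"Q2_LOO = {q2:.3f}, RMSE_CV = {rmse:.3f}")
print(f"R2_p on the 9 held-out compounds = {r2_prediction(model, X_val, y_val):.3f}")

res = y_randomization(refit, X_cal[model.descriptor_names], y_cal, n_iter=10, seed=7)
print(f"Y-randomization: original R2 = {res.original[0]:.3f}, "
      f"max permuted R2 = {res.max_permuted_r2():.3f}")
print("A sound model keeps a wide margin between its R2 and every permuted refit;")
print("overlap would mean the fit explains chance correlation.")
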