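# hsp90qsar

QSAR model building and validation for 3,4-isoxazolediamide inhibitors of
Hsp90 (heat-shock protein 90, an ATP-dependent chaperone and anticancer drug
target).  The package re-implements, as a tested reusable library, the
descriptor-based modelling workflow used to relate molecular descriptors to
inhibitory activity (pIC50) for a 50-compound isoxazolediamide series:

* **Preprocessing** — removal of constant/near-constant descriptor columns,
  then greedy pruning of collinear pairs (|r| > 0.9), keeping from each pair
  the member more correlated with the activity.
* **CDFS** (combined data-splitting feature selection) — repeated
  calibration/validation splits (by default 9 of 50 compounds held out, five
  repeats), a descriptor selector run per split, the selected descriptors
  pooled, and a *general model* refit on the pooled set.
* **Stepwise MLR** — forward-entry / backward-removal multiple linear
  regression on partial-F p-values (enter at p < 0.05, remove at p > 0.10).
* **GA-PLS** — genetic-algorithm search over descriptor-inclusion bit
  vectors, each subset scored by the cross-validated Q² of a NIPALS partial
  least squares model.
* **Validation** — leave-one-out / leave-3-out cross-validation
  (Q² = 1 − PRESS/Σ(y−ȳ)², RMSE_CV), external prediction R²p, and
  Y-randomization (refits on permuted activities as a chance-correlation
  null).
* **Applicability domain** — hat-matrix leverages, warning leverage
  h* = 3(k+1)/n, standardized residuals and William's-plot outlier flags.
* **Published equations** — the series' two final six-descriptor models
  (general MLR and GA-PLS) as fixed, citable predictors, plus the printed
  experimental/predicted activity tables as packaged fixtures.

Activities are pIC50 = −log10(IC50 in mM), the (unconventional) scale the
source activity tables use; the unit is an explicit parameter of the
conversion helpers.

Because the original 50 × 1126 descriptor matrix was never deposited, the
package ships a seeded synthetic generator (`hsp90qsar.synthetic`) that
reproduces the matrix's statistical structure — constant columns, planted
collinear blocks, a sparse six-descriptor linear signal calibrated to a
chosen signal R² — with full ground truth, so every pipeline stage is
testable end to end.

Intended users: cheminformaticians and method developers who need a
transparent, seedable reference implementation of the classic
stepwise-MLR / GA-PLS QSAR workflow with its validation battery.

## Worked example

```python
from hsp90qsar import paper_shaped_instance, run_cdfs

dataset, truth = paper_shaped_instance(seed=11)   # 50 x 300, signal R² = 0.775
report = run_cdfs(dataset, n_validation=9, n_repeats=5,
                  selector="stepwise", seed=11)
g = report.general_report
print(f"general model: N = {g.n_cal}, R2c = {g.r2_c:.3f}, "
      f"Q2_LOO = {g.q2:.3f}, R2p = {g.r2_p:.3f}")
print(f"Y-randomization: original R2 {report.y_rand.original[0]:.3f} "
      f"vs max permuted {report.y_rand.max_permuted_r2():.3f}")
```

prints

```
general model: N = 41, R2c = 0.891, Q2_LOO = 0.824, R2p = 0.295
Y-randomization: original R2 0.891 vs max permuted 0.319
```

The general model is refit on the 41 calibration compounds of the first
split.  Its calibration R² (0.891) exceeds the planted signal level (0.775):
with 41 compounds and ~270 candidate descriptors, stepwise selection
inevitably co-opts some chance correlates — visible here as the modest
external R²p.  The wide margin over every Y-randomized refit (0.319) shows
the model is nonetheless far from pure chance.  See `examples/` for one
short script per capability, and `docs/methods.md` for the statistical
conventions and their caveats.

A thin CLI mirrors the library (`hsp90qsar preprocess | split | fit-mlr |
fit-gapls | validate | ad | predict | simulate | run-cdfs`); run
`hsp90qsar --help`.

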