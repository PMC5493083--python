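"""Leverage applicability domain and the William's-plot table.

Leverage measures how far a compound sits from the calibration design's
centroid; the warning leverage h* = 3(k+1)/n flags structural extrapolation,
and standardized residuals beyond +/-2.5 SD flag response outliers.  For the
published six-descriptor models on the 50-compound series, h* = 0.42.
"""

import numpy as np

from hsp90qsar import fit_ols, generate, warning_leverage, williams_table

print(f"warning leverage for k=6 descriptors, n=50 compounds: {warning_leverage(6, 50):.2f}")

dataset, _ = generate(n=50, p=6, n_informative=3, seed=5, target_signal_r2=0.8)
X, y = dataset.X(), dataset.activities.copy()
y[9] += 5 * y.std()  # corrupt one activity to show the response-outlier flag

model = fit_ols(X, y)
assessment = williams_table(model, X, y, residual_limit=2.5)
t = assessment.table
print(f"h* = {assessment.h_star:.3f}, residual limit = +/-{assessment.residual_limit} SD")
print(f"leverage range: {t['leverage'].min():.3f} - {t['leverage'].max():.3f} "
      f"(sum = {t['leverage'].sum():.1f} = k+1)")
outliers = assessment.outliers()
print(f"{len(outliers)} flagged compound(s):")
print(outliers[["leverage", "std_residual", "response_outlier", "structural_outlier"]])
print("The corrupted compound is caught by its standardized residual; compounds")
print("beyond h* would be extrapolations whose predictions should not be trusted.")
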