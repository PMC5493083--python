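# Methods

This note records the statistical conventions, parameter choices and known
limitations of the package. Everything quantitative stated here is computed
by the test suite or the example scripts.

## The modelling problem

A QSAR (quantitative structure–activity relationship) model maps a vector of
molecular descriptors — numeric features of a molecule's constitution,
topology and 3D geometry (connectivity indices, 3D-MoRSE, WHIM, GETAWAY, RDF
families, quantum-chemical dipole components, …) — to a biological activity.
Here the activity is inhibition of Hsp90's ATPase-linked function by
3,4-isoxazolediamides, expressed as pIC50 = −log10(IC50 in mM). The
millimolar log scale is unusual (micromolar or molar scales are more common)
but is the scale on which the series' printed IC50 and pIC50 values are
mutually consistent; the packaged-fixture test verifies this for all 25
compounds carrying both values, within print rounding. The conversion
helpers expose the unit as a parameter.

## Pipeline stages and conventions

**Preprocessing.** A column is invariant when its most frequent value (after
rounding to 6 significant figures) occupies more than `dominant_fraction`
(default 0.95) of rows, or its variance is below `variance_floor` (default
1e-8). The dominant-fraction + variance-floor definition is deterministic
and unit-free; "near constant" has no canonical definition. Collinearity
pruning is greedy on Pearson |r|: while any surviving pair exceeds the
threshold (default 0.9), the largest-|r| pair is resolved by dropping the
member with smaller |corr(column, activity)|. Tie-breaks (first pair in
column order; drop the later column) make the procedure order-deterministic.
The greedy largest-first order was chosen because it makes the output
independent of column permutation up to those documented tie-breaks.

**Splitting.** Validation sets of `n_validation` (default 9 of 50 — the
series' own geometry, even though a literal 20% of 50 would be 10) are drawn
uniformly without replacement; repeat r uses substream (seed, r) so adding
repeats never changes earlier splits. Optional stratification bins compounds
by activity rank and draws one per bin. Unstratified is the default since
the source workflow states no stratification rule.

**Stepwise MLR.** Classic forward/backward selection on partial-F p-values
with the SPSS defaults p_enter = 0.05, p_remove = 0.10 (the source workflow
names SPSS stepwise without thresholds; these are assumptions, exposed as
parameters). `max_terms` defaults to 7, the largest elected model size in
the source workflow. OLS and stepwise operate on raw descriptors with an
intercept, so coefficients are in original descriptor units, comparable to
the published equations. Candidates whose entry would make the design
rank-deficient are skipped.

**PLS.** NIPALS with internal autoscaling (center, unit variance — standard
chemometrics practice); the fitted model is expressed back in original
units. With a single response the NIPALS inner iteration converges after one
weight update, so components are extracted in closed form; the implementation
is cross-checked against an independent reference implementation to 1e-10.
When the caller does not fix the component count it is chosen to maximize
leave-one-out Q², capped at min(6, rank); ties go to the smaller model. The
LOO search costs one NIPALS pass per fold because the coefficient path over
component counts is cumulative. The standard error of a PLS fit uses the
component count as the model dimensionality in RSS/(n − k − 1); PLS degrees
of freedom are not well defined and this choice is the conservative
convention.

**GA-PLS.** Generational GA over descriptor-inclusion bit vectors: tournament
selection (size 2), uniform crossover (rate 0.9), per-gene mutation (rate
1/p), elitism 2, population 50, 100 generations by default. None of these
are stated by the source workflow; they are ordinary textbook settings.
Fitness is the cross-validated Q² of a PLS model on the included columns
(component count per subset by the best cross-validated fit, capped at 6).
Parsimony is a hard cap (`max_subset_size`, default 10) rather than a
penalty: simpler to reason about and matching the six-descriptor outcome
scale. Oversized and empty chromosomes score −inf and can never be returned
as best. Leave-one-out fitness is the default; leave-3-out is available
(the source workflow reports a leave-3-out Q² for its GA-PLS model and is
ambiguous about which drove the fitness). With leave-3-out the folds are one
seeded disjoint triplet partition fixed for the whole run, so the fitness
cache contract — identical gene vectors give identical fitness — holds
exactly. Elitism makes best-ever fitness monotone, which the tests assert.

**Cross-validation.** Q² = 1 − PRESS/Σ(y − ȳ)² with ȳ the full calibration
mean (not per-fold means), the QSAR convention consistent with reporting a
single RMSE_CV = sqrt(PRESS/n). Leave-one-out is deterministic;
leave-k-out (k > 1) partitions compounds into disjoint groups of k (a
smaller final group when n is not divisible), repeated `n_rounds` (default
10) times with averaged statistics. The LOO path is verified against an
explicit per-sample-refit oracle to 1e-12 for OLS and fixed-subset
procedures, and to 1e-10 against a generic fold-refit loop for PLS.

**External prediction.** R²p is the squared product-moment correlation
between observed and predicted validation activities. This convention is
shift- and scale-invariant — a systematically biased model can score 1.0 —
which is why the stricter external Q²F1 (PRESS about the calibration mean)
is also provided (`q2_external`). The correlation convention is the primary
statistic because the source workflow's reported R²p values exceed its
calibration R², which only the correlation convention can produce.

**Y-randomization.** Activities are permuted uniformly (seeded), the model
refit, and R²/Q²LOO recorded, 10 iterations by default. The default refits
coefficients on the final fixed descriptor subset; passing the full selector
as the fit procedure gives the stricter re-selection variant. Under the null
(pure-noise data, fixed subset) the original R² is itself a draw from the
permutation distribution; the tests verify this calibration (equal means,
originals inside the permuted central range).

**Applicability domain.** Leverage h = x(XᵀX)⁻¹xᵀ on the intercept-augmented
calibration design; Σh over calibration compounds = k + 1 (hat-matrix
trace), asserted to 1e-10. Warning leverage h* = 3(k+1)/n. The n in h* is
configurable: "total" (calibration + validation; default) or "calibration".
The default matches the series' published threshold 0.42 = 3·7/50, although
the accompanying text defines n as the calibration size (3·7/41 ≈ 0.51);
the two conventions are never silently merged. Standardized residuals
divide by the SD of calibration residuals — population form (divisor n) by
default, the regression form (divisor n − k − 1) optionally; the source
workflow gives no formula. Response-outlier limits default to ±2.5 SD for
MLR-type and ±3.0 SD for PLS-type models, as in the source workflow.

**CDFS orchestration.** Each split's selector yields that split's elected
model (stepwise already maximizes within a split; when ranking between
candidate models is needed, the rule is maximize Q²LOO with R²c as
tie-break). The general model is the selector refit restricted to the pooled
descriptor union on the first split's calibration set (the source workflow
does not say which split was used; split 1 is recorded in the run manifest,
and `general_split="all"` refits on all compounds, changing the reported
calibration N). Every random draw derives from the master seed via named
substreams, so reports are byte-reproducible.

**Published equations.** Stored exactly as printed. The TIE coefficient is
printed as 0.001(±0.00); predictions involving large TIE values inherit that
truncation. Descriptor-name matching is whitespace/underscore-insensitive
("dipole z" ≡ "dipole_z"). Two Q²LOO values are reported for the general
MLR model in its source (0.637 in the equation block, 0.710 in the text);
the equation-block value is stored in `reported_stats` and neither is
reproducible without the original descriptor matrix.

## The synthetic generator

`generate` draws independent standard-normal base descriptors, a sparse
linear signal over `n_informative` of them (coefficients uniform on
`coefficient_range`, default (0.5, 1.5), random sign), Gaussian activity
noise, planted collinear children (child = r·parent + √(1−r²)·ε, parents
alternating between informative and non-informative columns so the pruning
rule is exercised in both directions) and constant columns. With
`target_signal_r2` set, the realized noise vector is orthogonalized against
the signal and rescaled so the achieved signal R² equals the target exactly
— a calibrated instance rather than a lucky draw.

`paper_shaped_instance` is the desk-scale stand-in for the series' matrix:
50 compounds × 300 descriptors (scaled down from the original 1126 so a full
pipeline run takes about a second and multi-seed studies stay fast), 6
informative descriptors at signal R² = 0.775 (midpoint of the 0.70–0.85
calibration-fit band), 20 collinear pairs at |r| = 0.95, 10 constant
columns, intercept 4.2 (the center of the series' pIC50 range).

What the generator does **not** emulate: real DRAGON descriptor marginals
(heavy-tailed or bounded in family-specific ways), inter-family correlation
structure beyond the planted pairs, and any relation between descriptor
identity and chemistry. Passing recovery tests on this generator therefore
demonstrates the pipeline's statistical behaviour under its stated
assumptions, not performance on real descriptor matrices.

## Known limitations

* **Variable selection at these dimensions is unstable.** With 41
  calibration compounds and ~270 candidate descriptors, each true
  descriptor's marginal |t| (≈2.4–4 at the calibrated signal level) is
  comparable to the expected maximum chance |t| over the candidate pool
  (≈3.1), so stepwise selection regularly admits chance correlates in place
  of weaker true descriptors; the elected models' calibration R² exceeds
  the planted signal level while external R²p drops. Pooling over five
  splits (CDFS) mitigates but does not remove this. Multi-seed runs of the
  full pipeline recover the planted six-descriptor set only partially —
  typically 2–5 of 6 representatives in the general model — even when a
  planted descriptor is credited through its |r| = 0.95 collinear child
  (within a planted collinear pair the members are statistically
  interchangeable at n = 50, and the pruning duel is decided by a noisy
  correlation difference, so identifiability is only up to the planted
  block). The cross-validated Q² of the general model nonetheless tracks
  the planted signal level closely, and Y-randomization cleanly separates
  signal models from permuted refits — these, not selection identity, are
  the robust outputs of the workflow at this sample size.
* LOO-based component selection and LOO Q² on a subset chosen using all
  calibration compounds carry selection bias; the external validation split
  is the unbiased check.
* The published equations are fixed literals; their coefficient
  uncertainties are reported, not re-derived, and the predicted-activity
  fixture columns cannot be regenerated without the original matrix.
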