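# Methods

This note documents the models, the numerical choices and the design
decisions behind `gagfib`, and what the synthetic-data tests do and do not
establish about real curated data.

## Kinetics

Aggregation time courses are summarised by the half-time `t½`. Two
phenomenological forward models are supported:

* **no lag phase** — exponential relaxation
  `A(t) = A∞ + (A0 − A∞)·exp(−k_agg·t)`;
* **lag phase** — Boltzmann sigmoid
  `A(t) = A0 + (A∞ − A0) / (1 + exp(−k_agg·(t − t½)))`.

With the tangent-at-midpoint convention, `t_lag = t½ − 2/k_agg`, so
experiments reporting only `(k_agg, t_lag)` yield `t½ = t_lag + 2/k_agg`.
The acceleration statistic `G = ln(t½(0)/t½(GAG))` depends only on the ratio
of half-times, so it is invariant to the time unit and, in the no-lag case,
to the factor 2 in the half-time convention (`G` becomes the log-ratio of
elongation rates exactly). The constant 2 only matters for entries combining
a non-zero lag with a rate; the bundled synthetic data never depends on it.

**Fitting.** Trust-region nonlinear least squares (`scipy.optimize
.least_squares`, `trf`) with five starts: one from data-driven heuristics
(`A0` = first signal, `A∞` = last, `t½` = mid-signal crossing,
`k_agg = 4/(t90 − t10)`) and four seeded jitters of it. Model choice under
`lag_present="auto"` is an extra-sum-of-squares F-test at α = 0.05 (the
sigmoid spends one parameter more than the exponential); ties and
non-significant improvements go to the simpler exponential. A constant trace
raises a degenerate-trace error; traces need ≥ 6 strictly increasing time
points.

## The database schema

One row per literature experiment: protein descriptors (length, net charge at
pH 7.5, Lys+Arg count, folding status, disease association), GAG descriptors
(sulfates and negative charges per disaccharide unit, uronic-acid type,
N/O-sulfation, optional molecular weight), solution descriptors (total solute
molarity in mM, concentrations, protein:GAG molar ratio, pH, temperature) and
the observed `t½` pair with `G`. Hard invariants: stored `G` must equal
`ln(t½(0)/t½(GAG))` to 1e-6; charges ≥ sulfates (each sulfate carries one
negative charge, the uronic carboxylate at most ~1 more); sulfation position
`none` exactly when the sulfation state is 0; the molar ratio must agree with
the concentration quotient within 5% when all three are present.

Files are UTF-8 tab-separated with one header row; floats are written with
`repr` so a save→load round trip is bit-identical. Missing optional fields
are empty cells, carried as absent and excluded pairwise. Recognised time
units are normalised to hours at load (cosmetic for `G`). Dummy coding drops
one reference level per dichotomous variable — glucuronic, O-sulfation,
globular, not-disease-related — with alphabetical-first as the fallback for
unregistered variables; any consistent coding yields the same fit.

## Univariate analyses

Pearson `r` with the exact two-tailed t-transform p-value (`n − 2` df) and
the OLS line, including its x-intercept (the descriptor value at which the
GAG has no net effect). Level means (e.g. per sulfation state) and bin means
(quartile-based edges by default, returned with the result so the binning is
reproducible) are correlated against level values / bin centers. Two-group
comparisons use Welch's unequal-variance t-test, the conservative default for
small unequal groups; groups with n < 2 return summaries without a test.

## Multivariate model and selection

The design matrix carries an intercept, the listed predictors, raw (uncentred)
squares for quadratic terms, and products for interactions (which must involve
at least one dummy). Estimation is OLS (statsmodels) with coefficient SEs
from the unbiased residual variance, the overall F-test, adjusted R²,
per-column VIF and the Breusch–Pagan test.

**Collinearity criterion.** Raw squares make a variable and its own square
strongly collinear by construction (VIF ≈ 10–15 for the molar-ratio pair on
typical data). That structural collinearity is inherent to fitting a
quadratic and says nothing about redundancy *between* descriptors, so the
model-acceptance criterion uses `vif_between_variables`: the VIF of each
column computed against the other columns after removing its own
polynomial/interaction partners. Raw VIFs are still computed and reported.
With a centred parameterisation the two notions would nearly coincide; raw
squares keep the published coefficient convention.

**Five acceptance criteria** for a candidate model: all non-intercept
coefficients p < 0.05; model F-test p < 0.05; adjusted R² maximal among
admissible candidates (the selection objective); all between-variable VIF
< 10 (flagged from 5); Breusch–Pagan p > 0.05. On a numerically exact fit
(zero residuals) the F and Breusch–Pagan statistics are degenerate; the fit
is then treated as maximally significant and homoscedastic.

**Search.** Best-subset enumerates every subset of the pruned candidate
columns (cap 12 columns; constant or mostly-missing candidates pruned),
honouring the hierarchy that a square may only enter with its linear term.
Stepwise runs forward selection (p-to-enter 0.05) with backward pruning
(p-to-remove 0.10), never orphaning a square, and criterion-checks the final
model. Ties in adjusted R² break toward fewer predictors, then lexicographic
column order, making selection deterministic. If no candidate passes, a
no-model error lists the near misses.

**The predictive equation.** `G = y0 + a·P_S + b·P_B + c·P_MR + c′·P_MR²`,
with the reference coefficient set (2.0, 0.30, −0.016, 0.11, −0.0020) and
SEs (0.7, 0.05, 0.004, 0.03, 0.0005). With `c′ < 0` the predicted effect
peaks at `P_MR = −c/(2c′)`; for the reference coefficients that vertex is
27.5, although the same analysis has been summarised verbally as an optimum
near 10 — the package reports the coefficient-derived closed form (verified
against a grid search) and flags the discrepancy rather than matching the
verbal figure.

## Validation

* **Subsampling bootstrap** (the "bootstrap" here is repeated random
  subsampling *without* replacement): each of 100 replicates partitions the
  table into a 2/3 training set and the disjoint 1/3 test set (26/13 at
  n = 39), refits the specification on the training part, predicts the test
  part and records the Pearson correlation between predicted and observed G.
  Summary: mean ± standard error of the 100 coefficients. Replicates with a
  singular training design or a degenerate test set are redrawn and counted.
* **Jackknife**: n leave-one-out refits, one out-of-sample prediction each;
  the summary is the R² (and p) of the ordinary regression of predicted on
  observed G — the usual analysis of a leave-one-out scatter plot — not the
  squared correlation around a forced identity line.
* **Prediction report**: predicted-vs-observed r, p, best-fit line, and the
  residual list with mean and spread.

## Synthetic data

The generator emulates the covariate regime of the curated literature
database: sulfation states {0, 1, 2, 3} weighted (0.15, 0.15, 0.40, 0.30)
toward the highly sulfated GAGs; solute molarity uniform on [20, 300] mM;
molar ratio log-uniform on [0.3, 60] (most mass at GAG excess, as in the
literature). `G` is the predictive equation at the sampled covariates plus
i.i.d. Gaussian noise **on the G scale** (the model is specified on that
scale); `noise_for_target_r2` returns
`signal_sd · sqrt(1/target − 1)`, calibrated so that the realised R² of a
refit averages the target (0.74 by default) — verified by Monte Carlo to
within 0.02. The half-time pair is back-filled as `(24 h, 24·e^(−G) h)`;
the 24 h base is arbitrary and `G` is invariant to it. Protein and GAG
descriptors come from pools of realistic, fully specified molecules
(α-synuclein, the 173–243 gelsolin fragment, heparin, hyaluronic acid, …)
assigned independently of `G`, so every generated row passes the database
invariants and any protein-descriptor association is noise by construction.

What the synthetic tests show: the estimation, selection and validation
machinery is correct under the model's own assumptions (exact recovery
without noise, calibrated coverage and recovery with noise). What they do not
show: that real curated data satisfy those assumptions — real tables have
correlated descriptors chosen by experimenters, non-Gaussian and possibly
heteroscedastic errors, and transcription ambiguities. Numbers computed on
the bundled synthetic table (e.g. the worked example's adjusted R² of 0.79 or
jackknife R² of 0.76) characterise the pipeline, not the literature.

**Selection-consistency universe.** The end-to-end recovery test (≥ 90/100
runs at n = 200, target R² 0.74) is evaluated over the identifiable candidate
universe: the three generating descriptors, the molar-ratio square, and a
pure-noise dummy decoy (uronic-acid type). The charge-per-disaccharide
descriptor is deliberately excluded from that universe: since almost every
GAG adds exactly one carboxylate charge to its sulfation state, charges track
sulfates at r ≈ 0.97, and no finite-sample procedure can reliably prefer one
of two such proxies — in simulation, including it drops exact recovery to
~68/100 purely through proxy substitution. That behaviour is real and is
covered by its own tests (the two measures are never co-selected: their
mutual VIF exceeds the criterion), but it measures the data's
identifiability, not the selection algorithm's consistency.

## Problem sizes and defaults

Study-sized analyses use n = 39 entries (the curated database's size) and
100 bootstrap replicates with 26/13 splits; selection-consistency and
calibration checks use n = 200 entries and 100 seeded replicates; kinetic
refits use 60-point traces, noiseless and at 2% Gaussian noise. All
stochastic components take explicit integer seeds (numpy `default_rng`), and
derived sub-seeds come from `SeedSequence` spawning.

## Known limitations

* The lag-time constant in `t½ = t_lag + 2/k_agg` is a convention; entries
  mixing lag and no-lag conventions from different sources could bias `G` at
  the ~`ln(2)`-scale worst case. Curators should record which convention a
  source used.
* Best-subset enumeration is exponential in the candidate count (capped at
  12 columns); larger universes need pre-pruning.
* The Breusch–Pagan criterion makes the homoscedasticity check reproducible
  but, at α = 0.05, rejects a correctly specified model 5% of the time — a
  visual residual check would "pass" some of those.
* The predictive equation is purely phenomenological: it encodes no
  nucleation–elongation mechanism and should not be extrapolated outside the
  covariate ranges it was fitted on (sulfation 0–3, molarity tens–hundreds of
  mM, molar ratio ~0.1–100).
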