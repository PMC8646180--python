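# Methods

This note documents the generative model, the two survival networks, the
evaluation suite, and the design choices that were genuinely open, together
with known limitations.

## Synthetic-trial generator

The generator emulates a randomized osteosarcoma trial with five prognostic
factors. The four binary factors (treatment regimen C/DI, sex, histological
response poor/good, margin incomplete/complete) define 16 strata; each
subject's stratum is drawn multinomially from the stratum proportions, and
age at surgery is drawn from the stratum-specific normal distribution (both
shipped in `data/default_config.yaml`). Ages below 0 are redrawn; this
truncation raises the mixture mean of age from the untruncated 16.155 to
16.247 years, which the tests account for. Ages are otherwise not truncated
to any observed range.

Survival times are log-normal AFT draws, `log T = μ + βᵀx + σε`. The
per-predictor effects β (on log survival time) are fixed configuration, not
estimates: a negligible treatment effect (+0.05, the trial found none), a
modest male disadvantage (−0.20), strong benefits of good histological
response (+0.80) and complete surgical margins (+0.60) — the two dominant
prognostic factors in this disease — and a mild age penalty (−0.025/year).
Only their direction is enforced by the calibration routine; users may
substitute their own.

Censoring times are Weibull. Five specifications are shipped:
(shape 0.75, scale 76 / 20.5 / 6.8 / 2.4) targeting 20/40/61/80% censoring,
and (shape 2.03, scale 5.72) as a second route to 61%. Because the realized
censoring fraction depends on the survival distribution, the intercept and
scale (μ, σ) are calibrated so that *all five* specifications realize their
nominal rates simultaneously: within each stratum `log T` is normal with mean
μ + βᵀx̄_s and variance σ² + (β_age σ_age,s)², so P(T > C) integrates exactly
over the 16-component mixture by Gauss–Hermite quadrature, and a Nelder–Mead
least-squares search over (μ, log σ) drives the five analytic censoring
fractions to their targets. The calibrated defaults μ = 1.5222, σ = 1.2232
leave every specification within 0.3 percentage points of nominal; a
single-target bisection on μ alone is available as an alternative mode. The
resulting marginal survival (S(2) ≈ 0.82, S(5) ≈ 0.58, median ≈ 6.5 years)
is in the range expected for this disease.

Reproducibility: every random stream is keyed by the triple
(master_seed, replicate, stream) through numpy's `SeedSequence`, so any
replicate — and any stage within it (covariates, survival, censoring, split,
model initialization) — can be regenerated in isolation, and identical seeds
give byte-identical datasets and results.

Two adverse training-data transforms are provided (applied to the training
half only): removing subjects censored before year 2, and administrative
censoring of all follow-up at year 5.

## Discretization and person-period expansion

Follow-up is cut into L intervals (τ_{l−1}, τ_l] with the last interval
open-ended; yearly (L=8), six-month (L=16) and three-month (L=32) schemes are
shipped, all spanning eight years. Exact boundary times belong to the earlier
interval (right-closed convention). Interval midpoints serve as the time
input of PLANN original; the open last interval's midpoint is placed half an
interval width past the last boundary (7.5 years for the yearly scheme).

Training expansion gives subject i one row per interval up to the interval
l_i containing the observed time, with the binary target equal to the event
indicator in row l_i and 0 before. A subject *censored* inside interval l_i
still contributes that interval with target 0 — the subject was at risk for
part of it, and this matches the discrete-hazard likelihood; the alternative
(dropping the partial last interval) is available behind a flag for
sensitivity analysis. Test expansion repeats every subject for all L
intervals in stable subject-major order.

## The networks

Both networks output a single logistic unit estimating the discrete hazard of
one person-period row, trained with binary cross-entropy (the discrete
survival likelihood on the long table). Predictions are clipped to
[1e−7, 1 − 1e−7] wherever logs or logits are taken.

**PLANN original** — inputs: standardized interval midpoint + the 5
covariates (age standardized, binaries as 0/1); logistic hidden layer of H
nodes; objective: summed cross-entropy + decay·‖w‖² (all weights and biases);
optimizer: full-batch L-BFGS with analytic gradients, initialization uniform
in ±0.5 from the seeded generator. Non-convergence within the iteration cap
returns the best-so-far weights with a warning flag. `hidden_size = 0` is a
testing hook that collapses the model to a plain logistic regression (checked
against an IRLS fit to < 1e−3).

**PLANN extended** — inputs: L interval dummies + the 5 covariates; hidden
activation selectable among logistic/ReLU/tanh (output strictly logistic);
mini-batch SGD with momentum on the *mean* weighted cross-entropy, inverted
dropout on the hidden layer (disabled at prediction), event rows weighted by
the weak-class weight ≥ 1; Glorot-uniform initialization. The epoch budget
(150) and batch size (64) are configuration defaults. A two-hidden-layer
variant is deliberately out of scope (overfitting risk in this small-data
setting).

Hazard-to-survival conversion: S(t₀) multiplies (1 − h_l) over intervals
whose upper boundary lies at or below t₀; the open last interval never
completes before a finite horizon. The nonlinear prognostic index of a
subject is the average over intervals of logit(h_l); like the Cox linear
index xᵀβ̂, higher values mean worse prognosis, so both feed the same
concordance routine.

## Cox comparator

Main effects only, no time-dependent terms. Coefficients come from lifelines'
partial-likelihood fitter (Efron tie handling; Breslow available through
statsmodels), zero-variance columns are dropped, and the Breslow-type
baseline cumulative hazard at x = 0 is computed in-module at event times with
right-continuous step evaluation (last value carried forward beyond the data,
flagged). With no informative covariates this reduces exactly to the
Nelson-Aalen estimator.

## Evaluation

* **Harrell's C**: usable pairs are those where the shorter time is an
  observed event, or the times are tied with exactly one event; tied-time
  double-event pairs are unusable; tied indices score 0.5. Checked exactly
  against brute-force pair enumeration.
* **IPCW Brier at t₀**: deaths at or before t₀ contribute (0 − Ŝ)²/Ĉ(t−);
  subjects beyond t₀ contribute (1 − Ŝ)²/Ĉ(t₀); earlier-censored subjects
  contribute 0; the sum is divided by n. Ĉ is the marginal reverse
  Kaplan-Meier estimate of the censoring distribution (covariates carry no
  censoring information in this design); at tied times deaths are taken to
  precede censorings. Zero weights (Ĉ = 0 at a contributing time) exclude
  the affected subjects with a warning.
* **IBS to 5 years**: the error curve is evaluated at the yearly horizons
  0–5 and integrated as a right-continuous step function, normalized by the
  horizon — i.e. the left-endpoint sum (B₀+…+B₄)/5, the convention of
  standard prediction-error-curve software on a user-supplied grid.
  Trapezoidal and yearly-mean variants are selectable; on a fine grid the
  step and trapezoid integrals agree, on the yearly grid the step integral
  is systematically lower because the curve rises.
* **Miscalibration MSE at t₀ ∈ {2, 5}**: subjects are split into 4
  equal-count groups by predicted survival (stable-order tie-break); per
  group the Kaplan-Meier survival at t₀ (last value carried forward if the
  group's follow-up ends earlier, flagged) is compared with the mean
  prediction; the squared differences are averaged over groups.

## Tuning and replication protocol

Hyperparameters are selected once per censoring scenario on the training half
of a dedicated n = 1000 dataset by 5-fold cross-validated grid search (folds
stratified on the event indicator and shared by both networks), optimizing
either the 5-year IBS or the C-index; ties go to the least complex
configuration (fewest hidden nodes, then strongest regularization). The
shipped grids are: hidden size {1,2,3,4,6,8} × decay {0,.01,.05,.1,.2} for
PLANN original, and nodesize {2,4,8} × dropout {0,.1,.2} × learning rate
{.01,.05,.1} × momentum {0,.5,.9} × class weight {1,1.05} × activation
{logistic,relu,tanh} for PLANN extended. Running this protocol selected the
shipped defaults: hidden size 1 with decay 0.2 for PLANN original (both
criteria), and nodesize 4, no dropout, learning rate 0.1, momentum 0.9,
class weight 1.05, ReLU for PLANN extended on the IBS criterion — the small
size and relatively strong regularization are exactly what this data regime
rewards.

The Monte-Carlo study then freezes those configurations and runs B replicate
datasets per cell: simulate → 50/50 split stratified on the event indicator
(odd counts favour training) → adverse transform on the training half only →
fit all three methods on the identical training half → score on the identical
test half. Replicates with fewer than two test events are redrawn with
logging. Aggregates are means and standard deviations *across replicates*.
The default B = 100 is a deliberate scale-down of the full B = 1000 study
(the seeded design makes larger runs a flag away); reported standard
deviations are correspondingly noisier.

## What the generator does and does not emulate

It reproduces the trial's covariate mixture, a realistic log-normal
survival-time distribution calibrated to the published censoring rates, and
independent Weibull censoring. It does **not** reproduce the original trial's
unpublished regression coefficients (effect sizes here are plausible
configuration, so absolute metric levels can differ from the original
analysis in the second decimal), nor missing data, competing risks,
covariate-dependent censoring, or time-varying effects. Passing tests
therefore demonstrate correctness of the pipeline and statistical agreement
of the study's headline behaviour, not clinical validity of the fitted
networks.

## Numerical choices and limitations

Hazard clipping at 1e−7; continuous inputs standardized by training-set
moments stored in the fitted model; L-BFGS convergence at ftol 1e−12 / gtol
1e−8 with a 500-iteration default cap (unregularized grid points routinely
hit the cap and are flagged, mirroring how such fits behave in practice);
PLANN extended has no early stopping — the epoch budget is part of the
frozen configuration. The C-index of PLANN extended under its IBS-tuned
ReLU configuration is noticeably more variable than PLANN original's; the
interval-averaged logit index is sensitive to saturated hazards in sparse
late intervals. Weight-singularity handling in the IPCW Brier (exclusion
with a warning) matters only at horizons beyond nearly all follow-up, which
the shipped 5-year horizon avoids.
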