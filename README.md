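# plannsim

Monte-Carlo comparison of **partial logistic artificial neural networks**
(PLANN original and PLANN extended) with **Cox proportional hazards models**
on synthetic clinical-trial survival data with right censoring.

## The problem

Whether machine-learning survival models outperform classical regression in a
*simple* clinical setting — a few hundred to a thousand patients, five
prognostic factors, substantial censoring — is an empirical question best
answered by simulation. This package generates synthetic datasets that mimic
a randomized osteosarcoma trial (four binary factors: treatment regimen, sex,
histological response, surgical margin; one continuous factor: age at
surgery), fits three competing survival models, and scores them with
censoring-aware discrimination and calibration metrics across censoring rates
(20/40/61/80%), sample sizes (250/1000) and adverse training-data scenarios.

It is aimed at biostatisticians who want a reproducible, fully seeded
simulation bench for discrete-time survival networks versus Cox models.

## Models and metrics

**Data generation.** Covariates are drawn from the 16 strata of the four
binary factors (with stratum-conditional normal age); survival times follow
a log-normal accelerated failure time model

    log T = μ + βᵀx + σε,   ε ~ N(0,1)

and censoring times follow a Weibull distribution whose (shape, scale) are
calibrated to realize a nominal censoring fraction.

**PLANN.** Follow-up is discretized into L intervals A_l = (τ_{l−1}, τ_l] and
each subject becomes one person-period row per interval at risk. A one-hidden-
layer network with a single logistic output estimates the discrete hazard
h_l = P(T ∈ A_l | T > τ_{l−1}); training minimizes the binary cross-entropy
−Σ_i Σ_{l≤l_i} [d_il log h_l + (1−d_il) log(1−h_l)], and survival follows as
S(t) = Π_{l: τ_l ≤ t} (1 − h_l).

* *PLANN original*: interval midpoint a_l as one time input, logistic hidden
  layer, full-batch quasi-Newton fit with weight decay (size/decay tuning).
* *PLANN extended*: L interval dummies as inputs, logistic/ReLU/tanh hidden
  layer, mini-batch SGD with momentum, inverted dropout, and a "weak class"
  weight (≥1) on the minority event rows.

**Cox baseline.** Main-effects Cox PH model by partial likelihood (Efron
ties), Breslow baseline cumulative hazard, Ŝ(t|x) = exp(−Λ̂₀(t) e^{xᵀβ̂}).

**Metrics** (all on held-out test halves): Harrell's C-index — for Cox on the
linear prognostic index xᵀβ̂, for PLANN on the interval-averaged hazard
log-odds (Σ_l logit h_l)/L; the IPCW Brier score at 0–5 years (inverse
probability of censoring weights from the reverse Kaplan-Meier estimator,
with left-limit evaluation Ĉ(t−)); the integrated Brier score over [0, 5]
years (step-function integration of the yearly error curve, normalized by
the horizon); and the 4-quantile-group miscalibration MSE at 2 and 5 years
(group Kaplan-Meier survival vs mean predicted survival).

## Worked example

Five Monte-Carlo replicates of the 61%-censoring scenario with n = 1000
subjects per dataset, using the shipped tuned hyperparameters:

```python
import plannsim as ps
from plannsim import experiment_harness as eh

scenario = eh.default_scenario("61-scenario1", n=1000, B=5, master_seed=7)
specs = eh.tuned_specs_from_config(ps.make_scheme("yearly"))
result = eh.run_experiment([scenario], tuned_specs=specs)
print(eh.summary_table(result.summary).to_markdown())
```

prints (mean over replicates, sd in parentheses):

```
| metric            | cox           | plann_extended | plann_original |
|:------------------|:--------------|:---------------|:---------------|
| brier_2y          | 0.143 (0.002) | 0.146 (0.002)  | 0.143 (0.003)  |
| brier_5y          | 0.229 (0.004) | 0.237 (0.005)  | 0.229 (0.005)  |
| cindex            | 0.638 (0.019) | 0.578 (0.054)  | 0.637 (0.019)  |
| ibs_5y            | 0.122 (0.002) | 0.125 (0.002)  | 0.122 (0.003)  |
| miscalibration_2y | 0.001 (0.001) | 0.002 (0.002)  | 0.001 (0.001)  |
| miscalibration_5y | 0.003 (0.002) | 0.004 (0.002)  | 0.003 (0.002)  |
```

Reading: at this censoring level the network and the Cox model discriminate
similarly (C ≈ 0.64 for Cox and PLANN original), prediction error to five
years is essentially tied (IBS ≈ 0.12), and the Cox model is at least as well
calibrated. The same pipeline is scriptable from the shell:

```bash
plannsim simulate --scenario 61-scenario1 --n 1000 --b 5 --seed 7 --out data/
plannsim tune --method plann_original --criterion ibs5 --scenario 61-scenario1
plannsim run --scenario 61-scenario1 --n 1000 --b 100 --seed 7 --out results/
plannsim report --results results/ --format md
```

## Layout

```
src/plannsim/
  trial_simulator.py     # covariates, AFT survival, Weibull censoring, splits
  person_period.py       # interval schemes, long-format expansion
  plann_models.py        # both networks: training, hazards, survival, PI
  cox_baseline.py        # Cox PH comparator (lifelines-backed)
  perf_metrics.py        # Harrell C, IPCW Brier, IBS, miscalibration
  experiment_harness.py  # CV tuning, Monte-Carlo replication, aggregation
  cli.py                 # simulate / tune / run / report
  data/default_config.yaml  # strata, calibrated coefficients, tuned specs
docs/methods.md          # modelling and design notes
```
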