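"""Study orchestration: cross-validated tuning and Monte-Carlo replication.

The study design: hyperparameters of each network are selected once per
censoring scenario by 5-fold cross-validated grid search on the training half
of a dedicated n=1000 dataset (the same folds for both networks), optimizing
either the integrated Brier score at 5 years or the C-index. The selected
configuration is then frozen, and B replicate datasets are simulated; each is
split 50/50 stratified on the event indicator, the adverse transform (if any)
is applied to the training half only, all three methods (Cox, PLANN original,
PLANN extended) are fit on the identical training half, and the metrics are
computed on the identical test half.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import cox_baseline, perf_metrics, plann_models
from .defaults import load_config
from .errors import DegenerateDataError, TuningError
from .person_period import IntervalScheme, make_scheme, to_long_train
from .trial_simulator import (
    ScenarioConfig,
    TrialDataset,
    apply_adverse_scenario,
    censoring_specs,
    replicate_rng,
    simulate_dataset,
    split_train_test,
)

METHODS = ("cox", "plann_original", "plann_extended")
BRIER_YEARS = (0, 1, 2, 3, 4, 5)
T_HOR = 5.0

# random-stream indices within a replicate (streams 0-2 are used by the
# simulator for covariates / survival / censoring)
STREAM_SPLIT = 3
STREAM_ORIGINAL = 4
STREAM_EXTENDED = 5
TUNING_REPLICATE = 2**20  # reserved replicate index for the tuning dataset


# ---------------------------------------------------------------------------
# Tuning
# ---------------------------------------------------------------------------

DEFAULT_GRID_ORIGINAL: dict[str, list] = {
    "hidden_size": [1, 2, 3, 4, 6, 8],
    "decay": [0.0, 0.01, 0.05, 0.1, 0.2],
}

DEFAULT_GRID_EXTENDED: dict[str, list] = {
    "nodesize": [2, 4, 8],
    "dropout_rate": [0.0, 0.1, 0.2],
    "learning_rate": [0.01, 0.05, 0.1],
    "momentum": [0.0, 0.5, 0.9],
    "class_weight": [1.0, 1.05],
    "hidden_activation": ["logistic", "relu", "tanh"],
}


@dataclass
class TuningGrid:
    """Cartesian hyperparameter grid plus the selection criterion."""

    method: str  # "plann_original" | "plann_extended"
    params: dict[str, list] = field(default_factory=dict)
    criterion: str = "ibs5"  # "ibs5" (minimize) | "cindex" (maximize)

    def __post_init__(self) -> None:
        if self.method not in ("plann_original", "plann_extended"):
            raise TuningError(f"unknown method {self.method!r}")
        if self.criterion not in ("ibs5", "cindex"):
            raise TuningError(f"unknown criterion {self.criterion!r}")
        if not self.params:
            self.params = dict(
                DEFAULT_GRID_ORIGINAL
                if self.method == "plann_original"
                else DEFAULT_GRID_EXTENDED
            )

    def points(self) -> list[dict[str, Any]]:
        keys = list(self.params)
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(self.params[k] for k in keys))
        ]


@dataclass
class TuningResult:
    method: str
    criterion: str
    best_params: dict[str, Any]
    best_cv_value: float
    cv_table: pd.DataFrame  # one row per grid point with the CV-mean criterion
    fold_assignment: np.ndarray  # fold label per training subject


def _complexity_key(method: str, params: dict[str, Any]) -> tuple:
    """Tie-break ordering: fewest hidden nodes, then strongest regularization."""
    if method == "plann_original":
        return (params["hidden_size"], -params["decay"])
    return (params["nodesize"], -params.get("dropout_rate", 0.0))


def make_folds(events: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k folds stratified on the event indicator; every subject appears once."""
    folds = np.empty(len(events), dtype=int)
    for value in (0, 1):
        idx = rng.permutation(np.flatnonzero(events == value))
        folds[idx] = np.arange(len(idx)) % k
    return folds


def _spec_for(method: str, params: dict[str, Any], scheme: IntervalScheme):
    if method == "plann_original":
        return plann_models.PlannOriginalSpec(scheme=scheme, **params)
    return plann_models.PlannExtendedSpec(scheme=scheme, **params)


def _fit_plann(method: str, spec, train: TrialDataset, rng: np.random.Generator):
    long = to_long_train(train, spec.scheme)
    if method == "plann_original":
        return plann_models.train_plann_original(long, spec, rng)
    return plann_models.train_plann_extended(long, spec, rng)


def _plann_criterion(model, test: TrialDataset, criterion: str) -> float:
    """Evaluate one fitted network on held-out subjects (lower is better)."""
    if criterion == "cindex":
        pi = plann_models.nonlinear_pi(model, test)
        return -perf_metrics.harrell_c(pi, test.times, test.events)
    hazards = plann_models.predict_hazards(model, test)
    curves = plann_models.survival_curve(hazards, model.scheme)
    grid = IBS_GRID
    briers = perf_metrics.brier_curve(grid, curves.grid(grid), test.times, test.events)
    return perf_metrics.ibs(grid, briers, T_HOR)


# The prediction-error curve is evaluated at the yearly horizons 0..5 and
# integrated as a step function (see perf_metrics.ibs).
IBS_GRID = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])


def cv_tune(
    method: str,
    grid: TuningGrid,
    scenario: ScenarioConfig,
    k: int = 5,
    tuning_n: int = 1000,
) -> TuningResult:
    """Grid search by k-fold cross-validation on one dedicated dataset.

    A single n=1000 dataset is simulated for the scenario's censoring spec
    (reserved replicate index, so it is disjoint from the study replicates)
    and only its training half is used. Ties on the CV criterion go to the
    least complex configuration.
    """
    ds = simulate_dataset(
        tuning_n, scenario.censoring, master_seed=scenario.master_seed,
        replicate=TUNING_REPLICATE, scenario=scenario.label,
    )
    train, _ = split_train_test(
        ds, replicate_rng(scenario.master_seed, TUNING_REPLICATE, STREAM_SPLIT)
    )
    folds = make_folds(
        train.events, k,
        replicate_rng(scenario.master_seed, TUNING_REPLICATE, STREAM_SPLIT + 100),
    )
    scheme = make_scheme("yearly")
    fit_stream = STREAM_ORIGINAL if method == "plann_original" else STREAM_EXTENDED

    rows = []
    for point_id, params in enumerate(grid.points()):
        values = []
        try:
            for fold in range(k):
                tr = TrialDataset(
                    train.data.iloc[folds != fold].reset_index(drop=True),
                    replicate_id=train.replicate_id, scenario=train.scenario,
                    split="train",
                )
                va = TrialDataset(
                    train.data.iloc[folds == fold].reset_index(drop=True),
                    replicate_id=train.replicate_id, scenario=train.scenario,
                    split="test",
                )
                rng = replicate_rng(
                    scenario.master_seed, TUNING_REPLICATE,
                    fit_stream + 10 * (fold + 1) + 1000 * point_id,
                )
                model = _fit_plann(method, _spec_for(method, params, scheme), tr, rng)
                values.append(_plann_criterion(model, va, grid.criterion))
        except Exception as exc:  # a failed grid point is recorded, not fatal
            warnings.warn(f"grid point {params} failed: {exc}", RuntimeWarning)
            rows.append({**params, "cv_value": np.nan})
            continue
        rows.append({**params, "cv_value": float(np.mean(values))})

    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["cv_value"])
    if ok.empty:
        raise TuningError("every grid point failed during cross-validation")
    # minimal cv_value (criteria are encoded so lower is better), ties -> least complex
    best_value = ok["cv_value"].min()
    tied = ok[ok["cv_value"] <= best_value + 1e-12]
    candidates = [
        {k_: r[k_] for k_ in grid.params} for _, r in tied.iterrows()
    ]
    best = min(candidates, key=lambda p: _complexity_key(method, p))
    # undo the sign flip used to make "higher C is better" a minimization
    reported = -best_value if grid.criterion == "cindex" else best_value
    if method == "plann_original":
        best = {"hidden_size": int(best["hidden_size"]), "decay": float(best["decay"])}
    return TuningResult(
        method=method,
        criterion=grid.criterion,
        best_params=best,
        best_cv_value=float(reported),
        cv_table=table,
        fold_assignment=folds,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo replication
# ---------------------------------------------------------------------------


def tuned_specs_from_config(
    scheme: IntervalScheme, config: dict | None = None, criterion: str = "ibs5"
) -> dict[str, Any]:
    """The frozen tuned hyperparameters shipped in (or loaded from) a config."""
    cfg = config or load_config()
    tuned = cfg["tuned_hyperparameters"]
    return {
        "plann_original": plann_models.PlannOriginalSpec(
            scheme=scheme, **tuned["plann_original"][criterion]
        ),
        "plann_extended": plann_models.PlannExtendedSpec(
            scheme=scheme, **tuned["plann_extended"][criterion]
        ),
    }


def evaluate_method(
    pi: np.ndarray,
    surv_at: dict[float, np.ndarray],
    ibs_value: float,
    test: TrialDataset,
) -> dict[str, float]:
    """All per-replicate metrics from a prognostic index and survival predictions."""
    out: dict[str, float] = {}
    out["cindex"] = perf_metrics.harrell_c(pi, test.times, test.events)
    cens = perf_metrics.censoring_km(test.times, test.events)
    for t0 in BRIER_YEARS:
        out[f"brier_{t0}y"] = perf_metrics.brier_ipcw(
            float(t0), surv_at[float(t0)], test.times, test.events, cens
        )
    out["ibs_5y"] = ibs_value
    for t0 in (2.0, 5.0):
        out[f"miscalibration_{t0:.0f}y"] = perf_metrics.miscalibration(
            t0, surv_at[t0], test.times, test.events
        )
    return out


def run_replicate(
    r: int,
    scenario: ScenarioConfig,
    tuned_specs: dict[str, Any],
    methods: Sequence[str] = METHODS,
    scheme: IntervalScheme | None = None,
) -> pd.DataFrame:
    """Simulate replicate r, fit every method on the shared training half,
    and return a tidy metric table evaluated on the shared test half."""
    scheme = scheme or make_scheme("yearly")
    ds = simulate_dataset(
        scenario.n, scenario.censoring, master_seed=scenario.master_seed,
        replicate=r, scenario=scenario.label,
    )
    train, test = split_train_test(
        ds, replicate_rng(scenario.master_seed, r, STREAM_SPLIT)
    )
    train = apply_adverse_scenario(train, scenario.adverse)
    if test.events.sum() < 2 or train.events.sum() < 2:
        raise DegenerateDataError(f"replicate {r} has too few events")

    grid = IBS_GRID
    horizons = sorted({float(t) for t in BRIER_YEARS} | {2.0, 5.0})
    rows = []
    for method in methods:
        if method == "cox":
            fit = cox_baseline.fit_cox(train)
            pi = cox_baseline.linear_pi(fit, test)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                surv_at = {
                    t0: cox_baseline.predict_survival(fit, test, t0) for t0 in horizons
                }
                surv_grid = np.column_stack(
                    [cox_baseline.predict_survival(fit, test, t0) for t0 in grid]
                )
        else:
            stream = STREAM_ORIGINAL if method == "plann_original" else STREAM_EXTENDED
            rng = replicate_rng(scenario.master_seed, r, stream)
            model = _fit_plann(method, tuned_specs[method], train, rng)
            hazards = plann_models.predict_hazards(model, test)
            curves = plann_models.survival_curve(hazards, model.scheme)
            h_clip = np.clip(hazards, plann_models.HAZARD_EPS, 1 - plann_models.HAZARD_EPS)
            pi = (np.log(h_clip) - np.log1p(-h_clip)).mean(axis=1)
            surv_at = {t0: curves.at(t0) for t0 in horizons}
            surv_grid = curves.grid(grid)
        briers = perf_metrics.brier_curve(grid, surv_grid, test.times, test.events)
        ibs_value = perf_metrics.ibs(grid, briers, T_HOR)
        metrics = evaluate_method(pi, surv_at, ibs_value, test)
        for name, value in metrics.items():
            rows.append(
                {
                    "scenario": scenario.label,
                    "method": method,
                    "replicate": r,
                    "metric": name,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ExperimentResult:
    report: pd.DataFrame  # tidy per-replicate metric rows
    summary: pd.DataFrame  # mean/sd per (scenario, method, metric)
    seed_ledger: pd.DataFrame  # replicate -> status (+ redraw bookkeeping)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.report.to_csv(out / "metrics.csv", index=False)
        self.summary.to_csv(out / "summary.csv", index=False)
        self.seed_ledger.to_csv(out / "seed_ledger.csv", index=False)


def run_experiment(
    scenarios: Sequence[ScenarioConfig],
    tuned_specs: dict[str, Any] | None = None,
    methods: Sequence[str] = METHODS,
    min_success_fraction: float = 0.8,
) -> ExperimentResult:
    """B replicates per scenario cell; degenerate replicates are redrawn
    (with logging) from indices past B. Aggregates mean and sd per metric."""
    scheme = make_scheme("yearly")
    tuned_specs = tuned_specs or tuned_specs_from_config(scheme)
    all_rows: list[pd.DataFrame] = []
    ledger_rows = []
    for scenario in scenarios:
        done, attempt, failures = 0, 0, 0
        while done < scenario.B:
            r = attempt
            attempt += 1
            try:
                all_rows.append(
                    run_replicate(r, scenario, tuned_specs, methods, scheme)
                )
                status = "ok"
                done += 1
            except DegenerateDataError as exc:
                status = f"skipped: {exc}"
                failures += 1
                if failures > scenario.B * (1 - min_success_fraction) + 10:
                    raise
            ledger_rows.append(
                {"scenario": scenario.label, "replicate": r, "status": status}
            )
    report = pd.concat(all_rows, ignore_index=True)
    summary = perf_metrics.aggregate_metrics(report)
    return ExperimentResult(
        report=report, summary=summary, seed_ledger=pd.DataFrame(ledger_rows)
    )


def default_scenario(
    label: str = "61-scenario1",
    n: int = 1000,
    B: int = 100,
    adverse: str = "none",
    master_seed: int = 0,
) -> ScenarioConfig:
    """A study cell using one of the shipped censoring specifications."""
    spec = censoring_specs()[label]
    return ScenarioConfig(n=n, B=B, censoring=spec, adverse=adverse,
                          master_seed=master_seed)


def summary_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Wide 'mean (sd)' layout: metrics as rows, methods as columns."""
    s = summary.copy()
    s["cell"] = s.apply(lambda r: f"{r['mean']:.3f} ({r['sd']:.3f})", axis=1)
    return s.pivot_table(
        index=["scenario", "metric"], columns="method", values="cell", aggfunc="first"
    )
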