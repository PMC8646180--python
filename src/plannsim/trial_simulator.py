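"""Synthetic osteosarcoma-trial data generator.

Emulates the covariate structure of the MRC BO06 / EORTC 80931 trial:

* 4 binary prognostic factors (treatment regimen, sex, histological response,
  surgical margin) whose 16 combinations occur with fixed proportions;
* age at surgery drawn from a stratum-specific normal distribution;
* overall-survival times from a log-normal accelerated failure time (AFT)
  model, ``log T = mu + beta' x + sigma * eps`` with standard-normal ``eps``;
* independent right-censoring times from a Weibull distribution whose shape
  and scale are chosen to realize a nominal censoring fraction
  (20/40/61/80 percent).

Two adverse training-data transforms are provided: dropping subjects censored
before two years, and administratively censoring all follow-up at five years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize

from .defaults import load_config
from .errors import CalibrationError, DegenerateDataError, InvalidArgumentError

BINARY_COVARIATES = ["treatment", "sex", "histology", "margin"]
COVARIATE_COLUMNS = BINARY_COVARIATES + ["age"]
DATASET_COLUMNS = ["id"] + COVARIATE_COLUMNS + ["time", "event"]

PROPORTION_TOLERANCE = 0.005  # printed stratum proportions are rounded to 2 dp


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StratumSpec:
    """One of the 16 combinations of the 4 binary prognostic factors.

    ``proportion`` is the fraction of subjects in the stratum; ``age_mean`` /
    ``age_sd`` parameterize the stratum-conditional normal distribution of age
    at surgery (years).
    """

    treatment: int  # 0 = regimen C, 1 = regimen DI
    sex: int  # 0 = female, 1 = male
    histology: int  # 0 = poor, 1 = good response
    margin: int  # 0 = unknown/incomplete, 1 = complete
    proportion: float
    age_mean: float
    age_sd: float

    def __post_init__(self) -> None:
        if self.proportion < 0:
            raise InvalidArgumentError("stratum proportion must be >= 0")
        if self.age_sd <= 0:
            raise InvalidArgumentError("stratum age_sd must be > 0")


@dataclass(frozen=True)
class AFTCoefficients:
    """Log-normal AFT model ``log T = intercept + betas' x + scale * eps``.

    ``betas`` acts on (treatment, sex, histology, margin, age), in that order,
    on the log survival-time scale: positive entries lengthen survival.
    """

    intercept: float
    betas: tuple[float, ...]
    scale: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "betas", tuple(float(b) for b in self.betas))
        if len(self.betas) != 5:
            raise InvalidArgumentError("betas must have exactly 5 entries")
        if self.scale <= 0:
            raise InvalidArgumentError("scale must be > 0")

    @property
    def beta_array(self) -> np.ndarray:
        return np.asarray(self.betas, dtype=float)


@dataclass(frozen=True)
class CensoringSpec:
    """Weibull censoring-time distribution targeting a nominal censoring rate."""

    shape: float
    scale: float
    nominal_censoring: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise InvalidArgumentError("Weibull shape and scale must be > 0")
        if not 0 < self.nominal_censoring < 1:
            raise InvalidArgumentError("nominal_censoring must be in (0, 1)")


ADVERSE_MODES = ("none", "drop_early_censored", "curtail_5y")


@dataclass
class ScenarioConfig:
    """One cell of the Monte-Carlo experiment matrix."""

    n: int
    B: int
    censoring: CensoringSpec
    adverse: str = "none"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 16:
            raise InvalidArgumentError("n must be >= 16")
        if self.B < 1:
            raise InvalidArgumentError("B must be >= 1")
        if self.adverse not in ADVERSE_MODES:
            raise InvalidArgumentError(f"unknown adverse mode {self.adverse!r}")

    @property
    def label(self) -> str:
        tag = self.censoring.label or f"{self.censoring.nominal_censoring:.0%}"
        return f"{tag}/n={self.n}/adverse={self.adverse}"


@dataclass
class TrialDataset:
    """Per-subject table: covariates, observed time (years), event indicator.

    ``latent_survival_time`` (the uncensored draw) is retained for oracle
    checks only and is never visible to any fitted model.
    """

    data: pd.DataFrame
    replicate_id: int = 0
    scenario: str = ""
    split: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.data.columns]
        if missing:
            raise InvalidArgumentError(f"dataset missing columns: {missing}")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data[COVARIATE_COLUMNS]

    @property
    def censoring_fraction(self) -> float:
        return 1.0 - float(self.data["event"].mean())

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out["split"] = self.split
        out["replicate"] = self.replicate_id
        out["scenario"] = self.scenario
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialDataset":
        df = pd.read_csv(path)
        split = str(df["split"].iloc[0]) if "split" in df else ""
        replicate = int(df["replicate"].iloc[0]) if "replicate" in df else 0
        scenario = str(df["scenario"].iloc[0]) if "scenario" in df else ""
        df = df.drop(columns=[c for c in ("split", "replicate", "scenario") if c in df])
        return cls(df, replicate_id=replicate, scenario=scenario, split=split)


# ---------------------------------------------------------------------------
# Packaged defaults
# ---------------------------------------------------------------------------


def default_strata(config: dict | None = None) -> list[StratumSpec]:
    """The 16 trial strata (proportions and per-stratum age moments)."""
    cfg = config or load_config()
    return [
        StratumSpec(int(t), int(s), int(h), int(m), p, mu, sd)
        for t, s, h, m, p, mu, sd in cfg["strata"]
    ]


def default_coefficients(config: dict | None = None) -> AFTCoefficients:
    """The calibrated default AFT coefficients (see the packaged config)."""
    cfg = config or load_config()
    c = cfg["aft_coefficients"]
    return AFTCoefficients(c["intercept"], tuple(c["betas"]), c["scale"])


def censoring_specs(config: dict | None = None) -> dict[str, CensoringSpec]:
    cfg = config or load_config()
    return {
        label: CensoringSpec(s["shape"], s["scale"], s["nominal_censoring"], label)
        for label, s in cfg["censoring_specs"].items()
    }


def expected_age(strata: Sequence[StratumSpec]) -> float:
    """Analytic mixture mean of age, sum_s p_s * mu_s (proportion-weighted)."""
    total = sum(s.proportion for s in strata)
    return sum(s.proportion * s.age_mean for s in strata) / total


def replicate_rng(master_seed: int, replicate: int, stream: int = 0) -> np.random.Generator:
    """Counter-based per-replicate generator.

    Seeding with the (master_seed, replicate, stream) triple makes every
    replicate (and every random stream within it) reproducible in isolation.
    """
    return np.random.default_rng(np.random.SeedSequence([master_seed, replicate, stream]))


# ---------------------------------------------------------------------------
# Simulation steps
# ---------------------------------------------------------------------------


def sample_covariates(
    n: int,
    strata: Sequence[StratumSpec],
    rng: np.random.Generator,
    age_floor: float = 0.0,
) -> pd.DataFrame:
    """Draw n subjects' covariates from the stratified mixture.

    Strata are drawn multinomially by proportion (renormalized); age is drawn
    from the subject's stratum-specific normal, redrawing values below
    ``age_floor``.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    props = np.array([s.proportion for s in strata], dtype=float)
    total = props.sum()
    if total <= 0:
        raise InvalidArgumentError("stratum proportions are all zero")
    if abs(total - 1.0) > PROPORTION_TOLERANCE * len(strata):
        raise InvalidArgumentError(
            f"stratum proportions sum to {total:.4f}, too far from 1"
        )
    props = props / total

    idx = rng.choice(len(strata), size=n, p=props)
    means = np.array([s.age_mean for s in strata])[idx]
    sds = np.array([s.age_sd for s in strata])[idx]
    age = rng.normal(means, sds)
    # redraw ages below the floor (negative ages are not meaningful)
    bad = age < age_floor
    while bad.any():
        age[bad] = rng.normal(means[bad], sds[bad])
        bad = age < age_floor

    binary = np.array(
        [[s.treatment, s.sex, s.histology, s.margin] for s in strata], dtype=int
    )[idx]
    df = pd.DataFrame(binary, columns=BINARY_COVARIATES)
    df["age"] = age
    return df


def simulate_survival_times(
    X: pd.DataFrame, coef: AFTCoefficients, rng: np.random.Generator
) -> np.ndarray:
    """Latent survival times T = exp(mu + beta' x + sigma * z), z ~ N(0,1)."""
    if isinstance(X, pd.DataFrame) and all(c in X.columns for c in COVARIATE_COLUMNS):
        X = X[COVARIATE_COLUMNS]
    Xm = np.asarray(X, dtype=float)
    if Xm.shape[1] != len(coef.betas):
        raise InvalidArgumentError(
            f"covariate width {Xm.shape[1]} != number of betas {len(coef.betas)}"
        )
    z = rng.standard_normal(Xm.shape[0])
    return np.exp(coef.intercept + Xm @ coef.beta_array + coef.scale * z)


def simulate_censoring(
    n: int, spec: CensoringSpec, rng: np.random.Generator
) -> np.ndarray:
    """n i.i.d. Weibull(shape, scale) censoring times."""
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    return spec.scale * rng.weibull(spec.shape, size=n)


def assemble_dataset(
    T: np.ndarray,
    C: np.ndarray,
    X: pd.DataFrame,
    replicate_id: int = 0,
    scenario: str = "",
) -> TrialDataset:
    """Observed data: time = min(T, C), event = 1{T <= C}."""
    T = np.asarray(T, dtype=float)
    C = np.asarray(C, dtype=float)
    if not (len(T) == len(C) == len(X)):
        raise InvalidArgumentError("T, C and X must have equal lengths")
    time = np.minimum(T, C)
    if np.any(time <= 0):
        raise RuntimeError("generator produced a nonpositive observed time")
    df = X.reset_index(drop=True).copy()
    df.insert(0, "id", np.arange(len(df)))
    df["time"] = time
    df["event"] = (T <= C).astype(int)
    df["latent_survival_time"] = T
    return TrialDataset(df, replicate_id=replicate_id, scenario=scenario)


def simulate_dataset(
    n: int,
    censoring: CensoringSpec,
    coef: AFTCoefficients | None = None,
    strata: Sequence[StratumSpec] | None = None,
    master_seed: int = 0,
    replicate: int = 0,
    scenario: str = "",
) -> TrialDataset:
    """Convenience: one full synthetic dataset, reproducible per replicate."""
    coef = coef or default_coefficients()
    strata = strata or default_strata()
    X = sample_covariates(n, strata, replicate_rng(master_seed, replicate, stream=0))
    T = simulate_survival_times(X, coef, replicate_rng(master_seed, replicate, stream=1))
    C = simulate_censoring(n, censoring, replicate_rng(master_seed, replicate, stream=2))
    return assemble_dataset(T, C, X, replicate_id=replicate,
                            scenario=scenario or censoring.label)


def apply_adverse_scenario(train: TrialDataset, mode: str) -> TrialDataset:
    """Adverse training-data transforms (training portion only).

    ``drop_early_censored`` removes subjects censored before 2 years;
    ``curtail_5y`` administratively censors all follow-up beyond 5 years;
    ``none`` is the identity.
    """
    if mode not in ADVERSE_MODES:
        raise InvalidArgumentError(f"unknown adverse mode {mode!r}")
    df = train.data.copy()
    if mode == "drop_early_censored":
        keep = ~((df["event"] == 0) & (df["time"] < 2.0))
        df = df.loc[keep].reset_index(drop=True)
    elif mode == "curtail_5y":
        over = df["time"] > 5.0
        df.loc[over, "time"] = 5.0
        df.loc[over, "event"] = 0
    if int(df["event"].sum()) == 0:
        raise DegenerateDataError("adverse transform left a training set with no events")
    return TrialDataset(df, replicate_id=train.replicate_id,
                        scenario=train.scenario, split=train.split)


def split_train_test(
    ds: TrialDataset, rng: np.random.Generator
) -> tuple[TrialDataset, TrialDataset]:
    """50/50 split stratified on the event indicator.

    Odd counts within an event stratum put the extra subject in the training
    half, so the event fractions of the halves differ by at most one subject.
    """
    events = ds.events
    if events.sum() < 2 or (events == 0).sum() < 2:
        raise DegenerateDataError("need >= 2 events and >= 2 censored subjects to split")
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for value in (1, 0):
        idx = np.flatnonzero(events == value)
        idx = rng.permutation(idx)
        k = math.ceil(len(idx) / 2)  # tie -> extra subject to the training half
        train_idx.append(idx[:k])
        test_idx.append(idx[k:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    make = lambda rows, tag: TrialDataset(
        ds.data.iloc[rows].reset_index(drop=True),
        replicate_id=ds.replicate_id, scenario=ds.scenario, split=tag,
    )
    return make(tr, "train"), make(te, "test")


# ---------------------------------------------------------------------------
# Coefficient calibration
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = hermegauss(60)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2.0 * np.pi)


def analytic_censoring_fraction(
    coef: AFTCoefficients,
    spec: CensoringSpec,
    strata: Sequence[StratumSpec],
) -> float:
    """P(T > C) under the generative model, by Gauss-Hermite quadrature.

    Within a stratum, log T is normal with mean
    ``mu + beta_bin' x + beta_age * age_mean`` and variance
    ``sigma^2 + (beta_age * age_sd)^2`` (age is itself normal), so the
    censoring probability integrates exactly over the 16-component mixture.
    """
    beta = coef.beta_array
    total_p = sum(s.proportion for s in strata)
    frac = 0.0
    for s in strata:
        lin = (
            coef.intercept
            + beta[0] * s.treatment
            + beta[1] * s.sex
            + beta[2] * s.histology
            + beta[3] * s.margin
            + beta[4] * s.age_mean
        )
        sd = math.sqrt(coef.scale**2 + (beta[4] * s.age_sd) ** 2)
        T = np.exp(lin + sd * _GH_NODES)
        p_cens = 1.0 - np.exp(-((T / spec.scale) ** spec.shape))
        frac += s.proportion / total_p * float(np.sum(_GH_WEIGHTS * p_cens))
    return frac


def realized_censoring_fraction(
    coef: AFTCoefficients,
    spec: CensoringSpec,
    strata: Sequence[StratumSpec] | None = None,
    n: int = 1000,
    replicates: int = 200,
    master_seed: int = 0,
) -> float:
    """Monte-Carlo mean censored fraction over replicated datasets."""
    strata = strata or default_strata()
    fracs = [
        simulate_dataset(n, spec, coef, strata, master_seed=master_seed,
                         replicate=r).censoring_fraction
        for r in range(replicates)
    ]
    return float(np.mean(fracs))


DEFAULT_BETAS = (0.05, -0.20, 0.80, 0.60, -0.025)


def calibrate_default_coefficients(
    strata: Sequence[StratumSpec] | None = None,
    censor_specs: Sequence[CensoringSpec] | None = None,
    betas: Sequence[float] = DEFAULT_BETAS,
    sigma: float | None = None,
    method: str = "joint",
    rng: np.random.Generator | None = None,
) -> AFTCoefficients:
    """Pin default AFT coefficients by calibrating against censoring targets.

    Relative effect sizes (``betas``) are fixed by configuration; only the
    intercept (and, for ``method='joint'``, the scale) are searched.

    * ``method='joint'``: least-squares fit of (mu, sigma) so every censoring
      spec realizes its nominal fraction (quadrature-based, deterministic).
    * ``method='bisect'``: fix sigma and root-find mu against the first
      spec's nominal fraction alone.

    When ``rng`` is supplied, the result is verified by simulation (200
    replicates of n=1000 against the first spec, tolerance +/- 0.01).
    """
    strata = list(strata or default_strata())
    if censor_specs is None:
        censor_specs = list(censoring_specs().values())
    censor_specs = list(censor_specs)
    if not censor_specs:
        raise InvalidArgumentError("need at least one censoring spec")
    betas = tuple(float(b) for b in betas)

    if method == "bisect":
        sig = 1.0 if sigma is None else float(sigma)
        spec = censor_specs[0]

        def gap(mu: float) -> float:
            c = AFTCoefficients(mu, betas, sig)
            return analytic_censoring_fraction(c, spec, strata) - spec.nominal_censoring

        lo, hi = -10.0, 10.0
        if gap(lo) * gap(hi) > 0:
            raise CalibrationError("bisection failed to bracket the censoring target")
        mu = optimize.brentq(gap, lo, hi, xtol=1e-10)
        coef = AFTCoefficients(mu, betas, sig)
    elif method == "joint":

        def objective(params: np.ndarray) -> float:
            c = AFTCoefficients(params[0], betas, math.exp(params[1]))
            return sum(
                (analytic_censoring_fraction(c, s, strata) - s.nominal_censoring) ** 2
                for s in censor_specs
            )

        x0 = np.array([1.5, math.log(sigma) if sigma else 0.0])
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options=dict(xatol=1e-9, fatol=1e-15, maxiter=4000),
        )
        if not res.success and res.fun > 1e-3:
            raise CalibrationError(f"joint calibration did not converge: {res.message}")
        coef = AFTCoefficients(res.x[0], betas, math.exp(res.x[1]))
    else:
        raise InvalidArgumentError(f"unknown calibration method {method!r}")

    if rng is not None:
        seed = int(rng.integers(2**31))
        realized = realized_censoring_fraction(
            coef, censor_specs[0], strata, master_seed=seed
        )
        if abs(realized - censor_specs[0].nominal_censoring) > 0.01:
            raise CalibrationError(
                f"simulated censoring {realized:.3f} misses target "
                f"{censor_specs[0].nominal_censoring:.2f} by more than 0.01"
            )
    return coef
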