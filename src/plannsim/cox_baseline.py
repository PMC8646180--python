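"""Cox proportional hazards comparator.

Main-effects Cox model (no interactions, no time-dependent terms) fitted by
partial likelihood — lifelines' ``CoxPHFitter`` (Efron tie handling) backs the
fit, with statsmodels ``PHReg`` available for Breslow ties. The baseline
cumulative hazard is the Breslow-type estimator computed at event times for
x = 0, so predicted survival is ``S(t0 | x) = exp(-Lambda0(t0) * exp(x'beta))``
and the linear prognostic index is ``PI = x'beta`` (higher = worse prognosis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .errors import DegenerateDataError, InvalidArgumentError
from .trial_simulator import COVARIATE_COLUMNS, TrialDataset


@dataclass
class CoxFit:
    """Fitted Cox model: coefficients and Breslow-type baseline."""

    betas: pd.Series  # indexed by covariate name; dropped columns get 0
    baseline_times: np.ndarray  # event times (sorted)
    baseline_cumhaz_values: np.ndarray  # Lambda0 at those times (x = 0)
    ties_method: str
    dropped_columns: list[str] = field(default_factory=list)
    converged: bool = True
    summary: pd.DataFrame | None = None

    def baseline_cumhaz(self, t) -> np.ndarray | float:
        """Right-continuous step evaluation of Lambda0; 0 before the first event.

        Times beyond the last event carry the last value forward (flagged).
        """
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if self.baseline_times.size and np.any(t_arr > self.baseline_times[-1]):
            warnings.warn(
                "baseline cumulative hazard extrapolated beyond the last event time "
                "(last value carried forward)",
                RuntimeWarning,
            )
        if not self.baseline_times.size:
            out = np.zeros_like(t_arr)
        else:
            idx = np.searchsorted(self.baseline_times, t_arr, side="right")
            padded = np.concatenate([[0.0], self.baseline_cumhaz_values])
            out = padded[idx]
        return float(out[0]) if np.isscalar(t) else out


def _breslow_baseline(
    times: np.ndarray, events: np.ndarray, pi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Breslow estimator of the baseline cumulative hazard at x = 0.

    Lambda0(t) = sum over event times u <= t of d_u / sum_{j: t_j >= u} exp(pi_j).
    """
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    risk = np.exp(pi[order])
    # risk-set totals: sum of exp(pi) over subjects with t_j >= u
    rev_cum = np.cumsum(risk[::-1])[::-1]
    event_times = np.unique(t_sorted[e_sorted == 1])
    increments = np.empty_like(event_times)
    for i, u in enumerate(event_times):
        d_u = np.sum((t_sorted == u) & (e_sorted == 1))
        at_risk = rev_cum[np.searchsorted(t_sorted, u, side="left")]
        increments[i] = d_u / at_risk
    return event_times, np.cumsum(increments)


def fit_cox(train: TrialDataset, ties: str = "efron") -> CoxFit:
    """Fit the main-effects Cox model on a training dataset.

    Zero-variance covariate columns are dropped (coefficient 0); with no
    informative covariates the baseline reduces to the Nelson-Aalen estimate.
    """
    if int(train.events.sum()) < 1:
        raise DegenerateDataError("Cox fit requires at least one event")
    df = train.data[COVARIATE_COLUMNS + ["time", "event"]].copy()
    variances = df[COVARIATE_COLUMNS].var(ddof=0)
    dropped = [c for c in COVARIATE_COLUMNS if variances[c] == 0]
    kept = [c for c in COVARIATE_COLUMNS if c not in dropped]

    betas = pd.Series(0.0, index=COVARIATE_COLUMNS)
    summary = None
    converged = True
    if kept:
        if ties == "efron":
            fitter = CoxPHFitter()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    fitter.fit(df[kept + ["time", "event"]],
                               duration_col="time", event_col="event")
                except Exception as exc:  # monotone likelihood etc.
                    warnings.warn(f"Cox fit flagged: {exc}", RuntimeWarning)
                    converged = False
                    fitter.fit(df[kept + ["time", "event"]],
                               duration_col="time", event_col="event",
                               fit_options={"step_size": 0.25})
            betas[kept] = fitter.params_.values
            summary = fitter.summary[["coef", "se(coef)", "exp(coef)"]].rename(
                columns={"se(coef)": "se", "exp(coef)": "hazard_ratio"}
            )
        elif ties == "breslow":
            from statsmodels.duration.hazard_regression import PHReg

            model = PHReg(df["time"], df[kept], status=df["event"], ties="breslow")
            res = model.fit()
            betas[kept] = res.params
            summary = pd.DataFrame(
                {"coef": res.params, "se": res.bse, "hazard_ratio": np.exp(res.params)},
                index=kept,
            )
        else:
            raise InvalidArgumentError(f"unknown ties method {ties!r}")

    pi = train.covariates.to_numpy(dtype=float) @ betas.to_numpy()
    bt, bch = _breslow_baseline(train.times, train.events, pi)
    return CoxFit(
        betas=betas,
        baseline_times=bt,
        baseline_cumhaz_values=bch,
        ties_method=ties,
        dropped_columns=dropped,
        converged=converged,
        summary=summary,
    )


def linear_pi(fit: CoxFit, ds: TrialDataset) -> np.ndarray:
    """Linear prognostic index x'beta per subject (higher = worse prognosis)."""
    return ds.covariates.to_numpy(dtype=float) @ fit.betas.to_numpy()


def predict_survival(fit: CoxFit, ds: TrialDataset, t0: float) -> np.ndarray:
    """S(t0 | x) = exp(-Lambda0(t0) * exp(x'beta)) per subject."""
    if t0 < 0:
        raise InvalidArgumentError("t0 must be >= 0")
    lam0 = fit.baseline_cumhaz(float(t0))
    return np.exp(-lam0 * np.exp(linear_pi(fit, ds)))
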