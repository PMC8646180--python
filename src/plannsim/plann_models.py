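"""Partial logistic artificial neural networks (PLANN) for discrete hazards.

Both networks are single-hidden-layer feed-forward models on person-period
data whose single logistic output estimates the discrete conditional hazard
``h_l = P(T in A_l | T > tau_{l-1})`` of one subject-interval row:

* **PLANN original** takes the interval midpoint ``a_l`` as one (standardized)
  time input next to the 5 covariates, uses a logistic hidden layer, and is
  fit by full-batch quasi-Newton minimization of the cross-entropy error with
  a weight-decay penalty — the classic (size, decay) parameterization.
* **PLANN extended** one-hot encodes the L intervals as L separate binary
  inputs, allows a logistic / ReLU / tanh hidden layer, and is fit by
  mini-batch gradient descent with momentum, inverted dropout on the hidden
  layer, and an optional "weak class" weight that up-weights event rows
  (the minority class in the long table). The output activation is always
  the logistic.

Training minimizes the discrete-hazard likelihood, which on person-period
rows is exactly the binary cross-entropy
``-sum_i sum_{l<=l_i} [d_il log h_l + (1 - d_il) log(1 - h_l)]``; with no
hidden layer this reduces to a linear logistic regression (used as a testing
hook against an IRLS oracle).

Survival follows from the hazards as ``S(t) = prod_{l: tau_l <= t}(1 - h_l)``,
and a subject-level nonlinear prognostic index is the interval-average of the
hazard log-odds ``theta_l = logit(h_l)`` (higher index = worse prognosis).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import InvalidArgumentError
from .person_period import IntervalScheme, LongTable, make_scheme, to_long_test
from .trial_simulator import COVARIATE_COLUMNS, TrialDataset

HAZARD_EPS = 1e-7  # clipping for logs/logits (numerical stability)

ACTIVATIONS = ("logistic", "relu", "tanh")


def _yearly() -> IntervalScheme:
    return make_scheme("yearly")


@dataclass
class PlannOriginalSpec:
    """(size, decay)-style network: midpoint time input, logistic hidden layer.

    ``hidden_size = 0`` is a degenerate testing hook: the network collapses to
    a plain logistic regression on the inputs.
    """

    hidden_size: int = 2
    decay: float = 0.1
    max_iterations: int = 500
    init_range: float = 0.5
    scheme: IntervalScheme = field(default_factory=_yearly)

    def __post_init__(self) -> None:
        if self.hidden_size < 0:
            raise InvalidArgumentError("hidden_size must be >= 0")
        if self.decay < 0:
            raise InvalidArgumentError("decay must be >= 0")


@dataclass
class PlannExtendedSpec:
    """Extended network: L interval dummies, selectable hidden activation,
    momentum SGD with inverted dropout and event-row class weighting."""

    nodesize: int = 4
    dropout_rate: float = 0.1
    learning_rate: float = 0.05
    momentum: float = 0.9
    class_weight: float = 1.05
    hidden_activation: str = "tanh"
    epochs: int = 150
    batch_size: int = 64
    scheme: IntervalScheme = field(default_factory=_yearly)

    def __post_init__(self) -> None:
        if self.nodesize < 1:
            raise InvalidArgumentError("nodesize must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise InvalidArgumentError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise InvalidArgumentError("learning_rate must be > 0")
        if not 0 <= self.momentum < 1:
            raise InvalidArgumentError("momentum must be in [0, 1)")
        if self.class_weight < 1:
            raise InvalidArgumentError("class_weight must be >= 1")
        if self.hidden_activation not in ACTIVATIONS:
            raise InvalidArgumentError(
                f"hidden_activation must be one of {ACTIVATIONS}"
            )


@dataclass
class NetworkWeights:
    """Two-layer weights; ``direct`` replaces the hidden layer when H = 0."""

    W1: np.ndarray  # (J, H) input -> hidden
    b1: np.ndarray  # (H,)   hidden biases
    w2: np.ndarray  # (H,)   hidden -> output
    b2: float  # output bias
    direct: np.ndarray | None = None  # (J,) input -> output, H = 0 only

    @property
    def hidden_size(self) -> int:
        return self.W1.shape[1]

    @property
    def input_size(self) -> int:
        return self.W1.shape[0] if self.direct is None else len(self.direct)


# ---------------------------------------------------------------------------
# Forward pass, loss, gradients
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _hidden(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "logistic":
        return _sigmoid(z)
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "tanh":
        return np.tanh(z)
    raise InvalidArgumentError(f"unknown activation {activation!r}")


def _hidden_grad(z: np.ndarray, a: np.ndarray, activation: str) -> np.ndarray:
    if activation == "logistic":
        return a * (1.0 - a)
    if activation == "relu":
        return (z > 0).astype(float)
    if activation == "tanh":
        return 1.0 - a * a
    raise InvalidArgumentError(f"unknown activation {activation!r}")


def forward(
    weights: NetworkWeights, features: np.ndarray, hidden_activation: str = "logistic"
) -> np.ndarray:
    """Per-row hazard: logistic output of the two-layer (or direct) network."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != weights.input_size:
        raise InvalidArgumentError(
            f"feature width {X.shape[1]} != network input width {weights.input_size}"
        )
    if weights.direct is not None:
        eta = X @ weights.direct + weights.b2
    else:
        if not (
            np.all(np.isfinite(weights.W1))
            and np.all(np.isfinite(weights.w2))
            and np.isfinite(weights.b2)
        ):
            raise FloatingPointError("non-finite network weights")
        a = _hidden(X @ weights.W1 + weights.b1, hidden_activation)
        eta = a @ weights.w2 + weights.b2
    return _sigmoid(eta)


def loss(
    predictions: np.ndarray,
    targets: np.ndarray,
    row_weights: np.ndarray | None = None,
    clip_eps: float = HAZARD_EPS,
) -> float:
    """Weighted binary cross-entropy summed over person-period rows.

    Predictions at 0 or 1 exactly are clipped to ``clip_eps`` (with a
    warning); row weights implement the weak-class weight.
    """
    h = np.asarray(predictions, dtype=float)
    d = np.asarray(targets, dtype=float)
    if np.any((h <= 0) | (h >= 1)):
        warnings.warn("predictions at the (0,1) boundary were clipped", RuntimeWarning)
    h = np.clip(h, clip_eps, 1.0 - clip_eps)
    w = np.ones_like(h) if row_weights is None else np.asarray(row_weights, dtype=float)
    return float(-np.sum(w * (d * np.log(h) + (1.0 - d) * np.log1p(-h))))


def _pack(weights: NetworkWeights) -> np.ndarray:
    if weights.direct is not None:
        return np.concatenate([weights.direct, [weights.b2]])
    return np.concatenate(
        [weights.W1.ravel(), weights.b1, weights.w2, [weights.b2]]
    )


def _unpack(theta: np.ndarray, J: int, H: int) -> NetworkWeights:
    if H == 0:
        return NetworkWeights(
            W1=np.zeros((J, 0)), b1=np.zeros(0), w2=np.zeros(0),
            b2=float(theta[J]), direct=theta[:J].copy(),
        )
    W1 = theta[: J * H].reshape(J, H)
    b1 = theta[J * H : J * H + H]
    w2 = theta[J * H + H : J * H + 2 * H]
    return NetworkWeights(W1=W1.copy(), b1=b1.copy(), w2=w2.copy(), b2=float(theta[-1]))


def _loss_and_grad(
    theta: np.ndarray,
    X: np.ndarray,
    d: np.ndarray,
    row_weights: np.ndarray,
    J: int,
    H: int,
    activation: str,
    decay: float = 0.0,
    normalize: bool = False,
    dropout_mask: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Cross-entropy (+ optional decay penalty) and its analytic gradient.

    ``normalize`` divides by the number of rows (mini-batch mean loss);
    ``dropout_mask`` is an inverted-dropout multiplier on hidden activations.
    """
    n = X.shape[0]
    scale = 1.0 / n if normalize else 1.0
    if H == 0:
        v, b2 = theta[:J], theta[J]
        eta = X @ v + b2
        a_raw = z = None
    else:
        W1 = theta[: J * H].reshape(J, H)
        b1 = theta[J * H : J * H + H]
        w2 = theta[J * H + H : J * H + 2 * H]
        b2 = theta[-1]
        z = X @ W1 + b1
        a_raw = _hidden(z, activation)
        a = a_raw if dropout_mask is None else a_raw * dropout_mask
        eta = a @ w2 + b2
    h = _sigmoid(eta)
    hc = np.clip(h, HAZARD_EPS, 1.0 - HAZARD_EPS)
    value = -np.sum(row_weights * (d * np.log(hc) + (1.0 - d) * np.log1p(-hc)))
    deta = row_weights * (h - d)  # exact for unclipped sigmoid + cross-entropy
    if H == 0:
        grad = np.concatenate([X.T @ deta, [deta.sum()]])
    else:
        gw2 = a.T @ deta
        gb2 = deta.sum()
        da = deta[:, None] * w2[None, :]
        if dropout_mask is not None:
            da = da * dropout_mask
        dz = da * _hidden_grad(z, a_raw, activation)
        grad = np.concatenate([(X.T @ dz).ravel(), dz.sum(axis=0), gw2, [gb2]])
    value *= scale
    grad *= scale
    if decay:
        value += decay * float(theta @ theta)
        grad = grad + 2.0 * decay * theta
    return value, grad


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------


def _standardize(
    df: pd.DataFrame, continuous: list[str], scaler: dict | None
) -> tuple[pd.DataFrame, dict]:
    df = df.copy()
    if scaler is None:
        scaler = {}
        for col in continuous:
            sd = float(df[col].std(ddof=0))
            scaler[col] = (float(df[col].mean()), sd if sd > 0 else 1.0)
    for col, (mean, sd) in scaler.items():
        df[col] = (df[col] - mean) / sd
    return df, scaler


def build_features(
    long_df: pd.DataFrame,
    kind: str,
    scheme: IntervalScheme,
    scaler: dict | None = None,
) -> tuple[np.ndarray, dict]:
    """Design matrix for a network from person-period rows.

    original: [midpoint, 5 covariates], midpoint and age standardized;
    extended: [L interval dummies, 5 covariates], age standardized.
    Binary inputs are passed through as 0/1.
    """
    if kind == "original":
        df, scaler = _standardize(long_df, ["midpoint", "age"], scaler)
        X = df[["midpoint"] + COVARIATE_COLUMNS].to_numpy(dtype=float)
    elif kind == "extended":
        df, scaler = _standardize(long_df, ["age"], scaler)
        dummies = np.eye(scheme.L)[df["interval"].to_numpy(dtype=int) - 1]
        X = np.hstack([dummies, df[COVARIATE_COLUMNS].to_numpy(dtype=float)])
    else:
        raise InvalidArgumentError(f"unknown model kind {kind!r}")
    return X, scaler


# ---------------------------------------------------------------------------
# Fitted model container
# ---------------------------------------------------------------------------


@dataclass
class PlannModel:
    """A fitted network: weights + input scaler + interval scheme."""

    kind: str  # "original" | "extended"
    weights: NetworkWeights
    scheme: IntervalScheme
    scaler: dict
    hidden_activation: str
    converged: bool = True
    n_iter: int = 0
    final_loss: float = float("nan")
    loss_history: list[float] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        w = self.weights
        state = {
            "kind": self.kind,
            "hidden_activation": self.hidden_activation,
            "scheme_kind": self.scheme.kind,
            "scaler": {k: list(v) for k, v in self.scaler.items()},
            "weights": {
                "W1": w.W1.tolist(),
                "b1": w.b1.tolist(),
                "w2": w.w2.tolist(),
                "b2": w.b2,
                "direct": None if w.direct is None else w.direct.tolist(),
            },
            "converged": self.converged,
            "n_iter": self.n_iter,
            "final_loss": self.final_loss,
        }
        Path(path).write_text(json.dumps(state))

    @classmethod
    def load(cls, path: str | Path) -> "PlannModel":
        state = json.loads(Path(path).read_text())
        ws = state["weights"]
        W1 = np.asarray(ws["W1"], dtype=float)
        if W1.ndim != 2:  # (J, 0) round-trips through JSON as J empty lists
            W1 = W1.reshape(len(ws["W1"]), 0)
        weights = NetworkWeights(
            W1=W1,
            b1=np.asarray(ws["b1"], dtype=float),
            w2=np.asarray(ws["w2"], dtype=float),
            b2=float(ws["b2"]),
            direct=None if ws["direct"] is None else np.asarray(ws["direct"], dtype=float),
        )
        return cls(
            kind=state["kind"],
            weights=weights,
            scheme=make_scheme(state["scheme_kind"]),
            scaler={k: tuple(v) for k, v in state["scaler"].items()},
            hidden_activation=state["hidden_activation"],
            converged=state["converged"],
            n_iter=state["n_iter"],
            final_loss=state["final_loss"],
        )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _check_train_table(long: LongTable) -> None:
    if long.role != "train":
        raise InvalidArgumentError("training requires a train-expansion LongTable")
    if int(long.data["d_target"].sum()) < 1:
        raise InvalidArgumentError("training table has no event rows")


def train_plann_original(
    long: LongTable, spec: PlannOriginalSpec, rng: np.random.Generator
) -> PlannModel:
    """Full-batch quasi-Newton (L-BFGS) fit of the penalized cross-entropy.

    Weight decay multiplies the squared norm of all weights and biases.
    Initialization is uniform in +/- init_range, drawn from ``rng``.
    """
    _check_train_table(long)
    X, scaler = build_features(long.data, "original", spec.scheme)
    d = long.data["d_target"].to_numpy(dtype=float)
    J, H = X.shape[1], spec.hidden_size
    n_params = (J + 1) if H == 0 else (J * H + 2 * H + 1)
    theta0 = rng.uniform(-spec.init_range, spec.init_range, size=n_params)
    ones = np.ones_like(d)

    history: list[float] = []

    def fun(theta: np.ndarray) -> tuple[float, np.ndarray]:
        return _loss_and_grad(theta, X, d, ones, J, H, "logistic", decay=spec.decay)

    def record(theta: np.ndarray) -> None:
        history.append(fun(theta)[0])

    res = optimize.minimize(
        fun, theta0, jac=True, method="L-BFGS-B", callback=record,
        options={"maxiter": spec.max_iterations, "ftol": 1e-12, "gtol": 1e-8},
    )
    converged = bool(res.success)
    if not converged:
        warnings.warn(
            f"PLANN original did not converge in {spec.max_iterations} iterations "
            f"({res.message}); returning best-so-far weights",
            RuntimeWarning,
        )
    return PlannModel(
        kind="original",
        weights=_unpack(res.x, J, H),
        scheme=spec.scheme,
        scaler=scaler,
        hidden_activation="logistic",
        converged=converged,
        n_iter=int(res.nit),
        final_loss=float(res.fun),
        loss_history=history,
    )


def train_plann_extended(
    long: LongTable, spec: PlannExtendedSpec, rng: np.random.Generator
) -> PlannModel:
    """Mini-batch SGD with momentum and inverted dropout on the hidden layer.

    The per-batch objective is the mean weighted cross-entropy (event rows
    weighted by ``class_weight``). Dropout is applied during training only;
    weights are Glorot-initialized from ``rng``.
    """
    _check_train_table(long)
    X, scaler = build_features(long.data, "extended", spec.scheme)
    d = long.data["d_target"].to_numpy(dtype=float)
    row_w = np.where(d == 1, spec.class_weight, 1.0)
    n, J = X.shape
    H = spec.nodesize

    lim1 = np.sqrt(6.0 / (J + H))
    lim2 = np.sqrt(6.0 / (H + 1))
    theta = np.concatenate(
        [
            rng.uniform(-lim1, lim1, size=J * H),
            np.zeros(H),
            rng.uniform(-lim2, lim2, size=H),
            [0.0],
        ]
    )
    velocity = np.zeros_like(theta)
    keep = 1.0 - spec.dropout_rate
    batch = min(spec.batch_size, n)
    history: list[float] = []

    for _ in range(spec.epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            rows = order[start : start + batch]
            mask = None
            if spec.dropout_rate > 0:
                mask = (rng.random((len(rows), H)) < keep) / keep
            _, grad = _loss_and_grad(
                theta, X[rows], d[rows], row_w[rows], J, H,
                spec.hidden_activation, normalize=True, dropout_mask=mask,
            )
            velocity = spec.momentum * velocity - spec.learning_rate * grad
            theta = theta + velocity
        epoch_loss, _ = _loss_and_grad(
            theta, X, d, row_w, J, H, spec.hidden_activation, normalize=True
        )
        history.append(float(epoch_loss))

    return PlannModel(
        kind="extended",
        weights=_unpack(theta, J, H),
        scheme=spec.scheme,
        scaler=scaler,
        hidden_activation=spec.hidden_activation,
        converged=True,
        n_iter=spec.epochs,
        final_loss=history[-1] if history else float("nan"),
        loss_history=history,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict_hazards(model: PlannModel, ds: TrialDataset) -> np.ndarray:
    """(n, L) matrix of interval hazards via the full test expansion."""
    long = to_long_test(ds, model.scheme)
    X, _ = build_features(long.data, model.kind, model.scheme, scaler=model.scaler)
    h = forward(model.weights, X, model.hidden_activation)
    h = np.clip(h, HAZARD_EPS, 1.0 - HAZARD_EPS)
    return h.reshape(ds.n, model.scheme.L)


class SurvivalCurves:
    """Step survival functions S(t) = prod_{l: tau_l <= t} (1 - h_l)."""

    def __init__(self, hazards: np.ndarray, scheme: IntervalScheme):
        hazards = np.asarray(hazards, dtype=float)
        if np.any((hazards <= 0) | (hazards >= 1)):
            raise InvalidArgumentError("hazards must lie strictly inside (0, 1)")
        self.scheme = scheme
        # running product over closed intervals only; the open last interval
        # has no finite upper boundary and never completes before any t0
        self._cumprod = np.cumprod(1.0 - hazards[:, : scheme.L - 1], axis=1)

    def at(self, t0: float) -> np.ndarray:
        """Per-subject survival just after t0 (S = 1 before the first boundary)."""
        if t0 < 0:
            raise InvalidArgumentError("t0 must be >= 0")
        k = int(np.searchsorted(self.scheme.upper_bounds, t0, side="right"))
        if k == 0:
            return np.ones(self._cumprod.shape[0])
        return self._cumprod[:, k - 1].copy()

    def grid(self, times: np.ndarray) -> np.ndarray:
        """(n, len(times)) survival matrix."""
        times = np.asarray(times, dtype=float)
        k = np.searchsorted(self.scheme.upper_bounds, times, side="right")
        padded = np.hstack([np.ones((self._cumprod.shape[0], 1)), self._cumprod])
        return padded[:, k]


def survival_curve(hazards: np.ndarray, scheme: IntervalScheme) -> SurvivalCurves:
    return SurvivalCurves(hazards, scheme)


def nonlinear_pi(model: PlannModel, ds: TrialDataset) -> np.ndarray:
    """Interval-averaged hazard log-odds, one score per subject.

    Higher values mean larger predicted hazards, i.e. shorter predicted
    survival (opposite ranking, matching the Cox linear prognostic index).
    """
    h = predict_hazards(model, ds)
    theta = np.log(h) - np.log1p(-h)
    return theta.mean(axis=1)
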