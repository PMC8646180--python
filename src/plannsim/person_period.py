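"""Discretization of follow-up and person-period (long-format) expansion.

Both survival networks operate on discrete time: follow-up is cut into L
non-overlapping intervals ``A_l = (tau_{l-1}, tau_l]`` (the last interval is
open-ended), and each subject becomes one row per interval. On training data a
subject contributes one row per interval observed, with a binary target that
is 1 only in the interval containing an event; on test data every subject is
expanded to all L intervals so the network can emit a full hazard profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .trial_simulator import COVARIATE_COLUMNS, TrialDataset

SCHEME_KINDS = {"yearly": 1.0, "six_month": 0.5, "three_month": 0.25}


@dataclass(frozen=True)
class IntervalScheme:
    """L intervals (tau_{l-1}, tau_l], last open-ended, with midpoints a_l."""

    kind: str
    boundaries: tuple[float, ...]  # tau_0 = 0 < tau_1 < ... < tau_{L-1}
    midpoints: tuple[float, ...]  # length L; open interval: last boundary + w/2

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries)
        m = np.asarray(self.midpoints)
        if b[0] != 0 or np.any(np.diff(b) <= 0):
            raise InvalidArgumentError("boundaries must start at 0 and strictly increase")
        if np.any(np.diff(m) <= 0) or len(m) != len(b):
            raise InvalidArgumentError("need L strictly increasing midpoints")

    @property
    def L(self) -> int:
        return len(self.midpoints)

    @property
    def upper_bounds(self) -> np.ndarray:
        """Finite upper boundaries tau_1..tau_{L-1} of the closed intervals."""
        return np.asarray(self.boundaries[1:], dtype=float)


def make_scheme(kind: str) -> IntervalScheme:
    """Shipped schemes: yearly (L=8), six_month (L=16), three_month (L=32).

    All three cover 8 years of follow-up; the last interval is open and its
    midpoint sits half an interval-width past the last boundary.
    """
    if kind not in SCHEME_KINDS:
        raise InvalidArgumentError(
            f"unknown scheme kind {kind!r}; expected one of {sorted(SCHEME_KINDS)}"
        )
    width = SCHEME_KINDS[kind]
    L = int(round(8.0 / width))
    boundaries = tuple(width * i for i in range(L))
    midpoints = tuple(width * i + width / 2.0 for i in range(L))
    return IntervalScheme(kind=kind, boundaries=boundaries, midpoints=midpoints)


def interval_of(t, scheme: IntervalScheme):
    """1-based interval index: smallest l with t <= tau_l; beyond -> L.

    Intervals are left-open/right-closed, so an exact boundary time belongs to
    the earlier interval. Accepts a scalar or an array.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr <= 0):
        raise InvalidArgumentError("times must be > 0")
    idx = np.searchsorted(scheme.upper_bounds, arr, side="left") + 1
    idx = np.minimum(idx, scheme.L)
    return int(idx) if np.isscalar(t) else idx


@dataclass
class LongTable:
    """Person-period rows: (id, interval, midpoint, covariates[, d_target])."""

    data: pd.DataFrame
    role: str  # "train" (per-interval-observed) or "test" (full expansion)
    scheme: IntervalScheme

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _expand(ds: TrialDataset, counts: np.ndarray, scheme: IntervalScheme) -> pd.DataFrame:
    """Repeat subject i counts[i] times with interval indices 1..counts[i]."""
    rows = np.repeat(np.arange(ds.n), counts)
    intervals = np.concatenate([np.arange(1, c + 1) for c in counts])
    df = ds.data.iloc[rows][["id"] + COVARIATE_COLUMNS].reset_index(drop=True)
    df.insert(1, "interval", intervals)
    df.insert(2, "midpoint", np.asarray(scheme.midpoints)[intervals - 1])
    return df


def to_long_train(
    ds: TrialDataset,
    scheme: IntervalScheme,
    include_censored_interval: bool = True,
) -> LongTable:
    """Training expansion: subject i contributes intervals 1..l_i.

    l_i is the interval containing the observed time; the target d_il is the
    event indicator in interval l_i and 0 before. By default a censoring time
    falling inside interval l contributes that interval with target 0 (the
    subject was at risk there); set ``include_censored_interval=False`` to
    drop the partial final interval of censored subjects instead (sensitivity
    analysis).
    """
    if ds.n == 0:
        raise InvalidArgumentError("dataset is empty")
    last = interval_of(ds.times, scheme)
    events = ds.events
    counts = last.copy()
    if not include_censored_interval:
        counts = np.where(events == 0, counts - 1, counts)
    df = _expand(ds, counts, scheme)
    # the target is 1 only in the final observed interval of an event subject
    ends = np.cumsum(counts)
    d = np.zeros(int(counts.sum()), dtype=int)
    event_rows = ends[events == 1] - 1
    d[event_rows] = 1
    df["d_target"] = d
    return LongTable(df, role="train", scheme=scheme)


def to_long_test(ds: TrialDataset, scheme: IntervalScheme) -> LongTable:
    """Full expansion: every subject repeated for all L intervals.

    Row order is subject-major, interval-minor, and stable across calls.
    """
    if ds.n == 0:
        raise InvalidArgumentError("dataset is empty")
    counts = np.full(ds.n, scheme.L, dtype=int)
    return LongTable(_expand(ds, counts, scheme), role="test", scheme=scheme)
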