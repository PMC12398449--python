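"""Lagged-exposure matrix and the unified 0/1 lag-weighting framework.

Three lag structures are expressed as inclusion weights ``W_l`` over lags
``0..max_lag``:

* scenario 1 (independent lag effects): one-hot at the target lag — one
  single-lag model per target;
* scenario 2 (joint / unconstrained distributed lag): all ones — every lag
  enters one model simultaneously;
* scenario 3 (stepwise cumulative): ones up to and including the target lag —
  one model per target, reporting the target lag's coefficient.

The weight interface accepts arbitrary non-negative vectors so that other
weighting schemes remain expressible; the three scenarios above only ever
produce 0/1 weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LagMatrix",
    "ScenarioSpec",
    "build_lag_matrix",
    "scenario_weights",
    "select_exposure_columns",
]


@dataclass(frozen=True)
class LagMatrix:
    """Exposure at lags 0..max_lag: ``values[t, l] = exposure[t - l]``.

    Entries whose source day falls before the series start (or is missing)
    are NaN; ``valid_mask`` flags rows where *all* lags are available.
    Per-model row eligibility is decided later from the selected lags only.
    """

    values: np.ndarray
    max_lag: int

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values).all(axis=1)

    def rows_valid_for(self, lag_indices) -> np.ndarray:
        """Rows where every lag in ``lag_indices`` is available."""
        return np.isfinite(self.values[:, list(lag_indices)]).all(axis=1)


@dataclass(frozen=True)
class ScenarioSpec:
    """A lag structure instance: scenario id, target, and derived weights."""

    scenario: int
    target_lag: int
    max_lag: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.shape != (self.max_lag + 1,):
            raise ValueError("weights must have length max_lag + 1")
        if not (w >= 0).all() or not (w > 0).any():
            raise ValueError("weights must be non-negative with at least one positive")


def build_lag_matrix(pm10, max_lag: int = 21) -> LagMatrix:
    """Stack the exposure series at lags 0..max_lag (column l = lag l)."""
    x = np.asarray(pm10, dtype=float)
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    n = len(x)
    if n <= max_lag:
        raise ValueError(f"series of length {n} too short for max_lag={max_lag}")
    values = np.full((n, max_lag + 1), np.nan)
    for l in range(max_lag + 1):
        values[l:, l] = x[: n - l]
    return LagMatrix(values, max_lag)


def scenario_weights(scenario: int, target_lag: int, max_lag: int = 21) -> np.ndarray:
    """0/1 inclusion weights for the given scenario and target lag."""
    if not 0 <= target_lag <= max_lag:
        raise ValueError(f"target_lag {target_lag} outside [0, {max_lag}]")
    w = np.zeros(max_lag + 1)
    if scenario == 1:
        w[target_lag] = 1.0
    elif scenario == 2:
        w[:] = 1.0
    elif scenario == 3:
        w[: target_lag + 1] = 1.0
    else:
        raise ValueError(f"scenario must be 1, 2 or 3, got {scenario}")
    return w


def select_exposure_columns(lags: LagMatrix, weights) -> tuple[np.ndarray, list[int]]:
    """Exposure design block for the given weights.

    Returns ``(block, lag_of_column)``: one column per positive weight, in
    ascending lag order, scaled by its weight (0/1 weights select columns
    unchanged).  Each column enters the model with its own coefficient.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (lags.max_lag + 1,):
        raise ValueError(
            f"weights length {w.shape} does not match max_lag={lags.max_lag}"
        )
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    sel = np.flatnonzero(w > 0)
    if sel.size == 0:
        raise ValueError("all-zero weight vector selects no exposure columns")
    block = lags.values[:, sel] * w[sel]
    return block, [int(l) for l in sel]
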