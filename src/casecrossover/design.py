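"""Confounder design: trailing moving averages and natural cubic spline bases.

The mortality model adjusts for weather by entering the trailing multi-day
moving averages of temperature and relative humidity through natural cubic
spline bases (cubic splines constrained to be linear beyond their boundary
knots).  Only the spanned function space matters downstream — the fit is
invariant to the basis parameterization — so the basis here uses the
classical truncated-power natural-spline construction with interior knots at
equally spaced quantiles and boundary knots at the data range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DailySeries

__all__ = [
    "BasisMatrix",
    "ConfounderDesign",
    "RankError",
    "trailing_moving_average",
    "natural_cubic_basis",
    "build_confounder_design",
]


class RankError(ValueError):
    """Too few distinct values to support the requested spline basis."""


@dataclass(frozen=True)
class BasisMatrix:
    """Natural cubic spline basis evaluated at the input points.

    ``values`` has one column per degree of freedom; every column has zero
    second derivative at and beyond both boundary knots, and the column
    space (plus an intercept) contains all linear functions of the input.
    """

    values: np.ndarray
    knots: np.ndarray        # interior knots
    boundary: tuple[float, float]
    df: int


@dataclass(frozen=True)
class ConfounderDesign:
    """Stacked spline bases of the moving-averaged weather variables."""

    matrix: np.ndarray       # n_days x (temp_df + rh_df)
    valid_mask: np.ndarray   # False where a moving average is undefined
    spec: tuple[int, int, int, int]  # (temp_window, temp_df, rh_window, rh_df)
    column_names: tuple[str, ...]


def trailing_moving_average(
    x, window: int, *, exclude_current: bool = False
) -> np.ndarray:
    """Trailing ``window``-day mean of a daily series.

    By default the window includes the current day (lags ``0..window-1``);
    with ``exclude_current=True`` it covers the strictly preceding days
    (lags ``1..window``).  Entries whose window is incomplete or contains a
    missing value are NaN.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("series is empty")
    if exclude_current:
        shifted = np.full_like(x, np.nan)
        shifted[1:] = x[:-1]
        x = shifted
    out = np.full(x.shape, np.nan)
    if len(x) >= window:
        windows = np.lib.stride_tricks.sliding_window_view(x, window)
        out[window - 1:] = windows.mean(axis=1)  # NaN propagates
    return out


def _natural_spline_columns(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Truncated-power natural cubic spline basis (no intercept column).

    ``knots`` holds all K knots including the two boundary knots.  Returns
    K-1 columns: the identity plus K-2 columns that are cubic between the
    boundary knots and exactly linear outside them.
    """
    K = len(knots)
    lo, hi = knots[0], knots[-1]
    scale = hi - lo

    def d(k: int) -> np.ndarray:
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - hi, 0.0) ** 3
        return num / (hi - knots[k])

    cols = [x]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append((d(k) - d_last) / scale**2)  # scaled for conditioning
    return np.column_stack(cols)


def natural_cubic_basis(
    x, df: int, boundary: tuple[float, float] | None = None
) -> BasisMatrix:
    """Natural cubic spline basis with ``df`` columns.

    Interior knots sit at equally spaced quantiles of the finite values of
    ``x``; boundary knots default to the observed min/max.  Rows where ``x``
    is NaN are NaN in every column.
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    x = np.asarray(x, dtype=float)
    finite = x[np.isfinite(x)]
    if len(np.unique(finite)) < df + 1:
        raise RankError(
            f"need at least {df + 1} distinct finite values for df={df}, "
            f"got {len(np.unique(finite))}"
        )
    if boundary is None:
        boundary = (float(finite.min()), float(finite.max()))
    lo, hi = boundary

    if df == 1:
        # pure linear term, no interior knots
        return BasisMatrix(x[:, None].copy(), np.empty(0), (lo, hi), 1)

    # df columns need df+1 knots in total -> df-1 interior knots
    probs = np.linspace(0, 100, df + 1)[1:-1]
    interior = np.percentile(finite, probs)
    knots = np.concatenate([[lo], interior, [hi]])
    if len(np.unique(knots)) != len(knots):
        raise RankError("tied knots: data too discrete for the requested df")
    values = _natural_spline_columns(x, knots)
    return BasisMatrix(values, interior, (lo, hi), df)


def build_confounder_design(
    series: DailySeries,
    temp_window: int = 4,
    temp_df: int = 6,
    rh_window: int = 4,
    rh_df: int = 3,
    *,
    window_excludes_current: bool = False,
) -> ConfounderDesign:
    """Spline bases of the moving-averaged temperature and humidity.

    The splines are built on the moving-averaged series (not the raw one);
    the default windows and degrees of freedom are the primary analysis
    adjustment (4-day averages, df 6 for temperature, df 3 for humidity).
    """
    if temp_window < 1 or rh_window < 1:
        raise ValueError("windows must be >= 1")
    if len(series) < max(temp_window, rh_window):
        raise ValueError(
            f"series of length {len(series)} shorter than max window "
            f"{max(temp_window, rh_window)}"
        )
    t_ma = trailing_moving_average(
        series.tmean, temp_window, exclude_current=window_excludes_current
    )
    rh_ma = trailing_moving_average(
        series.rh, rh_window, exclude_current=window_excludes_current
    )
    t_basis = natural_cubic_basis(t_ma, temp_df)
    rh_basis = natural_cubic_basis(rh_ma, rh_df)
    matrix = np.column_stack([t_basis.values, rh_basis.values])
    valid = np.isfinite(t_ma) & np.isfinite(rh_ma)
    names = tuple(
        [f"ns(tmean_ma{temp_window})[{j}]" for j in range(temp_df)]
        + [f"ns(rh_ma{rh_window})[{j}]" for j in range(rh_df)]
    )
    return ConfounderDesign(matrix, valid, (temp_window, temp_df, rh_window, rh_df), names)
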