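"""Time-stratified case-crossover stratification.

Each day is assigned to the stratum defined by its year, calendar month and
day of week, so the control days for any case day are exactly the other
days of the same weekday within the same calendar month.  Under conditional
(fixed-effects) Poisson inference, strata whose total death count is zero
carry no information; filtering them is therefore inference-neutral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StratumAssignment", "assign_strata", "filter_strata"]

ZERO_POLICIES = ("stratum_zero_total", "day_zero")


@dataclass(frozen=True)
class StratumAssignment:
    """Per-day stratum membership.

    ``codes`` are dense integer labels 0..n_strata-1 in order of first
    appearance; ``keys`` maps each code to its (year, month, iso_weekday)
    tuple, with ISO weekday numbering (Monday = 1).
    """

    codes: np.ndarray
    keys: tuple[tuple[int, int, int], ...]

    @property
    def n_strata(self) -> int:
        return len(self.keys)

    def __len__(self) -> int:
        return len(self.codes)


def assign_strata(dates) -> StratumAssignment:
    """Label each day with its year x month x day-of-week stratum."""
    idx = pd.DatetimeIndex(dates)
    key_frame = pd.DataFrame(
        {"year": idx.year, "month": idx.month, "dow": idx.dayofweek + 1}
    )
    codes, uniques = pd.factorize(
        pd.Series(zip(key_frame.year, key_frame.month, key_frame.dow)), sort=False
    )
    keys = tuple((int(y), int(m), int(d)) for (y, m, d) in uniques)
    return StratumAssignment(codes.astype(np.int64), keys)


def filter_strata(
    deaths, labels: StratumAssignment, policy: str = "stratum_zero_total"
) -> np.ndarray:
    """Indices of days kept under the zero-count exclusion policy.

    ``stratum_zero_total`` removes every day of any stratum whose summed
    deaths are zero (the default: such strata are non-informative under
    conditioning).  ``day_zero`` removes individual zero-count days.
    Returned indices are sorted ascending.
    """
    deaths = np.asarray(deaths)
    if len(deaths) != len(labels.codes):
        raise ValueError("deaths and stratum labels differ in length")
    if policy == "stratum_zero_total":
        totals = np.bincount(labels.codes, weights=deaths, minlength=labels.n_strata)
        keep = totals[labels.codes] > 0
    elif policy == "day_zero":
        keep = deaths > 0
    else:
        raise ValueError(f"unknown policy {policy!r}; expected one of {ZERO_POLICIES}")
    return np.flatnonzero(keep)
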