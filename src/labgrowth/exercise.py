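"""Total daily exercise (TDE) from binned weekday/weekend activity reports.

Owners reported, for each activity (on lead, off lead, fetching/chasing/
retrieving, other), how long the dog exercised on a typical weekday and
weekend day using time bins.  TDE combines the bin midpoints with weights
5/7 (weekday) and 2/7 (weekend day) and sums over activities; the modelled
response is its square root (tTDE).  The open-ended "over 2 h" bin is
treated as 2-4 h, i.e. midpoint 180 min.

The exact bin ladder below the top category came from the questionnaire
itself and is configuration data here, never hard-coded in computations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExerciseBins",
    "DEFAULT_BINS",
    "DEFAULT_ACTIVITIES",
    "RESTRICTION_LEVELS",
    "DailyExercise",
    "weighted_daily_average",
    "tde",
    "tde_frame",
    "summarize_tde",
]

WEEKDAY_WEIGHT = 5.0 / 7.0
WEEKEND_WEIGHT = 2.0 / 7.0

DEFAULT_ACTIVITIES = ("on_lead", "off_lead", "fetching", "other")

RESTRICTION_LEVELS = (
    "none", "dog_problem", "breeder_recommendation", "owner_ability",
    "time", "location",
)


@dataclass(frozen=True)
class ExerciseBins:
    """Ordered time bins, label -> (lower, upper) bounds in minutes."""

    bounds: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        prev_hi = 0.0
        for label, (lo, hi) in self.bounds.items():
            if lo > hi or lo < 0:
                raise ValueError(f"bin {label!r} has invalid bounds ({lo}, {hi})")
            if lo < prev_hi:
                raise ValueError(f"bin {label!r} overlaps the previous bin")
            prev_hi = hi

    def midpoint(self, label: str) -> float:
        try:
            lo, hi = self.bounds[label]
        except KeyError:
            raise KeyError(f"unknown exercise bin {label!r}") from None
        return (lo + hi) / 2.0

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.bounds)


#: Default ladder; the top category "over 2 h" maps to 2-4 h.
DEFAULT_BINS = ExerciseBins({
    "none": (0.0, 0.0),
    "0-30": (0.0, 30.0),
    "30-60": (30.0, 60.0),
    "60-120": (60.0, 120.0),
    "over2h": (120.0, 240.0),
})


@dataclass(frozen=True)
class DailyExercise:
    """TDE in minutes/day and its square-root transform."""

    tde_min: float
    ttde: float


def weighted_daily_average(weekday_min: float, weekend_min: float) -> float:
    """(5/7) x weekday + (2/7) x weekend-day minutes."""
    if weekday_min < 0 or weekend_min < 0:
        raise ValueError("exercise times must be nonnegative")
    return WEEKDAY_WEIGHT * weekday_min + WEEKEND_WEIGHT * weekend_min


def tde(
    weekday_bins: Mapping[str, str],
    weekend_bins: Mapping[str, str],
    bins: ExerciseBins = DEFAULT_BINS,
) -> DailyExercise:
    """TDE for one report: per-activity bin midpoints, day-weighted, summed.

    ``weekday_bins`` / ``weekend_bins`` map activity name -> bin label and
    must cover the same activities.
    """
    if set(weekday_bins) != set(weekend_bins):
        raise ValueError("weekday and weekend reports cover different activities")
    total = 0.0
    for activity, wd_label in weekday_bins.items():
        total += weighted_daily_average(
            bins.midpoint(wd_label), bins.midpoint(weekend_bins[activity])
        )
    return DailyExercise(tde_min=total, ttde=float(np.sqrt(total)))


def tde_frame(
    reports: pd.DataFrame,
    bins: ExerciseBins = DEFAULT_BINS,
    activities: Sequence[str] = DEFAULT_ACTIVITIES,
) -> pd.DataFrame:
    """Append ``tde_min`` and ``ttde`` columns to a reports frame.

    Expects one column pair per activity: ``{activity}_weekday`` and
    ``{activity}_weekend`` holding bin labels.
    """
    mid = {lab: bins.midpoint(lab) for lab in bins.labels}

    def lookup(col: pd.Series) -> np.ndarray:
        unknown = set(col.unique()) - set(mid)
        if unknown:
            raise KeyError(f"unknown exercise bin(s) {sorted(unknown)!r}")
        return col.map(mid).to_numpy(dtype=float)

    total = np.zeros(len(reports))
    for activity in activities:
        total += (
            WEEKDAY_WEIGHT * lookup(reports[f"{activity}_weekday"])
            + WEEKEND_WEIGHT * lookup(reports[f"{activity}_weekend"])
        )
    out = reports.copy()
    out["tde_min"] = total
    out["ttde"] = np.sqrt(total)
    return out


def summarize_tde(tde_values: Sequence[float]) -> dict[str, float]:
    """Mean, median and interquartile range of per-report TDE values."""
    v = np.asarray(tde_values, dtype=float)
    if v.size == 0:
        raise ValueError("no TDE values to summarize")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "mean": float(v.mean()),
        "median": float(med),
        "iqr_lower": float(q1),
        "iqr_upper": float(q3),
    }
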