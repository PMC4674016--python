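"""Descriptive-inference toolkit: 2x2 chi-squared tests with continuity
correction, Bonferroni thresholds, exact binomial proportion intervals and
the loss-to-follow-up flagging rule.

The continuity correction is applied as cc = min(0.5, |O - E|) per cell
(the classical Yates form), which is the convention required to reproduce
the study's printed statistics from its printed counts; it is on by
default and never increases the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ContingencyTable2x2",
    "Chi2Result",
    "ProportionCI",
    "FollowUpRecord",
    "chi2_2x2",
    "bonferroni_threshold",
    "binomial_ci",
    "flag_lost",
    "retention_rate",
    "LOSS_WINDOW_YOUNG_DAYS",
    "LOSS_WINDOW_OLD_DAYS",
]

#: A dog is assumed lost two months (61 d) after its last answer if under
#: one year of age, four months (122 d) if older.
LOSS_WINDOW_YOUNG_DAYS = 61
LOSS_WINDOW_OLD_DAYS = 122
ONE_YEAR_DAYS = 365


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts (n11, n12 / n21, n22) of a 2x2 table."""

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self) -> None:
        counts = (self.n11, self.n12, self.n21, self.n22)
        if any(c < 0 for c in counts):
            raise ValueError("cell counts must be nonnegative")
        if sum(counts) < 1:
            raise ValueError("table must contain at least one observation")

    def as_array(self) -> np.ndarray:
        return np.array([[self.n11, self.n12], [self.n21, self.n22]], dtype=float)


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    df: int = 1
    continuity_corrected: bool = True


@dataclass(frozen=True)
class ProportionCI:
    k: int
    n: int
    point: float
    lower: float
    upper: float
    method: str = "clopper-pearson"


@dataclass(frozen=True)
class FollowUpRecord:
    dog_id: str
    age_at_last_entry_days: float
    days_since_last_entry: float

    def __post_init__(self) -> None:
        if self.days_since_last_entry < 0:
            raise ValueError("days_since_last_entry must be nonnegative")


def chi2_2x2(table: ContingencyTable2x2, corrected: bool = True) -> Chi2Result:
    """Pearson chi-squared on a 2x2 table, Yates-corrected by default.

    statistic = sum over cells of (|O - E| - cc)^2 / E with
    cc = min(0.5, |O - E|) when ``corrected``, else 0; p from chi2(1 df).
    """
    obs = table.as_array()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("2x2 table has a zero margin")
    expected = np.outer(row, col) / obs.sum()
    dev = np.abs(obs - expected)
    if corrected:
        dev = dev - np.minimum(0.5, dev)
    stat = float(np.sum(dev**2 / expected))
    return Chi2Result(
        statistic=stat,
        p_value=float(sps.chi2.sf(stat, df=1)),
        continuity_corrected=corrected,
    )


def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """Per-test significance threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m_tests < 1:
        raise ValueError("m_tests must be at least 1")
    return alpha / m_tests


def binomial_ci(k: int, n: int, level: float = 0.95) -> ProportionCI:
    """Exact (Clopper-Pearson / beta-quantile) binomial proportion interval."""
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n with n >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    lower, upper = proportion_confint(k, n, alpha=1.0 - level, method="beta")
    return ProportionCI(k=k, n=n, point=k / n,
                        lower=float(lower), upper=float(upper))


def flag_lost(record: FollowUpRecord) -> bool:
    """Assumed-loss rule: >61 d of silence under one year of age, >122 d over."""
    young = record.age_at_last_entry_days < ONE_YEAR_DAYS
    window = LOSS_WINDOW_YOUNG_DAYS if young else LOSS_WINDOW_OLD_DAYS
    return record.days_since_last_entry > window


def retention_rate(records: Sequence[FollowUpRecord] | pd.DataFrame,
                   age_threshold_days: float) -> float:
    """Fraction of dogs reaching an age threshold that are not assumed lost.

    ``records`` is a sequence of FollowUpRecord or a frame with columns
    ``dog_id, age_at_last_entry_days, days_since_last_entry``.  A dog
    "reaches" the threshold if its age at last entry plus the elapsed
    silence passes it.
    """
    if isinstance(records, pd.DataFrame):
        records = [
            FollowUpRecord(str(r.dog_id), float(r.age_at_last_entry_days),
                           float(r.days_since_last_entry))
            for r in records.itertuples()
        ]
    eligible = [
        r for r in records
        if r.age_at_last_entry_days + r.days_since_last_entry >= age_threshold_days
    ]
    if not eligible:
        raise ValueError("no dog reaches the age threshold")
    retained = sum(
        1 for r in eligible
        if r.age_at_last_entry_days >= age_threshold_days or not flag_lost(r)
    )
    return retained / len(eligible)
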