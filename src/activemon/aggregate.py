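"""2-week median aggregation and adherence accounting.

Interval 1 covers days 1-14 and interval 2 days 15-28 (closed on both
ends), day 1 being the device-issuance day. An interval median is computed
only over QC-passing values and is *missing* when fewer than ``n_min``
passing observations fall in the interval (1 for the weekly cognitive
tests, 3 for all others).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .qc import n_min_for, round_rate
from .types import FeatureValue, Schedule, TestType

INTERVAL_DAYS = {1: (1, 14), 2: (15, 28)}


@dataclass
class AggregatedFeature:
    participant_id: str
    feature: str
    hand: Optional[str]
    interval: int
    median: Optional[float]
    n_observations: int

    @property
    def missing(self) -> bool:
        return self.median is None


def aggregate_interval(
    values: Sequence[FeatureValue],
    interval: int,
    n_min: Optional[int] = None,
) -> AggregatedFeature:
    """Median of one participant/feature/hand's passing values in one interval."""
    if interval not in INTERVAL_DAYS:
        raise ValueError(f"interval must be 1 or 2, got {interval}")
    if not values:
        raise ValueError("no feature values supplied")
    first = values[0]
    for v in values:
        if (v.participant_id, v.feature, v.hand) != (first.participant_id, first.feature, first.hand):
            raise ValueError("aggregate_interval expects one participant/feature/hand")
        if not 1 <= v.day <= 28:
            raise ValueError(f"day {v.day} outside the 4-week window")
    lo, hi = INTERVAL_DAYS[interval]
    in_window = [v.value for v in values if v.qc_status.passed and lo <= v.day <= hi]
    n_min = n_min if n_min is not None else n_min_for(first.test)
    median = float(np.median(in_window)) if len(in_window) >= n_min else None
    return AggregatedFeature(
        participant_id=first.participant_id,
        feature=first.feature.value,
        hand=first.hand.value if first.hand else None,
        interval=interval,
        median=median,
        n_observations=len(in_window),
    )


def aggregate_all(
    feature_values: Iterable[FeatureValue],
    n_min_overrides: Optional[dict] = None,
) -> pd.DataFrame:
    """Long table of interval medians for every participant/feature/hand."""
    groups: dict[tuple, list[FeatureValue]] = {}
    for fv in feature_values:
        key = (fv.participant_id, fv.feature, fv.hand)
        groups.setdefault(key, []).append(fv)
    rows = []
    for (pid, feature, hand), vals in groups.items():
        n_min = n_min_for(vals[0].test, n_min_overrides)
        for interval in (1, 2):
            agg = aggregate_interval(vals, interval, n_min=n_min)
            rows.append(
                {
                    "participant_id": pid,
                    "feature": feature.value,
                    "hand": hand.value if hand else "",
                    "interval": interval,
                    "median": agg.median,
                    "n_observations": agg.n_observations,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["participant_id", "feature", "hand", "interval", "median", "n_observations"],
    )
    return df.sort_values(["participant_id", "feature", "hand", "interval"]).reset_index(drop=True)


@dataclass
class AdherenceSummary:
    completed: int
    scheduled: int
    percent: float


def adherence(schedules: Iterable[Schedule], precision: int = 2) -> AdherenceSummary:
    """Overall completion percentage across the 4-week window."""
    completed = scheduled = 0
    for sched in schedules:
        completed += sched.n_completed
        scheduled += sched.n_scheduled
    if scheduled == 0:
        raise ZeroDivisionError("adherence undefined: nothing scheduled")
    if completed > scheduled:
        raise ValueError("completed cannot exceed scheduled")
    return AdherenceSummary(
        completed=completed,
        scheduled=scheduled,
        percent=round_rate(completed, scheduled, precision),
    )


def adherence_by_study(
    schedules: dict[str, Schedule],
    study_of: dict[str, str],
    precision: int = 2,
) -> pd.DataFrame:
    rows = []
    by_study: dict[str, list[Schedule]] = {}
    for pid, sched in schedules.items():
        by_study.setdefault(study_of[pid], []).append(sched)
    for study, scheds in sorted(by_study.items()):
        summary = adherence(scheds, precision=precision)
        rows.append(
            {
                "study": study,
                "completed": summary.completed,
                "scheduled": summary.scheduled,
                "percent": summary.percent,
            }
        )
    return pd.DataFrame(rows)
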