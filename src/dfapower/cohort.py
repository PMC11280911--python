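"""Data-quality filtering and 10-day workout grouping.

Four quality criteria decide whether a workout's windowed (P, a1) series
enters the analysis, applied strictly in this order:

1. artifact fraction of the RR series at most 5%;
2. only minutes 5-20 of the workout are kept (fatigue / strap-settling
   crop);
3. at least 90% of the kept samples must have non-zero power (pedaling
   consistency); the zero-power samples are then discarded;
4. at least 50% of the remaining samples must lie in the dynamic range
   a1 < 1.0 (otherwise the ride was too easy to inform the relationship).

Workouts that pass are pooled per user into disjoint ("tumbling") groups
of all workouts within 10 days of the earliest unassigned one; only
groups with at least 4 workouts are analysed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

from .dfa_windows import WindowSample
from .preprocess import PreprocessReport

__all__ = [
    "FilterConfig",
    "FilterReport",
    "WorkoutGroup",
    "filter_workout",
    "build_groups",
]


@dataclass(frozen=True)
class FilterConfig:
    max_artifact_fraction: float = 0.05
    crop_start_s: float = 300.0
    crop_end_s: float = 1200.0
    min_pedaling_fraction: float = 0.90
    min_dynamic_fraction: float = 0.50
    dynamic_cutoff_a1: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "max_artifact_fraction",
            "min_pedaling_fraction",
            "min_dynamic_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.crop_start_s >= self.crop_end_s:
            raise ValueError("crop_start_s must precede crop_end_s")


@dataclass(frozen=True)
class FilterReport:
    passed: bool
    reasons: tuple[str, ...]
    n_points_in: int
    n_points_retained: int
    pedaling_fraction: float
    dynamic_fraction: float

    def __post_init__(self) -> None:
        assert self.passed == (len(self.reasons) == 0)

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "reasons": list(self.reasons),
            "n_points_in": self.n_points_in,
            "n_points_retained": self.n_points_retained,
            "pedaling_fraction": self.pedaling_fraction,
            "dynamic_fraction": self.dynamic_fraction,
        }


def filter_workout(
    samples: list[WindowSample],
    report: PreprocessReport,
    cfg: FilterConfig | None = None,
) -> tuple[np.ndarray, FilterReport]:
    """Apply the four quality criteria to one workout's windowed series.

    Returns ``(points, report)`` where ``points`` is an ``(n, 2)`` array
    of retained ``(p, a1)`` pairs (empty when the workout is rejected).
    The criteria are evaluated in the fixed order documented in the
    module docstring; a failure records its tag but the remaining
    fractions are still reported for diagnostics.
    """
    cfg = cfg or FilterConfig()
    reasons: list[str] = []
    n_in = len(samples)

    if report.artifact_fraction > cfg.max_artifact_fraction:
        reasons.append("artifacts")

    cropped = [
        s
        for s in samples
        if s.valid and cfg.crop_start_s <= s.t_end <= cfg.crop_end_s
    ]
    if not cropped:
        reasons.append("empty_after_crop")
        rep = FilterReport(False, tuple(reasons), n_in, 0, float("nan"), float("nan"))
        return np.empty((0, 2)), rep

    with_power = [s for s in cropped if np.isfinite(s.p)]
    pedaling_fraction = (
        sum(1 for s in with_power if s.p > 0) / len(with_power)
        if with_power
        else 0.0
    )
    if pedaling_fraction < cfg.min_pedaling_fraction:
        reasons.append("pedaling")
    pedaling = [s for s in with_power if s.p > 0]

    dynamic_fraction = (
        sum(1 for s in pedaling if s.a1 < cfg.dynamic_cutoff_a1) / len(pedaling)
        if pedaling
        else 0.0
    )
    if dynamic_fraction < cfg.min_dynamic_fraction:
        reasons.append("dynamic_range")

    passed = not reasons
    points = (
        np.array([[s.p, s.a1] for s in pedaling], dtype=float)
        if passed
        else np.empty((0, 2))
    )
    rep = FilterReport(
        passed,
        tuple(reasons),
        n_in,
        len(points),
        pedaling_fraction,
        dynamic_fraction,
    )
    return points, rep


@dataclass
class WorkoutGroup:
    """All of one user's quality-passing workouts within a 10-day window."""

    group_id: str
    user_id: str
    workout_ids: list[str]
    start_date: datetime
    end_date: datetime
    points: np.ndarray  # (n, 2) pooled (p, a1)

    def __post_init__(self) -> None:
        assert self.end_date - self.start_date <= timedelta(days=10)

    def to_manifest(self) -> dict:
        return {
            "group_id": self.group_id,
            "user_id": self.user_id,
            "workout_ids": self.workout_ids,
            "start_date": self.start_date.isoformat(),
            "end_date": self.end_date.isoformat(),
            "n_points": int(self.points.shape[0]),
        }


@dataclass(frozen=True)
class FilteredWorkout:
    """Minimal record grouping needs: identity, date, retained points."""

    workout_id: str
    user_id: str
    start_date: datetime
    points: np.ndarray


def build_groups(
    workouts: list[FilteredWorkout],
    window_days: int = 10,
    min_workouts: int = 4,
) -> list[WorkoutGroup]:
    """Assemble disjoint per-user groups of workouts within ``window_days``.

    Greedy tumbling assignment: per user, sort by start date, open a
    window at the earliest unassigned workout, take every workout within
    ``window_days`` of it, and emit a group only when at least
    ``min_workouts`` fall inside.  Window members are consumed either
    way, so no workout can appear in two groups.
    """
    groups: list[WorkoutGroup] = []
    by_user: dict[str, list[FilteredWorkout]] = {}
    for w in workouts:
        by_user.setdefault(w.user_id, []).append(w)

    for user_id in sorted(by_user):
        ws = sorted(by_user[user_id], key=lambda w: w.start_date)
        i = 0
        while i < len(ws):
            anchor = ws[i].start_date
            members = [
                w for w in ws[i:] if w.start_date - anchor <= timedelta(days=window_days)
            ]
            if len(members) >= min_workouts:
                pts = np.concatenate([m.points for m in members], axis=0)
                groups.append(
                    WorkoutGroup(
                        group_id=f"{user_id}:{anchor.date().isoformat()}",
                        user_id=user_id,
                        workout_ids=[m.workout_id for m in members],
                        start_date=members[0].start_date,
                        end_date=members[-1].start_date,
                        points=pts,
                    )
                )
            i += len(members)
    return groups
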