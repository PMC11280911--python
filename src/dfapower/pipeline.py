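"""End-to-end orchestration of the analysis stages.

``run_single_workout`` follows the per-workout path: artifact handling
-> detrending -> windowed (P, a1) series -> quality filters -> single
segmentation -> representatives -> correlations -> fits.  A report is
produced even when the filters reject the workout (with the failing
criteria listed).

``run_cohort`` runs a directory of workouts, assembles 10-day groups,
analyses pooled points with group segmentation, gates the fits, and
derives the monitoring trends (threshold powers, 10-day rolling ESS and
power-to-HR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import models as models_mod
from . import monitoring, preprocess, representatives
from .config import PipelineConfig
from .dfa_windows import WindowSample, windowed_series
from .workout_io import Workout, read_workout

__all__ = ["run_single_workout", "analyze_workout", "run_cohort", "WorkoutResult"]

log = logging.getLogger("dfapower")


@dataclass
class WorkoutResult:
    """Intermediate per-workout products the cohort path reuses."""

    workout: Workout
    samples: list[WindowSample]
    points: np.ndarray
    filter_report: cohort_mod.FilterReport
    preprocess_report: preprocess.PreprocessReport
    ess: float
    p_over_hr: float | None


def _preprocess_and_window(w: Workout, cfg: PipelineConfig):
    corrected, prep = preprocess.detect_and_correct_artifacts(
        w.rr, cfg.artifact_params()
    )
    detrended = preprocess.detrend_smoothness_priors(corrected, cfg.detrend_params())
    samples = windowed_series(detrended, w.power, cfg.dfa_config())
    return corrected, samples, prep


def analyze_workout(w: Workout, cfg: PipelineConfig | None = None) -> WorkoutResult:
    """Run the per-workout stages on an in-memory workout."""
    cfg = cfg or PipelineConfig()
    corrected, samples, prep = _preprocess_and_window(w, cfg)
    points, frep = cohort_mod.filter_workout(samples, prep, cfg.filter_config())
    ess_val = monitoring.ess(w.power, cfg.ess_config(w.thresh))
    try:
        phr = monitoring.power_to_hr(
            Workout(
                w.workout_id,
                w.user_id,
                w.start_date,
                corrected,
                w.power,
                w.thresh,
                w.erg_mode,
            ),
            cfg.crop_start_s,
            cfg.crop_end_s,
        )
    except ValueError:
        phr = None
    return WorkoutResult(w, samples, points, frep, prep, ess_val, phr)


def _fit_block(
    reps: list[representatives.RepresentativePoint], cfg: PipelineConfig
) -> dict:
    """Both family fits, the best-fit gate, and threshold powers."""
    out: dict = {"linear": None, "hyperbolic": None, "selected": None, "gated": False, "thresholds": None}
    fit_reps = (
        [r for r in reps if r.region == "dynamic"]
        if cfg.fit_region == "dynamic"
        else reps
    )
    distinct = len({r.a1_avg for r in fit_reps})
    if len(fit_reps) < 3 or distinct < 3:
        return out
    lin = models_mod.fit_linear(fit_reps)
    hyp = models_mod.fit_hyperbolic(fit_reps)
    out["linear"] = lin.to_dict()
    out["hyperbolic"] = hyp.to_dict()
    best = models_mod.select_best_fit(lin, hyp, cfg.fit_gate)
    if best is not None:
        out["selected"] = best.family
        out["gated"] = True
        out["thresholds"] = models_mod.threshold_powers(best, cfg.fit_gate).to_dict()
    return out


def run_single_workout(
    rr_path: str | Path,
    power_path: str | Path,
    meta: dict | str | Path,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Analyse one workout from its files; returns the JSON-ready report."""
    cfg = cfg or PipelineConfig()
    w = read_workout(rr_path, power_path, meta)
    res = analyze_workout(w, cfg)
    report: dict = {
        "workout_id": w.workout_id,
        "user_id": w.user_id,
        "preprocess": res.preprocess_report.to_dict(),
        "filter": res.filter_report.to_dict(),
        "passed": res.filter_report.passed,
        "ess": res.ess,
        "p_over_hr": res.p_over_hr,
        "correlations": None,
        "representatives": [],
        "fits": None,
    }
    if not res.filter_report.passed:
        log.info(
            "workout %s rejected: %s", w.workout_id, list(res.filter_report.reasons)
        )
        return report
    scheme = representatives.segment(res.points, "single")
    reps = representatives.make_representatives(res.points, scheme, cfg.rep_min_single)
    corr = representatives.correlations(res.points, reps, "single", cfg.dynamic_cutoff_a1)
    report["correlations"] = corr.to_dict()
    report["representatives"] = [r.to_dict() for r in reps]
    report["fits"] = _fit_block(reps, cfg)
    return report


def _group_report(g: cohort_mod.WorkoutGroup, cfg: PipelineConfig) -> dict:
    scheme = representatives.segment(g.points, "group")
    reps = representatives.make_representatives(g.points, scheme, cfg.rep_min_group)
    corr = representatives.correlations(g.points, reps, "group", cfg.dynamic_cutoff_a1)
    return {
        **g.to_manifest(),
        "correlations": corr.to_dict(),
        "representatives": [r.to_dict() for r in reps],
        "fits": _fit_block(reps, cfg),
    }


def run_cohort(
    workout_dirs: list[Path] | str | Path,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Analyse a directory (or explicit list) of workout folders.

    Each workout folder holds ``rr.csv``, ``power.csv`` and ``meta.json``.
    Returns ``{"workouts": [...], "groups": [...], "trend": DataFrame-ready
    records}``; workouts failing quality filters are logged and excluded
    from grouping but still reported.
    """
    cfg = cfg or PipelineConfig()
    if not isinstance(workout_dirs, list):
        root = Path(workout_dirs)
        workout_dirs = sorted(
            d for d in root.iterdir() if (d / "rr.csv").exists()
        )
    results: list[WorkoutResult] = []
    workout_reports = []
    for d in workout_dirs:
        w = read_workout(d / "rr.csv", d / "power.csv", d / "meta.json")
        res = analyze_workout(w, cfg)
        results.append(res)
        workout_reports.append(
            {
                "workout_id": w.workout_id,
                "user_id": w.user_id,
                "start_date": w.start_date.isoformat(),
                "passed": res.filter_report.passed,
                "reasons": list(res.filter_report.reasons),
                "ess": res.ess,
                "p_over_hr": res.p_over_hr,
            }
        )
        if not res.filter_report.passed:
            log.info(
                "workout %s excluded: %s", w.workout_id, list(res.filter_report.reasons)
            )

    eligible = [
        cohort_mod.FilteredWorkout(
            r.workout.workout_id,
            r.workout.user_id,
            r.workout.start_date,
            r.points,
        )
        for r in results
        if r.filter_report.passed
    ]
    groups = cohort_mod.build_groups(
        eligible, cfg.group_window_days, cfg.group_min_workouts
    )
    if not groups:
        log.warning("no eligible workout groups")
    group_reports = [_group_report(g, cfg) for g in groups]

    trend = _build_trend(results, groups, group_reports, cfg)
    return {"workouts": workout_reports, "groups": group_reports, "trend": trend}


def _build_trend(
    results: list[WorkoutResult],
    groups: list[cohort_mod.WorkoutGroup],
    group_reports: list[dict],
    cfg: PipelineConfig,
) -> list[dict]:
    """Dated threshold-power estimates with rolling ESS / P-HR context.

    Threshold powers are anchored at each group's end date; ESS and
    power-to-HR are 10-day trailing means over workouts.
    """
    ess_series = [(r.workout.start_date, r.ess) for r in results]
    phr_series = [
        (r.workout.start_date, r.p_over_hr)
        for r in results
        if r.p_over_hr is not None
    ]
    ess_roll = dict(monitoring.rolling_trend(ess_series, cfg.trend_window_days))
    phr_roll = dict(monitoring.rolling_trend(phr_series, cfg.trend_window_days))

    rows = []
    for g, rep in zip(groups, group_reports):
        thr = rep["fits"]["thresholds"]
        if thr is None:
            continue
        date = g.end_date
        ess_dates = [d for d in ess_roll if d <= date]
        phr_dates = [d for d in phr_roll if d <= date]
        rows.append(
            {
                "date": date.isoformat(),
                "p_a1_1_0": thr["p_a1_1_0"],
                "p_a1_0_75": thr["p_a1_0_75"],
                "p_a1_0_5": thr["p_a1_0_5"],
                "ess_10d": ess_roll[max(ess_dates)] if ess_dates else None,
                "p_over_hr_10d": phr_roll[max(phr_dates)] if phr_dates else None,
            }
        )
    return rows


def trend_to_csv(trend: list[dict], path: str | Path) -> None:
    pd.DataFrame(
        trend,
        columns=["date", "p_a1_1_0", "p_a1_0_75", "p_a1_0_5", "ess_10d", "p_over_hr_10d"],
    ).to_csv(path, index=False)
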