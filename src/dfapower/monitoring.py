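"""Training-load monitoring: stress score, power-to-HR ratio, 10-day trends.

The External Stress Score (ESS) is a dimensionless workout-load number
normalised so that one hour ridden exactly at the threshold setting
scores 100.  The workout is cut into steps of at most 10 minutes
(fourth-power averaging is non-linear in time; short steps restore
linear accumulation), and within each step the intensity is the
fourth-power-weighted mean of the 30-s rolling average power,
normalised by the threshold:

    i_step = (mean(moving_av(power)^4))^(1/4) / thresh
    ESS    = sum over steps of sec_step/3600 * i_step^2 * 100

The power-to-HR ratio (W/BPM) is the mean power over minutes 5-20
divided by the mean heart rate over the same interval, HR being derived
from the artifact-corrected (not detrended) RR series.  Both metrics,
and the gated threshold-power estimates, are tracked as 10-day trailing
rolling averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .workout_io import PowerSeries, Workout

__all__ = [
    "EssConfig",
    "TrendPoint",
    "ess",
    "power_to_hr",
    "rolling_trend",
]


@dataclass(frozen=True)
class EssConfig:
    """Step length, rolling-average width and the normalising threshold."""

    thresh: float
    step_s: float = 600.0
    mov_avg_s: float = 30.0

    def __post_init__(self) -> None:
        if self.thresh <= 0:
            raise ValueError("thresh must be positive")
        if self.step_s <= 0 or self.mov_avg_s <= 0:
            raise ValueError("step_s and mov_avg_s must be positive")


def ess(power: PowerSeries, cfg: EssConfig) -> float:
    """External Stress Score of one workout.

    Steps are consecutive ``[k*step_s, (k+1)*step_s)`` slices of the
    recording (the last one shorter); the 30-s rolling average is
    trailing and restarts within each step (no cross-step leakage),
    expanding from the first available sample.  Recording gaps are
    skipped, not zero-filled.  ``sec_step`` is the actual time covered
    by the step's samples.
    """
    t = power.t
    w = power.watts
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    total = 0.0
    n_steps = int(np.ceil((t[-1] + dt / 2) / cfg.step_s))
    for k in range(max(n_steps, 1)):
        lo = np.searchsorted(t, k * cfg.step_s, side="left")
        hi = np.searchsorted(t, (k + 1) * cfg.step_s, side="left")
        if hi <= lo:
            continue
        ts, ws = t[lo:hi], w[lo:hi]
        ser = pd.Series(ws, index=pd.to_timedelta(ts, unit="s"))
        mov = ser.rolling(pd.Timedelta(seconds=cfg.mov_avg_s), min_periods=1).mean()
        i_step = float(np.mean(mov.to_numpy() ** 4) ** 0.25) / cfg.thresh
        sec_step = float(ts[-1] - ts[0]) + dt
        total += sec_step / 3600.0 * i_step**2 * 100.0
    return total


def power_to_hr(
    w: Workout,
    start_s: float = 300.0,
    end_s: float = 1200.0,
) -> float:
    """Mean power divided by mean heart rate over minutes 5-20 (W/BPM).

    Uses the artifact-corrected, non-detrended RR series: the ratio is a
    physiological efficiency measure and must not depend on the
    detrending applied for fluctuation analysis.
    """
    pm = (w.power.t >= start_s) & (w.power.t <= end_s)
    rm = (w.rr.t >= start_s) & (w.rr.t <= end_s)
    if not pm.any() or not rm.any():
        raise ValueError("no samples in the 5-20 minute interval")
    mean_p = float(w.power.watts[pm].mean())
    mean_hr = float(np.mean(60000.0 / w.rr.rr[rm]))
    return mean_p / mean_hr


@dataclass(frozen=True)
class TrendPoint:
    """One dated row of the monitoring trend."""

    date: datetime
    p_at_1_0: float | None = None
    p_at_0_75: float | None = None
    p_at_0_5: float | None = None
    ess_10d: float | None = None
    p_over_hr_10d: float | None = None


def rolling_trend(
    dated_values: list[tuple[datetime, float]],
    window_days: int = 10,
) -> list[tuple[datetime, float]]:
    """Trailing ``window_days``-day rolling mean of dated observations.

    For each date carrying data, the mean of every value with a date in
    ``(date - window_days, date]`` — only past data enters, and the
    denominator is the number of observations in the window (days with
    no data do not dilute the mean).
    """
    out: list[tuple[datetime, float]] = []
    items = sorted(dated_values, key=lambda dv: dv[0])
    dates = [d for d, _ in items]
    for d in sorted(set(dates)):
        window = [
            v
            for (dv, v) in items
            if timedelta(0) <= d - dv < timedelta(days=window_days)
        ]
        out.append((d, float(np.mean(window))))
    return out
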