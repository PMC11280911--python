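"""Reading and writing workout streams (RR intervals + cycling power).

The interchange format is deliberately minimal plain CSV:

* ``rr.csv``    — header ``t_s,rr_ms[,artifact]``, one row per heartbeat;
  ``t_s`` is the time of the beat that *terminates* the interval, in seconds
  from workout start.
* ``power.csv`` — header ``t_s,watts``, nominally 1 Hz (gaps allowed).
* ``meta.json`` — ``{workout_id, user_id, start_date, thresh_w, erg_mode}``.

Device-proprietary formats (FIT/TCX/GPX) are out of scope: the analysis is
device-agnostic and any exporter can produce these CSVs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RRSeries",
    "PowerSeries",
    "Workout",
    "ValidationError",
    "read_workout",
    "write_workout",
]


class ValidationError(ValueError):
    """A stream or metadata record violates a structural invariant."""


@dataclass
class RRSeries:
    """A sequence of interbeat (RR) intervals.

    ``t`` holds seconds since workout start, one entry per beat, taken as
    the time of the beat terminating the interval, so a physically
    consistent series satisfies ``t[i+1] - t[i] ~= rr[i+1] / 1000``.

    ``detrended`` marks residual series produced by detrending; these are
    zero-mean and may contain negative values, so the positivity invariant
    is only enforced on raw series.
    """

    t: np.ndarray
    rr: np.ndarray
    artifact: np.ndarray = field(default=None)  # type: ignore[assignment]
    detrended: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.artifact is None:
            self.artifact = np.zeros(self.t.shape, dtype=bool)
        else:
            self.artifact = np.asarray(self.artifact, dtype=bool)
        if self.t.ndim != 1 or self.t.shape != self.rr.shape:
            raise ValidationError("t and rr must be 1-D arrays of equal length")
        if self.artifact.shape != self.t.shape:
            raise ValidationError("artifact flags must match the beat count")
        if self.t.size == 0:
            raise ValidationError("empty RR series")
        if np.any(np.diff(self.t) < 0):
            raise ValidationError("RR timestamps must be non-decreasing")
        if not self.detrended and np.any(self.rr <= 0):
            raise ValidationError("RR intervals must be positive")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.rr)):
            raise ValidationError("non-finite values in RR series")

    def __len__(self) -> int:
        return int(self.t.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RRSeries):
            return NotImplemented
        return (
            np.allclose(self.t, other.t, rtol=1e-9, atol=0)
            and np.allclose(self.rr, other.rr, rtol=1e-9, atol=0)
            and bool(np.all(self.artifact == other.artifact))
        )


@dataclass
class PowerSeries:
    """Cycling power samples in Watts, nominally 1 Hz; gaps allowed."""

    t: np.ndarray
    watts: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.watts = np.asarray(self.watts, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.watts.shape:
            raise ValidationError("t and watts must be 1-D arrays of equal length")
        if self.t.size == 0:
            raise ValidationError("empty power series")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("power timestamps must be strictly increasing")
        if np.any(self.watts < 0):
            raise ValidationError("power must be non-negative")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.watts)):
            raise ValidationError("non-finite values in power series")

    def __len__(self) -> int:
        return int(self.t.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PowerSeries):
            return NotImplemented
        return np.allclose(self.t, other.t, rtol=1e-9, atol=0) and np.allclose(
            self.watts, other.watts, rtol=1e-9, atol=0
        )


@dataclass
class Workout:
    """One recorded cycling workout: RR + power streams plus metadata.

    ``thresh`` is the user's threshold-power setting in Watts, a proxy of
    the anaerobic threshold used to normalise the stress score.
    """

    workout_id: str
    user_id: str
    start_date: datetime
    rr: RRSeries
    power: PowerSeries
    thresh: float
    erg_mode: bool | None = None

    def __post_init__(self) -> None:
        if self.thresh <= 0:
            raise ValidationError("threshold power must be positive")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Workout):
            return NotImplemented
        return (
            self.workout_id == other.workout_id
            and self.user_id == other.user_id
            and self.start_date == other.start_date
            and self.rr == other.rr
            and self.power == other.power
            and abs(self.thresh - other.thresh) < 1e-9
            and self.erg_mode == other.erg_mode
        )


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pandas raises various parse errors
        raise ValidationError(f"malformed CSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    for col in required:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2  # +1 header, +1 one-based
            raise ValidationError(f"{path}: missing/unparseable value at line {line}")
        df[col] = coerced
    return df


def read_workout(
    rr_path: str | Path,
    power_path: str | Path,
    meta: dict | str | Path,
) -> Workout:
    """Read the CSV/JSON dialect and assemble a validated :class:`Workout`.

    Timestamps of both streams are re-based so the earliest sample of
    either stream is at ``t = 0``.

    ``meta`` may be a dict or a path to a ``meta.json`` file.
    """
    if not isinstance(meta, dict):
        with open(meta) as fh:
            meta = json.load(fh)

    rr_df = _read_csv(rr_path, ["t_s", "rr_ms"])
    pw_df = _read_csv(power_path, ["t_s", "watts"])

    artifact = None
    if "artifact" in rr_df.columns:
        artifact = rr_df["artifact"].astype(bool).to_numpy()

    rr = RRSeries(rr_df["t_s"].to_numpy(), rr_df["rr_ms"].to_numpy(), artifact)
    power = PowerSeries(pw_df["t_s"].to_numpy(), pw_df["watts"].to_numpy())

    # row-count conservation: the reader never silently drops records
    assert len(rr) == len(rr_df) and len(power) == len(pw_df)

    t0 = min(rr.t[0], power.t[0])
    if t0 != 0.0:
        rr = dataclasses.replace(rr, t=rr.t - t0)
        power = dataclasses.replace(power, t=power.t - t0)

    start = meta["start_date"]
    if isinstance(start, str):
        start = datetime.fromisoformat(start)

    return Workout(
        workout_id=str(meta["workout_id"]),
        user_id=str(meta["user_id"]),
        start_date=start,
        rr=rr,
        power=power,
        thresh=float(meta["thresh_w"]),
        erg_mode=meta.get("erg_mode"),
    )


def write_workout(w: Workout, out_dir: str | Path) -> dict[str, Path]:
    """Write ``rr.csv``, ``power.csv`` and ``meta.json`` for one workout.

    Round-trip contract: ``read_workout(**write_workout(w)) == w`` up to
    float formatting (17 significant digits are written).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rr_path = out_dir / "rr.csv"
    power_path = out_dir / "power.csv"
    meta_path = out_dir / "meta.json"

    rr_df = pd.DataFrame({"t_s": w.rr.t, "rr_ms": w.rr.rr})
    if w.rr.artifact.any():
        rr_df["artifact"] = w.rr.artifact.astype(int)
    rr_df.to_csv(rr_path, index=False, float_format="%.17g")
    pd.DataFrame({"t_s": w.power.t, "watts": w.power.watts}).to_csv(
        power_path, index=False, float_format="%.17g"
    )
    with open(meta_path, "w") as fh:
        json.dump(
            {
                "workout_id": w.workout_id,
                "user_id": w.user_id,
                "start_date": w.start_date.isoformat(),
                "thresh_w": w.thresh,
                "erg_mode": w.erg_mode,
            },
            fh,
            indent=2,
        )
    return {"rr_path": rr_path, "power_path": power_path, "meta": meta_path}
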