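"""Synthetic workouts with known ground truth.

The generator emulates the data-generating structure the analysis
assumes: cycling power drives, through a first-order cardiac lag, a
target short-term scaling exponent via an inverted linear law
``a1 = (P_lagged - q_true) / m_true`` (clamped), and the RR series is
scale-free Gaussian noise whose local spectral slope is scheduled so
that the *measured* windowed DFA-a1 tracks that target.

Noise synthesis is spectral: 1/f^beta Gaussian noise generated by FFT
in short overlapping blocks with amplitude cross-fading, the local beta
scheduled per block.  Because first-order DFA at boxes 4-16 does not
read the asymptotic exponent (beta + 1) / 2 exactly at these scales,
the beta that realises a wanted measured a1 is taken from a calibration
map built by brute-force simulation through the package's own
detrending + windowed-DFA pipeline, cached per seed.

Artifacts (missed / extra / ectopic beats) are injected at a configurable
per-beat rate so the artifact detector and the 5% quality gate can be
exercised end to end.  RR timestamps accumulate from the RR values, so
generated series are physically consistent.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

from .dfa_windows import DfaConfig, dfa_alpha1
from .preprocess import DetrendParams, detrend_smoothness_priors
from .workout_io import PowerSeries, RRSeries, Workout

__all__ = [
    "PhysioParams",
    "PowerProfile",
    "spectral_noise",
    "scheduled_noise",
    "calibration_map",
    "a1_to_beta",
    "generate_workout",
    "generate_cohort",
    "truth_sidecar",
]

_BLOCK = 64  # beats per synthesis block
_HOP = 32  # block hop (50% overlap)


@dataclass(frozen=True)
class PhysioParams:
    """Ground-truth physiology of a synthetic athlete.

    ``m_true``/``q_true`` define the linear law ``P = m*a1 + q`` that the
    pipeline should recover.  ``lag_tau_s`` is the time constant of the
    first-order cardiac response to power changes.  ``rr_mean_ms`` is
    the exercise interbeat interval (~400 ms, i.e. ~150 BPM, typical for
    endurance cycling intensity); ``rr_per_watt_ms`` couples the mean RR
    weakly to lagged power so heart rate drifts with intensity, giving
    the smoothness-priors detrending a genuine trend to remove.
    """

    m_true: float = -250.0
    q_true: float = 420.0
    a1_floor: float = 0.3
    a1_ceil: float = 1.4
    lag_tau_s: float = 30.0
    rr_mean_ms: float = 400.0
    rr_sd_ms: float = 25.0
    rr_per_watt_ms: float = 0.08
    artifact_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.m_true >= 0:
            raise ValueError("m_true must be negative (power suppresses a1)")
        if not self.a1_floor < self.a1_ceil:
            raise ValueError("a1_floor must be below a1_ceil")
        if self.lag_tau_s < 0 or self.rr_mean_ms <= 0:
            raise ValueError("invalid lag or RR mean")

    def a1_of_power(self, p: np.ndarray) -> np.ndarray:
        return np.clip((p - self.q_true) / self.m_true, self.a1_floor, self.a1_ceil)

    def power_of_a1(self, a1: float) -> float:
        return self.m_true * a1 + self.q_true


@dataclass(frozen=True)
class PowerProfile:
    """A 1 Hz power profile built from (duration_s, start_w, end_w) ramps."""

    segments: tuple[tuple[float, float, float], ...]
    kind: str = "steady"

    def __post_init__(self) -> None:
        if self.duration_s < 1320:
            raise ValueError("profile must last >= 1320 s so minutes 5-20 exist")
        for _, w0, w1 in self.segments:
            if w0 < 0 or w1 < 0:
                raise ValueError("power must be non-negative")

    @property
    def duration_s(self) -> float:
        return sum(d for d, _, _ in self.segments)

    def render(self) -> PowerSeries:
        """Render to a 1 Hz power series, t = 0 .. T-1."""
        t_parts, w_parts = [], []
        t0 = 0.0
        for dur, w0, w1 in self.segments:
            n = int(round(dur))
            tt = t0 + np.arange(n, dtype=float)
            frac = np.arange(n, dtype=float) / max(n - 1, 1)
            t_parts.append(tt)
            w_parts.append(w0 + (w1 - w0) * frac)
            t0 += n
        return PowerSeries(np.concatenate(t_parts), np.concatenate(w_parts))

    @staticmethod
    def steady(watts: float, duration_s: float = 1500.0) -> "PowerProfile":
        return PowerProfile(((duration_s, watts, watts),), kind="steady")

    @staticmethod
    def staircase(levels: list[float], step_s: float = 250.0) -> "PowerProfile":
        segs = tuple((step_s, lv, lv) for lv in levels)
        return PowerProfile(segs, kind="steady")

    @staticmethod
    def intervals(
        low: float,
        high: float,
        work_s: float = 90.0,
        recovery_s: float = 150.0,
        n_reps: int = 6,
        tail_s: float = 120.0,
    ) -> "PowerProfile":
        segs: list[tuple[float, float, float]] = []
        for _ in range(n_reps):
            segs.append((recovery_s, low, low))
            segs.append((work_s, high, high))
        segs.append((tail_s, low, low))
        return PowerProfile(tuple(segs), kind="intervals")

    @staticmethod
    def erg_ramp(
        start_w: float, end_w: float, duration_s: float = 1500.0
    ) -> "PowerProfile":
        return PowerProfile(((duration_s, start_w, end_w),), kind="erg_ramp")


def spectral_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Standardised Gaussian 1/f^beta noise via FFT synthesis."""
    f = np.fft.rfftfreq(n, d=1.0)
    f[0] = f[1] if n > 1 else 1.0
    amp = f ** (-beta / 2.0)
    phases = rng.normal(size=f.size) + 1j * rng.normal(size=f.size)
    x = np.fft.irfft(amp * phases, n=n)
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def scheduled_noise(beta_per_sample: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise whose local spectral slope follows a schedule.

    Overlapping blocks of ``_BLOCK`` samples are synthesised with the
    block-mean beta, windowed with a sine amplitude envelope (50%
    overlap-add) and renormalised pointwise, which keeps unit variance
    while letting the local scaling exponent vary.
    """
    beta = np.asarray(beta_per_sample, dtype=float)
    n = beta.size
    out = np.zeros(n)
    norm = np.zeros(n)
    env = np.sin(np.pi * (np.arange(_BLOCK) + 0.5) / _BLOCK)
    start = -_HOP
    while start < n:
        sl = slice(max(start, 0), min(start + _BLOCK, n))
        if sl.stop > sl.start:
            b = float(beta[sl].mean())
            block = spectral_noise(_BLOCK, b, rng)
            e = env[sl.start - start : sl.stop - start]
            out[sl] += block[sl.start - start : sl.stop - start] * e
            norm[sl] += e**2
        start += _HOP
    return out / np.sqrt(norm)


_CAL_BETAS = np.arange(-1.0, 2.81, 0.2)
_CAL_BEATS = 4096


def _mean_windowed_a1(rr: RRSeries, cfg: DfaConfig) -> float:
    t_total = rr.t[-1]
    vals = []
    t_end = cfg.window_s
    while t_end <= t_total:
        lo = np.searchsorted(rr.t, t_end - cfg.window_s, side="right")
        hi = np.searchsorted(rr.t, t_end, side="right")
        a1 = dfa_alpha1(rr.rr[lo:hi], cfg)
        if np.isfinite(a1):
            vals.append(a1)
        t_end += cfg.grid_s
    return float(np.mean(vals))


@functools.lru_cache(maxsize=4)
def calibration_map(seed: int = 2024) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Brute-force map from spectral slope beta to measured windowed a1.

    For each beta on a fixed grid, a long constant-beta RR series is
    synthesised with the block machinery, detrended with the standard
    smoothness priors, and the mean windowed DFA-a1 is measured through
    the package's own pipeline.  The map is made strictly monotone
    (cumulative max plus a tiny ramp) so it can be inverted by linear
    interpolation.  Cached per seed.
    """
    rng = np.random.default_rng(seed)
    cfg = DfaConfig()
    a1s = []
    for beta in _CAL_BETAS:
        x = scheduled_noise(np.full(_CAL_BEATS, beta), rng)
        rr_ms = 400.0 + 25.0 * x
        rr = RRSeries(np.cumsum(rr_ms) / 1000.0, rr_ms)
        rr_d = detrend_smoothness_priors(rr, DetrendParams())
        a1s.append(_mean_windowed_a1(rr_d, cfg))
    a1s = np.maximum.accumulate(np.asarray(a1s))
    a1s = a1s + 1e-9 * np.arange(a1s.size)  # strict monotonicity for interp
    return tuple(_CAL_BETAS), tuple(a1s)


def a1_to_beta(a1: np.ndarray, seed: int = 2024) -> np.ndarray:
    """Invert the calibration map; errors outside the calibrated range."""
    betas, a1s = calibration_map(seed)
    a1 = np.asarray(a1, dtype=float)
    lo, hi = a1s[0], a1s[-1]
    if np.any(a1 < lo - 0.02) or np.any(a1 > hi + 0.02):
        raise ValueError(
            f"a1 target outside calibrated range [{lo:.3f}, {hi:.3f}]"
        )
    return np.interp(a1, a1s, betas)


def _lagged(p: np.ndarray, tau_s: float, dt: float = 1.0) -> np.ndarray:
    if tau_s == 0:
        return p.astype(float)
    alpha = 1.0 - np.exp(-dt / tau_s)
    out = np.empty_like(p, dtype=float)
    acc = float(p[0])
    for i, v in enumerate(p):
        acc += alpha * (v - acc)
        out[i] = acc
    return out


def _inject_artifacts(
    rr_ms: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Corrupt ~``rate`` of beats with missed / extra / ectopic events.

    A missed beat (two intervals merged by the monitor) corrupts one
    recorded beat; extra (one interval split) and ectopic (early beat
    plus compensatory pause) corrupt two, so events are drawn until the
    corrupted-beat budget ``rate * n`` is spent.
    """
    rr = list(rr_ms)
    n = len(rr)
    budget = int(rng.binomial(n, rate))
    used: set[int] = set()
    guard = 0
    while budget > 0 and guard < 10 * n:
        guard += 1
        i = int(rng.integers(5, len(rr) - 5))
        if any(abs(i - j) < 4 for j in used):
            continue
        kind = ["missed", "extra", "ectopic"][int(rng.integers(3))]
        if kind == "missed":
            rr[i] = rr[i] + rr[i + 1]
            del rr[i + 1]
            used = {j if j < i else j - 1 for j in used} | {i}
            budget -= 1
        elif kind == "extra" and budget >= 2:
            f = float(rng.uniform(0.4, 0.6))
            total = rr[i]
            rr[i] = total * f
            rr.insert(i + 1, total * (1 - f))
            used = {j if j <= i else j + 1 for j in used} | {i, i + 1}
            budget -= 2
        elif kind == "ectopic" and budget >= 2:
            early = float(rng.uniform(0.30, 0.40)) * rr[i]
            rr[i] -= early
            rr[i + 1] += early
            used |= {i, i + 1}
            budget -= 2
    return np.asarray(rr)


def generate_workout(
    profile: PowerProfile,
    physio: PhysioParams,
    seed: int,
    *,
    workout_id: str = "w0",
    user_id: str = "u0",
    start_date: datetime | None = None,
    thresh: float | None = None,
    cal_seed: int = 2024,
) -> Workout:
    """One synthetic workout, deterministic for a given seed.

    Steps: render 1 Hz power; lag it with a first-order exponential
    filter; invert the true law into a clamped a1 target; schedule the
    noise spectral slope from the calibration map; emit RR as
    ``rr_mean(t) + rr_sd * x(t)``; inject artifacts; timestamp beats by
    cumulative sum.
    """
    rng = np.random.default_rng(seed)
    power = profile.render()
    p_lag = _lagged(power.watts, physio.lag_tau_s)
    a1_target_1hz = physio.a1_of_power(p_lag)

    t_total = power.t[-1] + 1.0
    n_beats = int(np.ceil(t_total * 1000.0 / physio.rr_mean_ms)) + 4
    beat_t_approx = (np.arange(n_beats) + 1) * physio.rr_mean_ms / 1000.0
    a1_per_beat = np.interp(beat_t_approx, power.t, a1_target_1hz)
    beta_per_beat = a1_to_beta(a1_per_beat, seed=cal_seed)

    x = scheduled_noise(beta_per_beat, rng)
    p_ref = physio.power_of_a1(0.7)
    p_lag_per_beat = np.interp(beat_t_approx, power.t, p_lag)
    rr_base = physio.rr_mean_ms - physio.rr_per_watt_ms * (p_lag_per_beat - p_ref)
    rr_ms = np.maximum(rr_base + physio.rr_sd_ms * x, 250.0)

    if physio.artifact_rate > 0:
        rr_ms = _inject_artifacts(rr_ms, physio.artifact_rate, rng)

    t = np.cumsum(rr_ms) / 1000.0
    keep = t <= t_total
    rr = RRSeries(t[keep], rr_ms[keep])

    if thresh is None:
        thresh = physio.power_of_a1(0.5)
    return Workout(
        workout_id=workout_id,
        user_id=user_id,
        start_date=start_date or datetime(2024, 1, 1, 8, 0),
        rr=rr,
        power=power,
        thresh=float(thresh),
        erg_mode=profile.kind == "erg_ramp",
    )


#: staircase levels (W) for the default cohort under the default law:
#: a1 targets 1.08, 0.92, 0.76, 0.60, 0.46, 0.32 — mostly in the dynamic
#: range with one easy level populating the upper region
_DEFAULT_LEVELS = [150.0, 190.0, 230.0, 270.0, 305.0, 340.0]


def _default_profile(j: int) -> PowerProfile:
    if j % 3 == 2:
        return PowerProfile.intervals(low=185.0, high=330.0)
    rot = (j * 2) % len(_DEFAULT_LEVELS)
    levels = _DEFAULT_LEVELS[rot:] + _DEFAULT_LEVELS[:rot]
    return PowerProfile.staircase(levels)


def generate_cohort(
    n_users: int = 2,
    workouts_per_user: int = 6,
    days_span: int = 8,
    physio: PhysioParams | list[PhysioParams] | None = None,
    seed: int = 0,
    start: datetime | None = None,
    cal_seed: int = 2024,
) -> list[Workout]:
    """A calendar-dated multi-user cohort with per-user ground truth.

    Workouts are spread evenly over ``days_span`` days; with the default
    span of 8 days and >= 4 workouts per user, every user yields at
    least one valid 10-day group by construction.  Profiles rotate
    through staircases (level order rotated per workout so every a1 bin
    is visited) with interval sessions mixed in.
    """
    if physio is None:
        physio = PhysioParams()
    physios = physio if isinstance(physio, list) else [physio] * n_users
    if len(physios) != n_users:
        raise ValueError("need one PhysioParams per user")
    start = start or datetime(2024, 3, 1, 9, 0)

    out: list[Workout] = []
    for u in range(n_users):
        for j in range(workouts_per_user):
            day = round(j * days_span / max(workouts_per_user - 1, 1))
            out.append(
                generate_workout(
                    _default_profile(j),
                    physios[u],
                    seed=seed + 1000 * u + j,
                    workout_id=f"u{u}w{j}",
                    user_id=f"u{u}",
                    start_date=start + timedelta(days=day, hours=u),
                    cal_seed=cal_seed,
                )
            )
    return out


def truth_sidecar(physio: PhysioParams, seed: int) -> dict:
    """Ground-truth record written next to simulated workouts."""
    return {
        "m_true": physio.m_true,
        "q_true": physio.q_true,
        "lag_tau_s": physio.lag_tau_s,
        "artifact_rate": physio.artifact_rate,
        "seed": seed,
    }
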