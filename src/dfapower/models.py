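"""Linear and hyperbolic power-a1 laws with gated threshold estimation.

Two two-parameter families relate power to the scaling exponent:

    P = m * a1 + q          (linear; m < 0 for a responder)
    P = s / a1 + t          (hyperbolic; linear in 1/a1)

Both are fitted by ordinary least squares to the representative points,
with R^2 evaluated in the original power space so the families compare
like-for-like.  The better fit is used to evaluate the power at the
physiological landmarks a1 = 1.0, 0.75 (aerobic-threshold proxy) and
0.5 (anaerobic-threshold proxy) — but only when its R^2 exceeds 0.75,
the robustness gate for emitting threshold estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .representatives import RepresentativePoint

__all__ = [
    "FitResult",
    "ThresholdEstimates",
    "R2_GATE",
    "fit_linear",
    "fit_hyperbolic",
    "select_best_fit",
    "threshold_powers",
]

R2_GATE = 0.75


@dataclass(frozen=True)
class FitResult:
    family: str  # "linear" | "hyperbolic"
    params: tuple[float, float]  # (m, q) or (s, t)
    r2: float
    n_points: int

    def predict(self, a1: float | np.ndarray) -> float | np.ndarray:
        a, b = self.params
        if self.family == "linear":
            return a * np.asarray(a1, dtype=float) + b
        return a / np.asarray(a1, dtype=float) + b

    def to_dict(self) -> dict:
        keys = ("m", "q") if self.family == "linear" else ("s", "t")
        return {
            "family": self.family,
            keys[0]: self.params[0],
            keys[1]: self.params[1],
            "r2": self.r2,
            "n_points": self.n_points,
        }


@dataclass(frozen=True)
class ThresholdEstimates:
    """Power at the a1 landmarks, emitted only from a gated fit."""

    p_at_1_0: float
    p_at_0_75: float
    p_at_0_5: float
    source_fit: FitResult
    gated: bool = True

    def to_dict(self) -> dict:
        return {
            "p_a1_1_0": self.p_at_1_0,
            "p_a1_0_75": self.p_at_0_75,
            "p_a1_0_5": self.p_at_0_5,
            "family": self.source_fit.family,
            "r2": self.source_fit.r2,
        }


def _xy(reps: list[RepresentativePoint]) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([r.a1_avg for r in reps], dtype=float)
    y = np.array([r.p_avg for r in reps], dtype=float)
    return x, y


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def fit_linear(reps: list[RepresentativePoint]) -> FitResult:
    """OLS of p_avg on a1_avg: P = m*a1 + q."""
    x, y = _xy(reps)
    if x.size < 3:
        raise ValueError("need at least 3 representatives")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in a1")
    m, q = np.polyfit(x, y, 1)
    fit = FitResult("linear", (float(m), float(q)), 0.0, int(x.size))
    r2 = _r2(y, np.asarray(fit.predict(x)))
    return FitResult("linear", (float(m), float(q)), r2, int(x.size))


def fit_hyperbolic(reps: list[RepresentativePoint]) -> FitResult:
    """OLS of p_avg on 1/a1_avg: P = s/a1 + t, R^2 in the original space.

    The model is linear in its parameters under the 1/a1 transform, so
    the least-squares solution is exact; no iterative fitting.
    """
    x, y = _xy(reps)
    if x.size < 3:
        raise ValueError("need at least 3 representatives")
    if np.any(x == 0):
        raise ValueError("a1_avg = 0 is outside the hyperbolic model domain")
    u = 1.0 / x
    if np.ptp(u) == 0:
        raise ValueError("zero variance in 1/a1")
    s, t = np.polyfit(u, y, 1)
    fit = FitResult("hyperbolic", (float(s), float(t)), 0.0, int(x.size))
    r2 = _r2(y, np.asarray(fit.predict(x)))
    return FitResult("hyperbolic", (float(s), float(t)), r2, int(x.size))


def select_best_fit(
    linear: FitResult,
    hyperbolic: FitResult,
    gate: float = R2_GATE,
) -> FitResult | None:
    """Best-fit rule: the family with R^2 nearest 1, used only past the gate.

    Ties go to the linear model (the simpler, preferred interpretation).
    Returns ``None`` when neither R^2 exceeds ``gate``.
    """
    best = linear if linear.r2 >= hyperbolic.r2 else hyperbolic
    return best if best.r2 > gate else None


def threshold_powers(fit: FitResult, gate: float = R2_GATE) -> ThresholdEstimates:
    """Evaluate a gated fit at a1 = 1.0, 0.75 and 0.5."""
    if fit.r2 <= gate:
        raise ValueError(f"gate failed: R^2 = {fit.r2:.3f} <= {gate}")
    return ThresholdEstimates(
        p_at_1_0=float(fit.predict(1.0)),
        p_at_0_75=float(fit.predict(0.75)),
        p_at_0_5=float(fit.predict(0.5)),
        source_fit=fit,
    )
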