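"""Shared fixtures and independent oracles.

The oracles here are deliberately naive, loop-based implementations —
independent of the vectorised production code paths they are used to
check.
"""

from __future__ import annotations

import numpy as np
import pytest

from dfapower.workout_io import PowerSeries, RRSeries


def reference_dfa_alpha1(
    x, n_min: int = 4, n_max: int = 16, bias_correction: bool = True
) -> float:
    """Naive DFA: explicit per-box polyfit, no vectorisation.

    Matches the production conventions (non-overlapping boxes from the
    start, remainder discarded, natural log) including the optional
    finite-box correction factor, which is a closed form applied
    identically on both sides.
    """
    x = np.asarray(x, dtype=float)
    profile = np.cumsum(x - np.mean(x))
    ns, fs = [], []
    for n in range(n_min, n_max + 1):
        k = len(profile) // n
        sq = []
        for b in range(k):
            seg = profile[b * n : (b + 1) * n]
            t = np.arange(n)
            coef = np.polyfit(t, seg, 1)
            resid = seg - np.polyval(coef, t)
            sq.extend(resid**2)
        f = np.sqrt(np.mean(sq))
        if bias_correction:
            f /= np.sqrt(1.0 - 4.0 / n**2)
        ns.append(n)
        fs.append(f)
    return float(np.polyfit(np.log(ns), np.log(fs), 1)[0])


def brute_spearman(x, y) -> float:
    """Spearman r by explicit average ranks + Pearson on the ranks."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        sv = v[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def rr_from_values(values, t0: float = 0.0) -> RRSeries:
    """Physically consistent RR series: timestamps accumulate from rr."""
    values = np.asarray(values, dtype=float)
    return RRSeries(t0 + np.cumsum(values) / 1000.0, values)


def constant_power(watts: float, duration_s: int) -> PowerSeries:
    t = np.arange(duration_s, dtype=float)
    return PowerSeries(t, np.full(duration_s, float(watts)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
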