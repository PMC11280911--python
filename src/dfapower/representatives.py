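"""Representative-point segmentation and the correlation variants.

Because the cardiac response lags mechanical power, raw simultaneous
(P, a1) pairs are noisy: a power burst produces points with high power
but still-high a1, and the recovery produces the mirror image.  The
representative method mitigates this by slicing the a1 axis into
equal-width intervals, averaging power and a1 within each sufficiently
populated interval into one representative point, and correlating the
representatives instead of the raw cloud.

Two segmentation layouts exist:

* ``single`` (one workout): 8 equal bins on ``[a1_min, a1*]`` with
  ``a1* = min(1.2, a1_max)``; representatives need >= 8 member points.
* ``group`` (pooled workouts): 9 bins on the dynamic range
  ``[a1_min, 1.0]`` plus 5 bins on ``[1.0, a1*]`` with
  ``a1* = min(1.8, a1_max)``; representatives need >= 10 points.

Correlations are Spearman rank correlations; sizes are read against the
conventional bands 0.3 <= |r| < 0.5 low, 0.6 <= |r| < 0.8 moderate,
|r| >= 0.8 high.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SegmentationScheme",
    "RepresentativePoint",
    "CorrelationReport",
    "MIN_COUNT",
    "segment",
    "make_representatives",
    "correlations",
    "correlation_size_class",
]

#: minimum member points per representative, by segmentation mode
MIN_COUNT = {"single": 8, "group": 10}

_N_BINS_SINGLE = 8
_N_BINS_DYNAMIC = 9
_N_BINS_UPPER = 5
_CAP_SINGLE = 1.2
_CAP_GROUP = 1.8
_DYNAMIC_EDGE = 1.0


@dataclass(frozen=True)
class SegmentationScheme:
    mode: str
    edges_dynamic: np.ndarray
    edges_upper: np.ndarray
    a1_min: float
    a1_star: float


@dataclass(frozen=True)
class RepresentativePoint:
    a1_avg: float
    p_avg: float
    a1_sd: float
    p_sd: float
    n_points: int
    region: str  # "dynamic" | "upper"

    def to_dict(self) -> dict:
        return {
            "a1_avg": self.a1_avg,
            "p_avg": self.p_avg,
            "a1_sd": self.a1_sd,
            "p_sd": self.p_sd,
            "n_points": self.n_points,
            "region": self.region,
        }


def segment(points: np.ndarray, mode: str) -> SegmentationScheme:
    """Build the a1-interval layout for a point cloud.

    ``points`` is an ``(n, 2)`` array of ``(p, a1)`` pairs.  Bins are
    half-open ``[lo, hi)`` except the last bin of each region, which is
    closed at ``a1*`` (resp. the dynamic edge).
    """
    if mode not in MIN_COUNT:
        raise ValueError(f"unknown segmentation mode {mode!r}")
    a1 = np.asarray(points, dtype=float)[:, 1]
    a1 = a1[np.isfinite(a1)]
    if np.unique(a1).size < 2:
        raise ValueError("degenerate range: need at least 2 distinct a1 values")
    a1_min = float(a1.min())
    a1_max = float(a1.max())

    if mode == "single":
        a1_star = min(_CAP_SINGLE, a1_max)
        if a1_star <= a1_min:
            raise ValueError("degenerate range: a1* not above a1_min")
        edges = np.linspace(a1_min, a1_star, _N_BINS_SINGLE + 1)
        return SegmentationScheme("single", edges, np.array([]), a1_min, a1_star)

    a1_star = min(_CAP_GROUP, a1_max)
    if a1_min >= _DYNAMIC_EDGE:
        raise ValueError("degenerate range: no points below the dynamic edge")
    edges_dyn = np.linspace(a1_min, _DYNAMIC_EDGE, _N_BINS_DYNAMIC + 1)
    if a1_star > _DYNAMIC_EDGE:
        edges_up = np.linspace(_DYNAMIC_EDGE, a1_star, _N_BINS_UPPER + 1)
    else:
        edges_up = np.array([])
        a1_star = _DYNAMIC_EDGE
    return SegmentationScheme("group", edges_dyn, edges_up, a1_min, a1_star)


def _bin_members(
    a1: np.ndarray, edges: np.ndarray
) -> list[np.ndarray]:
    """Index masks per bin: [lo, hi) everywhere, last bin closed."""
    masks = []
    n_bins = edges.size - 1
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        if b == n_bins - 1:
            m = (a1 >= lo) & (a1 <= hi)
        else:
            m = (a1 >= lo) & (a1 < hi)
        masks.append(m)
    return masks


def make_representatives(
    points: np.ndarray,
    scheme: SegmentationScheme,
    min_count: int | None = None,
) -> list[RepresentativePoint]:
    """Average each sufficiently populated a1 interval into one point.

    Sample (n-1) standard deviations accompany the means.  Points with
    ``a1 > a1*`` are outside the scheme and contribute nothing; bins with
    fewer than ``min_count`` members (mode default: 8 single / 10 group)
    yield no representative.
    """
    if min_count is None:
        min_count = MIN_COUNT[scheme.mode]
    pts = np.asarray(points, dtype=float)
    p, a1 = pts[:, 0], pts[:, 1]

    reps: list[RepresentativePoint] = []
    regions = [("dynamic", scheme.edges_dynamic)]
    if scheme.edges_upper.size:
        regions.append(("upper", scheme.edges_upper))
    for region, edges in regions:
        for mask in _bin_members(a1, edges):
            # the dynamic-region closed top edge overlaps the first upper
            # bin's open bottom edge; assign boundary points to dynamic only
            if region == "upper":
                mask = mask & (a1 > edges[0])
            n = int(mask.sum())
            if n < min_count:
                continue
            reps.append(
                RepresentativePoint(
                    a1_avg=float(a1[mask].mean()),
                    p_avg=float(p[mask].mean()),
                    a1_sd=float(a1[mask].std(ddof=1)) if n > 1 else 0.0,
                    p_sd=float(p[mask].std(ddof=1)) if n > 1 else 0.0,
                    n_points=n,
                    region=region,
                )
            )
    return reps


def correlation_size_class(r: float) -> str:
    """Conventional qualitative size of a Spearman correlation."""
    a = abs(r)
    if a >= 0.8:
        return "high"
    if 0.6 <= a < 0.8:
        return "moderate"
    if 0.3 <= a < 0.5:
        return "low"
    return "unclassified"


@dataclass
class CorrelationReport:
    """Spearman correlations of the standard and representative variants.

    A variant that cannot be computed (fewer than 3 points, or zero rank
    variance) is ``None`` with an explanatory tag in ``tags``.
    """

    r_standard_total: float | None = None
    r_standard_dynamic: float | None = None
    r_representative_dynamic: float | None = None
    r_representative_all: float | None = None
    p_values: dict = field(default_factory=dict)
    size_class: dict = field(default_factory=dict)
    tags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "r_standard_total": self.r_standard_total,
            "r_standard_dynamic": self.r_standard_dynamic,
            "r_representative_dynamic": self.r_representative_dynamic,
            "r_representative_all": self.r_representative_all,
            "p_values": self.p_values,
            "size_class": self.size_class,
            "tags": self.tags,
        }

    def strongest_representative_r(self) -> float | None:
        """Single summary r: the representative variant with larger |r|."""
        cands = [
            r
            for r in (self.r_representative_dynamic, self.r_representative_all)
            if r is not None
        ]
        return max(cands, key=abs) if cands else None


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | str:
    if x.size < 3:
        return "insufficient"
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return "zero_rank_variance"
    r, p = stats.spearmanr(x, y)
    if not np.isfinite(r):
        return "zero_rank_variance"
    return float(r), float(p)


def correlations(
    points: np.ndarray,
    reps: list[RepresentativePoint],
    mode: str,
    dynamic_cutoff: float = _DYNAMIC_EDGE,
) -> CorrelationReport:
    """Standard (all points / dynamic range) and representative Spearman r.

    ``r_representative_all`` is computed only in group mode and only when
    upper-region representatives exist.  Ties get average ranks and
    p-values come from the asymptotic approximation.
    """
    pts = np.asarray(points, dtype=float)
    rep = CorrelationReport()

    def put(name: str, x: np.ndarray, y: np.ndarray, insufficient_tag: str) -> None:
        res = _spearman(x, y)
        if isinstance(res, str):
            rep.tags[name] = insufficient_tag if res == "insufficient" else res
            return
        r, p = res
        setattr(rep, name, r)
        rep.p_values[name] = p
        rep.size_class[name] = correlation_size_class(r)

    put("r_standard_total", pts[:, 1], pts[:, 0], "insufficient_points")
    dyn = pts[pts[:, 1] < dynamic_cutoff]
    put("r_standard_dynamic", dyn[:, 1], dyn[:, 0], "insufficient_points")

    rdyn = [q for q in reps if q.region == "dynamic"]
    put(
        "r_representative_dynamic",
        np.array([q.a1_avg for q in rdyn]),
        np.array([q.p_avg for q in rdyn]),
        "insufficient_reps",
    )
    if mode == "group" and any(q.region == "upper" for q in reps):
        put(
            "r_representative_all",
            np.array([q.a1_avg for q in reps]),
            np.array([q.p_avg for q in reps]),
            "insufficient_reps",
        )
    return rep
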