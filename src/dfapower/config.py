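"""Pipeline configuration: every analysis constant in one validated place.

Defaults are the canonical values of the method: 5% artifact ceiling,
minutes 5-20 crop, 90% pedaling, 50% dynamic-range share, 120-s windows
on a 5-s grid with box sizes 4-16, smoothness-priors lambda 500, 8/9+5
segmentation bins capped at 1.2/1.8, representative minima 8/10, 10-day
groups of at least 4 workouts, R^2 gate 0.75, 10-min ESS steps with a
30-s rolling average.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .cohort import FilterConfig
from .dfa_windows import DfaConfig
from .monitoring import EssConfig
from .preprocess import ArtifactParams, DetrendParams

__all__ = ["PipelineConfig"]


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    # artifact detection
    local_window_beats: int = 11
    rel_threshold: float = 0.25
    abs_threshold_ms: float = 20.0
    # detrending
    detrend_lambda: float = 500.0
    # windowed DFA
    n_min: int = 4
    n_max: int = 16
    window_s: float = 120.0
    grid_s: float = 5.0
    min_beats: int = 32
    bias_correction: bool = True
    # quality filters
    max_artifact_fraction: float = 0.05
    crop_start_s: float = 300.0
    crop_end_s: float = 1200.0
    min_pedaling_fraction: float = 0.90
    min_dynamic_fraction: float = 0.50
    dynamic_cutoff_a1: float = 1.0
    # representatives
    rep_min_single: int = 8
    rep_min_group: int = 10
    # model fits
    fit_gate: float = 0.75
    fit_region: str = "all"  # "all" | "dynamic"
    # grouping
    group_window_days: int = 10
    group_min_workouts: int = 4
    # monitoring
    ess_step_s: float = 600.0
    ess_mov_avg_s: float = 30.0
    trend_window_days: int = 10

    # ---- views onto the per-module parameter objects ----

    def artifact_params(self) -> ArtifactParams:
        return ArtifactParams(
            self.local_window_beats, self.rel_threshold, self.abs_threshold_ms
        )

    def detrend_params(self) -> DetrendParams:
        return DetrendParams(self.detrend_lambda)

    def dfa_config(self) -> DfaConfig:
        return DfaConfig(
            self.n_min,
            self.n_max,
            self.window_s,
            self.grid_s,
            self.min_beats,
            self.bias_correction,
        )

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            self.max_artifact_fraction,
            self.crop_start_s,
            self.crop_end_s,
            self.min_pedaling_fraction,
            self.min_dynamic_fraction,
            self.dynamic_cutoff_a1,
        )

    def ess_config(self, thresh: float) -> EssConfig:
        return EssConfig(thresh=thresh, step_s=self.ess_step_s, mov_avg_s=self.ess_mov_avg_s)

    # ---- file round-trip ----

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            yaml.safe_load(text)
            if path.suffix.lower() in {".yml", ".yaml"}
            else json.loads(text)
        )
        return cls.model_validate(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = self.model_dump()
        if path.suffix.lower() in {".yml", ".yaml"}:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2))
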