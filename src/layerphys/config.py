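"""Pipeline configuration: analysis windows, thresholds, boundaries, seeds."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .datatypes import DEFAULT_LAYER_BOUNDARIES, LayerBoundaryTable

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # analysis windows (s)
    response_delay_s: float = 0.5
    response_dur_s: float = 1.5
    baseline_dur_s: float = 1.5
    # unit QC
    refractory_ms: float = 1.0
    max_violation_rate: float = 0.005
    min_rate_hz: float = 0.1
    # optotagging
    optotag_search_window_ms: float = 25.0
    optotag_min_responsive_fraction: float = 0.5
    # burst analysis
    burst_isi_cutoff_ms: float = 5.0
    # inference
    n_resamples: int = 250
    alpha: float = 0.05
    seed: int = 0
    # simulation defaults
    n_units: int = 200
    n_trials: int = 40
    # behavior cohort defaults
    n_animals: int = 10
    vf_threshold_g: float = 0.6  # cohort-median 60% withdrawal force
    vf_threshold_sigma: float = 0.25  # lognormal inter-animal spread
    vf_slope: float = 3.0  # psychometric slope per decade of force
    vf_laser_shift: float = 4.0  # >1: laser lowers the threshold (hypersensitivity)
    vf_n_per_filament: int = 5
    place_duration_s: float = 1200.0
    place_dt_s: float = 1.0
    place_p_stay_baseline: float = 0.95
    place_p_stay_conditioned: float = 0.8  # paired-chamber stay prob. under stimulation
    # anatomy
    layer_boundaries: list = field(
        default_factory=lambda: [list(iv) for iv in DEFAULT_LAYER_BOUNDARIES.intervals]
    )

    def __post_init__(self) -> None:
        for name in (
            "response_delay_s", "response_dur_s", "baseline_dur_s", "refractory_ms",
            "max_violation_rate", "min_rate_hz", "burst_isi_cutoff_ms", "alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def boundaries(self) -> LayerBoundaryTable:
        return LayerBoundaryTable([(str(l), float(a), float(b))
                                   for l, a, b in self.layer_boundaries])

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
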