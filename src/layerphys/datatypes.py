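"""Core in-memory containers shared across the analysis modules.

Times are stored in seconds as 64-bit floats throughout; on-disk columns
carry explicit unit suffixes (``_s``, ``_um``, ``_mW``, ``_g``, ``_us``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Closed vocabulary of stimulus conditions: laser-only (L), mechanical-only
#: (M), combined mechanical + laser (ML), and brief optotagging pulses.
CONDITIONS = ("L", "M", "ML", "PULSE")


@dataclass
class Unit:
    """One sorted single unit: spike times plus probe/waveform metadata."""

    unit_id: str
    spike_times: np.ndarray  # seconds, strictly increasing
    depth_um: float | None = None
    channel: int | None = None
    trough_peak_us: float | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)
        if self.spike_times.ndim != 1:
            raise ValueError(f"unit {self.unit_id}: spike_times must be 1-D")
        if np.any(np.diff(self.spike_times) < 0):
            raise ValueError(f"unit {self.unit_id}: spike_times not sorted")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


@dataclass
class SpikeTrainSet:
    """A recording's worth of curated single units."""

    units: list[Unit]
    recording_duration: float
    sampling_rate: float = float("nan")

    def __post_init__(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate unit_id in SpikeTrainSet")
        if self.recording_duration <= 0:
            raise ValueError("recording_duration must be positive")
        for u in self.units:
            if u.n_spikes and (
                u.spike_times[0] < 0 or u.spike_times[-1] > self.recording_duration
            ):
                raise ValueError(
                    f"unit {u.unit_id}: spikes outside [0, recording_duration]"
                )

    def __len__(self) -> int:
        return len(self.units)

    def __getitem__(self, unit_id: str) -> Unit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]


_EVENT_COLUMNS = ["condition", "onset_s", "duration_s", "laser_power_mW", "force_g"]


@dataclass
class EventTable:
    """Per-trial stimulus records; the alignment reference for all windows.

    Wraps a DataFrame with columns ``condition``, ``onset_s``, ``duration_s``
    and optional ``laser_power_mW`` / ``force_g``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy().reset_index(drop=True)
        for col in ("condition", "onset_s", "duration_s"):
            if col not in df.columns:
                raise ValueError(f"EventTable missing required column {col!r}")
        bad = ~df["condition"].isin(CONDITIONS)
        if bad.any():
            rows = df.index[bad].tolist()
            raise ValueError(
                f"unknown condition value(s) {sorted(df.loc[bad, 'condition'].unique())} "
                f"in row(s) {rows}; allowed: {CONDITIONS}"
            )
        if (df["duration_s"] <= 0).any():
            rows = df.index[df["duration_s"] <= 0].tolist()
            raise ValueError(f"non-positive duration_s in row(s) {rows}")
        if np.any(np.diff(df["onset_s"].to_numpy()) < 0):
            raise ValueError("onsets must be non-decreasing")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def of_condition(self, condition: str) -> "EventTable":
        sub = self.df[self.df["condition"] == condition]
        if sub.empty:
            raise ValueError(f"no events of condition {condition!r}")
        return EventTable(sub)

    @property
    def conditions(self) -> list[str]:
        return [c for c in CONDITIONS if (self.df["condition"] == c).any()]

    def onsets(self, condition: str | None = None) -> np.ndarray:
        df = self.df if condition is None else self.of_condition(condition).df
        return df["onset_s"].to_numpy(dtype=float)


@dataclass
class AlignedResponses:
    """Spike times of one unit aligned to the onsets of one condition.

    ``baseline`` / ``response`` hold per-trial arrays of spike times relative
    to stimulus onset, restricted to the baseline window [-baseline_dur, 0)
    and the response window [delay, delay + response_dur) respectively.
    """

    unit_id: str
    condition: str
    baseline: list[np.ndarray]
    response: list[np.ndarray]
    window: "object"  # WindowSpec; kept loose to avoid an import cycle

    @property
    def n_trials(self) -> int:
        return len(self.response)

    def counts(self, which: str) -> np.ndarray:
        """Per-trial spike counts in the requested window."""
        trials = self._trials(which)
        return np.array([t.size for t in trials], dtype=np.int64)

    def _trials(self, which: str) -> list[np.ndarray]:
        if which == "baseline":
            return self.baseline
        if which == "response":
            return self.response
        raise ValueError("which must be 'baseline' or 'response'")


@dataclass
class UnitConditionMetrics:
    """Per unit x condition response quantities."""

    unit_id: str
    condition: str
    r_base_hz: float
    r_stim_hz: float
    mi: float  # NaN when both rates are zero
    rp: float
    bp: float  # NaN when no spiking events in the response windows
    n_trials: int


@dataclass
class ModulationCall:
    """Per unit x condition significance outcome."""

    unit_id: str
    condition: str
    p_count: float  # NaN if untestable
    p_timing: float  # NaN if untestable
    significant: bool
    direction: str  # enhanced | suppressed | timing_only | none
    delta_count: float  # mean (response - baseline) spikes/trial


@dataclass
class PsychometricCurve:
    """Force -> withdrawal-probability mapping with stop-rule censoring."""

    forces_g: np.ndarray
    withdrawal_prob: np.ndarray
    censored: np.ndarray  # True where untested due to the stop rule (prob imputed 1.0)
    n_trials: np.ndarray

    def __post_init__(self) -> None:
        self.forces_g = np.asarray(self.forces_g, dtype=float)
        self.withdrawal_prob = np.asarray(self.withdrawal_prob, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        self.n_trials = np.asarray(self.n_trials, dtype=int)
        if np.any(np.diff(self.forces_g) <= 0):
            raise ValueError("forces must be strictly ascending")
        if self.censored.any():
            first = int(np.argmax(self.censored))
            if not self.censored[first:].all():
                raise ValueError("censored forces must be contiguous at the high end")


@dataclass
class PlaceSession:
    """Chamber occupancy (seconds) for one place-preference session."""

    time_paired_s: float
    time_unpaired_s: float
    time_neutral_s: float = 0.0
    label: str = "baseline"

    def __post_init__(self) -> None:
        for v in (self.time_paired_s, self.time_unpaired_s, self.time_neutral_s):
            if v < 0:
                raise ValueError("occupancy times must be non-negative")


@dataclass
class LayerBoundaryTable:
    """Ordered (label, [upper, lower) depth in um) cortical layer intervals."""

    intervals: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_lower = -np.inf
        for label, upper, lower in self.intervals:
            if lower <= upper:
                raise ValueError(f"layer {label}: empty interval [{upper}, {lower})")
            if upper < prev_lower:
                raise ValueError("layer intervals must be disjoint and ascending")
            prev_lower = lower


#: Default boundaries; consistent with example unit depths (an L6 unit at
#: 1205 um, an L5 unit at 589 um). Real use requires histology-derived values.
DEFAULT_LAYER_BOUNDARIES = LayerBoundaryTable(
    [
        ("L2/3", 100.0, 350.0),
        ("L4", 350.0, 500.0),
        ("L5", 500.0, 900.0),
        ("L6", 900.0, 1300.0),
    ]
)
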