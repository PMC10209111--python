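"""Unit quality control, optotagging, and anatomical assignment.

QC accepts curated single units with a refractory-violation fraction below
0.5% (1 ms refractory period) and an overall rate above 0.1 Hz. Optotagged
units are identified by low-latency (< 9.5 ms), low-jitter (SD < 3 ms for
L5, < 2 ms for L6-CT populations) first-spike responses to brief laser
pulses; putative fast-spiking units (waveform peak-to-second-trough
latency < 215 us) are excluded from the optotagged sets. Cortical units
are registered to histological layer borders by depth; thalamic VPL units
are assigned by the contiguous channel range containing mechanically
responsive units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import EventTable, LayerBoundaryTable, Unit

__all__ = [
    "QCResult",
    "LatencyStats",
    "qc_unit",
    "first_spike_latency_stats",
    "classify_optotagged",
    "is_fast_spiking",
    "assign_layer",
    "select_vpl_channel_range",
]

JITTER_THRESHOLDS_MS = {"L5": 3.0, "L6CT": 2.0}
LATENCY_THRESHOLD_MS = 9.5
FS_TROUGH_PEAK_US = 215.0


@dataclass(frozen=True)
class QCResult:
    passed: bool
    violation_rate: float
    overall_rate_hz: float
    reasons: tuple[str, ...] = field(default_factory=tuple)


def qc_unit(
    unit: Unit,
    recording_duration: float,
    refractory_ms: float = 1.0,
    max_violation_rate: float = 0.005,
    min_rate_hz: float = 0.1,
) -> QCResult:
    """Refractory-violation and minimum-rate quality control."""
    if recording_duration <= 0:
        raise ValueError("recording duration must be positive")
    if unit.n_spikes < 2:
        return QCResult(False, float("nan"), unit.n_spikes / recording_duration,
                        ("too_few_spikes",))
    isis = np.diff(unit.spike_times)
    violation_rate = float((isis < refractory_ms / 1000.0).mean())
    rate = unit.n_spikes / recording_duration
    reasons = []
    if violation_rate >= max_violation_rate:
        reasons.append("refractory")
    if rate <= min_rate_hz:
        reasons.append("rate")
    return QCResult(not reasons, violation_rate, rate, tuple(reasons))


@dataclass(frozen=True)
class LatencyStats:
    """First-spike latency statistics over laser pulses."""

    mean_ms: float  # NaN when no responsive pulses
    sd_ms: float  # NaN when < 2 responsive pulses
    responsive_fraction: float
    n_pulses: int


def first_spike_latency_stats(
    unit: Unit,
    pulse_events: EventTable,
    search_window_ms: float = 25.0,
    min_pulses: int = 10,
) -> LatencyStats:
    """Latency to first evoked spike within a search window after each pulse.

    Mean and sample SD (n-1) are taken over responsive pulses only;
    ``responsive_fraction`` counts responsive pulses over all pulses.
    """
    onsets = pulse_events.onsets("PULSE")
    if onsets.size < min_pulses:
        raise ValueError(f"need >= {min_pulses} pulse trials, got {onsets.size}")
    t = unit.spike_times
    win = search_window_ms / 1000.0
    latencies = []
    for onset in onsets:
        i = np.searchsorted(t, onset, side="left")
        if i < t.size and t[i] < onset + win:
            latencies.append((t[i] - onset) * 1000.0)
    frac = len(latencies) / onsets.size
    if not latencies:
        return LatencyStats(float("nan"), float("nan"), 0.0, onsets.size)
    lat = np.asarray(latencies)
    sd = float(lat.std(ddof=1)) if lat.size > 1 else float("nan")
    return LatencyStats(float(lat.mean()), sd, frac, onsets.size)


def classify_optotagged(
    stats: LatencyStats,
    population: str,
    min_responsive_fraction: float = 0.5,
    latency_threshold_ms: float = LATENCY_THRESHOLD_MS,
) -> bool:
    """Tag a unit as belonging to the opsin-expressing population.

    Requires mean first-spike latency < 9.5 ms and jitter (SD) below the
    population-specific threshold (3 ms L5, 2 ms L6-CT), with at least
    ``min_responsive_fraction`` of pulses evoking a spike.
    """
    if population not in JITTER_THRESHOLDS_MS:
        raise ValueError(f"unknown population {population!r}; expected L5 or L6CT")
    if np.isnan(stats.mean_ms) or np.isnan(stats.sd_ms):
        return False
    if stats.responsive_fraction < min_responsive_fraction:
        return False
    return (
        stats.mean_ms < latency_threshold_ms
        and stats.sd_ms < JITTER_THRESHOLDS_MS[population]
    )


def is_fast_spiking(trough_peak_us: float | None) -> bool | None:
    """Narrow-waveform (putative fast-spiking) flag; None when metric missing."""
    if trough_peak_us is None or np.isnan(trough_peak_us):
        return None
    return trough_peak_us < FS_TROUGH_PEAK_US


def assign_layer(depth_um: float, boundaries: LayerBoundaryTable) -> str:
    """Label of the layer interval containing the depth; 'unassigned' outside."""
    if depth_um < 0:
        raise ValueError("depth must be non-negative")
    for label, upper, lower in boundaries.intervals:
        if upper <= depth_um < lower:
            return label
    return "unassigned"


def select_vpl_channel_range(
    channel_significance: dict[int, bool],
) -> tuple[int, int] | None:
    """Contiguous channel span hosting mechanically responsive units.

    ``channel_significance`` maps channel index -> whether any unit on that
    channel is significantly modulated by M or ML. Returns the inclusive
    [first, last] significant channel interval (units on channels inside it
    are assigned to VPL), or None when no channel qualifies.
    """
    sig = sorted(ch for ch, flag in channel_significance.items() if flag)
    if not sig:
        return None
    return (sig[0], sig[-1])
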