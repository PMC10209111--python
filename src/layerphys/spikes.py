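"""Window alignment and per-unit spike-train response quantities.

The analysis convention: for every 5 s stimulus, spiking is quantified in a
1.5 s response window that starts 500 ms after stimulus onset (the delay
discards the transient at onset and the mechanical actuator lag), and in a
1.5 s baseline window immediately preceding onset. Windows are half-open so
that every spike in a trial span falls in exactly one of baseline, delay
gap, response, or post-response.

Quantities:
  mean rate r      = (sum of counts / n trials) / window duration
  modulation index = (r_stim - r_base) / (r_stim + r_base), in [-1, 1]
  response prob.   = fraction of trials with >= 1 response-window spike
  burst prob.      = bursts / (bursts + single-spike events), bursts being
                     runs of spikes with inter-spike intervals < 5 ms
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AlignedResponses, EventTable, Unit

__all__ = [
    "WindowSpec",
    "align_spikes",
    "mean_rate",
    "modulation_index",
    "response_probability",
    "parse_burst_events",
    "burst_probability",
    "classify_burst_regime",
    "isi_cdf",
    "population_median_cdf",
    "pressure_derivative",
]


@dataclass(frozen=True)
class WindowSpec:
    """Analysis windows relative to stimulus onset (seconds)."""

    response_delay_s: float = 0.5
    response_dur_s: float = 1.5
    baseline_dur_s: float = 1.5

    def __post_init__(self) -> None:
        if min(self.response_delay_s, self.response_dur_s, self.baseline_dur_s) <= 0:
            raise ValueError("window parameters must be positive")

    @property
    def response_start(self) -> float:
        return self.response_delay_s

    @property
    def response_end(self) -> float:
        return self.response_delay_s + self.response_dur_s


def align_spikes(
    unit: Unit,
    events: EventTable,
    condition: str,
    window: WindowSpec = WindowSpec(),
) -> AlignedResponses:
    """Align a unit's spikes to the onsets of one condition.

    Baseline sample: spikes in [onset - baseline_dur, onset); response
    sample: spikes in [onset + delay, onset + delay + dur). Both half-open,
    so a spike exactly at onset belongs to neither. The same windows are
    applied to every condition, laser-only trials included.
    """
    onsets = events.onsets(condition)
    t = unit.spike_times
    baseline, response = [], []
    for onset in onsets:
        lo = np.searchsorted(t, onset - window.baseline_dur_s, side="left")
        hi = np.searchsorted(t, onset, side="left")
        baseline.append(t[lo:hi] - onset)
        lo = np.searchsorted(t, onset + window.response_start, side="left")
        hi = np.searchsorted(t, onset + window.response_end, side="left")
        response.append(t[lo:hi] - onset)
    return AlignedResponses(unit.unit_id, condition, baseline, response, window)


def mean_rate(aligned: AlignedResponses, which: str) -> float:
    """Mean firing rate (Hz) in the baseline or response window."""
    if aligned.n_trials == 0:
        raise ValueError("need at least one trial")
    counts = aligned.counts(which)
    dur = (
        aligned.window.baseline_dur_s
        if which == "baseline"
        else aligned.window.response_dur_s
    )
    return float(counts.mean() / dur)


def modulation_index(r_stim: float, r_base: float) -> float:
    """(r_stim - r_base) / (r_stim + r_base); NaN when both rates are zero."""
    if r_stim < 0 or r_base < 0:
        raise ValueError("rates must be non-negative")
    if r_stim == 0 and r_base == 0:
        return float("nan")
    return (r_stim - r_base) / (r_stim + r_base)


def response_probability(aligned: AlignedResponses) -> float:
    """Fraction of trials with at least one response-window spike."""
    if aligned.n_trials == 0:
        raise ValueError("need at least one trial")
    counts = aligned.counts("response")
    return float((counts > 0).mean())


def parse_burst_events(
    spike_times_s: np.ndarray, isi_cutoff_ms: float = 5.0
) -> list[tuple[str, np.ndarray]]:
    """Partition a sorted spike train into burst and single-spike events.

    Consecutive spikes whose inter-spike interval is strictly below the
    cutoff are merged into one burst event; an isolated spike is a single
    event. Returns (kind, spike indices) per event, kind in {"burst",
    "single"}.
    """
    t = np.asarray(spike_times_s, dtype=float)
    if t.size == 0:
        return []
    if np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    cutoff = isi_cutoff_ms / 1000.0
    # new event wherever the preceding ISI is >= cutoff; first spike always starts one
    breaks = np.flatnonzero(np.diff(t) >= cutoff) + 1
    groups = np.split(np.arange(t.size), breaks)
    return [("burst" if g.size > 1 else "single", g) for g in groups]


def burst_probability(
    aligned: AlignedResponses, isi_cutoff_ms: float = 5.0
) -> float:
    """Fraction of response-window spiking events that are bursts.

    Events are parsed per trial (ISIs never bridge trials) and pooled
    across trials. NaN when the unit emitted no response-window spikes.
    """
    n_burst = n_total = 0
    for trial in aligned.response:
        for kind, _ in parse_burst_events(trial, isi_cutoff_ms):
            n_total += 1
            n_burst += kind == "burst"
    if n_total == 0:
        return float("nan")
    return n_burst / n_total


def classify_burst_regime(bp: float, threshold: float = 0.1) -> str:
    """'bursty' when BP strictly exceeds the threshold, else 'tonic'."""
    if np.isnan(bp):
        raise ValueError("BP undefined")
    return "bursty" if bp > threshold else "tonic"


def isi_cdf(
    aligned: AlignedResponses, bin_ms: float = 1.0, max_ms: float = 500.0
) -> np.ndarray | None:
    """Empirical CDF of within-trial response-window ISIs on a 1 ms grid.

    Returns CDF values at bin edges bin_ms, 2*bin_ms, ..., max_ms (fraction
    of ISIs <= edge), or None when the unit has no ISIs (fewer than two
    spikes in every trial).
    """
    isis = [np.diff(trial) for trial in aligned.response if trial.size >= 2]
    if not isis:
        return None
    isi_ms = np.concatenate(isis) * 1000.0
    edges = np.arange(bin_ms, max_ms + bin_ms / 2, bin_ms)
    # tiny tolerance so ISIs nominally equal to an edge land in that bin
    return np.searchsorted(np.sort(isi_ms), edges + 1e-6, side="right") / isi_ms.size


def population_median_cdf(unit_cdfs: list[np.ndarray | None]) -> np.ndarray:
    """Median across units per bin of per-unit ISI CDFs (None entries skipped)."""
    kept = [c for c in unit_cdfs if c is not None]
    if not kept:
        raise ValueError("no units with defined ISI CDFs")
    return np.median(np.vstack(kept), axis=0)


def pressure_derivative(trace: np.ndarray, dt_s: float = 1.0) -> np.ndarray:
    """First temporal derivative of a uniformly sampled pressure trace.

    Central differences in the interior, one-sided at the edges.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValueError("need at least two samples")
    return np.gradient(trace, dt_s)
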