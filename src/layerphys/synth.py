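"""Synthetic sessions with known ground truth.

The generators emulate the statistical structure the analysis assumes,
not the biophysics that produces it:

* spike trains are Poisson cluster processes — event onsets are Poisson
  at the unit's baseline rate, multiplied by a per-condition gain inside
  the stimulus window (after the 500 ms delay); each event expands into a
  burst with probability ``burst_prob`` (geometric number of extra spikes
  at a fixed short intra-burst interval);
* optotagged units emit one additional low-jitter spike per laser pulse
  with probability ``reliability`` at a truncated-normal latency;
* von Frey withdrawal is per-trial Bernoulli under a logistic psychometric
  function of log force, whose threshold is divided by ``laser_shift`` on
  laser-on trials (shift > 1 models hypersensitivity);
* place sessions are a paired/neutral/unpaired Markov chain sampled on a
  fixed time step, with uniform positions inside the occupied chamber.

All generators are deterministic given the seed; per-unit streams are
spawned from one root SeedSequence so results do not depend on unit order.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .datatypes import EventTable, SpikeTrainSet, Unit
from .behavior import DEFAULT_FILAMENTS_G

__all__ = [
    "OptotagSpec",
    "UnitSpec",
    "GroundTruthManifest",
    "make_default_protocol",
    "default_population",
    "simulate_session",
    "simulate_vonfrey",
    "simulate_place_session",
    "place_stationary_pi",
    "PLACE_ARENA",
]


@dataclass(frozen=True)
class OptotagSpec:
    latency_mean_ms: float
    latency_sd_ms: float
    reliability: float

    def __post_init__(self) -> None:
        if self.latency_sd_ms <= 0:
            raise ValueError("latency SD must be positive")
        if not 0 <= self.reliability <= 1:
            raise ValueError("reliability must be in [0, 1]")


@dataclass(frozen=True)
class UnitSpec:
    """Ground-truth parameters of one simulated unit."""

    unit_id: str
    baseline_rate_hz: float
    gain: dict = field(default_factory=lambda: {"L": 1.0, "M": 1.0, "ML": 1.0})
    burst_prob: float = 0.0
    burst_size_mean: float = 1.5  # mean extra spikes per burst (geometric)
    intra_burst_isi_ms: float = 2.5
    optotag: OptotagSpec | None = None
    depth_um: float | None = None
    channel: int | None = None
    trough_peak_us: float | None = None

    def __post_init__(self) -> None:
        if self.baseline_rate_hz < 0:
            raise ValueError("baseline rate must be non-negative")
        if any(g < 0 for g in self.gain.values()):
            raise ValueError("gains must be non-negative")
        if not 0 <= self.burst_prob <= 1:
            raise ValueError("burst_prob must be in [0, 1]")
        if self.burst_size_mean < 1:
            raise ValueError("burst_size_mean must be >= 1")


@dataclass
class GroundTruthManifest:
    """Everything needed to regenerate a session bit-exactly."""

    seed: int
    specs: list[UnitSpec]
    protocol_params: dict

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "protocol_params": self.protocol_params,
            "specs": [asdict(s) for s in self.specs],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def make_default_protocol(
    n_trials: int = 40,
    stim_duration_s: float = 5.0,
    n_pulses: int = 40,
    pulse_duration_s: float = 0.010,
    start_s: float = 10.0,
) -> EventTable:
    """Interleaved M / ML / L trials plus a terminal optotagging pulse train.

    Onset-to-onset spacing follows the stimulation protocol: 60 s from M to
    ML, 30 s otherwise; stimuli last 5 s. The pulse train (10 ms pulses at
    1 Hz) follows the last trial.
    """
    rows = []
    t = start_s
    for _ in range(n_trials):
        rows.append(("M", t, stim_duration_s))
        t += 60.0
        rows.append(("ML", t, stim_duration_s))
        t += 30.0
        rows.append(("L", t, stim_duration_s))
        t += 30.0
    for _ in range(n_pulses):
        rows.append(("PULSE", t, pulse_duration_s))
        t += 1.0
    df = pd.DataFrame(rows, columns=["condition", "onset_s", "duration_s"])
    return EventTable(df)


def default_population(
    n_units: int = 200,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    frac_enhanced: dict | None = None,
    frac_suppressed: dict | None = None,
    tagged_fraction: float = 0.0,
) -> list[UnitSpec]:
    """A thalamic-relay-like unit population.

    Baseline rates are lognormal (median 4 Hz, sigma 0.6 on the log);
    burstiness varies across units (burst_prob uniform on [0, 0.5]).
    Default per-condition enhanced/suppressed fractions mirror a combined
    mechanical + corticothalamic-drive session: most units enhanced in ML,
    fewer in M, with a small suppressed minority.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    frac_enhanced = frac_enhanced or {"L": 0.5, "M": 0.4, "ML": 0.75}
    frac_suppressed = frac_suppressed or {"L": 0.1, "M": 0.1, "ML": 0.1}
    specs = []
    for i in range(n_units):
        gain = {}
        for cond in ("L", "M", "ML"):
            u = rng.uniform()
            if u < frac_enhanced[cond]:
                gain[cond] = float(np.exp(rng.uniform(np.log(1.6), np.log(4.0))))
            elif u < frac_enhanced[cond] + frac_suppressed[cond]:
                gain[cond] = float(np.exp(rng.uniform(np.log(0.1), np.log(0.5))))
            else:
                gain[cond] = 1.0
        tag = None
        if rng.uniform() < tagged_fraction:
            tag = OptotagSpec(
                latency_mean_ms=float(rng.uniform(4.0, 8.0)),
                latency_sd_ms=float(rng.uniform(0.5, 1.5)),
                reliability=float(rng.uniform(0.7, 1.0)),
            )
        specs.append(
            UnitSpec(
                unit_id=f"u{i:04d}",
                baseline_rate_hz=float(np.exp(rng.normal(np.log(4.0), 0.6))),
                gain=gain,
                burst_prob=float(rng.uniform(0.0, 0.5)),
                optotag=tag,
                depth_um=float(rng.uniform(100.0, 1300.0)),
                channel=int(rng.integers(0, 64)),
                trough_peak_us=float(rng.uniform(250.0, 600.0)),
            )
        )
    return specs


def _piecewise_poisson_events(
    rng: np.random.Generator,
    duration: float,
    base_rate: float,
    windows: list[tuple[float, float, float]],
) -> np.ndarray:
    """Event onsets of a piecewise-constant-rate Poisson process.

    ``windows`` are disjoint (start, end, rate) overrides; the base rate
    applies everywhere else.
    """
    segments = []
    cursor = 0.0
    for start, end, rate in sorted(windows):
        if start > cursor:
            segments.append((cursor, start, base_rate))
        segments.append((start, min(end, duration), rate))
        cursor = min(end, duration)
    if cursor < duration:
        segments.append((cursor, duration, base_rate))
    out = []
    for start, end, rate in segments:
        span = end - start
        if span <= 0 or rate <= 0:
            continue
        n = rng.poisson(rate * span)
        if n:
            out.append(start + rng.uniform(0.0, span, size=n))
    if not out:
        return np.array([])
    return np.sort(np.concatenate(out))


def _expand_bursts(rng: np.random.Generator, events: np.ndarray, spec: UnitSpec) -> np.ndarray:
    if events.size == 0 or spec.burst_prob == 0.0:
        return events
    is_burst = rng.uniform(size=events.size) < spec.burst_prob
    isi = spec.intra_burst_isi_ms / 1000.0
    extras = []
    n_extra = rng.geometric(1.0 / spec.burst_size_mean, size=int(is_burst.sum()))
    for t, k in zip(events[is_burst], n_extra):
        extras.append(t + isi * np.arange(1, k + 1))
    return np.sort(np.concatenate([events] + extras))


def _enforce_dead_time(t: np.ndarray, dead_s: float) -> np.ndarray:
    """Impose an absolute refractory period by dropping trailing spikes of
    sub-dead-time pairs (iterated to convergence; removes <1% of spikes at
    realistic rates)."""
    while t.size > 1:
        bad = np.flatnonzero(np.diff(t) < dead_s)
        if bad.size == 0:
            break
        # drop the second member of each violating pair, one per run
        drop = bad[np.insert(np.diff(bad) > 1, 0, True)] + 1
        t = np.delete(t, drop)
    return t


def simulate_session(
    specs: list[UnitSpec],
    protocol: EventTable,
    seed: int,
    response_delay_s: float = 0.5,
    dead_time_ms: float = 1.5,
) -> tuple[SpikeTrainSet, EventTable, GroundTruthManifest]:
    """Simulate a full recording session from unit specs and a protocol.

    ``dead_time_ms`` imposes an absolute refractory period (spikes closer
    than this to their predecessor are dropped), matching the curated-unit
    assumption of downstream quality control.
    """
    if not specs:
        raise ValueError("empty spec list")
    df = protocol.df
    duration = float((df["onset_s"] + df["duration_s"]).max() + 30.0)
    root = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in root.spawn(len(specs))]
    pulse_onsets = (
        df.loc[df["condition"] == "PULSE", "onset_s"].to_numpy(dtype=float)
    )
    units = []
    for spec, rng in zip(specs, streams):
        windows = []
        for cond in ("L", "M", "ML"):
            g = spec.gain.get(cond, 1.0)
            if g == 1.0:
                continue
            sub = df[df["condition"] == cond]
            for onset, dur in zip(sub["onset_s"], sub["duration_s"]):
                windows.append(
                    (onset + response_delay_s, onset + dur, spec.baseline_rate_hz * g)
                )
        events = _piecewise_poisson_events(rng, duration, spec.baseline_rate_hz, windows)
        spikes = _expand_bursts(rng, events, spec)
        if spec.optotag is not None and pulse_onsets.size:
            responds = rng.uniform(size=pulse_onsets.size) < spec.optotag.reliability
            lat = rng.normal(
                spec.optotag.latency_mean_ms, spec.optotag.latency_sd_ms,
                size=pulse_onsets.size,
            )
            lat = np.abs(lat) / 1000.0  # truncate at zero by reflection
            spikes = np.sort(np.concatenate([spikes, pulse_onsets[responds] + lat[responds]]))
        spikes = spikes[(spikes >= 0) & (spikes <= duration)]
        spikes = _enforce_dead_time(spikes, dead_time_ms / 1000.0)
        units.append(
            Unit(spec.unit_id, spikes, depth_um=spec.depth_um, channel=spec.channel,
                 trough_peak_us=spec.trough_peak_us)
        )
    trains = SpikeTrainSet(units, recording_duration=duration, sampling_rate=30030.0)
    manifest = GroundTruthManifest(
        seed=seed, specs=list(specs),
        protocol_params={"n_events": len(df), "duration_s": duration,
                         "response_delay_s": response_delay_s},
    )
    return trains, protocol, manifest


# -- behavior generators -----------------------------------------------------

#: Offset making the planted threshold the 60% withdrawal force (logit 0.6).
_LOGIT_060 = float(np.log(0.6 / 0.4))


def vonfrey_probabilities(
    forces_g: np.ndarray, threshold_g: float, slope: float, laser_shift: float = 1.0,
    laser_on: bool = False,
) -> np.ndarray:
    """Withdrawal probability under the logistic psychometric model.

    ``threshold_g`` is the force evoking withdrawal in 60% of trials (the
    assay's reported threshold); ``slope`` is per decade of force. On
    laser-on trials the threshold is divided by ``laser_shift``.
    """
    from scipy.special import expit

    th = threshold_g / laser_shift if laser_on else threshold_g
    x = slope * (np.log10(np.asarray(forces_g, dtype=float)) - np.log10(th))
    return expit(x + _LOGIT_060)


def simulate_vonfrey(
    psychometric: dict,
    filaments=DEFAULT_FILAMENTS_G,
    n_per_filament: int = 5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    laser_on: bool = False,
) -> pd.DataFrame:
    """Trial-level von Frey outcomes with the ascending stop rule.

    ``psychometric`` needs keys ``threshold_g``, ``slope`` and optionally
    ``laser_shift``. Once a filament withdraws on all trials, stronger
    filaments are emitted as censored rows (no trials conducted).
    """
    filaments = np.asarray(filaments, dtype=float)
    if np.any(np.diff(filaments) <= 0):
        raise ValueError("filaments must be strictly ascending")
    if n_per_filament < 1:
        raise ValueError("n_per_filament must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    probs = vonfrey_probabilities(
        filaments, psychometric["threshold_g"], psychometric["slope"],
        psychometric.get("laser_shift", 1.0), laser_on,
    )
    rows = []
    stopped = False
    for force, p in zip(filaments, probs):
        if stopped:
            rows.append({"force_g": force, "trial": -1, "withdrawal": np.nan,
                         "censored": True, "laser": laser_on})
            continue
        outcomes = rng.uniform(size=n_per_filament) < p
        for j, w in enumerate(outcomes):
            rows.append({"force_g": force, "trial": j, "withdrawal": int(w),
                         "censored": False, "laser": laser_on})
        if outcomes.all():
            stopped = True
    return pd.DataFrame(rows)


#: Arena geometry (cm): paired chamber, neutral corridor, unpaired chamber.
PLACE_ARENA = {
    "paired": (0.0, 15.0, 0.0, 15.0),
    "neutral": (15.0, 23.0, 3.5, 11.5),
    "unpaired": (23.0, 38.0, 0.0, 15.0),
}


def simulate_place_session(
    p_stay_paired: float,
    p_stay_unpaired: float,
    duration_s: float,
    dt_s: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """(n, 2) position trace of a paired/neutral/unpaired Markov walk.

    The animal stays in an occupied chamber with the given per-step
    probability, otherwise moves to the neutral corridor, from which it
    enters either chamber with equal probability on the next step.
    Positions are uniform within the occupied region of ``PLACE_ARENA``.
    """
    for p in (p_stay_paired, p_stay_unpaired):
        if not 0 < p < 1:
            raise ValueError("stay probabilities must lie in (0, 1)")
    if dt_s >= duration_s:
        raise ValueError("dt must be smaller than the session duration")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration_s / dt_s))
    states = np.empty(n, dtype=object)
    state = "neutral"
    stay = {"paired": p_stay_paired, "unpaired": p_stay_unpaired}
    for i in range(n):
        states[i] = state
        if state == "neutral":
            state = "paired" if rng.uniform() < 0.5 else "unpaired"
        elif rng.uniform() >= stay[state]:
            state = "neutral"
    pos = np.empty((n, 2))
    for name, rect in PLACE_ARENA.items():
        mask = states == name
        k = int(mask.sum())
        if k:
            pos[mask, 0] = rng.uniform(rect[0], rect[1], size=k)
            pos[mask, 1] = rng.uniform(rect[2], rect[3], size=k)
    return pos


def place_stationary_pi(p_stay_paired: float, p_stay_unpaired: float) -> float:
    """Stationary preference index of the place chain (closed form).

    Occupancy of each chamber is proportional to 1/(1 - p_stay); the
    neutral corridor cancels out of the index.
    """
    wp = 1.0 / (1.0 - p_stay_paired)
    wu = 1.0 / (1.0 - p_stay_unpaired)
    return (wp - wu) / (wp + wu)
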