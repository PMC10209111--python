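"""Per unit x condition modulation decisions.

A unit counts as modulated in a condition when either of two tests is
significant at alpha = 0.05:

* a count test — two-sided Wilcoxon signed-rank on paired per-trial
  baseline vs response spike counts; and
* a timing test — a ZETA-style time-locked deviation statistic: the
  maximal mean-centred deviation of the pooled relative spike-time CDF
  from the time-uniform CDF over the response window, with an empirical
  null built from circular shifts of each trial's spike times by
  independent uniform offsets.

Direction (enhanced/suppressed) follows the sign of the mean count change
when the count test is significant; units significant only in timing are
reported as ``timing_only`` (count change plotted at zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AlignedResponses, ModulationCall
from .stats import wilcoxon_signed_rank

__all__ = [
    "paired_count_test",
    "timing_deviation_test",
    "classify_modulation",
    "modulation_call",
    "condition_proportions",
]


def paired_count_test(baseline_counts, response_counts) -> float:
    """Two-sided Wilcoxon signed-rank p for paired per-trial spike counts."""
    b = np.asarray(baseline_counts, dtype=float)
    r = np.asarray(response_counts, dtype=float)
    if b.shape != r.shape:
        raise ValueError("paired arrays must have equal length")
    return wilcoxon_signed_rank(r, b).p


def _deviation_stat(sorted_times: np.ndarray, span: float) -> float:
    """Max |mean-centred (ECDF - uniform CDF)| evaluated at the spike times."""
    n = sorted_times.size
    d = np.arange(1, n + 1) / n - sorted_times / span
    return float(np.abs(d - d.mean()).max())


@dataclass(frozen=True)
class TimingTestResult:
    statistic: float
    p: float
    n_spikes: int
    n_resamples: int


def timing_deviation_test(
    aligned: AlignedResponses,
    n_resamples: int = 250,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> TimingTestResult:
    """ZETA-style test for time-locked spiking within the response window.

    Pools relative spike times across trials, compares their empirical CDF
    with the uniform CDF over the window span, and calibrates the maximal
    mean-centred deviation against ``n_resamples`` circular shifts of each
    trial's spike times by independent uniform offsets. p carries the
    add-one correction, so the smallest attainable value is
    1/(n_resamples+1). Units with zero spikes in the span are untestable
    (statistic and p NaN).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    window = aligned.window
    span = window.response_dur_s
    trials = [t - window.response_start for t in aligned.response]
    counts = np.array([t.size for t in trials])
    pooled = np.concatenate(trials) if trials else np.array([])
    n = pooled.size
    if n == 0:
        return TimingTestResult(float("nan"), float("nan"), 0, n_resamples)
    stat = _deviation_stat(np.sort(pooled), span)
    trial_of_spike = np.repeat(np.arange(len(trials)), counts)
    offsets = rng.uniform(0.0, span, size=(n_resamples, len(trials)))
    shifted = (pooled[None, :] + offsets[:, trial_of_spike]) % span
    shifted.sort(axis=1)
    ecdf = np.arange(1, n + 1) / n
    d = ecdf[None, :] - shifted / span
    null = np.abs(d - d.mean(axis=1, keepdims=True)).max(axis=1)
    p = (1 + int((null >= stat).sum())) / (n_resamples + 1)
    return TimingTestResult(stat, p, n, n_resamples)


def classify_modulation(
    p_count: float,
    p_timing: float,
    delta_count: float,
    alpha: float = 0.05,
) -> tuple[bool, str]:
    """Combine the two tests into (significant, direction).

    enhanced / suppressed require a significant count test with the
    matching sign of the mean count change; timing_only marks units whose
    spike timing, but not count, changed.
    """
    count_ok = not np.isnan(p_count)
    timing_ok = not np.isnan(p_timing)
    if not count_ok and not timing_ok:
        raise ValueError("both tests undefined")
    count_sig = count_ok and p_count <= alpha
    timing_sig = timing_ok and p_timing <= alpha
    if count_sig and delta_count > 0:
        return True, "enhanced"
    if count_sig and delta_count < 0:
        return True, "suppressed"
    if timing_sig:
        return True, "timing_only"
    return False, "none"


def modulation_call(
    aligned: AlignedResponses,
    n_resamples: int = 250,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    alpha: float = 0.05,
) -> ModulationCall:
    """Run both tests on aligned responses and build the ModulationCall."""
    b = aligned.counts("baseline")
    r = aligned.counts("response")
    p_count = paired_count_test(b, r)
    timing = timing_deviation_test(aligned, n_resamples=n_resamples, rng=rng, seed=seed)
    delta = float((r - b).mean())
    significant, direction = classify_modulation(p_count, timing.p, delta, alpha)
    return ModulationCall(
        aligned.unit_id, aligned.condition, p_count, timing.p, significant, delta_count=delta,
        direction=direction,
    )


def condition_proportions(calls: list[ModulationCall]) -> "pd.DataFrame":
    """Enhanced/suppressed/timing_only/none fractions per condition.

    Returns a tidy table with counts and fractions; fractions sum to 1
    within each condition.
    """
    import pandas as pd

    if not calls:
        raise ValueError("no modulation calls")
    df = pd.DataFrame(
        {"condition": [c.condition for c in calls],
         "direction": [c.direction for c in calls]}
    )
    rows = []
    for cond, sub in df.groupby("condition", sort=False):
        n = len(sub)
        for direction in ("enhanced", "suppressed", "timing_only", "none"):
            k = int((sub["direction"] == direction).sum())
            rows.append(
                {"condition": cond, "direction": direction, "count": k,
                 "n": n, "fraction": k / n}
            )
    return pd.DataFrame(rows)
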