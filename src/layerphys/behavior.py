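"""Behavioral quantification: von Frey psychometrics, sensitization AUC,
place preference, and paw-lift intensity thresholds.

The von Frey assay applies an ascending series of calibrated filaments
(default eight, 0.04-2.0 g, five trials each) to the hindpaw. A stop rule
applies: once a filament evokes withdrawal on every trial, stronger
filaments are not tested; those untested forces are recorded as censored
and imputed a withdrawal probability of 1.0 (the conservative continuation
of an all-withdrawal filament), flagged so users can exclude them.

The mechanical threshold is the smallest force evoking withdrawal in 60%
of trials, interpolated on log10(force) between bracketing filaments (the
filament series is approximately geometric). Overall sensitivity is the
trapezoidal area under the withdrawal curve (AUC) on the linear force
axis; higher AUC means higher sensitivity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import PlaceSession, PsychometricCurve

__all__ = [
    "DEFAULT_FILAMENTS_G",
    "withdrawal_curve",
    "threshold_at",
    "sensitivity_auc",
    "preference_index",
    "occupancy_times",
    "paw_lift_threshold",
    "CENSORED_ABOVE_MAX",
]

#: Standard eight-filament ascending series, grams.
DEFAULT_FILAMENTS_G = (0.04, 0.07, 0.16, 0.4, 0.6, 1.0, 1.4, 2.0)

#: Sentinel returned by threshold_at when the curve never reaches the level.
CENSORED_ABOVE_MAX = float("inf")


def withdrawal_curve(trials: pd.DataFrame) -> PsychometricCurve:
    """Build the psychometric curve from trial-level von Frey outcomes.

    ``trials`` needs columns ``force_g`` and ``withdrawal`` (0/1) and may
    carry a ``censored`` flag for stop-rule rows (no trials conducted).
    Tested forces get withdrawals/trials; censored forces get probability
    1.0 with the censored flag set.
    """
    if trials.empty:
        raise ValueError("no trials")
    forces, probs, censored, ns = [], [], [], []
    stop_fired = False
    for force, grp in trials.groupby("force_g", sort=True):
        forces.append(float(force))
        is_censored = bool(grp.get("censored", pd.Series(False, index=grp.index)).all())
        if is_censored or stop_fired:
            probs.append(1.0)
            censored.append(True)
            ns.append(0)
            continue
        n = len(grp)
        p = float(grp["withdrawal"].mean())
        probs.append(p)
        censored.append(False)
        ns.append(n)
        if p == 1.0:
            stop_fired = True
    return PsychometricCurve(
        np.array(forces), np.array(probs), np.array(censored), np.array(ns)
    )


def threshold_at(curve: PsychometricCurve, level: float = 0.6) -> float:
    """Smallest force with withdrawal probability >= level.

    Interpolates on log10(force) between the bracketing filament pair when
    the level is crossed between filaments; returns the first filament's
    force if it already meets the level, and ``CENSORED_ABOVE_MAX`` (inf)
    when the curve (censored values included) never reaches the level.
    """
    f = curve.forces_g
    p = curve.withdrawal_prob
    if f.size == 0:
        raise ValueError("empty curve")
    if p[0] >= level:
        return float(f[0])
    idx = np.flatnonzero(p >= level)
    if idx.size == 0:
        return CENSORED_ABOVE_MAX
    i = int(idx[0])
    lo, hi = f[i - 1], f[i]
    plo, phi = p[i - 1], p[i]
    if phi == plo:
        return float(hi)
    frac = (level - plo) / (phi - plo)
    return float(10 ** (np.log10(lo) + frac * (np.log10(hi) - np.log10(lo))))


def sensitivity_auc(curve: PsychometricCurve, normalize: bool = False,
                    log_axis: bool = False) -> float:
    """Trapezoidal area under the withdrawal curve (probability * grams).

    Censored (imputed) points are included. ``normalize`` divides by the
    force range, giving a mean withdrawal probability; ``log_axis``
    integrates over log10(force) instead of force.
    """
    if curve.forces_g.size < 2:
        raise ValueError("need >= 2 forces")
    if curve.censored.all():
        raise ValueError("curve is entirely censored")
    x = np.log10(curve.forces_g) if log_axis else curve.forces_g
    auc = float(np.trapezoid(curve.withdrawal_prob, x))
    if normalize:
        auc /= float(x[-1] - x[0])
    return auc


def preference_index(time_paired_s: float, time_unpaired_s: float) -> float:
    """(paired - unpaired) / (paired + unpaired), in [-1, 1].

    +1 is full preference for, -1 full avoidance of, the laser-paired
    chamber. NaN when no time was spent in either chamber.
    """
    if time_paired_s < 0 or time_unpaired_s < 0:
        raise ValueError("occupancy times must be non-negative")
    total = time_paired_s + time_unpaired_s
    if total == 0:
        return float("nan")
    return (time_paired_s - time_unpaired_s) / total


def occupancy_times(
    positions: np.ndarray,
    dt_s: float,
    paired_rect: tuple[float, float, float, float],
    unpaired_rect: tuple[float, float, float, float],
    label: str = "baseline",
) -> PlaceSession:
    """Dwell times per chamber from a uniformly sampled (x, y) trace.

    Rectangles are (xmin, xmax, ymin, ymax) and must be disjoint; samples
    in neither chamber (the neutral zone or outside the arena) count as
    neutral.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ValueError("positions must be (n, 2)")
    if _rects_overlap(paired_rect, unpaired_rect):
        raise ValueError("chamber rectangles must be disjoint")
    in_paired = _in_rect(pos, paired_rect)
    in_unpaired = _in_rect(pos, unpaired_rect)
    n = pos.shape[0]
    t_p = float(in_paired.sum() * dt_s)
    t_u = float(in_unpaired.sum() * dt_s)
    t_n = float(n * dt_s - t_p - t_u)
    return PlaceSession(t_p, t_u, t_n, label=label)


def _in_rect(pos: np.ndarray, rect) -> np.ndarray:
    xmin, xmax, ymin, ymax = rect
    return (
        (pos[:, 0] >= xmin) & (pos[:, 0] < xmax)
        & (pos[:, 1] >= ymin) & (pos[:, 1] < ymax)
    )


def _rects_overlap(a, b) -> bool:
    return not (a[1] <= b[0] or b[1] <= a[0] or a[3] <= b[2] or b[3] <= a[2])


def paw_lift_threshold(outcomes: pd.DataFrame) -> tuple[float, bool]:
    """Highest laser intensity with no paw lifts across its trials.

    ``outcomes`` needs columns ``intensity`` (ascending levels) and
    ``lift`` (0/1 per trial). Returns (intensity, flagged); flagged is True
    when every intensity produced at least one lift, in which case the
    lowest tested intensity is returned as a marker.
    """
    if outcomes.empty:
        raise ValueError("no trials")
    lifts = outcomes.groupby("intensity", sort=True)["lift"].sum()
    quiet = lifts.index[lifts == 0]
    if quiet.empty:
        return float(lifts.index.min()), True
    return float(quiet.max()), False
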