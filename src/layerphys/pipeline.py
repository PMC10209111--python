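"""End-to-end orchestration: simulate-or-load -> QC -> metrics -> calls ->
population tables, and the behavioral counterpart.

Runs are deterministic given the config seed: one root SeedSequence fans
out to independent per-stage streams (simulation, inference, behavior), so
adding or reordering stages does not silently change results. Every run
can write its tables plus a manifest (config hash, seed, stage row counts).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import modulation as mod
from . import spikes as spk
from . import synth
from . import units as ucl
from .config import PipelineConfig
from .datatypes import EventTable, SpikeTrainSet
from .io import write_results_table
from .stats import ProportionTable, chisq_homogeneity, marascuillo

__all__ = ["run_ephys_pipeline", "run_behavior_pipeline", "config_hash"]

log = logging.getLogger("layerphys")

ANALYSIS_CONDITIONS = ("L", "M", "ML")


def config_hash(config: PipelineConfig) -> str:
    payload = yaml.safe_dump(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _window(config: PipelineConfig) -> spk.WindowSpec:
    return spk.WindowSpec(
        config.response_delay_s, config.response_dur_s, config.baseline_dur_s
    )


def run_ephys_pipeline(
    config: PipelineConfig,
    trains: SpikeTrainSet | None = None,
    events: EventTable | None = None,
    out_dir: str | Path | None = None,
    specs: list | None = None,
) -> dict:
    """Full electrophysiology analysis; simulates a session when none given.

    Returns a dict with keys ``metrics`` (per unit x condition response
    quantities), ``calls`` (modulation decisions), ``proportions``
    (direction fractions per condition with chi-square and Marascuillo
    annotations), ``qc`` (per-unit pass/fail with reasons), ``isi_curves``
    (population-median ISI CDFs per condition) and ``manifest``.
    """
    root = np.random.SeedSequence(config.seed)
    sim_ss, infer_ss = root.spawn(2)
    if trains is None or events is None:
        if specs is None:
            specs = synth.default_population(
                config.n_units, rng=np.random.default_rng(sim_ss)
            )
        trains, events, _ = synth.simulate_session(
            specs, synth.make_default_protocol(config.n_trials),
            seed=int(sim_ss.generate_state(1)[0] % (2**31)),
            response_delay_s=config.response_delay_s,
        )
    window = _window(config)
    boundaries = config.boundaries

    qc_rows = []
    kept = []
    for unit in trains.units:
        res = ucl.qc_unit(
            unit, trains.recording_duration, config.refractory_ms,
            config.max_violation_rate, config.min_rate_hz,
        )
        layer = (
            ucl.assign_layer(unit.depth_um, boundaries)
            if unit.depth_um is not None else "unassigned"
        )
        qc_rows.append(
            {"unit_id": unit.unit_id, "qc_pass": res.passed,
             "reasons": ";".join(res.reasons) or "-",
             "violation_rate": res.violation_rate,
             "overall_rate_hz": res.overall_rate_hz, "layer": layer}
        )
        if res.passed:
            kept.append(unit)
    log.info("QC: %d/%d units pass", len(kept), len(trains.units))

    conditions = [c for c in ANALYSIS_CONDITIONS if c in events.conditions]
    infer_children = infer_ss.spawn(len(kept) * len(conditions))
    metric_rows, call_objs, isi_by_cond = [], [], {c: [] for c in conditions}
    stream = iter(infer_children)
    for unit in kept:
        for cond in conditions:
            aligned = spk.align_spikes(unit, events, cond, window)
            r_base = spk.mean_rate(aligned, "baseline")
            r_stim = spk.mean_rate(aligned, "response")
            metric_rows.append(
                {
                    "unit_id": unit.unit_id, "condition": cond,
                    "r_base_hz": r_base, "r_stim_hz": r_stim,
                    "mi": spk.modulation_index(r_stim, r_base),
                    "rp": spk.response_probability(aligned),
                    "bp": spk.burst_probability(aligned, config.burst_isi_cutoff_ms),
                    "n_trials": aligned.n_trials,
                }
            )
            call_objs.append(
                mod.modulation_call(
                    aligned, n_resamples=config.n_resamples,
                    rng=np.random.default_rng(next(stream)), alpha=config.alpha,
                )
            )
            isi_by_cond[cond].append(spk.isi_cdf(aligned))
    metrics = pd.DataFrame(metric_rows)
    calls = pd.DataFrame([asdict(c) for c in call_objs])
    log.info("metrics: %d rows; calls: %d rows", len(metrics), len(calls))

    proportions = mod.condition_proportions(call_objs) if call_objs else pd.DataFrame()
    annotations = _proportion_tests(call_objs, config.alpha) if call_objs else pd.DataFrame()

    isi_curves = {}
    for cond, cdfs in isi_by_cond.items():
        defined = [c for c in cdfs if c is not None]
        if defined:
            isi_curves[cond] = spk.population_median_cdf(cdfs)

    manifest = {
        "config_hash": config_hash(config), "seed": config.seed,
        "n_units_in": len(trains.units), "n_units_analyzed": len(kept),
        "n_units_excluded": len(trains.units) - len(kept),
        "n_metric_rows": len(metrics), "n_calls": len(calls),
    }
    result = {
        "metrics": metrics, "calls": calls, "proportions": proportions,
        "proportion_tests": annotations,
        "qc": pd.DataFrame(qc_rows), "isi_curves": isi_curves,
        "manifest": manifest,
    }
    if out_dir is not None:
        _write_ephys(result, Path(out_dir))
    return result


def _proportion_tests(call_objs, alpha: float) -> pd.DataFrame:
    """Chi-square homogeneity of the modulated fraction across conditions,
    with Marascuillo pairwise comparisons when >= 3 conditions."""
    by_cond: dict[str, list] = {}
    for c in call_objs:
        by_cond.setdefault(c.condition, []).append(c)
    groups = tuple(
        (cond, sum(cl.significant for cl in cls), len(cls))
        for cond, cls in by_cond.items()
    )
    rows = []
    if len(groups) >= 2:
        table = ProportionTable(groups)
        res = chisq_homogeneity(table)
        rows.append({"test": "chi2_homogeneity", "pair": "-", "statistic": res.statistic,
                     "df": res.df, "p": res.p, "significant": res.p <= alpha})
        if len(groups) >= 3:
            for cmp in marascuillo(table, alpha):
                rows.append({"test": "marascuillo", "pair": "|".join(cmp["pair"]),
                             "statistic": cmp["diff"], "df": np.nan,
                             "p": np.nan, "significant": cmp["significant"]})
    return pd.DataFrame(rows)


def _write_ephys(result: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("metrics", "calls", "proportions", "proportion_tests", "qc"):
        write_results_table(result[name], out_dir / f"{name}.tsv")
    curves = result["isi_curves"]
    if curves:
        df = pd.DataFrame({f"cdf_{c}": v for c, v in curves.items()})
        df.insert(0, "bin_ms", np.arange(1, len(df) + 1))
        write_results_table(df, out_dir / "isi_curves.tsv")
    write_results_table(
        pd.DataFrame([result["manifest"]]), out_dir / "manifest.tsv"
    )


def run_behavior_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> dict:
    """Simulated behavioral cohort: von Frey off/on plus place sessions.

    Per animal: psychometric curves with and without laser, 60% withdrawal
    thresholds, sensitization AUCs, and baseline/conditioning preference
    indices; plus group summaries (mean +/- SEM).
    """
    root = np.random.SeedSequence(config.seed).spawn(3)[2]
    streams = root.spawn(config.n_animals)
    rows = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        th = config.vf_threshold_g * float(
            np.exp(rng.normal(0.0, config.vf_threshold_sigma))
        )
        psych = {"threshold_g": th, "slope": config.vf_slope,
                 "laser_shift": config.vf_laser_shift}
        rec = {"animal": f"a{i:02d}", "planted_threshold_g": th}
        for label, on in (("off", False), ("on", True)):
            trials = synth.simulate_vonfrey(
                psych, n_per_filament=config.vf_n_per_filament, rng=rng, laser_on=on
            )
            curve = bhv.withdrawal_curve(trials)
            rec[f"threshold_{label}_g"] = bhv.threshold_at(curve)
            rec[f"auc_{label}"] = bhv.sensitivity_auc(curve)
        for label, p_paired in (
            ("baseline", config.place_p_stay_baseline),
            ("conditioning", config.place_p_stay_conditioned),
        ):
            pos = synth.simulate_place_session(
                p_paired, config.place_p_stay_baseline,
                config.place_duration_s, config.place_dt_s, rng=rng,
            )
            sess = bhv.occupancy_times(
                pos, config.place_dt_s,
                synth.PLACE_ARENA["paired"], synth.PLACE_ARENA["unpaired"],
                label=label,
            )
            rec[f"pi_{label}"] = bhv.preference_index(
                sess.time_paired_s, sess.time_unpaired_s
            )
        rows.append(rec)
    per_animal = pd.DataFrame(rows)
    numeric = per_animal.drop(columns=["animal"])
    summary = pd.DataFrame(
        {
            "measure": numeric.columns,
            "mean": numeric.mean().to_numpy(),
            "sem": (numeric.std(ddof=1) / np.sqrt(len(numeric))).to_numpy(),
        }
    )
    manifest = {"config_hash": config_hash(config), "seed": config.seed,
                "n_animals": config.n_animals}
    result = {"per_animal": per_animal, "summary": summary, "manifest": manifest}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_results_table(per_animal, out / "behavior_per_animal.tsv")
        write_results_table(summary, out / "behavior_summary.tsv")
        write_results_table(pd.DataFrame([manifest]), out / "behavior_manifest.tsv")
    return result
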