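"""Readers and writers for the on-disk formats.

Sorted spikes are exchanged in the Phy/Kilosort directory dialect:
``spike_times.npy`` (per-spike sample indices), ``spike_clusters.npy``
(per-spike cluster labels) and ``cluster_info.tsv`` (one row per cluster
with curation group, depth, channel and optional waveform metric). Only
clusters curated as "good" are analyzed. A plain CSV fallback
(unit_id, spike_time_s) is provided for portability.

Event and behavior tables are delimited text with a header and
unit-suffixed column names; results are written as TSV with floats at six
significant digits, round-tripping through the matching reader.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import EventTable, SpikeTrainSet, Unit

__all__ = [
    "read_sorted_spikes",
    "read_spikes_csv",
    "read_event_table",
    "read_table",
    "write_results_table",
    "write_event_table",
]

log = logging.getLogger("layerphys")

_CLUSTER_ID_ALIASES = ("unit_id", "cluster_id", "id")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_sorted_spikes(
    path: str | Path,
    sampling_rate: float,
    recording_duration_s: float | None = None,
) -> SpikeTrainSet:
    """Read a Phy/Kilosort-style sorted-spike directory.

    Converts sample indices to seconds and keeps only clusters whose
    curation group is "good". A cluster listed in the metadata but absent
    from the label array becomes a unit with zero spikes (warned).
    """
    path = Path(path)
    for fname in ("spike_times.npy", "spike_clusters.npy", "cluster_info.tsv"):
        if not (path / fname).exists():
            raise FileNotFoundError(f"missing {fname} in {path}")
    samples = np.load(path / "spike_times.npy").ravel()
    clusters = np.load(path / "spike_clusters.npy").ravel()
    if samples.size != clusters.size:
        raise ValueError(
            f"spike_times ({samples.size}) and spike_clusters ({clusters.size}) "
            "lengths differ"
        )
    info = pd.read_csv(path / "cluster_info.tsv", sep="\t")
    id_col = next((c for c in _CLUSTER_ID_ALIASES if c in info.columns), None)
    if id_col is None:
        raise ValueError(
            f"cluster_info.tsv needs one of {_CLUSTER_ID_ALIASES} columns"
        )
    if "group" not in info.columns:
        raise ValueError("cluster_info.tsv needs a 'group' column")
    times = samples.astype(np.float64) / sampling_rate
    order = np.argsort(times, kind="stable")
    times, clusters = times[order], clusters[order]
    duration = (
        recording_duration_s
        if recording_duration_s is not None
        else float(times[-1]) if times.size else 1.0
    )
    units = []
    for _, row in info.iterrows():
        if str(row["group"]).strip().lower() != "good":
            continue
        cid = row[id_col]
        t = times[clusters == cid]
        if t.size == 0:
            warnings.warn(f"cluster {cid} listed in metadata but has no spikes")
        units.append(
            Unit(
                unit_id=str(cid),
                spike_times=t,
                depth_um=_opt_float(row, "depth_um", "depth"),
                channel=_opt_int(row, "channel", "ch"),
                trough_peak_us=_opt_float(row, "trough_peak_us"),
            )
        )
    return SpikeTrainSet(units, recording_duration=duration, sampling_rate=sampling_rate)


def _opt_float(row, *names) -> float | None:
    for n in names:
        if n in row.index and pd.notna(row[n]):
            return float(row[n])
    return None


def _opt_int(row, *names) -> int | None:
    v = _opt_float(row, *names)
    return None if v is None else int(v)


def read_spikes_csv(
    path: str | Path,
    recording_duration_s: float | None = None,
    metadata: pd.DataFrame | None = None,
) -> SpikeTrainSet:
    """Plain-text fallback: columns unit_id, spike_time_s (+ optional metadata)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in ("unit_id", "spike_time_s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    meta = (metadata.set_index("unit_id") if metadata is not None else None)
    duration = (
        recording_duration_s
        if recording_duration_s is not None
        else float(df["spike_time_s"].max())
    )
    units = []
    for uid, grp in df.groupby("unit_id", sort=True):
        kw = {}
        if meta is not None and str(uid) in meta.index.astype(str):
            row = meta.loc[meta.index.astype(str) == str(uid)].iloc[0]
            kw = {
                "depth_um": _opt_float(row, "depth_um"),
                "channel": _opt_int(row, "channel"),
                "trough_peak_us": _opt_float(row, "trough_peak_us"),
            }
        units.append(Unit(str(uid), np.sort(grp["spike_time_s"].to_numpy()), **kw))
    return SpikeTrainSet(units, recording_duration=duration)


def read_event_table(path: str | Path) -> EventTable:
    """Read and validate a delimited trial-event table.

    Requires columns condition, onset_s, duration_s; optional
    laser_power_mW and force_g columns are carried through. Unknown
    condition strings raise, naming the offending rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    return EventTable(df)


def write_event_table(events: EventTable, path: str | Path) -> Path:
    return write_results_table(events.df, path)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read any results/behavior table written by :func:`write_results_table`."""
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path))


def write_results_table(records, path: str | Path) -> Path:
    """Write records (DataFrame or list of dicts) as TSV/CSV.

    Stable column order, floats at six significant digits; an empty record
    list produces a header-only file when columns are known.
    """
    path = Path(path)
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.6g")
    log.debug("wrote %d rows to %s", len(df), path)
    return path
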