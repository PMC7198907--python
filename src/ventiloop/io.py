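"""Shared I/O: CSV channel bundles (canonical interchange), event tables,
EDF ingestion, and fit summaries.

A recording is exchanged as a directory of one CSV per channel
(``time_s,value``) plus ``manifest.json`` describing sample intervals and
checksums — diffable, round-trippable and friendly to version control.  EDF
polysomnography files are read (never written) through :mod:`mne` when it is
installed; channel-name aliases map site-specific labels onto the canonical
flow/spo2/hr/map channels.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .breaths import BreathTable, VentilationSignal
from .scoring import RespiratoryEvent, SleepIndices, SpO2Trace
from .simulator import SimRecording

__all__ = [
    "write_recording_bundle",
    "read_recording",
    "events_to_csv",
    "events_from_csv",
    "breath_table_to_csv",
    "breath_table_from_csv",
    "ventilation_to_csv",
    "ventilation_from_csv",
    "indices_to_json",
    "DEFAULT_CHANNEL_ALIASES",
]

DEFAULT_CHANNEL_ALIASES = {
    "flow": ["flow", "nasalpressure", "nasal_pressure", "pnasal", "airflow",
             "nasal pressure", "cannula"],
    "spo2": ["spo2", "sao2", "oximetry", "sat"],
    "hr": ["hr", "heartrate", "pulse", "heart_rate"],
    "map_bp": ["map", "map_bp", "bp", "meanbp", "mean_arterial_pressure"],
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_channel(path: Path, time_s: np.ndarray, values: np.ndarray) -> None:
    pd.DataFrame({"time_s": time_s, "value": values}).to_csv(
        path, index=False, float_format="%.10g")


def write_recording_bundle(rec: SimRecording, out_dir) -> Path:
    """Write a recording as a CSV channel bundle with a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = rec.flow.size
    channels = {
        "flow": (np.arange(n) * rec.dt_s, rec.flow, rec.dt_s),
        "spo2": (rec.spo2.time_s, rec.spo2.spo2_pct, 1.0),
        "hr": (np.arange(rec.hr.size, dtype=float), rec.hr, 1.0),
        "map_bp": (np.arange(rec.map_bp.size, dtype=float), rec.map_bp, 1.0),
        "sleep_mask": (np.arange(rec.sleep_mask.size, dtype=float),
                       rec.sleep_mask.astype(int), 1.0),
    }
    manifest = {"format": "ventiloop-csv-bundle-v1", "channels": {}}
    for name, (t, v, dt) in channels.items():
        f = out / f"{name}.csv"
        _write_channel(f, t, v)
        manifest["channels"][name] = {"file": f.name, "dt_s": dt,
                                      "n": int(len(v)), "sha256": _sha256(f)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def read_recording(path, format: str = "csv-bundle",
                   aliases: Optional[dict] = None) -> SimRecording:
    """Load a recording from a CSV bundle or an EDF file.

    EDF requires :mod:`mne`; channel labels are matched case-insensitively
    against ``aliases`` (default map covers common PSG montage names).  A
    missing flow channel is an error; a missing SpO2 channel yields a
    recording whose ``spo2`` trace is flat 100% and is reported by the caller
    as degraded (hypopnea scoring needs SpO2).
    """
    path = Path(path)
    if format == "csv-bundle":
        return _read_bundle(path)
    if format == "edf":
        return _read_edf(path, aliases or DEFAULT_CHANNEL_ALIASES)
    raise ValueError(f"unknown recording format {format!r}")


def _read_bundle(path: Path) -> SimRecording:
    manifest = json.loads((path / "manifest.json").read_text())
    ch = manifest["channels"]

    def load(name):
        df = pd.read_csv(path / ch[name]["file"])
        return df["time_s"].to_numpy(), df["value"].to_numpy()

    _, flow = load("flow")
    t_spo2, spo2 = load("spo2")
    _, hr = load("hr")
    _, mp = load("map_bp")
    _, mask = load("sleep_mask")
    return SimRecording(
        flow=flow, spo2=SpO2Trace(t_spo2, spo2), hr=hr, map_bp=mp,
        sleep_mask=mask.astype(bool), dt_s=float(ch["flow"]["dt_s"]))


def resolve_channel(available: Sequence[str], canonical: str,
                    aliases: dict) -> Optional[str]:
    """Case-insensitive alias lookup of a canonical channel name."""
    wanted = [a.lower() for a in aliases.get(canonical, [canonical])]
    for name in available:
        if name.lower().strip() in wanted:
            return name
    return None


def _read_edf(path: Path, aliases: dict) -> SimRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return recording_from_channels(
        {name: raw.get_data(picks=[name])[0] for name in raw.ch_names},
        sfreq=float(raw.info["sfreq"]), aliases=aliases)


def recording_from_channels(channels: dict, sfreq: float,
                            aliases: Optional[dict] = None) -> SimRecording:
    """Build a recording from named sample arrays at a common rate.

    Split out from the EDF reader so alias resolution and resampling are
    testable without binary files.
    """
    aliases = aliases or DEFAULT_CHANNEL_ALIASES
    names = list(channels)
    flow_name = resolve_channel(names, "flow", aliases)
    if flow_name is None:
        raise ValueError(f"no flow channel found among {names} "
                         "(extend the alias map if the label is unusual)")
    flow = np.asarray(channels[flow_name], dtype=float)
    dt = 1.0 / sfreq
    dur = flow.size * dt
    n1 = int(dur)
    t1 = np.arange(n1, dtype=float)

    def at_1hz(name, default):
        ch = resolve_channel(names, name, aliases)
        if ch is None:
            return np.full(n1, default), False
        v = np.asarray(channels[ch], dtype=float)
        tsrc = np.arange(v.size) * dt
        return np.interp(t1, tsrc, v), True

    spo2, has_spo2 = at_1hz("spo2", 100.0)
    hr, _ = at_1hz("hr", np.nan)
    mp, _ = at_1hz("map_bp", np.nan)
    rec = SimRecording(flow=flow, spo2=SpO2Trace(t1, np.clip(spo2, 0, 100)),
                       hr=hr, map_bp=mp, sleep_mask=np.ones(n1, dtype=bool),
                       dt_s=dt)
    rec.has_spo2 = has_spo2  # degraded-mode marker
    return rec


# ---------------------------------------------------------------------------
# tabular artifacts
# ---------------------------------------------------------------------------

def events_to_csv(events: Sequence[RespiratoryEvent], path) -> None:
    pd.DataFrame([{
        "onset_s": e.onset_s, "duration_s": e.duration_s, "kind": e.kind,
        "flow_reduction_frac": e.flow_reduction_frac,
        "desat_pct": e.linked_desat_pct if e.linked_desat_pct is not None else "",
    } for e in events]).to_csv(path, index=False)


def events_from_csv(path) -> list[RespiratoryEvent]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        desat = r.get("desat_pct")
        desat = None if pd.isna(desat) or desat == "" else float(desat)
        out.append(RespiratoryEvent(float(r["onset_s"]), float(r["duration_s"]),
                                    str(r["kind"]), float(r["flow_reduction_frac"]),
                                    desat))
    return out


def breath_table_to_csv(bt: BreathTable, path) -> None:
    pd.DataFrame({
        "onset_s": bt.breath_onset_s, "vt_au": bt.tidal_volume_au,
        "rate_bpm": bt.resp_rate_bpm, "vent_au": bt.ventilation_au,
        "duration_s": bt.duration_s, "peak_flow": bt.peak_flow,
    }).to_csv(path, index=False)


def breath_table_from_csv(path) -> BreathTable:
    df = pd.read_csv(path)
    return BreathTable(df["onset_s"].to_numpy(), df["vt_au"].to_numpy(),
                       df["rate_bpm"].to_numpy(), df["vent_au"].to_numpy(),
                       duration_s=df["duration_s"].to_numpy(),
                       peak_flow=df["peak_flow"].to_numpy())


def ventilation_to_csv(vs: VentilationSignal, path) -> None:
    pd.DataFrame({"time_s": vs.time_s, "vent_au": vs.values}).to_csv(
        path, index=False, float_format="%.10g")


def ventilation_from_csv(path, dt_s: float = 1.0) -> VentilationSignal:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if t.size >= 2:
        dt_s = float(t[1] - t[0])
    return VentilationSignal(df["vent_au"].to_numpy(), dt_s)


def indices_to_json(indices: SleepIndices, path) -> None:
    Path(path).write_text(json.dumps({
        "ahi": indices.ahi, "odi": indices.odi,
        "mean_desat_pct": indices.mean_desat_pct,
        "nadir_spo2_pct": indices.nadir_spo2_pct,
        "peak_spo2_pct": indices.peak_spo2_pct,
        "tst_min": indices.tst_min,
    }, indent=1, sort_keys=True))
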