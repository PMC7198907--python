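"""Top-level pipeline: simulate (or ingest) -> breaths -> ventilation ->
event scoring -> dynamic loop gain -> report.

Every stage's outputs are written before the next begins; the run report
carries a parameter hash and per-file checksums so a fixed seed reproduces the
report byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io as vio
from .breaths import build_ventilation_signal, detect_breaths
from .loopgain import extract_windows, fit_drive_model, night_loop_gain, window_loop_gain
from .scoring import compute_indices, detect_desaturations, score_events
from .simulator import SimConfig, simulate_night

__all__ = ["RunConfig", "RunReport", "run_pipeline", "analyze_recording"]

log = logging.getLogger("ventiloop")

_KNOWN_TOP = {"seed", "out_dir", "log_level", "input_path", "input_format",
              "simulator", "scoring", "loopgain"}


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips losslessly through YAML."""

    seed: int = 0
    out_dir: str = "ventiloop_run"
    log_level: str = "INFO"
    input_path: Optional[str] = None     # None -> simulate
    input_format: str = "csv-bundle"
    simulator: dict = field(default_factory=dict)
    scoring: dict = field(default_factory=dict)
    loopgain: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - _KNOWN_TOP
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)} "
                             f"(expected a subset of {sorted(_KNOWN_TOP)})")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    def params_hash(self) -> str:
        """Hash of the parameters that affect results (out_dir and log level
        are excluded so identical runs to different directories hash equal)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunReport:
    params_hash: str
    seed: int
    outputs: dict          # filename -> sha256
    indices: Optional[dict]
    night_loop_gain: Optional[dict]
    warnings: list

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                         sort_keys=True))


def analyze_recording(flow: np.ndarray, spo2, sleep_mask, dt_s: float,
                      tst_min: Optional[float] = None,
                      loopgain_params: Optional[dict] = None):
    """Run breaths -> ventilation -> scoring -> loop gain on raw channels.

    Returns (breath_table, ventilation_signal, events, desats, indices,
    night_loop_gain).  This is the library-level core of ``run_pipeline``.
    """
    loopgain_params = loopgain_params or {}
    total_s = flow.size * dt_s
    bt = detect_breaths(flow, dt_s, allow_empty=True)
    vs = build_ventilation_signal(bt, dt_s=1.0, span=(0.0, total_s))
    events = score_events(flow, spo2, sleep_mask, dt_s=dt_s)
    desats = detect_desaturations(spo2) if spo2 is not None else []
    if tst_min is None:
        tst_min = (float(np.sum(sleep_mask)) / 60.0 if sleep_mask is not None
                   else total_s / 60.0)
    indices = compute_indices(events, desats, spo2, tst_min)
    windows = extract_windows(vs, events, **loopgain_params)
    estimates = [window_loop_gain(fit_drive_model(w), w) for w in windows]
    nlg = night_loop_gain(estimates)
    return bt, vs, events, desats, indices, nlg


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the full pipeline and persist every stage's outputs."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_list: list[str] = []

    if cfg.input_path is None:
        sim_cfg = SimConfig(seed=cfg.seed, **cfg.simulator)
        rec, truth = simulate_night(sim_cfg)
        vio.write_recording_bundle(rec, out / "recording")
        vio.events_to_csv(truth.planted_events, out / "planted_events.csv")
        log.info("simulated %.0f s night, true LG %.3f",
                 sim_cfg.duration_s, truth.true_loop_gain_at_cycling_freq)
    else:
        rec = vio.read_recording(cfg.input_path, cfg.input_format)
        if not getattr(rec, "has_spo2", True):
            warnings_list.append("no SpO2 channel: hypopnea scoring disabled")

    spo2 = rec.spo2
    bt, vs, events, desats, indices, nlg = analyze_recording(
        rec.flow, spo2, rec.sleep_mask, rec.dt_s,
        loopgain_params=cfg.loopgain)

    vio.breath_table_to_csv(bt, out / "breaths.csv")
    vio.ventilation_to_csv(vs, out / "ventilation.csv")
    vio.events_to_csv(events, out / "events.csv")
    vio.indices_to_json(indices, out / "indices.json")
    windows_rows = [{"start_s": e.start_s, "lg": e.lg, "f_cycle_hz": e.f_cycle_hz,
                     "fit_r2": e.fit_r2, "accepted": e.accepted}
                    for e in nlg.window_estimates]
    import pandas as pd

    pd.DataFrame(windows_rows, columns=["start_s", "lg", "f_cycle_hz",
                                        "fit_r2", "accepted"]).to_csv(
        out / "windows.csv", index=False, float_format="%.8g")
    if nlg.indeterminate:
        warnings_list.append("loop gain indeterminate (no accepted windows)")
        nlg_dict = {"median_lg": None, "n_windows_used": 0}
    else:
        nlg_dict = {"median_lg": nlg.median_lg, "n_windows_used": nlg.n_windows_used}
    Path(out / "night_loop_gain.json").write_text(
        json.dumps(nlg_dict, indent=1, sort_keys=True))

    outputs = {}
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "report.json":
            outputs[str(f.relative_to(out))] = hashlib.sha256(f.read_bytes()).hexdigest()
    report = RunReport(
        params_hash=cfg.params_hash(), seed=cfg.seed, outputs=outputs,
        indices=dataclasses.asdict(indices), night_loop_gain=nlg_dict,
        warnings=warnings_list)
    report.to_json(out / "report.json")
    return report
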