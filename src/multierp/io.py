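"""File formats: events TSV, recording container, config, manifest.

The events table is a BIDS-inspired UTF-8 TSV with a fixed column order and
'.' decimals.  Recordings persist as little-endian float32 flat binary
(channels x samples) plus a JSON sidecar and the event TSV with a sample
column.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import ParadigmConfig
from .errors import ParameterError
from .simulate import EVENT_COLUMNS, Montage, RawRecording

EVENTS_TSV_COLUMNS = ["onset_ms", "duration_ms", "level", "block", "trial",
                      "event_type", "marker_code"]


def write_trials_tsv(trials: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    trials.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path


def read_trials_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8")


def events_frame(schedule, config: ParadigmConfig | None = None) -> pd.DataFrame:
    """One row per scheduled event (trial start, visual onset, tones)."""
    cfg = config or schedule.config
    rows = []
    for r in schedule.trials.to_dict("records"):
        onset = float(r["onset_ms"])
        base = {"level": r["level"], "block": r["block"], "trial": r["trial"],
                "marker_code": r["marker_code"]}
        rows.append({"onset_ms": onset, "duration_ms": r["duration_ms"],
                     "event_type": "trial_start", **base})
        if r["kind"] != "stimulus":
            continue
        vis = onset + cfg.pre_mask_ms
        rows.append({"onset_ms": vis, "duration_ms": cfg.stim_duration_ms,
                     "event_type": "stimulus", **base})
        if r["tone_slot"] == "pair" and r["tone_pair_type"] != "silent":
            s1 = vis + float(r["tone_offset_ms"])
            rows.append({"onset_ms": s1, "duration_ms": cfg.tone_duration_ms,
                         "event_type": "tone_s1", **base})
            rows.append({"onset_ms": s1 + cfg.s1_s2_gap_ms,
                         "duration_ms": cfg.tone_duration_ms,
                         "event_type": "tone_s2", **base})
    df = pd.DataFrame(rows).sort_values(
        ["onset_ms", "event_type"], kind="stable").reset_index(drop=True)
    return df[EVENTS_TSV_COLUMNS]


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    missing = set(EVENTS_TSV_COLUMNS) - set(events.columns)
    if missing:
        raise ParameterError(f"events table missing columns: {sorted(missing)}")
    events.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", encoding="utf-8")
    missing = set(EVENTS_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ParameterError(
            f"{path}: missing required column(s) {sorted(missing)}")
    return df


def save_recording(rec: RawRecording, stem: str | Path) -> dict:
    """Write <stem>.f32 (flat binary), <stem>.json sidecar and
    <stem>.events.tsv; returns the sidecar dict."""
    stem = Path(stem)
    data = rec.signal.astype("<f4")
    data.tofile(stem.with_suffix(".f32"))
    sidecar = {
        "srate_hz": rec.srate_hz,
        "n_channels": rec.signal.shape[0],
        "n_samples": rec.signal.shape[1],
        "channels": list(rec.montage.channels),
        "units": "uV",
        "dtype": "<f4",
        "order": "channels x samples, C-contiguous",
        "meta": rec.meta,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    rec.events.to_csv(stem.with_suffix(".events.tsv"), sep="\t", index=False)
    return sidecar


def load_recording(stem: str | Path) -> RawRecording:
    stem = Path(stem)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    data = np.fromfile(stem.with_suffix(".f32"), dtype="<f4").astype(float)
    data = data.reshape(sidecar["n_channels"], sidecar["n_samples"])
    events = pd.read_csv(stem.with_suffix(".events.tsv"), sep="\t")
    montage = Montage(channels=tuple(sidecar["channels"]), layout={})
    return RawRecording(signal=data, srate_hz=sidecar["srate_hz"],
                        montage=montage, events=events,
                        meta=sidecar.get("meta", {}))


def load_config(path: str | Path | None) -> ParadigmConfig:
    if path is None:
        return ParadigmConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return ParadigmConfig.from_dict(data)


def config_hash(config: ParadigmConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path: str | Path, config: ParadigmConfig,
                   seeds: dict, files: dict) -> dict:
    """Run manifest: config hash, seeds, produced files, version, time."""
    from . import __version__
    path = Path(path)
    for name, f in files.items():
        if not Path(f).exists():
            raise ParameterError(f"manifest references missing file: {f}")
    manifest = {
        "config_hash": config_hash(config),
        "config": config.to_dict(),
        "seeds": seeds,
        "files": {k: str(v) for k, v in files.items()},
        "tool_version": __version__,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path.write_text(json.dumps(manifest, indent=2))
    return manifest


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
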