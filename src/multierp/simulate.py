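"""Seeded synthetic EEG for a generated schedule.

The recording is a linear superposition of 1/f background noise and ten
condition-dependent component templates, each a Gaussian-envelope deflection
locked to a stimulus, tone, or response event.  A behavioral model supplies
button presses (log-normal RT truncated at the response window, level-
dependent error rates, elevated lapses in the first post-reversal block), so
response-locked components and corollary-discharge tones have realistic
event streams.  Template parameters are configuration, not estimates: they
are the ground truth that downstream recovery tests check against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .config import ImageKind, Level, ParadigmConfig
from .errors import ParameterError
from .schedule import LevelSchedule, encode_event_marker

# ---------------------------------------------------------------------------
# Montage

DEFAULT_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FCz", "C3", "Cz", "C4",
    "P3", "Pz", "P4", "PO7", "POz", "PO8", "O1", "O2",
]

REQUIRED_CHANNELS = {"POz", "PO7", "PO8", "Pz", "FCz", "Cz", "C3", "C4"}

_LAYOUT = {  # schematic 2-D positions (x: left-, right+; y: front+)
    "Fp1": (-0.3, 1.0), "Fp2": (0.3, 1.0), "F7": (-0.8, 0.6),
    "F3": (-0.4, 0.6), "Fz": (0.0, 0.6), "F4": (0.4, 0.6), "F8": (0.8, 0.6),
    "FCz": (0.0, 0.3), "C3": (-0.4, 0.0), "Cz": (0.0, 0.0), "C4": (0.4, 0.0),
    "P3": (-0.4, -0.5), "Pz": (0.0, -0.5), "P4": (0.4, -0.5),
    "PO7": (-0.6, -0.8), "POz": (0.0, -0.8), "PO8": (0.6, -0.8),
    "O1": (-0.3, -1.0), "O2": (0.3, -1.0),
}


@dataclass(frozen=True)
class Montage:
    channels: tuple[str, ...] = tuple(DEFAULT_CHANNELS)
    layout: dict = field(default_factory=lambda: dict(_LAYOUT))

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ParameterError("duplicate channel names in montage")
        missing = REQUIRED_CHANNELS - set(self.channels)
        if missing:
            raise ParameterError(f"montage lacks contrast channels {missing}")

    def index(self, name: str) -> int:
        return self.channels.index(name)


# ---------------------------------------------------------------------------
# Behavior

@dataclass(frozen=True)
class SubjectProfile:
    rt_median_ms: float = 420.0
    rt_sigma: float = 0.25            # log-normal shape
    accuracy: dict = field(default_factory=lambda: {
        Level.LEARN.value: 0.96, Level.WHO.value: 0.94,
        Level.DISCERN.value: 0.85})
    post_reversal_lapse: float = 0.25  # extra error prob, 1st rule_B block
    noise_uv: float = 4.0

    def __post_init__(self) -> None:
        for lv, a in self.accuracy.items():
            if not 0 < a <= 1:
                raise ParameterError(f"accuracy for {lv} outside (0, 1]")


def simulate_behavior(schedule: LevelSchedule, profile: SubjectProfile,
                      seed: int = 0) -> pd.DataFrame:
    """Per-trial responses: button, RT (ms from visual onset), accuracy.

    Responses occur only on active stimulus trials.  RT is log-normal with
    the profile's median, truncated at the response window (late draws are
    misses).  Error probability is level-dependent and elevated in the first
    block after the Discern rule reversal.
    """
    cfg = schedule.config
    rng = np.random.default_rng(seed)
    t = schedule.trials
    first_rule_b = None
    if schedule.level is Level.DISCERN:
        rb = t.loc[t["block_mode"] == "rule_B", "block"]
        first_rule_b = int(rb.min()) if len(rb) else None

    buttons, rts, accs = [], [], []
    for r in t.to_dict("records"):
        expected = r["expected_button"]
        if r["kind"] != "stimulus" or expected == "none":
            buttons.append("none"); rts.append(np.nan); accs.append("na")
            continue
        p_err = 1.0 - profile.accuracy[r["level"]]
        if first_rule_b is not None and r["block"] == first_rule_b:
            p_err = min(1.0, p_err + profile.post_reversal_lapse)
        rt = float(np.exp(np.log(profile.rt_median_ms)
                          + profile.rt_sigma * rng.standard_normal()))
        if rt > cfg.response_window_ms:
            buttons.append("none"); rts.append(np.nan); accs.append("miss")
            continue
        if rng.random() < p_err:
            buttons.append("left" if expected == "right" else "right")
            accs.append("incorrect")
        else:
            buttons.append(expected)
            accs.append("correct")
        rts.append(rt)
    out = t[["trial", "block", "kind"]].copy()
    out["button"] = buttons
    out["rt_ms"] = rts
    out["accuracy"] = accs
    return out


# ---------------------------------------------------------------------------
# Component templates

AmplitudeRule = Callable[[dict], float]
TopographyRule = Callable[[dict], dict]


@dataclass
class ComponentTemplate:
    """One ERP generator: Gaussian deflection locked to an event type.

    ``lock`` selects which events of the merged event table trigger the
    component ("stimulus", "tone", or "response"); ``amplitude`` maps the
    event row to a peak amplitude in microvolts (0 = not rendered);
    ``topography`` maps channel name to weight.
    """

    name: str
    lock: str
    peak_latency_ms: float
    width_ms: float
    amplitude: AmplitudeRule
    topography: dict | TopographyRule

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ParameterError("width_ms must be positive")

    def topo_for(self, event: dict) -> dict:
        if callable(self.topography):
            return self.topography(event)
        return self.topography


#: Level scaling applied to the N170 amplitude (complexity effect).
N170_LEVEL_SCALE = {Level.LEARN.value: 0.6, Level.WHO.value: 0.8,
                    Level.DISCERN.value: 1.0}

N170_CONDITION_UV = {
    ImageKind.MOONEY_FACE.value: -3.0,      # FacePresent
    ImageKind.MOONEY_DISTORTED.value: -1.0,  # FaceAbsent
    ImageKind.KANIZSA.value: -4.5,          # ShapePresent
    ImageKind.KANIZSA_DISTORTED.value: -2.0,  # ShapeAbsent
}

#: Corollary-discharge attenuation for self-triggered tones.
CD_ATTENUATION = 0.4


def _n170_amp(ev: dict) -> float:
    if ev["event_type"] != "stimulus" or ev["image"] == "none":
        return 0.0
    return N170_CONDITION_UV[ev["image"]] * N170_LEVEL_SCALE[ev["level"]]


def _n2pc_topo(ev: dict) -> dict:
    contra = "PO8" if ev["side"] == "left" else "PO7"
    return {contra: 1.0}


def _lrp_topo(ev: dict) -> dict:
    contra = "C4" if ev["button"] == "left" else "C3"
    return {contra: 1.0}


def _cd_scale(ev: dict) -> float:
    return CD_ATTENUATION if ev["cd_tone"] == "on_response" else 1.0


def default_templates() -> list[ComponentTemplate]:
    """The ten built-in generators, one per analyzed component."""
    return [
        ComponentTemplate(
            "C1", "stimulus", 80, 25,
            lambda ev: {"top": -2.0, "bottom": 2.0}.get(ev["distractor"], 0.0),
            {"POz": 1.0, "O1": 0.4, "O2": 0.4}),
        ComponentTemplate(
            "P50", "tone", 55, 15,
            lambda ev: ({"tone_s1": 4.0, "tone_s2": 1.6}.get(ev["event_type"], 0.0)
                        if ev["event_type"] in ("tone_s1", "tone_s2") else 0.0),
            {"Cz": 1.0, "FCz": 0.8}),
        ComponentTemplate(
            "MMN", "tone", 180, 40,
            lambda ev: (-4.0 if ev.get("tone_is_deviant") else -0.5)
            if ev["event_type"] == "tone_s2" else 0.0,
            {"FCz": 1.0, "Fz": 0.7, "Cz": 0.7}),
        ComponentTemplate(
            "N1", "tone", 100, 25,
            lambda ev: -3.5 * _cd_scale(ev)
            if ev["event_type"] == "tone_cd" else 0.0,
            {"Cz": 1.0, "FCz": 0.8}),
        ComponentTemplate(
            "P2", "tone", 220, 40,
            lambda ev: 3.5 * _cd_scale(ev)
            if ev["event_type"] == "tone_cd" else 0.0,
            {"Cz": 1.0, "FCz": 0.8}),
        ComponentTemplate(
            "N170", "stimulus", 220, 35, _n170_amp,
            {"PO8": 1.0, "PO7": 0.8}),
        ComponentTemplate(
            "N2pc", "stimulus", 250, 40,
            lambda ev: -1.5 if ev["event_type"] == "stimulus"
            and ev["side"] in ("left", "right") else 0.0,
            _n2pc_topo),
        ComponentTemplate(
            "LRP", "response", -60, 60,
            lambda ev: -2.0 if ev["button"] in ("left", "right") else 0.0,
            _lrp_topo),
        ComponentTemplate(
            "P300", "stimulus", 400, 80,
            lambda ev: {"rare": 5.0, "frequent": 1.0}.get(ev["category"], 0.0),
            {"Pz": 1.0, "P3": 0.6, "P4": 0.6, "POz": 0.5}),
        ComponentTemplate(
            "ERN", "response", 60, 35,
            lambda ev: {"incorrect": -4.5, "correct": -0.5}.get(
                ev["accuracy"], 0.0),
            {"FCz": 1.0, "Fz": 0.6}),
    ]


# ---------------------------------------------------------------------------
# Recording container and event table

@dataclass
class RawRecording:
    signal: np.ndarray            # channels x samples, microvolts
    srate_hz: float
    montage: Montage
    events: pd.DataFrame          # one row per event, "sample" column
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.signal).all():
            raise ParameterError("signal contains non-finite samples")
        ev = self.events
        if len(ev) and not ev["sample"].is_monotonic_increasing:
            self.events = ev.sort_values("sample", kind="stable").reset_index(
                drop=True)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.srate_hz


EVENT_COLUMNS = [
    "sample", "onset_ms", "event_type", "level", "block", "block_mode",
    "trial", "kind", "image", "side", "category", "distractor",
    "tone_pair_type", "tone_offset_ms", "tone_is_deviant", "cd_tone",
    "expected_button", "button", "rt_ms", "accuracy", "marker_code",
]


def build_event_table(schedule: LevelSchedule,
                      behavior: pd.DataFrame | None,
                      srate_hz: float,
                      pad_start_ms: float = 2000.0) -> pd.DataFrame:
    """Merge the schedule and behavior into a flat per-event table.

    Event types: ``trial_start``, ``stimulus`` (visual onset), ``tone_s1``,
    ``tone_s2`` (paired tones; silent slots emit nothing), ``tone_cd``
    (corollary-discharge tone), ``response``.
    """
    cfg = schedule.config
    t = schedule.trials
    if behavior is not None:
        t = t.merge(behavior[["trial", "button", "rt_ms", "accuracy"]],
                    on="trial", how="left")
    else:
        t = t.assign(button="none", rt_ms=np.nan, accuracy="na")
    rows: list[dict] = []

    def emit(onset_ms: float, etype: str, r: dict, **extra) -> None:
        base = {
            "onset_ms": onset_ms + pad_start_ms, "event_type": etype,
            "level": r["level"], "block": r["block"],
            "block_mode": r["block_mode"], "trial": r["trial"],
            "kind": r["kind"], "image": r["image"], "side": r["side"],
            "category": r["category"], "distractor": r["distractor"],
            "tone_pair_type": r["tone_pair_type"],
            "tone_offset_ms": r["tone_offset_ms"],
            "tone_is_deviant": False, "cd_tone": r["cd_tone"],
            "expected_button": r["expected_button"], "button": r["button"],
            "rt_ms": r["rt_ms"], "accuracy": r["accuracy"],
            "marker_code": encode_event_marker(
                r, str(r["button"]), str(r["accuracy"])),
        }
        base.update(extra)
        rows.append(base)

    rng_cd = np.random.default_rng([schedule.seed, 0xCD])
    for r in t.to_dict("records"):
        onset = float(r["onset_ms"])
        emit(onset, "trial_start", r)
        if r["kind"] != "stimulus":
            continue
        vis = onset + cfg.pre_mask_ms
        emit(vis, "stimulus", r)
        if r["tone_slot"] == "pair" and r["tone_pair_type"] != "silent":
            s1 = vis + float(r["tone_offset_ms"])
            emit(s1, "tone_s1", r)
            emit(s1 + cfg.s1_s2_gap_ms, "tone_s2", r,
                 tone_is_deviant=(r["tone_pair_type"] == "std_dev"))
        responded = r["button"] in ("left", "right")
        if responded:
            emit(vis + float(r["rt_ms"]), "response", r)
        if r["cd_tone"] == "on_response" and responded:
            emit(vis + float(r["rt_ms"]), "tone_cd", r)
        elif r["cd_tone"] == "random_delay":
            stim_off = vis + cfg.stim_duration_ms
            delay = rng_cd.uniform(*cfg.cd_random_delay_ms)
            if responded:
                emit(stim_off + delay, "tone_cd", r)
            else:  # tone at response-window timeout
                emit(vis + cfg.response_window_ms, "tone_cd", r)
    ev = pd.DataFrame(rows)
    ev["sample"] = np.round(ev["onset_ms"] * srate_hz / 1000.0).astype(int)
    ev = ev.sort_values(["sample", "event_type"], kind="stable")
    return ev[EVENT_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Signal synthesis

def pink_noise(n_channels: int, n_samples: int, srate_hz: float,
               amplitude_uv: float, seed: int = 0) -> np.ndarray:
    """Channel-independent 1/f noise scaled to the given RMS amplitude."""
    if n_samples <= srate_hz:
        raise ParameterError("need more than one second of samples")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / srate_hz)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])   # power ~ 1/f
    shaping[0] = 0.0
    spec = np.fft.rfft(white, axis=1) * shaping
    out = np.fft.irfft(spec, n=n_samples, axis=1)
    if amplitude_uv == 0:
        return np.zeros((n_channels, n_samples))
    rms = out.std(axis=1, keepdims=True)
    return out / rms * amplitude_uv


def render_component(template: ComponentTemplate, events: pd.DataFrame,
                     montage: Montage, n_samples: int,
                     srate_hz: float) -> np.ndarray:
    """Additive channels x samples signal for one template.

    Each matching event contributes amplitude * topography *
    Gaussian(t; lock + latency, width).  Events whose deflection would fall
    beyond the recording end are skipped.
    """
    sig = np.zeros((len(montage.channels), n_samples))
    lock_types = {"stimulus": ("stimulus",),
                  "tone": ("tone_s1", "tone_s2", "tone_cd"),
                  "response": ("response",)}[template.lock]
    sel = events[events["event_type"].isin(lock_types)]
    half = 4 * template.width_ms          # support of the envelope
    tgrid_ms = np.arange(-half, half + 1000.0 / srate_hz, 1000.0 / srate_hz)
    envelope = np.exp(-0.5 * (tgrid_ms / template.width_ms) ** 2)
    offset = int(round((template.peak_latency_ms - half) * srate_hz / 1000.0))
    for ev in sel.to_dict("records"):
        amp = template.amplitude(ev)
        if amp == 0.0:
            continue
        start = int(ev["sample"]) + offset
        stop = start + len(envelope)
        if start < 0 or stop > n_samples:
            continue
        topo = template.topo_for(ev)
        for ch, w in topo.items():
            sig[montage.index(ch), start:stop] += amp * w * envelope
    return sig


def simulate_recording(schedule: LevelSchedule,
                       montage: Montage | None = None,
                       profile: SubjectProfile | None = None,
                       templates: list[ComponentTemplate] | None = None,
                       seed: int = 0,
                       srate_hz: float = 250.0,
                       pad_ms: float = 2000.0) -> RawRecording:
    """Noise + superposed components + sample-accurate event table."""
    montage = montage or Montage()
    profile = profile or SubjectProfile()
    templates = templates if templates is not None else default_templates()
    for tpl in templates:
        # need at least ~2 samples per envelope sigma
        if srate_hz * tpl.width_ms / 1000.0 < 2.0:
            raise ParameterError(
                f"srate {srate_hz} too low for template {tpl.name}")
    behavior = simulate_behavior(schedule, profile, seed=seed)
    events = build_event_table(schedule, behavior, srate_hz,
                               pad_start_ms=pad_ms)
    n_samples = int(round(
        (schedule.total_duration_ms + 2 * pad_ms) * srate_hz / 1000.0))
    sig = pink_noise(len(montage.channels), n_samples, srate_hz,
                     profile.noise_uv, seed=seed + 1)
    for tpl in templates:
        sig += render_component(tpl, events, montage, n_samples, srate_hz)
    meta = {"level": schedule.level.value, "seed": seed,
            "schedule_seed": schedule.seed, "pad_ms": pad_ms,
            "noise_uv": profile.noise_uv}
    return RawRecording(signal=sig, srate_hz=srate_hz, montage=montage,
                        events=events, meta=meta)
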