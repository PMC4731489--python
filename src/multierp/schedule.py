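"""Seeded generation of the three-level trial/block/event structure.

A level is 16 blocks; each block is 25 stimulus trials followed by 3
baseline trials (fixation only).  Within a block one image type is frequent
(80% of stimulus trials, always on one side of fixation) and two rare types
share the opposite side (20% combined).  The two rare types are held fixed
across the blocks of a level and their per-block counts alternate 3/2 and
2/3 so each totals exactly 10% of the level's stimulus trials.

Paired auditory tones occupy every 4th stimulus trial (a "tone slot"); each
slot is followed by at least three toneless trials.  Among slots the mix is
exactly 80% standard-standard pairs, 10% pairs with a deviant second tone
and 10% silent slots.  The second tone always starts 500 ms after the first.

Trial length is 60 ms pre-mask + 240 ms stimulus + 700 ms response window +
200 ms minimum end baseline = 1200 ms, extended by a uniform 0-700 ms
jitter, so durations span [1200, 1900] ms with mean 1550 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (DISCERN_MODES, LEARN_MODES, MEANINGFUL_IMAGES,
                     WHO_MODES, ImageKind, Level, ParadigmConfig)
from .errors import EncodingError, GenerationError, RuleError

TRIAL_COLUMNS = [
    "trial", "block", "block_mode", "index_in_block", "kind",
    "image", "image_variant", "side", "category",
    "tone_slot", "tone_offset_ms", "tone_pair_type",
    "distractor", "cd_tone",
    "duration_ms", "onset_ms", "expected_button", "marker_code",
]

_VARIANT_COUNTS = {
    ImageKind.MOONEY_FACE: 30,
    ImageKind.MOONEY_DISTORTED: 30,
    ImageKind.KANIZSA: 2,
    ImageKind.KANIZSA_DISTORTED: 2,
}


@dataclass(frozen=True)
class BlockSpec:
    """Static description of one block's oddball assignment."""

    index: int                      # 1-based
    level: Level
    mode: str
    frequent_image: ImageKind
    frequent_side: str              # "left" | "right"
    rare_images: tuple[ImageKind, ImageKind]
    rare_counts: tuple[int, int]    # per-block counts for rare_images

    def __post_init__(self) -> None:
        if self.frequent_image in self.rare_images:
            raise GenerationError("frequent image cannot also be rare")
        if len(set(self.rare_images)) != 2:
            raise GenerationError("rare_images must hold 2 distinct kinds")

    @property
    def rare_side(self) -> str:
        return "right" if self.frequent_side == "left" else "left"


@dataclass
class LevelSchedule:
    """Complete ordered event plan for one game level."""

    level: Level
    seed: int
    config: ParadigmConfig
    blocks: list[BlockSpec]
    trials: pd.DataFrame = field(repr=False)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def total_duration_ms(self) -> int:
        last = self.trials.iloc[-1]
        return int(last.onset_ms + last.duration_ms)


@dataclass
class ScheduleStats:
    n_trials: int
    n_blocks: int
    frequent_pct: float
    rare_pct: float
    deviant_tone_pct_of_tone_slots: float
    mean_duration_ms: float
    min_duration_ms: int
    max_duration_ms: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _block_modes(level: Level, config: ParadigmConfig,
                 rng: np.random.Generator) -> list[str]:
    n = config.blocks_per_level
    if level is Level.LEARN:
        # odd-numbered blocks passive, even-numbered active
        return [LEARN_MODES[0] if (i + 1) % 2 else LEARN_MODES[1]
                for i in range(n)]
    if level is Level.WHO:
        modes = [WHO_MODES[0]] * (n // 2) + [WHO_MODES[1]] * (n // 2)
        rng.shuffle(modes)
        return modes
    return [DISCERN_MODES[0] if i < n // 2 else DISCERN_MODES[1]
            for i in range(n)]


def assign_block_oddball(block_index: int, level: Level,
                         rng: np.random.Generator,
                         mode: str,
                         rare_pair: tuple[ImageKind, ImageKind],
                         frequent_pool: tuple[ImageKind, ImageKind],
                         config: ParadigmConfig | None = None) -> BlockSpec:
    """Choose the frequent image/side and the rare split for one block.

    The rare pair is fixed per level; blocks alternate a 3/2 and 2/3 split
    between the two rare kinds so the level totals are exact.
    """
    cfg = config or ParadigmConfig()
    if not 1 <= block_index <= cfg.blocks_per_level:
        raise GenerationError(f"block_index {block_index} out of range")
    frequent = frequent_pool[int(rng.integers(len(frequent_pool)))]
    side = "left" if rng.integers(2) == 0 else "right"
    hi = cfg.rare_per_block // 2 + cfg.rare_per_block % 2   # e.g. 3 of 5
    lo = cfg.rare_per_block - hi
    counts = (hi, lo) if block_index % 2 else (lo, hi)
    return BlockSpec(index=block_index, level=level, mode=mode,
                     frequent_image=frequent, frequent_side=side,
                     rare_images=rare_pair, rare_counts=counts)


def response_rule(level: Level, block_mode: str, trial) -> str:
    """Expected button ("left"/"right"/"none") for a stimulus trial.

    Learn passive blocks require no response; Learn active and both Who
    modes map the button to the side of the salient image; Discern maps
    meaningful images to left under rule_A and to right after the reversal.
    """
    kind = trial["kind"] if not isinstance(trial, str) else trial
    if kind == "baseline":
        raise RuleError("baseline trials have no response rule")
    if level is Level.LEARN and block_mode == "passive":
        return "none"
    if level in (Level.LEARN, Level.WHO):
        return trial["side"]
    meaningful = ImageKind(trial["image"]) in MEANINGFUL_IMAGES
    if block_mode == "rule_A":
        return "left" if meaningful else "right"
    return "right" if meaningful else "left"


def encode_event_marker(trial, response_button: str = "na",
                        accuracy: str = "na") -> str:
    """Structured condition code, bijective with its field tuple."""
    required = ("block", "block_mode", "kind")
    for f in required:
        if f not in trial or trial[f] in ("", None):
            raise EncodingError(f"unresolved trial field: {f}")
    if trial["kind"] == "baseline":
        img = side = cat = tone = dist = "none"
    else:
        img, side, cat = trial["image"], trial["side"], trial["category"]
        dist = trial["distractor"]
        if trial["tone_slot"] == "pair":
            tone = f"{int(trial['tone_offset_ms']):+d}:{trial['tone_pair_type']}"
        else:
            tone = "none"
    level = trial["level"] if "level" in trial else trial.get("level", "?")
    return "|".join([str(level), f"b{int(trial['block']):02d}",
                     trial["block_mode"], img, side, cat, tone, dist,
                     response_button, accuracy])


def decode_event_marker(code: str) -> dict:
    parts = code.split("|")
    if len(parts) != 10:
        raise EncodingError(f"malformed marker code: {code!r}")
    keys = ("level", "block", "block_mode", "image", "side", "category",
            "tone", "distractor", "response_button", "accuracy")
    out = dict(zip(keys, parts))
    out["block"] = int(out["block"][1:])
    return out


class MarkerRegistry:
    """Sequential (first-seen order) numeric aliases for marker codes."""

    def __init__(self) -> None:
        self._codes: dict[str, int] = {}

    def alias(self, code: str) -> int:
        if code not in self._codes:
            self._codes[code] = len(self._codes) + 1
        return self._codes[code]

    def __len__(self) -> int:
        return len(self._codes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"numeric_alias": list(self._codes.values()),
             "marker_code": list(self._codes.keys())})


def assign_tone_events(trials: pd.DataFrame, config: ParadigmConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Mark tone slots on every 4th stimulus trial and draw pair types.

    Pair-type counts are exact per level: 80% standard-standard, 10% with a
    deviant S2, 10% silent.
    """
    stim_idx = trials.index[trials["kind"] == "stimulus"]
    slots = stim_idx[::config.tone_slot_stride]
    n = len(slots)
    if n == 0:
        raise GenerationError("sequence too short for any tone slot")
    n_std = round(config.tone_std_fraction * n)
    n_dev = round(config.tone_dev_fraction * n)
    n_sil = n - n_std - n_dev
    pair_types = np.array(["std_std"] * n_std + ["std_dev"] * n_dev
                          + ["silent"] * n_sil)
    rng.shuffle(pair_types)
    offsets = rng.choice(config.tone_offsets_ms, size=n)
    trials.loc[slots, "tone_slot"] = "pair"
    trials.loc[slots, "tone_pair_type"] = pair_types
    trials.loc[slots, "tone_offset_ms"] = offsets.astype(float)
    return trials


def compute_trial_timing(trials: pd.DataFrame, config: ParadigmConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-trial jitter and accumulate onsets."""
    jitter = rng.integers(0, config.jitter_max_ms + 1, size=len(trials))
    trials["duration_ms"] = config.fixed_trial_ms + jitter
    dur = trials["duration_ms"].to_numpy()
    onsets = np.concatenate([[0], np.cumsum(dur)[:-1]])
    trials["onset_ms"] = onsets
    return trials


def generate_level(level: Level | str, config: ParadigmConfig | None = None,
                   seed: int = 0) -> LevelSchedule:
    """Generate the full, deterministic schedule for one game level."""
    level = Level(level)
    cfg = config or ParadigmConfig()
    rng = np.random.default_rng(seed)

    kinds = list(ImageKind)
    order = rng.permutation(len(kinds))
    rare_pair = (kinds[order[0]], kinds[order[1]])
    frequent_pool = (kinds[order[2]], kinds[order[3]])
    modes = _block_modes(level, cfg, rng)

    blocks: list[BlockSpec] = []
    rows: list[dict] = []
    trial_no = 0
    for b in range(1, cfg.blocks_per_level + 1):
        spec = assign_block_oddball(b, level, rng, modes[b - 1], rare_pair,
                                    frequent_pool, cfg)
        blocks.append(spec)
        images = np.array([spec.frequent_image.value] * cfg.stim_trials_per_block,
                          dtype=object)
        rare_labels = ([spec.rare_images[0].value] * spec.rare_counts[0]
                       + [spec.rare_images[1].value] * spec.rare_counts[1])
        rng.shuffle(rare_labels)
        # first two stimulus trials stay frequent
        rare_pos = rng.choice(np.arange(2, cfg.stim_trials_per_block),
                              size=cfg.rare_per_block, replace=False)
        rare_pos.sort()
        images[rare_pos] = rare_labels
        for p in range(cfg.stim_trials_per_block):
            trial_no += 1
            img = ImageKind(images[p])
            is_rare = p in rare_pos
            row = {
                "trial": trial_no, "block": b, "block_mode": spec.mode,
                "index_in_block": p + 1, "kind": "stimulus",
                "image": img.value,
                "image_variant": int(rng.integers(_VARIANT_COUNTS[img])),
                "side": spec.rare_side if is_rare else spec.frequent_side,
                "category": "rare" if is_rare else "frequent",
                "tone_slot": "none", "tone_offset_ms": np.nan,
                "tone_pair_type": "none",
                "distractor": "top" if rng.integers(2) == 0 else "bottom",
                "cd_tone": ("on_response" if spec.mode == "cd_immediate"
                            else "random_delay" if spec.mode == "cd_random"
                            else "none"),
            }
            rows.append(row)
        for p in range(cfg.baseline_trials_per_block):
            trial_no += 1
            rows.append({
                "trial": trial_no, "block": b, "block_mode": spec.mode,
                "index_in_block": cfg.stim_trials_per_block + p + 1,
                "kind": "baseline", "image": "none", "image_variant": -1,
                "side": "none", "category": "none",
                "tone_slot": "none", "tone_offset_ms": np.nan,
                "tone_pair_type": "none", "distractor": "none",
                "cd_tone": "none",
            })

    trials = pd.DataFrame(rows)
    trials["level"] = level.value
    trials = assign_tone_events(trials, cfg, rng)
    trials = compute_trial_timing(trials, cfg, rng)
    trials["expected_button"] = [
        response_rule(level, r["block_mode"], r) if r["kind"] == "stimulus"
        else "none"
        for r in trials.to_dict("records")]
    trials["marker_code"] = [encode_event_marker(r)
                             for r in trials.to_dict("records")]
    trials = trials[["level"] + TRIAL_COLUMNS]
    return LevelSchedule(level=level, seed=seed, config=cfg, blocks=blocks,
                         trials=trials)


def generate_run(config: ParadigmConfig | None = None,
                 seed: int = 0) -> dict[Level, LevelSchedule]:
    """Generate all three levels with level-distinct sub-seeds."""
    cfg = config or ParadigmConfig()
    ss = np.random.SeedSequence(seed).spawn(len(Level))
    return {lv: generate_level(lv, cfg, seed=int(s.generate_state(1)[0]))
            for lv, s in zip(Level, ss)}


def validate_schedule(schedule: LevelSchedule) -> tuple[ScheduleStats, list[str]]:
    """Check every structural invariant; violations reported, not raised."""
    cfg = schedule.config
    t = schedule.trials
    v: list[str] = []

    if len(t) != cfg.trials_per_level:
        v.append(f"expected {cfg.trials_per_level} trials, found {len(t)}")
    n_blocks = t["block"].nunique()
    if n_blocks != cfg.blocks_per_level:
        v.append(f"expected {cfg.blocks_per_level} blocks, found {n_blocks}")
    for b, grp in t.groupby("block"):
        kinds = grp["kind"].to_numpy()
        if (kinds[:cfg.stim_trials_per_block] != "stimulus").any() or \
           (kinds[cfg.stim_trials_per_block:] != "baseline").any():
            v.append(f"block {b}: trial ordering violates 25 stimulus + 3 baseline")

    stim = t[t["kind"] == "stimulus"]
    base = t[t["kind"] == "baseline"]
    n_freq = int((stim["category"] == "frequent").sum())
    n_rare = int((stim["category"] == "rare").sum())
    if n_freq != round(cfg.frequent_fraction * len(stim)):
        v.append(f"frequent count {n_freq} != expected")
    for kind, cnt in stim[stim["category"] == "rare"]["image"].value_counts().items():
        expected = round(len(stim) * (1 - cfg.frequent_fraction) / 2)
        if cnt != expected:
            v.append(f"rare type {kind} count {cnt} != {expected}")

    if (base["image"] != "none").any() or (base["tone_slot"] != "none").any() \
            or (base["distractor"] != "none").any():
        v.append("baseline trials must have no image/tones/distractors")

    slot_mask = (t["tone_slot"] == "pair").to_numpy()
    slot_idx = np.flatnonzero(slot_mask)
    if len(slot_idx) > 1 and np.diff(slot_idx).min() < cfg.tone_slot_stride:
        v.append("tone-slot spacing < stride (slot must be followed by >=3 "
                 "toneless trials)")
    slots = t[slot_mask]
    if len(slots):
        mix = slots["tone_pair_type"].value_counts(normalize=True)
        for name, frac in (("std_std", cfg.tone_std_fraction),
                           ("std_dev", cfg.tone_dev_fraction),
                           ("silent", cfg.tone_silent_fraction)):
            if abs(mix.get(name, 0.0) - frac) > 1e-9:
                v.append(f"tone pair mix for {name}: {mix.get(name, 0.0)} "
                         f"!= {frac}")
        bad = ~slots["tone_offset_ms"].isin(cfg.tone_offsets_ms)
        if bad.any():
            v.append("tone offsets outside configured set")

    dmin, dmax = int(t["duration_ms"].min()), int(t["duration_ms"].max())
    lo, hi = cfg.fixed_trial_ms, cfg.fixed_trial_ms + cfg.jitter_max_ms
    if dmin < lo or dmax > hi:
        v.append(f"durations [{dmin}, {dmax}] outside [{lo}, {hi}]")
    onsets = t["onset_ms"].to_numpy()
    if not np.array_equal(
            onsets[1:], onsets[:-1] + t["duration_ms"].to_numpy()[:-1]):
        v.append("onsets are not cumulative")

    ndev = int((slots["tone_pair_type"] == "std_dev").sum()) if len(slots) else 0
    stats = ScheduleStats(
        n_trials=len(t), n_blocks=n_blocks,
        frequent_pct=100.0 * n_freq / max(len(stim), 1),
        rare_pct=100.0 * n_rare / max(len(stim), 1),
        deviant_tone_pct_of_tone_slots=100.0 * ndev / max(len(slots), 1),
        mean_duration_ms=float(t["duration_ms"].mean()),
        min_duration_ms=dmin, max_duration_ms=dmax)
    return stats, v
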