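"""Paradigm configuration and shared enumerations.

The task runs in three game levels of increasing complexity (``Learn``,
``Who``, ``Discern``).  Each level is 16 blocks of 25 stimulus trials plus 3
baseline trials; one salient image type appears on one side of fixation on
80% of stimulus trials while two other types share the opposite side for the
remaining 20% (10% each).  Paired auditory tones, bilateral visual
distractors and a jittered trial length complete the design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum

from .errors import ConfigError, DomainError


class Level(str, Enum):
    LEARN = "Learn"
    WHO = "Who"
    DISCERN = "Discern"


class ImageKind(str, Enum):
    MOONEY_FACE = "MooneyFace"
    MOONEY_DISTORTED = "MooneyDistorted"
    KANIZSA = "Kanizsa"
    KANIZSA_DISTORTED = "KanizsaDistorted"


#: Image kinds read as "meaningful" under the Discern response rules.
MEANINGFUL_IMAGES = frozenset({ImageKind.MOONEY_FACE, ImageKind.KANIZSA})

#: Block modes, keyed by level.
LEARN_MODES = ("passive", "active")
WHO_MODES = ("cd_immediate", "cd_random")
DISCERN_MODES = ("rule_A", "rule_B")

FEEDBACK_LOW = "Well tried! Try to respond more accurately."
FEEDBACK_MID = "Good job, Keep it up!"
FEEDBACK_HIGH = "Outstanding! Now try to respond a bit faster."


@dataclass(frozen=True)
class ParadigmConfig:
    """All timing/probability constants of the paradigm, with defaults."""

    stim_duration_ms: int = 240
    response_window_ms: int = 700
    end_baseline_min_ms: int = 200
    jitter_max_ms: int = 700
    pre_mask_ms: int = 60
    tone_offsets_ms: tuple[int, ...] = (-240, -40, 160)
    s1_s2_gap_ms: int = 500
    standard_tone_hz: int = 1000
    deviant_tone_hz: int = 1500
    tone_duration_ms: int = 15
    cd_tone_duration_ms: int = 230
    blocks_per_level: int = 16
    stim_trials_per_block: int = 25
    baseline_trials_per_block: int = 3
    frequent_fraction: float = 0.8
    feedback_low_pct: float = 85.0
    feedback_high_pct: float = 95.0
    # Tone-slot mix, as fractions of tone-slot trials.
    tone_std_fraction: float = 0.8
    tone_dev_fraction: float = 0.1
    tone_silent_fraction: float = 0.1
    tone_slot_stride: int = 4
    # cd_random delay after stimulus offset, uniform on this range.
    cd_random_delay_ms: tuple[int, int] = (100, 500)

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities ------------------------------------------------
    @property
    def trials_per_block(self) -> int:
        return self.stim_trials_per_block + self.baseline_trials_per_block

    @property
    def trials_per_level(self) -> int:
        return self.blocks_per_level * self.trials_per_block

    @property
    def stim_trials_per_level(self) -> int:
        return self.blocks_per_level * self.stim_trials_per_block

    @property
    def frequent_per_block(self) -> int:
        return round(self.frequent_fraction * self.stim_trials_per_block)

    @property
    def rare_per_block(self) -> int:
        return self.stim_trials_per_block - self.frequent_per_block

    @property
    def fixed_trial_ms(self) -> int:
        return (self.pre_mask_ms + self.stim_duration_ms
                + self.response_window_ms + self.end_baseline_min_ms)

    @property
    def tone_slots_per_level(self) -> int:
        n = self.stim_trials_per_level
        return (n + self.tone_slot_stride - 1) // self.tone_slot_stride

    def validate(self) -> None:
        durations = (self.stim_duration_ms, self.response_window_ms,
                     self.end_baseline_min_ms, self.pre_mask_ms,
                     self.tone_duration_ms, self.cd_tone_duration_ms,
                     self.s1_s2_gap_ms)
        if any(d <= 0 for d in durations):
            raise ConfigError("all durations must be positive")
        if self.jitter_max_ms < 0:
            raise ConfigError("jitter_max_ms must be >= 0")
        nfreq = self.frequent_fraction * self.stim_trials_per_block
        if abs(nfreq - round(nfreq)) > 1e-9:
            raise ConfigError(
                f"frequent_fraction * stim_trials_per_block = {nfreq} "
                "must be an integer")
        if self.blocks_per_level % 2:
            raise ConfigError("blocks_per_level must be even")
        mix = (self.tone_std_fraction + self.tone_dev_fraction
               + self.tone_silent_fraction)
        if abs(mix - 1.0) > 1e-9:
            raise ConfigError("tone-slot fractions must sum to 1")
        nslots = self.tone_slots_per_level
        for frac in (self.tone_std_fraction, self.tone_dev_fraction,
                     self.tone_silent_fraction):
            k = frac * nslots
            if abs(k - round(k)) > 1e-9:
                raise ConfigError(
                    "tone-slot fractions must give integer counts over "
                    f"{nslots} slots")
        if self.tone_slot_stride < 4:
            raise ConfigError("tone_slot_stride must be >= 4 (spacing rule)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tone_offsets_ms"] = list(self.tone_offsets_ms)
        d["cd_random_delay_ms"] = list(self.cd_random_delay_ms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParadigmConfig":
        d = dict(d)
        if "tone_offsets_ms" in d:
            d["tone_offsets_ms"] = tuple(d["tone_offsets_ms"])
        if "cd_random_delay_ms" in d:
            d["cd_random_delay_ms"] = tuple(d["cd_random_delay_ms"])
        return cls(**d)


def feedback_message(accuracy_pct: float,
                     config: ParadigmConfig | None = None) -> str:
    """Performance feedback shown after every two blocks.

    Total monotone step function on [0, 100]; the 85 and 95 boundaries fall
    in the middle band.
    """
    cfg = config or ParadigmConfig()
    if not (0 <= accuracy_pct <= 100):
        raise DomainError(f"accuracy_pct {accuracy_pct} outside [0, 100]")
    if accuracy_pct < cfg.feedback_low_pct:
        return FEEDBACK_LOW
    if accuracy_pct <= cfg.feedback_high_pct:
        return FEEDBACK_MID
    return FEEDBACK_HIGH
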