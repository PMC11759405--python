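"""Study protocol: trial timeline of the picture-viewing experiment.

The emulated protocol shows, per trial, a 2 s "new trial" cue, three
affective images of one emotion quality for 15 s each (nominal intensities
drawn from a discrete set), a 30 s black screen and a 30 s neutral image.
Eight trials per quality are run (24 in total, about 43 minutes); the first
trial of each quality is practice and excluded from analysis, leaving 7
analysed trials per quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ProtocolConfig", "TrialPlan", "Timeline", "generate_protocol"]

DEFAULT_QUALITIES = ("Q1", "Q2", "Q3")
#: Nominal image-intensity levels available to the stimulus set.
IMAGE_LEVELS = (0.3, 0.6, 0.9)


@dataclass(frozen=True)
class ProtocolConfig:
    n_subjects: int = 21
    qualities: tuple[str, ...] = DEFAULT_QUALITIES
    trials_per_quality: int = 8
    practice_per_quality: int = 1
    cue_s: float = 2.0
    image_s: float = 15.0
    n_images: int = 3
    black_s: float = 30.0
    neutral_s: float = 30.0
    fs_raw: float = 256.0
    image_levels: tuple[float, ...] = IMAGE_LEVELS
    seed: int = 0

    def __post_init__(self):
        counts = (self.n_subjects, self.trials_per_quality, self.n_images,
                  len(self.qualities))
        if any(c <= 0 for c in counts):
            raise ValueError("counts must be positive")
        durations = (self.cue_s, self.image_s, self.black_s, self.neutral_s,
                     self.fs_raw)
        if any(d <= 0 for d in durations):
            raise ValueError("durations and sampling rate must be positive")
        if not 0 <= self.practice_per_quality < self.trials_per_quality:
            raise ValueError("practice trials must leave analysed trials")

    @property
    def trial_duration_s(self) -> float:
        return (self.cue_s + self.n_images * self.image_s + self.black_s
                + self.neutral_s)

    @property
    def total_duration_s(self) -> float:
        return self.trial_duration_s * self.trials_per_quality * len(self.qualities)

    @property
    def analysed_per_quality(self) -> int:
        return self.trials_per_quality - self.practice_per_quality


@dataclass(frozen=True)
class TrialPlan:
    index: int
    quality: str
    practice: bool
    image_levels: tuple[float, ...]
    cue_s: float
    image_s: float
    black_s: float
    neutral_s: float

    @property
    def duration_s(self) -> float:
        return (self.cue_s + len(self.image_levels) * self.image_s
                + self.black_s + self.neutral_s)

    def image_onsets_s(self) -> tuple[float, ...]:
        return tuple(self.cue_s + i * self.image_s
                     for i in range(len(self.image_levels)))


@dataclass(frozen=True)
class Timeline:
    config: ProtocolConfig
    trials: tuple[TrialPlan, ...] = field(default_factory=tuple)

    @property
    def analysed(self) -> tuple[TrialPlan, ...]:
        return tuple(t for t in self.trials if not t.practice)

    def analysed_by_quality(self, quality: str) -> tuple[TrialPlan, ...]:
        return tuple(t for t in self.analysed if t.quality == quality)

    @property
    def total_duration_s(self) -> float:
        return sum(t.duration_s for t in self.trials)


def generate_protocol(config: ProtocolConfig,
                      seed: int | None = None) -> Timeline:
    """Draw a seeded trial timeline.

    The first ``practice_per_quality`` trials run in fixed quality order at
    the start of the session; the remaining trials are shuffled.  Per-image
    nominal intensity levels are drawn uniformly from the configured
    discrete set.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    order: list[tuple[str, bool]] = []
    for q in config.qualities:
        order.extend([(q, True)] * config.practice_per_quality)
    analysed = []
    for q in config.qualities:
        analysed.extend([(q, False)] * config.analysed_per_quality)
    analysed = [analysed[i] for i in rng.permutation(len(analysed))]
    order.extend(analysed)
    trials = []
    for i, (q, practice) in enumerate(order):
        levels = tuple(rng.choice(config.image_levels, size=config.n_images))
        trials.append(TrialPlan(
            index=i, quality=q, practice=practice, image_levels=levels,
            cue_s=config.cue_s, image_s=config.image_s,
            black_s=config.black_s, neutral_s=config.neutral_s))
    return Timeline(config=config, trials=tuple(trials))
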