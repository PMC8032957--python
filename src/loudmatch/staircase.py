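"""Adaptive 1-up-1-down loudness matching and match extraction.

Each trial the listener compares headphone and loudspeaker presentation
and reports which was louder; the headphone playback level is raised after
"loudspeaker louder" and lowered after "headphone louder", so the track
converges on the 50% point of the listener's psychometric function.  The
step size starts at 10 dB and is reduced to 5 dB and 1 dB after the first
and second upper reversals; these large initial steps together with a
start level well below the expected match act as a bracketing of the
equal-loudness level.  Reversals occurring before the 1 dB step takes
effect belong to the bracketing phase and are discarded; the run ends once
three upper and three lower measurement-phase reversals have been
collected, and the equal-loudness level is the median of those six
reversal levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)

HEADPHONE_LOUDER = "headphone_louder"
LOUDSPEAKER_LOUDER = "loudspeaker_louder"

Responder = Callable[[float], str]


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of the adaptive track."""

    step_schedule: tuple[float, ...] = (10.0, 5.0, 1.0)
    measurement_upper: int = 3
    measurement_lower: int = 3
    start_offset_range: tuple[float, float] = (15.0, 30.0)
    level_floor: float = 0.0
    level_ceiling: float = 110.0
    max_trials: int = 100

    def __post_init__(self) -> None:
        steps = np.asarray(self.step_schedule)
        if steps.size < 1 or np.any(steps <= 0) or np.any(np.diff(steps) >= 0):
            raise ValueError("step schedule must be strictly decreasing and positive")
        if self.measurement_upper < 1 or self.measurement_lower < 1:
            raise ValueError("at least one measurement reversal of each kind is required")
        if self.level_floor >= self.level_ceiling:
            raise ValueError("level floor must lie below the ceiling")
        lo, hi = self.start_offset_range
        if lo <= 0 or hi < lo:
            raise ValueError("start offset range must be positive and ordered")


@dataclass
class Trial:
    level: float
    response: str
    step: float
    phase: str  # "bracketing" | "measurement"


@dataclass
class StaircaseTrack:
    """Full trial history of one adaptive run."""

    trials: list[Trial] = field(default_factory=list)
    upper_reversals: list[int] = field(default_factory=list)  # trial indices
    lower_reversals: list[int] = field(default_factory=list)
    measurement_upper_levels: list[float] = field(default_factory=list)
    measurement_lower_levels: list[float] = field(default_factory=list)
    clipped: bool = False

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class EqualLoudnessMatch:
    """Converged headphone playback level (voltage-domain dB)."""

    hp_level: float
    n_trials: int
    converged: bool


def extract_match(track: StaircaseTrack) -> float:
    """Median of the pooled three upper and three lower measurement reversals."""
    up = track.measurement_upper_levels
    lo = track.measurement_lower_levels
    if len(up) < 3 or len(lo) < 3:
        raise ValueError(
            f"insufficient measurement reversals ({len(up)} upper, {len(lo)} lower)"
        )
    return float(np.median(np.array(up[:3] + lo[:3])))


def bracketing_start(
    expected_match: float,
    policy: tuple[float, float] = (15.0, 30.0),
    seed: int | np.random.Generator | None = None,
) -> float:
    """Start level below the expected match by a uniformly drawn offset."""
    lo, hi = policy
    if lo <= 0 or hi < lo:
        raise ValueError("offset policy must be positive and ordered")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return float(expected_match - rng.uniform(lo, hi))


def run_staircase(
    responder: Responder,
    config: StaircaseConfig = StaircaseConfig(),
    start_level: float = 40.0,
    seed: int | None = None,  # kept for interface symmetry; procedure is deterministic
) -> tuple[StaircaseTrack, EqualLoudnessMatch]:
    """Run the 1-up-1-down track against a responder until convergence.

    The responder maps a headphone playback level (dB) to one of the two
    verdicts.  Levels are clipped to the configured floor/ceiling (logged);
    non-convergence within ``max_trials`` yields an unconverged result
    rather than an exception.
    """
    track = StaircaseTrack()
    level = float(np.clip(start_level, config.level_floor, config.level_ceiling))
    step_idx = 0
    phase = "bracketing"
    bracketing_upper = 0
    prev_direction: int | None = None

    for t in range(config.max_trials):
        response = responder(level)
        if response not in (HEADPHONE_LOUDER, LOUDSPEAKER_LOUDER):
            raise ValueError(f"responder returned unknown verdict {response!r}")
        direction = 1 if response == LOUDSPEAKER_LOUDER else -1

        if prev_direction is not None and direction != prev_direction:
            if prev_direction == 1:  # peak: upper reversal
                track.upper_reversals.append(t)
                if phase == "measurement":
                    track.measurement_upper_levels.append(level)
                else:
                    bracketing_upper += 1
                    if step_idx < len(config.step_schedule) - 1:
                        step_idx += 1
                    if bracketing_upper >= 2 or step_idx == len(config.step_schedule) - 1:
                        phase = "measurement"
            else:  # valley: lower reversal
                track.lower_reversals.append(t)
                if phase == "measurement":
                    track.measurement_lower_levels.append(level)
        prev_direction = direction

        step = config.step_schedule[step_idx]
        track.trials.append(Trial(level, response, step, phase))

        done = (
            len(track.measurement_upper_levels) >= config.measurement_upper
            and len(track.measurement_lower_levels) >= config.measurement_lower
        )
        if done:
            match = extract_match(track)
            return track, EqualLoudnessMatch(match, track.n_trials, True)

        new_level = level + direction * step
        clipped = float(np.clip(new_level, config.level_floor, config.level_ceiling))
        if clipped != new_level:
            track.clipped = True
            logger.warning("staircase level clipped to %.1f dB", clipped)
        level = clipped

    # not converged: fall back to the median of whatever measurement
    # reversals exist, else the last presented level
    pooled = track.measurement_upper_levels + track.measurement_lower_levels
    hp = float(np.median(pooled)) if pooled else level
    hp = float(np.clip(hp, config.level_floor, config.level_ceiling))
    logger.warning("staircase did not converge within %d trials", config.max_trials)
    return track, EqualLoudnessMatch(hp, track.n_trials, False)
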