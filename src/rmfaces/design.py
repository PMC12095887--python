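"""Stimulus continuum, animations, and trial schedules for the probe-judgement task.

The stimulus set is a 21-level morph continuum per avatar between a fully angry
(level 1) and a fully happy (level 21) expression; level 11 is the ambiguous
midpoint (50% anger, 50% happiness).  Animations run 11 frames from one pole to
the midpoint; probes sit at the endpoint or 1-3 frames before/beyond it.

Two coordinate systems coexist:

* **physical level** (1..21) identifies a picture on the continuum and is the
  coordinate of the staircase task;
* **motion-aligned level** puts the animation endpoint at 11 with larger values
  further along the motion direction, for *both* emotions.  All probe-task
  analysis happens in this coordinate, so a forward bias is positive regardless
  of whether the animation ran angry-to-ambiguous or happy-to-ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

ANGRY_TO_AMBIGUOUS = "angry-to-ambiguous"
HAPPY_TO_AMBIGUOUS = "happy-to-ambiguous"
EMOTIONS = (ANGRY_TO_AMBIGUOUS, HAPPY_TO_AMBIGUOUS)

N_LEVELS = 21
ENDPOINT = 11  # ambiguous midpoint, both coordinates
PROBE_MOTION_LEVELS = tuple(range(8, 15))  # 3 before .. 3 beyond the endpoint
N_REPETITIONS = 3
N_TRAINING_TRIALS = 5

#: default avatar roster: 2 sexes x 2 identities
DEFAULT_AVATARS = (
    ("f1", "female"),
    ("f2", "female"),
    ("m1", "male"),
    ("m2", "male"),
)

SCHEDULE_COLUMNS = [
    "trial_index",
    "is_training",
    "emotion",
    "avatar_sex",
    "avatar_id",
    "probe_motion_level",
    "probe_physical_level",
    "repetition",
    "seed",
]


@dataclass(frozen=True)
class ContinuumSpec:
    """A 21-step anger/happiness morph continuum for one avatar."""

    avatar_id: str
    avatar_sex: str
    n_levels: int = N_LEVELS

    def anger_share(self, level: int) -> float:
        """Fraction of anger at a physical level (1.0 at level 1, 0.0 at 21)."""
        self._check_level(level)
        return (self.n_levels - level) / (self.n_levels - 1)

    def happiness_share(self, level: int) -> float:
        self._check_level(level)
        return (level - 1) / (self.n_levels - 1)

    def stimulus_ids(self) -> list[str]:
        """Unique identifier per picture on this avatar's continuum."""
        return [f"{self.avatar_id}_L{level:02d}" for level in range(1, self.n_levels + 1)]

    def _check_level(self, level: int) -> None:
        if not 1 <= level <= self.n_levels:
            raise ValueError(f"physical level {level} outside 1..{self.n_levels}")


@dataclass(frozen=True)
class AnimationSpec:
    """An 11-frame animation ending at the ambiguous midpoint.

    Frame durations are 200 ms for the first and last frames and 80 ms for the
    nine intermediate frames; the post-animation mask lasts 250 ms.
    """

    emotion: str
    frames: tuple[int, ...]
    durations_ms: tuple[int, ...] = (200,) + (80,) * 9 + (200,)
    mask_duration_ms: int = 250

    @property
    def total_duration_ms(self) -> int:
        return sum(self.durations_ms)


@dataclass(frozen=True)
class TrialSpec:
    """One probe-judgement trial: a condition cell plus the probed level."""

    emotion: str
    avatar_sex: str
    avatar_id: str
    probe_motion_level: int
    repetition: int
    is_training: bool = False
    fixation_ms: float = 1000.0  # jittered 800-1200 ms in the timeline

    @property
    def probe_physical_level(self) -> int:
        return motion_to_physical(self.emotion, self.probe_motion_level)


def build_continuum(avatar_id: str, avatar_sex: str) -> ContinuumSpec:
    """Build the 21-level morph continuum for one avatar."""
    if avatar_sex not in ("male", "female"):
        raise ValueError(f"avatar_sex must be 'male' or 'female', got {avatar_sex!r}")
    return ContinuumSpec(avatar_id=avatar_id, avatar_sex=avatar_sex)


def build_animation(emotion: str, continuum: ContinuumSpec) -> AnimationSpec:
    """Build the 11-frame animation for an emotion condition on a continuum.

    Angry-to-ambiguous runs physical levels 1..11 ascending; happy-to-ambiguous
    runs 21..11 descending.  Both end on the ambiguous midpoint.
    """
    _check_emotion(emotion)
    if emotion == ANGRY_TO_AMBIGUOUS:
        frames = tuple(range(1, ENDPOINT + 1))
    else:
        frames = tuple(range(continuum.n_levels, ENDPOINT - 1, -1))
    return AnimationSpec(emotion=emotion, frames=frames)


def motion_to_physical(emotion: str, motion_level: int) -> int:
    """Map a motion-aligned probe level to its physical continuum level.

    Identity for angry-to-ambiguous (motion runs up the continuum); mirrored
    about the midpoint (22 - L) for happy-to-ambiguous.
    """
    _check_emotion(emotion)
    if emotion == ANGRY_TO_AMBIGUOUS:
        return motion_level
    return 2 * ENDPOINT - motion_level


def all_stimulus_ids(avatars: Sequence[tuple[str, str]] = DEFAULT_AVATARS) -> list[str]:
    """Every picture identifier across the avatar roster (84 for the default 4)."""
    ids: list[str] = []
    for avatar_id, avatar_sex in avatars:
        ids.extend(build_continuum(avatar_id, avatar_sex).stimulus_ids())
    return ids


def generate_schedule(
    seed: int,
    avatars: Sequence[tuple[str, str]] = DEFAULT_AVATARS,
    n_training: int = N_TRAINING_TRIALS,
) -> list[TrialSpec]:
    """Generate a randomised trial schedule for one session.

    The analysis block is the full factorial 2 Emotion x 2 Avatar Sex x
    2 Avatar Identity x 7 Probe x 3 repetitions = 168 trials, uniformly
    shuffled.  ``n_training`` flagged training trials, built from a held-out
    avatar so no training stimulus recurs in the main task, precede them.
    Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)

    trials: list[TrialSpec] = []
    for emotion in EMOTIONS:
        for avatar_id, avatar_sex in avatars:
            for level in PROBE_MOTION_LEVELS:
                for rep in range(1, N_REPETITIONS + 1):
                    trials.append(
                        TrialSpec(
                            emotion=emotion,
                            avatar_sex=avatar_sex,
                            avatar_id=avatar_id,
                            probe_motion_level=level,
                            repetition=rep,
                            fixation_ms=float(rng.uniform(800, 1200)),
                        )
                    )
    order = rng.permutation(len(trials))
    trials = [trials[i] for i in order]

    training: list[TrialSpec] = []
    for _ in range(n_training):
        training.append(
            TrialSpec(
                emotion=EMOTIONS[int(rng.integers(2))],
                avatar_sex="female" if rng.integers(2) else "male",
                avatar_id="train",
                probe_motion_level=int(rng.choice(PROBE_MOTION_LEVELS)),
                repetition=1,
                is_training=True,
                fixation_ms=float(rng.uniform(800, 1200)),
            )
        )
    return training + trials


def schedule_to_frame(trials: Sequence[TrialSpec], seed: int | None = None) -> pd.DataFrame:
    rows = []
    for i, t in enumerate(trials):
        rows.append(
            {
                "trial_index": i,
                "is_training": t.is_training,
                "emotion": t.emotion,
                "avatar_sex": t.avatar_sex,
                "avatar_id": t.avatar_id,
                "probe_motion_level": t.probe_motion_level,
                "probe_physical_level": t.probe_physical_level,
                "repetition": t.repetition,
                "seed": seed if seed is not None else pd.NA,
            }
        )
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


def write_schedule(trials: Sequence[TrialSpec], path, seed: int | None = None) -> None:
    schedule_to_frame(trials, seed=seed).to_csv(path, index=False)


def read_schedule(path) -> list[TrialSpec]:
    df = pd.read_csv(path)
    missing = set(SCHEDULE_COLUMNS) - {"seed"} - set(df.columns)
    if missing:
        raise ValueError(f"schedule file missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            TrialSpec(
                emotion=row["emotion"],
                avatar_sex=row["avatar_sex"],
                avatar_id=str(row["avatar_id"]),
                probe_motion_level=int(row["probe_motion_level"]),
                repetition=int(row["repetition"]),
                is_training=bool(row["is_training"]),
            )
        )
    return out


def _check_emotion(emotion: str) -> None:
    if emotion not in EMOTIONS:
        raise ValueError(f"unknown emotion condition {emotion!r}; expected one of {EMOTIONS}")
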