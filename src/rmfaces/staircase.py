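"""Transformed two-up/two-down staircases for the ambiguity-threshold task.

Each avatar gets two randomly interleaved staircases on the physical morph
continuum (1 = fully angry, 21 = fully happy), one starting at each pole.  The
level moves only after two successive identical categorizations, stepping
toward the pole of the *other* category — two "angry" responses push the level
up (happier), two "happy" responses push it down (angrier) — so both stairs
home in on the category boundary.  (A literal mode that steps toward the pole
of the repeated response is available behind ``boundary_seeking=False`` for
comparison; it runs away from the boundary and is not used in analysis.)

Steps are three pictures before a stair's first reversal and one picture
afterwards; a reversal is a sign flip of the realised movement direction, the
first movement setting the direction without counting.  A stair completes
after at least four reversals and at least five presentations.

The ambiguity threshold for an avatar is the mean of the levels at which
reversals occurred while the one-picture step was in force, pooled over the
avatar's two stairs; values below 11 mean a slightly angry picture is perceived
as ambiguous.  The staircase JND is the sample SD of those same levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LEVEL_MIN, LEVEL_MAX = 1, 21


@dataclass(frozen=True)
class StairConfig:
    start_levels: tuple[int, int] = (LEVEL_MIN, LEVEL_MAX)
    step_before_first_reversal: int = 3
    step_after: int = 1
    min_reversals: int = 4
    min_presentations: int = 5
    boundary_seeking: bool = True

    def __post_init__(self) -> None:
        if self.step_before_first_reversal <= 0 or self.step_after <= 0:
            raise ValueError("step sizes must be positive")
        if self.min_reversals < 1:
            raise ValueError("min_reversals must be >= 1")


@dataclass
class StairState:
    """One staircase: current level, response run, and reversal history."""

    stair_id: str
    avatar_id: str
    start_level: int
    config: StairConfig = field(default_factory=StairConfig)
    current_level: int = 0
    presentations: int = 0
    run: list[str] = field(default_factory=list)
    movement_direction: int = 0        # -1 toward angry, +1 toward happy, 0 unset
    reversals: list[tuple[int, int]] = field(default_factory=list)  # (level, step)
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not LEVEL_MIN <= self.start_level <= LEVEL_MAX:
            raise ValueError("start level outside the continuum")
        self.current_level = self.start_level

    @property
    def had_first_reversal(self) -> bool:
        return len(self.reversals) >= 1

    @property
    def step_size(self) -> int:
        return (
            self.config.step_after
            if self.had_first_reversal
            else self.config.step_before_first_reversal
        )

    @property
    def complete(self) -> bool:
        return is_complete(self)


def init_session(
    avatar_ids, config: StairConfig | None = None
) -> list[StairState]:
    """Two stairs per avatar, one from the fully angry and one from the fully
    happy pole."""
    config = config or StairConfig()
    if not avatar_ids:
        raise ValueError("need at least one avatar")
    stairs = []
    for avatar in avatar_ids:
        for j, start in enumerate(config.start_levels):
            stairs.append(
                StairState(
                    stair_id=f"{avatar}_s{j}",
                    avatar_id=str(avatar),
                    start_level=start,
                    config=config,
                )
            )
    return stairs


def next_stair(session: list[StairState], rng: np.random.Generator) -> StairState:
    """Uniformly random choice among the session's incomplete stairs."""
    open_stairs = [s for s in session if not s.complete]
    if not open_stairs:
        raise RuntimeError("all stairs are complete")
    return open_stairs[int(rng.integers(len(open_stairs)))]


def update_stair(stair: StairState, response: str) -> StairState:
    """Register one categorization on a stair and apply the two-up/two-down rule.

    The stair moves only after two successive identical responses; the pair
    counter then resets.  Movement is clamped to [1, 21]; a reversal is logged,
    tagged with the step size in force, whenever the realised direction flips.
    """
    if stair.complete:
        raise RuntimeError(f"stair {stair.stair_id} already complete")
    if response not in ("angry", "happy"):
        raise ValueError(f"response must be 'angry' or 'happy', got {response!r}")

    stair.presentations += 1
    level_before = stair.current_level
    step_used = 0
    reversal = False

    stair.run.append(response)
    if len(stair.run) >= 2 and stair.run[-1] == stair.run[-2]:
        step = stair.step_size
        if stair.config.boundary_seeking:
            direction = +1 if response == "angry" else -1
        else:  # literal reading: toward the repeated category's pole
            direction = -1 if response == "angry" else +1
        if stair.movement_direction != 0 and direction != stair.movement_direction:
            reversal = True
            stair.reversals.append((stair.current_level, step))
        stair.movement_direction = direction
        stair.current_level = int(
            np.clip(stair.current_level + direction * step, LEVEL_MIN, LEVEL_MAX)
        )
        step_used = step
        stair.run.clear()

    stair.history.append(
        {
            "stair_id": stair.stair_id,
            "avatar": stair.avatar_id,
            "start_level": stair.start_level,
            "presentation_index": stair.presentations,
            "level": level_before,
            "response": response,
            "step_size": step_used,
            "is_reversal": reversal,
        }
    )
    return stair


def is_complete(stair: StairState) -> bool:
    """A stair is finished after >= 4 reversals and >= 5 presentations."""
    return (
        len(stair.reversals) >= stair.config.min_reversals
        and stair.presentations >= stair.config.min_presentations
    )


def _step1_reversal_levels(stairs, step_size: int = 1) -> np.ndarray:
    levels = [
        lvl for s in stairs for (lvl, step) in s.reversals if step == step_size
    ]
    return np.asarray(levels, dtype=float)


def ambiguity_threshold(stairs) -> float:
    """Mean level of the reversals recorded at step size 1, pooled over stairs."""
    levels = _step1_reversal_levels(stairs)
    if levels.size == 0:
        raise ValueError("no step-1 reversals recorded")
    return float(levels.mean())


def staircase_jnd(stairs) -> float:
    """Sample SD of the step-1 reversal levels (dispersion-based JND)."""
    levels = _step1_reversal_levels(stairs)
    if levels.size < 2:
        raise ValueError("need at least two step-1 reversals")
    return float(levels.std(ddof=1))


def run_session(
    observer,
    avatar_ids,
    rng: np.random.Generator,
    config: StairConfig | None = None,
    max_presentations: int = 10_000,
) -> list[StairState]:
    """Drive a full interleaved session with a synthetic categorizer.

    ``observer`` provides categorizations through
    :func:`rmfaces.observer.simulate_categorization`.
    """
    from .observer import simulate_categorization

    session = init_session(avatar_ids, config=config)
    total = 0
    while any(not s.complete for s in session):
        stair = next_stair(session, rng)
        response = simulate_categorization(observer, stair.current_level, rng)
        update_stair(stair, response)
        total += 1
        if total > max_presentations:
            raise RuntimeError("session failed to terminate")
    return session


def session_log(session) -> pd.DataFrame:
    rows = [row for s in session for row in s.history]
    return pd.DataFrame(rows)
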