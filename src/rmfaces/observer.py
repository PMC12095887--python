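"""Generative model of a participant in the probe-judgement and staircase tasks.

The observer stores a noisy memory of the animation endpoint.  In motion-aligned
coordinates the remembered endpoint is ``R = 11 + delta + eps`` where ``delta``
is an emotion-specific forward displacement (the representational-momentum
parameter; positive = shifted further along the motion) and
``eps ~ N(0, sigma^2)`` is memory noise.  The probe at motion level ``L`` is
judged "equal" when ``|L - R| < c`` for an equality criterion half-width ``c``.
Attentional lapses occur with probability ``lapse`` and answer "equal" with
probability ``guess_equal`` at uniform confidence.  On non-lapse trials the
confidence rating grades the distance of the evidence ``|L - R|`` from the
criterion boundary ``c`` through three increasing cutpoints.

This mechanism integrates in closed form: the probability of an "equal"
response is a difference of Gaussian CDFs, giving the bell-shaped
proportion-"equal" profile over probe levels whose peak sits at ``11 + delta``.

For the staircase task the observer categorises a static picture as happy with
probability ``Phi((level - cat_threshold) / cat_sigma)`` on the physical
continuum (level 21 = fully happy).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import (
    ANGRY_TO_AMBIGUOUS,
    DEFAULT_AVATARS,
    EMOTIONS,
    ENDPOINT,
    HAPPY_TO_AMBIGUOUS,
    TrialSpec,
    generate_schedule,
)

TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "trial_index",
    "is_training",
    "emotion",
    "avatar_sex",
    "avatar_id",
    "probe_motion_level",
    "response",
    "rt_ms",
    "confidence",
]

#: questionnaire instruments simulated at the participant level, with
#: (mean, sd, lower bound, upper bound) of a truncated discretised normal.
#: SPQ moments follow the study population this package targets; the others
#: are plausible non-clinical student-sample values (see docs/methods.md).
SCORE_DISTRIBUTIONS: dict[str, tuple[float, float, int, int]] = {
    "spq_total": (18.16, 9.64, 0, 74),
    "pdi_total": (5.5, 3.5, 0, 21),
    "lshs_total": (14.0, 8.0, 0, 48),
    "sticsa_state": (32.0, 8.0, 21, 84),
    "sticsa_trait": (36.0, 9.0, 21, 84),
    "tmt_a": (25.0, 8.0, 8, 90),
    "letter_number": (14.0, 3.0, 0, 24),
}


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of one synthetic observer.

    delta_* are forward displacements in motion-aligned frames; sigma is the
    memory-noise SD; criterion the equality half-width c; conf_cutpoints map
    evidence-to-boundary distance onto ratings 1-4; cat_threshold/cat_sigma
    drive the static categoriser; rt_* parameterise a shifted lognormal RT.
    """

    delta_happy: float = 0.36
    delta_angry: float = 0.09
    sigma: float = 1.0
    criterion: float = 1.5
    lapse: float = 0.05
    guess_equal: float = 0.5
    conf_cutpoints: tuple[float, float, float] = (0.4, 0.9, 1.6)
    cat_threshold: float = 11.0
    cat_sigma: float = 1.0
    rt_location: float = 6.0   # log-ms
    rt_scale: float = 0.35
    rt_shift_ms: float = 300.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.criterion <= 0:
            raise ValueError("criterion must be positive")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")
        if not (self.conf_cutpoints[0] < self.conf_cutpoints[1] < self.conf_cutpoints[2]):
            raise ValueError("conf_cutpoints must be strictly increasing")
        if self.rt_shift_ms < 0:
            raise ValueError("rt_shift_ms must be non-negative")

    def delta(self, emotion: str) -> float:
        if emotion == HAPPY_TO_AMBIGUOUS:
            return self.delta_happy
        if emotion == ANGRY_TO_AMBIGUOUS:
            return self.delta_angry
        raise ValueError(f"unknown emotion condition {emotion!r}")


@dataclass(frozen=True)
class TrialResult:
    trial: TrialSpec
    response: str          # "equal" | "different"
    rt_ms: float
    confidence: int        # 1..4


@dataclass
class CohortConfig:
    """Group structure for a simulated cohort.

    ``param_means``/``param_sds`` give per-group normal distributions for any
    :class:`ObserverParams` field (unspecified fields stay at the defaults with
    zero between-subject spread).  ``score_shifts`` adds a per-group offset to
    the questionnaire score means.
    """

    n_per_group: int = 48
    groups: tuple[str, ...] = ("low", "high")
    param_means: dict[str, dict[str, float]] = field(default_factory=dict)
    param_sds: dict[str, dict[str, float]] = field(default_factory=dict)
    score_shifts: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for mapping in (self.param_means, self.param_sds, self.score_shifts):
            for g in mapping:
                if g not in self.groups:
                    raise ValueError(f"config references unknown group {g!r}")


#: between-subject SDs used when CohortConfig does not override them
DEFAULT_PARAM_SDS = {
    "delta_happy": 0.6,
    "delta_angry": 0.6,
    "sigma": 0.2,
    "criterion": 0.25,
    "cat_threshold": 0.8,
    "cat_sigma": 0.3,
}


def equal_probability(params: ObserverParams, emotion: str, motion_level: float) -> float:
    """Analytic probability of an "equal" response at a motion-aligned level.

    Integrates the generative mechanism exactly::

        p = (1-lapse) * [Phi((L-mu+c)/sigma) - Phi((L-mu-c)/sigma)]
            + lapse * guess_equal,   mu = 11 + delta(emotion)
    """
    mu = ENDPOINT + params.delta(emotion)
    core = norm.cdf((motion_level - mu + params.criterion) / params.sigma) - norm.cdf(
        (motion_level - mu - params.criterion) / params.sigma
    )
    return float((1.0 - params.lapse) * core + params.lapse * params.guess_equal)


def simulate_trial(
    params: ObserverParams, trial: TrialSpec, rng: np.random.Generator
) -> TrialResult:
    """Simulate one probe-judgement trial (response, confidence, RT)."""
    L = trial.probe_motion_level
    if rng.random() < params.lapse:
        response = "equal" if rng.random() < params.guess_equal else "different"
        confidence = int(rng.integers(1, 5))
    else:
        remembered = ENDPOINT + params.delta(trial.emotion) + rng.normal(0.0, params.sigma)
        evidence = abs(L - remembered)
        response = "equal" if evidence < params.criterion else "different"
        margin = abs(evidence - params.criterion)
        confidence = 1 + int(np.searchsorted(params.conf_cutpoints, margin, side="right"))
    rt = params.rt_shift_ms + float(
        np.exp(rng.normal(params.rt_location, params.rt_scale))
    )
    return TrialResult(trial=trial, response=response, rt_ms=rt, confidence=confidence)


def simulate_categorization(
    params: ObserverParams, physical_level: int, rng: np.random.Generator
) -> str:
    """Categorise a static picture as "angry" or "happy".

    P(happy) = Phi((level - cat_threshold) / cat_sigma); cat_sigma -> 0 gives a
    hard boundary at cat_threshold.
    """
    if not 1 <= physical_level <= 21:
        raise ValueError(f"physical level {physical_level} outside 1..21")
    if params.cat_sigma <= 0:
        p_happy = 1.0 if physical_level > params.cat_threshold else (
            0.5 if physical_level == params.cat_threshold else 0.0
        )
    else:
        p_happy = norm.cdf((physical_level - params.cat_threshold) / params.cat_sigma)
    return "happy" if rng.random() < p_happy else "angry"


def draw_observer(
    group: str, config: CohortConfig, rng: np.random.Generator
) -> ObserverParams:
    """Draw participant-level parameters from the group's distributions."""
    base = ObserverParams()
    means = dict(config.param_means.get(group, {}))
    sds = dict(config.param_sds.get(group, {}))
    values: dict[str, float] = {}
    for name in ("delta_happy", "delta_angry", "sigma", "criterion",
                 "cat_threshold", "cat_sigma", "lapse"):
        mean = means.get(name, getattr(base, name))
        sd = sds.get(name, DEFAULT_PARAM_SDS.get(name, 0.0))
        val = rng.normal(mean, sd) if sd > 0 else mean
        if name in ("sigma", "criterion", "cat_sigma"):
            val = max(val, 0.1)
        if name == "lapse":
            val = float(np.clip(val, 0.0, 0.5))
        if name == "cat_threshold":
            val = float(np.clip(val, 2.0, 20.0))
        values[name] = float(val)
    return replace(base, **values)


def _truncated_discrete_normal(
    mean: float, sd: float, lo: int, hi: int, rng: np.random.Generator
) -> int:
    while True:
        x = int(round(rng.normal(mean, sd)))
        if lo <= x <= hi:
            return x


def draw_scores(
    group: str, config: CohortConfig, rng: np.random.Generator
) -> dict[str, int]:
    """Draw questionnaire/cognitive scores for one participant."""
    shifts = config.score_shifts.get(group, {})
    out = {}
    for name, (mean, sd, lo, hi) in SCORE_DISTRIBUTIONS.items():
        out[name] = _truncated_discrete_normal(mean + shifts.get(name, 0.0), sd, lo, hi, rng)
    # SPQ factor scores: rough fixed shares of the total (cognitive-perceptual,
    # interpersonal, disorganised); bounded by the instrument structure.
    total = out["spq_total"]
    cp = int(round(total * 0.35))
    inter = int(round(total * 0.40))
    out["spq_cognitive_perceptual"] = min(cp, total)
    out["spq_interpersonal"] = min(inter, total - 0)
    out["spq_disorganised"] = max(total - cp - inter, 0)
    return out


def simulate_cohort(
    config: CohortConfig,
    avatars=DEFAULT_AVATARS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort: per-participant probe-task trials and scores.

    Returns ``(trials, participants)``: a long-format trial table (one row per
    probe-judgement trial, training trials flagged) and a participant table
    with group labels and questionnaire scores.  Fully deterministic in
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    trial_rows: list[dict] = []
    part_rows: list[dict] = []
    pid = 0
    for group in config.groups:
        for _ in range(config.n_per_group):
            pid += 1
            participant_id = f"p{pid:03d}"
            params = draw_observer(group, config, rng)
            scores = draw_scores(group, config, rng)
            schedule = generate_schedule(seed=int(rng.integers(2**31)), avatars=avatars)
            for idx, trial in enumerate(schedule):
                res = simulate_trial(params, trial, rng)
                trial_rows.append(
                    {
                        "participant_id": participant_id,
                        "group": group,
                        "trial_index": idx,
                        "is_training": trial.is_training,
                        "emotion": trial.emotion,
                        "avatar_sex": trial.avatar_sex,
                        "avatar_id": trial.avatar_id,
                        "probe_motion_level": trial.probe_motion_level,
                        "response": res.response,
                        "rt_ms": res.rt_ms,
                        "confidence": res.confidence,
                    }
                )
            part_rows.append(
                {
                    "participant_id": participant_id,
                    "group": group,
                    "delta_happy": params.delta_happy,
                    "delta_angry": params.delta_angry,
                    "cat_threshold": params.cat_threshold,
                    **scores,
                }
            )
    trials = pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS)
    participants = pd.DataFrame(part_rows)
    return trials, participants
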