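"""Tabular I/O, the pixel-difference stimulus check, and the full pipeline.

All tabular data travel as UTF-8 CSV with a header row and "." decimals.
`run_pipeline` chains the whole analysis — simulate (or ingest) trials,
RT cleaning, psychometric fits, participant exclusions, weighted confidence,
questionnaire split, and the group statistics — logging the counts excluded at
each stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import confidence as conf_mod
from . import psychfit, stats
from .design import EMOTIONS
from .observer import TRIAL_COLUMNS, CohortConfig, simulate_cohort

log = logging.getLogger("rmfaces")

_VALID_RESPONSES = {"equal", "different"}


@dataclass
class RunConfig:
    """Knobs of the end-to-end pipeline."""

    seed: int = 0
    n_per_group: int = 48
    rt_threshold_ms: float = 250.0
    pse_bounds: tuple[float, float] = (5.0, 16.0)
    jnd_method: str = "hwhm"
    split: str = "median"              # "median" | "tertile"
    split_score: str = "spq_total"
    confidence_aggregation: str = "pooled"
    cohort: CohortConfig | None = None

    def __post_init__(self) -> None:
        if self.rt_threshold_ms <= 0:
            raise ValueError("rt_threshold_ms must be positive")
        if not self.pse_bounds[0] < self.pse_bounds[1]:
            raise ValueError("pse_bounds must be ordered")


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the trial-table schema, raising with row/column diagnostics."""
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    bad = ~df["response"].isin(_VALID_RESPONSES)
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(
            f"invalid value {df.loc[row, 'response']!r} in column 'response', row {row}"
        )
    conf = pd.to_numeric(df["confidence"], errors="coerce")
    bad = ~conf.isin([1, 2, 3, 4])
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(
            f"invalid value {df.loc[row, 'confidence']!r} in column 'confidence', "
            f"row {row}: ratings run 1-4"
        )
    bad = pd.to_numeric(df["rt_ms"], errors="coerce") < 0
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(f"negative rt_ms in row {row}")
    out = df.copy()
    out["confidence"] = conf.astype(int)
    out["probe_motion_level"] = out["probe_motion_level"].astype(int)
    out["is_training"] = out["is_training"].astype(bool)
    return out


def read_trials(path) -> pd.DataFrame:
    return validate_trials(pd.read_csv(path))


def write_trials(df: pd.DataFrame, path) -> None:
    validate_trials(df).to_csv(path, index=False)


def pixel_diff_percent(image_a, image_b) -> float:
    """Mean absolute pixel difference between two images, as % of the range.

    Accepts PIL images or arrays; identical images give 0, all-black versus
    all-white gives 100.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image dimensions differ: {a.shape} vs {b.shape}")
    rng = 255.0 if max(a.max(initial=0), b.max(initial=0)) > 1.0 else 1.0
    return float(np.mean(np.abs(a - b)) / rng * 100.0)


def run_pipeline(config: RunConfig, trials: pd.DataFrame | None = None,
                 participants: pd.DataFrame | None = None) -> dict:
    """Run the full analysis and return a report dictionary.

    With no input tables a cohort is simulated from ``config``.  The report
    holds the per-stage exclusion counts, the fits and confidence tables, and
    the group-statistics results (mixed ANOVAs on PSE, JND and weighted
    confidence; one-sample t of PSE against the endpoint; chi-square on
    RM > JND proportions).  Deterministic in ``config.seed``.
    """
    if trials is None:
        cohort = config.cohort or CohortConfig(
            n_per_group=config.n_per_group, seed=config.seed
        )
        trials, participants = simulate_cohort(cohort)
    trials = validate_trials(trials)
    if participants is None:
        raise ValueError("participant table required when trials are supplied")

    report: dict = {"seed": config.seed, "counts": {}}

    analysis = trials.loc[~trials["is_training"]]
    cleaned, n_fast = psychfit.exclude_fast_trials(analysis, config.rt_threshold_ms)
    report["counts"]["trials_total"] = len(analysis)
    report["counts"]["trials_rt_excluded"] = n_fast
    log.info("RT exclusion: %d of %d trials (%.2f%%)",
             n_fast, len(analysis), 100 * n_fast / max(len(analysis), 1))

    profiles = psychfit.build_profiles(cleaned)
    fits = [psychfit.fit_psychometric(p) for p in profiles]
    for f in fits:
        if f.converged:
            f.jnd = psychfit.jnd_from_fit(f, method=config.jnd_method)
    fits = psychfit.apply_participant_exclusions(
        fits, lower=config.pse_bounds[0], upper=config.pse_bounds[1]
    )
    fit_df = psychfit.fits_to_frame(fits)
    excluded_ids = set(fit_df.loc[fit_df["excluded"], "participant_id"])
    report["counts"]["participants_total"] = fit_df["participant_id"].nunique()
    report["counts"]["participants_excluded"] = len(excluded_ids)
    log.info("participant exclusion: %d of %d", len(excluded_ids),
             fit_df["participant_id"].nunique())
    report["fits"] = fit_df

    conf_df = conf_mod.confidence_table(
        cleaned, aggregation=config.confidence_aggregation
    )
    report["confidence"] = conf_df

    retained = fit_df.loc[~fit_df["excluded"]]
    wide_pse = retained.pivot(index="participant_id", columns="emotion", values="pse")
    wide_jnd = retained.pivot(index="participant_id", columns="emotion", values="jnd")
    wide_pse = wide_pse.reindex(columns=list(EMOTIONS)).dropna()
    wide_jnd = wide_jnd.reindex(columns=list(EMOTIONS)).loc[wide_pse.index]
    conf_wide = (
        conf_df.pivot(index="participant_id", columns="emotion",
                      values="weighted_confidence")
        .reindex(columns=list(EMOTIONS))
        .loc[wide_pse.index]
    )

    parts = participants.set_index("participant_id").loc[wide_pse.index]
    scores = parts[config.split_score].to_numpy()
    if config.split == "median":
        labels = stats.median_split(scores)
    elif config.split == "tertile":
        labels = stats.tertile_split(scores)
    else:
        raise ValueError(f"unknown split {config.split!r}")
    keep = labels != "middle"
    report["counts"]["split"] = {
        "high": int((labels == "high").sum()),
        "low": int((labels == "low").sum()),
        "discarded": int((~keep).sum()),
    }

    y_pse = wide_pse.to_numpy()[keep]
    y_jnd = wide_jnd.to_numpy()[keep]
    y_conf = conf_wide.to_numpy()[keep]
    glab = labels[keep]

    report["anova_pse"] = stats.mixed_anova_2x2(
        y_pse, glab, effect_names=("Group", "Emotion", "Group*Emotion")
    ).to_frame()
    report["anova_jnd"] = stats.mixed_anova_2x2(
        y_jnd, glab, effect_names=("Group", "Emotion", "Group*Emotion")
    ).to_frame()
    report["anova_confidence"] = stats.mixed_anova_2x2(
        y_conf, glab, effect_names=("Group", "Emotion", "Group*Emotion")
    ).to_frame()

    # forward-bias tests: PSE > endpoint, one-tailed, per emotion
    report["forward_bias"] = {
        emo: stats.one_sample_t(wide_pse[emo].to_numpy(), 11.0, tail="greater")
        for emo in EMOTIONS
    }

    # RM > JND proportions by group, per emotion
    chi = {}
    for j, emo in enumerate(EMOTIONS):
        exceeds = (y_pse[:, j] - 11.0) > y_jnd[:, j]
        hi, lo = glab == "high", glab == "low"
        a, b = int((exceeds & hi).sum()), int((~exceeds & hi).sum())
        c, d = int((exceeds & lo).sum()), int((~exceeds & lo).sum())
        try:
            chi[emo] = {**stats.chi_square_2x2(a, b, c, d),
                        "table": [[a, b], [c, d]]}
        except ValueError:
            chi[emo] = {"table": [[a, b], [c, d]], "chi2": None, "p": None}
    report["rm_exceeds_jnd_chi2"] = chi

    report["ks_pse"] = {
        emo: stats.ks_normality(wide_pse[emo].to_numpy()) for emo in EMOTIONS
    }
    return report
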