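"""Weighted confidence in biased "equal" judgements (second-order task).

An "equal" error is an "equal" response to a probe that differs from the
animation endpoint (motion-aligned level != 11).  The weighted-confidence
statistic for a participant x emotion cell multiplies how often such errors
occur by how confident the participant was when making them:

    weighted = P(equal | probe != endpoint) * mean confidence on those errors

Its range is [0, 4] (ratings run 1-4); with no errors the statistic is 0.
Only erroneous "equal" responses enter, because the statistic quantifies
confidence in the context of a perceptual bias, not overall confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ENDPOINT


@dataclass
class ConfidenceSummary:
    participant_id: str
    emotion: str
    prop_equal_errors: float
    mean_conf_equal_errors: float  # NaN when no errors
    weighted_confidence: float


def weighted_confidence(
    trials: pd.DataFrame,
    participant_id: str,
    emotion: str,
    aggregation: str = "pooled",
) -> ConfidenceSummary:
    """Weighted confidence for one participant x emotion cell.

    ``aggregation='pooled'`` (default) computes one error proportion and one
    confidence mean over all non-endpoint probes; ``'per_level'`` forms the
    product per probe level and averages it over the six non-endpoint levels.
    """
    sub = trials
    if "is_training" in sub.columns:
        sub = sub.loc[~sub["is_training"].astype(bool)]
    sub = sub.loc[
        (sub["participant_id"] == participant_id) & (sub["emotion"] == emotion)
    ]
    diff_probe = sub.loc[sub["probe_motion_level"] != ENDPOINT]
    if len(diff_probe) == 0:
        raise ValueError(
            f"no non-endpoint trials for {participant_id!r} / {emotion!r}"
        )

    if aggregation == "pooled":
        errors = diff_probe.loc[diff_probe["response"] == "equal"]
        prop = len(errors) / len(diff_probe)
        mean_conf = float(errors["confidence"].mean()) if len(errors) else float("nan")
        weighted = prop * mean_conf if len(errors) else 0.0
    elif aggregation == "per_level":
        products = []
        all_errors = []
        for _, lvl_trials in diff_probe.groupby("probe_motion_level"):
            errs = lvl_trials.loc[lvl_trials["response"] == "equal"]
            if len(errs):
                products.append(len(errs) / len(lvl_trials) * errs["confidence"].mean())
                all_errors.append(errs)
            else:
                products.append(0.0)
        weighted = float(np.mean(products))
        errors = pd.concat(all_errors) if all_errors else diff_probe.iloc[0:0]
        prop = len(errors) / len(diff_probe)
        mean_conf = float(errors["confidence"].mean()) if len(errors) else float("nan")
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")

    return ConfidenceSummary(
        participant_id=participant_id,
        emotion=emotion,
        prop_equal_errors=float(prop),
        mean_conf_equal_errors=mean_conf,
        weighted_confidence=float(weighted),
    )


def confidence_table(trials: pd.DataFrame, aggregation: str = "pooled") -> pd.DataFrame:
    """Weighted-confidence summaries for every participant x emotion cell."""
    rows = []
    for (pid, emo), _ in trials.groupby(["participant_id", "emotion"], sort=True):
        s = weighted_confidence(trials, pid, emo, aggregation=aggregation)
        rows.append(
            {
                "participant_id": s.participant_id,
                "emotion": s.emotion,
                "prop_equal_errors": s.prop_equal_errors,
                "mean_conf": s.mean_conf_equal_errors,
                "weighted_confidence": s.weighted_confidence,
            }
        )
    return pd.DataFrame(rows)
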