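"""PSE/JND estimation by fitting a scaled logistic probability density.

The proportion of "equal" responses over probe levels forms a bell-shaped
profile.  Its location and width are estimated by least-squares fitting of a
scaled logistic density

    f(L) = 4 A exp(-z) / (1 + exp(-z))^2,    z = (L - mu) / s

parameterised so the curve peaks at height ``A`` when ``L = mu``.  The fitted
mean ``mu`` is the point of subjective equality (PSE): the probe level at which
"equal" responses are most likely.  A PSE above the motion-aligned endpoint 11
is a forward bias (representational momentum); below, a backward bias.  The
just-noticeable difference (JND) is derived from the deviation ``s``; the
default is the half-width at half maximum of the fitted density,
``s * ln(3 + 2*sqrt(2))``.

Trial-level cleaning removes responses faster than 250 ms; participant-level
exclusion drops anyone whose PSE falls below 5 or above 16 in either emotion
condition (three levels beyond the most extreme probes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .design import EMOTIONS, PROBE_MOTION_LEVELS

RT_EXCLUSION_MS = 250.0
PSE_LOWER, PSE_UPPER = 5.0, 16.0

#: half-width at half maximum of the unit logistic density: solve f = A/2
HWHM_FACTOR = math.log(3 + 2 * math.sqrt(2))

FIT_BOUNDS = {"mu": (5.0, 17.0), "s": (0.05, 10.0), "A": (1e-6, 1.0)}


@dataclass
class ProportionProfile:
    """Proportion of "equal" responses per probe level for one participant x emotion."""

    participant_id: str
    emotion: str
    levels: np.ndarray
    n_trials: np.ndarray
    n_equal: np.ndarray
    flagged: bool = False  # empty cell(s) present

    @property
    def proportions(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_trials > 0, self.n_equal / self.n_trials, np.nan)


@dataclass
class PsychFit:
    """Fitted scaled logistic density for one profile."""

    participant_id: str
    emotion: str
    mu: float
    s: float
    A: float
    jnd: float
    sse: float
    converged: bool
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def rm(self) -> float:
        """Forward displacement (representational momentum) in frames."""
        return self.mu - 11.0


def exclude_fast_trials(
    trials: pd.DataFrame, threshold_ms: float = RT_EXCLUSION_MS
) -> tuple[pd.DataFrame, int]:
    """Drop trials with RT strictly below ``threshold_ms``.

    Returns the retained trials and the number removed.
    """
    if "rt_ms" not in trials.columns:
        raise KeyError("trials table has no 'rt_ms' column")
    keep = trials["rt_ms"] >= threshold_ms
    return trials.loc[keep].copy(), int((~keep).sum())


def build_profiles(
    trials: pd.DataFrame, levels=PROBE_MOTION_LEVELS
) -> list[ProportionProfile]:
    """Aggregate cleaned trials into per-(participant, emotion) proportion profiles.

    Training trials are dropped if an ``is_training`` column is present.
    Profiles with any empty level cell are flagged.
    """
    data = trials
    if "is_training" in data.columns:
        data = data.loc[~data["is_training"].astype(bool)]
    levels = np.asarray(levels)
    profiles = []
    for (pid, emotion), sub in data.groupby(["participant_id", "emotion"], sort=True):
        n_trials = np.zeros(len(levels), dtype=int)
        n_equal = np.zeros(len(levels), dtype=int)
        counts = sub.groupby("probe_motion_level")["response"].agg(
            n="size", eq=lambda r: int((r == "equal").sum())
        )
        for i, lvl in enumerate(levels):
            if lvl in counts.index:
                n_trials[i] = counts.loc[lvl, "n"]
                n_equal[i] = counts.loc[lvl, "eq"]
        profiles.append(
            ProportionProfile(
                participant_id=str(pid),
                emotion=str(emotion),
                levels=levels.copy(),
                n_trials=n_trials,
                n_equal=n_equal,
                flagged=bool((n_trials == 0).any()),
            )
        )
    return profiles


def scaled_logistic_density(L, mu: float, s: float, A: float):
    """Scaled logistic density peaking at height A at L = mu."""
    z = (np.asarray(L, dtype=float) - mu) / s
    ez = np.exp(-np.abs(z))  # symmetric form, overflow-safe
    val = 4.0 * A * ez / (1.0 + ez) ** 2
    return val if np.ndim(L) else float(val)


def fit_psychometric(
    profile: ProportionProfile,
    init: tuple[float, float, float] | None = None,
    bounds: dict | None = None,
    loss: str = "least_squares",
) -> PsychFit:
    """Least-squares fit of the scaled logistic density to a proportion profile.

    Multi-start initialisation: ``mu0`` at the argmax level, ``s0`` in
    {0.5, 1, 2}, ``A0`` the maximum proportion; the best local solution wins.
    A profile with no identifiable peak (flat within 1e-3) or fewer than 5
    informative levels is returned unconverged.  ``loss='binomial'`` swaps the
    squared-error objective for a binomial negative log-likelihood.
    """
    bounds = {**FIT_BOUNDS, **(bounds or {})}
    mask = profile.n_trials > 0
    L = profile.levels[mask].astype(float)
    p = profile.proportions[mask]
    n = profile.n_trials[mask].astype(float)

    def failed(reason: str) -> PsychFit:
        return PsychFit(
            participant_id=profile.participant_id,
            emotion=profile.emotion,
            mu=np.nan, s=np.nan, A=np.nan, jnd=np.nan, sse=np.nan,
            converged=False, excluded=True, exclusion_reason=reason,
        )

    if mask.sum() < 5:
        return failed("fewer than 5 levels with data")
    if np.ptp(p) < 1e-3:
        return failed("flat profile: no identifiable peak")

    lo = np.array([bounds["mu"][0], bounds["s"][0], bounds["A"][0]])
    hi = np.array([bounds["mu"][1], bounds["s"][1], bounds["A"][1]])

    starts = []
    if init is not None:
        starts.append(np.clip(np.asarray(init, dtype=float), lo, hi))
    mu0 = L[int(np.argmax(p))]
    A0 = float(np.clip(p.max(), bounds["A"][0], bounds["A"][1]))
    for s0 in (0.5, 1.0, 2.0):
        starts.append(np.clip(np.array([mu0, s0, A0]), lo, hi))

    best_x, best_cost = None, np.inf
    if loss == "binomial":
        eps = 1e-9

        def nll(theta):
            f = np.clip(scaled_logistic_density(L, *theta), eps, 1 - eps)
            return float(-np.sum(n * (p * np.log(f) + (1 - p) * np.log(1 - f))))

        for theta0 in starts:
            res = minimize(nll, theta0, method="L-BFGS-B", bounds=list(zip(lo, hi)))
            if res.success and res.fun < best_cost:
                best_x, best_cost = res.x, float(res.fun)
    else:

        def residuals(theta):
            return scaled_logistic_density(L, *theta) - p

        for theta0 in starts:
            try:
                res = least_squares(residuals, theta0, bounds=(lo, hi))
            except Exception:
                continue
            if res.success and res.cost < best_cost:
                best_x, best_cost = res.x, float(res.cost)
    if best_x is None:
        return failed("optimizer failed to converge")

    mu, s, A = (float(v) for v in best_x)
    fitted = scaled_logistic_density(L, mu, s, A)
    sse = float(np.sum((fitted - p) ** 2))
    fit = PsychFit(
        participant_id=profile.participant_id,
        emotion=profile.emotion,
        mu=mu, s=s, A=A,
        jnd=jnd_from_scale(s),
        sse=sse,
        converged=True,
    )
    return fit


def jnd_from_scale(s: float, method: str = "hwhm") -> float:
    """JND from the fitted deviation: HWHM (default) or the raw scale."""
    if method == "hwhm":
        return s * HWHM_FACTOR
    if method == "scale":
        return s
    raise ValueError(f"unknown JND method {method!r}")


def jnd_from_fit(fit: PsychFit, method: str = "hwhm") -> float:
    if not fit.converged:
        raise ValueError("cannot derive a JND from an unconverged fit")
    return jnd_from_scale(fit.s, method=method)


def apply_participant_exclusions(
    fits: list[PsychFit],
    lower: float = PSE_LOWER,
    upper: float = PSE_UPPER,
) -> list[PsychFit]:
    """Exclude participants whose PSE leaves [lower, upper] in either emotion.

    The exclusion is participant-wide: one out-of-range (or unconverged)
    condition drops both of the participant's fits.  Idempotent.
    """
    bad: set[str] = set()
    for f in fits:
        if not f.converged or not (lower <= f.mu <= upper):
            bad.add(f.participant_id)
    out = []
    for f in fits:
        if f.participant_id in bad:
            reason = f.exclusion_reason or (
                "unconverged fit in at least one condition"
                if not f.converged
                else f"PSE outside [{lower}, {upper}] in at least one condition"
            )
            out.append(
                PsychFit(
                    **{**f.__dict__, "excluded": True, "exclusion_reason": reason}
                )
            )
        else:
            out.append(PsychFit(**{**f.__dict__, "excluded": False, "exclusion_reason": ""}))
    return out


def rm_exceeds_jnd(fit: PsychFit) -> bool:
    """True when the forward displacement strictly exceeds the JND."""
    if not fit.converged or fit.excluded:
        raise ValueError("RM > JND is defined only for converged, retained fits")
    return (fit.mu - 11.0) > fit.jnd


def fits_to_frame(fits: list[PsychFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": f.participant_id,
                "emotion": f.emotion,
                "pse": f.mu,
                "s": f.s,
                "A": f.A,
                "jnd": f.jnd,
                "sse": f.sse,
                "converged": f.converged,
                "excluded": f.excluded,
                "reason": f.exclusion_reason,
            }
            for f in fits
        ]
    )
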