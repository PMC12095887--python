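"""Group-level statistics: splits, mixed ANOVA, covariates, and classical tests.

The central analysis is a 2 x 2 mixed ANOVA with a between-subjects group
factor (e.g. high/low schizotypy from a questionnaire split) and a two-level
within-subjects factor (emotion condition).  With exactly two within levels the
design satisfies sphericity trivially, so no Greenhouse-Geisser machinery is
needed; every effect is tested on (1, N-2) degrees of freedom.  Effect sizes
are partial eta squared, SS_effect / (SS_effect + SS_error).

The implementation uses the classical sums-of-squares decomposition written
out directly (between-subject error for the group effect; the subject x within
interaction error for the within and interaction effects).  Unbalanced groups
are handled with Type-III (unweighted cell means) tests, matching standard
psychology software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class EffectRow:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float


@dataclass
class AnovaTable:
    rows: list[EffectRow]

    def __getitem__(self, effect: str) -> EffectRow:
        for r in self.rows:
            if r.effect == effect:
                return r
        raise KeyError(effect)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])


# ---------------------------------------------------------------------------
# questionnaire scoring and group splits
# ---------------------------------------------------------------------------

#: synthetic SPQ key for testing: 74 items spread over the nine dimensions and
#: the three-factor structure.  The real instrument's item allocation is not
#: bundled; pass your own key_map for real data.
SYNTHETIC_SPQ_KEY = {
    "dimensions": {
        "ideas_of_reference": list(range(0, 9)),
        "odd_beliefs": list(range(9, 16)),
        "unusual_perceptual": list(range(16, 25)),
        "suspiciousness": list(range(25, 33)),
        "social_anxiety": list(range(33, 41)),
        "no_close_friends": list(range(41, 50)),
        "constricted_affect": list(range(50, 58)),
        "odd_behaviour": list(range(58, 65)),
        "odd_speech": list(range(65, 74)),
    },
    "factors": {
        "cognitive_perceptual": [
            "ideas_of_reference", "odd_beliefs", "unusual_perceptual", "suspiciousness",
        ],
        "interpersonal": [
            "social_anxiety", "no_close_friends", "constricted_affect", "suspiciousness",
        ],
        "disorganised": ["odd_behaviour", "odd_speech"],
    },
}


def score_spq(item_responses, key_map=None) -> dict[str, int]:
    """Score a 74-item yes/no questionnaire: total, dimension, and factor sums.

    ``item_responses`` is a length-74 vector of 0/1 (or booleans); the total is
    the count of "yes" answers.  ``key_map`` maps dimensions to item indices
    and factors to dimension names (suspiciousness is shared between the
    cognitive-perceptual and interpersonal factors, as in the three-factor
    model).
    """
    key_map = key_map or SYNTHETIC_SPQ_KEY
    items = np.asarray(item_responses).astype(int)
    if items.shape != (74,):
        raise ValueError(f"expected 74 items, got shape {items.shape}")
    if not np.isin(items, (0, 1)).all():
        raise ValueError("item responses must be dichotomous (0/1)")
    out: dict[str, int] = {"total": int(items.sum())}
    dims = {
        name: int(items[np.asarray(idx)].sum())
        for name, idx in key_map["dimensions"].items()
    }
    out.update(dims)
    for factor, dim_names in key_map["factors"].items():
        out[factor] = int(sum(dims[d] for d in dim_names))
    return out


def median_split(scores, ties: str = "low") -> np.ndarray:
    """Label scores "high"/"low" about the median; ties go to ``ties``."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 scores")
    if np.ptp(scores) == 0:
        raise ValueError("all scores equal: split undefined")
    if ties not in ("low", "high"):
        raise ValueError("ties must be 'low' or 'high'")
    med = np.median(scores)
    labels = np.where(scores > med, "high", "low")
    if ties == "high":
        labels = np.where(scores >= med, "high", "low")
    return labels


def tertile_split(scores) -> np.ndarray:
    """Label scores "low"/"middle"/"high" by tertiles; boundary ties fall into
    the middle (discarded) group."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 3:
        raise ValueError("need at least 3 scores")
    if np.ptp(scores) == 0:
        raise ValueError("all scores equal: split undefined")
    q1, q2 = np.quantile(scores, [1 / 3, 2 / 3])
    labels = np.full(scores.shape, "middle", dtype=object)
    labels[scores < q1] = "low"
    labels[scores > q2] = "high"
    return labels.astype(str)


# ---------------------------------------------------------------------------
# mixed 2 x 2 ANOVA and covariate models
# ---------------------------------------------------------------------------

def _f_p(F: float, df1: int, df2: int) -> float:
    return float(sps.f.sf(F, df1, df2))


def mixed_anova_2x2(
    y: np.ndarray,
    group: np.ndarray,
    effect_names: tuple[str, str, str] = ("Group", "Within", "Interaction"),
) -> AnovaTable:
    """Mixed ANOVA with a 2-level between and a 2-level within factor.

    ``y`` is an (N, 2) array of each subject's scores at the two within
    levels; ``group`` a length-N vector of two distinct labels.  Returns the
    group, within, and interaction effects, each on (1, N-2) df, with partial
    eta squared.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("y must be (N, 2): two within-subject levels per subject")
    if len(group) != len(y):
        raise ValueError("group labels and y rows must align")
    if np.isnan(y).any():
        raise ValueError("missing cells are not supported")
    glabels = np.unique(group)
    if len(glabels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(glabels)}")

    n = np.array([(group == g).sum() for g in glabels], dtype=float)
    if (n < 2).any():
        raise ValueError("each group needs at least 2 subjects")
    N = int(n.sum())
    k = 2  # within levels

    subj_mean = y.mean(axis=1)
    d = y[:, 1] - y[:, 0]
    g_mask = [group == g for g in glabels]

    # between-subjects part: one-way ANOVA on subject means, scaled by k
    grand = subj_mean.mean()
    group_means = np.array([subj_mean[m].mean() for m in g_mask])
    ss_group = k * float(np.sum(n * (group_means - grand) ** 2))
    ss_err_b = k * float(
        sum(np.sum((subj_mean[m] - gm) ** 2) for m, gm in zip(g_mask, group_means))
    )

    # within-subjects part via difference scores (saturated two-group model)
    d_means = np.array([d[m].mean() for m in g_mask])
    b0 = d_means.mean()            # unweighted (Type III) within-effect estimate
    b1 = d_means[1] - d_means[0]   # interaction estimate
    inv_n = float(np.sum(1.0 / n))
    ss_within = b0**2 / (inv_n / 4.0) / 2.0
    ss_inter = b1**2 / inv_n / 2.0
    ss_err_w = float(sum(np.sum((d[m] - dm) ** 2) for m, dm in zip(g_mask, d_means))) / 2.0

    df_den = N - 2

    def row(name: str, ss_eff: float, ss_err: float) -> EffectRow:
        ms_err = ss_err / df_den
        if ms_err <= 0:
            F = 0.0 if ss_eff <= 1e-12 else float("inf")
        else:
            F = ss_eff / ms_err
        denom = ss_eff + ss_err
        eta = ss_eff / denom if denom > 0 else 0.0
        return EffectRow(name, float(F), 1, df_den, _f_p(F, 1, df_den), float(eta))

    return AnovaTable(
        [
            row(effect_names[0], ss_group, ss_err_b),
            row(effect_names[1], ss_within, ss_err_w),
            row(effect_names[2], ss_inter, ss_err_w),
        ]
    )


def rm_ancova_2level(
    y: np.ndarray,
    covariate: np.ndarray,
    names: tuple[str, str, str] = ("Covariate", "Within", "Within*Covariate"),
) -> AnovaTable:
    """Two-level repeated-measures ANCOVA with one mean-centred covariate.

    The covariate-by-within interaction is the slope of the within-subject
    difference score regressed on the centred covariate; the within main
    effect is that regression's intercept test; the covariate main effect is
    the slope of the subject-mean regression.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("y must be (N, 2)")
    if len(x) != len(y):
        raise ValueError("covariate length must match y")
    if np.std(x) == 0:
        raise ValueError("covariate has zero variance")
    import statsmodels.api as sm

    xc = x - x.mean()
    X = sm.add_constant(xc)
    N = len(y)
    df_den = N - 2

    d = y[:, 1] - y[:, 0]
    fit_d = sm.OLS(d, X).fit()
    m = y.mean(axis=1)
    fit_m = sm.OLS(m, X).fit()

    def from_t(name: str, t: float) -> EffectRow:
        F = float(t**2)
        eta = F / (F + df_den)
        return EffectRow(name, F, 1, df_den, _f_p(F, 1, df_den), float(eta))

    return AnovaTable(
        [
            from_t(names[0], fit_m.tvalues[1]),
            from_t(names[1], fit_d.tvalues[0]),
            from_t(names[2], fit_d.tvalues[1]),
        ]
    )


# ---------------------------------------------------------------------------
# classical tests
# ---------------------------------------------------------------------------

def one_sample_t(values, mu0: float, tail: str = "two-sided") -> dict[str, float]:
    """One-sample t-test with Cohen's d = (mean - mu0) / sd.

    ``tail``: "two-sided", "greater" (mean > mu0), or "less".
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    n = x.size
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    df = n - 1
    if tail == "two-sided":
        p = 2 * sps.t.sf(abs(t), df)
    elif tail == "greater":
        p = sps.t.sf(t, df)
    elif tail == "less":
        p = sps.t.cdf(t, df)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return {"t": float(t), "df": int(df), "p": float(p), "d": float((x.mean() - mu0) / sd)}


def tukey_posthoc(
    cell_means: dict[str, float], ms_error: float, n: int, df_error: int
) -> pd.DataFrame:
    """Tukey-adjusted pairwise comparisons of design-cell means.

    ``ms_error`` is the relevant ANOVA error mean square and ``n`` the number
    of observations per cell; p-values come from the studentized range
    distribution with k = number of cells.
    """
    names = list(cell_means)
    k = len(names)
    se = np.sqrt(ms_error / n)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = cell_means[names[i]] - cell_means[names[j]]
            q = abs(diff) / se if se > 0 else 0.0
            p = float(sps.studentized_range.sf(q, k, df_error)) if se > 0 else 1.0
            rows.append(
                {"a": names[i], "b": names[j], "diff": float(diff), "q": float(q),
                 "p_tukey": min(p, 1.0)}
            )
    return pd.DataFrame(rows)


def spearman_rho(x, y) -> dict[str, float]:
    """Spearman rank correlation with its two-sided p-value."""
    rho, p = sps.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p)}


def chi_square_2x2(a: int, b: int, c: int, d: int, correction: bool = False) -> dict:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]] (no Yates by default)."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("zero margin: chi-square undefined")
    num = abs(a * d - b * c)
    if correction:
        num = max(num - n / 2.0, 0.0)
    chi2 = n * num**2 / margins
    return {"chi2": float(chi2), "df": 1, "p": float(sps.chi2.sf(chi2, 1))}


def ks_normality(values) -> dict[str, float]:
    """Kolmogorov-Smirnov test against a normal with the sample's mean and SD.

    Plugging in estimated moments makes the test conservative (the Lilliefors
    correction is intentionally not applied; see docs/methods.md).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    D, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return {"D": float(D), "p": float(p)}


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha for an (n_respondents, k_items) matrix."""
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 items")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1).sum()
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    return float(k / (k - 1) * (1 - item_var / total_var))
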