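# Methods

## The task and its coordinates

The probe-judgement task presents an 11-frame animation of an avatar face
morphing along a 21-level anger–happiness continuum (level 1 fully angry,
level 21 fully happy, level 11 a 50/50 ambiguous blend) from one pole to the
ambiguous midpoint, then a probe at the endpoint or 1–3 frames before/beyond
it. Analysis uses a *motion-aligned* coordinate: level 11 is the endpoint and
larger values lie further along the motion direction, for both emotion
conditions. This makes a forward (representational-momentum) bias positive
regardless of whether the animation ran angry→ambiguous (physical identity)
or happy→ambiguous (mirror, physical = 22 − motion). Physical levels are used
only for stimulus identity and the staircase task.

The full factorial — 2 Emotion × 2 Avatar Sex × 2 Avatar Identity × 7 Probe ×
3 repetitions — gives 168 analysis trials, preceded by 5 flagged training
trials. The composition of training trials is not constrained by the task
design beyond "not reused in the main task", so the generator draws them from
a held-out avatar; analysis readers drop them. Animation timing (200 ms
first/last frame, 80 ms intermediate frames, 250 ms mask, 800–1200 ms
fixation jitter) is carried as metadata and does not enter any statistic.

## The generative observer

No generative model is prescribed by the task, so the synthetic observer is
the minimal mechanism whose predictions are bell-shaped and symmetric absent
bias: the remembered endpoint is `R = 11 + δ_emotion + ε`, `ε ~ N(0, σ²)`,
and the observer answers "equal" iff `|L − R| < c` (an interval criterion of
half-width `c`). Attentional lapses (probability λ) answer "equal" with
probability 0.5 at uniformly random confidence, decoupling metacognition from
lapsing. This integrates exactly to

    p(L) = (1 − λ)[Φ((L − μ + c)/σ) − Φ((L − μ − c)/σ)] + λ/2,   μ = 11 + δ,

which the property tests verify against vectorised Monte-Carlo simulation of
the mechanism itself. Confidence on non-lapse trials grades the distance of
the evidence `|L − R|` from the criterion boundary through three increasing
cutpoints (defaults 0.4 / 0.9 / 1.6 frames → ratings 1–4). RTs are shifted
lognormal (shift 300 ms, log-location 6.0, log-scale 0.35 → median ≈ 700 ms);
with a 300 ms shift the 250 ms RT exclusion removes nothing, which matches
the near-zero exclusion rates typical of this paradigm.

Default displacements are δ_happy = 0.36 and δ_angry = 0.09 frames — a small
forward bias when the face moves toward anger and a near-zero one when it
moves toward happiness, the asymmetry this paradigm is designed to detect —
with between-subject SD 0.6; σ = 1 frame, c = 1.5 frames, λ = 0.05. For the static categorization task the observer responds
"happy" with probability `Φ((level − b)/σ_cat)` (boundary b, default 11;
σ_cat default 1).

Cohorts draw participant-level parameters from per-group normal
distributions and questionnaire totals from truncated discretised normals.
SPQ totals use mean 18.16, SD 9.64, bounded 0–74 (the student-population
values the paradigm targets); PDI (0–21), LSHS (0–48), STICSA state/trait
(21–84), TMT-A, and Letter–Number Span use plausible non-clinical student
values chosen once (5.5 ± 3.5, 14 ± 8, 32 ± 8, 36 ± 9, 25 ± 8 s, 14 ± 3).
SPQ factor scores are fixed shares of the total rather than item-derived; an
item-level scorer with a synthetic 74-item key exists separately to exercise
questionnaire scoring. What the generator deliberately does **not** emulate:
serial dependencies between trials, RT–accuracy coupling, fatigue or
learning, item-level questionnaire correlation structure, and any real link
between questionnaire scores and observer parameters (group structure is
opt-in via config). Passing tests therefore demonstrate correctness of the
pipeline's estimators on data satisfying the stated mechanism, not the
validity of that mechanism for human observers.

## Psychometric fit

PSE and JND come from least-squares fitting of a scaled logistic density to
the per-level proportion of "equal" responses, with three free parameters:
mean μ (the PSE), deviation s, and scaling factor A. The density is
parameterised so that A *is* the peak proportion,
`f(L) = 4A e^(−z)/(1+e^(−z))²`, `z = (L−μ)/s` — interpretable and bounded in
(0, 1], unlike an unconstrained area parameter. Least squares on level-wise
proportions (unweighted by trial count) is the primary objective; a binomial
likelihood objective is available via `loss="binomial"`. Multi-start
initialisation (μ₀ = argmax level, s₀ ∈ {0.5, 1, 2}, A₀ = max proportion)
with bounds μ ∈ [5, 17], s ∈ (0.05, 10], A ∈ (0, 1] guards against local
minima; a dense grid-search oracle in the tests confirms the optimum. A
profile that is flat to within 10⁻³, has fewer than five informative levels,
or defeats every start is returned unconverged.

The JND default is the half-width at half maximum of the fitted density,
`s·ln(3+2√2) ≈ 1.76 s` (solve `f = A/2`); the raw deviation `s` is available
as a configurable alternative, since the mapping from deviation to JND is a
convention rather than a fixed rule.

Exclusions: trials with RT strictly below 250 ms are removed (250 ms itself
is retained — "shorter than" is read strictly); a participant whose PSE in
*either* emotion falls below 5 or above 16 (three levels beyond the extreme
probes) is excluded entirely. The exclusion pass is idempotent.

## Staircase

Two interleaved staircases per avatar start at the two continuum poles.
After two successive identical categorizations the level steps toward the
pole of the *opposite* category (two "angry" → happier, two "happy" →
angrier), the pair counter resets, and steps are 3 pictures before a stair's
first reversal and 1 afterwards; levels clamp to [1, 21]. The phrase
"changed towards a fully angry or happy expression" admits a literal reading
that steps toward the repeated category's own pole; that rule runs away from
the category boundary and cannot terminate sensibly, so the boundary-seeking
reading is the default and the literal one sits behind
`StairConfig(boundary_seeking=False)` for comparison. A reversal is a sign
flip of the realised movement direction (the first movement sets direction
without counting) and is tagged with the step size in force when it
occurred, so the first reversal carries step 3. Stairs complete at ≥ 4
reversals and ≥ 5 presentations.

The ambiguity threshold is the mean of step-1 reversal levels pooled over an
avatar's stairs; because the two-in-a-row rule moves up when `(1−p)² > p²`
and down when `p² > (1−p)²`, the symmetric two-stair design equilibrates at
the 50% point of the categorization function, i.e. at the boundary b — the
convergence test confirms a bias below 0.5 level for b ∈ [9, 13] and
σ_cat ∈ [0.5, 2]. The staircase JND is the sample SD of the step-1 reversal
levels; the derivation of a JND from reversal dispersion is likewise a
convention, and SD-of-reversals is this package's documented choice.

## Weighted confidence

`weighted = P("equal" | probe ≠ endpoint) × mean confidence on those errors`,
range [0, 4], zero when no errors occur. Pooled aggregation (one proportion,
one mean over all non-endpoint probes) is the default; a per-level variant
(product per probe level, averaged over levels) is available, since "mean of
the product" admits both readings. Pooled is the default: its scale is the
natural one for a single error-rate-times-confidence summary per condition.
Endpoint probes never contribute; errors are not weighted by displacement.

## Statistics

The 2×2 mixed ANOVA is a hand-written classical sums-of-squares
decomposition: the group effect is a one-way ANOVA on subject means (between-
subject error), the within and interaction effects are intercept and slope
tests of the within-subject difference score (subject × within error), all on
(1, N−2) df. Unbalanced groups get Type-III (unweighted cell-means) tests,
matching standard psychology software; the unit tests verify exact agreement
with pingouin's `mixed_anova` and with an independent model-comparison
regression oracle, plus a 10⁴-permutation check of the interaction p.
Sphericity machinery is omitted on purpose: a two-level within factor
satisfies sphericity trivially, so a Greenhouse–Geisser correction can never
trigger in this design. Effect sizes are partial η² = SS_eff/(SS_eff+SS_err);
confidence intervals for Cohen's d are out of scope (point estimates only).

Repeated-measures ANCOVA with one covariate mean-centres the covariate and
tests: covariate main effect (slope of subject means), within main effect
(intercept of the difference-score regression), and covariate × within
interaction (its slope). Centring cannot change the interaction F (slopes
are location-invariant); it is applied anyway so intercepts are interpretable.

χ² on 2×2 tables uses the Pearson statistic without Yates correction (the
correction is available via a flag). The KS normality test plugs in the
sample mean and SD without a Lilliefors correction, which makes it
conservative; this is the documented default, not an oversight. Median
splits send at-median ties to "low" by default (configurable); tertile
splits use linear-interpolation quantiles at 1/3 and 2/3 with boundary ties
falling into the discarded middle group.

## Power simulation

Per simulation, each group's two within-condition scores are drawn from a
bivariate normal with the configured cell means, common SD, and
within-subject correlation; the mixed ANOVA is run and rejections at α are
tallied. Defaults mirror a preregistration-style scenario (high group
0.45/−0.1, low group 0.2/0.1, n = 52/group, 2,000 simulations, α = .05) with
sd = 1 and r = 0.5 as documented defaults — the variance assumptions are
required inputs, and published power figures under unknown variance
assumptions are not treated as reproducible. Monte-Carlo SEs
`√(p(1−p)/n_sims)` accompany every estimate.

## Problem sizes and determinism

Every stochastic component funnels through `numpy.random.default_rng` seeds;
cohorts, sessions, and power runs are byte-reproducible. The test suite
exercises parameter recovery with 10,000 trials per displacement condition
(four replicate observers × 2,500 trials), staircase convergence with 200
sessions per boundary × noise cell, and calibration runs of 1,000–2,000
simulations — sizes at which Monte-Carlo error is far below the tolerances
being checked while the whole suite stays fast on one CPU.

## Known limitations

- The observer model is intentionally minimal; asymmetric criteria,
  non-Gaussian memory noise, and confidence computed from posterior
  probability rather than boundary distance are all plausible alternatives
  it does not cover.
- The psychometric fit assumes a unimodal, symmetric profile; strongly
  bimodal response patterns are flagged only via non-convergence or the
  PSE-bounds exclusion.
- `rm_ancova_2level` and `mixed_anova_2x2` are specialised to two-level
  factors by design; they are not general k×m ANOVA implementations.
- The staircase threshold estimator pools reversals without modelling the
  slight asymmetry a finite step size induces near the continuum bounds;
  with boundaries well inside [1, 21] the bias is below half a level.
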