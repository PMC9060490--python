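# Methods

This note documents the models behind `vaxdyn`, their assumptions, the
defaults of the synthetic-data generator, and the numerical choices — the
things a maintainer or careful user needs and the API reference does not say.

## Data model

A panel is a long-format table, one row per respondent × wave, with
agreement levels for the voluntary and mandated regime on the 0–4 Likert
scale, a vaccination status (`unvaccinated`/`once`/`twice`), and covariates.
Invariants enforced on load: levels in {0..4} or missing, at most one row per
(respondent, wave), vaccination status non-decreasing across waves. Missing
values are empty CSV cells; there are no sentinel integers. Floats are
serialized with shortest-repr formatting and parsed with round-trip
precision, so write→read is exact field-for-field.

Respondents vaccinated twice at a wave have missing attitude levels by
construction (they were no longer asked). Two explicit policies exist and
each analysis defaults to the one that matches its construction:

- `as_willing` — population-share analyses (consistency classes, crowding
  pie): being fully vaccinated places the respondent with the willing.
- `exclude` — wave-to-wave switching tables and transition estimation,
  where an attitude *pair* is needed.

Respondents vaccinated once keep their stated attitudes at face value; the
data model carries the status so a different policy can be applied downstream.

An optional `weight` column is carried through subsetting untouched; all
default analyses are unweighted.

## Consistency and switching

Levels collapse to opposed {0,1}, undecided {2}, willing {3,4}. A complete
trajectory is `consistently_X` iff it is category X in every wave, else
`inconsistent`; the four classes are exhaustive and mutually exclusive, and
their shares are reported both as exact rationals (counts over n) and floats.
The per-wave opposed shares and their unweighted mean over panel waves are
computed alongside, since the misreport model consumes exactly that pair
(consistent share, mean cross-section share). The mean is over the panel's
own waves, not over any external cross-section samples.

## Markov attitude dynamics

Transition matrices are row-wise relative frequencies of paired observations
between two waves — the maximum-likelihood estimate under a first-order,
time-homogeneous Markov assumption. Both the 5-level and the collapsed
3-category state space are supported; 5-level is the default. Rows whose
origin state is unobserved are imputed as self-loops and flagged
(`imputed_rows`); a uniform row is available behind a flag, and Laplace-α
smoothing behind another (default α = 0, no smoothing).

The stationary distribution solves the balance conditions πP = π, Σπ = 1 by
replacing one redundant balance equation with the normalization constraint
and solving the linear system. Power iteration (tolerance 1e-10, cap 10⁶
iterations) is implemented as an independent cross-check, not as the default
path. Uniqueness is decided structurally before solving: the chain's
positive-entry digraph is condensed and the closed (recurrent) communicating
classes counted; more than one closed class raises an error naming the
classes (an identity matrix, where every distribution is stationary, is the
canonical case). Transient states receive mass 0, which the linear solve
produces naturally.

The stationary distribution is a thought experiment — "what if these
transition rates persisted" — not a forecast; the projection utility makes
the same point by iterating initial·Pᵏ. Uncertainty in π is quantified by a
respondent-level bootstrap (resample respondents with replacement,
re-estimate P and π); replicates with reducible resampled chains are redrawn.
No delta-method intervals are offered.

## Random-misreport mixture model

Structural constants: K categories, opposed set of m of them, W waves;
p_opp = m/K, p_not = 1 − m/K (defaults 0.4/0.6). The truly-invariant opposed
fraction x answers opposed with probability 1 − p_not·μ per wave; everyone
else with p_opp·μ, independently across waves. The two observed moments give

    x (1 − p_not μ)^W + (1 − x)(p_opp μ)^W = c
    x (1 − p_not μ)   + (1 − x) p_opp μ    = a

The solver eliminates x through the linear equation,
x(μ) = (a − p_opp μ)/(1 − μ), scans the residual of the W-th-power equation
on a 10⁵-point grid over μ ∈ [0, 1 − 1e-9], and refines every sign change by
Brent's method to machine tolerance. μ = 1 is excluded (x is undefined
there). All roots with x ∈ [0, 1] are reported; if several exist the
smallest-μ root is primary — the most conservative attribution of response
error. Preconditions: c, a ∈ (0, 1) and c ≤ a (consistency over W waves
cannot exceed a single wave's share); with W ≥ 2 and 0 < c < a a root always
exists because the residual is a − c > 0 at μ = 0 and a^W − c < 0 where x(μ)
reaches 0, so the no-root error path only fires for degenerate specs
(e.g. W = 1 with c ≠ a).

Interpretation is attached to the solution object: x is an **upper bound**
on hard-core opposition, since the scenario attributes every observed
attitude change to noise.

## Crowding-out tabulation

Within one wave, respondents are conditioned on their voluntary-regime
category and decomposed by their mandated-regime category. Respondents
without both responses (notably the twice-vaccinated) are excluded; the
decomposition identity — destination counts sum to the conditioning
subgroup's count — then holds exactly. Shares are population-denominated by
default (so destination shares sum to the conditioning share) with
within-subgroup normalization behind a flag. The net effect counts
*movements* only: share becoming willing minus share becoming opposed, with
the conditioning category's own stayers contributing to neither term.

The naive uptake prediction is the share with voluntary level 3–4 plus the
share already vaccinated twice, over all respondents of the wave.

## Binary attitude regressions

Outcomes: `consistently_opposed` (1 iff opposed in every wave) and
`moved_opposed_to_willing` (risk set = opposed at the origin wave; 1 iff
willing at the destination wave). Estimators: maximum-likelihood logit
(statsmodels, Newton) and the least-squares linear probability model.
Numeric predictors are standardized with the sample SD (n − 1); categorical
predictors enter as treatment-coded indicators and are not standardized —
"standardized coefficients" refers to the numeric block. Per-wave belief
covariates contribute their level at a chosen wave and, optionally, the
change to the following wave. Confidence intervals are 95% Wald.
Non-convergence and coefficient blow-up (|β| > 50 on standardized scale) are
surfaced as a separation error rather than returned silently.

Tjur's R² = mean(p̂ | y = 1) − mean(p̂ | y = 0). For an OLS linear probability
model with intercept this equals the regression R² exactly (tested to
1e-10). McFadden's pseudo-R² is reported for logits as the secondary
measure. The full vs sociodemographics-only comparison re-fits both models
on the *identical* estimation sample (list-wise deletion over the union of
predictors, enforced before either fit) and reports both Tjur's R² values
and their difference.

## Synthetic-data generator

The generator emulates the structural form the analyses assume, not any
particular dataset's joint covariate distribution. Defaults — chosen once as
the study conditions and held fixed:

- n = 2,018 respondents, 3 waves.
- Initial voluntary Likert distribution (.12, .08, .13, .17, .50): 20%
  opposed, 13% undecided; mandated (.20, .09, .16, .15, .40): 29% opposed.
- Transition matrices with transient voluntary opposition (P(0→{3,4}) +
  P(1→{3,4}) large, so the opposed share drifts toward ~12% by wave 3) and
  sticky mandated opposition (P(0→0) = 0.6).
- `misreport_rate` = 0: the misreport scenario is a hypothetical bound, not
  the maintained model; tests that need contamination set it explicitly.
  Misreports apply independently per wave and, by default, per regime; a
  flag shares the per-(respondent, wave) misreport event across the two
  regimes, since either reading of the scenario is defensible.
- `uptake_probability` = 0.09 among the latently willing at the final wave,
  so ≈ 0.09 × 0.73 ≈ 6.6% of the panel is vaccinated twice by wave 3 (their
  attitudes are then missing); `partial_uptake_probability` = 0.05 assigns
  `once` status without hiding attitudes.
- Covariates: age ~ N(53, 14²) clipped to 18–95, gender (47% female),
  region (21% East), education (30/45/25 low/mid/high), and two per-wave
  belief indices (trust in institutions, belief in vaccine effectiveness) as
  standard-normal random walks with step SD 0.3.

Covariate-dependent switching uses a multinomial-logit tilt: destination
logits are log P₀[i,j] + s_j·Σ β_c z_c with destination scores s_j = (j−2)/2,
so a positive coefficient shifts transitions toward willingness while a zero
coefficient reproduces the baseline matrix exactly. The voluntary and
mandated chains are independent by default; a coupling knob draws the
mandated initial state as the voluntary one shifted down by `regime_offset`
levels with probability `coupling_strength` (transitions then follow the
mandated matrix regardless), reproducing the systematically more
oppositional mandated responses when enabled.

Randomness comes from one `numpy` PCG64 generator seeded by the single
config seed and consumed in a fixed vectorized order, which makes output
byte-identical across runs of the same version; per-respondent substreams
were considered and rejected as needless given vectorized draws.

What the generator does *not* emulate: panel attrition and re-recruitment,
post-stratification weights, item nonresponse correlated with attitudes,
question-order and demand effects, and any real joint distribution of
sociodemographics and beliefs. Passing recovery tests therefore show the
estimators are correct under the assumed data-generating process, not that
the assumptions hold in any real survey.

## Problem sizes in the test suite

Recovery tests use the sizes at which their sampling-error bounds are sharp
but cheap: 20,000 respondents for transition recovery (3 multinomial SEs
entrywise), 10,000 for logit coefficient recovery (3 Wald SEs), 10⁶ draws
for the misreport-population Monte Carlo (3 binomial SEs), a 20 × 20 (x, μ)
grid for the solver round trip at 1e-8. The full suite runs in well under a
minute on one core.

## Known limitations

- Transition estimation assumes first-order dynamics and, for projections,
  time-homogeneity; the package's own two-wave-pair interface is the right
  tool for showing that homogeneity fails (the pairs differ).
- The misreport solver is moment-matching by design; it does not use the
  full response-pattern likelihood and reports no sampling uncertainty for
  (x, μ). Feeding it bootstrap-resampled (c, a) pairs is the supported route.
- The regression module does no imputation; list-wise deletion only.
- Likert states are treated as unordered categories in the Markov machinery;
  no ordinal smoothing is applied.
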