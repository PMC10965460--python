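# Methods

## The estimation problem

Two standard estimators of health-adjusted life expectancy (HALE) for a
dichotomous chronic condition (here T2DM) are implemented side by side.

**Sullivan.** A period (current) life table is compiled from an age-grouped
mortality schedule by Chiang's method, and each interval's person-years are
weighted by the proportion of the interval's population free of the
condition. The estimand is the expected disease-free remaining years of a
survivor to exact age x *drawn from the current population at that age* —
a mixture of healthy and already-diseased individuals, since persons with
the condition still contribute their (1 − π)-weighted survivorship through
the marginal life table.

**Multistate.** A three-state illness-death Markov process (1 = disease
free, 2 = diseased, 3 = dead; no recovery) is fitted to two-wave panel
data, and e_rs(x) = ∫₀^{ω−x} P_rs(x, x+u) du gives the expected years in
living state s for a person in state r at age x. HALE here is e₁₁ — it
conditions on *starting disease-free* — and LE is e₁₁ + e₁₂.

The two estimands coincide only when prevalence at the starting age is
zero; in general Sullivan-HALE ≈ (1 − π(x)) · e₁₁ under age-constant
intensities. The cross-method consistency test exploits exactly this:
it uses a low-prevalence configuration (π(65) ≈ 1%) so that the two
routes must agree within a few percent, and its docstring records why.

## Chiang life table

Interior intervals convert the central death rate m to a conditional death
probability with q = n·m / (1 + n(1 − a)m), a being the mean fraction of
the interval lived by those dying in it (default 0.5 everywhere — standard
practice at ages 5+, and this package targets a 65+ population; a is
configurable per interval for full-table use). The terminal open-ended
interval takes q = 1 and L = l/m, the exponential-tail closure; a terminal
interval with survivors but no deaths is an error rather than a silent
infinity. Interior zero-death intervals are allowed (q = 0). The radix
(default 100,000) cancels from e; a property test asserts this to 1e−9
relative (exact cancellation is not available in floating point).

Default banding is 5-year intervals from 65 with an open terminal band.
The terminal band deserves care: e_terminal = 1/m_terminal, and with half
of a 65+ cohort surviving to the terminal age, over half the weight of
e(65) can sit on that single estimated rate. Schedules whose terminal band
has thin exposure (e.g. a short-follow-up cohort aggregated on its own)
give very noisy LE; the synthetic module therefore also provides
`expected_mortality_schedule`, a deterministic period schedule computed
from known intensities that stands in for the large external surveillance
mortality data set such analyses normally use.

## Prevalence

Point estimates are cases/n with a Wilson score interval by default (well
behaved at boundary counts; a Wald option exists). Direct standardisation
is a weighted mean with user-supplied standard-population weights — census
weights are external data and are not bundled. In the Sullivan sum,
intervals above the oldest observed prevalence band reuse the last
observed band's value (the sum needs π on every interval to the terminal
age; carrying forward is the least-assumption choice and is tested against
an explicitly padded table).

## Multistate model

**Parameterisation.** Gompertz (log-linear in age) intensities with
proportional covariate effects, q_rs(a, z) = exp(α_rs + ξ_rs(a − 65) +
β_rs′z), reference age 65, covariate default the male indicator. ξ ≡ 0
gives an age-constant model used throughout the tests because its
occupancy probabilities and life expectancies have closed forms. α = −∞
is accepted as an exactly-zero intensity so degenerate processes (no
onset, no mortality) are representable.

**Transition probabilities.** For the upper-triangular generator the
interval solution has the closed form P₁₁ = e^{−(q₁₂+q₁₃)t},
P₂₂ = e^{−q₂₃t}, P₁₂ = q₁₂ t e^{−(q₁₂+q₁₃)t} · exprel((q₁₂+q₁₃−q₂₃)t)
with exprel(x) = (eˣ−1)/x. The exprel form is algebraically identical to
the eigendecomposition expression q₁₂(e^{−q₂₃t} − e^{−(q₁₂+q₁₃)t})/(q₁₂+q₁₃−q₂₃)
but stays exact and stable through the eigenvalue collision
q₁₂+q₁₃ = q₂₃, so no fallback branch is needed; a test pins the collision
case to an ODE solution at 1e−10. Age-varying intensities are treated as
piecewise constant at subinterval midpoints on a grid of width ≤
grid_step; the scheme is second-order, and matching a high-accuracy ODE
solve to 1e−8 requires ~0.004-year steps in the oracle tests, while the
likelihood default of 0.25 years keeps the approximation error orders of
magnitude below sampling noise.

**Likelihood.** One term per subject: log P_{s₀s₁}(a₀, a₁) for subjects
re-observed alive (onset interval-censored by construction), and
log[P_{s₀1}q₁₃(a_d) + P_{s₀2}q₂₃(a_d)] for exact death ages with unknown
pre-death state — the register-linkage design. An interval-censored-death
variant is not separately coded; deaths are the exact-age kind throughout.
Observed impossible transitions (2→1) yield −∞ with a warning naming the
record. Lost-to-follow-up subjects are excluded; a censor-at-baseline
option is accepted for interface completeness but is arithmetically
identical, because censoring at a subject's only observation contributes
a likelihood factor of one.

**Optimisation and uncertainty.** BFGS on the unconstrained log-intensity
scale. The objective is the *mean* log-likelihood so the gradient-norm
tolerance (default 1e−6) is sample-size free; with finite-difference
gradients a 1e−8 tolerance on the total log-likelihood of 10⁴ subjects is
below numerical noise, which is why the per-record scaling was chosen.
Starting values are crude occurrence/exposure rates. Non-convergence
raises; a BFGS "precision loss" stop is accepted only if the gradient is
already small. The covariance is the inverse observed information by
numerical differentiation; life-expectancy intervals come from a seeded
parametric bootstrap (normal draws on the parameter scale, percentile
intervals).

**Life expectancy.** Trapezoid integration of the occupancy row on a
0.1-year grid to max_age 110 (halving the grid moves results by <1e−3 y,
tested). Survival mass above 1e−3 remaining at max_age triggers a
truncation warning — age-constant fits inherently leave a small
exponential tail and will warn if max_age is too low.

## Synthetic cohort generator

The generator is the model's generative twin plus the survey design
around it: every subject starts disease-free at the burn-in age (default
50) so that baseline prevalence at enrolment (65–79, uniform) emerges from
the process itself with structurally realistic onset-age censoring. Event
times are drawn by inverse transform on the closed-form Gompertz
cumulative hazard; competing risks out of state 1 are resolved as the
minimum of the two cause-specific times. Left truncation at enrolment is
handled by redrawing a subject's trajectory (keeping sex and entry age)
until death postdates entry. The follow-up gap is uniform (default
3 ± 1 y, emulating a baseline fielded over ~2 years). One master seed;
per-subject substreams keyed by (seed, subject index), so record i is
bit-reproducible and invariant to cohort size.

Dropout is a Bernoulli flag (default 0.115) drawn *independently of the
outcome*: a lost subject's vital status is unknown, exactly as when
follow-up status is ascertained at the second wave. This matters — marking
only known survivors as lost while always retaining deaths is informative
dropout and inflates fitted mortality by roughly 1/(1 − p_lost) (+13% at
the default rate, enough to bias disease-free life expectancy by ~3.5%);
replicate-fit experiments confirmed the MCAR mechanism leaves all nine
parameters and the derived life expectancies unbiased. Under MCAR,
excluding the lost from the likelihood is valid, matching how such
cohorts are analysed.

Default intensities were calibrated once, via the occupancy ODE, to the
study conditions the generator emulates: overall baseline prevalence
≈12.8% (men ≈10%, women ≈14.5%), total LE at 65 of roughly 18.5 y (men)
and 21.7 y (women), onset lower in men (β₁₂ = −0.42) and mortality higher
in men (β₁₃ = β₂₃ = 0.48) with a 1.8-fold diseased-mortality excess. A
single Gompertz intensity set cannot match that prevalence *and* the
~1.7%/y observed-incidence ambience simultaneously; prevalence was
prioritised and incidence comes out ~25% low. The generator reproduces the
structure of a real two-wave rural cohort, not its full heterogeneity: no
informative dropout, no covariates beyond sex, no calendar effects, no
measurement error in disease ascertainment, and exact death ages. Passing
tests therefore demonstrate correctness of the estimators under the
assumed illness-death law, not robustness to those violations.

## Problem sizes

Test and script sizes were chosen to keep Monte-Carlo error well inside
the asserted tolerances: 50,000 subjects for closed-form occupancy checks
(3 Monte-Carlo SEs), 20,000 for parameter recovery (each parameter within
3 SEs; life expectancies within 5% relative, whose sampling SD is ~1.5%
at that n), 8 × 1,500 replicate fits for interval coverage, and the
default 10,318 for the acceptance pipeline.
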