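# Methods

## The measurement model

Owner-reported shoulder heights are modelled as draws from a saturating
(monomolecular) growth curve with additive Gaussian noise and a latent
three-way unit-error class per record:

    h_i     ~ Normal(mu(age_i) * m_{class_i}, 1/tau)
    mu(age) = a * (1 - exp(-b * (age + c)))
    class_i ~ Categorical(pi),  m = (2.54, 1, 1/2.54)

`a` is the asymptotic mean height in cm; `b` (per day) sets the growth
tempo — the gap to `a` halves every ln2/b days; `c` (days) shifts the curve
so height is non-zero at birth. The exponent is read as `-b*(age + c)`,
the additive-offset form: it is the only reading under which the offset
produces a non-zero birth height (a multiplicative power form would give
zero height at age zero). `tau` is the noise precision (sd = 1/sqrt(tau),
cm). The class multipliers encode the two possible unit errors a
drop-down-unit questionnaire admits: a height measured in cm but entered
as inches is stored multiplied by 2.54; the reverse error divides by 2.54.
One latent class is drawn per observation, not per dog — repeated errors by
the same owner are treated as independent events.

Priors, in the precision parameterization throughout: `a ~ N(56, prec
0.01)` (sd 10 cm), centred on the Kennel Club breed-standard height;
`b ~ U(0, 1.5)`; `c ~ U(0, 100)` days; `tau ~ Gamma(0.001, 0.001)`
(shape/rate); `pi ~ Dirichlet(0.1, 0.8, 0.1)`. The N(56, 0.01) prior must
be mean+precision rather than mean+variance: with prior sd 0.1 cm the male
posterior could never sit 3 cm from the prior centre, as it does. The
Dirichlet has total concentration 1 — extremely weak — but its mean encodes
the 10%/80%/10% prior belief about error rates; it is config-overridable.
Sexes are fitted separately; there is no pooling and no per-dog random
effect (a known limitation: repeated measures of one dog are treated as
exchangeable around the population curve).

Stored heights at or below 1 cm (zeros and ones typed by owners) are
removed before fitting, and dogs losing every record are reported.

## Inference

Metropolis-within-Gibbs with the update order classes, a, b, c, tau, pi:

* **classes** — exact Gibbs; the full conditional is the normalized
  three-component density, computed in log space (softmax).
* **a** — conjugate normal: the likelihood is linear in `a` given the
  design vector `x_i = g(age_i) * m_{class_i}`.
* **tau** — conjugate gamma on the residual sum of squares.
* **pi** — conjugate Dirichlet on the class counts.
* **b, c** — Gaussian random-walk Metropolis with reflection at the
  uniform-prior bounds (reflection is symmetric, so the acceptance ratio is
  the bare likelihood ratio).

The schedule is 1000 adaptation iterations, 2000 burn-in, 5000 retained.
During adaptation only, every 50 iterations each proposal scale is
multiplied by `exp(1.5 * (acceptance - 0.3))`, steering acceptance toward
~30% (inside the 20–45% band for scalar random walks); scales are then
frozen so the retained chain is a valid time-homogeneous Markov chain.
Initial values are a = prior mean, b = 0.01/day, c = 10 d, sd = 5 cm,
classes all "ok" — deliberately generic juvenile-growth magnitudes, not
data-derived. Chains are deterministic given the seed.

`sample_posterior` can pin `b`, `c`, `pi` or the class vector. This is a
diagnostic hook: the test suite uses it to compare the sampler against a
dense-grid numerical posterior over (a, tau), a check that would be
intractable in the full parameter space.

Per-observation class posteriors are the retained-iteration membership
frequencies. Classification takes the argmax class, with two conservative
rules: exact ties go to "ok", and a non-ok call must reach a posterior
probability threshold (default 0.5) or the record falls back to "ok" — the
pipeline never corrects a height without posterior support. Corrected
height = stored value × (1/2.54, 1 or 2.54), the exact inverses of the
class distortions. The threshold rule is a declared convention of this
package; argmax-at-0.5 is one of several rules the original analysis could
have used.

Diagnostics: ESS and (for ≥2 chains) split-chain R-hat are delegated to
arviz; Metropolis acceptance rates are reported per fit and parameters
with ESS < 100 are flagged.

## Unit handling

The storage rules use the database's own rounded constants verbatim —
2.54 cm/inch, 2.20 lb/kg, 28.3 g/oz — not higher-precision physical
constants. Reanalysis fidelity requires reproducing what the database
stored, including its rounding.

## Exercise metrics

TDE for one report = sum over activities of (5/7 × weekday-bin midpoint +
2/7 × weekend-bin midpoint); tTDE = sqrt(TDE). Because the weights are
linear, weighting-then-summing and summing-then-weighting coincide; the
per-activity form is implemented. The default bin ladder is none, 0–30,
30–60, 60–120 and over-2h minutes, with the open-ended top bin read as
2–4 h (midpoint 180 min); a zero bin has midpoint 0. The ladder is
configuration data — every computation takes the bins as an argument — so
users with the actual questionnaire categories can substitute them.

## Cohort statistics

The 2×2 chi-squared statistic uses the cell-wise Yates continuity
correction `cc = min(0.5, |O−E|)`, on by default: this is the convention
that reproduces the published statistics from their printed counts, and it
never exceeds the uncorrected statistic. Proportion intervals are exact
Clopper–Pearson (beta quantiles); the method label travels with the
result because published intervals from unstated methods (often Wilson or
Wald) will differ in the third decimal. Loss to follow-up fixes "two
months" at 61 days and "four months" at 122, with "under one year" meaning
age < 365 days; calendar-month arithmetic is deliberately avoided.

## The synthetic cohort generator

The generator emulates the study design, with ground truth retained for
every draw:

* **Visits** at recruitment age, then every 30 days to day 365, then every
  91 days to day 547 (heights were collected to 18 months). Optional
  uniform ±jitter is off by default so runs are exactly reproducible;
  real return intervals were far more irregular than any jitter model.
* **Recruitment age** lognormal with median 92 days and shape sigma = 0.4,
  clipped to [30, 365] — a right-skewed shape whose only calibrated
  feature is the median, the one figure available.
* **Sex** male with probability 2266/4307, the registered-cohort ratio.
* **Growth** per sex from the published posterior means (female a = 55.1,
  b = 0.0132, c = 7.03, sd = 4.67; male 59.0, 0.0126, 9.37, 5.01).
  Stored values are drawn as Normal(mu·m_class, sd) — the generator is the
  fitted model, so parameter-recovery runs test inference, not model
  misspecification. The standalone `contaminate_units` utility instead
  scales an already-noisy value (noise scales with the multiplier); the
  distinction is immaterial for classification, where the classes sit
  ~2.54× apart against ~5 cm noise.
* **Contamination** 5%/90%/5% by default, drawn per observation — the
  even split of roughly the misreporting rate implied by the published
  fit (470 of 12 479 heights, ≈3.8%).
* **Households** at the registered-cohort frequencies; **dropout** is
  geometric per visit with a family baseline hazard of 0.08 (≈43%
  one-year retention over ~10 visits, near the published 44%) scaled by
  the published hazard ratios (0.77 more-than-one-adult, 0.47 retired,
  0.81 single, 1.14 not reported). Directions are fixed; magnitudes are
  this package's choice.
* **Exercise reports** draw bin labels i.i.d. per activity/day-part from
  fixed categoricals chosen so off-lead and "other" dominate and mean TDE
  lands in the 2–3 h/day range. Real reports are autocorrelated within dog
  and seasonal; simulated ones are not.

Randomness is split per dog via `SeedSequence.spawn`, so enlarging a
cohort preserves every existing dog byte-for-byte.

What passing tests on this generator do **not** show: robustness to
non-Gaussian height noise, owner-level error clustering, informative
dropout correlated with growth, or real return-interval irregularity.

## Problem sizes and numerical choices

Parameter-recovery checks use 20 cohorts of 200 dogs (≈700–800
observations each) at the full 1000/2000/5000 schedule — large enough that
posterior means land within ~1% of truth for `a` while a complete
20-replicate run stays in tens of seconds. Classification checks use one
400-dog cohort with only mature (≥180 d) observations contaminated, since
below ~3 months the class means are separated by only a few noise sd and
no rule can recover them reliably. The pipeline's determinism check runs a
40-dog cohort with a shortened chain; determinism does not depend on size.

Degenerate inputs: empty observation sets, mixed-sex frames, non-simplex
probability vectors, zero-margin tables and negative ages all raise before
any computation. Mixture weights of exactly zero are handled in log space
(log 0 = -inf) rather than special-cased.
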