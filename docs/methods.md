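# Methods

## Estimand and model

For a binary phenotype, the sibling recurrence risk ratio is

```
lambda_s = Kr / K,
Kr = (affected siblings of affected probands) / (all siblings of affected probands),
K  = population prevalence.
```

Both quantities are binomial proportions: `Kr = x_r / n_r` pooled over the
siblings reported by probands positive for the phenotype, and `K = x / n`
from an independent population survey. The design is ecological — the two
proportions come from different samples with different instruments — so the
package treats each as an estimate with its own sampling error and never as
a known constant.

Siblings are counted as affected for *any* form of the phenotype (the family
question asks only whether the sibling is affected, not which subtype), while
probands are stratified by subtype and sex. Sibling affection is modelled as
exchangeable and independent given the proband; no within-family correlation
beyond the ratio itself is assumed, which is exactly what the plug-in
`Kr/K` estimand measures.

## Phenotype classification

Tinnitus presence is an affirmative answer on the past-year screening item
(A17: "yes, most/all", "yes, a lot", "yes, some"); "do not know" and missing
responses count as not-tinnitus, with missing answers tallied separately in
the `FilterReport`. The exclusion cascade runs in a fixed order — intersex,
prefer-not-to-say, clinician-heard (objective) tinnitus — recording only the
first applicable reason, and its counts always partition the input. This
precedence reproduces the recruitment arithmetic 2457 − 11 − 141 = 2305 of
the motivating study; the ordering of sex-based before objective exclusions
is implied by those counts rather than stated anywhere, and is fixed here by
convention.

Subtypes are defined independently of one another: bilateral ("both ears"
responses on B15), unilateral ("right"/"left"), constant (B2), severe (B4
"severely"). "Inside head" and missing laterality yield neither laterality
flag; a missing response on any subtype item withholds only that subtype.
Bilateral and unilateral are mutually exclusive by construction; the other
flags may co-occur.

## Prevalence and the Wilson interval

Prevalence CIs use the Wilson score interval (the inversion of the
one-sample score test), delegated to
`statsmodels.stats.proportion.proportion_confint(method="wilson")` with
endpoints snapped to exact 0/1 at the degenerate counts and clipped around
the point estimate to absorb float noise; an independent root-finding
inversion of the score equation backs it in the test suite. The default
confidence level is 0.95 everywhere.

When only a rounded published prevalence is available, the affected count is
reconstructed as `round(p_hat * n)` (round-half-to-even) and the estimate is
flagged `reconstructed`; the flag propagates into reports. Reconstruction
from a 2-decimal percentage can shift the last printed digit of downstream
ratios by one unit — the package reports the recomputed value, not the
published one, in that situation.

Age matching supports two modes. The default, range truncation, restricts
the population rows to the [min, max] of the target ages — the literal
reading of matching "the age range" — and is idempotent. The stricter
option subsamples within 5-year, left-closed bins anchored at age 18 to
reproduce the target's bin frequencies with a seeded generator, at the cost
of sample size. The original study's exact age-correction procedure is not
publicly documented, which is why both readings are exposed and the milder
one is the default.

## Bootstrap inference for lambda_s

Each of `n_boot` replicates draws

```
x* ~ Binomial(n_r, x_r / n_r)      (family source)
y* ~ Binomial(n,   x   / n)        (population source)
lambda* = (x* / n_r) / (y* / n)
```

and the 95% CI is the 2.5th/97.5th nearest-rank (type-1) empirical
percentile of the `lambda*` draws — deterministic given the mandatory seed
and free of interpolation-dialect ambiguity. Replicates with `y* = 0` are
redrawn so the percentile arithmetic stays finite; the redraw count is
reported and more than 1% of replicates aborts the run, preventing silent
bias when the population sample is far too small.

The two-sided p-value against `lambda_s = 1` is the add-one-smoothed
percentile form

```
p = min(1, 2 * min(#{lambda* <= 1} + 1, #{lambda* >= 1} + 1) / (n_boot + 1)),
```

monotone in evidence and never exactly zero (floor ≈ 2/(n_boot+1), ≈ 0.0002
at 10,000 replicates). p < 0.05 and "CI excludes 1" agree up to one
percentile step; the reporting layer's significance column uses the CI
criterion.

Parametric binomial resampling is the default because an individual-level
binary sample reduces without loss to its binomial count; a nonparametric
mode that resamples the underlying 0/1 outcome vectors with replacement is
provided and verified to target the same distribution (ECDF sup-distance
< 0.01 at 1e5 replicates on small instances). Defaults: `n_boot = 10,000`,
`conf_level = 0.95`, seed required.

Measured operating characteristics (recomputed by the test suite): CI
coverage 93–97% at true lambda 2 with 500 siblings against a 50,000-person
survey; type-I rejection ≤ 10% nominal at large samples; relative bias of
the point estimate < 5% at the scale of the motivating study's severe
stratum (361 probands, ≈ 300 siblings).

## Synthetic data generator

`GeneratorConfig` defaults encode the study conditions the package was built
around: subtype prevalences 8.49% / 6.68% / 7.38% / 2.55% (bilateral /
unilateral / constant / severe), a 27.2% family-history recall missingness
rate, 2,305 probands, uniform ages 18–90, equal sex ratio, Poisson(2)
sibship sizes, flat age effect and unit sex multipliers (so the null is
simple). Population indicators are Bernoulli with log-odds
`logit(K) + log(sex multiplier) + slope * (age − midpoint)/10`.

Each proband is assigned exactly one subtype from a configurable mixture
(default: weights proportional to the base prevalences), the defining
questionnaire item is set accordingly, and the remaining items are sampled
uniformly over the categories that do *not* confer another subtype flag
(including missing responses). This exclusivity is deliberate: each
sibling's affection probability is `min(1, lambda * K)` of the proband's
assigned stratum, so letting probands acquire incidental second flags would
mix sibling rates across strata and bias per-stratum recovery (in early
testing, by a factor ≈ 2 in the rarest stratum). The cost is that the
generator does not emulate the real co-occurrence of subtypes (a severely
affected proband is often also constant); estimates on real data pool
genuinely overlapping strata and passing recovery tests on synthetic data
do not certify behaviour under such overlap.

Other simplifications relative to real cohorts: no realistic national
demography, no twin structure, no hearing-loss co-modelling, missingness
completely at random rather than recall-biased.

## Numerical and design choices

- All internal values are unrounded; display rounding (2 decimals for
  ratios, 2-decimal percentages for prevalence) happens only in reporting.
- Per-stratum bootstrap seeds derive from the master seed via
  `numpy.random.SeedSequence`, making a full multi-stratum fit reproducible
  from a single integer.
- Simulation-heavy checks are sized to keep a full test run around a minute
  on one core: coverage uses 3,000 simulated datasets at 2,000 replicates
  each; bias monotonicity uses 1,500 runs per size over three doublings.
- Degenerate inputs fail loudly with the stratum named: empty strata, zero
  prevalence (lambda undefined), all-missing sibling data, missing seeds.

## Known limitations

- Ascertainment bias of the proband survey (volunteers with bothersome
  phenotypes over-enrol) is not corrected; lambda_s inherits it.
- No offspring/parent ratios, covariate adjustment, or delta-method /
  likelihood variants of the variance.
- The published sex-stratified prevalences for the constant subtype in the
  motivating study duplicate the bilateral column and are internally
  inconsistent with its sex-stratified ratios; the package computes whatever
  its inputs imply and deliberately asserts nothing against those two cells.
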