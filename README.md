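# sibrisk

Familial aggregation analysis for questionnaire-defined phenotypes: estimate
the **sibling recurrence risk ratio**

```
lambda_s = Kr / K
```

where `Kr` (the recurrence risk) is the proportion of affected siblings among
all siblings of affected probands, and `K` is the phenotype's prevalence in
the general population. `lambda_s > 1` indicates familial clustering of the
phenotype — the classical first step of a genetic-epidemiological workup.

The package was built for tinnitus subtypes (bilateral, unilateral, constant,
severe) defined from screening-questionnaire items, but the estimator is
trait-agnostic. Its distinguishing feature is **two-source uncertainty
propagation**: `Kr` and `K` come from different surveys, and both are
estimated binomial proportions. A percentile bootstrap redraws the affected
counts of *both* samples in every replicate, yielding confidence intervals
and p-values for `lambda_s` that honestly reflect both sources of noise.
Prevalence confidence intervals use the Wilson score interval, which keeps
its nominal coverage at the small proportions typical of severe phenotypes.

Who is this for: epidemiologists and statistical geneticists who have (a) a
proband survey with family-history counts and (b) population prevalence
figures — individual-level rows or published aggregates — and who want
stratified `lambda_s` estimates with defensible uncertainty.

## What's in the box

- `sibrisk.subtyping` — questionnaire classification: tinnitus presence
  (item A17), objective-tinnitus exclusion (B17), laterality (B15),
  constancy (B2), severity (B4), plus the cohort exclusion cascade with a
  full accounting `FilterReport`.
- `sibrisk.prevalence` — Wilson score intervals, prevalence estimation from
  individual-level or aggregate inputs (including reconstruction of counts
  from rounded published percentages), and age matching (range truncation or
  5-year-bin frequency matching).
- `sibrisk.aggregation` — `FamilialAggregationModel` / `...Results`
  (statsmodels-style `fit()` + `summary()`), the underlying functions
  `build_family_aggregate`, `lambda_point`, `bootstrap_lambda`, and the
  config-driven `run_analysis`.
- `sibrisk.synthdata` — a generator for matched synthetic population and
  proband/family tables with configurable true `lambda`, so the whole
  pipeline is testable without access to the original cohorts.
- `sibrisk` CLI — `prevalence`, `aggregate`, `simulate`, `full-run`
  subcommands with provenance records for reproducible runs.

## Worked example

Simulate a study of 2,305 probands against a 50,000-person population survey
with true ratios (1.8, 2.0, 2.3, 7.3) per subtype, then fit:

```python
from sibrisk import GeneratorConfig, generate_families, generate_population
from sibrisk.aggregation import run_analysis
from sibrisk.subtyping import FAMILY_SCHEMA

cfg = GeneratorConfig(
    seed=42, pop_n=50_000, family_n_probands=2305,
    true_lambda={"bilateral": 1.8, "unilateral": 2.0,
                 "constant": 2.3, "severe": 7.3},
)
res = run_analysis({
    "family": generate_families(cfg)[list(FAMILY_SCHEMA)],
    "population": generate_population(cfg),
    "n_boot": 10_000, "seed": 42,
    "strata": [["bilateral", "both"], ["unilateral", "both"],
               ["constant", "both"], ["severe", "both"]],
})
print(res.summary())
```

```
Sibling recurrence risk ratio (lambda_s)
==============================================================================
stratum                relatives affected              lambda (CI)         p
------------------------------------------------------------------------------
bilateral/both              1223      213     2.04 (1.79-2.30) *      0.0002
unilateral/both              833      108     1.97 (1.63-2.33) *      0.0002
constant/both               1001      175     2.45 (2.12-2.79) *      0.0002
severe/both                  349       66     7.36 (5.78-9.11) *      0.0002
------------------------------------------------------------------------------
* CI excludes 1 at the configured confidence level
```

Reading the severe row: siblings of severely affected probands carry tinnitus
at 66/349 ≈ 18.9%, against a simulated population prevalence of ≈2.6% —
a 7.4-fold recurrence ratio whose 95% CI (5.78–9.11) excludes 1, so the
familial aggregation is significant (bootstrap p ≈ 0.0002, the smoothed floor
at 10,000 replicates). Every estimate recovers its simulated true ratio
within its interval.

The same analysis from the shell:

```bash
sibrisk simulate --seed 42 --pop-n 50000 --n-probands 2305 --out study/
sibrisk aggregate --family study/families.csv --population study/population.csv \
    --n-boot 10000 --seed 42 --out results/
```

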