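"""Sibling recurrence risk ratios with two-source bootstrap inference.

The familial aggregation of a trait is summarised by the sibling recurrence
risk ratio

    lambda_s = Kr / K,

where Kr — the recurrence risk — is the proportion of affected siblings among
all siblings of affected probands, and K is the trait's prevalence in the
general population.  lambda_s > 1 indicates familial clustering.

Both Kr and K are estimated binomial proportions from two different samples
(a proband/family survey and a population survey), so the uncertainty of the
ratio must propagate both sources.  ``bootstrap_lambda`` does this with a
percentile bootstrap: each replicate redraws the affected-sibling count and
the population affected count from their estimated binomials, forms the
ratio, and the confidence interval is read off the empirical percentiles.
A two-sided add-one-smoothed percentile p-value tests lambda_s = 1.

``FamilialAggregationModel`` packages the computation statsmodels-style: the
model is built from a classified proband table and a population prevalence
source; ``fit()`` returns a ``FamilialAggregationResults`` carrying one
lambda estimate per (subtype, sex) stratum with CIs, p-values and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .prevalence import (
    PrevalenceEstimate,
    age_match,
    estimate_prevalence,
    wilson_interval,
)
from .subtyping import SUBTYPES

SEX_STRATA = ("both", "male", "female")

#: Fraction of replicates allowed to be redrawn for a zero population count
#: before the bootstrap aborts (a zero denominator would make lambda* infinite).
MAX_REDRAW_FRACTION = 0.01


@dataclass(frozen=True)
class FamilyAggregate:
    """Sibling counts pooled over the affected probands of one stratum."""

    subtype: str
    sex: str
    n_probands: int
    n_relatives: int
    x_relatives: int
    n_missing_sibdata: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.x_relatives <= self.n_relatives:
            raise ValueError(
                f"affected siblings {self.x_relatives} outside "
                f"[0, {self.n_relatives}]"
            )

    @property
    def kr(self) -> float:
        """Recurrence risk: affected siblings / total siblings."""
        if self.n_relatives == 0:
            raise ValueError(
                f"stratum {self.subtype}/{self.sex}: no siblings, Kr undefined"
            )
        return self.x_relatives / self.n_relatives


@dataclass(frozen=True)
class LambdaResult:
    """A lambda_s point estimate with percentile-bootstrap inference."""

    subtype: str
    sex: str
    lambda_hat: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    seed: int
    fam: FamilyAggregate
    k: PrevalenceEstimate
    conf_level: float = 0.95
    n_redrawn: int = 0
    method: str = "parametric"

    @property
    def significant(self) -> bool:
        """True when the CI excludes the null value 1."""
        return self.ci_low > 1.0 or self.ci_high < 1.0


def build_family_aggregate(
    family: pd.DataFrame, subtype: str, sex: str = "both"
) -> FamilyAggregate:
    """Pool sibling counts over probands positive for ``subtype``.

    ``family`` is a classified proband table carrying the subtype flag
    columns, proband ``sex``, and the A8 sibling counts.  Probands with
    missing sibling data are dropped and counted in the aggregate's
    ``n_missing_sibdata``.  Stratification by ``sex`` selects on the
    proband's sex; siblings are counted as affected for any tinnitus.
    """
    if subtype not in family.columns:
        raise ValueError(f"no subtype flag column {subtype!r} in family table")
    if sex not in SEX_STRATA:
        raise ValueError(f"sex must be one of {SEX_STRATA}, got {sex!r}")
    rows = family[family[subtype].astype(bool)]
    if "included" in family.columns:
        rows = rows[rows["included"].astype(bool)]
    if sex != "both":
        rows = rows[rows["sex"] == sex]
    sib_total = pd.to_numeric(rows["a8_siblings_total"], errors="coerce")
    sib_aff = pd.to_numeric(rows["a8_siblings_tinnitus"], errors="coerce")
    usable = sib_total.notna() & sib_aff.notna()
    n_missing = int((~usable).sum())
    rows, sib_total, sib_aff = rows[usable], sib_total[usable], sib_aff[usable]
    if len(rows) == 0:
        raise ValueError(
            f"stratum {subtype}/{sex}: no probands with usable sibling data"
        )
    return FamilyAggregate(
        subtype=subtype,
        sex=sex,
        n_probands=len(rows),
        n_relatives=int(sib_total.sum()),
        x_relatives=int(sib_aff.sum()),
        n_missing_sibdata=n_missing,
    )


def lambda_point(fam: FamilyAggregate, k: PrevalenceEstimate) -> float:
    """Plug-in recurrence risk ratio Kr / K, unrounded."""
    if k.p_hat <= 0:
        raise ValueError(
            f"population prevalence is zero for {fam.subtype}/{fam.sex}; "
            "lambda undefined"
        )
    return fam.kr / k.p_hat


def _percentile(sorted_draws: np.ndarray, q: float) -> float:
    """Nearest-rank (type-1) empirical quantile."""
    n = sorted_draws.size
    rank = int(np.ceil(q * n))
    return float(sorted_draws[min(max(rank, 1), n) - 1])


def bootstrap_lambda(
    fam: FamilyAggregate,
    k: PrevalenceEstimate,
    n_boot: int = 10_000,
    conf_level: float = 0.95,
    seed: int | None = None,
    method: str = "parametric",
) -> LambdaResult:
    """Percentile-bootstrap CI and p-value for lambda_s = Kr / K.

    Each replicate draws x* ~ Binomial(n_relatives, Kr-hat) for the family
    sample and y* ~ Binomial(k.n, k.x/k.n) for the population sample and
    forms lambda* = (x*/n_relatives)/(y*/k.n); uncertainty from both sources
    therefore propagates into the interval.  CI endpoints are the
    (1−conf)/2 and (1+conf)/2 nearest-rank percentiles of the lambda* draws.
    The two-sided p-value against lambda_s = 1 is add-one smoothed:
    min(1, 2·min(#{lambda* ≤ 1}+1, #{lambda* ≥ 1}+1)/(n_boot+1)), so it is
    never exactly zero.  Replicates with y* = 0 are redrawn (the count is
    reported; more than 1% aborts).  ``method="nonparametric"`` resamples the
    underlying 0/1 outcome vectors with replacement instead of drawing the
    binomial counts directly; the two schemes target the same distribution.
    """
    if fam.n_relatives <= 0:
        raise ValueError(f"stratum {fam.subtype}/{fam.sex}: no siblings")
    if k.n <= 0 or k.x < 0:
        raise ValueError("population estimate must carry positive n and count x")
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    rng = np.random.default_rng(seed)
    p_fam = fam.x_relatives / fam.n_relatives
    p_pop = k.x / k.n

    if method == "parametric":
        x_star = rng.binomial(fam.n_relatives, p_fam, size=n_boot)
        y_star = rng.binomial(k.n, p_pop, size=n_boot)
    elif method == "nonparametric":
        fam_outcomes = np.zeros(fam.n_relatives, dtype=np.int8)
        fam_outcomes[: fam.x_relatives] = 1
        pop_outcomes = np.zeros(k.n, dtype=np.int8)
        pop_outcomes[: k.x] = 1
        idx_f = rng.integers(0, fam.n_relatives, size=(n_boot, fam.n_relatives))
        x_star = fam_outcomes[idx_f].sum(axis=1)
        # population vectors are large; resample counts in chunks to bound memory
        y_star = np.empty(n_boot, dtype=np.int64)
        chunk = max(1, int(2e7 // max(k.n, 1)))
        for start in range(0, n_boot, chunk):
            stop = min(start + chunk, n_boot)
            idx_p = rng.integers(0, k.n, size=(stop - start, k.n))
            y_star[start:stop] = pop_outcomes[idx_p].sum(axis=1)
    else:
        raise ValueError(f"unknown bootstrap method {method!r}")

    n_redrawn = 0
    zero = y_star == 0
    while zero.any():
        n_redrawn += int(zero.sum())
        if n_redrawn > MAX_REDRAW_FRACTION * n_boot:
            raise RuntimeError(
                f"more than {MAX_REDRAW_FRACTION:.0%} of bootstrap replicates "
                "had a zero population count; prevalence sample too small"
            )
        y_star[zero] = rng.binomial(k.n, p_pop, size=int(zero.sum()))
        zero = y_star == 0

    lam_star = np.sort((x_star / fam.n_relatives) / (y_star / k.n))
    alpha = 1.0 - conf_level
    ci_low = _percentile(lam_star, alpha / 2)
    ci_high = _percentile(lam_star, 1.0 - alpha / 2)
    n_le = int((lam_star <= 1.0).sum())
    n_ge = int((lam_star >= 1.0).sum())
    p_value = min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (n_boot + 1))
    return LambdaResult(
        subtype=fam.subtype,
        sex=fam.sex,
        lambda_hat=lambda_point(fam, k),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p_value,
        n_boot=n_boot,
        seed=int(seed),
        fam=fam,
        k=k,
        conf_level=conf_level,
        n_redrawn=n_redrawn,
        method=method,
    )


# ---------------------------------------------------------------------------
# model / results


class FamilialAggregationResults:
    """Fit results: one lambda_s estimate per requested stratum.

    ``results`` holds the per-stratum :class:`LambdaResult` objects;
    ``diagnostics`` lists strata that failed their preconditions together
    with the reason (they are reported, never silently dropped).
    """

    def __init__(
        self,
        results: Sequence[LambdaResult],
        diagnostics: Sequence[dict] | None = None,
    ):
        self.results = list(results)
        self.diagnostics = list(diagnostics or [])

    def to_frame(self) -> pd.DataFrame:
        """Tabulate results in the layout of a recurrence-risk table."""
        rows = []
        for r in self.results:
            rows.append(
                {
                    "subtype": r.subtype,
                    "sex": r.sex,
                    "n_probands": r.fam.n_probands,
                    "n_relatives": r.fam.n_relatives,
                    "x_relatives": r.fam.x_relatives,
                    "k_hat": r.k.p_hat,
                    "lambda": r.lambda_hat,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p_value": r.p_value,
                    "significant": r.significant,
                }
            )
        for d in self.diagnostics:
            rows.append(
                {
                    "subtype": d.get("subtype"),
                    "sex": d.get("sex"),
                    "n_probands": np.nan,
                    "n_relatives": np.nan,
                    "x_relatives": np.nan,
                    "k_hat": np.nan,
                    "lambda": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_value": np.nan,
                    "significant": False,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable table: lambda (95% CI), p-value per stratum."""
        lines = [
            "Sibling recurrence risk ratio (lambda_s)",
            "=" * 78,
            f"{'stratum':<22}{'relatives':>10}{'affected':>9}"
            f"{'lambda (CI)':>25}{'p':>10}",
            "-" * 78,
        ]
        for r in self.results:
            mark = "*" if r.significant else " "
            lines.append(
                f"{r.subtype + '/' + r.sex:<22}{r.fam.n_relatives:>10}"
                f"{r.fam.x_relatives:>9}"
                f"{r.lambda_hat:>9.2f} ({r.ci_low:.2f}-{r.ci_high:.2f}){mark:>2}"
                f"{r.p_value:>12.4f}"
            )
        for d in self.diagnostics:
            lines.append(
                f"{d.get('subtype', '?')}/{d.get('sex', '?')}: "
                f"not estimated -- {d.get('error', 'failed preconditions')}"
            )
        lines.append("-" * 78)
        lines.append("* CI excludes 1 at the configured confidence level")
        return "\n".join(lines)


class FamilialAggregationModel:
    """Sibling recurrence risk model over a classified proband table.

    Parameters
    ----------
    family : DataFrame
        One row per proband with subtype flag columns, proband ``sex`` and
        the sibling counts ``a8_siblings_total`` / ``a8_siblings_tinnitus``
        (the joined output of the subtyping step).
    population : DataFrame or mapping
        Either individual-level population rows (``sex`` plus one 0/1 column
        per subtype) or an aggregate table with columns
        (subtype, sex, n, x and/or p_hat).
    strata : sequence of (subtype, sex)
        Strata to estimate; defaults to every subtype crossed with
        both/male/female.
    """

    def __init__(
        self,
        family: pd.DataFrame,
        population,
        strata: Sequence[tuple[str, str]] | None = None,
        conf_level: float = 0.95,
    ):
        self.family = family
        self.population = population
        self.strata = list(strata) if strata is not None else [
            (sub, sx) for sub in SUBTYPES for sx in SEX_STRATA
        ]
        self.conf_level = conf_level

    @classmethod
    def from_questionnaire(
        cls,
        records,
        population,
        strata: Sequence[tuple[str, str]] | None = None,
        conf_level: float = 0.95,
    ) -> "FamilialAggregationModel":
        """Build the model from raw questionnaire records.

        Runs the subtype classification and exclusion cascade, then joins the
        resulting flags back to the sibling counts.
        """
        from .subtyping import apply_cohort_filters, assignments_to_frame

        records = list(records)
        assignments, report = apply_cohort_filters(records)
        flags = assignments_to_frame(assignments)
        sibs = pd.DataFrame(
            {
                "id": pd.Series([r.id for r in records], dtype=object),
                "sex": pd.Series([r.sex for r in records], dtype=object),
                "a8_siblings_total": [r.a8_siblings_total for r in records],
                "a8_siblings_tinnitus": [r.a8_siblings_tinnitus for r in records],
            }
        )
        joined = flags.merge(sibs, on="id", validate="one_to_one")
        model = cls(joined, population, strata=strata, conf_level=conf_level)
        model.filter_report = report
        return model

    def _prevalence_for(self, subtype: str, sex: str) -> PrevalenceEstimate:
        pop = self.population
        if isinstance(pop, pd.DataFrame) and {"subtype", "n"} <= set(pop.columns):
            row = pop[(pop["subtype"] == subtype) & (pop["sex"] == sex)]
            if len(row) == 0:
                raise ValueError(
                    f"no aggregate prevalence row for {subtype}/{sex}"
                )
            return estimate_prevalence(
                row.iloc[0].to_dict(), subtype, sex, self.conf_level
            )
        return estimate_prevalence(pop, subtype, sex, self.conf_level)

    def fit(
        self,
        n_boot: int = 10_000,
        seed: int | None = None,
        method: str = "parametric",
    ) -> FamilialAggregationResults:
        """Estimate lambda_s with bootstrap inference for every stratum.

        Per-stratum bootstrap seeds are derived deterministically from
        ``seed``, so a refit with the same seed reproduces every interval.
        """
        if seed is None:
            raise ValueError("fit requires an explicit seed for the bootstrap")
        stratum_seeds = np.random.SeedSequence(seed).generate_state(
            len(self.strata)
        ) % (2**31)
        results, diagnostics = [], []
        for (subtype, sex), s in zip(self.strata, stratum_seeds):
            try:
                fam = build_family_aggregate(self.family, subtype, sex)
                k = self._prevalence_for(subtype, sex)
                results.append(
                    bootstrap_lambda(
                        fam,
                        k,
                        n_boot=n_boot,
                        conf_level=self.conf_level,
                        seed=int(s),
                        method=method,
                    )
                )
            except (ValueError, RuntimeError) as exc:
                diagnostics.append(
                    {"subtype": subtype, "sex": sex, "error": str(exc)}
                )
        return FamilialAggregationResults(results, diagnostics)


def run_analysis(config: Mapping) -> FamilialAggregationResults:
    """Run the full prevalence + aggregation pipeline from a config mapping.

    Config keys: ``family`` (path to a proband table or a DataFrame in the
    questionnaire schema), ``population`` (path or DataFrame; aggregate
    tables are recognised by their ``subtype``/``n`` columns), ``strata``
    (list of [subtype, sex]; default all), ``n_boot``, ``conf_level``,
    ``seed`` (required), ``method``, and optionally ``age_match``
    ({"mode": "range"|"bins", plus bin options}) applied to individual-level
    population rows using the family sample's ages as the target.
    """
    from .subtyping import read_family_table, records_from_frame

    fam_input = config["family"]
    if isinstance(fam_input, pd.DataFrame):
        records = records_from_frame(fam_input)
    else:
        records = read_family_table(str(fam_input))

    pop_input = config["population"]
    if not isinstance(pop_input, (pd.DataFrame, dict)):
        from .prevalence import read_aggregate_table, read_population_table

        path = str(pop_input)
        table = read_aggregate_table(path) if path.endswith(".json") else None
        if table is None:
            table = pd.read_csv(
                path, sep="\t" if path.endswith((".tsv", ".tab", ".txt")) else ","
            )
        pop_input = table

    am = config.get("age_match")
    if am and isinstance(pop_input, pd.DataFrame) and "age" in pop_input.columns:
        target = [r.age for r in records if r.age is not None]
        pop_input, match_report = age_match(
            pop_input,
            target,
            mode=am.get("mode", "range"),
            bin_width=am.get("bin_width", 5),
            bin_anchor=am.get("bin_anchor", 18),
            seed=am.get("seed", config.get("seed")),
        )
    else:
        match_report = None

    strata = config.get("strata")
    if strata is not None:
        strata = [tuple(s) for s in strata]
    model = FamilialAggregationModel.from_questionnaire(
        records,
        pop_input,
        strata=strata,
        conf_level=float(config.get("conf_level", 0.95)),
    )
    results = model.fit(
        n_boot=int(config.get("n_boot", 10_000)),
        seed=int(config["seed"]),
        method=config.get("method", "parametric"),
    )
    results.filter_report = model.filter_report
    results.match_report = match_report
    return results
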