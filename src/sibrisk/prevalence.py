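"""Population prevalence estimation with Wilson score intervals.

Prevalence K of each tinnitus subtype is a binomial proportion x/n from a
population survey, supplied either as individual-level rows (age, sex, one
0/1 indicator per subtype) or as aggregate counts.  Confidence intervals use
the Wilson score interval, the inversion of the one-sample score test, which
keeps its nominal coverage at the small proportions typical of severe
tinnitus.  When the survey sample is older or younger than the family sample
being compared against, rows can first be age-matched to the target group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

SEXES = ("both", "male", "female")


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A binomial proportion with its Wilson score interval.

    ``reconstructed`` flags estimates whose affected count ``x`` was
    back-calculated from a rounded published prevalence rather than observed.
    """

    subtype: str
    sex: str
    n: int
    x: int
    p_hat: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95
    age_matched: bool = False
    reconstructed: bool = False

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"sample size must be positive, got n={self.n}")
        if not 0 <= self.x <= self.n:
            raise ValueError(f"affected count x={self.x} outside [0, n={self.n}]")
        if not 0 < self.conf_level < 1:
            raise ValueError(f"conf_level must be in (0, 1), got {self.conf_level}")


def wilson_interval(
    x: int,
    n: int,
    conf_level: float = 0.95,
    *,
    subtype: str = "any",
    sex: str = "both",
    age_matched: bool = False,
    reconstructed: bool = False,
) -> PrevalenceEstimate:
    """Wilson score interval for a binomial proportion x/n.

    The interval has centre (p̂ + z²/2n)/(1 + z²/n) and half-width
    z·sqrt(p̂(1−p̂)/n + z²/4n²)/(1 + z²/n), with z the standard-normal
    quantile at (1 + conf_level)/2.
    """
    if n <= 0:
        raise ValueError(f"sample size must be positive, got n={n}")
    if not 0 <= x <= n:
        raise ValueError(f"affected count x={x} outside [0, n={n}]")
    if not 0 < conf_level < 1:
        raise ValueError(f"conf_level must be in (0, 1), got {conf_level}")
    ci_low, ci_high = proportion_confint(
        x, n, alpha=1.0 - conf_level, method="wilson"
    )
    # snap away float noise at the degenerate proportions and keep the
    # interval inside [0, 1] around the point estimate
    p_hat = x / n
    ci_low = 0.0 if x == 0 else max(0.0, min(float(ci_low), p_hat))
    ci_high = 1.0 if x == n else min(1.0, max(float(ci_high), p_hat))
    return PrevalenceEstimate(
        subtype=subtype,
        sex=sex,
        n=int(n),
        x=int(x),
        p_hat=p_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        conf_level=conf_level,
        age_matched=age_matched,
        reconstructed=reconstructed,
    )


def reconstruct_count(p_hat: float, n: int) -> int:
    """Back-calculate an affected count from a rounded published proportion.

    Uses round-half-to-even on p̂·n, matching the precision loss of tables
    that print prevalence to two decimal percentage points.
    """
    return int(round(p_hat * n))


def estimate_prevalence(
    data,
    subtype: str,
    sex: str = "both",
    conf_level: float = 0.95,
    *,
    age_matched: bool = False,
) -> PrevalenceEstimate:
    """Estimate prevalence of ``subtype`` for one sex stratum.

    ``data`` is either a DataFrame of individual-level rows (columns ``sex``
    and a 0/1 column named after the subtype) or an aggregate mapping with
    keys ``n`` and either ``x`` or ``p_hat``.  ``sex="both"`` pools males and
    females.  Aggregates specified by a rounded ``p_hat`` get a reconstructed
    count and the estimate is flagged accordingly.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    if isinstance(data, pd.DataFrame):
        if subtype not in data.columns:
            raise ValueError(f"no indicator column {subtype!r} in population data")
        rows = data if sex == "both" else data[data["sex"] == sex]
        if len(rows) == 0:
            raise ValueError(f"empty population stratum: subtype={subtype}, sex={sex}")
        indicator = rows[subtype].astype(int)
        return wilson_interval(
            int(indicator.sum()),
            len(rows),
            conf_level,
            subtype=subtype,
            sex=sex,
            age_matched=age_matched,
        )
    # aggregate input
    agg = dict(data)
    n = int(agg["n"])
    if n <= 0:
        raise ValueError(f"empty population stratum: subtype={subtype}, sex={sex}")
    if agg.get("x") is not None and not pd.isna(agg.get("x")):
        x, reconstructed = int(agg["x"]), False
    elif agg.get("p_hat") is not None and not pd.isna(agg.get("p_hat")):
        x, reconstructed = reconstruct_count(float(agg["p_hat"]), n), True
    else:
        raise ValueError(
            f"aggregate input for subtype={subtype}, sex={sex} needs 'x' or 'p_hat'"
        )
    return wilson_interval(
        x,
        n,
        conf_level,
        subtype=subtype,
        sex=sex,
        age_matched=age_matched,
        reconstructed=reconstructed,
    )


# ---------------------------------------------------------------------------
# age matching


@dataclass
class MatchReport:
    """Sizes and per-bin counts from an age-matching pass."""

    mode: str
    n_before: int
    n_after: int
    age_min: float
    age_max: float
    bin_counts: dict[str, int] = field(default_factory=dict)


def _age_bounds(target_ages) -> tuple[float, float]:
    arr = np.asarray(target_ages, dtype=float)
    if arr.ndim == 0 or arr.size == 0:
        raise ValueError("target_ages must be a non-empty sequence or (min, max) pair")
    return float(arr.min()), float(arr.max())


def age_match(
    population_rows: pd.DataFrame,
    target_ages,
    mode: str = "range",
    *,
    bin_width: int = 5,
    bin_anchor: int = 18,
    seed: int | None = None,
) -> tuple[pd.DataFrame, MatchReport]:
    """Restrict a population sample to the age profile of a target group.

    ``mode="range"`` (default) truncates to the [min, max] of the target
    ages.  ``mode="bins"`` additionally subsamples within left-closed
    right-open ``bin_width``-year bins anchored at ``bin_anchor`` so the
    matched sample reproduces the target's bin frequencies; subsampling uses
    a seeded generator.  Range truncation is idempotent.
    """
    if "age" not in population_rows.columns or population_rows["age"].isna().any():
        raise ValueError("age must be present on every population row")
    lo, hi = _age_bounds(target_ages)
    ages = population_rows["age"].astype(float)
    in_range = population_rows[(ages >= lo) & (ages <= hi)]
    if len(in_range) == 0:
        raise ValueError(
            f"no population rows in target age range [{lo:g}, {hi:g}]"
        )
    if mode == "range":
        report = MatchReport(
            mode=mode,
            n_before=len(population_rows),
            n_after=len(in_range),
            age_min=lo,
            age_max=hi,
        )
        return in_range, report
    if mode != "bins":
        raise ValueError(f"unknown age-match mode {mode!r}")

    target = np.asarray(target_ages, dtype=float)
    if target.size < 2:
        raise ValueError("bin mode needs individual target ages, not a range")
    bins = lambda a: ((np.asarray(a, dtype=float) - bin_anchor) // bin_width).astype(int)
    target_bins, pop_bins = bins(target), bins(in_range["age"])
    bin_ids, target_counts = np.unique(target_bins, return_counts=True)
    target_freq = target_counts / target_counts.sum()
    avail = np.array([(pop_bins == b).sum() for b in bin_ids])
    if (avail == 0).any() and (target_freq[avail == 0] > 0).any():
        empty = bin_ids[(avail == 0)]
        raise ValueError(f"population has no rows in target age bins {empty.tolist()}")
    # largest total m keeping every bin's demand within supply
    m = int(np.floor((avail / target_freq).min()))
    take = np.floor(m * target_freq).astype(int)
    rng = np.random.default_rng(seed)
    pieces, bin_counts = [], {}
    for b, k in zip(bin_ids, take):
        members = in_range.index[pop_bins == b]
        chosen = rng.choice(members, size=k, replace=False)
        pieces.append(in_range.loc[chosen])
        lo_b = bin_anchor + b * bin_width
        bin_counts[f"[{lo_b},{lo_b + bin_width})"] = int(k)
    matched = pd.concat(pieces).sort_index() if pieces else in_range.iloc[:0]
    report = MatchReport(
        mode=mode,
        n_before=len(population_rows),
        n_after=len(matched),
        age_min=lo,
        age_max=hi,
        bin_counts=bin_counts,
    )
    return matched, report


def read_population_table(path: str) -> pd.DataFrame:
    """Read individual-level population rows (CSV/TSV by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def read_aggregate_table(path: str) -> pd.DataFrame:
    """Read aggregate prevalence rows (subtype, sex, n, x and/or p_hat)."""
    if str(path).endswith(".json"):
        return pd.read_json(path)
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    return pd.read_csv(path, sep=sep)
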