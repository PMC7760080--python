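"""Synthetic two-source cohort generator.

Emulates the statistical structure the aggregation analysis assumes: a large
population survey with age/sex-dependent subtype prevalence, and a separate
proband/family survey whose siblings are affected at rate lambda·K.  Both
tables are written in exactly the delimited-text schemas the subtyping and
prevalence readers consume, so every pipeline stage is testable end to end
without external data.

Defaults mirror the study conditions of the source cohorts: subtype
prevalences bilateral 8.49%, unilateral 6.68%, constant 7.38%, severe 2.55%,
and a 27.2% sibling-recall missingness rate.  Sibling affection is
exchangeable-independent given the proband — no within-family correlation
beyond the lambda ratio itself — which matches the lambda_s = Kr/K estimand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .subtyping import B15_BILATERAL, B15_UNILATERAL, FAMILY_SCHEMA, SUBTYPES

DEFAULT_PREVALENCE = {
    "bilateral": 0.0849,
    "unilateral": 0.0668,
    "constant": 0.0738,
    "severe": 0.0255,
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    ``age_effect`` is a log-odds slope per decade of age (0 keeps prevalence
    flat); ``prevalence_sex_multiplier`` scales the odds per sex;
    ``true_lambda`` is the recurrence risk ratio induced per subtype (or per
    (subtype, sex) proband stratum); ``sibship_dist`` is ``("poisson", mean)``
    or ``("fixed", k)``; ``recall_missing_rate`` is the probability that a
    proband cannot recall the family history, blanking both A8 fields.
    """

    seed: int = 0
    pop_n: int = 100_000
    family_n_probands: int = 2305
    base_prevalence: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    sex_ratio_male: float = 0.5
    prevalence_sex_multiplier: dict = field(
        default_factory=lambda: {"male": 1.0, "female": 1.0}
    )
    true_lambda: dict = field(default_factory=lambda: {s: 1.0 for s in SUBTYPES})
    age_range: tuple = (18, 90)
    age_effect: float = 0.0
    sibship_dist: tuple = ("poisson", 2.0)
    recall_missing_rate: float = 0.272
    subtype_mixture: dict | None = None  # default: proportional to prevalence

    def __post_init__(self) -> None:
        for subtype, k in self.base_prevalence.items():
            if not 0 < k < 1:
                raise ValueError(f"prevalence for {subtype} outside (0,1): {k}")
            lam = self._lambda_for(subtype, "male"), self._lambda_for(subtype, "female")
            for sex_lam in lam:
                if sex_lam * self._k_for(subtype, "both") > 1:
                    raise ValueError(
                        f"true_lambda*K > 1 for {subtype}: sibling affection "
                        "probability would not be a valid probability"
                    )
        if not 0 <= self.recall_missing_rate <= 1:
            raise ValueError("recall_missing_rate must be in [0, 1]")
        kind, _ = self.sibship_dist
        if kind not in ("poisson", "fixed"):
            raise ValueError(f"unknown sibship distribution {kind!r}")

    def _lambda_for(self, subtype: str, sex: str) -> float:
        if (subtype, sex) in self.true_lambda:
            return float(self.true_lambda[(subtype, sex)])
        return float(self.true_lambda.get(subtype, 1.0))

    def _k_for(self, subtype: str, sex: str) -> float:
        base = self.base_prevalence[subtype]
        if sex == "both":
            return base
        odds = base / (1 - base) * self.prevalence_sex_multiplier.get(sex, 1.0)
        return odds / (1 + odds)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_population(cfg: GeneratorConfig) -> pd.DataFrame:
    """Draw individual-level population rows (age, sex, subtype indicators).

    Ages are uniform over ``age_range``; each subtype indicator is Bernoulli
    with log-odds = logit(base prevalence) + log(sex odds multiplier) +
    age_effect·(age − age midpoint)/10, so with the default flat age effect
    and unit multipliers the marginal prevalence equals the base value.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.age_range
    ages = rng.integers(lo, hi + 1, size=cfg.pop_n)
    sexes = np.where(rng.random(cfg.pop_n) < cfg.sex_ratio_male, "male", "female")
    mid = (lo + hi) / 2.0
    out = {"age": ages, "sex": sexes}
    for subtype, base in cfg.base_prevalence.items():
        logit = np.log(base / (1 - base))
        mult = np.where(
            sexes == "male",
            cfg.prevalence_sex_multiplier.get("male", 1.0),
            cfg.prevalence_sex_multiplier.get("female", 1.0),
        )
        eta = logit + np.log(mult) + cfg.age_effect * (ages - mid) / 10.0
        p = _logistic(eta)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError(f"invalid probability for {subtype} after multipliers")
        out[subtype] = (rng.random(cfg.pop_n) < p).astype(int)
    return pd.DataFrame(out)


def _uniform_choice(rng, options, size):
    return rng.choice(np.asarray(options, dtype=object), size=size)


def generate_families(cfg: GeneratorConfig) -> pd.DataFrame:
    """Draw a proband/family table in the questionnaire schema.

    Every proband is tinnitus-positive and assigned exactly one subtype from
    the configured mixture (default: weights proportional to the base
    prevalences).  The defining questionnaire item is set so the subtyping
    rules recover the assigned subtype; the remaining items are sampled
    uniformly over the categories that do not confer a different subtype
    flag (including missing responses), so generated subtype flags are
    mutually exclusive and each analysis stratum contains exactly the
    probands whose siblings were simulated at that stratum's lambda·K.
    Sibship sizes follow ``sibship_dist``; each sibling is independently
    affected with probability min(1, lambda·K) for the proband's stratum.
    With probability ``recall_missing_rate`` both A8 fields are blanked.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n = cfg.family_n_probands
    subtypes = list(cfg.base_prevalence)
    weights = np.array(
        [
            (cfg.subtype_mixture or cfg.base_prevalence)[s]
            for s in subtypes
        ],
        dtype=float,
    )
    weights /= weights.sum()
    assigned = rng.choice(subtypes, size=n, p=weights)

    sexes = np.where(rng.random(n) < cfg.sex_ratio_male, "male", "female")
    lo, hi = cfg.age_range
    ages = rng.integers(lo, hi + 1, size=n)
    a17 = _uniform_choice(rng, ["yes_most", "yes_alot", "yes_some"], n)
    # non-conferring defaults, then force the defining item per assignment
    b15 = _uniform_choice(rng, ["inside_head", "missing"], n)
    b2 = _uniform_choice(rng, ["intermittent", "not_in_quiet", "missing"], n)
    b4 = _uniform_choice(rng, ["moderately", "slightly", "not_at_all", "missing"], n)
    mask = assigned == "bilateral"
    b15[mask] = _uniform_choice(rng, sorted(B15_BILATERAL), int(mask.sum()))
    mask = assigned == "unilateral"
    b15[mask] = _uniform_choice(rng, sorted(B15_UNILATERAL), int(mask.sum()))
    b2[assigned == "constant"] = "constant"
    b4[assigned == "severe"] = "severely"

    kind, param = cfg.sibship_dist
    if kind == "poisson":
        sib_total = rng.poisson(float(param), size=n)
    else:
        sib_total = np.full(n, int(param))
    aff_table = {
        (s, sex): min(1.0, cfg._lambda_for(s, sex) * cfg._k_for(s, "both"))
        for s in subtypes
        for sex in ("male", "female")
    }
    p_aff = np.array([aff_table[s, sex] for s, sex in zip(assigned, sexes)])
    sib_aff = rng.binomial(sib_total, p_aff)

    df = pd.DataFrame(
        {
            "id": [f"P{i:06d}" for i in range(n)],
            "age": ages,
            "sex": sexes,
            "a17_tinnitus": a17,
            "b17_clinician_heard": "no",
            "b15_laterality": b15,
            "b2_daypattern": b2,
            "b4_severity": b4,
            "a8_siblings_total": sib_total.astype(float),
            "a8_siblings_tinnitus": sib_aff.astype(float),
            "assigned_subtype": assigned,
        }
    )
    missing = rng.random(n) < cfg.recall_missing_rate
    df.loc[missing, ["a8_siblings_total", "a8_siblings_tinnitus"]] = np.nan
    return df


def write_study(cfg: GeneratorConfig, outdir: str) -> dict:
    """Write a complete synthetic study directory.

    Emits ``population.csv``, ``families.csv`` (questionnaire schema, minus
    the generator's bookkeeping column) and ``generator_config.yaml``;
    returns the paths.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pop = generate_population(cfg)
    fam = generate_families(cfg)
    pop_path = out / "population.csv"
    fam_path = out / "families.csv"
    pop.to_csv(pop_path, index=False)
    fam[list(FAMILY_SCHEMA)].to_csv(fam_path, index=False)
    cfg_dict = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(cfg).items()
        if not isinstance(v, dict) or all(isinstance(kk, str) for kk in v)
    }
    cfg_path = out / "generator_config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg_dict, sort_keys=True))
    return {"population": str(pop_path), "families": str(fam_path), "config": str(cfg_path)}
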