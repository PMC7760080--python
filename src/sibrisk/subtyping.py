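"""Questionnaire-driven tinnitus phenotype subtyping.

Converts raw ESIT-SQ-style questionnaire responses into phenotype subtype
assignments (bilateral, unilateral, constant, severe) and applies the cohort
exclusion cascade: sex categories that cannot be analysed in the sex-stratified
design are removed first, then objective tinnitus (tinnitus a clinician has
heard), leaving the subjective-tinnitus study sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

MISSING = "missing"

#: Admissible category labels per questionnaire item.  These spellings are the
#: published column dialect; readers may alias other spellings onto them.
CATEGORIES: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female", "intersex", "prefer_not_to_say", MISSING),
    "a17_tinnitus": (
        "yes_most",
        "yes_alot",
        "yes_some",
        "no_past_year",
        "no_never",
        "dont_know",
        MISSING,
    ),
    "b17_clinician_heard": ("yes", "no", MISSING),
    "b15_laterality": (
        "right",
        "left",
        "both_worse_right",
        "both_worse_left",
        "both_equal",
        "inside_head",
        MISSING,
    ),
    "b2_daypattern": ("constant", "intermittent", "not_in_quiet", MISSING),
    "b4_severity": ("severely", "moderately", "slightly", "not_at_all", MISSING),
}

A17_POSITIVE = frozenset({"yes_most", "yes_alot", "yes_some"})
B15_BILATERAL = frozenset({"both_worse_right", "both_worse_left", "both_equal"})
B15_UNILATERAL = frozenset({"right", "left"})

SUBTYPES = ("bilateral", "unilateral", "constant", "severe")

EXCLUSION_REASONS = (
    "none",
    "no_tinnitus",
    "intersex",
    "prefer_not_to_say",
    "objective_tinnitus",
)

#: Expected header of a proband/family table.
FAMILY_SCHEMA = (
    "id",
    "age",
    "sex",
    "a17_tinnitus",
    "b17_clinician_heard",
    "b15_laterality",
    "b2_daypattern",
    "b4_severity",
    "a8_siblings_total",
    "a8_siblings_tinnitus",
)


@dataclass(frozen=True)
class QuestionnaireRecord:
    """One proband's raw questionnaire responses plus demographics.

    Sibling counts come from the family-history item (A8): total number of
    siblings and the number known to have tinnitus.  ``None`` encodes a
    missing response throughout.
    """

    id: str
    age: int | None = None
    sex: str = MISSING
    a17_tinnitus: str = MISSING
    b17_clinician_heard: str = MISSING
    b15_laterality: str = MISSING
    b2_daypattern: str = MISSING
    b4_severity: str = MISSING
    a8_siblings_total: int | None = None
    a8_siblings_tinnitus: int | None = None

    def __post_init__(self) -> None:
        for fname in (
            "sex",
            "a17_tinnitus",
            "b17_clinician_heard",
            "b15_laterality",
            "b2_daypattern",
            "b4_severity",
        ):
            value = getattr(self, fname)
            if value not in CATEGORIES[fname]:
                raise ValueError(
                    f"unknown category {value!r} for field {fname!r} "
                    f"(record {self.id!r}); expected one of {CATEGORIES[fname]}"
                )
        if self.age is not None and self.age < 18:
            raise ValueError(f"record {self.id!r}: age {self.age} < 18 (adults only)")
        if (
            self.a8_siblings_total is not None
            and self.a8_siblings_tinnitus is not None
            and self.a8_siblings_tinnitus > self.a8_siblings_total
        ):
            raise ValueError(
                f"record {self.id!r}: affected siblings "
                f"{self.a8_siblings_tinnitus} > total siblings {self.a8_siblings_total}"
            )
        for fname in ("a8_siblings_total", "a8_siblings_tinnitus"):
            value = getattr(self, fname)
            if value is not None and value < 0:
                raise ValueError(f"record {self.id!r}: {fname} must be >= 0")


@dataclass(frozen=True)
class SubtypeAssignment:
    """Derived phenotype flags for one record, with exclusion provenance.

    ``included`` marks membership in the final study sample (tinnitus-positive
    and not excluded).  Subtype flags are only ever set on included records;
    they are not mutually exclusive except bilateral/unilateral, which
    partition laterality.
    """

    id: str
    included: bool
    exclusion_reason: str
    any_tinnitus: bool
    bilateral: bool = False
    unilateral: bool = False
    constant: bool = False
    severe: bool = False


@dataclass
class FilterReport:
    """Counts from the exclusion cascade over a record set."""

    total: int = 0
    included: int = 0
    excluded_by_reason: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in EXCLUSION_REASONS if r != "none"}
    )
    missing_a17: int = 0

    @property
    def excluded(self) -> int:
        return sum(self.excluded_by_reason.values())

    def to_dict(self) -> dict:
        return asdict(self)


def classify(record: QuestionnaireRecord) -> SubtypeAssignment:
    """Classify one questionnaire record into subtype flags.

    Tinnitus presence is any affirmative answer on the past-year tinnitus item
    (A17); "do not know" and missing count as not-tinnitus.  Exclusions are
    evaluated in order: sex categories outside the male/female stratification
    (intersex, then prefer-not-to-say), then objective tinnitus (clinician has
    heard it, B17); non-tinnitus records carry the ``no_tinnitus`` reason.
    Laterality (B15) maps "both ears" answers to bilateral and single-ear
    answers to unilateral; "inside head" and missing yield neither.  Constant
    is the "constant" day-pattern (B2); severe is the "severely" bothered
    response (B4).  A missing response on a subtype item withholds only that
    subtype flag.
    """
    any_tinnitus = record.a17_tinnitus in A17_POSITIVE

    if record.sex == "intersex":
        reason = "intersex"
    elif record.sex == "prefer_not_to_say":
        reason = "prefer_not_to_say"
    elif record.b17_clinician_heard == "yes":
        reason = "objective_tinnitus"
    elif not any_tinnitus:
        reason = "no_tinnitus"
    else:
        reason = "none"

    included = reason == "none"
    if not included:
        return SubtypeAssignment(
            id=record.id,
            included=False,
            exclusion_reason=reason,
            any_tinnitus=any_tinnitus,
        )

    return SubtypeAssignment(
        id=record.id,
        included=True,
        exclusion_reason="none",
        any_tinnitus=True,
        bilateral=record.b15_laterality in B15_BILATERAL,
        unilateral=record.b15_laterality in B15_UNILATERAL,
        constant=record.b2_daypattern == "constant",
        severe=record.b4_severity == "severely",
    )


def apply_cohort_filters(
    records: Iterable[QuestionnaireRecord],
) -> tuple[list[SubtypeAssignment], FilterReport]:
    """Classify every record and tally the exclusion cascade.

    The counts partition the input: ``included`` plus the per-reason exclusion
    counts equals the number of records.  Records with a missing A17 response
    are classified as not-tinnitus but additionally tallied in
    ``missing_a17``.
    """
    report = FilterReport()
    assignments: list[SubtypeAssignment] = []
    for record in records:
        assignment = classify(record)
        assignments.append(assignment)
        report.total += 1
        if record.a17_tinnitus == MISSING:
            report.missing_a17 += 1
        if assignment.included:
            report.included += 1
        else:
            report.excluded_by_reason[assignment.exclusion_reason] += 1
    return assignments, report


# ---------------------------------------------------------------------------
# delimited-text interface


def _delimiter_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_family_table(
    path: str, aliases: Mapping[str, str] | None = None
) -> list[QuestionnaireRecord]:
    """Read a proband/family table (CSV or TSV, chosen by extension).

    ``aliases`` maps file column names onto the published schema names, e.g.
    ``{"gender": "sex"}``.  Empty cells become missing values.
    """
    df = pd.read_csv(path, sep=_delimiter_for(path), dtype=str)
    if aliases:
        df = df.rename(columns=dict(aliases))
    missing_cols = [c for c in FAMILY_SCHEMA if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> list[QuestionnaireRecord]:
    """Build validated records from a DataFrame in the published schema."""

    def _cat(value) -> str:
        if value is None or (isinstance(value, float) and pd.isna(value)):
            return MISSING
        s = str(value).strip()
        return s if s else MISSING

    def _count(value) -> int | None:
        if value is None or (isinstance(value, float) and pd.isna(value)):
            return None
        s = str(value).strip()
        if not s or s.lower() in ("na", "nan", MISSING):
            return None
        return int(float(s))

    records = []
    for row in df.to_dict("records"):
        records.append(
            QuestionnaireRecord(
                id=str(row["id"]),
                age=_count(row.get("age")),
                sex=_cat(row.get("sex")),
                a17_tinnitus=_cat(row.get("a17_tinnitus")),
                b17_clinician_heard=_cat(row.get("b17_clinician_heard")),
                b15_laterality=_cat(row.get("b15_laterality")),
                b2_daypattern=_cat(row.get("b2_daypattern")),
                b4_severity=_cat(row.get("b4_severity")),
                a8_siblings_total=_count(row.get("a8_siblings_total")),
                a8_siblings_tinnitus=_count(row.get("a8_siblings_tinnitus")),
            )
        )
    return records


_ASSIGNMENT_COLUMNS = (
    "id",
    "included",
    "exclusion_reason",
    "any_tinnitus",
    "bilateral",
    "unilateral",
    "constant",
    "severe",
)


def assignments_to_frame(assignments: Sequence[SubtypeAssignment]) -> pd.DataFrame:
    """Tabulate assignments, one row per record."""
    return pd.DataFrame(
        [asdict(a) for a in assignments], columns=list(_ASSIGNMENT_COLUMNS)
    )


def write_assignments(
    assignments: Sequence[SubtypeAssignment], path: str
) -> None:
    assignments_to_frame(assignments).to_csv(
        path, sep=_delimiter_for(path), index=False
    )
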