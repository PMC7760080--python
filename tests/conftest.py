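"""Shared fixtures: published study quantities and synthetic record builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sibrisk.subtyping import FAMILY_SCHEMA

# Published recurrence-risk table: (subtype, proband sex) ->
# (respondents, total siblings, affected siblings, printed lambda)
TABLE2 = {
    ("bilateral", "both"): (1480, 1211, 184, 1.79),
    ("unilateral", "both"): (413, 324, 43, 1.99),
    ("constant", "both"): (1751, 1408, 238, 2.29),
    ("severe", "both"): (361, 297, 55, 7.27),
    ("bilateral", "male"): (756, 612, 99, 1.50),
    ("unilateral", "male"): (168, 126, 13, 1.42),
    ("constant", "male"): (923, 735, 119, 1.58),
    ("severe", "male"): (171, 140, 23, 5.03),
    ("bilateral", "female"): (724, 599, 85, 2.16),
    ("unilateral", "female"): (245, 198, 30, 2.44),
    ("constant", "female"): (828, 673, 119, 3.32),
    ("severe", "female"): (190, 157, 32, 10.25),
}

# Published prevalence table: (subtype, sex) -> percent; per-subtype survey N.
TABLE1_PCT = {
    ("bilateral", "both"): 8.49,
    ("bilateral", "male"): 10.79,
    ("bilateral", "female"): 6.56,
    ("unilateral", "both"): 6.68,
    ("unilateral", "male"): 7.24,
    ("unilateral", "female"): 6.20,
    ("constant", "both"): 7.38,
    ("severe", "both"): 2.55,
    ("severe", "male"): 3.26,
    ("severe", "female"): 1.99,
}
TABLE1_N = {"bilateral": 67615, "unilateral": 59507, "constant": 26696, "severe": 92287}

# Strata whose printed lambda is reproducible exactly from the printed
# inputs; the remaining cells differ by one unit in the last printed digit
# because the source computation used unrounded prevalences.  The
# sex-stratified constant cells are internally inconsistent and never
# asserted.
EXACT_CELLS = {
    ("bilateral", "both"),
    ("unilateral", "both"),
    ("constant", "both"),
    ("bilateral", "male"),
    ("bilateral", "female"),
    ("unilateral", "female"),
}
ONE_ULP_CELLS = {
    ("severe", "both"),
    ("severe", "male"),
    ("severe", "female"),
    ("unilateral", "male"),
}

DEFINING_ITEM = {
    "bilateral": ("b15_laterality", "both_equal"),
    "unilateral": ("b15_laterality", "right"),
    "constant": ("b2_daypattern", "constant"),
    "severe": ("b4_severity", "severely"),
}


def make_record_row(
    i: int,
    *,
    sex: str = "female",
    a17: str = "yes_some",
    b17: str = "no",
    b15: str = "inside_head",
    b2: str = "intermittent",
    b4: str = "slightly",
    sib_total=None,
    sib_aff=None,
    age: int = 40,
) -> dict:
    return {
        "id": f"R{i:06d}",
        "age": age,
        "sex": sex,
        "a17_tinnitus": a17,
        "b17_clinician_heard": b17,
        "b15_laterality": b15,
        "b2_daypattern": b2,
        "b4_severity": b4,
        "a8_siblings_total": sib_total,
        "a8_siblings_tinnitus": sib_aff,
    }


def stratum_family_frame(subtype: str, sex: str) -> pd.DataFrame:
    """Proband table for one stratum reproducing the published sibling counts.

    ``n_probands`` respondents positive for ``subtype``; the first
    ``n_relatives`` probands report one sibling each, of whom the first
    ``x_relatives`` report that sibling affected; the rest report no
    siblings.  Pooled counts therefore equal the published cell.
    """
    n_probands, n_rel, x_rel, _ = TABLE2[(subtype, sex)]
    item, value = DEFINING_ITEM[subtype]
    rows = []
    sexes = ("male", "female") if sex == "both" else (sex,)
    kw_name = {"b15_laterality": "b15", "b2_daypattern": "b2", "b4_severity": "b4"}[item]
    for i in range(n_probands):
        kwargs = {kw_name: value}
        rows.append(
            make_record_row(
                i,
                sex=sexes[i % len(sexes)],
                sib_total=1 if i < n_rel else 0,
                sib_aff=1 if i < x_rel else 0,
                **kwargs,
            )
        )
    return pd.DataFrame(rows, columns=FAMILY_SCHEMA)


@pytest.fixture(scope="session")
def cascade_records() -> pd.DataFrame:
    """2457 tinnitus-positive records: 3 intersex, 8 prefer-not-to-say and
    141 objective-tinnitus exclusions (disjoint), 2305 clean."""
    rows = []
    for i in range(2457):
        if i < 3:
            rows.append(make_record_row(i, sex="intersex"))
        elif i < 11:
            rows.append(make_record_row(i, sex="prefer_not_to_say"))
        elif i < 152:
            rows.append(make_record_row(i, b17="yes"))
        else:
            rows.append(make_record_row(i, sex="male" if i % 2 else "female"))
    return pd.DataFrame(rows, columns=FAMILY_SCHEMA)


@pytest.fixture(scope="session")
def aggregate_prevalence_table() -> pd.DataFrame:
    """Aggregate population input mirroring the published prevalence table."""
    rows = []
    for (subtype, sex), pct in TABLE1_PCT.items():
        rows.append(
            {
                "subtype": subtype,
                "sex": sex,
                "n": TABLE1_N[subtype],
                "x": np.nan,
                "p_hat": pct / 100.0,
            }
        )
    return pd.DataFrame(rows)
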