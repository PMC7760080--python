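"""Report rendering and provenance records.

Internal values stay unrounded; rendering rounds for display only — two
decimals for lambda and its CI, two-decimal percentages for prevalence,
matching epidemiological table conventions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .aggregation import FamilialAggregationResults
from .prevalence import PrevalenceEstimate


def prevalence_table(estimates: Sequence[PrevalenceEstimate]) -> pd.DataFrame:
    """Subtype-by-sex prevalence table with CI strings (percent scale)."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "subtype": e.subtype,
                "sex": e.sex,
                "n": e.n,
                "x": e.x,
                "prevalence_pct": round(100 * e.p_hat, 2),
                "ci_pct": f"({100 * e.ci_low:.2f}-{100 * e.ci_high:.2f})",
                "age_matched": e.age_matched,
                "reconstructed": e.reconstructed,
            }
        )
    return pd.DataFrame(rows)


def lambda_table(results: FamilialAggregationResults) -> pd.DataFrame:
    """Recurrence-risk-ratio table with display rounding and a significance
    column (CI excludes 1 at the configured level)."""
    df = results.to_frame()
    for col in ("lambda", "ci_low", "ci_high"):
        df[col] = df[col].round(2)
    df["p_value"] = df["p_value"].round(4)
    return df


def _sha256(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def provenance_record(
    config: Mapping, seed: int, input_paths: Sequence[str] = ()
) -> dict:
    """Machine-readable run provenance: config hash, seed, version, input
    checksums.  Deterministic for identical configs, so reruns byte-reproduce."""
    canon = json.dumps(
        {k: str(v) for k, v in sorted(config.items())}, sort_keys=True
    )
    return {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(canon.encode()).hexdigest(),
        "seed": int(seed),
        "inputs": {str(p): _sha256(p) for p in input_paths if Path(str(p)).exists()},
    }


def write_outputs(
    outdir: str,
    *,
    tables: Mapping[str, pd.DataFrame] | None = None,
    records: Mapping[str, Mapping] | None = None,
) -> list[str]:
    """Write each table as CSV + JSON and each record as JSON under outdir."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in (tables or {}).items():
        csv_path = out / f"{name}.csv"
        df.to_csv(csv_path, index=False)
        json_path = out / f"{name}.json"
        json_path.write_text(df.to_json(orient="records", indent=2))
        written += [str(csv_path), str(json_path)]
    for name, rec in (records or {}).items():
        path = out / f"{name}.json"
        path.write_text(json.dumps(rec, indent=2, default=str))
        written.append(str(path))
    return written
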