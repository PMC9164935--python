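"""Readers and writers for the package's CSV and JSON artifacts.

CSV dialect is fixed: comma separated, UTF-8, ``.`` decimal point with a
header row.  Locale comma decimals are rejected rather than guessed at,
to avoid silent unit errors in lab values.  Validation errors name the
offending row (1-based, excluding the header).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import yaml

from .phenotype import PARAMETERS, CaseFeatures, DiliPhenotype
from .scoring import CaseScore

__all__ = [
    "read_cases",
    "write_cases",
    "read_labs",
    "write_events",
    "write_phenotype",
    "read_phenotype",
    "write_scores",
    "load_config",
]

PathLike = Union[str, Path]

_CASE_COLUMNS = ["case_id", "drug", "latency_days", "r_value", "ast_alt_ratio"]
_LAB_COLUMNS = ["patient_id", "arm", "study_day", "analyte", "value", "uln"]


def _parse_decimal(raw, column: str, row: int) -> Optional[float]:
    """Strict decimal parsing; empty cells become None, comma decimals
    and other junk raise with the row number."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    s = str(raw).strip()
    if s == "":
        return None
    if "," in s:
        raise ValueError(
            f"row {row}: column {column!r}: comma decimal {s!r} rejected (use '.')"
        )
    try:
        return float(s)
    except ValueError:
        raise ValueError(f"row {row}: column {column!r}: non-numeric value {s!r}") from None


def read_cases(path: PathLike) -> list[CaseFeatures]:
    """Read a case-features CSV (case_id, drug, latency_days, r_value,
    ast_alt_ratio, optional arm) into validated records."""
    df = pd.read_csv(path, dtype=str)
    missing = set(_CASE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    has_arm = "arm" in df.columns
    cases = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        kwargs = {p: _parse_decimal(rec[p], p, i) for p in PARAMETERS}
        try:
            cases.append(
                CaseFeatures(
                    case_id=str(rec["case_id"]),
                    drug=str(rec["drug"]),
                    arm=(str(rec["arm"]) if has_arm and not pd.isna(rec["arm"]) else None),
                    **kwargs,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return cases


def write_cases(cases: Iterable[CaseFeatures], path: PathLike) -> None:
    rows = [
        {
            "case_id": c.case_id,
            "drug": c.drug,
            "latency_days": c.latency_days,
            "r_value": c.r_value,
            "ast_alt_ratio": c.ast_alt_ratio,
            "arm": c.arm,
        }
        for c in cases
    ]
    pd.DataFrame(rows, columns=_CASE_COLUMNS + ["arm"]).to_csv(path, index=False)


def read_labs(path: PathLike) -> pd.DataFrame:
    """Read a long-format lab CSV and validate its schema and values."""
    df = pd.read_csv(path, dtype={"patient_id": str, "arm": str, "analyte": str})
    missing = set(_LAB_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def write_events(events: pd.DataFrame, path: PathLike) -> None:
    events.to_csv(path, index=False)


def write_phenotype(phenotype: DiliPhenotype, path: PathLike) -> None:
    """Serialize a phenotype to JSON (lossless round-trip)."""
    Path(path).write_text(json.dumps(phenotype.to_dict(), indent=2) + "\n", encoding="utf-8")


def read_phenotype(path: PathLike) -> DiliPhenotype:
    return DiliPhenotype.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def write_scores(scores: Iterable[CaseScore], path: PathLike) -> None:
    """Write cohort scores as a worked-example-style CSV: per-parameter
    value and points, the weighted-parameter marker, and the total."""
    rows = []
    for s in scores:
        row: dict = {"case_id": s.case_id, "arm": s.arm}
        for name, ps in s.parameters.items():
            row[f"{name}"] = ps.value
            row[f"{name}_band"] = ps.band.value
            row[f"{name}_points"] = ps.points
            if ps.weighted:
                row["weighted_parameter"] = name
        row["total"] = s.total
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_config(path: PathLike) -> dict:
    """Load a YAML or JSON configuration mapping."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data
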