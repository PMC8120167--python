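"""ClinicalTable schema, validated readers and result writers.

The interchange format is plain CSV.  One row per patient with the
categorical clinico-pathological covariates, the continuous TSR (stored as
a fraction in [0, 1]; it is rendered as a percentage only in reports),
follow-up time in months and the event indicator (1 = locoregional
recurrence or metastasis within follow-up, 0 = censored).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CLINICAL_LEVELS",
    "CLINICAL_COLUMNS",
    "SchemaError",
    "read_clinical",
    "validate_clinical",
    "write_clinical",
    "write_segmentation_csv",
    "write_km_csv",
]

CLINICAL_LEVELS: dict[str, set[str]] = {
    "age_group": {"<=50", ">50"},
    "menopausal": {"pre", "post"},
    "histotype": {"IDC", "other"},
    "t_stage": {"T1", "T2", "T3"},
    "n_status": {"neg", "pos"},
    "grade": {"I", "II", "III"},
    "er": {"pos", "neg"},
    "pr": {"pos", "neg"},
    "her2": {"amp", "non-amp"},
}

CLINICAL_COLUMNS = ["patient_id", *CLINICAL_LEVELS, "tsr", "time_months", "event"]


class SchemaError(ValueError):
    """Clinical table violates the schema; carries row-level diagnostics."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("clinical table schema violations:\n  " + "\n  ".join(problems))


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Validate (and lightly coerce) a clinical table in place.

    Raises :class:`SchemaError` listing every offending row and column.
    ``tsr`` may be missing (NaN) but must otherwise lie in [0, 1].
    """
    problems: list[str] = []
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError([f"missing columns: {missing}"])
    if len(df) == 0:
        raise SchemaError(["table has no rows"])
    df = df.copy()
    for col, levels in CLINICAL_LEVELS.items():
        vals = df[col].astype(str)
        bad = ~vals.isin(levels)
        for idx in df.index[bad]:
            problems.append(f"row {idx}: {col}={df.loc[idx, col]!r} not in {sorted(levels)}")
        df[col] = vals
    tsr = pd.to_numeric(df["tsr"], errors="coerce")
    bad_tsr = df["tsr"].notna() & (tsr.isna() | (tsr < 0) | (tsr > 1))
    for idx in df.index[bad_tsr]:
        problems.append(f"row {idx}: tsr={df.loc[idx, 'tsr']!r} not a fraction in [0, 1]")
    df["tsr"] = tsr
    t = pd.to_numeric(df["time_months"], errors="coerce")
    bad_t = t.isna() | (t < 0)
    for idx in df.index[bad_t]:
        problems.append(f"row {idx}: time_months={df.loc[idx, 'time_months']!r} invalid")
    df["time_months"] = t
    e = pd.to_numeric(df["event"], errors="coerce")
    bad_e = ~e.isin([0, 1])
    for idx in df.index[bad_e]:
        problems.append(f"row {idx}: event={df.loc[idx, 'event']!r} must be 0 or 1")
    df["event"] = e
    if problems:
        raise SchemaError(problems)
    df["event"] = df["event"].astype(int)
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read and validate a ClinicalTable CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError([f"{path}: empty file"]) from exc
    return validate_clinical(df)


def write_clinical(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_segmentation_csv(results, path: str | Path) -> Path:
    """One row per assessed core: id, pixel areas and TSR."""
    rows = [
        {
            "core_id": r.core_id,
            "tumor_px": r.areas["tumor"],
            "stroma_px": r.areas["stroma"],
            "core_px": r.areas["core"],
            "tsr": r.tsr,
        }
        for r in results
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_km_csv(curve, path: str | Path) -> Path:
    """Kaplan-Meier curve as (time, survival, at_risk) rows."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"time": curve.times, "survival": curve.survival, "at_risk": curve.at_risk}
    ).to_csv(path, index=False)
    return path


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    path.write_text(json.dumps(obj, indent=2, default=default))
    return path
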