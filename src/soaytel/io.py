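"""Delimited-text table schemas and lossless readers/writers.

All tables are plain CSV with a header row.  Schemas (version 1):

phenotypes: sample_id,animal_id,year,age,sex,mother_id,father_id,plate_id,mac,pac,rtl
    sex in {F, M}; mac/pac integer years >= 1; rtl > 0; missing rtl allowed
    (empty field) for not-yet-measured samples.
plates (long format): plate,well,sample,amplicon,role,cycle,fluorescence
    amplicon in {TEL, B2M}; role in {sample, calibrator, NTC}.
rtl: sample_id,plate_id,role,cq_tel,cq_b2m,rtl,excluded,reason
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

SCHEMA_VERSION = 1

PHENOTYPE_COLUMNS = [
    "sample_id", "animal_id", "year", "age", "sex",
    "mother_id", "father_id", "plate_id", "mac", "pac", "rtl",
]
PLATE_COLUMNS = ["plate", "well", "sample", "amplicon", "role", "cycle", "fluorescence"]
RTL_COLUMNS = ["sample_id", "plate_id", "role", "cq_tel", "cq_b2m", "rtl", "excluded", "reason"]

_SEX_CODES = {"F", "M"}
_AMPLICONS = {"TEL", "B2M"}
_ROLES = {"sample", "calibrator", "NTC"}


def _require_columns(df, columns, what):
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing columns {missing}", column=missing[0])


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, PHENOTYPE_COLUMNS, "phenotype")
    bad_sex = ~df["sex"].isin(_SEX_CODES)
    if bad_sex.any():
        i = int(np.flatnonzero(bad_sex)[0])
        raise SchemaError(
            f"unknown sex code {df['sex'].iloc[i]!r}", row=i, column="sex"
        )
    for col in ("mac", "pac"):
        x = df[col]
        if (x < 1).any() or not np.allclose(x, np.round(x)):
            i = int(np.flatnonzero((x < 1) | ~np.isclose(x, np.round(x)))[0])
            raise SchemaError(f"{col} must be an integer >= 1", row=i, column=col)
    if "rtl" in df and df["rtl"].notna().any():
        bad = df["rtl"].notna() & (df["rtl"] <= 0)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise SchemaError("rtl must be > 0", row=i, column="rtl")
    return df


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["sex"] = df["sex"].astype(str)
    return validate_phenotypes(df)


def write_phenotypes(df: pd.DataFrame, path) -> Path:
    validate_phenotypes(df)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def validate_plates(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, PLATE_COLUMNS, "plate")
    for col, allowed in (("amplicon", _AMPLICONS), ("role", _ROLES)):
        bad = ~df[col].isin(allowed)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"unknown {col} code {df[col].iloc[i]!r}", row=i, column=col
            )
    if (df["fluorescence"] <= 0).any():
        i = int(np.flatnonzero(df["fluorescence"] <= 0)[0])
        raise SchemaError("fluorescence must be positive", row=i, column="fluorescence")
    return df


def read_plates(path) -> pd.DataFrame:
    return validate_plates(pd.read_csv(path))


def write_plates(df: pd.DataFrame, path) -> Path:
    validate_plates(df)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_rtl(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    _require_columns(df, RTL_COLUMNS, "rtl")
    df["reason"] = df["reason"].fillna("")
    return df


def write_rtl(df: pd.DataFrame, path) -> Path:
    _require_columns(df, RTL_COLUMNS, "rtl")
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_external_phenotypes(
    path,
    column_map: dict[str, str],
    sex_codes: dict[str, str] | None = None,
    delimiter: str = ",",
) -> pd.DataFrame:
    """Ingest a third-party phenotype table via an explicit column mapping.

    ``column_map`` maps our schema names (see PHENOTYPE_COLUMNS) to the
    column names used in the external file; nothing is guessed.
    ``sex_codes`` optionally recodes the external sex labels to F/M.
    """
    raw = pd.read_csv(path, delimiter=delimiter)
    missing = [v for v in column_map.values() if v not in raw.columns]
    if missing:
        raise SchemaError(f"external table missing mapped columns {missing}",
                          column=missing[0])
    df = pd.DataFrame({ours: raw[theirs] for ours, theirs in column_map.items()})
    if sex_codes:
        df["sex"] = df["sex"].map(lambda s: sex_codes.get(s, s))
    df["sex"] = df["sex"].astype(str)
    for col in PHENOTYPE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return validate_phenotypes(df[PHENOTYPE_COLUMNS])
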