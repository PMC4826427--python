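"""CSV schemas: person cohort, population rate tables, Lexis cell tables.

Dates are written ISO-8601 alongside decimal-year columns (``*_yr``); the
reader prefers the decimal-year columns when present and otherwise
converts dates (month-precision dates ``YYYY-MM`` are imputed to day 15,
accommodating registries that record events at month resolution).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .timeutil import dates_to_years, years_to_dates

PERSON_DATE_COLS = {"dob": "birth", "dx_date": "dx", "cancer_date": "cancer",
                    "death_date": "death", "entry": "entry", "exit": "exit"}


def write_persons(df: pd.DataFrame, path) -> None:
    """Write a cohort (internal decimal-year frame) to the person CSV schema."""
    out = pd.DataFrame({"id": df["id"], "country": df["country"], "sex": df["sex"]})
    for col, internal in PERSON_DATE_COLS.items():
        y = df[internal]
        out[col] = years_to_dates(y).dt.strftime("%Y-%m-%d")
        out[col] = out[col].where(y.notna(), "")
    out["cancer_site"] = df["site"].fillna("") if "site" in df else ""
    for col, internal in PERSON_DATE_COLS.items():
        out[f"{col}_yr"] = df[internal].round(6)
    out.to_csv(path, index=False)


def read_persons(path) -> pd.DataFrame:
    """Read the person CSV back into the internal decimal-year frame."""
    raw = pd.read_csv(path, dtype={"cancer_site": str})
    df = pd.DataFrame({"id": raw["id"], "country": raw["country"], "sex": raw["sex"]})
    for col, internal in PERSON_DATE_COLS.items():
        ycol = f"{col}_yr"
        if ycol in raw.columns:
            df[internal] = pd.to_numeric(raw[ycol], errors="coerce")
        else:
            df[internal] = dates_to_years(_impute_month(raw[col]))
    site = raw.get("cancer_site", pd.Series("", index=raw.index)).fillna("")
    df["site"] = site.where(site != "", None)
    return df


def _impute_month(s: pd.Series) -> pd.Series:
    s = s.astype(str).replace({"nan": "", "NaT": ""})
    month_only = s.str.fullmatch(r"\d{4}-\d{2}")
    return s.where(~month_only, s + "-15").replace({"": None})


def write_population(df: pd.DataFrame, path) -> None:
    cols = ["country", "sex", "age", "period", "person_years", "site", "cases"]
    df[cols].to_csv(path, index=False)


def read_population(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cells(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "cohort" not in out.columns and {"age", "period"}.issubset(out.columns):
        out["cohort"] = out["period"] - out["age"]
    lead = [c for c in ("country", "sex", "age", "period", "cohort", "duration",
                        "site", "events", "pyrs") if c in out.columns]
    out[lead].to_csv(path, index=False)


def read_cells(path) -> pd.DataFrame:
    return pd.read_csv(path)
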