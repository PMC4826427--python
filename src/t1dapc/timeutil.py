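"""Date <-> decimal-year conversion.

All internal computation uses continuous decimal years with the convention
1 year = 365.25 days, anchored at 1970-01-01 = 1970.0.  This removes
leap-year ambiguity from person-time arithmetic: differences of decimal
years are exactly proportional to day counts.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

_EPOCH = _dt.date(1970, 1, 1)
DAYS_PER_YEAR = 365.25


def date_to_year(d) -> float:
    """Convert a date (datetime.date, ISO string, or pd.Timestamp) to decimal years."""
    if d is None or (isinstance(d, float) and np.isnan(d)):
        return np.nan
    if isinstance(d, str):
        d = _dt.date.fromisoformat(d)
    elif isinstance(d, pd.Timestamp):
        d = d.date()
    elif isinstance(d, _dt.datetime):
        d = d.date()
    return 1970.0 + (d - _EPOCH).days / DAYS_PER_YEAR


def year_to_date(y: float) -> _dt.date:
    """Inverse of :func:`date_to_year` (rounded to the nearest day)."""
    days = int(round((y - 1970.0) * DAYS_PER_YEAR))
    return _EPOCH + _dt.timedelta(days=days)


def dates_to_years(s: pd.Series) -> pd.Series:
    """Vectorised conversion of a column of ISO dates to decimal years."""
    ts = pd.to_datetime(s, errors="coerce")
    days = (ts - pd.Timestamp(_EPOCH)).dt.days
    return 1970.0 + days / DAYS_PER_YEAR


def years_to_dates(y: pd.Series) -> pd.Series:
    days = np.round((np.asarray(y, dtype=float) - 1970.0) * DAYS_PER_YEAR)
    out = pd.Series(pd.NaT, index=getattr(y, "index", None), dtype="datetime64[ns]")
    ok = np.isfinite(days)
    out[ok] = pd.Timestamp(_EPOCH) + pd.to_timedelta(days[ok], unit="D")
    return out
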