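"""Exact follow-up splitting on the Lexis diagram.

Each cohort member's follow-up is a 45-degree line segment in the age x
calendar-time plane, additionally classified by time since diabetes
diagnosis.  The splitter cuts the follow-up interval at every age-year
birthday, every calendar-year boundary and every duration cut point, so
each resulting segment lies wholly inside one 1-year age class, one 1-year
period class and one duration band.  Segment intervals are half-open
[t0, t1); person-time is conserved exactly because segment lengths
telescope to exit - entry.

Censoring variants
------------------
``all_sites``
    Follow-up ends at the first cancer (any site), death or study end,
    whichever comes first; the event is attached to the final segment.
``site_specific``
    Follow-up runs to death or study end, ignoring the cancer date, so one
    person-time table serves every site-specific analysis; the cancer
    event is attached to the segment containing its date (an event exactly
    on a boundary belongs to the segment starting there).  This
    overestimates T1D person-time slightly; see
    :func:`overestimation_check`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS, DurationBands, POP_LEVEL, UNKNOWN_LEVEL

VARIANTS = ("all_sites", "site_specific")

_EPS = 1e-12


@dataclass
class PersonRecord:
    """One cohort member, all times in decimal years.

    ``exit`` is the end of observation ignoring cancer (the earlier of
    death and study end); the ``all_sites`` splitting variant truncates
    further at the cancer date.
    """

    id: object
    country: str
    sex: str
    birth: float
    entry: float
    exit: float
    dx: float = np.nan          # diabetes diagnosis; NaN for prevalent cases with no date
    cancer: float = np.nan      # first primary cancer
    site: object = None
    death: float = np.nan

    def validate(self):
        if self.exit < self.entry:
            raise ValueError(f"person {self.id}: exit {self.exit} < entry {self.entry}")
        if np.isfinite(self.dx) and self.dx - self.birth >= 40.0:
            raise ValueError(f"person {self.id}: diabetes diagnosed at age >= 40")
        for nm in ("cancer", "death"):
            v = getattr(self, nm)
            if np.isfinite(v) and v < self.entry - 1e-9:
                raise ValueError(f"person {self.id}: {nm} before entry")


@dataclass
class FollowUpSegment:
    """One maximal sub-interval of follow-up inside a single Lexis cell."""

    person_id: object
    country: str
    sex: str
    age: int
    period: int
    cohort: int
    duration: str
    pyrs: float
    event_site: object = None


def _persons_frame(persons) -> pd.DataFrame:
    if isinstance(persons, pd.DataFrame):
        return persons
    rows = []
    for p in persons:
        rows.append(dict(id=p.id, country=p.country, sex=p.sex, birth=p.birth,
                         dx=p.dx, cancer=p.cancer, site=p.site, death=p.death,
                         entry=p.entry, exit=p.exit))
    return pd.DataFrame(rows)


def split_cohort(persons, bands: DurationBands = DEFAULT_BANDS,
                 variant: str = "all_sites", max_age: float = 90.0) -> pd.DataFrame:
    """Split every person's follow-up into Lexis segments (vectorised).

    Parameters
    ----------
    persons : DataFrame or iterable of PersonRecord
        Decimal-year columns ``birth, dx, cancer, death, entry, exit`` plus
        ``id, country, sex, site``.
    bands : DurationBands
        Duration cut points (years since diagnosis).
    variant : {"all_sites", "site_specific"}
        Censoring variant, see module docstring.
    max_age : float
        Follow-up is administratively censored at this age.

    Returns
    -------
    DataFrame with one row per segment: id, country, sex, age, period,
    cohort, duration, dx_age_band, pyrs, event_site, variant.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    df = _persons_frame(persons)
    n = len(df)
    if n == 0:
        return _empty_segments(variant)

    b = df["birth"].to_numpy(dtype=float)
    dx = df.get("dx", pd.Series(np.nan, index=df.index)).to_numpy(dtype=float)
    t_c = df.get("cancer", pd.Series(np.nan, index=df.index)).to_numpy(dtype=float)
    entry = df["entry"].to_numpy(dtype=float)
    exit_ = df["exit"].to_numpy(dtype=float)
    if np.any(exit_ < entry - 1e-9):
        bad = df.loc[exit_ < entry - 1e-9, "id"].tolist()[:5]
        raise ValueError(f"exit before entry for person(s) {bad}")

    end = np.minimum(exit_, b + max_age)
    has_cancer = np.isfinite(t_c)
    if variant == "all_sites":
        end = np.where(has_cancer, np.minimum(end, t_c), end)
    eventful = has_cancer & (t_c <= end + 1e-12)

    cuts = np.asarray(bands.cuts)
    has_dx = np.isfinite(dx)
    dur_labels = np.asarray(bands.labels, dtype=object)

    sites = df.get("site", pd.Series([None] * n)).to_numpy(dtype=object)
    ids = df["id"].to_numpy(dtype=object)
    country = df["country"].to_numpy(dtype=object)
    sex = df["sex"].to_numpy(dtype=object)
    dx_age = np.where(has_dx, dx - b, np.nan)

    t = entry.copy()
    out = {k: [] for k in ("row", "t0", "t1")}
    max_iter = int(np.nanmax(end - entry)) * 3 + len(cuts) + 10 if n else 0
    for _ in range(max_iter):
        active = t < end - _EPS
        if not np.any(active):
            break
        ia = np.flatnonzero(active)
        ta = t[ia]
        next_age = b[ia] + np.floor(ta - b[ia] + _EPS) + 1.0
        next_per = np.floor(ta + _EPS) + 1.0
        t1 = np.minimum(next_age, next_per)
        hd = has_dx[ia]
        if np.any(hd):
            dur = ta[hd] - dx[ia][hd]
            idx = np.searchsorted(cuts, dur + _EPS, side="right")
            nxt = np.where(idx < len(cuts), dx[ia][hd] + cuts[np.minimum(idx, len(cuts) - 1)],
                           np.inf)
            t1_hd = t1[hd].copy()
            t1[hd] = np.minimum(t1_hd, nxt)
        t1 = np.minimum(t1, end[ia])
        t1 = np.maximum(t1, np.nextafter(ta, np.inf))
        out["row"].append(ia)
        out["t0"].append(ta)
        out["t1"].append(t1)
        t[ia] = t1

    if not out["row"]:
        return _empty_segments(variant)
    row = np.concatenate(out["row"])
    t0 = np.concatenate(out["t0"])
    t1 = np.concatenate(out["t1"])

    mid = 0.5 * (t0 + t1)
    age = np.floor(mid - b[row]).astype(int)
    period = np.floor(mid).astype(int)
    dur_level = np.full(row.shape, UNKNOWN_LEVEL, dtype=object)
    hd = has_dx[row]
    dur_level[hd] = dur_labels[
        np.clip(np.searchsorted(cuts, (t0 - dx[row])[hd] + _EPS, side="right") - 1,
                0, len(cuts) - 1)
    ]
    # event attachment: inside the half-open segment, or -- for an event
    # that terminates follow-up exactly at exit -- the final segment
    ev = eventful[row] & (
        ((t_c[row] >= t0) & (t_c[row] < t1))
        | ((np.abs(t_c[row] - end[row]) <= 1e-12) & (np.abs(t1 - end[row]) <= 1e-12))
    )
    event_site = np.where(ev, sites[row], None)

    seg = pd.DataFrame({
        "id": ids[row], "country": country[row], "sex": sex[row],
        "age": age, "period": period, "cohort": period - age,
        "duration": dur_level,
        "dx_age_band": _dx_age_band(dx_age[row]),
        "pyrs": t1 - t0, "event_site": event_site,
    })
    seg["variant"] = variant
    return seg


def _dx_age_band(dx_age: np.ndarray) -> np.ndarray:
    out = np.full(dx_age.shape, None, dtype=object)
    fin = np.isfinite(dx_age)
    out[fin & (dx_age < 30)] = "<30"
    out[fin & (dx_age >= 30) & (dx_age < 35)] = "30-35"
    out[fin & (dx_age >= 35)] = "35-40"
    return out


def _empty_segments(variant) -> pd.DataFrame:
    return pd.DataFrame({
        "id": pd.Series(dtype=object), "country": pd.Series(dtype=object),
        "sex": pd.Series(dtype=object), "age": pd.Series(dtype=int),
        "period": pd.Series(dtype=int), "cohort": pd.Series(dtype=int),
        "duration": pd.Series(dtype=object), "dx_age_band": pd.Series(dtype=object),
        "pyrs": pd.Series(dtype=float), "event_site": pd.Series(dtype=object),
        "variant": pd.Series(dtype=object),
    })


def split_follow_up(person: PersonRecord, bands: DurationBands = DEFAULT_BANDS,
                    variant: str = "all_sites", max_age: float = 90.0) -> list:
    """Split one person's follow-up; returns ``FollowUpSegment`` objects."""
    person.validate()
    seg = split_cohort([person], bands=bands, variant=variant, max_age=max_age)
    return [
        FollowUpSegment(person_id=r.id, country=r.country, sex=r.sex, age=r.age,
                        period=r.period, cohort=r.cohort, duration=r.duration,
                        pyrs=r.pyrs, event_site=r.event_site)
        for r in seg.itertuples(index=False)
    ]


def tabulate(segments: pd.DataFrame,
             by=("country", "sex", "age", "period", "duration"),
             site=None) -> pd.DataFrame:
    """Aggregate segments into an events/person-years (Lexis cell) table.

    Parameters
    ----------
    segments : DataFrame
        Output of :func:`split_cohort`; must come from a single censoring
        variant.
    by : sequence of str
        Stratification keys (cohort is recomputed as period - age).
    site : str or None
        Count events of this site only; ``None`` counts any first primary.

    Returns
    -------
    DataFrame with the stratum keys plus ``cohort``, ``events``, ``pyrs``;
    cells with zero person-years do not appear.  Total events and total
    person-years are conserved.
    """
    if "variant" in segments.columns and segments["variant"].nunique() > 1:
        raise ValueError("segments mix censoring variants; tabulate them separately")
    seg = segments.copy()
    if site is None:
        seg["events"] = seg["event_site"].notna().astype(int)
    else:
        seg["events"] = (seg["event_site"] == site).astype(int)
    out = (seg.groupby(list(by), sort=True, observed=True, dropna=False)[
        ["events", "pyrs"]].sum().reset_index())
    if {"age", "period"}.issubset(out.columns) and "cohort" not in by:
        out["cohort"] = out["period"] - out["age"]
    out = out[out["pyrs"] > 0].reset_index(drop=True)
    return out


def overestimation_check(persons, bands: DurationBands = DEFAULT_BANDS,
                         max_age: float = 90.0) -> float:
    """Relative person-time overestimation of the site-specific variant.

    Returns (Y_site_specific - Y_all_sites) / Y_all_sites for the cohort:
    the price of ignoring the cancer date when measuring follow-up.
    """
    df = _persons_frame(persons)
    if len(df) == 0:
        raise ValueError("empty cohort")
    y_all = split_cohort(df, bands=bands, variant="all_sites", max_age=max_age)["pyrs"].sum()
    y_ss = split_cohort(df, bands=bands, variant="site_specific", max_age=max_age)["pyrs"].sum()
    if y_all <= 0:
        raise ValueError("cohort has no follow-up time")
    return float((y_ss - y_all) / y_all)


class LexisSplitter:
    """Transformer wrapping :func:`split_cohort` / :func:`tabulate`.

    Follows the scikit-learn transformer protocol (stateless): ``fit``
    validates parameters, ``transform`` maps a person table to a segment
    table.  Compose with :class:`t1dapc.model.APCRateModel` in a pipeline.
    """

    def __init__(self, bands: DurationBands = DEFAULT_BANDS,
                 variant: str = "all_sites", max_age: float = 90.0):
        self.bands = bands
        self.variant = variant
        self.max_age = max_age

    def get_params(self, deep=True):
        return {"bands": self.bands, "variant": self.variant, "max_age": self.max_age}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not isinstance(self.bands, DurationBands):
            self.bands = DurationBands(tuple(self.bands))
        self.n_features_in_ = 0
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit()
        return split_cohort(X, bands=self.bands, variant=self.variant,
                            max_age=self.max_age)

    def fit_transform(self, X, y=None):
        return self.fit().transform(X)
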