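"""Design matrices for the smooth age-period-cohort rate model.

The incidence model is

    log(lambda_napcd) = f_n(a) + g_n(p) + h_n(c) + delta_d

with per-country natural cubic splines f_n, g_n, h_n in age ``a``, period
``p`` (date of follow-up) and cohort ``c = p - a`` (date of birth), and a
diabetes effect ``delta_d`` that is either a single type 1 diabetes
contrast or one contrast per duration band, with the general population as
reference.

Because a, p and c are linearly dependent, the three spline blocks carry
one redundant linear direction per country.  The default identifiability
constraint detrends the cohort basis (person-years-weighted zero mean and
zero slope), absorbing the drift into the period term; the alternative
``detrend-period`` constraint does the reverse.  ``delta_d`` is a
within-stratum contrast and is invariant to this choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS, DurationBands, POP_LEVEL, UNKNOWN_LEVEL
from .knots import DegenerateKnotsError, KnotVector, balanced_knots

TIMESCALES = ("age", "period", "cohort")
CONSTRAINTS = ("detrend-cohort", "detrend-period")
DX_AGE_BANDS = ("<30", "30-35", "35-40")


class RankDeficiencyError(ValueError):
    """Design is rank deficient beyond the known APC redundancy."""


def natural_spline_basis(x, all_knots) -> np.ndarray:
    """Natural (restricted) cubic spline basis including intercept and linear term.

    Uses the classical truncated-power construction: with knots
    xi_1 < ... < xi_K the basis is {1, x, N_3, ..., N_K} where
    ``N_{k+2} = d_k - d_{K-1}`` and
    ``d_k(x) = [(x - xi_k)_+^3 - (x - xi_K)_+^3] / (xi_K - xi_k)``.
    The function is linear beyond the boundary knots and has continuous
    second derivatives everywhere.  Evaluation is carried out on the
    affinely rescaled coordinate (x - xi_1)/(xi_K - xi_1) for conditioning;
    this reparametrises but does not change the spanned function space.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(all_knots, dtype=float)
    K = knots.size
    if K < 2:
        raise ValueError("need at least the two boundary knots")
    lo, hi = knots[0], knots[-1]
    if hi <= lo:
        raise ValueError("boundary knots must be distinct")
    t = (x - lo) / (hi - lo)
    xi = (knots - lo) / (hi - lo)
    cols = [np.ones_like(t), t]
    if K > 2:
        def d(k):
            return (np.clip(t - xi[k], 0, None) ** 3
                    - np.clip(t - xi[K - 1], 0, None) ** 3) / (xi[K - 1] - xi[k])
        dlast = d(K - 2)
        for k in range(K - 2):
            cols.append(d(k) - dlast)
    return np.column_stack(cols)


@dataclass
class ModelSpec:
    """Specification of one rate-model fit.

    Parameters
    ----------
    diabetes_term : {"binary", "duration"}
        Single T1D contrast, or one contrast per duration band.
    delta_scope : {"common", "per_country"}
        Whether delta is shared across countries or country-specific
        (the extended model of the heterogeneity test).
    n_knots : int
        Interior knots per timescale per country; halved while intervals
        would hold fewer than ``min_events_per_interval`` events.
    constraint : {"detrend-cohort", "detrend-period"}
        APC identifiability constraint (see module docstring).
    knot_events : {"pooled", "t1d", "pop"}
        Which events drive the case-balanced knot placement.
    dx_interaction : bool
        Add an interaction between delta and age-at-diagnosis bands
        (<30, 30-35, 35-40); requires a ``dx_age_band`` cell column.
    """

    diabetes_term: str = "binary"
    delta_scope: str = "common"
    n_knots: int = 5
    min_events_per_interval: int = 50
    constraint: str = "detrend-cohort"
    knot_events: str = "pooled"
    bands: DurationBands = field(default_factory=lambda: DEFAULT_BANDS)
    dx_interaction: bool = False

    def __post_init__(self):
        if self.diabetes_term not in ("binary", "duration"):
            raise ValueError(f"unknown diabetes_term {self.diabetes_term!r}")
        if self.delta_scope not in ("common", "per_country"):
            raise ValueError(f"unknown delta_scope {self.delta_scope!r}")
        if self.constraint not in CONSTRAINTS:
            raise ValueError(f"unknown constraint {self.constraint!r}")
        if self.knot_events not in ("pooled", "t1d", "pop"):
            raise ValueError(f"unknown knot_events {self.knot_events!r}")


@dataclass
class DesignInfo:
    """A realised design: matrix, column names and bookkeeping."""

    X: np.ndarray
    colnames: list
    delta_cols: dict          # delta label (or (country, label) / ("dx", band)) -> column index
    knots: dict               # (country, timescale) -> KnotVector or None
    constraint: str
    spec: ModelSpec
    dropped: list = field(default_factory=list)

    @property
    def ncol(self) -> int:
        return self.X.shape[1]


def _knot_values(cells: pd.DataFrame, timescale: str) -> np.ndarray:
    if timescale == "age":
        return cells["age"].to_numpy(dtype=float) + 0.5
    if timescale == "period":
        return cells["period"].to_numpy(dtype=float) + 0.5
    return cells["period"].to_numpy(dtype=float) - cells["age"].to_numpy(dtype=float)


def choose_knots(cells: pd.DataFrame, spec: ModelSpec) -> dict:
    """Case-balanced knots per (country, timescale), with sparse-data halving."""
    out = {}
    for country, sub in cells.groupby("country", sort=True):
        if spec.knot_events == "t1d":
            sub_ev = sub[sub["duration"] != POP_LEVEL]
        elif spec.knot_events == "pop":
            sub_ev = sub[sub["duration"] == POP_LEVEL]
        else:
            sub_ev = sub
        events = sub_ev["events"].to_numpy(dtype=float)
        total = events.sum()
        for ts in TIMESCALES:
            values = _knot_values(sub_ev, ts)
            interior = spec.n_knots
            while interior > 0 and total / (interior + 1) < spec.min_events_per_interval:
                interior //= 2
            kv = None
            while kv is None:
                try:
                    kv = balanced_knots(values, interior + 1, weights=events, timescale=ts)
                except DegenerateKnotsError:
                    if interior == 0:
                        break
                    interior //= 2
            out[(country, ts)] = kv
    return out


def _weighted_project_out(B: np.ndarray, Z: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Remove the weighted projection of each column of B onto span(Z)."""
    Zw = Z * w[:, None]
    beta = np.linalg.lstsq(Zw.T @ Z, Zw.T @ B, rcond=None)[0]
    return B - Z @ beta


def _delta_columns(cells: pd.DataFrame, spec: ModelSpec, countries) -> tuple:
    dur = cells["duration"].to_numpy(dtype=object)
    is_t1d = dur != POP_LEVEL
    cols, names, delta_cols = [], [], {}
    if spec.diabetes_term == "binary":
        levels = [("t1d", is_t1d)]
    else:
        if np.any(dur == UNKNOWN_LEVEL):
            raise ValueError(
                "duration model cannot include 'unknown'-duration person-time; "
                "drop those cells first"
            )
        levels = [(lab, dur == lab) for lab in spec.bands.labels]
    country_arr = cells["country"].to_numpy(dtype=object)
    for lab, mask in levels:
        if spec.delta_scope == "per_country":
            for n in countries:
                cols.append((mask & (country_arr == n)).astype(float))
                names.append(f"delta[{n}:{lab}]")
                delta_cols[(n, lab)] = len(names) - 1
        else:
            cols.append(mask.astype(float))
            names.append(f"delta[{lab}]")
            delta_cols[lab] = len(names) - 1
    if spec.dx_interaction:
        if "dx_age_band" not in cells.columns:
            raise ValueError("dx_interaction requires a 'dx_age_band' column")
        bands = cells["dx_age_band"].to_numpy(dtype=object)
        present = [b for b in DX_AGE_BANDS if np.any(is_t1d & (bands == b))]
        missing = [b for b in DX_AGE_BANDS if b not in present]
        if missing:
            raise ValueError(f"empty age-at-diagnosis band(s): {missing}")
        for b in DX_AGE_BANDS[1:]:  # first band is the reference
            cols.append((is_t1d & (bands == b)).astype(float))
            names.append(f"delta_x_dxage[{b}]")
            delta_cols[("dx", b)] = len(names) - 1
    return cols, names, delta_cols


def build_design(cells: pd.DataFrame, spec: ModelSpec, knots: dict | None = None) -> DesignInfo:
    """Assemble the APC + diabetes design matrix for a Lexis cell table.

    One row per cell; splines are evaluated at cell midpoints
    (a + 1/2, p + 1/2) and at c = p - a for cohort.  Basis columns that are
    constant over the data (degenerate timescales, e.g. a single stratum)
    are dropped.  Raises :class:`RankDeficiencyError` if the constrained
    design is still rank deficient.
    """
    required = {"country", "duration", "events", "pyrs", "age", "period"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cell table lacks columns: {sorted(missing)}")
    cells = cells.reset_index(drop=True)
    n = len(cells)
    if n == 0:
        raise ValueError("empty cell table")
    w = cells["pyrs"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("all cells must have positive person-years")
    countries = sorted(cells["country"].unique())
    if knots is None:
        knots = choose_knots(cells, spec)

    blocks, names = [], []
    country_arr = cells["country"].to_numpy(dtype=object)
    for ci, country in enumerate(countries):
        mask = country_arr == country
        wm = w * mask
        # country intercept
        blocks.append(mask.astype(float))
        names.append(f"icpt[{country}]")
        for ts in TIMESCALES:
            kv = knots.get((country, ts))
            if kv is None:
                continue
            vals = _knot_values(cells, ts)
            B = natural_spline_basis(vals, kv.all_knots)
            if spec.constraint == "detrend-cohort":
                detrended = "cohort"
            else:
                detrended = "period"
            if ts == "age":
                keep = B[:, 1:]                     # intercept held by the country dummy
            elif ts == detrended:
                if B.shape[1] <= 2:
                    continue                        # linear basis vanishes entirely
                Z = B[:, :2]                        # {1, linear}
                keep = _weighted_project_out(B[:, 2:], Z, wm)
            else:
                Z = B[:, :1]
                keep = _weighted_project_out(B[:, 1:], Z, wm)
            keep = keep * mask[:, None]
            for j in range(keep.shape[1]):
                blocks.append(keep[:, j])
                names.append(f"{ts}[{country}]:{j}")

    dcols, dnames, delta_cols = _delta_columns(cells, spec, countries)
    offset_delta = len(names)
    blocks.extend(dcols)
    names.extend(dnames)
    delta_cols = {k: v + offset_delta for k, v in delta_cols.items()}

    X = np.column_stack(blocks)
    # drop structural columns that are numerically constant-zero / constant,
    # and delta levels with no person-time at all (nothing to estimate)
    scale = np.max(np.abs(X), axis=0)
    span = X.max(axis=0) - X.min(axis=0)
    is_icpt = np.array([nm.startswith("icpt") for nm in names])
    is_delta = np.array([nm.startswith("delta") for nm in names])
    keep_mask = (is_icpt
                 | (is_delta & (scale > 0))
                 | (~is_icpt & ~is_delta
                    & (scale > 1e-10) & (span > 1e-10 * np.maximum(scale, 1.0))))
    dropped = [nm for nm, k in zip(names, keep_mask) if not k]
    if dropped:
        old_idx = np.flatnonzero(keep_mask)
        remap = {int(o): i for i, o in enumerate(old_idx)}
        delta_cols = {k: remap[v] for k, v in delta_cols.items() if v in remap}
        X = X[:, keep_mask]
        names = [nm for nm, k in zip(names, keep_mask) if k]

    colnorm = np.linalg.norm(X, axis=0)
    rank = np.linalg.matrix_rank(X / np.maximum(colnorm, 1e-300), tol=1e-8)
    if rank < X.shape[1]:
        raise RankDeficiencyError(
            f"design has rank {rank} < {X.shape[1]} columns after APC constraints"
        )
    return DesignInfo(X=X, colnames=names, delta_cols=delta_cols, knots=knots,
                      constraint=spec.constraint, spec=spec, dropped=dropped)
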