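"""Poisson rate model for type 1 diabetes versus general-population cancer incidence.

The model for the incidence rate in stratum (country n, age a, period p,
cohort c, diabetes duration d) is

    log(lambda_napcd) = f_n(a) + g_n(p) + h_n(c) + delta_d

fitted by Poisson regression with the events as outcome and log
person-years as offset; f, g, h are per-country natural cubic splines with
case-balanced knots (see :mod:`t1dapc.design`).  Because the model is a
proportional-hazards model with a smooth reference surface, exp(delta)
generalises the classical standardised incidence/mortality ratio, which
:func:`smr_oracle` computes from empirical rates as an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .bands import DEFAULT_BANDS, DurationBands, POP_LEVEL, UNKNOWN_LEVEL
from .design import (DesignInfo, ModelSpec, RankDeficiencyError, build_design,
                     choose_knots)

Z95 = stats.norm.ppf(0.975)  # 1.959964...


class NotConvergedError(RuntimeError):
    pass


@dataclass
class RateModelFit:
    """A fitted rate model: coefficients, covariance and fit statistics."""

    coef: pd.Series
    cov: np.ndarray
    deviance: float
    df_resid: int
    llf: float
    converged: bool
    design: DesignInfo
    separation: list = field(default_factory=list)

    @property
    def delta(self) -> pd.Series:
        """The diabetes-contrast coefficients, by label."""
        return pd.Series({k: self.coef.iloc[v]
                          for k, v in self.design.delta_cols.items()})

    def delta_se(self) -> pd.Series:
        return pd.Series({k: np.sqrt(self.cov[v, v])
                          for k, v in self.design.delta_cols.items()})

    def delta_contrast(self, a, b) -> tuple:
        """Estimate and SE of delta_a - delta_b (e.g. first vs last band)."""
        i, j = self.design.delta_cols[a], self.design.delta_cols[b]
        est = float(self.coef.iloc[i] - self.coef.iloc[j])
        var = self.cov[i, i] + self.cov[j, j] - 2 * self.cov[i, j]
        return est, float(np.sqrt(max(var, 0.0)))


@dataclass(frozen=True)
class HREstimate:
    """exp(delta) with its Wald 95% CI (log-scale SE)."""

    label: object
    hr: float
    lo95: float
    hi95: float
    se_log: float


def fit_poisson(design, events, person_years, tol: float = 1e-8,
                max_iter: int = 100) -> RateModelFit:
    """Maximum-likelihood Poisson fit with offset log(person-years).

    Fitting is iteratively reweighted least squares (via statsmodels GLM),
    converged when the relative deviance change drops below ``tol``.
    Strata with zero events stay in the likelihood; zero person-years are
    rejected (their offset would be -inf).  A diabetes-contrast level
    whose person-time carries no events is flagged in ``separation`` (its
    MLE diverges); the partial fit is still returned.
    """
    if isinstance(design, DesignInfo):
        X, names, info = design.X, design.colnames, design
    else:
        X = np.asarray(design, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
        info = DesignInfo(X=X, colnames=names, delta_cols={}, knots={},
                          constraint="none", spec=None)
    y = np.asarray(events, dtype=float)
    w = np.asarray(person_years, dtype=float)
    if np.any(w <= 0):
        raise ValueError("person-years must be strictly positive (offset is log Y)")
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(w))
    res = model.fit(maxiter=max_iter, tol=tol, tol_criterion="deviance")
    separation = []
    for key, col in info.delta_cols.items():
        exposed = X[:, col] != 0
        if exposed.any() and y[exposed].sum() == 0:
            separation.append(key)
    return RateModelFit(
        coef=pd.Series(res.params, index=names), cov=np.asarray(res.cov_params()),
        deviance=float(res.deviance), df_resid=int(res.df_resid),
        llf=float(res.llf), converged=bool(res.converged), design=info,
        separation=separation,
    )


def hr_table(fit: RateModelFit, spec: ModelSpec | None = None) -> pd.DataFrame:
    """HR = exp(delta) with Wald 95% CIs, one row per delta level in band order."""
    if not fit.converged:
        raise NotConvergedError("refusing HR table from a non-converged fit")
    spec = spec or fit.design.spec
    delta = fit.delta
    se = fit.delta_se()

    def sort_key(label):
        if isinstance(label, tuple):
            country, lab = label
        else:
            country, lab = "", label
        if spec is not None and spec.diabetes_term == "duration":
            order = {b: i for i, b in enumerate(spec.bands.labels)}
            return (country, order.get(lab, len(order)))
        return (country, str(lab))

    rows = []
    # a separated level (zero events) has a diverging SE; its CI limit
    # overflows to inf, which is the honest answer
    with np.errstate(over="ignore"):
        for label in sorted(delta.index, key=sort_key):
            d, s = float(delta[label]), float(se[label])
            rows.append({
                "label": (label if not isinstance(label, tuple)
                          else ":".join(map(str, label))),
                "hr": float(np.exp(d)),
                "lo95": float(np.exp(d - Z95 * s)),
                "hi95": float(np.exp(d + Z95 * s)),
                "se_log": s,
            })
    return pd.DataFrame(rows)


class APCRateModel:
    """Scikit-learn style estimator for the smooth APC + diabetes rate model.

    ``fit`` takes a Lexis cell table (columns country, sex is assumed
    pre-filtered, age, period, duration, events, pyrs) containing both
    general-population rows (duration == "pop") and T1D rows.  Fitted
    attributes carry a trailing underscore.

    Parameters mirror :class:`t1dapc.design.ModelSpec`.
    """

    def __init__(self, diabetes_term="binary", delta_scope="common", n_knots=5,
                 min_events_per_interval=50, constraint="detrend-cohort",
                 knot_events="pooled", bands=DEFAULT_BANDS, dx_interaction=False,
                 tol=1e-8, max_iter=100):
        self.diabetes_term = diabetes_term
        self.delta_scope = delta_scope
        self.n_knots = n_knots
        self.min_events_per_interval = min_events_per_interval
        self.constraint = constraint
        self.knot_events = knot_events
        self.bands = bands
        self.dx_interaction = dx_interaction
        self.tol = tol
        self.max_iter = max_iter

    # -- sklearn protocol ------------------------------------------------
    _param_names = ("diabetes_term", "delta_scope", "n_knots",
                    "min_events_per_interval", "constraint", "knot_events",
                    "bands", "dx_interaction", "tol", "max_iter")

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            diabetes_term=self.diabetes_term, delta_scope=self.delta_scope,
            n_knots=self.n_knots,
            min_events_per_interval=self.min_events_per_interval,
            constraint=self.constraint, knot_events=self.knot_events,
            bands=self.bands, dx_interaction=self.dx_interaction)

    @staticmethod
    def _prepare(cells: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
        cells = cells[cells["pyrs"] > 0].reset_index(drop=True)
        if spec.diabetes_term == "duration":
            # prevalent cases without a diagnosis date have unknown duration
            cells = cells[cells["duration"] != UNKNOWN_LEVEL].reset_index(drop=True)
        return cells

    def fit(self, X: pd.DataFrame, y=None, knots=None):
        spec = self._spec()
        cells = self._prepare(X, spec)
        if knots is None:
            knots = choose_knots(cells, spec)
        design = build_design(cells, spec, knots=knots)
        fit = fit_poisson(design, cells["events"], cells["pyrs"],
                          tol=self.tol, max_iter=self.max_iter)
        self.spec_ = spec
        self.cells_ = cells
        self.design_ = design
        self.fit_ = fit
        self.knots_ = design.knots
        self.coef_ = fit.coef
        self.cov_ = fit.cov
        self.deviance_ = fit.deviance
        self.llf_ = fit.llf
        self.converged_ = fit.converged
        self.separation_ = fit.separation
        self.n_features_in_ = design.ncol
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Expected events for a cell table (rate x person-years)."""
        design = build_design(self._prepare(X, self.spec_), self.spec_,
                              knots=self.knots_)
        eta = design.X @ self.coef_.to_numpy()
        return np.exp(eta) * self._prepare(X, self.spec_)["pyrs"].to_numpy()

    def hr_table(self) -> pd.DataFrame:
        return hr_table(self.fit_, self.spec_)

    def hr_estimates(self) -> list:
        tab = self.hr_table()
        return [HREstimate(r.label, r.hr, r.lo95, r.hi95, r.se_log)
                for r in tab.itertuples(index=False)]


# -- model comparison tests ----------------------------------------------

def _lr_test(fit0: RateModelFit, fit1: RateModelFit, df: int) -> dict:
    stat = max(0.0, 2.0 * (fit1.llf - fit0.llf))
    return {"statistic": float(stat), "df": int(df),
            "p": float(stats.chi2.sf(stat, df)) if df > 0 else 1.0}


def heterogeneity_test(cells: pd.DataFrame, diabetes_term="binary",
                       **model_kw) -> dict:
    """Likelihood-ratio test of per-country vs common diabetes HR.

    Fits the model with a single delta shared across countries and the
    extended model with one delta per country (same spline knots, so the
    models are nested), and compares twice the log-likelihood difference
    with chi-square on (countries - 1) x levels degrees of freedom.
    """
    t1d = cells[cells["duration"] != POP_LEVEL]
    n_countries = t1d.loc[t1d["events"] > 0, "country"].nunique()
    if n_countries < 2:
        raise ValueError("heterogeneity test needs >= 2 countries with T1D events")
    common = APCRateModel(diabetes_term=diabetes_term, delta_scope="common",
                          **model_kw).fit(cells)
    ext = APCRateModel(diabetes_term=diabetes_term, delta_scope="per_country",
                       **model_kw).fit(cells, knots=common.knots_)
    df = len(ext.design_.delta_cols) - len(common.design_.delta_cols)
    return _lr_test(common.fit_, ext.fit_, df)


def age_at_dx_interaction(cells: pd.DataFrame, diabetes_term="binary",
                          **model_kw) -> dict:
    """LR test of an age-at-diagnosis (<30, 30-35, 35-40) by HR interaction.

    Checks whether the diabetes contrast differs by age at diabetes
    diagnosis — a probe of the under-40 cohort definition.  The cell table
    must carry a ``dx_age_band`` column on T1D rows.
    """
    if "dx_age_band" not in cells.columns:
        raise ValueError("cells need a 'dx_age_band' column")
    base = APCRateModel(diabetes_term=diabetes_term, dx_interaction=False,
                        **model_kw).fit(cells)
    inter = APCRateModel(diabetes_term=diabetes_term, dx_interaction=True,
                         **model_kw).fit(cells, knots=base.knots_)
    df = len(inter.design_.delta_cols) - len(base.design_.delta_cols)
    return _lr_test(base.fit_, inter.fit_, df)


def eligibility(counts_by_sex: dict, site: str | None = None, min_cases: int = 200,
                overrides=("kidney",)) -> bool:
    """Should this site get a duration model?

    True iff every sex present has at least ``min_cases`` T1D cancer
    cases, or the site is in the override list (kidney by default, for its
    established association with type 2 diabetes).  Sex-specific sites
    pass a single-sex dict and are judged on that count alone.
    """
    if site is not None and site in overrides:
        return True
    if not counts_by_sex:
        return False
    return all(int(c) >= min_cases for c in counts_by_sex.values())


def smr_oracle(t1d_cells: pd.DataFrame, pop_cells: pd.DataFrame,
               strata=("country", "age", "period")) -> float:
    """Classical standardised incidence ratio from empirical rates.

    SMR = sum(observed T1D events) / sum(Y_t1d x empirical population
    rate), matched on the given strata.  Under the shared
    proportional-hazards assumption this is the empirical-rate analogue of
    exp(delta); it serves as an independent oracle for the smooth model.
    """
    strata = list(strata)
    pop = pop_cells.copy()
    pop["rate"] = pop["events"] / pop["pyrs"]
    merged = t1d_cells.merge(pop[strata + ["rate"]], on=strata, how="left",
                             validate="many_to_one")
    if merged["rate"].isna().any():
        raise ValueError("T1D strata missing from the population table")
    expected = float((merged["pyrs"] * merged["rate"]).sum())
    if expected <= 0:
        raise ZeroDivisionError("zero expected count")
    return float(merged["events"].sum() / expected)
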