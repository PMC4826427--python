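import numpy as np
import pandas as pd
import pytest

import t1dapc as t
from t1dapc.design import (ModelSpec, RankDeficiencyError, build_design,
                           natural_spline_basis)
from t1dapc.model import (NotConvergedError, Z95, age_at_dx_interaction,
                          eligibility, fit_poisson, heterogeneity_test,
                          hr_table, smr_oracle)
from t1dapc.pipeline import model_table


def single_stratum_cells(e1=30, y1=1000.0, e0=200, y0=20000.0):
    return pd.DataFrame({
        "country": ["X", "X"], "sex": ["M", "M"], "age": [50, 50],
        "period": [2000, 2000], "duration": ["pop", "0-1"],
        "events": [e0, e1], "pyrs": [y0, y1]})


class TestSplineBasis:
    def test_two_knots_degenerate_to_linear(self):
        x = np.linspace(0, 10, 7)
        B = natural_spline_basis(x, [0.0, 10.0])
        assert B.shape == (7, 2)
        assert np.allclose(B[:, 0], 1.0)
        assert np.allclose(np.diff(B[:, 1]), np.diff(B[:, 1])[0])

    def test_c2_continuity_across_interior_knot(self):
        knots = [0.0, 2.5, 6.0, 10.0]
        h = 1e-4
        for knot in knots[1:-1]:
            x = np.array([knot - 2 * h, knot - h, knot, knot + h, knot + 2 * h])
            B = natural_spline_basis(x, knots)
            d2 = (B[:-2] - 2 * B[1:-1] + B[2:]) / h**2
            # second difference just left vs just right of the knot
            assert np.allclose(d2[0], d2[2], atol=1e-3)

    def test_linear_beyond_boundary_knots(self):
        knots = [0.0, 3.0, 7.0, 10.0]
        x = np.array([10.5, 11.5, 12.5, 13.5])
        B = natural_spline_basis(x, knots)
        second_diff = B[:-2] - 2 * B[1:-1] + B[2:]
        assert np.allclose(second_diff, 0.0, atol=1e-9)


class TestBuildDesign:
    def test_zero_interior_knots_gives_linear_terms(self, small_fit_inputs):
        *_, tab = small_fit_inputs
        spec = ModelSpec(n_knots=0, min_events_per_interval=0)
        d = build_design(tab, spec)
        per_ts = [c for c in d.colnames if c.startswith("age[")]
        assert len(per_ts) == 2  # one linear age column per country
        assert all(kv is None or kv.interior == () for kv in d.knots.values())

    def test_population_rows_have_zero_delta_columns(self, small_fit_inputs):
        *_, tab = small_fit_inputs
        d = build_design(tab, ModelSpec())
        pop_rows = (tab["duration"] == "pop").to_numpy()
        j = d.delta_cols["t1d"]
        assert np.all(d.X[pop_rows, j] == 0)
        assert np.all(d.X[~pop_rows, j] == 1)

    def test_unknown_duration_rejected_in_duration_model(self):
        cells = single_stratum_cells()
        cells.loc[1, "duration"] = "unknown"
        with pytest.raises(ValueError, match="unknown"):
            build_design(cells, ModelSpec(diabetes_term="duration"))

    def test_redundant_extra_column_detected(self, small_fit_inputs):
        *_, tab = small_fit_inputs
        spec = ModelSpec()
        d = build_design(tab, spec)
        X = np.column_stack([d.X, d.X[:, -1]])  # duplicate a column
        from t1dapc.design import DesignInfo
        colnorm = np.linalg.norm(X, axis=0)
        assert np.linalg.matrix_rank(X / colnorm, tol=1e-8) < X.shape[1]


class TestPoissonFit:
    def test_identical_rates_give_hr_one(self):
        cells = single_stratum_cells(e1=20, y1=1000.0, e0=400, y0=20000.0)
        m = t.APCRateModel().fit(cells)
        assert m.hr_table()["hr"].iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_single_stratum_closed_form(self):
        m = t.APCRateModel().fit(single_stratum_cells())
        row = m.hr_table().iloc[0]
        assert row["hr"] == pytest.approx(3.0, abs=1e-8)
        se = np.sqrt(1 / 30 + 1 / 200)
        assert row["lo95"] == pytest.approx(3.0 * np.exp(-Z95 * se), abs=1e-6)
        assert row["hi95"] == pytest.approx(3.0 * np.exp(+Z95 * se), abs=1e-6)

    def test_recovers_true_hr_within_three_se(self, small_fit_inputs):
        *_, tab = small_fit_inputs
        m = t.APCRateModel().fit(tab)
        d = m.fit_.delta["t1d"]
        se = m.fit_.delta_se()["t1d"]
        assert abs(d - np.log(1.5)) < 3 * se

    def test_zero_person_years_rejected(self):
        cells = single_stratum_cells(y1=0.0)
        with pytest.raises(ValueError):
            fit_poisson(build_design(cells.assign(pyrs=[1.0, 1.0]), ModelSpec()),
                        cells["events"], cells["pyrs"])

    def test_separation_flagged_when_level_has_no_events(self):
        cells = single_stratum_cells(e1=0)
        m = t.APCRateModel().fit(cells)
        assert m.separation_ == ["t1d"]

    def test_deviance_not_increased_by_extra_knots(self, small_fit_inputs):
        *_, tab = small_fit_inputs
        dev = [t.APCRateModel(n_knots=k, min_events_per_interval=0).fit(tab).deviance_
               for k in (0, 2, 5)]
        assert dev[0] >= dev[1] - 1e-6 and dev[1] >= dev[2] - 1e-6

    def test_delta_invariant_to_apc_constraint(self, small_fit_inputs):
        *_, tab = small_fit_inputs
        m1 = t.APCRateModel(constraint="detrend-cohort").fit(tab)
        m2 = t.APCRateModel(constraint="detrend-period").fit(tab, knots=m1.knots_)
        assert abs(m1.fit_.delta["t1d"] - m2.fit_.delta["t1d"]) < 1e-6

    def test_hr_invariant_to_person_year_rescaling(self, small_fit_inputs):
        *_, tab = small_fit_inputs
        m1 = t.APCRateModel().fit(tab)
        m2 = t.APCRateModel().fit(tab.assign(pyrs=tab["pyrs"] * 137.0),
                                  knots=m1.knots_)
        assert m1.hr_table()["hr"].iloc[0] == pytest.approx(
            m2.hr_table()["hr"].iloc[0], rel=1e-8)


class TestHRTable:
    def test_wald_interval_formula(self):
        # delta=0, SE=0.1 -> HR 1.00, CI (exp(-1.96*0.1), exp(+1.96*0.1))
        from t1dapc.design import DesignInfo
        info = DesignInfo(X=np.eye(2), colnames=["icpt[X]", "delta[t1d]"],
                          delta_cols={"t1d": 1}, knots={}, constraint="none",
                          spec=ModelSpec())
        fit = t.RateModelFit(coef=pd.Series([0.0, 0.0], index=info.colnames),
                             cov=np.diag([0.0, 0.01]), deviance=0.0, df_resid=0,
                             llf=0.0, converged=True, design=info)
        row = hr_table(fit).iloc[0]
        assert row["hr"] == 1.0
        assert row["lo95"] == pytest.approx(np.exp(-Z95 * 0.1), abs=1e-12)
        assert row["hi95"] == pytest.approx(np.exp(Z95 * 0.1), abs=1e-12)

    def test_vanishing_se_collapses_interval(self):
        from t1dapc.design import DesignInfo
        info = DesignInfo(X=np.eye(2), colnames=["icpt[X]", "delta[t1d]"],
                          delta_cols={"t1d": 1}, knots={}, constraint="none",
                          spec=ModelSpec())
        fit = t.RateModelFit(coef=pd.Series([0.0, np.log(2)], index=info.colnames),
                             cov=np.zeros((2, 2)), deviance=0.0, df_resid=0,
                             llf=0.0, converged=True, design=info)
        row = hr_table(fit).iloc[0]
        assert row["hr"] == pytest.approx(2.0)
        assert row["lo95"] == pytest.approx(2.0) and row["hi95"] == pytest.approx(2.0)

    def test_duration_rows_in_band_order(self, small_fit_inputs):
        *_, tab = small_fit_inputs
        m = t.APCRateModel(diabetes_term="duration").fit(tab)
        labels = list(m.hr_table()["label"])
        expect = [b for b in t.DEFAULT_BANDS.labels if b in labels]
        assert labels == expect

    def test_nonconverged_fit_refused(self):
        from t1dapc.design import DesignInfo
        info = DesignInfo(X=np.eye(1), colnames=["delta[t1d]"],
                          delta_cols={"t1d": 0}, knots={}, constraint="none",
                          spec=ModelSpec())
        fit = t.RateModelFit(coef=pd.Series([0.0], index=info.colnames),
                             cov=np.eye(1), deviance=0.0, df_resid=0, llf=0.0,
                             converged=False, design=info)
        with pytest.raises(NotConvergedError):
            hr_table(fit)


class TestEligibility:
    @pytest.mark.parametrize("counts,site,expect", [
        ({"M": 250, "F": 210}, None, True),
        ({"M": 150, "F": 300}, "kidney", True),
        ({"M": 199, "F": 500}, None, False),
        ({"M": 200, "F": 200}, None, True),
        ({"F": 1723}, None, True),     # sex-specific site, single count
        ({"M": 159}, None, False),
    ])
    def test_min_case_rule_with_kidney_override(self, counts, site, expect):
        assert eligibility(counts, site=site) is expect


class TestSMROracle:
    def test_identical_rates_give_unity(self):
        cells = single_stratum_cells(e1=50, y1=1000.0, e0=1000, y0=20000.0)
        t1d = cells[cells["duration"] != "pop"]
        pop = cells[cells["duration"] == "pop"]
        assert smr_oracle(t1d, pop) == pytest.approx(1.0)

    def test_single_stratum_equals_saturated_hr(self):
        cells = single_stratum_cells()
        t1d = cells[cells["duration"] != "pop"]
        pop = cells[cells["duration"] == "pop"]
        smr = smr_oracle(t1d, pop)
        hr = t.APCRateModel().fit(cells).hr_table()["hr"].iloc[0]
        assert smr == pytest.approx(hr, abs=1e-8)

    def test_zero_expected_rejected(self):
        cells = single_stratum_cells(e0=0)
        with pytest.raises(ZeroDivisionError):
            smr_oracle(cells[cells["duration"] != "pop"],
                       cells[cells["duration"] == "pop"])

    def test_close_to_smooth_hr_on_simulated_data(self, small_fit_inputs):
        _, cells, pop, tab = small_fit_inputs
        from t1dapc.pipeline import pop_model_rows
        popm = pop_model_rows(pop)
        popm = popm[popm["sex"] == "M"]
        t1d = tab[tab["duration"] != "pop"]
        smr = smr_oracle(t1d, popm, strata=("country", "age", "period"))
        m = t.APCRateModel().fit(tab)
        se = m.fit_.delta_se()["t1d"]
        assert abs(np.log(smr) - m.fit_.delta["t1d"]) < 2 * se


class TestModelComparisons:
    def test_heterogeneity_requires_two_countries(self):
        with pytest.raises(ValueError):
            heterogeneity_test(single_stratum_cells())

    def test_homogeneous_data_large_p(self, small_fit_inputs):
        *_, tab = small_fit_inputs
        res = heterogeneity_test(tab)
        assert res["df"] == 1
        assert res["p"] > 0.001  # no simulated heterogeneity

    def test_detects_strong_country_heterogeneity(self, binary_effect):
        # one register simulated at HR 2.5, the other at 1.0
        cfg = t.desk_binary_config(seed=77, persons=20000)
        persons = []
        for country, hr in (("DK", 2.5), ("SE", 1.0)):
            c = t.SimConfig(**{**cfg.__dict__,
                               "study_windows": {country: (2000.0, 2010.0)},
                               "persons": 10000, "seed": 77 + hash(country) % 100})
            eff = [t.TrueEffect(site="carcinoma", sex="*", binary_multiplier=hr)]
            persons.append(t.simulate_t1d_cohort(c, eff))
        persons = pd.concat(persons, ignore_index=True)
        seg = t.split_cohort(persons, variant="all_sites")
        cells = t.tabulate(seg, by=("country", "sex", "age", "period", "duration"))
        pop = t.simulate_registry_tables(cfg)
        res = heterogeneity_test(model_table(pop, cells, sex="M"))
        assert res["p"] < 0.001

    def test_dx_age_interaction_null_and_errors(self, small_cohort):
        cfg, persons = small_cohort
        seg = t.split_cohort(persons, variant="all_sites")
        cells = t.tabulate(seg, by=("country", "sex", "age", "period",
                                    "duration", "dx_age_band"))
        pop = t.simulate_registry_tables(cfg)
        tab = model_table(pop, cells, sex="M")
        res = age_at_dx_interaction(tab)
        assert res["df"] == 2
        assert 0.0 <= res["p"] <= 1.0
        # single populated band -> named error
        only_young = tab[(tab["duration"] == "pop")
                         | (tab["dx_age_band"] == "<30")]
        with pytest.raises(ValueError, match="30-35"):
            age_at_dx_interaction(only_young)
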