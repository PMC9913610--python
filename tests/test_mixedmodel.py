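import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from recurve import legendre
from recurve import mixedmodel as mm
from recurve.mixedmodel import (REMLModel, ScalarEffect, fit_repeatability,
                                fit_rrm, genetic_trend, information_criteria,
                                relative_importance, trajectory_table)
from recurve.simulate import SimConfig, simulate_ra_dataset, simulate_rep_dataset


class TestInformationCriteria:
    @pytest.mark.parametrize("logl,k,aic", [(-183253, 4, 366514),
                                            (-173721, 11, 347464)])
    def test_aic_from_printed_model_comparison(self, logl, k, aic):
        assert information_criteria(logl, k)["AIC"] == pytest.approx(aic)

    def test_bic_uses_record_count(self):
        out = information_criteria(-183253, 4, 57018)
        assert round(out["BIC"]) == 366550

    def test_zero_case(self):
        out = information_criteria(0.0, 0, 1)
        assert out["AIC"] == 0.0 and out["BIC"] == 0.0


class TestRelativeImportance:
    def test_component_shares(self):
        comp = {"animal": 91.82, "pe": 105.55, "hys": 27.38, "residual": 79.52}
        ri = relative_importance(comp)
        assert round(ri["animal"], 2) == 30.18
        assert round(ri["pe"], 2) == 34.69
        assert round(ri["hys"], 2) == 9.00
        assert round(ri["residual"], 2) == 26.13
        assert sum(ri.values()) == pytest.approx(100.0)

    def test_single_component(self):
        assert relative_importance({"a": 3.0})["a"] == pytest.approx(100.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            relative_importance({"a": 0.0})


def _balanced_oneway(n_groups=60, m=5, sa2=4.0, se2=2.0, seed=1):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, np.sqrt(sa2), n_groups)
    y = np.repeat(a, m) + rng.normal(0, np.sqrt(se2), n_groups * m) + 10.0
    groups = np.repeat(np.arange(n_groups), m)
    return y, groups, n_groups, m


class TestEngineOracles:
    def test_balanced_oneway_equals_anova(self):
        """On a balanced one-way layout REML equals the ANOVA estimators."""
        y, groups, q, m = _balanced_oneway()
        Z = sparse.csr_matrix((np.ones(len(y)), (np.arange(len(y)), groups)),
                              shape=(len(y), q))
        model = REMLModel(y, np.ones((len(y), 1)), [ScalarEffect("g", Z)])
        th, res = model.fit()
        gm = y.reshape(q, m).mean(axis=1)
        msb = m * np.sum((gm - y.mean()) ** 2) / (q - 1)
        msw = np.sum((y.reshape(q, m) - gm[:, None]) ** 2) / (q * (m - 1))
        assert th.resid[0] == pytest.approx(msw, abs=1e-6)
        assert th.scalars["g"] == pytest.approx((msb - msw) / m, abs=1e-6)

    def test_scalar_and_onecoef_regression_paths_agree(self, small_rep_dataset):
        """A repeatability animal effect is the order-0 random regression:
        the two engine code paths must give the same restricted logL."""
        from recurve.pedigree import (a_inverse_sparse, a_logdet,
                                      inbreeding_meuwissen_luo)
        ped, table, _ = small_rep_dataset
        table = table[table["cow"].isin(table["cow"].unique()[:120])]
        F = inbreeding_meuwissen_luo(ped)
        ainv = a_inverse_sparse(ped, F)
        ld = a_logdet(ped, F)
        y = table["re"].to_numpy(float)
        X = np.ones((len(y), 1))
        Zp, _ = mm._indicator(table["cow"])
        phi0 = np.full((len(y), 1), legendre.legendre_basis(0.0, 0)[0, 0])

        scalar = REMLModel(y, X, [
            ScalarEffect("animal", mm._animal_indicator(table["cow"], ped), ainv, ld),
            ScalarEffect("pe", Zp)])
        th1, r1 = scalar.fit()
        kron = REMLModel(y, X, [
            mm.RegressionEffect("animal", mm._regression_Z(table["cow"], phi0, ped, 1),
                                ainv, ld, 1),
            ScalarEffect("pe", Zp)])
        th2, r2 = kron.fit()
        assert r1.logL == pytest.approx(r2.logL, abs=1e-4)
        # Ka is expressed on the normalized-polynomial scale: Ka00 = 2 sigma_a2
        assert th2.kas["animal"][0, 0] == pytest.approx(2.0 * th1.scalars["animal"],
                                                        rel=5e-3)

    def test_logl_never_decreases(self, small_ra_dataset):
        ped, table, _ = small_ra_dataset
        res = fit_rrm(table, ped, r=1)
        diffs = np.diff(res.history)
        assert (diffs > -1e-6 * np.abs(res.history[0])).all()


class TestRepeatabilityFit:
    def test_components_and_h2(self, small_rep_dataset):
        ped, table, truth = small_rep_dataset
        res = fit_repeatability(table, ped)
        assert res.converged
        assert res.n_params == 4
        total = res.components["total"]
        assert total == pytest.approx(np.var(table["re"], ddof=1), rel=0.35)
        assert 0.0 < res.meta["h2"] < 1.0
        assert res.meta["repeatability"] >= res.meta["h2"]
        # EGVs exist for every pedigree animal, parents included
        assert len(res.solutions["egv"]) == len(ped)

    def test_blup_regression_of_truth_on_egv_near_one(self, small_rep_dataset):
        """BLUP property: cov(true BV, EGV)/var(EGV) ~ 1."""
        ped, table, truth = small_rep_dataset
        res = fit_repeatability(table, ped)
        egv = res.solutions["egv"]
        tv = truth.breeding_values.reindex(egv.index)
        recorded = egv.index.isin(table["cow"].unique())
        slope = np.polyfit(egv[recorded], tv[recorded], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.25)

    def test_flat_variance_design_still_fits(self):
        """Single record per unrelated cow: only the total is identifiable;
        the fit must still complete with the total near var(y)."""
        rng = np.random.default_rng(5)
        n = 300
        frame = pd.DataFrame({"animal": [f"c{i}" for i in range(n)],
                              "sire": "0", "dam": "0"})
        from recurve.pedigree import sort_pedigree
        ped = sort_pedigree(frame)
        table = pd.DataFrame({"cow": ped.ids, "cn": 1,
                              "re": rng.normal(70, 15, n),
                              "hys": [f"h{i % 12}" for i in range(n)],
                              "fc_class": 0, "res_class": 1})
        res = fit_repeatability(table, ped)
        assert res.components["total"] == pytest.approx(np.var(table["re"], ddof=1),
                                                        rel=0.2)


class TestRrmFit:
    @pytest.mark.parametrize("r,k", [(1, 11), (2, 14)])
    def test_parameter_counts(self, r, k, small_ra_dataset):
        ped, table, _ = small_ra_dataset
        res = fit_rrm(table, ped, r=r, max_iter=3)
        assert res.n_params == k

    def test_trajectory_table_shape_and_bounds(self, small_ra_dataset):
        ped, table, _ = small_ra_dataset
        res = fit_rrm(table, ped, r=2)
        traj = trajectory_table(res)
        assert list(traj["cn"]) == list(range(1, 10))
        assert ((traj["h2"] >= 0) & (traj["h2"] <= 1)).all()
        assert (traj["total_var"] > traj["genetic_var"]).all()
        # generated totals fall steeply from calving 1 to later parities
        assert traj["total_var"].iloc[0] > 2 * traj["total_var"].iloc[4]

    def test_invalid_order_rejected(self, small_ra_dataset):
        ped, table, _ = small_ra_dataset
        with pytest.raises(ValueError):
            fit_rrm(table, ped, r=3)

    def test_ka_positive_definite(self, small_ra_dataset):
        ped, table, _ = small_ra_dataset
        res = fit_rrm(table, ped, r=2)
        assert np.linalg.eigvalsh(res.components["Ka"]).min() > 0


def test_bootstrap_hook_returns_component_rows(small_rep_dataset):
    from recurve.mixedmodel import bootstrap_components
    ped, table, _ = small_rep_dataset
    sub = table[table["cow"].isin(table["cow"].unique()[:60])]
    bc = bootstrap_components(sub, ped, n_boot=2, seed=3)
    assert list(bc.columns) == ["animal", "pe", "hys", "residual"]
    assert len(bc) == 2 and (bc >= 0).all().all()


class TestGeneticTrend:
    def test_flat_egv_flat_trend(self):
        egv = pd.Series(0.0, index=list("abcd"))
        years = pd.Series([2000, 2000, 2001, 2001], index=list("abcd"))
        trend = genetic_trend(egv, years)
        assert (trend["mean_egv"] == 0).all()

    def test_single_year_one_point(self):
        egv = pd.Series([1.0, 2.0], index=["a", "b"])
        years = pd.Series([2005, 2005], index=["a", "b"])
        assert len(genetic_trend(egv, years)) == 1

    def test_directional_selection_gives_positive_slope(self, rng):
        years = np.repeat(np.arange(1990, 2000), 30)
        ids = [f"a{i}" for i in range(len(years))]
        egv = pd.Series(0.5 * (years - 1990) + rng.normal(0, 1, len(years)),
                        index=ids)
        trend = genetic_trend(egv, pd.Series(years, index=ids))
        slope = np.polyfit(trend["year"], trend["mean_egv"], 1)[0]
        assert slope > 0.3
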