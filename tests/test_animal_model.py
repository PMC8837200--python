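import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from stressg import pedigree as pg
from stressg import simulate as sim
from stressg import animal_model as am


def half_sib_data(n_sires=30, n_off=12, va=1.0, ve=2.0, seed=7):
    rng = np.random.default_rng(seed)
    recs = [pg.PedigreeRecord(f"S{s}", sex="M") for s in range(n_sires)]
    recs += [pg.PedigreeRecord(f"O{s}_{k}", sire=f"S{s}", generation=1)
             for s in range(n_sires) for k in range(n_off)]
    ped = pg.validate_and_sort(recs)
    A = pg.additive_relationship_matrix(ped)
    u = rng.normal(0, np.sqrt(va / 4), n_sires)
    rows = []
    for s in range(n_sires):
        for k in range(n_off):
            rows.append({
                "id": f"O{s}_{k}", "trait": "t",
                "value": 5.0 + u[s] + rng.normal(0, np.sqrt(ve + 0.75 * va)),
            })
    df = pd.DataFrame(rows)
    df["trial"] = np.arange(len(df)).astype(str)
    return ped, A, df


def simple_spec(extra_random=(), fixed=("1",)):
    random = [am.RandomTerm("animal", "id", None, am.Unstructured(1), pedigree=True)]
    random += list(extra_random)
    return am.ModelSpec(["t"], random, am.ResidualSpec("trial", am.Unstructured(1)),
                        {"t": list(fixed)})


class TestDesignBuilder:
    def test_intercept_categorical_and_interaction(self):
        df = pd.DataFrame({
            "sex": ["M", "F", "M", "F"],
            "mass": [1.0, 2.0, 3.0, 4.0],
        })
        X, names = am.build_design(df, ["sex", "mass", "sex:mass"])
        assert names == ["(Intercept)", "sex[M]", "mass", "sex[M]:mass"]
        assert np.allclose(X[:, 1], [1, 0, 1, 0])
        assert np.allclose(X[:, 3], [1.0, 0.0, 3.0, 0.0])

    def test_aliased_columns_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]})
        X, names = am.build_design(df, ["a", "b"])
        with pytest.warns(UserWarning, match="aliased"):
            X2, names2 = am._drop_aliased(X, names)
        assert X2.shape[1] == 2  # intercept + one of the pair


class TestREMLCore:
    def test_anova_equivalence_on_balanced_half_sib(self):
        ped, A, df = half_sib_data()
        fit = am.reml_fit(simple_spec(), df, A, tol=1e-12)
        ymat = df["value"].to_numpy().reshape(30, 12)
        ms_s = 12 * np.var(ymat.mean(axis=1), ddof=1)
        ms_w = np.mean(np.var(ymat, axis=1, ddof=1))
        va_anova = 4 * (ms_s - ms_w) / 12
        assert fit.varcomp.scalar("animal") == pytest.approx(va_anova, rel=1e-6)

    def test_one_way_repeatability_anova_equivalence(self):
        # repeated measures, no pedigree: REML equals expected-mean-squares
        rng = np.random.default_rng(3)
        n_id, n_rep = 80, 4
        u = rng.normal(0, 1.0, n_id)
        rows = []
        for i in range(n_id):
            for r in range(n_rep):
                rows.append({"id": f"i{i}", "trait": "t",
                             "value": u[i] + rng.normal(0, 1.5)})
        df = pd.DataFrame(rows)
        df["trial"] = np.arange(len(df)).astype(str)
        spec = am.ModelSpec(["t"], [am.RandomTerm("pe", "id", None, am.Unstructured(1))],
                            am.ResidualSpec("trial", am.Unstructured(1)), {"t": ["1"]})
        fit = am.reml_fit(spec, df, None, tol=1e-12)
        y = df["value"].to_numpy().reshape(n_id, n_rep)
        ms_b = n_rep * np.var(y.mean(axis=1), ddof=1)
        ms_w = np.mean(np.var(y, axis=1, ddof=1))
        assert fit.varcomp.scalar("pe") == pytest.approx((ms_b - ms_w) / n_rep, rel=1e-6)
        assert fit.varcomp.scalar("residual") == pytest.approx(ms_w, rel=1e-6)

    def test_boundary_when_no_genetic_variance(self):
        ped, A, df = half_sib_data(va=0.0, ve=2.0, seed=11)
        fit = am.reml_fit(simple_spec(), df, A)
        vp = df["value"].var()
        assert fit.varcomp.scalar("animal") < 0.02 * vp

    def test_loglik_invariant_to_row_order_and_relabelling(self):
        ped, A, df = half_sib_data(n_sires=10, n_off=6)
        fit = am.reml_fit(simple_spec(), df, A, tol=1e-11)
        shuffled = df.sample(frac=1.0, random_state=5).reset_index(drop=True)
        fit2 = am.reml_fit(simple_spec(), shuffled, A, tol=1e-11)
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-5)
        # relabel individuals consistently
        ren = {i: f"x_{i}" for i in df["id"].unique()}
        df3 = df.assign(id=df["id"].map(ren))
        A3 = pg.RelationshipMatrix([ren.get(i, i) for i in A.individuals], A.values)
        fit3 = am.reml_fit(simple_spec(), df3, A3, tol=1e-11)
        assert fit3.loglik == pytest.approx(fit.loglik, abs=1e-5)

    def test_constrained_fit_never_beats_unconstrained(self, default_study, default_A):
        ph = default_study.phenotypes
        sub = ph[ph["trait"].isin(["relative_area", "time_in_middle"])]
        common = dict(trait_col="trait", value_col="value")
        res = am.ResidualSpec("trial", am.Unstructured(2))
        fixed = {t: ["sex"] for t in ("relative_area", "time_in_middle")}
        full = am.ModelSpec(["relative_area", "time_in_middle"],
                            [am.RandomTerm("animal", "id", "trait", am.Unstructured(2),
                                           pedigree=True)], res, fixed, **common)
        diag = am.ModelSpec(["relative_area", "time_in_middle"],
                            [am.RandomTerm("animal", "id", "trait", am.Diagonal(2),
                                           pedigree=True)], res, fixed, **common)
        f_full = am.reml_fit(full, sub, default_A)
        f_diag = am.reml_fit(diag, sub, default_A)
        assert f_diag.loglik <= f_full.loglik + 1e-6


class TestLRT:
    def test_boundary_mixture_at_zero_is_half(self):
        res = am.lrt(-100.0, -100.0, df=1, boundary=True)
        assert res.p_value == 0.5
        assert res.statistic == 0.0

    def test_boundary_mixture_large_statistic(self):
        # halved chi2_1 tail
        res = am.lrt(-90.0, -100.005, boundary=True)
        assert res.statistic == pytest.approx(20.01)
        assert res.p_value == pytest.approx(0.5 * chi2.sf(20.01, 1))
        assert res.p_value < 0.001

    def test_df15_statistic(self):
        res = am.lrt(-54.47, -100.0, df=15)
        assert res.statistic == pytest.approx(91.06)
        assert res.p_value == pytest.approx(chi2.sf(91.06, 15))
        assert res.p_value < 0.001

    def test_negative_statistic_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="higher restricted likelihood"):
            res = am.lrt(-100.5, -100.0, df=1)
        assert res.statistic == 0.0

    def test_df_from_parameter_counts(self):
        ped, A, df = half_sib_data(n_sires=8, n_off=4)
        f1 = am.reml_fit(simple_spec(), df, A)
        spec0 = am.ModelSpec(["t"], [], am.ResidualSpec("trial", am.Unstructured(1)),
                             {"t": ["1"]})
        f0 = am.reml_fit(spec0, df, None)
        res = am.lrt(f1, f0)
        assert res.df == 1


class TestDerivedRatios:
    def _vc(self, va, vpe, vgroup, vr):
        return am.VarianceComponents({
            "animal": (["t"], np.array([[va]])),
            "pe": (["t"], np.array([[vpe]])),
            "group": (["t"], np.array([[vgroup]])),
            "residual": (["t"], np.array([[vr]])),
        })

    def test_h2_and_repeatability_from_components(self):
        vc = self._vc(0.34, 0.18, 0.08, 1.13)
        assert am.heritability(vc, "t") == pytest.approx(0.34 / 1.73)
        assert am.repeatability(vc, "t") == pytest.approx(0.52 / 1.73)

    def test_va_equal_total_gives_one(self):
        assert am.heritability(self._vc(2.0, 0.0, 0.0, 0.0), "t") == 1.0

    def test_repeatability_at_least_h2(self):
        for args in [(0.3, 0.2, 0.1, 1.0), (0.0, 0.5, 0.1, 1.0), (1.0, 0.0, 0.2, 0.4)]:
            vc = self._vc(*args)
            assert am.repeatability(vc, "t") >= am.heritability(vc, "t")

    def test_zero_total_variance_raises(self):
        with pytest.raises(ValueError):
            am.heritability(self._vc(0, 0, 0, 0), "t")

    def test_delta_method_se_positive(self):
        ped, A, df = half_sib_data()
        fit = am.reml_fit(simple_spec(), df, A)
        h2, se = am.heritability(fit, "t")
        assert 0 < h2 < 1
        assert se > 0


class TestWald:
    def test_balanced_single_observation_matches_ols(self):
        rng = np.random.default_rng(9)
        n = 120
        sex = np.repeat(["M", "F"], n // 2)
        y = 1.0 + 0.8 * (sex == "M") + rng.normal(0, 1.0, n)
        df = pd.DataFrame({"id": [f"i{k}" for k in range(n)], "trait": "t",
                           "value": y, "sex": sex})
        df["trial"] = df["id"]
        spec = am.ModelSpec(["t"], [], am.ResidualSpec("trial", am.Unstructured(1)),
                            {"t": ["sex"]})
        fit = am.reml_fit(spec, df, None, tol=1e-12)
        F, ddf, p = am.wald_fixed(fit, "t:sex[M]")
        # equals squared t from OLS with REML (n-p) residual variance
        import statsmodels.api as sm
        X = sm.add_constant((sex == "M").astype(float))
        ols = sm.OLS(y, X).fit()
        assert F == pytest.approx(float(ols.tvalues[1] ** 2), rel=1e-6)
        assert ddf == pytest.approx(n - 2, rel=0.05)

    def test_null_effect_gives_moderate_f(self):
        rng = np.random.default_rng(4)
        ped, A, df = half_sib_data(n_sires=12, n_off=6, seed=13)
        df["cov"] = rng.normal(size=len(df))
        fit = am.reml_fit(simple_spec(fixed=("cov",)), df, A)
        F, ddf, p = am.wald_fixed(fit, "t:cov")
        assert p > 0.01  # a random covariate should rarely be highly significant


class TestBLUP:
    def test_blups_shrink_to_zero_when_va_at_boundary(self):
        # a fit whose genetic variance collapsed to the boundary predicts
        # (essentially) zero genetic deviations for everyone
        ped, A, df = half_sib_data(va=0.0, ve=2.0, seed=11)
        fit = am.reml_fit(simple_spec(), df, A)
        assert fit.varcomp.scalar("animal") < 0.02 * df["value"].var()
        assert np.abs(am.blup(fit).to_numpy()).max() < 0.1

    def test_blup_calibration_slope(self):
        # regression of true breeding values on BLUPs has slope ~ 1
        ped = pg.simulate_pedigree(2, 15, 3, 5, seed=31)
        A = pg.additive_relationship_matrix(ped)
        bv = sim.sample_breeding_values(ped, np.array([[1.0]]), seed=31)
        rng = np.random.default_rng(31)
        ids = [r.id for r in ped if r.generation > 0]
        rows = []
        for i in ids:
            for rep in range(3):
                rows.append({"id": i, "trait": "t",
                             "value": float(bv.loc[i, 0]) + rng.normal(0, 1.0)})
        df = pd.DataFrame(rows)
        df["trial"] = np.arange(len(df)).astype(str)
        fit = am.reml_fit(simple_spec(), df, A)
        pred = am.blup(fit)
        truth = bv.loc[pred.index, 0].to_numpy()
        est = pred.to_numpy()[:, 0]
        slope = np.polyfit(est, truth, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.25)
        assert est.var() < truth.var()  # shrinkage

    def test_unphenotyped_relative_receives_information(self):
        ped, A, df = half_sib_data(n_sires=10, n_off=6, seed=2)
        fit = am.reml_fit(simple_spec(), df, A)
        pred = am.blup(fit, A=A)
        sires = [f"S{s}" for s in range(10)]
        assert set(sires) <= set(pred.index)
        assert np.abs(pred.loc[sires].to_numpy()).max() > 0


class TestGxESequence:
    @pytest.fixture(scope="class")
    def gxe_study(self):
        study = sim.generate_study(cortisol_gxe=sim.CortisolGxEModel(), seed=501)
        A = pg.additive_relationship_matrix(study.pedigree)
        cort = study.phenotypes.query("trait=='ln_cortisol'")
        return am.gxe_model_sequence(cort, A), study

    def test_all_models_converge_and_nest(self, gxe_study):
        out, _ = gxe_study
        fits = out["fits"]
        assert all(f.converged for f in fits.values())
        # nested likelihoods are ordered
        assert fits["no_genetics"].loglik <= fits["common_genetics"].loglik + 1e-6
        assert fits["common_genetics"].loglik <= fits["context_variances"].loglik + 1e-6
        assert fits["context_variances"].loglik <= fits["free_correlation"].loglik + 1e-6

    def test_genetic_variance_detected(self, gxe_study):
        out, _ = gxe_study
        assert out["lrt_va"].statistic > 0
        assert out["lrt_va"].boundary

    def test_context_variances_in_plausible_range(self, gxe_study):
        out, _ = gxe_study
        truth = sim.CortisolGxEModel()
        assert out["Va"]["cortisol_1"] == pytest.approx(truth.Va1, abs=0.08)
        assert out["Va"]["cortisol_3"] == pytest.approx(truth.Va3, abs=0.08)

    def test_duplicate_context_observation_rejected(self, gxe_study):
        _, study = gxe_study
        cort = study.phenotypes.query("trait=='ln_cortisol'")
        dup = pd.concat([cort, cort.iloc[[0]]], ignore_index=True)
        A = pg.additive_relationship_matrix(study.pedigree)
        with pytest.raises(ValueError, match="more than one observation"):
            am.gxe_model_sequence(dup, A)


class TestModelSpecIO:
    def test_yaml_round_trip(self, tmp_path):
        spec = am.ModelSpec(
            ["a", "b"],
            [am.RandomTerm("animal", "id", "trait", am.Unstructured(2), pedigree=True),
             am.RandomTerm("group", "grp", None, am.Unstructured(1))],
            am.ResidualSpec("trial", am.BlockDiagonal(2, [[0], [1]])),
            {"a": ["sex"], "b": ["sex", "age_z"]}, standardize=True,
        )
        p = tmp_path / "spec.yaml"
        spec.to_yaml(p)
        back = am.ModelSpec.from_yaml(p)
        assert back.traits == spec.traits
        assert back.standardize is True
        assert back.random[0].pedigree and back.random[0].axis_col == "trait"
        assert isinstance(back.residual.structure, am.BlockDiagonal)
        assert back.fixed == spec.fixed


class TestSimulateRefit:
    def test_simulated_response_has_model_scale(self):
        ped, A, df = half_sib_data()
        fit = am.reml_fit(simple_spec(), df, A)
        y = am.simulate_response(fit, seed=3)
        assert y.shape == (len(df),)
        assert y.var() == pytest.approx(df["value"].var(), rel=0.3)

    def test_refit_recovers_similar_components(self):
        ped, A, df = half_sib_data(n_sires=40, n_off=10)
        fit = am.reml_fit(simple_spec(), df, A)
        re = am.refit(fit, am.simulate_response(fit, seed=8))
        assert re.varcomp.scalar("residual") == pytest.approx(
            fit.varcomp.scalar("residual"), rel=0.3
        )
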