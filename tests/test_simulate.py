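import numpy as np
import pandas as pd
import pytest

from stressg import defaults
from stressg import pedigree as pg
from stressg import simulate as sim


class TestBreedingValues:
    def test_zero_G_gives_zero_deviations(self, textbook_pedigree):
        bv = sim.sample_breeding_values(textbook_pedigree, np.zeros((2, 2)), seed=1)
        assert np.all(bv.to_numpy() == 0.0)

    def test_founder_variance_matches_G(self):
        ped = pg.validate_and_sort([pg.PedigreeRecord(f"f{i}") for i in range(5000)])
        bv = sim.sample_breeding_values(ped, np.array([[1.0]]), seed=2)
        assert bv.to_numpy().var() == pytest.approx(1.0, abs=0.06)

    def test_half_sib_family_mean_covariance_is_quarter_va(self):
        # classical identity: var of sire-family means ~ Va/4 for half sibs
        n_sires, n_off, va = 400, 8, 2.0
        recs = [pg.PedigreeRecord(f"s{i}", sex="M") for i in range(n_sires)]
        recs += [pg.PedigreeRecord(f"o{i}_{k}", sire=f"s{i}")
                 for i in range(n_sires) for k in range(n_off)]
        ped = pg.validate_and_sort(recs)
        bv = sim.sample_breeding_values(ped, np.array([[va]]), seed=3)
        off = bv.loc[[f"o{i}_{k}" for i in range(n_sires) for k in range(n_off)]]
        means = off.to_numpy().reshape(n_sires, n_off).mean(axis=1)
        # var(family mean) = Va/4 + (3/4 Va)/n_off
        expected = va / 4 + 0.75 * va / n_off
        assert means.var(ddof=1) == pytest.approx(expected, rel=0.15)

    def test_stacked_covariance_equals_A_kron_G(self):
        recs = [pg.PedigreeRecord("a"), pg.PedigreeRecord("b"),
                pg.PedigreeRecord("c", "a", "b"), pg.PedigreeRecord("d", "a", "b"),
                pg.PedigreeRecord("e", "c", "d")]
        ped = pg.validate_and_sort(recs)
        A = pg.additive_relationship_matrix(ped).values
        G = np.array([[1.0, 0.5], [0.5, 2.0]])
        draws = np.stack([
            sim.sample_breeding_values(ped, G, seed=s).to_numpy().ravel()
            for s in range(4000)
        ])
        emp = np.cov(draws.T)
        # stacking is individual-major: cov = A (x) G under (ind, trait) order
        target = np.kron(A, G)
        assert np.max(np.abs(emp - target)) < 0.25

    def test_dimension_mismatch_raises(self, textbook_pedigree):
        with pytest.raises(ValueError):
            sim.sample_breeding_values(textbook_pedigree, np.array([[1.0, 0.0]]), seed=0)


class TestAssignGroups:
    def _frame(self, n, n_fam=10):
        return pd.DataFrame({
            "id": [f"i{k}" for k in range(n)],
            "sex": ["M", "F"] * (n // 2) + ["M"] * (n % 2),
            "family": [f"fam{k % n_fam}" for k in range(n)],
        })

    def test_forty_fish_two_groups_of_twenty(self):
        groups = sim.assign_groups(self._frame(40), seed=0)
        sizes = groups.value_counts()
        assert sorted(sizes) == [20, 20]

    def test_seventeen_fish_single_group(self):
        groups = sim.assign_groups(self._frame(17), seed=0)
        assert groups.nunique() == 1
        assert len(groups) == 17

    def test_sex_balance_within_one(self):
        df = self._frame(72)
        groups = sim.assign_groups(df, seed=1)
        merged = df.set_index("id").join(groups)
        for _, g in merged.groupby("group"):
            counts = g["sex"].value_counts()
            assert abs(counts.get("M", 0) - counts.get("F", 0)) <= 1

    def test_families_dispersed(self):
        # 600 fish in 40 full-sib families of 15: no group may hold most of one
        df = pd.DataFrame({
            "id": [f"i{k}" for k in range(600)],
            "sex": ["M", "F"] * 300,
            "family": [f"fam{k // 15}" for k in range(600)],
        })
        groups = sim.assign_groups(df, seed=2)
        merged = df.set_index("id").join(groups)
        for _, g in merged.groupby("family"):
            top = g["group"].value_counts().iloc[0]
            assert top <= 0.5 * len(g)

    def test_infeasible_sizes_raise(self):
        with pytest.raises(ValueError):
            sim.assign_groups(self._frame(10), seed=0)   # below minimum
        with pytest.raises(ValueError):
            sim.assign_groups(self._frame(21), seed=0)   # cannot split 16-20


class TestCovariates:
    def _trials(self):
        rows = []
        for k in range(18):
            rows.append((f"i{k}", "g0", "oft", 1))
            rows.append((f"i{k}", "g0", "oft", 2))
        return pd.DataFrame(rows, columns=["id", "group", "assay", "repeat"])

    def test_order_is_exact_permutation_within_group_repeat(self):
        cov = sim.simulate_covariates(self._trials(), seed=4)
        for _, g in cov.groupby(["assay", "repeat"]):
            assert sorted(g["order"]) == list(range(1, 19))

    def test_scaled_covariates_are_standardised(self):
        cov = sim.simulate_covariates(self._trials(), seed=4)
        for col in ("temperature_z", "time_z", "age_z"):
            assert cov[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert cov[col].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_bit_identical_under_seed(self):
        a = sim.simulate_covariates(self._trials(), seed=9)
        b = sim.simulate_covariates(self._trials(), seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestPhenotypes:
    def test_zero_variances_give_constant_traits(self):
        ped = pg.simulate_pedigree(1, 2, 4, 5, seed=0)
        q = 2
        model = sim.TraitModel(
            ["relative_area", "ln_cortisol"],
            np.zeros((q, q)), np.zeros((q, q)), np.zeros((q, q)), np.zeros((q, q)),
            means={"relative_area": 3.0, "ln_cortisol": 8.0},
        )
        bv = sim.sample_breeding_values(ped, model.G, seed=1)
        off = ped.to_frame().query("generation==1")
        groups = sim.assign_groups(
            pd.DataFrame({"id": off["id"], "sex": off["sex"], "family": off["dam"]}),
            seed=1,
        )
        ph = sim.simulate_phenotypes(ped, bv, groups, model, seed=1)
        for t, mu in [("relative_area", 3.0), ("ln_cortisol", 8.0)]:
            assert np.allclose(ph.loc[ph.trait == t, "value"], mu)

    def test_cortisol_context_means_follow_gxe_model(self, default_study):
        ph = default_study.phenotypes
        c1 = ph.query("trait=='ln_cortisol' and context==1")["value"].mean()
        c3 = ph.query("trait=='ln_cortisol' and context==3")["value"].mean()
        # context-3 mean sits ~0.45 below context 1 (8.47 - 8.02)
        assert c1 - c3 == pytest.approx(0.45, abs=0.12)

    def test_phenotypic_variance_close_to_component_sum(self, default_study):
        ph = default_study.phenotypes
        fr = ph.query("trait=='sqrt_freezings'")["value"]
        vp = defaults.UNIVARIATE_COMPONENTS["sqrt_freezings"]
        total = sum(vp.values())
        assert fr.var() == pytest.approx(total, rel=0.25)

    def test_validate_phenotypes(self, default_study):
        sim.validate_phenotypes(default_study.phenotypes, default_study.pedigree)
        bad = default_study.phenotypes.copy()
        bad.loc[0, "id"] = "not_in_pedigree"
        with pytest.raises(ValueError):
            sim.validate_phenotypes(bad, default_study.pedigree)

    def test_raw_scale_emitter(self, default_study):
        raw = sim.to_raw_scale(default_study.phenotypes)
        em = raw.query("trait=='emergence_s'")["value"]
        assert np.all(em > 0) and np.all(em <= 900.0)
        fz = raw.query("trait=='freezings'")["value"]
        assert np.all(fz == np.round(fz)) and np.all(fz >= 0)
        assert np.all(raw.query("trait=='cortisol_ng_hr'")["value"] > 0)


class TestStudy:
    def test_generate_study_reproducible(self):
        a = sim.generate_study(n_sires=4, seed=55)
        b = sim.generate_study(n_sires=4, seed=55)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        assert a.pedigree.ids == b.pedigree.ids

    def test_design_counts(self, default_study):
        ph = default_study.phenotypes
        oft = ph.query("assay=='oft'").groupby("id")["repeat"].max()
        assert oft.between(2, 4).all()
        groups = default_study.groups
        sizes = groups.value_counts()
        assert sizes.between(16, 20).all()
        cort = ph.query("trait=='ln_cortisol'")
        assert set(cort["context"].unique()) == {1, 3}
        per_fish = cort.groupby(["id", "context"]).size()
        assert (per_fish == 1).all()

    def test_study_writes_files(self, tmp_path, default_study):
        default_study.write(tmp_path / "study")
        assert (tmp_path / "study" / "pedigree.csv").exists()
        assert (tmp_path / "study" / "phenotypes.csv").exists()
        assert (tmp_path / "study" / "truth.yaml").exists()

    def test_gxe_study_realises_context_specific_variances(self):
        study = sim.generate_study(cortisol_gxe=sim.CortisolGxEModel(), seed=77)
        ph = study.phenotypes.query("trait=='ln_cortisol'")
        v1 = ph.query("context==1")["value"].var()
        v3 = ph.query("context==3")["value"].var()
        m = sim.CortisolGxEModel()
        assert v1 == pytest.approx(m.Va1 + m.Vgroup1 + m.Vr1 + 0.02, rel=0.35)
        assert v3 == pytest.approx(m.Va3 + m.Vgroup3 + m.Vr3 + 0.02, rel=0.35)
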