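import warnings

import numpy as np
import pandas as pd
import pytest

from herdclust.clustering import Partition
from herdclust.simulate import (
    FertilitySimConfig,
    GeneticSimConfig,
    simulate_fertility,
    simulate_pedigree,
    simulate_test_days,
)
from herdclust.traits import (
    fit_model1,
    fit_model2,
    lsmeans,
    scs_transform,
    year_season,
)


class TestScsTransform:
    @pytest.mark.parametrize(
        "scc,scs", [(100_000, 3.0), (400_000, 5.0), (50_000, 2.0), (200_000, 4.0)]
    )
    def test_reference_points(self, scc, scs):
        assert scs_transform(scc) == pytest.approx(scs)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            scs_transform(0)
        with pytest.raises(ValueError):
            scs_transform(np.array([100_000.0, -5.0]))


class TestYearSeason:
    @pytest.mark.parametrize(
        "date,season",
        [
            ("2017-12-15", "Dec-Feb"),
            ("2018-03-01", "Mar-May"),
            ("2018-02-28", "Dec-Feb"),
            ("2018-07-04", "Jun-Aug"),
            ("2018-09-01", "Sep-Nov"),
        ],
    )
    def test_four_season_levels(self, date, season):
        assert year_season(date) == season

    def test_december_belongs_to_following_winter(self):
        assert year_season("2017-12-15", with_year=True) == "2018:Dec-Feb"
        assert year_season("2018-01-15", with_year=True) == "2018:Dec-Feb"
        assert year_season("2018-11-30", with_year=True) == "2018:Sep-Nov"


@pytest.fixture(scope="module")
def testday_fit():
    cfg = GeneticSimConfig(
        seed=5, n_sires=10, daughters_per_sire=20, n_herds=12,
        cluster_env_sd=2.0, herd_env_sd=0.3,
    )
    ped, bv = simulate_pedigree(cfg)
    rec, part, truth = simulate_test_days(ped, bv, cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tfit = fit_model1(rec, part, "milk")
    return cfg, rec, part, truth, tfit


class TestModel1:
    def test_planted_cluster_contrasts_recovered_within_2se(self, testday_fit):
        cfg, rec, part, truth, tfit = testday_fit
        # true HC contrast = difference of mean cluster-month environments
        cme = pd.DataFrame(
            [(cl, eff) for (cl, _), eff in truth["cluster_month_effects"].items()],
            columns=["cl", "eff"],
        ).groupby("cl")["eff"].mean()
        lsm = lsmeans(tfit, "hc")
        est = lsm.table["estimate"]
        for a, b in [("HC1", "HC2"), ("HC1", "HC3"), ("HC2", "HC4")]:
            ia, ib = int(a[2]) - 1, int(b[2]) - 1
            true_diff = cme[ia] - cme[ib]
            got_diff = est[a] - est[b]
            se = np.sqrt(lsm.table["se"][a] ** 2 + lsm.table["se"][b] ** 2)
            assert abs(got_diff - true_diff) < 3 * se + 0.5

    def test_variance_components_positive_and_plausible(self, testday_fit):
        cfg, _, _, _, tfit = testday_fit
        v = tfit.fit.variances
        assert v["animal"] > 0 and v["residual"] > 0
        # iid animal effect absorbs sigma_a2 + sigma_pe2 = 5; the residual
        # also carries the within-cluster share of the cluster-month
        # environment that the HC fixed effect cannot explain
        assert 2.0 < v["animal"] < 9.0
        assert 3.0 < v["residual"] < 12.0

    def test_letters_consistent_with_pairwise_pvalues(self, testday_fit):
        *_, tfit = testday_fit
        lsm = lsmeans(tfit, "hc")
        letters = lsm.table["letters"]
        for a in letters.index:
            for b in letters.index:
                if a >= b:
                    continue
                shared = set(letters[a]) & set(letters[b])
                if lsm.pairwise.loc[a, b] < lsm.alpha:
                    assert not shared  # significantly different -> no shared letter
                else:
                    assert shared  # not different -> must share a letter


class TestModel2:
    @pytest.fixture(scope="class")
    def fertility(self):
        return simulate_fertility(FertilitySimConfig(seed=9, n_cows=800))

    def test_planted_cfi_shift_recovered(self, fertility):
        records, part, _ = fertility
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tfit = fit_model2(records, part, "CFI")
        lsm = lsmeans(tfit, "hc").table["estimate"]
        # planted shifts (0, 20, -5, 5) days relative to cluster 1
        assert lsm["HC2"] - lsm["HC1"] == pytest.approx(20, abs=6)
        assert lsm["HC3"] - lsm["HC1"] == pytest.approx(-5, abs=6)

    def test_sire_variance_recovered_in_order_of_magnitude(self, fertility):
        records, part, truth = fertility
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tfit = fit_model2(records, part, "CFI")
        # planted sire SD 5 -> variance 25; loose simulation CI
        assert 5 < tfit.fit.variances["sire"] < 90

    def test_single_record_sires_are_shrunken_not_dropped(self, fertility):
        records, part, _ = fertility
        records = records.copy()
        lone = records.iloc[[0]].copy()
        lone["service_sire"] = "SS_once"
        records = pd.concat([records, lone], ignore_index=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tfit = fit_model2(records, part, "CFI")
        assert "SS_once" in tfit.fit.u["sire"].index
        # heavy shrinkage toward zero for one observation
        assert abs(tfit.fit.u["sire"]["SS_once"]) < 15

    def test_sfi_logit_fit_orders_clusters(self, fertility):
        records, part, _ = fertility
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tfit = fit_model2(records, part, "SFI")
        lsm = lsmeans(tfit, "hc").table
        # planted logit shifts (0, -0.5, +0.3, -0.8)
        assert lsm["estimate"]["HC3"] > lsm["estimate"]["HC4"]
        assert (lsm["response"] > 0).all() and (lsm["response"] < 1).all()

    def test_complete_separation_detected(self, fertility):
        records, part, _ = fertility
        records = records.copy()
        cluster_of = dict(zip(part.herd_ids, part.labels))
        in_c0 = records["herd"].map(cluster_of) == 0
        records.loc[in_c0, "SFI"] = 0  # a herd cluster where nothing succeeds
        with pytest.warns(UserWarning, match="separation"):
            tfit = fit_model2(records, part, "SFI")
        assert "HC1" in tfit.separation

    def test_unknown_trait_rejected(self, fertility):
        records, part, _ = fertility
        with pytest.raises(ValueError):
            fit_model2(records, part, "milk")


class TestLsmeans:
    def _fit(self, df, trait="y", factors_data=None):
        part = Partition(sorted(df["herd"].unique()), np.zeros(df["herd"].nunique(), int))
        return df, part

    def test_balanced_design_lsm_equals_cell_means(self, rng):
        # balanced two-factor layout with one record per cell and no noise
        levels_hc = ["h1", "h2"]
        rows = []
        for rep in range(30):
            for hc_i, herd in enumerate(levels_hc):
                for breed in ("DSN", "HF"):
                    rows.append(
                        {
                            "animal": f"a{rep}{herd}{breed}",
                            "herd": herd,
                            "breed": breed,
                            "lactation": 1,
                            "insem_month": 1,
                            "semen": "frozen",
                            "service_sire": "s1",
                            "insem_age": 30.0,
                            "CFI": 60.0 + 10 * hc_i + 4 * (breed == "HF"),
                        }
                    )
        df = pd.DataFrame(rows)
        part = Partition(levels_hc, [0, 1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tfit = fit_model2(df, part, "CFI")
        lsm = lsmeans(tfit, "hc").table["estimate"]
        cell = df.groupby(df["herd"])["CFI"].mean()
        assert lsm["HC1"] == pytest.approx(cell["h1"], abs=1e-4)
        assert lsm["HC2"] == pytest.approx(cell["h2"], abs=1e-4)

    def test_unbalanced_two_factor_toy_matches_reference_grid_formula(self):
        # unbalanced counts; LSM must equal X_ref @ beta, not the raw mean
        rows = []
        vals = {("h1", "DSN"): [10.0, 12.0, 11.0], ("h1", "HF"): [20.0],
                ("h2", "DSN"): [15.0], ("h2", "HF"): [25.0, 27.0]}
        i = 0
        for (herd, breed), ys in vals.items():
            for y in ys:
                rows.append({"animal": f"a{i}", "herd": herd, "breed": breed,
                             "lactation": 1, "insem_month": 1, "semen": "frozen",
                             "service_sire": "s1", "insem_age": 30.0, "CFI": y})
                i += 1
        df = pd.DataFrame(rows)
        part = Partition(["h1", "h2"], [0, 1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tfit = fit_model2(df, part, "CFI")
        beta = tfit.fit.beta
        lsm = lsmeans(tfit, "hc").table["estimate"]
        # reference grid averages the breed effect with weight 1/2
        expect_h1 = beta["(Intercept)"] + 0.5 * beta["breed[HF]"] \
            + beta.get("insem_age", 0.0) * df["insem_age"].mean()
        assert lsm["HC1"] == pytest.approx(expect_h1, abs=1e-6)
        diff = lsm["HC2"] - lsm["HC1"]
        assert diff == pytest.approx(beta["hc[HC2]"], abs=1e-6)
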