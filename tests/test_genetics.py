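import warnings

import numpy as np
import pandas as pd
import pytest

from herdclust.clustering import Partition
from herdclust.genetics import (
    PedigreeTable,
    VarianceComponents,
    a_inverse,
    build_cg,
    em_reml,
    inbreeding,
    legendre_dim,
    solve_mme,
)
from herdclust.simulate import (
    GeneticSimConfig,
    simulate_pedigree,
    simulate_test_days,
)

from oracles import tabular_A


class TestLegendre:
    def test_closed_forms_at_special_points(self):
        lo, hi = 5.0, 365.0
        mid = (lo + hi) / 2
        assert np.allclose(legendre_dim(mid, window=(lo, hi)), [1, 0, -0.5, 0])
        assert np.allclose(legendre_dim(hi, window=(lo, hi)), [1, 1, 1, 1])
        assert np.allclose(legendre_dim(lo, window=(lo, hi)), [1, -1, 1, -1])

    def test_out_of_window_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            v = legendre_dim(400.0, window=(5.0, 365.0))
        assert np.allclose(v, [1, 1, 1, 1])


class TestPedigree:
    def test_topological_sort_and_implicit_founders(self):
        t = pd.DataFrame(
            {"animal": ["kid", "dam1"], "sire": ["sire1", np.nan], "dam": ["dam1", np.nan]}
        )
        ped = PedigreeTable(t)
        order = ped.animals
        assert order.index("kid") > order.index("dam1")
        assert "sire1" in order  # parent-only animal added as founder

    def test_cycle_detected(self):
        t = pd.DataFrame(
            {"animal": ["a", "b"], "sire": ["b", "a"], "dam": [np.nan, np.nan]}
        )
        with pytest.raises(ValueError, match="cycle"):
            PedigreeTable(t)


class TestAInverse:
    def test_founders_only_is_identity(self):
        ped = PedigreeTable(
            pd.DataFrame({"animal": list("abc"), "sire": np.nan, "dam": np.nan})
        )
        assert np.allclose(a_inverse(ped).toarray(), np.eye(3))

    def test_trio_matches_dense_inverse_of_tabular_a(self):
        ped = PedigreeTable(
            pd.DataFrame(
                {
                    "animal": ["s", "d", "o"],
                    "sire": [np.nan, np.nan, "s"],
                    "dam": [np.nan, np.nan, "d"],
                }
            )
        )
        A = tabular_A(ped.table)
        assert np.allclose(A, [[1, 0, 0.5], [0, 1, 0.5], [0.5, 0.5, 1]])
        assert np.allclose(a_inverse(ped).toarray(), np.linalg.inv(A), atol=1e-10)

    def test_full_sib_mating_inbreeding(self):
        ped = PedigreeTable(
            pd.DataFrame(
                {
                    "animal": ["s", "d", "x", "y", "z"],
                    "sire": [np.nan, np.nan, "s", "s", "x"],
                    "dam": [np.nan, np.nan, "d", "d", "y"],
                }
            )
        )
        F = inbreeding(ped)
        assert F[ped.animals.index("z")] == pytest.approx(0.25)
        A = tabular_A(ped.table)
        assert A[ped.animals.index("z"), ped.animals.index("z")] == pytest.approx(1.25)
        assert np.allclose(a_inverse(ped).toarray() @ A, np.eye(5), atol=1e-10)

    def test_random_pedigrees_inverse_of_tabular_a(self, rng):
        for _ in range(5):
            n_f, n_o = 6, 20
            animals = [f"f{i}" for i in range(n_f)]
            rows = [{"animal": a, "sire": np.nan, "dam": np.nan} for a in animals]
            for j in range(n_o):
                s, d = rng.choice(len(animals), 2, replace=False)
                rows.append(
                    {"animal": f"o{j}", "sire": animals[s], "dam": animals[d]}
                )
                animals.append(f"o{j}")
            ped = PedigreeTable(pd.DataFrame(rows))
            A = tabular_A(ped.table)
            assert np.allclose(
                a_inverse(ped).toarray() @ A, np.eye(len(animals)), atol=1e-8
            )


class TestBuildCG:
    def records(self):
        return pd.DataFrame(
            {
                "herd": ["h1", "h1", "h1", "h2", "h2", "h2"],
                "test_date": ["2018-05-03"] * 6,
                "animal": list("abcdef"),
            }
        )

    def test_same_cluster_same_day_merges_two_herds(self):
        part = Partition(["h1", "h2"], [0, 0])
        htd = build_cg(self.records(), part, "HTD")
        hctd = build_cg(self.records(), part, "HCTD")
        assert htd.n_groups_raw == 2
        assert hctd.n_groups_raw == 1

    def test_scheme_coarsening_on_simulated_data(self):
        cfg = GeneticSimConfig(seed=2, n_sires=8, daughters_per_sire=12, n_herds=16)
        ped, bv = simulate_pedigree(cfg)
        rec, part, _ = simulate_test_days(ped, bv, cfg)
        counts = {}
        occ = {}
        for scheme in ("HTD", "HCTD", "HTM", "HCTM"):
            cg = build_cg(rec, part, scheme, min_size=3, policy="keep")
            counts[scheme] = cg.n_groups_raw
            occ[scheme] = cg.occupancy().mean()
        assert counts["HCTD"] <= counts["HTD"]
        assert counts["HCTM"] <= counts["HTM"]
        assert occ["HCTD"] > occ["HTD"]

    def test_drop_policy_removes_underfilled_groups(self):
        part = Partition(["h1", "h2"], [0, 1])
        rec = self.records().iloc[[0, 1, 2, 3]]  # h2 has a single record
        cg = build_cg(rec, part, "HTD", min_size=3, policy="drop")
        assert len(cg.dropped) == 1
        assert cg.n_groups == 1 and cg.n_groups_raw == 2

    def test_merge_policy_pools_adjacent_groups(self):
        rec = pd.DataFrame(
            {
                "herd": ["h1"] * 5,
                "test_date": ["2018-01-10", "2018-01-10", "2018-02-10",
                              "2018-03-10", "2018-03-10"],
                "animal": list("abcde"),
            }
        )
        cg = build_cg(rec, None, "HTD", min_size=3, policy="merge")
        assert len(cg.dropped) == 0
        assert cg.occupancy().min() >= 2  # tail group joins its neighbour
        assert cg.n_groups < cg.n_groups_raw

    def test_cluster_scheme_without_partition_fails(self):
        with pytest.raises(ValueError, match="partition"):
            build_cg(self.records(), None, "HCTD")


@pytest.fixture(scope="module")
def small_evaluation():
    cfg = GeneticSimConfig(
        seed=4, n_sires=10, daughters_per_sire=20, n_herds=10,
        cluster_env_sd=1.5, herd_env_sd=0.5, records_per_cow=4,
    )
    ped, bv = simulate_pedigree(cfg)
    rec, part, truth = simulate_test_days(ped, bv, cfg)
    vc = VarianceComponents(cfg.sigma_a2, cfg.sigma_pe2, cfg.sigma_e2)
    cg = build_cg(rec, part, "HTD", min_size=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = solve_mme(rec, cg, ped, vc)
    return cfg, ped, bv, rec, part, cg, vc, sol


class TestSolveMme:
    def test_unrelated_single_records_shrink_by_heritability(self):
        # closed form: with unrelated animals, one record each and only an
        # intercept, EBV_i = h2 * (y_i - GLS mean)
        n = 8
        ped = PedigreeTable(
            pd.DataFrame({"animal": [f"a{i}" for i in range(n)],
                          "sire": np.nan, "dam": np.nan})
        )
        y = np.arange(n, dtype=float)
        rec = pd.DataFrame(
            {
                "animal": [f"a{i}" for i in range(n)],
                "herd": "h1",
                "breed": "DSN",
                "test_date": "2018-06-01",
                "calving_date": "2018-01-01",
                "lactation": 1,
                "dim": 150.0,
                "calving_age": 30.0,
                "milk": y,
            }
        )
        part = Partition(["h1"], [0])
        cg = build_cg(rec, part, "HTD", min_size=3)
        vc = VarianceComponents(2.0, 1.0, 5.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = solve_mme(rec, cg, ped, vc)
        h2 = vc.h2
        expected = h2 * (y - y.mean())
        assert np.allclose(sol.ebv.to_numpy(), expected, atol=1e-8)

    def test_pure_fixed_phenotypes_give_zero_ebvs(self, small_evaluation):
        cfg, ped, bv, rec, part, cg, vc, _ = small_evaluation
        rec0 = rec.copy()
        # phenotype = deterministic function of fixed effects only
        rec0["milk"] = 10.0 + 2.0 * (rec0["breed"] == "HF") + 0.5 * rec0["lactation"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = solve_mme(rec0, build_cg(rec0, part, "HTD", min_size=3), ped, vc)
        assert np.max(np.abs(sol.ebv.to_numpy())) < 1e-6

    def test_ebv_accuracy_matches_reported_reliability(self, small_evaluation):
        cfg, ped, bv, rec, part, cg, vc, sol = small_evaluation
        cows = [a for a in ped.animals if str(a).startswith("C")]
        corr = np.corrcoef(sol.ebv[cows], bv[cows])[0, 1]
        expected_acc = np.sqrt(sol.reliability[cows].mean())
        assert abs(corr - expected_acc) < 0.12

    def test_reliabilities_in_unit_interval(self, small_evaluation):
        *_, sol = small_evaluation
        assert (sol.reliability >= 0).all() and (sol.reliability < 1).all()

    def test_ebvs_invariant_to_record_order_and_cg_relabeling(self, small_evaluation):
        cfg, ped, bv, rec, part, cg, vc, sol = small_evaluation
        rec2 = rec.sample(frac=1.0, random_state=7).reset_index(drop=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol2 = solve_mme(rec2, build_cg(rec2, part, "HTD", min_size=3), ped, vc)
        assert np.allclose(sol.ebv.to_numpy(), sol2.ebv[sol.ebv.index].to_numpy(),
                           atol=1e-6)

    def test_singleton_clusters_make_hctd_identical_to_htd(self, small_evaluation):
        cfg, ped, bv, rec, part, cg, vc, sol = small_evaluation
        singleton = Partition(part.herd_ids, np.arange(part.n))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol_hctd = solve_mme(
                rec, build_cg(rec, singleton, "HCTD", min_size=3), ped, vc
            )
        assert np.allclose(sol.ebv.to_numpy(), sol_hctd.ebv.to_numpy(), atol=1e-8)
        assert np.allclose(
            sol.reliability.to_numpy(), sol_hctd.reliability.to_numpy(), atol=1e-8
        )


class TestEmReml:
    def test_likelihood_history_nondecreasing(self, small_evaluation):
        cfg, ped, bv, rec, part, cg, vc, _ = small_evaluation
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est, hist = em_reml(rec, cg, ped, tol=1e-3, max_iter=25)
        assert np.all(np.diff(hist) >= -1e-6)
        assert 0 < est.h2 < 1 and 0 < est.repeatability < 1

    def test_zero_additive_variance_reaches_floor(self):
        cfg = GeneticSimConfig(
            seed=8, n_sires=6, daughters_per_sire=15, n_herds=6, sigma_a2=0.0,
            records_per_cow=4,
        )
        ped, bv = simulate_pedigree(cfg)
        assert np.allclose(bv, 0.0)
        rec, part, _ = simulate_test_days(ped, bv, cfg)
        cg = build_cg(rec, part, "HTD", min_size=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est, hist = em_reml(rec, cg, ped, tol=1e-4, max_iter=60)
        assert est.h2 < 0.1
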