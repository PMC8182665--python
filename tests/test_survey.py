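import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herdclust.survey import (
    DegenerateVariableError,
    TypedSurvey,
    UndefinedDistanceError,
    VariableSpec,
    edit_variables,
    gower_matrix,
    read_survey,
    write_variable_specs,
    z_transform,
)

from conftest import random_mixed_survey
from oracles import naive_gower


class TestZTransform:
    def test_symmetric_triple(self):
        assert np.allclose(z_transform([1, 2, 3]), [-1, 0, 1])

    def test_constant_column_rejected(self):
        with pytest.raises(DegenerateVariableError):
            z_transform([5, 5, 5])

    def test_moments_recomputed(self, rng):
        x = rng.normal(3, 7, size=50)
        x[[4, 9]] = np.nan
        z = z_transform(x)
        obs = z[~np.isnan(z)]
        assert abs(obs.mean()) < 1e-12
        assert abs(obs.std(ddof=1) - 1) < 1e-12
        assert np.isnan(z[4]) and np.isnan(z[9])


class TestEditVariables:
    def test_single_level_and_duplicates_removed(self, rng):
        base = rng.normal(size=8)
        values = pd.DataFrame(
            {
                "q1": base,
                "q2": base.copy(),  # exact duplicate, r = 1
                "c1": ["x"] * 8,  # single observed level
                "c2": list("aabbaabb"),
            },
            index=[f"h{i}" for i in range(8)],
        )
        specs = [
            VariableSpec("q1", "quantitative"),
            VariableSpec("q2", "quantitative"),
            VariableSpec("c1", "nominal"),
            VariableSpec("c2", "nominal"),
        ]
        edited, log = edit_variables(TypedSurvey(values, specs))
        kept = [s.name for s in edited.specs]
        assert kept == ["q1", "c2"]
        reasons = {e["name"]: e["reason"] for e in log}
        assert "c1" in reasons and "q2" in reasons

    def test_planted_survey_shape_survives_editing(self):
        # generator plants 11 removable columns among 117; editing keeps 106
        from herdclust.simulate import SurveySimConfig, simulate_survey

        survey, _ = simulate_survey(SurveySimConfig(seed=42))
        assert survey.values.shape[1] == 117
        edited, log = edit_variables(survey)
        assert len(edited.specs) == 106
        assert len(log) == 11


class TestGower:
    def test_identical_rows_have_zero_distance(self):
        values = pd.DataFrame(
            {"q": [1.0, 1.0, 2.0], "c": ["a", "a", "b"]}, index=list("xyz")
        )
        specs = [VariableSpec("q", "quantitative"), VariableSpec("c", "nominal")]
        D = gower_matrix(TypedSurvey(values, specs))
        assert D.D[0, 1] == 0.0

    def test_all_nominal_disagreement_is_one(self):
        values = pd.DataFrame({"c1": ["a", "b"], "c2": ["x", "y"]}, index=["u", "v"])
        specs = [VariableSpec("c1", "nominal"), VariableSpec("c2", "nominal")]
        D = gower_matrix(TypedSurvey(values, specs))
        assert D.D[0, 1] == 1.0

    def test_hand_example_matches_formula(self):
        # 4 herds x (1 quantitative, 1 nominal, 1 asymmetric binary)
        values = pd.DataFrame(
            {
                "q": [0.0, 2.0, 4.0, 4.0],
                "c": ["a", "a", "b", "b"],
                "b": [0, 1, 0, 1],
            },
            index=list("wxyz"),
        )
        specs = [
            VariableSpec("q", "quantitative"),
            VariableSpec("c", "nominal"),
            VariableSpec("b", "binary_asymmetric", (0, 1)),
        ]
        D = gower_matrix(TypedSurvey(values, specs)).D
        # pair (w, x): q: |0-2|/4; c equal; b: 0 vs 1 -> mismatch; 3 comparables
        assert D[0, 1] == pytest.approx((0.5 + 0.0 + 1.0) / 3)
        # pair (w, y): both b absent -> excluded; q: 1; c mismatch -> (1+1)/2
        assert D[0, 2] == pytest.approx((1.0 + 1.0) / 2)
        # pair (y, z): q equal, c equal, b mismatch
        assert D[2, 3] == pytest.approx(1.0 / 3)
        assert np.allclose(D, naive_gower(values, specs))

    def test_matches_naive_oracle_on_random_mixed_surveys(self, rng):
        for _ in range(10):
            survey = random_mixed_survey(rng, n_herds=8, missing_rate=0.15)
            D = gower_matrix(survey).D
            assert np.allclose(D, naive_gower(survey.values, survey.specs), atol=1e-12)

    def test_pseudometric_bounds_symmetry(self, rng):
        for _ in range(5):
            survey = random_mixed_survey(rng, n_herds=12)
            D = gower_matrix(survey).D
            assert np.allclose(D, D.T)
            assert np.all(np.diag(D) == 0)
            assert D.min() >= 0 and D.max() <= 1

    def test_quantitative_only_equals_manhattan_mean(self, rng):
        survey = random_mixed_survey(rng, n_herds=15, n_quant=4, n_qual=0)
        D = gower_matrix(survey).D
        X = survey.values.to_numpy(dtype=float)
        rngs = X.max(axis=0) - X.min(axis=0)
        for i in range(15):
            for j in range(15):
                expect = np.mean(np.abs(X[i] - X[j]) / rngs)
                assert D[i, j] == pytest.approx(expect)

    def test_removing_agreeing_variable_never_increases_distance(self, rng):
        for _ in range(5):
            survey = random_mixed_survey(rng, n_herds=6, n_quant=0, n_qual=5)
            D_full = gower_matrix(survey).D
            for s in survey.specs:
                col = survey.values[s.name]
                agree = col.iloc[0] == col.iloc[1] and not (
                    s.vtype == "binary_asymmetric" and col.iloc[0] == 0
                )
                if agree:
                    reduced = survey.select(
                        [t.name for t in survey.specs if t.name != s.name]
                    )
                    D_red = gower_matrix(reduced).D
                    assert D_red[0, 1] >= D_full[0, 1] - 1e-12

    def test_incomparable_pair_raises(self):
        values = pd.DataFrame({"q": [1.0, np.nan], "c": [np.nan, "a"]}, index=["u", "v"])
        specs = [VariableSpec("q", "quantitative"), VariableSpec("c", "nominal")]
        with pytest.raises(UndefinedDistanceError):
            gower_matrix(TypedSurvey(values, specs))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    st.lists(
        st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
        min_size=3,
        max_size=40,
    ).filter(
        # avoid catastrophic cancellation: spread must be resolvable
        lambda xs: np.std(xs, ddof=1) > 1e-3 * (1 + max(abs(x) for x in xs))
    )
)
def test_z_transform_always_standardizes(xs):
    z = z_transform(xs)
    assert abs(z.mean()) < 1e-6
    assert abs(np.std(z, ddof=1) - 1) < 1e-6


def test_survey_roundtrip_through_csv_and_yaml(tmp_path, rng):
    survey = random_mixed_survey(rng, n_herds=6)
    survey.values.rename_axis("herd_id").to_csv(tmp_path / "survey.csv")
    write_variable_specs(survey.specs, tmp_path / "specs.yaml")
    loaded = read_survey(tmp_path / "survey.csv", tmp_path / "specs.yaml")
    assert loaded.herd_ids == survey.herd_ids
    assert [s.vtype for s in loaded.specs] == [s.vtype for s in survey.specs]
    D0 = gower_matrix(survey).D
    # binary columns come back as integers; distances must be unchanged
    assert np.allclose(gower_matrix(loaded).D, D0)
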