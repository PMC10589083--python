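import numpy as np
import pandas as pd
import pytest

from nutriprod.composition import RdaSet
from nutriprod.productivity import compute_productivity
from nutriprod.regression import (
    FOOD_REGRESSORS,
    OUTCOMES,
    RegressionError,
    RegressionResult,
    build_design_matrix,
    mark_significance_and_top3,
    ols_fit,
    run_regressions,
)
from nutriprod.survey import validate_survey
from nutriprod.synthetic import generate_survey
from nutriprod.typology import classify_farms, trim_small_systems

from conftest import make_farm, make_harvest


def normal_equations(X, y):
    """Independent textbook oracle: beta = (X'X)^-1 X'y, classical SEs."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    return beta, se


@pytest.fixture(scope="module")
def fitted_inputs(comp_module, rda_module, survey_module):
    ds = survey_module.dataset
    classified = classify_farms(ds.harvests, comp_module, farm_ids=list(ds.farms["farm_id"]))
    retained, _ = trim_small_systems(classified)
    results = compute_productivity(ds, comp_module, rda_module)
    Y, X = build_design_matrix(ds, retained, comp_module, results)
    return Y, X


@pytest.fixture(scope="module")
def comp_module():
    from nutriprod.composition import default_composition

    return default_composition()


@pytest.fixture(scope="module")
def rda_module():
    return RdaSet.default()


@pytest.fixture(scope="module")
def survey_module():
    return generate_survey(seed=11)


class TestDesignMatrix:
    def test_default_synthetic_sample_is_700(self, fitted_inputs):
        Y, X = fitted_inputs
        assert len(X) == 700
        assert len(Y) == 700

    def test_aquatic_only_farm_has_zero_terrestrial_yields(self, comp_module, rda_module):
        ds = validate_survey(
            pd.DataFrame([make_farm(f"a{i}") for i in range(3)]),
            pd.DataFrame(
                [make_harvest(f"a{i}", "catla", 100.0, 50.0, 120.0) for i in range(3)]
            ),
        )
        classified = classify_farms(ds.harvests, comp_module)
        results = compute_productivity(ds, comp_module, rda_module)
        _, X = build_design_matrix(ds, classified, comp_module, results)
        terrestrial_cols = [c for c in FOOD_REGRESSORS if "fish" not in c and "carp" not in c and "crustaceans" not in c]
        assert (X[terrestrial_cols].to_numpy() == 0).all()

    def test_yield_units_tonnes_per_hectare(self, comp_module, rda_module):
        ds = validate_survey(
            pd.DataFrame([make_farm("a", land_ha=0.0, pond_ha=1.0)]),
            pd.DataFrame([make_harvest("a", "catla", 500.0, 100.0, 150.0)]),
        )
        classified = classify_farms(ds.harvests, comp_module)
        results = compute_productivity(ds, comp_module, rda_module)
        _, X = build_design_matrix(ds, classified, comp_module, results)
        assert X["yield_carp_t_ha"].iloc[0] == pytest.approx(0.5)

    def test_rank_deficiency_is_reported(self, fitted_inputs):
        Y, X = fitted_inputs
        X2 = X.copy()
        X2["dup"] = X2["yield_carp_t_ha"]
        with pytest.raises(RegressionError, match="singular|rank"):
            ols_fit(X2, Y[OUTCOMES[0]])


class TestOlsFit:
    def test_exact_linear_outcome_gives_r2_one(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(
            {"const": 1.0, "x1": rng.normal(size=40), "x2": rng.normal(size=40)}
        )
        y = pd.Series(2.0 + 3.0 * X["x1"] - 1.5 * X["x2"], name="y")
        res = ols_fit(X, y)
        assert res.rsquared == pytest.approx(1.0)
        assert res.params["x1"] == pytest.approx(3.0)

    def test_five_point_bivariate_against_hand_oracle(self):
        X = pd.DataFrame({"const": 1.0, "x": [0.0, 1.0, 2.0, 3.0, 4.0]})
        y = pd.Series([1.1, 1.9, 3.2, 3.8, 5.1], name="y")
        res = ols_fit(X, y)
        beta, se = normal_equations(X, y)
        assert np.allclose(res.params.to_numpy(), beta, rtol=1e-10)
        assert np.allclose(res.bse.to_numpy(), se, rtol=1e-10)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"const": 1.0, "x": rng.normal(size=30)})
        y = pd.Series(1.0 + 0.5 * X["x"] + rng.normal(scale=0.1, size=30), name="y")
        res = ols_fit(X, y)
        perm = rng.permutation(30)
        res_p = ols_fit(X.iloc[perm].reset_index(drop=True), y.iloc[perm].reset_index(drop=True))
        assert np.allclose(res.params.to_numpy(), res_p.params.to_numpy())

    def test_matches_normal_equations_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(15, 50))
            p = int(rng.integers(1, 8))
            X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)])
            X.insert(0, "const", 1.0)
            y = pd.Series(rng.normal(size=n), name="y")
            res = ols_fit(X, y)
            beta, se = normal_equations(X, y)
            assert np.allclose(res.params.to_numpy(), beta, rtol=1e-8)
            assert np.allclose(res.bse.to_numpy(), se, rtol=1e-8)

    def test_too_few_rows_rejected(self):
        X = pd.DataFrame({"const": [1.0, 1.0], "x": [0.0, 1.0]})
        with pytest.raises(RegressionError, match="more observations"):
            ols_fit(X, pd.Series([1.0, 2.0]))


def fake_result(coefs, pvalues):
    terms = list(coefs)
    params = pd.Series(coefs)
    return RegressionResult(
        outcome="y",
        params=params,
        bse=pd.Series(1.0, index=terms),
        pvalues=pd.Series(pvalues),
        conf_int_95=pd.DataFrame({"low": params - 2, "high": params + 2}),
        rsquared=0.5,
        nobs=700,
        se_flavor="nonrobust",
    )


class TestMarksAndTop3:
    def test_significance_marks(self):
        res = fake_result(
            {"yield_carp_t_ha": 1.0, "yield_rice_t_ha": 1.0, "sold_rice": 1.0, "const": 1.0},
            {"yield_carp_t_ha": 0.005, "yield_rice_t_ha": 0.03, "sold_rice": 0.07, "const": 0.5},
        )
        marked = mark_significance_and_top3(res)
        assert marked.marks["yield_carp_t_ha"] == "c"
        assert marked.marks["yield_rice_t_ha"] == "b"
        assert marked.marks["sold_rice"] == "a"
        assert marked.marks["const"] == ""

    def test_no_significant_coefficients_no_top3(self):
        res = fake_result({"yield_carp_t_ha": 9.0}, {"yield_carp_t_ha": 0.2})
        assert mark_significance_and_top3(res).top3 == frozenset()

    def test_only_significant_coefficients_flagged(self):
        res = fake_result(
            {"yield_carp_t_ha": 1.0, "yield_rice_t_ha": 5.0, "aquatic_sold_share": -2.0},
            {"yield_carp_t_ha": 0.04, "yield_rice_t_ha": 0.5, "aquatic_sold_share": 0.01},
        )
        top3 = mark_significance_and_top3(res).top3
        assert top3 == {"yield_carp_t_ha", "aquatic_sold_share"}

    def test_top3_by_magnitude_controls_excluded(self):
        coefs = {
            "yield_carp_t_ha": 5.0,
            "yield_rice_t_ha": -4.0,
            "yield_other_fruits_t_ha": 3.0,
            "aquatic_sold_share": 2.0,
            "head_age": 100.0,  # control: never flagged
            "const": 50.0,
        }
        pvalues = {k: 0.001 for k in coefs}
        top3 = mark_significance_and_top3(fake_result(coefs, pvalues)).top3
        assert top3 == {"yield_carp_t_ha", "yield_rice_t_ha", "yield_other_fruits_t_ha"}


class TestFixedEffects:
    def test_within_upazila_shift_moves_only_that_dummy(self, fitted_inputs, survey_module):
        Y, X = fitted_inputs
        dummy_cols = [c for c in X.columns if c.startswith("upazila_")]
        target = dummy_cols[0]
        y = Y[OUTCOMES[0]]
        base = ols_fit(X, y)
        shifted = y + 500.0 * X[target]
        res = ols_fit(X, shifted)
        for term in X.columns:
            if term == target:
                assert res.params[term] - base.params[term] == pytest.approx(500.0, abs=1e-6)
            else:
                assert res.params[term] == pytest.approx(base.params[term], abs=1e-6)


@pytest.fixture(scope="module")
def regressions(survey_module, comp_module, rda_module):
    return run_regressions(survey_module.dataset, comp_module, rda_module)


class TestRegressionTable:
    def test_eight_models_on_700_farms(self, regressions):
        assert len(regressions.results) == 8
        assert regressions.nobs == 700
        assert [r.outcome for r in regressions.results] == list(OUTCOMES)

    def test_r_squared_in_unit_interval(self, regressions):
        for res in regressions.results:
            assert 0.0 <= res.rsquared <= 1.0

    def test_terrestrial_b12_coefficients_centred_on_zero(self, comp_module, rda_module):
        # B12 comes only from aquatic foods, so terrestrial-yield coefficients
        # in the B12 model are true zeros; pooled t-statistics should look
        # like standard normal noise.
        terrestrial = [
            c
            for c in FOOD_REGRESSORS
            if not any(k in c for k in ("carp", "fish", "crustaceans"))
        ]
        tstats = []
        for seed in (21, 22, 23):
            survey = generate_survey(seed=seed)
            regressions = run_regressions(survey.dataset, comp_module, rda_module, se_flavor="HC3")
            b12 = regressions.results[-1]
            assert b12.outcome == "ae_vitamin_b12"
            tstats += [b12.params[c] / b12.bse[c] for c in terrestrial]
        tstats = np.asarray(tstats)
        assert abs(tstats.mean()) < 0.8
        assert np.mean(np.abs(tstats) < 2.58) >= 0.8

    def test_long_table_has_marks_and_layout(self, regressions):
        long = regressions.long
        assert set(long["outcome"]) == set(OUTCOMES)
        assert set(long["mark"]) <= {"", "a", "b", "c"}
        assert long.groupby("outcome")["top3"].sum().max() <= 3


class TestParameterRecoveryScaling:
    def test_estimates_concentrate_with_sample_size(self, comp_module, rda_module):
        """Pooled RMSE of food-group coefficients shrinks as n grows 700 -> 7000."""
        from nutriprod.synthetic import GeneratorConfig

        def pooled_errors(n_farms, seeds):
            errors, scales = [], []
            config = GeneratorConfig(n_farms=n_farms)
            for seed in seeds:
                survey = generate_survey(config, seed=seed)
                beta = survey.ground_truth.beta_true
                regressions = run_regressions(survey.dataset, comp_module, rda_module, se_flavor="HC3")
                for res in regressions.results:
                    for group in beta.index:
                        term = f"yield_{group}_t_ha"
                        truth = beta.loc[group, res.outcome]
                        scale = max(abs(truth), 1e-9)
                        errors.append((res.params[term] - truth) / scale)
            return np.asarray(errors)

        small = pooled_errors(700, range(400, 406))
        large = pooled_errors(7000, range(500, 506))
        rmse_small = np.sqrt(np.mean(small**2))
        rmse_large = np.sqrt(np.mean(large**2))
        assert rmse_large < rmse_small
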