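import numpy as np
import pandas as pd
import pytest

from nutriprod.composition import NUTRIENTS, NutrientVector, RdaSet
from nutriprod.productivity import (
    AE_COLUMNS,
    PriceError,
    annual_adult_equivalents,
    build_price_book,
    compute_productivity,
    economic_productivity,
    nutrient_productivity,
    system_summaries,
)
from nutriprod.survey import validate_survey
from nutriprod.typology import classify_farms

from conftest import make_farm, make_harvest


def survey_of(farms, harvests):
    return validate_survey(pd.DataFrame(farms), pd.DataFrame(harvests))


class TestPriceBook:
    def test_observed_farm_price(self):
        ds = survey_of(
            [make_farm("a")], [make_harvest("a", "catla", 20.0, 10.0, 50.0)]
        )
        book = build_price_book(ds)
        row = book.prices.iloc[0]
        assert row["price_usd_per_kg"] == pytest.approx(5.0)
        assert row["provenance"] == "observed_farm"

    def test_imputation_ladder(self):
        farms = [
            make_farm("s1", "uA"),
            make_farm("s2", "uA"),
            make_farm("s3", "uA"),
            make_farm("n1", "uA"),
            make_farm("n2", "uB"),
        ]
        harvests = [
            make_harvest("s1", "rice_aman", 100.0, 50.0, 10.0),  # 0.2 $/kg
            make_harvest("s2", "rice_aman", 100.0, 50.0, 15.0),  # 0.3 $/kg
            make_harvest("s3", "rice_aman", 100.0, 50.0, 20.0),  # 0.4 $/kg
            make_harvest("n1", "rice_aman", 80.0),  # non-seller, same upazila
            make_harvest("n2", "rice_aman", 80.0),  # non-seller, other upazila
            # keep every farm inside the aquaculture frame
            make_harvest("s1", "catla", 10.0, 5.0, 10.0),
            make_harvest("s2", "catla", 10.0, 5.0, 10.0),
            make_harvest("s3", "catla", 10.0, 5.0, 10.0),
            make_harvest("n1", "catla", 10.0, 5.0, 10.0),
            make_harvest("n2", "catla", 10.0, 5.0, 10.0),
        ]
        book = build_price_book(survey_of(farms, harvests))
        prices = book.prices.set_index(["farm_id", "food_code"])
        in_group = prices.loc[("n1", "rice_aman")]
        assert in_group["price_usd_per_kg"] == pytest.approx(0.3)  # upazila median
        assert in_group["provenance"] == "imputed_group_median"
        fallback = prices.loc[("n2", "rice_aman")]
        assert fallback["price_usd_per_kg"] == pytest.approx(0.3)  # sample median
        assert fallback["provenance"] == "imputed_sample_median"

    def test_unsellable_food_is_hard_error(self):
        ds = survey_of(
            [make_farm("a")],
            [
                make_harvest("a", "catla", 10.0, 5.0, 10.0),
                make_harvest("a", "taro", 40.0),  # produced, never sold by anyone
            ],
        )
        with pytest.raises(PriceError, match="taro"):
            build_price_book(ds)


class TestEconomicProductivity:
    def test_no_production_no_costs_is_zero(self):
        ds = survey_of([make_farm("a")], [])
        farm = ds.farms.iloc[0]
        book = build_price_book(ds)
        assert economic_productivity(farm, ds.farm_harvests("a"), book) == 0.0

    def test_hand_arithmetic(self):
        # 1 ha, 500 kg prawn at 4 $/kg, costs $600 -> (2000 - 600) / 1 = 1400.
        ds = survey_of(
            [make_farm("a", land_ha=0.5, pond_ha=0.5, production_costs_usd=600.0)],
            [make_harvest("a", "golda", 500.0, 500.0, 2000.0)],
        )
        farm = ds.farms.iloc[0]
        got = economic_productivity(farm, ds.farm_harvests("a"), build_price_book(ds))
        assert got == pytest.approx(1400.0)

    def test_doubling_area_halves_result(self):
        def econ(pond):
            ds = survey_of(
                [make_farm("a", land_ha=0.0, pond_ha=pond, production_costs_usd=300.0)],
                [make_harvest("a", "golda", 500.0, 500.0, 2000.0)],
            )
            return economic_productivity(
                ds.farms.iloc[0], ds.farm_harvests("a"), build_price_book(ds)
            )

        assert econ(2.0) == pytest.approx(econ(1.0) / 2.0)

    def test_negative_net_value_passes_through(self):
        ds = survey_of(
            [make_farm("a", production_costs_usd=5000.0)],
            [make_harvest("a", "catla", 10.0, 10.0, 20.0)],
        )
        got = economic_productivity(
            ds.farms.iloc[0], ds.farm_harvests("a"), build_price_book(ds)
        )
        assert got < 0

    def test_matches_line_by_line_oracle_on_synthetic_farms(self, comp, rda, synthetic_survey):
        ds = synthetic_survey.dataset
        book = build_price_book(ds)
        results = compute_productivity(ds, comp, rda, price_book=book)
        per_farm = results.per_farm.set_index("farm_id")
        prices = book.prices.set_index(["farm_id", "food_code"])["price_usd_per_kg"]
        rng = np.random.default_rng(0)
        farm_ids = rng.choice(ds.farms["farm_id"], size=100, replace=False)
        farms = ds.farms.set_index("farm_id")
        for farm_id in farm_ids:
            value = 0.0
            for row in ds.farm_harvests(farm_id).itertuples():
                if row.quantity_kg > 0:
                    value += row.quantity_kg * prices.loc[(farm_id, row.food_code)]
            farm = farms.loc[farm_id]
            expected = (value - farm["production_costs_usd"]) / farm["area_ha"]
            assert per_farm.loc[farm_id, "economic_usd_per_ha"] == pytest.approx(
                expected, rel=1e-9
            )


class TestAdultEquivalents:
    def test_one_annual_requirement_is_one_ae(self, rda):
        amount = NutrientVector.from_array(rda.as_array() * 365.0)
        assert np.allclose(annual_adult_equivalents(amount, rda), 1.0)

    def test_zero_amount(self, rda):
        assert np.allclose(annual_adult_equivalents(NutrientVector.zero(), rda), 0.0)

    def test_energy_scale_example(self, rda):
        # 7.39e7 kJ/ha covers 7.39e7 / (9200 * 365) = 22.0 adult-years.
        amount = NutrientVector.from_mapping({"energy_kj": 7.39e7})
        got = annual_adult_equivalents(amount, rda)[NUTRIENTS.index("energy_kj")]
        assert got == pytest.approx(22.0, abs=0.05)

    def test_linearity_and_rda_inverse_proportionality(self, rda):
        rng = np.random.default_rng(42)
        for _ in range(100):
            amount = NutrientVector.from_array(rng.uniform(0, 1e8, len(NUTRIENTS)))
            scale = rng.uniform(0.1, 10)
            base = annual_adult_equivalents(amount, rda)
            assert np.allclose(
                annual_adult_equivalents(amount * scale, rda), base * scale, rtol=1e-12
            )
            halved = RdaSet(
                values={n: rda[n] / 2.0 for n in NUTRIENTS}, b12_unit=rda.b12_unit
            )
            assert np.allclose(
                annual_adult_equivalents(amount, halved), base * 2.0, rtol=1e-12
            )


class TestNutrientProductivity:
    def test_plant_only_production_has_zero_b12(self, comp, rda):
        ds = survey_of(
            [make_farm("a")],
            [
                make_harvest("a", "catla", 1.0),  # minimal aquatic to stay in frame
                make_harvest("a", "rice_aman", 2000.0),
            ],
        )
        out = nutrient_productivity(ds.farms.iloc[0], ds.farm_harvests("a"), comp, rda)
        by_group = out["by_group3"]
        assert by_group.loc["rice", "ae_vitamin_b12"] == 0.0

    def test_determinism_identical_farms(self, comp, rda):
        farms = [make_farm("a"), make_farm("b")]
        harvests = [
            make_harvest("a", "catla", 100.0, 50.0, 120.0),
            make_harvest("b", "catla", 100.0, 50.0, 120.0),
        ]
        results = compute_productivity(survey_of(farms, harvests), comp, rda)
        a, b = results.per_farm.set_index("farm_id").loc[["a", "b"]].to_numpy()
        assert np.allclose(a, b)

    def test_merging_farms_gives_area_weighted_mean(self, comp, rda):
        farms = [
            make_farm("a", land_ha=0.0, pond_ha=1.0),
            make_farm("b", land_ha=0.0, pond_ha=3.0),
            make_farm("m", land_ha=0.0, pond_ha=4.0),
        ]
        harvests = [
            make_harvest("a", "catla", 100.0),
            make_harvest("a", "mola", 30.0),
            make_harvest("b", "catla", 400.0),
            make_harvest("m", "catla", 500.0),
            make_harvest("m", "mola", 30.0),
        ]
        ds = survey_of(farms, harvests)
        out = {
            f: nutrient_productivity(
                ds.farms.set_index("farm_id").loc[f], ds.farm_harvests(f), comp, rda
            )["ae"].as_array()
            for f in ("a", "b", "m")
        }
        weighted = (1.0 * out["a"] + 3.0 * out["b"]) / 4.0
        assert np.allclose(out["m"], weighted, rtol=1e-12)

    def test_missing_composition_entry_policy(self, comp, rda):
        ds = survey_of(
            [make_farm("a")],
            [
                make_harvest("a", "catla", 10.0, 5.0, 10.0),
                make_harvest("a", "dragonfruit", 10.0, 5.0, 10.0),
            ],
        )
        with pytest.raises(PriceError, match="dragonfruit"):
            compute_productivity(ds, comp, rda)
        results = compute_productivity(ds, comp, rda, on_missing_food="skip")
        assert len(results.per_farm) == 1


class TestDecompositionsAndInvariance:
    def test_group_decompositions_sum_to_totals(self, comp, rda, synthetic_survey):
        results = compute_productivity(synthetic_survey.dataset, comp, rda)
        totals = results.per_farm.set_index("farm_id")
        for decomposition in (results.by_group3, results.by_subcategory):
            sums = decomposition.groupby("farm_id")[
                ["value_usd_per_ha", *AE_COLUMNS]
            ].sum()
            joined = sums.join(totals, lsuffix="_dec")
            assert np.allclose(
                joined["value_usd_per_ha"],
                joined["gross_value_usd_per_ha"],
                rtol=1e-9,
            )
            for col in AE_COLUMNS:
                assert np.allclose(joined[f"{col}_dec"], joined[col], rtol=1e-9)

    def test_per_ha_metrics_invariant_to_common_scaling(self, comp, rda, tiny_survey):
        base = compute_productivity(tiny_survey, comp, rda).per_farm
        k = 3.7
        farms = tiny_survey.farms.copy()
        for col in ("land_ha", "pond_ha", "production_costs_usd"):
            farms[col] = farms[col] * k
        harvests = tiny_survey.harvests.copy()
        for col in ("quantity_kg", "quantity_sold_kg", "sales_value_usd"):
            harvests[col] = harvests[col] * k
        scaled_ds = validate_survey(
            farms.drop(columns="area_ha"), harvests
        )
        scaled = compute_productivity(scaled_ds, comp, rda).per_farm
        metric_cols = ["economic_usd_per_ha", *AE_COLUMNS]
        assert np.allclose(
            base[metric_cols].to_numpy(), scaled[metric_cols].to_numpy(), rtol=1e-9
        )


class TestSystemSummaries:
    def test_single_farm_system_equals_farm_values(self, comp, rda, tiny_survey):
        classified = classify_farms(
            tiny_survey.harvests, comp, farm_ids=list(tiny_survey.farms["farm_id"])
        )
        results = compute_productivity(tiny_survey, comp, rda)
        summaries = system_summaries(tiny_survey, classified, results, comp)
        systems = summaries["systems"].set_index(["aquatic", "terrestrial"])
        farm_b = results.per_farm.set_index("farm_id").loc["b"]
        row = systems.loc[("FP", "rice_vf")]
        assert row["n_farms"] == 1
        assert row["mean_economic_usd_per_ha"] == pytest.approx(
            farm_b["economic_usd_per_ha"]
        )

    def test_all_sold_gives_full_share(self, comp, rda):
        ds = survey_of(
            [make_farm("a")], [make_harvest("a", "catla", 100.0, 100.0, 150.0)]
        )
        classified = classify_farms(ds.harvests, comp, farm_ids=["a"])
        results = compute_productivity(ds, comp, rda)
        summaries = system_summaries(ds, classified, results, comp)
        share = summaries["by_group3"]["share_sold_mean"].iloc[0]
        assert share == pytest.approx(1.0)
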