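import pandas as pd
import pytest

from nutriprod.composition import RdaSet, default_composition
from nutriprod.synthetic import generate_survey, generate_reference_typology


@pytest.fixture(scope="session")
def comp():
    return default_composition()


@pytest.fixture(scope="session")
def rda():
    return RdaSet.default()


@pytest.fixture(scope="session")
def reference_typology():
    return generate_reference_typology()


@pytest.fixture(scope="session")
def synthetic_survey():
    """One default synthetic survey round shared across read-only tests."""
    return generate_survey(seed=11)


@pytest.fixture()
def toy_composition_frame(comp):
    """A 20-food table covering all 12 sub-categories, derived from the default."""
    per_group = {
        "carp": 3,
        "other_stocked_fish": 2,
        "unstocked_fish": 2,
        "crustaceans": 2,
        "rice": 2,
        "leafy_vegetables": 1,
        "vitaminA_rich_vegetables": 1,
        "other_vegetables": 3,
        "root_crops": 1,
        "vitaminA_rich_fruits": 1,
        "other_fruits": 1,
        "nuts_oilseeds": 1,
    }
    frame = comp.frame
    parts = [
        frame[frame["subcategory"] == group].head(k)
        for group, k in per_group.items()
    ]
    out = pd.concat(parts, ignore_index=True)
    assert len(out) == 20
    return out


def make_farm(
    farm_id="farm1",
    upazila_id="uA",
    land_ha=0.5,
    pond_ha=0.5,
    production_costs_usd=0.0,
    **overrides,
):
    row = {
        "farm_id": farm_id,
        "upazila_id": upazila_id,
        "head_age": 45.0,
        "head_education": 5.0,
        "head_female": 0.0,
        "n_members": 4.0,
        "dependency_ratio": 0.6,
        "off_farm_income": 1.0,
        "travel_time_city": 60.0,
        "land_ha": land_ha,
        "pond_ha": pond_ha,
        "production_costs_usd": production_costs_usd,
    }
    row.update(overrides)
    return row


def make_harvest(farm_id, food_code, quantity_kg, quantity_sold_kg=0.0, sales_value_usd=0.0):
    return {
        "farm_id": farm_id,
        "food_code": food_code,
        "quantity_kg": quantity_kg,
        "quantity_sold_kg": quantity_sold_kg,
        "sales_value_usd": sales_value_usd,
    }


@pytest.fixture()
def tiny_survey():
    """Three handcrafted farms: fish-only, prawn+rice+vegetables, shrimp-only."""
    from nutriprod.survey import validate_survey

    farms = pd.DataFrame(
        [
            make_farm("a", "uA", land_ha=0.0, pond_ha=1.0, production_costs_usd=600.0),
            make_farm("b", "uA", land_ha=0.6, pond_ha=0.4, production_costs_usd=300.0),
            make_farm("c", "uB", land_ha=0.0, pond_ha=2.0, production_costs_usd=100.0),
        ]
    )
    harvests = pd.DataFrame(
        [
            make_harvest("a", "catla", 500.0, 400.0, 800.0),
            make_harvest("a", "mola", 50.0, 10.0, 25.0),
            make_harvest("b", "rohu", 300.0, 200.0, 380.0),
            make_harvest("b", "golda", 100.0, 90.0, 650.0),
            make_harvest("b", "rice_aman", 1200.0, 300.0, 95.0),
            make_harvest("b", "okra", 80.0, 40.0, 18.0),
            make_harvest("c", "bagda", 200.0, 200.0, 1500.0),
            make_harvest("c", "tilapia", 400.0, 350.0, 390.0),
        ]
    )
    return validate_survey(farms, harvests)
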