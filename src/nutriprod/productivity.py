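"""Economic and nutrient productivity per hectare.

Economic productivity is the annual value of food production per hectare of
land and water: every produced quantity (sold or consumed on farm) is valued
at the farm's unit price, reported production costs are subtracted, and the
result is divided by the total sample-parcel area. Nutrient productivity is
expressed in annual adult equivalents per hectare (AE ha-1): the amount of
each nutrient produced per hectare divided by one adult's annual requirement
(daily RDA x 365). Both metrics decompose by food group (aquatic foods /
vegetables and fruits / rice, and the 12 regression sub-categories).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .composition import (
    NUTRIENTS,
    FoodComposition,
    NutrientVector,
    RdaSet,
)
from .survey import SurveyDataset

logger = logging.getLogger(__name__)

GROUP3: tuple[str, ...] = ("aquatic", "vegetables_fruits", "rice")

AE_COLUMNS: tuple[str, ...] = tuple(f"ae_{n}" for n in NUTRIENTS)

PROVENANCE_ORDER = ("observed_farm", "imputed_group_median", "imputed_sample_median")


class PriceError(ValueError):
    """A produced food's unit price cannot be resolved."""


@dataclass
class PriceBook:
    """Farm x food unit prices (US$ per kg of whole product).

    ``prices`` has one row per farm x food with positive production:
    ``farm_id, food_code, price_usd_per_kg, provenance``. Provenance is
    ``observed_farm`` when the farm itself sold the food (sales value over
    quantity sold), else the median price among sellers in the same upazila,
    else the sample-wide median among sellers.
    """

    prices: pd.DataFrame

    def lookup(self, farm_id: str, food_code: str) -> float:
        row = self.prices[
            (self.prices["farm_id"] == farm_id)
            & (self.prices["food_code"] == food_code)
        ]
        if row.empty:
            raise PriceError(f"no price for farm {farm_id!r}, food {food_code!r}")
        return float(row["price_usd_per_kg"].iloc[0])


def group3_of(composition: FoodComposition) -> pd.DataFrame:
    """Map food_code -> 3-level food group (aquatic / vegetables_fruits / rice)."""
    frame = composition.frame[["food_code", "realm", "subcategory"]].copy()
    frame["group3"] = np.where(
        frame["realm"] == "aquatic",
        "aquatic",
        np.where(frame["subcategory"] == "rice", "rice", "vegetables_fruits"),
    )
    return frame[["food_code", "subcategory", "group3"]]


def _aggregated_harvests(dataset: SurveyDataset) -> pd.DataFrame:
    """Harvest lines summed per farm x food, positive production only."""
    h = dataset.harvests
    h = h[h["quantity_kg"] > 0]
    if h.empty:
        return h.copy()
    return (
        h.groupby(["farm_id", "food_code"], as_index=False)[
            ["quantity_kg", "quantity_sold_kg", "sales_value_usd"]
        ].sum()
    )


def build_price_book(dataset: SurveyDataset) -> PriceBook:
    """Resolve a unit price for every farm x food with positive production.

    Farm-specific observed prices come first; produced-but-unsold lines fall
    back to the median observed price among sellers of the food in the same
    upazila, then to the sample-wide median. A food produced somewhere but
    sold nowhere in the sample is a hard error.
    """
    h = _aggregated_harvests(dataset)
    if h.empty:
        return PriceBook(
            prices=pd.DataFrame(
                columns=["farm_id", "food_code", "price_usd_per_kg", "provenance"]
            )
        )
    h = h.merge(dataset.farms[["farm_id", "upazila_id"]], on="farm_id", how="left")

    sellers = h[h["quantity_sold_kg"] > 0].copy()
    sellers["observed_price"] = (
        sellers["sales_value_usd"] / sellers["quantity_sold_kg"]
    )
    if (sellers["observed_price"] <= 0).any():
        bad = sellers.loc[sellers["observed_price"] <= 0, "food_code"].unique()
        raise PriceError(f"non-positive observed unit prices for: {sorted(bad)}")

    group_median = (
        sellers.groupby(["food_code", "upazila_id"])["observed_price"]
        .median()
        .rename("group_median")
    )
    sample_median = (
        sellers.groupby("food_code")["observed_price"].median().rename("sample_median")
    )

    out = h.merge(
        sellers[["farm_id", "food_code", "observed_price"]],
        on=["farm_id", "food_code"],
        how="left",
    )
    out = out.merge(group_median, on=["food_code", "upazila_id"], how="left")
    out = out.merge(sample_median, on="food_code", how="left")

    price = out["observed_price"]
    provenance = pd.Series("observed_farm", index=out.index)
    need = price.isna()
    provenance[need & out["group_median"].notna()] = "imputed_group_median"
    price = price.fillna(out["group_median"])
    need = price.isna()
    provenance[need & out["sample_median"].notna()] = "imputed_sample_median"
    price = price.fillna(out["sample_median"])

    if price.isna().any():
        orphan_foods = sorted(out.loc[price.isna(), "food_code"].unique())
        raise PriceError(
            "foods produced but sold nowhere in the sample (no price source): "
            f"{orphan_foods}"
        )
    return PriceBook(
        prices=pd.DataFrame(
            {
                "farm_id": out["farm_id"],
                "food_code": out["food_code"],
                "price_usd_per_kg": price,
                "provenance": provenance,
            }
        )
    )


def annual_adult_equivalents(
    amount_per_ha: NutrientVector | np.ndarray, rda: RdaSet
) -> np.ndarray:
    """Convert per-hectare nutrient amounts to annual adult equivalents.

    AE_n = amount_n / (RDA_n x 365): the number of adults whose full-year
    requirement of nutrient n the per-hectare output covers. Linear in the
    amounts and inversely proportional to the RDA values.
    """
    if isinstance(amount_per_ha, NutrientVector):
        amount_per_ha = amount_per_ha.as_array()
    return np.asarray(amount_per_ha, dtype=float) / (rda.as_array() * 365.0)


@dataclass
class ProductivityResults:
    """Per-farm productivity with food-group decompositions.

    ``per_farm``: one row per farm with ``economic_usd_per_ha``,
    ``gross_value_usd_per_ha`` and ``ae_<nutrient>`` columns.
    ``by_group3`` / ``by_subcategory``: long frames of the same quantities
    split by food group; value and AE columns sum to the farm totals (costs
    are whole-farm and appear only in the net economic total).
    """

    per_farm: pd.DataFrame
    by_group3: pd.DataFrame
    by_subcategory: pd.DataFrame


def _empty_results(farms: pd.DataFrame) -> ProductivityResults:
    per_farm = farms[["farm_id", "area_ha", "production_costs_usd"]].copy()
    per_farm["gross_value_usd_per_ha"] = 0.0
    per_farm["economic_usd_per_ha"] = (
        -per_farm["production_costs_usd"] / per_farm["area_ha"]
    )
    for col in AE_COLUMNS:
        per_farm[col] = 0.0
    empty = pd.DataFrame(
        columns=["farm_id", "group", "value_usd_per_ha", *AE_COLUMNS]
    )
    return ProductivityResults(
        per_farm=per_farm.drop(columns="production_costs_usd"),
        by_group3=empty,
        by_subcategory=empty.copy(),
    )


def compute_productivity(
    dataset: SurveyDataset,
    composition: FoodComposition,
    rda: RdaSet,
    price_book: PriceBook | None = None,
    on_missing_food: Literal["error", "skip"] = "error",
) -> ProductivityResults:
    """Economic and nutrient productivity for every farm in the survey.

    ``on_missing_food`` controls what happens when a produced food has no
    composition entry: hard error by default, or skip with a logged warning
    (silent nutrient undercounting is the worst failure mode, so skipping is
    opt-in).
    """
    if price_book is None:
        price_book = build_price_book(dataset)

    h = _aggregated_harvests(dataset)
    if h.empty:
        return _empty_results(dataset.farms)

    comp = composition.frame[
        ["food_code", "subcategory"] + [f"density_{n}" for n in NUTRIENTS]
    ]
    merged = h.merge(comp, on="food_code", how="left")
    missing = merged["subcategory"].isna()
    if missing.any():
        foods = sorted(merged.loc[missing, "food_code"].unique())
        if on_missing_food == "error":
            raise PriceError(
                f"foods missing from the composition table: {foods} "
                "(pass on_missing_food='skip' to drop them with a warning)"
            )
        logger.warning("skipping foods missing from composition table: %s", foods)
        merged = merged[~missing]

    g3 = group3_of(composition)[["food_code", "group3"]]
    merged = merged.merge(g3, on="food_code", how="left")
    merged = merged.merge(
        price_book.prices[["farm_id", "food_code", "price_usd_per_kg"]],
        on=["farm_id", "food_code"],
        how="left",
    )
    if merged["price_usd_per_kg"].isna().any():
        foods = sorted(
            merged.loc[merged["price_usd_per_kg"].isna(), "food_code"].unique()
        )
        raise PriceError(f"price book does not cover produced foods: {foods}")

    merged["value_usd"] = merged["quantity_kg"] * merged["price_usd_per_kg"]
    for n in NUTRIENTS:
        merged[f"amount_{n}"] = merged["quantity_kg"] * merged[f"density_{n}"]

    amount_cols = [f"amount_{n}" for n in NUTRIENTS]

    def _per_ha(frame: pd.DataFrame, key: list[str]) -> pd.DataFrame:
        sums = frame.groupby(key, as_index=False)[["value_usd"] + amount_cols].sum()
        sums = sums.merge(dataset.farms[["farm_id", "area_ha"]], on="farm_id")
        out = sums[key].copy()
        out["value_usd_per_ha"] = sums["value_usd"] / sums["area_ha"]
        amounts_per_ha = sums[amount_cols].to_numpy() / sums[["area_ha"]].to_numpy()
        ae = amounts_per_ha / (rda.as_array() * 365.0)
        for j, col in enumerate(AE_COLUMNS):
            out[col] = ae[:, j]
        return out

    totals = _per_ha(merged, ["farm_id"])
    by_group3 = _per_ha(merged, ["farm_id", "group3"]).rename(
        columns={"group3": "group"}
    )
    by_subcat = _per_ha(merged, ["farm_id", "subcategory"]).rename(
        columns={"subcategory": "group"}
    )

    per_farm = dataset.farms[["farm_id", "area_ha", "production_costs_usd"]].merge(
        totals, on="farm_id", how="left"
    )
    per_farm[["value_usd_per_ha", *AE_COLUMNS]] = per_farm[
        ["value_usd_per_ha", *AE_COLUMNS]
    ].fillna(0.0)
    per_farm = per_farm.rename(columns={"value_usd_per_ha": "gross_value_usd_per_ha"})
    per_farm["economic_usd_per_ha"] = (
        per_farm["gross_value_usd_per_ha"]
        - per_farm["production_costs_usd"] / per_farm["area_ha"]
    )
    per_farm = per_farm.drop(columns="production_costs_usd")
    cols = ["farm_id", "area_ha", "gross_value_usd_per_ha", "economic_usd_per_ha"]
    per_farm = per_farm[cols + list(AE_COLUMNS)]
    return ProductivityResults(
        per_farm=per_farm, by_group3=by_group3, by_subcategory=by_subcat
    )


def economic_productivity(
    farm: Mapping[str, float],
    farm_harvests: pd.DataFrame,
    price_book: PriceBook,
) -> float:
    """Net value of one farm's production per hectare of land and water.

    All produced quantities (sold and self-consumed alike) are valued at the
    farm's resolved unit price; reported variable production costs are
    subtracted; the result is divided by the farm's total parcel area.
    Negative values (costs exceeding production value) pass through.
    """
    area = float(farm["area_ha"])
    costs = float(farm["production_costs_usd"])
    h = farm_harvests[farm_harvests["quantity_kg"] > 0]
    value = 0.0
    for row in h.itertuples():
        value += row.quantity_kg * price_book.lookup(str(row.farm_id), row.food_code)
    return (value - costs) / area


def nutrient_productivity(
    farm: Mapping[str, float],
    farm_harvests: pd.DataFrame,
    composition: FoodComposition,
    rda: RdaSet,
    on_missing_food: Literal["error", "skip"] = "error",
) -> dict:
    """One farm's per-nutrient AEs ha-1 with food-group decompositions.

    Returns ``{"ae": NutrientVector, "by_group3": DataFrame,
    "by_subcategory": DataFrame}``; each decomposition's AE columns sum to
    the farm total.
    """
    area = float(farm["area_ha"])
    h = farm_harvests[farm_harvests["quantity_kg"] > 0].copy()
    comp = composition.frame[
        ["food_code", "subcategory"] + [f"density_{n}" for n in NUTRIENTS]
    ]
    merged = h.merge(comp, on="food_code", how="left")
    missing = merged["subcategory"].isna()
    if missing.any():
        foods = sorted(merged.loc[missing, "food_code"].unique())
        if on_missing_food == "error":
            raise PriceError(f"foods missing from the composition table: {foods}")
        logger.warning("skipping foods missing from composition table: %s", foods)
        merged = merged[~missing]
    merged = merged.merge(
        group3_of(composition)[["food_code", "group3"]], on="food_code", how="left"
    )

    rda_annual = rda.as_array() * 365.0
    density = merged[[f"density_{n}" for n in NUTRIENTS]].to_numpy()
    amounts = merged[["quantity_kg"]].to_numpy() * density

    def _table(key: str) -> pd.DataFrame:
        groups = merged[key]
        frame = pd.DataFrame(amounts, columns=list(AE_COLUMNS))
        frame[key] = groups.values
        sums = frame.groupby(key).sum()
        return sums / area / rda_annual

    total = amounts.sum(axis=0) / area / rda_annual
    return {
        "ae": NutrientVector.from_array(total),
        "by_group3": _table("group3"),
        "by_subcategory": _table("subcategory"),
    }


def farm_group_quantities(
    dataset: SurveyDataset, composition: FoodComposition
) -> pd.DataFrame:
    """Per farm x 3-level group: kg/ha produced and the share of it sold."""
    h = _aggregated_harvests(dataset)
    if h.empty:
        return pd.DataFrame(
            columns=["farm_id", "group3", "kg_per_ha", "share_sold"]
        )
    h = h.merge(group3_of(composition)[["food_code", "group3"]], on="food_code")
    sums = h.groupby(["farm_id", "group3"], as_index=False)[
        ["quantity_kg", "quantity_sold_kg"]
    ].sum()
    sums = sums.merge(dataset.farms[["farm_id", "area_ha"]], on="farm_id")
    sums["kg_per_ha"] = sums["quantity_kg"] / sums["area_ha"]
    sums["share_sold"] = sums["quantity_sold_kg"] / sums["quantity_kg"]
    return sums[["farm_id", "group3", "kg_per_ha", "share_sold"]]


def system_summaries(
    dataset: SurveyDataset,
    classified: pd.DataFrame,
    results: ProductivityResults,
    composition: FoodComposition,
) -> dict[str, pd.DataFrame]:
    """Unweighted per-system means of the farm-level metrics.

    Returns ``systems`` (one row per farming system: farm count, mean
    economic productivity, mean AEs per nutrient) and ``by_group3`` (per
    system x food group: mean kg/ha produced, mean farm-level share sold,
    mean value and AE contributions per ha). Shares sold are averaged across
    the farms producing the group, not pooled. Systems with no farms are
    simply absent.
    """
    labels = classified[["farm_id", "aquatic", "terrestrial"]]
    per_farm = results.per_farm.merge(labels, on="farm_id", how="inner")
    if per_farm.empty:
        raise ValueError("no classified farms to summarize")

    keys = ["aquatic", "terrestrial"]
    systems = (
        per_farm.groupby(keys)
        .agg(
            n_farms=("farm_id", "size"),
            mean_economic_usd_per_ha=("economic_usd_per_ha", "mean"),
            mean_gross_value_usd_per_ha=("gross_value_usd_per_ha", "mean"),
            **{
                f"mean_{col}": (col, "mean")
                for col in AE_COLUMNS
            },
        )
        .reset_index()
    )

    quantities = farm_group_quantities(dataset, composition).merge(
        labels, on="farm_id", how="inner"
    )
    decomp = results.by_group3.rename(columns={"group": "group3"}).merge(
        labels, on="farm_id", how="inner"
    )
    # Means over ALL farms in the system (absent group counts as zero) for
    # quantities/value/AE; share sold averaged over producing farms only.
    n_by_system = per_farm.groupby(keys)["farm_id"].size().rename("n_farms")

    q_sums = quantities.groupby(keys + ["group3"]).agg(
        kg_per_ha_sum=("kg_per_ha", "sum"),
        share_sold_mean=("share_sold", "mean"),
        n_producing=("farm_id", "size"),
    )
    d_sums = decomp.groupby(keys + ["group3"])[
        ["value_usd_per_ha", *AE_COLUMNS]
    ].sum()
    by_group = q_sums.join(d_sums, how="outer").reset_index().merge(
        n_by_system.reset_index(), on=keys
    )
    value_ae = ["value_usd_per_ha", *AE_COLUMNS, "kg_per_ha_sum"]
    by_group[value_ae] = by_group[value_ae].fillna(0.0)
    by_group["mean_kg_per_ha"] = by_group["kg_per_ha_sum"] / by_group["n_farms"]
    by_group["mean_value_usd_per_ha"] = (
        by_group["value_usd_per_ha"] / by_group["n_farms"]
    )
    for col in AE_COLUMNS:
        by_group[f"mean_{col}"] = by_group[col] / by_group["n_farms"]
    keep = keys + [
        "group3",
        "n_producing",
        "mean_kg_per_ha",
        "share_sold_mean",
        "mean_value_usd_per_ha",
    ] + [f"mean_{col}" for col in AE_COLUMNS]
    return {"systems": systems, "by_group3": by_group[keep]}
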