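"""Survey microdata model and I/O.

Two tables describe one survey round: ``farms`` (one row per farm: location,
areas, household covariates, production costs) and ``harvests`` (one row per
farm x food production line over the most recent cropping cycle, with the
quantity sold and its sales value). Quantities are whole-product wet weight
in kg; monetary fields are US$ (any currency conversion is a preprocessing
responsibility). Validation is total: a dataset that loads without error
satisfies every invariant the downstream stages assume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO

import pandas as pd

logger = logging.getLogger(__name__)

FARM_COLUMNS: tuple[str, ...] = (
    "farm_id",
    "upazila_id",
    "head_age",
    "head_education",
    "head_female",
    "n_members",
    "dependency_ratio",
    "off_farm_income",
    "travel_time_city",
    "land_ha",
    "pond_ha",
    "production_costs_usd",
)

HARVEST_COLUMNS: tuple[str, ...] = (
    "farm_id",
    "food_code",
    "quantity_kg",
    "quantity_sold_kg",
    "sales_value_usd",
)

_NUMERIC_FARM = (
    "head_age",
    "head_education",
    "head_female",
    "n_members",
    "dependency_ratio",
    "off_farm_income",
    "travel_time_city",
    "land_ha",
    "pond_ha",
    "production_costs_usd",
)

_SOLD_TOL = 1e-9


class SurveyValidationError(ValueError):
    """Survey data violates the documented schema or an invariant."""


@dataclass
class SurveyDataset:
    """Validated farms + harvests tables.

    ``farms`` carries a derived ``area_ha`` column: the total sample-parcel
    area, agricultural land plus pond, the denominator of every per-hectare
    metric.
    """

    farms: pd.DataFrame
    harvests: pd.DataFrame

    @property
    def n_farms(self) -> int:
        return len(self.farms)

    def farm_harvests(self, farm_id: str) -> pd.DataFrame:
        return self.harvests[self.harvests["farm_id"] == farm_id]


def _offending(rows: pd.DataFrame, cols: list[str], limit: int = 10) -> str:
    return rows[cols].head(limit).to_string(index=False)


def validate_survey(farms: pd.DataFrame, harvests: pd.DataFrame) -> SurveyDataset:
    """Validate raw tables and return a :class:`SurveyDataset`.

    Hard errors: missing columns, missing values, duplicate farm ids, orphan
    harvest lines, non-positive parcel area or pond area, negative costs,
    quantity sold exceeding quantity produced, positive sales value with zero
    quantity sold.
    """
    farms = farms.copy()
    harvests = harvests.copy() if len(harvests) else pd.DataFrame(
        columns=list(HARVEST_COLUMNS)
    )

    missing = set(FARM_COLUMNS) - set(farms.columns)
    if missing:
        raise SurveyValidationError(f"farm table missing columns: {sorted(missing)}")
    missing = set(HARVEST_COLUMNS) - set(harvests.columns)
    if missing:
        raise SurveyValidationError(
            f"harvest table missing columns: {sorted(missing)}"
        )

    farms["farm_id"] = farms["farm_id"].astype(str)
    farms["upazila_id"] = farms["upazila_id"].astype(str)
    for col in _NUMERIC_FARM:
        farms[col] = pd.to_numeric(farms[col], errors="coerce")
    if farms[list(FARM_COLUMNS)].isna().any().any():
        bad = farms[farms[list(FARM_COLUMNS)].isna().any(axis=1)]
        raise SurveyValidationError(
            "farm table has missing/non-numeric values:\n"
            + _offending(bad, ["farm_id"])
        )
    if farms["farm_id"].duplicated().any():
        dupes = sorted(farms.loc[farms["farm_id"].duplicated(), "farm_id"])
        raise SurveyValidationError(f"duplicate farm_id: {dupes}")

    farms["area_ha"] = farms["land_ha"] + farms["pond_ha"]
    checks = [
        (farms["pond_ha"] <= 0, "pond_ha must be positive (all farms practice aquaculture)"),
        (farms["land_ha"] < 0, "land_ha must be non-negative"),
        (farms["area_ha"] <= 0, "total parcel area must be positive"),
        (farms["production_costs_usd"] < 0, "production costs must be non-negative"),
        (~farms["head_female"].isin([0, 1]), "head_female must be 0/1"),
        (~farms["off_farm_income"].isin([0, 1]), "off_farm_income must be 0/1"),
        (farms["dependency_ratio"] < 0, "dependency_ratio must be non-negative"),
        (farms["n_members"] < 1, "n_members must be at least 1"),
    ]
    for mask, message in checks:
        if mask.any():
            raise SurveyValidationError(
                f"{message}; offending farms:\n"
                + _offending(farms[mask], ["farm_id"])
            )

    harvests["farm_id"] = harvests["farm_id"].astype(str)
    harvests["food_code"] = harvests["food_code"].astype(str)
    for col in ("quantity_kg", "quantity_sold_kg", "sales_value_usd"):
        harvests[col] = pd.to_numeric(harvests[col], errors="coerce")
    if len(harvests):
        if harvests[list(HARVEST_COLUMNS)].isna().any().any():
            bad = harvests[harvests[list(HARVEST_COLUMNS)].isna().any(axis=1)]
            raise SurveyValidationError(
                "harvest table has missing/non-numeric values:\n"
                + _offending(bad, ["farm_id", "food_code"])
            )
        orphans = ~harvests["farm_id"].isin(set(farms["farm_id"]))
        if orphans.any():
            raise SurveyValidationError(
                "harvest lines reference unknown farms:\n"
                + _offending(harvests[orphans], ["farm_id", "food_code"])
            )
        neg = (harvests["quantity_kg"] < 0) | (harvests["quantity_sold_kg"] < 0)
        if neg.any():
            raise SurveyValidationError(
                "negative quantities:\n"
                + _offending(harvests[neg], ["farm_id", "food_code", "quantity_kg"])
            )
        over = harvests["quantity_sold_kg"] > harvests["quantity_kg"] + _SOLD_TOL
        if over.any():
            raise SurveyValidationError(
                "quantity_sold_kg exceeds quantity_kg:\n"
                + _offending(
                    harvests[over],
                    ["farm_id", "food_code", "quantity_kg", "quantity_sold_kg"],
                )
            )
        ghost = (harvests["quantity_sold_kg"] == 0) & (harvests["sales_value_usd"] != 0)
        if ghost.any():
            raise SurveyValidationError(
                "sales value reported with zero quantity sold:\n"
                + _offending(harvests[ghost], ["farm_id", "food_code", "sales_value_usd"])
            )
        if (harvests["sales_value_usd"] < 0).any():
            bad = harvests[harvests["sales_value_usd"] < 0]
            raise SurveyValidationError(
                "negative sales value:\n"
                + _offending(bad, ["farm_id", "food_code", "sales_value_usd"])
            )

    dataset = SurveyDataset(farms=farms, harvests=harvests)
    logger.info(
        "survey loaded: %d farms, %d harvest lines, %d distinct foods",
        len(farms),
        len(harvests),
        harvests["food_code"].nunique() if len(harvests) else 0,
    )
    return dataset


def load_survey(
    farm_csv: str | Path | IO[str], harvest_csv: str | Path | IO[str]
) -> SurveyDataset:
    """Read and validate the two survey CSVs."""
    farms = pd.read_csv(farm_csv)
    harvests = pd.read_csv(harvest_csv)
    return validate_survey(farms, harvests)


def write_survey(
    dataset: SurveyDataset,
    farms_path: str | Path | IO[str],
    harvests_path: str | Path | IO[str],
) -> None:
    """Write the survey back to CSV; round-trips losslessly with the loader."""
    dataset.farms[list(FARM_COLUMNS)].to_csv(farms_path, index=False)
    dataset.harvests[list(HARVEST_COLUMNS)].to_csv(harvests_path, index=False)
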