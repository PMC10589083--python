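"""Farming-system typology.

Each surveyed farm is cross-classified by its aquatic-food combination --
fish only (F), fish and prawn (FP), fish, prawn and shrimp (FPS), fish and
shrimp (FS) -- and its terrestrial integration: none, rice only, vegetables
and fruits only, or both. Prawn/shrimp membership is a species flag on the
crustacean entries of the composition table, not a hardcoded name list. The
module also tabulates the 4 x 4 sample-distribution table, applies the
small-cell trimming rule, and exposes the rounded percentage helpers used in
the descriptive results.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import pandas as pd

from .composition import FoodComposition

logger = logging.getLogger(__name__)

AQUATIC_SYSTEMS: tuple[str, ...] = ("F", "FP", "FPS", "FS")
TERRESTRIAL_SYSTEMS: tuple[str, ...] = ("none", "rice", "vf", "rice_vf")


class TypologyError(ValueError):
    """A farm or table cannot be classified/tabulated as requested."""


@dataclass(frozen=True)
class FarmingSystem:
    aquatic: str
    terrestrial: str

    def __post_init__(self) -> None:
        if self.aquatic not in AQUATIC_SYSTEMS:
            raise TypologyError(f"unknown aquatic system {self.aquatic!r}")
        if self.terrestrial not in TERRESTRIAL_SYSTEMS:
            raise TypologyError(f"unknown terrestrial system {self.terrestrial!r}")


def _system_labels(
    has_prawn: pd.Series, has_shrimp: pd.Series, has_rice: pd.Series, has_vf: pd.Series
) -> tuple[pd.Series, pd.Series]:
    aquatic = pd.Series("F", index=has_prawn.index)
    aquatic[has_prawn & ~has_shrimp] = "FP"
    aquatic[~has_prawn & has_shrimp] = "FS"
    aquatic[has_prawn & has_shrimp] = "FPS"
    terrestrial = pd.Series("none", index=has_rice.index)
    terrestrial[has_rice & ~has_vf] = "rice"
    terrestrial[~has_rice & has_vf] = "vf"
    terrestrial[has_rice & has_vf] = "rice_vf"
    return aquatic, terrestrial


def classify_farms(
    harvests: pd.DataFrame,
    composition: FoodComposition,
    farm_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Classify farms into the 4 x 4 grid from their harvest lines.

    Classification depends only on which foods have positive production, so
    it is invariant to line order and to splitting or merging lines of the
    same food. ``farm_ids``, when given, is the full sample frame; any listed
    farm without aquatic production is an error (the frame is aquaculture
    farms by construction). Returns a frame with columns ``farm_id``,
    ``aquatic``, ``terrestrial``.
    """
    produced = harvests.loc[harvests["quantity_kg"] > 0, ["farm_id", "food_code"]]
    merged = produced.merge(
        composition.frame[["food_code", "realm", "subcategory", "species_flag"]],
        on="food_code",
        how="left",
    )
    unknown = merged["realm"].isna()
    if unknown.any():
        missing = sorted(merged.loc[unknown, "food_code"].unique())
        raise TypologyError(f"foods missing from composition table: {missing}")

    flags = (
        merged.assign(
            aquatic_any=merged["realm"] == "aquatic",
            finfish=(merged["realm"] == "aquatic")
            & (merged["subcategory"] != "crustaceans"),
            prawn=merged["species_flag"] == "prawn",
            shrimp=merged["species_flag"] == "shrimp",
            rice=merged["subcategory"] == "rice",
            vf=(merged["realm"] == "terrestrial") & (merged["subcategory"] != "rice"),
        )
        .groupby("farm_id")[["aquatic_any", "finfish", "prawn", "shrimp", "rice", "vf"]]
        .any()
    )

    if farm_ids is not None:
        flags = flags.reindex([str(f) for f in farm_ids], fill_value=False)

    no_aquatic = ~flags["aquatic_any"]
    if no_aquatic.any():
        raise TypologyError(
            "farms with zero aquatic production are outside the sample frame: "
            f"{sorted(flags.index[no_aquatic])}"
        )
    crustacean_only = flags["aquatic_any"] & ~flags["finfish"]
    if crustacean_only.any():
        logger.warning(
            "farms with crustaceans but no finfish, classified by crustacean "
            "presence alone: %s",
            sorted(flags.index[crustacean_only]),
        )

    aquatic, terrestrial = _system_labels(
        flags["prawn"], flags["shrimp"], flags["rice"], flags["vf"]
    )
    return pd.DataFrame(
        {"farm_id": flags.index, "aquatic": aquatic.values, "terrestrial": terrestrial.values}
    ).reset_index(drop=True)


def classify_farm(
    farm_harvests: pd.DataFrame, composition: FoodComposition
) -> FarmingSystem:
    """Classify a single farm's harvest lines."""
    out = classify_farms(farm_harvests, composition)
    if len(out) != 1:
        raise TypologyError("expected harvest lines for exactly one farm")
    row = out.iloc[0]
    return FarmingSystem(aquatic=row["aquatic"], terrestrial=row["terrestrial"])


def contingency_table(classified: pd.DataFrame) -> pd.DataFrame:
    """4 x 4 count table, rows terrestrial x columns aquatic, no margins."""
    table = pd.crosstab(classified["terrestrial"], classified["aquatic"])
    table = table.reindex(
        index=list(TERRESTRIAL_SYSTEMS), columns=list(AQUATIC_SYSTEMS), fill_value=0
    )
    table.index.name = "terrestrial"
    table.columns.name = "aquatic"
    return table.astype(int)


def with_margins(table: pd.DataFrame) -> pd.DataFrame:
    """Append row/column/grand totals (labelled ``total``)."""
    out = table.copy()
    out["total"] = out.sum(axis=1)
    out.loc["total"] = out.sum(axis=0)
    return out


def trim_small_systems(
    classified: pd.DataFrame, max_excluded_cell_size: int = 12
) -> tuple[pd.DataFrame, list[tuple[str, str, int]]]:
    """Drop farms in systems with at most ``max_excluded_cell_size`` members.

    Returns the retained subset and the list of excluded cells as
    ``(aquatic, terrestrial, count)`` (zero-count cells included).
    """
    table = contingency_table(classified)
    excluded: list[tuple[str, str, int]] = []
    small = set()
    for terrestrial in TERRESTRIAL_SYSTEMS:
        for aquatic in AQUATIC_SYSTEMS:
            count = int(table.loc[terrestrial, aquatic])
            if count <= max_excluded_cell_size:
                excluded.append((aquatic, terrestrial, count))
                small.add((aquatic, terrestrial))
    keep = [
        (row.aquatic, row.terrestrial) not in small
        for row in classified.itertuples()
    ]
    retained = classified[keep].reset_index(drop=True)
    logger.info(
        "trimmed %d farms in %d small cells; retained %d",
        len(classified) - len(retained),
        len(small),
        len(retained),
    )
    return retained, excluded


def round_half_up(value: float) -> int:
    """Round to the nearest integer, halves away from zero upward."""
    return int(math.floor(value + 0.5))


def share_of_sample(
    table: pd.DataFrame, predicate: Callable[[str, str], bool]
) -> int:
    """Percentage of the sample in cells matching ``predicate(aquatic, terrestrial)``.

    Rounded half-up to the nearest integer, as printed in the descriptive
    results.
    """
    grand = int(table.values.sum())
    if grand == 0:
        raise TypologyError("empty contingency table")
    matched = sum(
        int(table.loc[t, a])
        for t in TERRESTRIAL_SYSTEMS
        for a in AQUATIC_SYSTEMS
        if predicate(a, t)
    )
    return round_half_up(100.0 * matched / grand)


def integration_rate(table: pd.DataFrame, aquatic: str) -> int:
    """Percentage of an aquatic column integrated with any terrestrial food."""
    if aquatic not in AQUATIC_SYSTEMS:
        raise TypologyError(f"unknown aquatic system {aquatic!r}")
    column_total = int(table[aquatic].sum())
    if column_total == 0:
        raise TypologyError(f"aquatic column {aquatic!r} is empty")
    integrated = column_total - int(table.loc["none", aquatic])
    return round_half_up(100.0 * integrated / column_total)


def assign_subcategory(food_code: str, composition: FoodComposition) -> str:
    """The analytic sub-category (one of 12) of a food."""
    return composition[food_code].subcategory
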