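"""Food-composition reference data.

Maps each food to its edible portion, nutrient concentrations (per 100 g of
edible portion, the food-composition-table convention) and the analytic
sub-category used throughout the typology and regression stages. Seven
nutrients are tracked: energy (kJ), protein (g), calcium (mg), iron (mg),
zinc (mg), vitamin A (µg retinol activity equivalents) and vitamin B12 (unit
configurable, µg by default, carried symbolically so that the composition
table and the RDA set always agree).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

NUTRIENTS: tuple[str, ...] = (
    "energy_kj",
    "protein_g",
    "calcium_mg",
    "iron_mg",
    "zinc_mg",
    "vitamin_a_ug_rae",
    "vitamin_b12",
)

#: CSV column per nutrient (concentrations per 100 g edible portion).
NUTRIENT_COLUMNS: dict[str, str] = {
    "energy_kj": "energy_kj_100g",
    "protein_g": "protein_g_100g",
    "calcium_mg": "calcium_mg_100g",
    "iron_mg": "iron_mg_100g",
    "zinc_mg": "zinc_mg_100g",
    "vitamin_a_ug_rae": "vita_ug_rae_100g",
    "vitamin_b12": "vitb12_100g",
}

AQUATIC_SUBCATEGORIES: tuple[str, ...] = (
    "carp",
    "other_stocked_fish",
    "unstocked_fish",
    "crustaceans",
)
TERRESTRIAL_SUBCATEGORIES: tuple[str, ...] = (
    "rice",
    "leafy_vegetables",
    "vitaminA_rich_vegetables",
    "other_vegetables",
    "root_crops",
    "vitaminA_rich_fruits",
    "other_fruits",
    "nuts_oilseeds",
)
SUBCATEGORIES: tuple[str, ...] = AQUATIC_SUBCATEGORIES + TERRESTRIAL_SUBCATEGORIES
#: Terrestrial sub-categories pooled as "vegetables and fruits" at 3-group level.
VF_SUBCATEGORIES: tuple[str, ...] = tuple(
    s for s in TERRESTRIAL_SUBCATEGORIES if s != "rice"
)

REALMS = ("aquatic", "terrestrial")
SPECIES_FLAGS = ("prawn", "shrimp")

COMPOSITION_SCHEMA: tuple[str, ...] = (
    "food_code",
    "food_name",
    "realm",
    "subcategory",
    "edible_portion",
    *NUTRIENT_COLUMNS.values(),
)


class CompositionError(ValueError):
    """Invalid or inconsistent food-composition data."""


@dataclass(frozen=True)
class NutrientVector:
    """Componentwise amounts of the seven tracked nutrients.

    Units are fixed per component (kJ, g, mg, mg, mg, µg RAE, configured B12
    unit) and never mixed; addition and scalar multiplication are
    componentwise.
    """

    _values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self._values) != len(NUTRIENTS):
            raise CompositionError(
                f"expected {len(NUTRIENTS)} components, got {len(self._values)}"
            )

    @classmethod
    def from_mapping(cls, amounts: Mapping[str, float]) -> "NutrientVector":
        unknown = set(amounts) - set(NUTRIENTS)
        if unknown:
            raise CompositionError(f"unknown nutrients: {sorted(unknown)}")
        return cls(tuple(float(amounts.get(n, 0.0)) for n in NUTRIENTS))

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "NutrientVector":
        return cls(tuple(float(v) for v in values))

    @classmethod
    def zero(cls) -> "NutrientVector":
        return cls((0.0,) * len(NUTRIENTS))

    def as_array(self) -> np.ndarray:
        return np.asarray(self._values, dtype=float)

    def as_series(self) -> pd.Series:
        return pd.Series(self._values, index=list(NUTRIENTS), dtype=float)

    def __getitem__(self, nutrient: str) -> float:
        return self._values[NUTRIENTS.index(nutrient)]

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        return NutrientVector(
            tuple(a + b for a, b in zip(self._values, other._values))
        )

    def __mul__(self, scalar: float) -> "NutrientVector":
        return NutrientVector(tuple(v * float(scalar) for v in self._values))

    __rmul__ = __mul__

    def __iter__(self) -> Iterator[float]:
        return iter(self._values)


#: Recommended dietary allowances for a moderately active adult, per day.
DEFAULT_RDA_VALUES: dict[str, float] = {
    "energy_kj": 9_200.0,
    "protein_g": 55.0,
    "calcium_mg": 1_000.0,
    "iron_mg": 13.0,
    "zinc_mg": 10.0,
    "vitamin_a_ug_rae": 900.0,
    "vitamin_b12": 2.5,
}


@dataclass(frozen=True)
class RdaSet:
    """Daily adult requirements used to normalize nutrient amounts to AEs.

    ``b12_unit`` is carried symbolically; the default (µg) matches the µg
    concentrations of the packaged composition table. A user supplying a
    table in different B12 units must configure the same unit here.
    """

    values: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RDA_VALUES)
    )
    b12_unit: str = "ug"

    def __post_init__(self) -> None:
        missing = set(NUTRIENTS) - set(self.values)
        if missing:
            raise CompositionError(f"RDA missing nutrients: {sorted(missing)}")
        for name in NUTRIENTS:
            if not self.values[name] > 0:
                raise CompositionError(f"RDA for {name} must be positive")

    @classmethod
    def default(cls) -> "RdaSet":
        return cls()

    @classmethod
    def from_config(cls, block: Mapping[str, float] | None) -> "RdaSet":
        """Build from a YAML ``rda:`` block of overrides (may be empty)."""
        values = dict(DEFAULT_RDA_VALUES)
        b12_unit = "ug"
        if block:
            block = dict(block)
            b12_unit = str(block.pop("vitamin_b12_unit", b12_unit))
            unknown = set(block) - set(NUTRIENTS)
            if unknown:
                raise CompositionError(f"unknown RDA keys: {sorted(unknown)}")
            values.update({k: float(v) for k, v in block.items()})
        return cls(values=values, b12_unit=b12_unit)

    def __getitem__(self, nutrient: str) -> float:
        return float(self.values[nutrient])

    def as_array(self) -> np.ndarray:
        return np.asarray([self.values[n] for n in NUTRIENTS], dtype=float)


@dataclass(frozen=True)
class FoodCompositionEntry:
    """One food of the composition reference."""

    food_code: str
    food_name: str
    realm: str
    subcategory: str
    edible_portion: float
    nutrients_per_100g_edible: NutrientVector
    species_flag: str | None = None  # "prawn"/"shrimp" on crustacean entries

    def __post_init__(self) -> None:
        if self.realm not in REALMS:
            raise CompositionError(
                f"{self.food_code}: realm must be one of {REALMS}, got {self.realm!r}"
            )
        if self.subcategory not in SUBCATEGORIES:
            raise CompositionError(
                f"{self.food_code}: unknown subcategory {self.subcategory!r}; "
                f"valid labels: {', '.join(SUBCATEGORIES)}"
            )
        expected_realm = (
            "aquatic" if self.subcategory in AQUATIC_SUBCATEGORIES else "terrestrial"
        )
        if self.realm != expected_realm:
            raise CompositionError(
                f"{self.food_code}: subcategory {self.subcategory!r} implies realm "
                f"{expected_realm!r} but entry declares {self.realm!r}"
            )
        if not 0.0 <= self.edible_portion <= 1.0:
            raise CompositionError(
                f"{self.food_code}: edible_portion must lie in [0, 1], "
                f"got {self.edible_portion}"
            )
        if any(v < 0 for v in self.nutrients_per_100g_edible):
            raise CompositionError(
                f"{self.food_code}: nutrient concentrations must be non-negative"
            )
        if self.species_flag is not None and self.species_flag not in SPECIES_FLAGS:
            raise CompositionError(
                f"{self.food_code}: species_flag must be one of {SPECIES_FLAGS}"
            )

    @property
    def nutrients_per_kg_whole(self) -> NutrientVector:
        """Nutrients in 1 kg of whole (as-produced) product.

        Per-100 g-edible concentrations scale by 10 to per-kg-edible, then by
        the edible portion to the whole-product basis.
        """
        return self.nutrients_per_100g_edible * (10.0 * self.edible_portion)


class FoodComposition:
    """Validated collection of :class:`FoodCompositionEntry`, keyed by code."""

    def __init__(self, entries: Iterable[FoodCompositionEntry]):
        self._entries: dict[str, FoodCompositionEntry] = {}
        for entry in entries:
            if entry.food_code in self._entries:
                raise CompositionError(f"duplicate food_code: {entry.food_code!r}")
            self._entries[entry.food_code] = entry
        self._frame: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, food_code: str) -> bool:
        return food_code in self._entries

    def __getitem__(self, food_code: str) -> FoodCompositionEntry:
        try:
            return self._entries[food_code]
        except KeyError:
            raise CompositionError(f"unknown food_code: {food_code!r}") from None

    def __iter__(self) -> Iterator[FoodCompositionEntry]:
        return iter(self._entries.values())

    @property
    def food_codes(self) -> list[str]:
        return list(self._entries)

    def foods_in_subcategory(self, subcategory: str) -> list[str]:
        return [e.food_code for e in self if e.subcategory == subcategory]

    @property
    def frame(self) -> pd.DataFrame:
        """Tabular view with whole-product nutrient densities per kg.

        Columns: the schema fields plus ``density_<nutrient>`` giving the
        nutrient content of 1 kg of whole product (edible portion applied).
        """
        if self._frame is None:
            rows = []
            for e in self:
                row = {
                    "food_code": e.food_code,
                    "food_name": e.food_name,
                    "realm": e.realm,
                    "subcategory": e.subcategory,
                    "edible_portion": e.edible_portion,
                    "species_flag": e.species_flag,
                }
                per100 = e.nutrients_per_100g_edible
                for n in NUTRIENTS:
                    row[NUTRIENT_COLUMNS[n]] = per100[n]
                    row[f"density_{n}"] = per100[n] * 10.0 * e.edible_portion
                rows.append(row)
            self._frame = pd.DataFrame(rows)
        return self._frame.copy()


def nutrient_yield(entry: FoodCompositionEntry, quantity_kg: float) -> NutrientVector:
    """Nutrients in ``quantity_kg`` of whole product of one food.

    The as-produced weight is reduced to its edible portion and multiplied by
    the per-kg-edible concentrations; linear in ``quantity_kg``.
    """
    if quantity_kg < 0:
        raise CompositionError(f"quantity_kg must be non-negative, got {quantity_kg}")
    return entry.nutrients_per_kg_whole * quantity_kg


def _entry_from_row(row: pd.Series) -> FoodCompositionEntry:
    per100 = NutrientVector.from_mapping(
        {n: float(row[col]) for n, col in NUTRIENT_COLUMNS.items()}
    )
    flag = row.get("species_flag")
    if flag is not None and (pd.isna(flag) or flag == ""):
        flag = None
    return FoodCompositionEntry(
        food_code=str(row["food_code"]),
        food_name=str(row["food_name"]),
        realm=str(row["realm"]),
        subcategory=str(row["subcategory"]),
        edible_portion=float(row["edible_portion"]),
        nutrients_per_100g_edible=per100,
        species_flag=None if flag is None else str(flag),
    )


def load_composition_table(source: str | Path | IO[str]) -> FoodComposition:
    """Load and validate a composition CSV (documented schema, UTF-8).

    Raises :class:`CompositionError` on duplicate codes, out-of-range edible
    portions or unknown sub-category labels. Emits a ``UserWarning`` if a
    terrestrial food declares a positive vitamin B12 concentration, since B12
    occurs only in animal-source foods.
    """
    table = pd.read_csv(source)
    missing = set(COMPOSITION_SCHEMA) - set(table.columns)
    if missing:
        raise CompositionError(f"composition CSV missing columns: {sorted(missing)}")
    if table["food_code"].duplicated().any():
        dupes = sorted(table.loc[table["food_code"].duplicated(), "food_code"])
        raise CompositionError(f"duplicate food_code: {dupes}")
    comp = FoodComposition(_entry_from_row(row) for _, row in table.iterrows())
    offenders = [
        e.food_code
        for e in comp
        if e.realm == "terrestrial" and e.nutrients_per_100g_edible["vitamin_b12"] > 0
    ]
    if offenders:
        warnings.warn(
            "terrestrial foods with positive vitamin B12 concentration "
            f"(B12 occurs only in animal-source foods): {offenders}",
            UserWarning,
            stacklevel=2,
        )
    return comp


def write_composition_table(comp: FoodComposition, path: str | Path | IO[str]) -> None:
    """Write a composition table; round-trips bit-identically with the loader."""
    cols = list(COMPOSITION_SCHEMA) + ["species_flag"]
    frame = comp.frame[cols]
    frame.to_csv(path, index=False)


def default_composition() -> FoodComposition:
    """The packaged 36-food reference table (synthetic, illustrative values)."""
    ref = resources.files("nutriprod.data") / "food_composition.csv"
    with ref.open("r", encoding="utf-8") as fh:
        return load_composition_table(fh)
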