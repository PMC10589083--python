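"""Synthetic survey generator.

Emulates the statistical structure the analysis assumes: 721 aquaculture
farms distributed over the 4 x 4 farming-system grid at the observed cell
frequencies, mean parcel size 0.78 ha, roughly nine aquatic products per
farm and 3.5 horticultural products per producing farm, and average shares
sold of about 71% (aquatic foods), 57% (vegetables and fruits) and 33%
(rice).

Outcomes are generated structurally -- quantities, then prices and nutrient
densities, then productivity -- never by writing a regression outcome
directly. The implied true coefficient of a food group's yield (t/ha) on
each outcome is a constant: the group-mean whole-product nutrient density
(scaled to AE units) for nutrient outcomes, or the group-mean price for the
economic outcome. Within-group food-mix variation (symmetric inclusion plus
symmetric Dirichlet weights, so every food's expected weight is exactly
1/m), farm-level price noise and cost noise are the exogenous error
channels, which makes OLS on the generated data unbiased for the recorded
ground truth. Upazila offsets enter through production costs, i.e. the
economic outcome carries true fixed effects and the nutrient outcomes carry
none.

Randomness: a single master seed keys a Philox counter-based generator;
farm ``i`` always draws from jump ``i + 1`` of that stream, so enlarging a
survey never perturbs the farms already generated.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .composition import (
    NUTRIENTS,
    FoodComposition,
    RdaSet,
    default_composition,
)
from .regression import OUTCOMES
from .survey import SurveyDataset, validate_survey, write_survey
from .typology import AQUATIC_SYSTEMS, TERRESTRIAL_SYSTEMS

_FINFISH_GROUPS = ("carp", "other_stocked_fish", "unstocked_fish")
_VF_GROUPS = (
    "leafy_vegetables",
    "vitaminA_rich_vegetables",
    "other_vegetables",
    "root_crops",
    "vitaminA_rich_fruits",
    "other_fruits",
    "nuts_oilseeds",
)

#: Mean unit price (US$/kg whole product) per food in the default generator.
DEFAULT_PRICES: dict[str, float] = {
    "catla": 2.0,
    "rohu": 1.8,
    "mrigal": 1.4,
    "silver_carp": 1.1,
    "common_carp": 1.3,
    "tilapia": 1.1,
    "pangas": 0.9,
    "koi": 1.6,
    "shing": 3.0,
    "mola": 2.2,
    "tengra": 2.6,
    "puti": 1.5,
    "taki": 1.8,
    "golda": 7.0,
    "bagda": 7.0,
    "rice_aman": 0.30,
    "rice_boro": 0.30,
    "red_amaranth": 0.35,
    "spinach": 0.30,
    "kalmi": 0.25,
    "pumpkin": 0.30,
    "carrot": 0.45,
    "okra": 0.45,
    "bottle_gourd": 0.30,
    "bitter_gourd": 0.55,
    "long_bean": 0.50,
    "eggplant": 0.40,
    "potato": 0.25,
    "taro": 0.35,
    "mango_ripe": 0.80,
    "papaya_ripe": 0.45,
    "banana": 0.45,
    "guava": 0.50,
    "jujube": 0.60,
    "coconut_mature": 0.55,
    "mustard_seed": 1.10,
}

#: Per-group yield distributions, kg of whole product per parcel hectare.
DEFAULT_YIELDS: dict[str, tuple[float, float]] = {
    "carp": (1400.0, 0.5),
    "other_stocked_fish": (900.0, 0.5),
    "unstocked_fish": (250.0, 0.6),
    "crustaceans": (300.0, 0.5),
    "rice": (4000.0, 0.3),
    "leafy_vegetables": (600.0, 0.6),
    "vitaminA_rich_vegetables": (800.0, 0.6),
    "other_vegetables": (1500.0, 0.6),
    "root_crops": (1200.0, 0.6),
    "vitaminA_rich_fruits": (800.0, 0.6),
    "other_fruits": (1000.0, 0.6),
    "nuts_oilseeds": (500.0, 0.6),
}

#: Probability a producing farm includes each individual food of a group.
DEFAULT_FOOD_INCLUSION: dict[str, float] = {
    "carp": 0.75,
    "other_stocked_fish": 0.60,
    "unstocked_fish": 0.70,
    "crustaceans": 1.0,  # forced by the farming system
    "rice": 0.70,
    "leafy_vegetables": 0.50,
    "vitaminA_rich_vegetables": 0.55,
    "other_vegetables": 0.45,
    "root_crops": 0.50,
    "vitaminA_rich_fruits": 0.50,
    "other_fruits": 0.45,
    "nuts_oilseeds": 0.50,
}

#: Probability a farm produces each finfish group (crustaceans follow the system).
DEFAULT_FINFISH_GROUP_PROB: dict[str, float] = {
    "carp": 0.96,
    "other_stocked_fish": 0.82,
    "unstocked_fish": 0.83,
}

#: Probability a vegetables/fruits-integrated farm produces each VF group.
DEFAULT_VF_GROUP_PROB: dict[str, float] = {
    "leafy_vegetables": 0.50,
    "vitaminA_rich_vegetables": 0.45,
    "other_vegetables": 0.70,
    "root_crops": 0.15,
    "vitaminA_rich_fruits": 0.30,
    "other_fruits": 0.50,
    "nuts_oilseeds": 0.25,
}


def load_reference_system_counts() -> pd.DataFrame:
    """The published 4 x 4 sample-distribution counts (terrestrial x aquatic)."""
    ref = resources.files("nutriprod.data") / "system_counts.csv"
    with ref.open("r", encoding="utf-8") as fh:
        long = pd.read_csv(fh)
    table = long.pivot(index="terrestrial", columns="aquatic", values="count")
    table = table.reindex(
        index=list(TERRESTRIAL_SYSTEMS), columns=list(AQUATIC_SYSTEMS)
    )
    table.index.name = "terrestrial"
    table.columns.name = "aquatic"
    return table.astype(int)


def generate_reference_typology() -> pd.DataFrame:
    """721 classified farms tabulating cell-for-cell to the published counts."""
    counts = load_reference_system_counts()
    rows = []
    i = 0
    for terrestrial in TERRESTRIAL_SYSTEMS:
        for aquatic in AQUATIC_SYSTEMS:
            for _ in range(int(counts.loc[terrestrial, aquatic])):
                i += 1
                rows.append(
                    {
                        "farm_id": f"rt_{i:04d}",
                        "aquatic": aquatic,
                        "terrestrial": terrestrial,
                    }
                )
    return pd.DataFrame(rows)


class ShareSoldParams(BaseModel):
    """Zero-inflated Beta for the farm x food share of production sold."""

    model_config = ConfigDict(frozen=True)

    zero_prob: float = Field(ge=0.0, lt=1.0)
    beta_mean: float = Field(gt=0.0, lt=1.0)
    beta_concentration: float = Field(gt=0.0)

    @property
    def mean(self) -> float:
        return (1.0 - self.zero_prob) * self.beta_mean


DEFAULT_SHARE_SOLD: dict[str, ShareSoldParams] = {
    "aquatic": ShareSoldParams(zero_prob=0.05, beta_mean=0.7474, beta_concentration=8.0),
    "vegetables_fruits": ShareSoldParams(
        zero_prob=0.20, beta_mean=0.7125, beta_concentration=6.0
    ),
    "rice": ShareSoldParams(zero_prob=0.45, beta_mean=0.60, beta_concentration=6.0),
}


class GeneratorConfig(BaseModel):
    """All tunable parameters of the survey generator.

    Defaults are the study conditions: 721 farms at the published cell
    frequencies ("exact" largest-remainder assignment, so the default survey
    trims to exactly 700), mean parcel size 0.78 ha, and share-sold means of
    0.71 / 0.57 / 0.33 for aquatic foods / vegetables and fruits / rice.
    """

    model_config = ConfigDict(frozen=True)

    n_farms: int = Field(default=721, ge=1)
    cell_assignment: Literal["exact", "multinomial"] = "exact"
    cell_probabilities: dict[str, dict[str, float]] | None = None  # terrestrial->aquatic
    mean_farm_size_ha: float = Field(default=0.78, gt=0.0)
    farm_size_sigma_log: float = Field(default=0.5, gt=0.0)
    n_upazilas: int = Field(default=10, ge=1)
    yields: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_YIELDS)
    )
    food_inclusion_prob: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_FOOD_INCLUSION)
    )
    finfish_group_prob: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_FINFISH_GROUP_PROB)
    )
    vf_group_prob: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_VF_GROUP_PROB)
    )
    dirichlet_concentration: float = Field(default=4.0, gt=0.0)
    prices: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_PRICES))
    price_sigma_log: float = Field(default=0.2, ge=0.0)
    share_sold: dict[str, ShareSoldParams] = Field(
        default_factory=lambda: dict(DEFAULT_SHARE_SOLD)
    )
    cost_base_usd_per_ha: float = Field(default=1500.0, ge=0.0)
    cost_upazila_sd: float = Field(default=300.0, ge=0.0)
    cost_noise_sd: float = Field(default=400.0, ge=0.0)

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        for group, (mean, sigma) in self.yields.items():
            if mean <= 0 or sigma <= 0:
                raise ValueError(f"yield parameters for {group} must be positive")
        for name, p in {
            **self.food_inclusion_prob,
            **self.finfish_group_prob,
            **self.vf_group_prob,
        }.items():
            if not 0.0 < p <= 1.0:
                raise ValueError(f"inclusion probability for {name} not in (0, 1]")
        if any(p <= 0 for p in self.prices.values()):
            raise ValueError("all price means must be positive")
        if self.cell_probabilities is not None:
            total = sum(
                p for row in self.cell_probabilities.values() for p in row.values()
            )
            if any(
                p < 0
                for row in self.cell_probabilities.values()
                for p in row.values()
            ):
                raise ValueError("cell probabilities must be non-negative")
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"cell probabilities sum to {total}, expected 1")
        return self

    def cell_probability_vector(self) -> tuple[list[tuple[str, str]], np.ndarray]:
        """(terrestrial, aquatic) cells in fixed order with their probabilities."""
        cells = [(t, a) for t in TERRESTRIAL_SYSTEMS for a in AQUATIC_SYSTEMS]
        if self.cell_probabilities is None:
            counts = load_reference_system_counts()
            probs = np.array(
                [counts.loc[t, a] for t, a in cells], dtype=float
            )
            probs /= probs.sum()
        else:
            probs = np.array(
                [self.cell_probabilities.get(t, {}).get(a, 0.0) for t, a in cells]
            )
        return cells, probs


@dataclass
class GroundTruth:
    """What the generator knows that the analyst must recover."""

    beta_true: pd.DataFrame  # index: 12 subcategories, columns: 8 outcomes
    fe_cost_offsets: dict[str, float]  # upazila -> cost offset (US$/ha)
    assignments: pd.DataFrame  # farm_id, aquatic, terrestrial
    seed: int
    config: dict

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "beta_true": {
                outcome: {
                    group: float(self.beta_true.loc[group, outcome])
                    for group in self.beta_true.index
                }
                for outcome in self.beta_true.columns
            },
            "fe_cost_offsets": {k: float(v) for k, v in self.fe_cost_offsets.items()},
            "assignments": self.assignments.to_dict(orient="records"),
            "config": self.config,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


@dataclass
class SyntheticSurvey:
    dataset: SurveyDataset
    ground_truth: GroundTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "farms": out / "farms.csv",
            "harvests": out / "harvests.csv",
            "ground_truth": out / "ground_truth.yaml",
        }
        write_survey(self.dataset, paths["farms"], paths["harvests"])
        self.ground_truth.to_yaml(paths["ground_truth"])
        return paths


def compute_beta_true(
    composition: FoodComposition,
    prices: Mapping[str, float],
    rda: RdaSet,
) -> pd.DataFrame:
    """Structural yield coefficients implied by composition and mean prices.

    For a group yield measured in t/ha, one extra tonne of the group (at the
    expected within-group mix, 1/m per food) adds ``1000 x mean(price)``
    dollars of value per hectare, and ``10000 x mean(EP x conc) / (RDA x
    365)`` annual AEs of each nutrient per hectare.
    """
    frame = composition.frame
    rda_annual = rda.as_array() * 365.0
    rows = {}
    for subcat, sub in frame.groupby("subcategory"):
        mean_price = float(np.mean([prices[f] for f in sub["food_code"]]))
        densities = sub[[f"density_{n}" for n in NUTRIENTS]].to_numpy().mean(axis=0)
        row = {"economic_usd_per_ha": 1000.0 * mean_price}
        for j, n in enumerate(NUTRIENTS):
            row[f"ae_{n}"] = 1000.0 * densities[j] / rda_annual[j]
        rows[subcat] = row
    beta = pd.DataFrame(rows).T.loc[:, list(OUTCOMES)]
    beta.index.name = "subcategory"
    return beta


def _assign_cells(
    config: GeneratorConfig, rng: np.random.Generator
) -> list[tuple[str, str]]:
    cells, probs = config.cell_probability_vector()
    n = config.n_farms
    if config.cell_assignment == "multinomial":
        counts = rng.multinomial(n, probs)
    else:
        raw = n * probs
        counts = np.floor(raw).astype(int)
        remainder = raw - counts
        short = n - counts.sum()
        for idx in np.argsort(-remainder, kind="stable")[:short]:
            counts[idx] += 1
    assignment: list[tuple[str, str]] = []
    for cell, count in zip(cells, counts):
        assignment.extend([cell] * int(count))
    return assignment


def _groups_for_farm(
    aquatic: str,
    terrestrial: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> list[str]:
    groups = [g for g in _FINFISH_GROUPS if rng.random() < config.finfish_group_prob[g]]
    if not groups:
        groups = ["carp"]  # every sampled farm stocks fish
    if aquatic != "F":
        groups.append("crustaceans")
    if terrestrial in ("rice", "rice_vf"):
        groups.append("rice")
    if terrestrial in ("vf", "rice_vf"):
        vf = [g for g in _VF_GROUPS if rng.random() < config.vf_group_prob[g]]
        if not vf:
            vf = ["other_vegetables"]
        groups.extend(vf)
    return groups


def _foods_for_group(
    group: str,
    aquatic: str,
    group_foods: Mapping[str, list[str]],
    crustacean_codes: dict[str, str],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> list[str]:
    if group == "crustaceans":
        if aquatic == "FP":
            return [crustacean_codes["prawn"]]
        if aquatic == "FS":
            return [crustacean_codes["shrimp"]]
        return [crustacean_codes["prawn"], crustacean_codes["shrimp"]]
    foods = group_foods[group]
    theta = config.food_inclusion_prob[group]
    picked = [f for f in foods if rng.random() < theta]
    if not picked:
        picked = [foods[rng.integers(len(foods))]]
    return picked


def generate_survey(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    composition: FoodComposition | None = None,
) -> SyntheticSurvey:
    """Generate one deterministic synthetic survey round.

    Same (config, seed) twice gives byte-identical output. The returned
    dataset has already passed the survey validator, so the full pipeline
    runs on it without validation errors.
    """
    config = config or GeneratorConfig()
    composition = composition or default_composition()

    frame = composition.frame
    group_foods: dict[str, list[str]] = {
        g: sorted(sub["food_code"]) for g, sub in frame.groupby("subcategory")
    }
    crust = frame[frame["subcategory"] == "crustaceans"]
    crustacean_codes = {
        str(row.species_flag): str(row.food_code) for row in crust.itertuples()
    }
    for flag in ("prawn", "shrimp"):
        if flag not in crustacean_codes:
            raise ValueError(
                f"composition table lacks a crustacean entry flagged {flag!r}"
            )
    missing_prices = [
        f for f in frame["food_code"] if f not in config.prices
    ]
    if missing_prices:
        raise ValueError(f"price means missing for foods: {missing_prices}")

    base = np.random.Philox(key=seed)
    global_rng = np.random.Generator(base.jumped(0))
    cells = _assign_cells(config, global_rng)
    upazila_ids = [f"u{k:02d}" for k in range(config.n_upazilas)]
    fe_offsets = dict(
        zip(upazila_ids, global_rng.normal(0.0, config.cost_upazila_sd, config.n_upazilas))
    )

    area_mu = np.log(config.mean_farm_size_ha) - config.farm_size_sigma_log**2 / 2.0
    price_mu = {
        f: np.log(p) - config.price_sigma_log**2 / 2.0
        for f, p in config.prices.items()
    }

    farm_rows: list[dict] = []
    harvest_rows: list[dict] = []
    for i, (terrestrial, aquatic) in enumerate(cells):
        rng = np.random.Generator(base.jumped(i + 1))
        farm_id = f"f{i + 1:05d}"
        upazila = upazila_ids[int(rng.integers(config.n_upazilas))]
        area = float(rng.lognormal(area_mu, config.farm_size_sigma_log))
        if terrestrial == "none":
            pond, land = area, 0.0
        else:
            pond_share = float(rng.beta(4.0, 3.0))
            pond = max(pond_share * area, 1e-3)
            land = area - pond

        covariates = {
            "head_age": float(np.clip(round(rng.normal(46.0, 12.0)), 21, 90)),
            "head_education": float(min(int(rng.poisson(5.0)), 16)),
            "head_female": float(rng.random() < 0.10),
            "n_members": float(1 + int(rng.poisson(3.5))),
            "dependency_ratio": round(float(rng.gamma(2.0, 0.35)), 3),
            "off_farm_income": float(rng.random() < 0.5),
            "travel_time_city": round(
                float(rng.lognormal(np.log(60.0) - 0.5**2 / 2.0, 0.5)), 1
            ),
        }

        for group in _groups_for_farm(aquatic, terrestrial, config, rng):
            mean_kg_ha, sigma = config.yields[group]
            group_kg = area * float(
                rng.lognormal(np.log(mean_kg_ha) - sigma**2 / 2.0, sigma)
            )
            foods = _foods_for_group(
                group, aquatic, group_foods, crustacean_codes, config, rng
            )
            weights = rng.dirichlet(
                np.full(len(foods), config.dirichlet_concentration)
            )
            realm = "aquatic" if group in (*_FINFISH_GROUPS, "crustaceans") else None
            group3 = (
                "aquatic"
                if realm == "aquatic"
                else ("rice" if group == "rice" else "vegetables_fruits")
            )
            sold_params = config.share_sold[group3]
            for food, w in zip(foods, weights):
                quantity = group_kg * float(w)
                if rng.random() < sold_params.zero_prob:
                    share = 0.0
                else:
                    a = sold_params.beta_mean * sold_params.beta_concentration
                    b = (1.0 - sold_params.beta_mean) * sold_params.beta_concentration
                    share = float(rng.beta(a, b))
                sold = share * quantity
                price = float(rng.lognormal(price_mu[food], config.price_sigma_log))
                harvest_rows.append(
                    {
                        "farm_id": farm_id,
                        "food_code": food,
                        "quantity_kg": quantity,
                        "quantity_sold_kg": sold,
                        "sales_value_usd": sold * price,
                    }
                )

        cost_per_ha = max(
            config.cost_base_usd_per_ha
            + fe_offsets[upazila]
            + float(rng.normal(0.0, config.cost_noise_sd)),
            50.0,
        )
        farm_rows.append(
            {
                "farm_id": farm_id,
                "upazila_id": upazila,
                **covariates,
                "land_ha": land,
                "pond_ha": pond,
                "production_costs_usd": cost_per_ha * area,
            }
        )

    dataset = validate_survey(pd.DataFrame(farm_rows), pd.DataFrame(harvest_rows))
    assignments = pd.DataFrame(
        {
            "farm_id": [r["farm_id"] for r in farm_rows],
            "aquatic": [a for (_, a) in cells],
            "terrestrial": [t for (t, _) in cells],
        }
    )
    truth = GroundTruth(
        beta_true=compute_beta_true(composition, config.prices, RdaSet.default()),
        fe_cost_offsets=fe_offsets,
        assignments=assignments,
        seed=int(seed),
        config=config.model_dump(mode="json"),
    )
    return SyntheticSurvey(dataset=dataset, ground_truth=truth)
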