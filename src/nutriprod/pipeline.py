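"""Pipeline orchestration and reporting tables.

Runs validate -> classify -> trim -> price -> productivity -> regress ->
summarize over one survey round and emits tidy CSV tables mirroring the
descriptive figures (per-system quantities and shares sold; economic value
by food group; economic productivity overlaid with the seven nutrient AE
series; nutrient shares by food group) plus the regression table. Outputs
are deterministic given inputs and config; the config is snapshotted into
the output directory for provenance. Plot rendering is deliberately out of
scope: the tables are the contract.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .composition import RdaSet, default_composition, load_composition_table
from .productivity import (
    AE_COLUMNS,
    build_price_book,
    compute_productivity,
    system_summaries,
)
from .regression import run_regressions
from .survey import load_survey
from .typology import classify_farms, contingency_table, trim_small_systems, with_margins

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Everything one pipeline run depends on."""

    model_config = ConfigDict(frozen=True)

    farms_csv: str
    harvests_csv: str
    composition_csv: str | None = None  # packaged default table when None
    rda: dict[str, float] | None = None  # overrides for the rda: block
    trim_threshold: int = Field(default=12, ge=0)
    se_flavor: str = "nonrobust"
    out_dir: str = "results"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def figure_tables(summaries: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Tidy per-system tables mirroring the descriptive figures.

    ``fig1``: mean kg/ha produced and share sold (%) per system x food
    group. ``fig2``: mean production value (US$/ha) per system x food group.
    ``fig3``: economic productivity overlaid with the seven AE series per
    system. ``nutrient_shares``: percentage of each nutrient's AEs derived
    from each food group, summing to 100 within system x nutrient.
    """
    by_group = summaries["by_group3"]
    systems = summaries["systems"]

    fig1 = by_group[
        ["aquatic", "terrestrial", "group3", "mean_kg_per_ha", "share_sold_mean"]
    ].copy()
    fig1["share_sold_pct"] = 100.0 * fig1.pop("share_sold_mean")

    fig2 = by_group[
        ["aquatic", "terrestrial", "group3", "mean_value_usd_per_ha"]
    ].copy()

    fig3 = systems[
        ["aquatic", "terrestrial", "n_farms", "mean_economic_usd_per_ha"]
        + [f"mean_{c}" for c in AE_COLUMNS]
    ].copy()

    long = by_group.melt(
        id_vars=["aquatic", "terrestrial", "group3"],
        value_vars=[f"mean_{c}" for c in AE_COLUMNS],
        var_name="nutrient",
        value_name="mean_ae_per_ha",
    )
    long["nutrient"] = long["nutrient"].str.replace("mean_ae_", "", regex=False)
    totals = long.groupby(["aquatic", "terrestrial", "nutrient"])[
        "mean_ae_per_ha"
    ].transform("sum")
    long["share_pct"] = (
        100.0 * long["mean_ae_per_ha"] / totals.where(totals > 0)
    ).fillna(0.0)
    return {"fig1": fig1, "fig2": fig2, "fig3": fig3, "nutrient_shares": long}


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline and write the output bundle.

    Pre-flight checks every input path before any output is written, so a
    missing file never leaves partial outputs behind. Returns the paths of
    the emitted tables.
    """
    logging.basicConfig(level=config.log_level)
    inputs = [config.farms_csv, config.harvests_csv]
    if config.composition_csv is not None:
        inputs.append(config.composition_csv)
    missing = [p for p in inputs if not Path(p).is_file()]
    if missing:
        raise FileNotFoundError(f"pre-flight: missing input files: {missing}")

    run_id = hashlib.sha256(
        b"|".join(Path(p).read_bytes() for p in inputs)
    ).hexdigest()[:12]

    composition = (
        default_composition()
        if config.composition_csv is None
        else load_composition_table(config.composition_csv)
    )
    rda = RdaSet.from_config(config.rda)
    dataset = load_survey(config.farms_csv, config.harvests_csv)

    classified = classify_farms(
        dataset.harvests, composition, farm_ids=list(dataset.farms["farm_id"])
    )
    table = contingency_table(classified)
    retained, excluded = trim_small_systems(classified, config.trim_threshold)
    logger.info(
        "run %s: %d farms classified, %d retained after trimming cells %s",
        run_id,
        len(classified),
        len(retained),
        excluded,
    )

    price_book = build_price_book(dataset)
    results = compute_productivity(dataset, composition, rda, price_book=price_book)
    summaries = system_summaries(
        dataset,
        retained,
        results,
        composition,
    )
    figures = figure_tables(summaries)
    regressions = run_regressions(
        dataset,
        composition,
        rda,
        trim_threshold=config.trim_threshold,
        se_flavor=config.se_flavor,
        price_book=price_book,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        path = out / f"{name}.csv"
        frame.to_csv(path, index=index)
        paths[name] = path

    _write("contingency_table", with_margins(table), index=True)
    _write("farm_productivity", results.per_farm)
    _write("system_summaries", summaries["systems"])
    _write("fig1_quantities_shares", figures["fig1"])
    _write("fig2_value_by_group", figures["fig2"])
    _write("fig3_econ_and_nutrients", figures["fig3"])
    _write("nutrient_shares_by_group", figures["nutrient_shares"])
    _write("regression_table", regressions.long)
    wide = regressions.wide
    md_lines = ["| term | " + " | ".join(wide.columns) + " |"]
    md_lines.append("|" + " --- |" * (len(wide.columns) + 1))
    for term, row in wide.iterrows():
        md_lines.append(f"| {term} | " + " | ".join(str(v) for v in row) + " |")
    (out / "regression_table.md").write_text("\n".join(md_lines) + "\n")
    paths["regression_table_md"] = out / "regression_table.md"

    snapshot = dict(config.model_dump(), run_id=run_id, n_retained=len(retained))
    (out / "run_config.yaml").write_text(yaml.safe_dump(snapshot, sort_keys=True))
    paths["run_config"] = out / "run_config.yaml"
    return paths
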