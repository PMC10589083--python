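"""Correlates of economic and nutrient productivity.

Eight OLS regressions share one design matrix built on the trimmed sample:
the outcome (economic productivity in US$ ha-1, or one of seven nutrient
productivities in AE ha-1) is regressed on the 12 food-group yields in
tonnes per hectare, three market-orientation indicators (share of aquatic
production sold as a fraction, and 0/1 indicators for having sold vegetables
/fruits and rice), household controls, and subdistrict (upazila) fixed
effects. Coefficients carry the conventional significance marks (a: p<0.10,
b: p<0.05, c: p<0.01) and the three largest statistically significant
food/market coefficients per model are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .composition import FoodComposition, RdaSet
from .productivity import (
    AE_COLUMNS,
    PriceBook,
    ProductivityResults,
    build_price_book,
    compute_productivity,
    group3_of,
)
from .survey import SurveyDataset
from .typology import classify_farms, trim_small_systems

OUTCOMES: tuple[str, ...] = ("economic_usd_per_ha",) + AE_COLUMNS

FOOD_REGRESSORS: tuple[str, ...] = tuple(
    f"yield_{s}_t_ha"
    for s in (
        "carp",
        "other_stocked_fish",
        "unstocked_fish",
        "crustaceans",
        "rice",
        "leafy_vegetables",
        "vitaminA_rich_vegetables",
        "other_vegetables",
        "root_crops",
        "vitaminA_rich_fruits",
        "other_fruits",
        "nuts_oilseeds",
    )
)
MARKET_REGRESSORS: tuple[str, ...] = ("aquatic_sold_share", "sold_fv", "sold_rice")
CONTROLS: tuple[str, ...] = (
    "head_age",
    "head_education",
    "head_female",
    "n_members",
    "dependency_ratio",
    "off_farm_income",
    "travel_time_city",
    "land_ha",
    "pond_ha",
)

SIGNIFICANCE_MARKS = (("c", 0.01), ("b", 0.05), ("a", 0.10))


class RegressionError(ValueError):
    """The design matrix or fit is invalid (rank deficiency, too few rows)."""


@dataclass(frozen=True)
class RegressionResult:
    """One fitted model with its annotations."""

    outcome: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int_95: pd.DataFrame
    rsquared: float
    nobs: int
    se_flavor: str
    marks: dict[str, str] = field(default_factory=dict)
    top3: frozenset = field(default_factory=frozenset)


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Name the columns implicated in a rank deficiency (QR pivot heuristic)."""
    arr = X.to_numpy(dtype=float)
    _, r, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    bad = piv[np.where(diag <= tol)[0]] if len(diag) else []
    deficient = [X.columns[i] for i in np.atleast_1d(bad)]
    return deficient or list(X.columns)


def build_design_matrix(
    dataset: SurveyDataset,
    retained: pd.DataFrame,
    composition: FoodComposition,
    results: ProductivityResults,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outcome block Y (n x 8) and regressor matrix X for the trimmed sample.

    Food-group yields are production summed to the 12 sub-categories,
    converted kg -> t and divided by the farm's total parcel area. One dummy
    per upazila is included, dropping a reference level, plus an intercept.
    """
    farm_ids = retained["farm_id"]
    farms = (
        dataset.farms.set_index("farm_id").loc[farm_ids].reset_index()
    )

    h = dataset.harvests[dataset.harvests["quantity_kg"] > 0]
    h = h[h["farm_id"].isin(set(farm_ids))]
    g = group3_of(composition)
    merged = h.merge(g, on="food_code", how="left")

    yields = (
        merged.groupby(["farm_id", "subcategory"])["quantity_kg"]
        .sum()
        .unstack(fill_value=0.0)
    )
    X = pd.DataFrame(index=farms["farm_id"])
    for col in FOOD_REGRESSORS:
        subcat = col[len("yield_") : -len("_t_ha")]
        kg = (
            yields[subcat].reindex(X.index).fillna(0.0)
            if subcat in yields.columns
            else pd.Series(0.0, index=X.index)
        )
        X[col] = kg / farms.set_index("farm_id")["area_ha"] / 1000.0

    aq = merged[merged["group3"] == "aquatic"].groupby("farm_id")[
        ["quantity_kg", "quantity_sold_kg"]
    ].sum()
    share = (aq["quantity_sold_kg"] / aq["quantity_kg"]).reindex(X.index)
    if share.isna().any():
        missing = sorted(share.index[share.isna()])
        raise RegressionError(f"retained farms without aquatic production: {missing}")
    X["aquatic_sold_share"] = share

    sold = merged[merged["quantity_sold_kg"] > 0]
    sold_fv = set(sold.loc[sold["group3"] == "vegetables_fruits", "farm_id"])
    sold_rice = set(sold.loc[sold["group3"] == "rice", "farm_id"])
    X["sold_fv"] = [1.0 if f in sold_fv else 0.0 for f in X.index]
    X["sold_rice"] = [1.0 if f in sold_rice else 0.0 for f in X.index]

    controls = farms.set_index("farm_id")[list(CONTROLS)].astype(float)
    X = X.join(controls)

    dummies = pd.get_dummies(
        farms.set_index("farm_id")["upazila_id"].astype(str),
        prefix="upazila",
        drop_first=True,
        dtype=float,
    )
    X = X.join(dummies)
    X.insert(0, "const", 1.0)

    if len(X) > X.shape[1]:  # with n <= p deficiency is trivial; ols_fit rejects it
        rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
        if rank < X.shape[1]:
            raise RegressionError(
                f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
                f"suspect columns: {_collinear_columns(X)}"
            )

    Y = (
        results.per_farm.set_index("farm_id")
        .loc[X.index, ["economic_usd_per_ha", *AE_COLUMNS]]
        .copy()
    )
    return Y, X


def ols_fit(
    X: pd.DataFrame, y: pd.Series, se_flavor: str = "nonrobust"
) -> RegressionResult:
    """Ordinary least squares with conventional (default) or HC1 robust SEs."""
    if len(X) <= X.shape[1]:
        raise RegressionError(
            f"need more observations ({len(X)}) than regressors ({X.shape[1]})"
        )
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise RegressionError("singular design matrix")
    if se_flavor not in ("nonrobust", "HC1", "HC2", "HC3"):
        raise RegressionError(f"unknown standard-error flavor {se_flavor!r}")
    model = sm.OLS(np.asarray(y, dtype=float), X.astype(float))
    fit = model.fit() if se_flavor == "nonrobust" else model.fit(cov_type=se_flavor)
    ci = fit.conf_int(alpha=0.05)
    ci.columns = ["low", "high"]
    return RegressionResult(
        outcome=str(y.name) if y.name else "y",
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        conf_int_95=ci,
        rsquared=float(fit.rsquared),
        nobs=int(fit.nobs),
        se_flavor=se_flavor,
    )


def mark_significance_and_top3(
    result: RegressionResult,
    candidates: tuple[str, ...] = FOOD_REGRESSORS + MARKET_REGRESSORS,
) -> RegressionResult:
    """Attach significance marks and flag the top-3 coefficients.

    Marks follow a: p<0.10, b: p<0.05, c: p<0.01 (most stringent wins). The
    top-3 flag goes to the three food/market regressors (controls, fixed
    effects and the constant excluded) with the largest absolute coefficient
    among those significant at p<0.10; ties break by smaller p-value, then
    by column order.
    """
    marks: dict[str, str] = {}
    for term, p in result.pvalues.items():
        mark = ""
        for letter, cut in SIGNIFICANCE_MARKS:
            if p < cut:
                mark = letter
                break
        marks[term] = mark

    present = [c for c in candidates if c in result.params.index]
    significant = [c for c in present if result.pvalues[c] < 0.10]
    ranked = sorted(
        significant,
        key=lambda c: (-abs(result.params[c]), result.pvalues[c], present.index(c)),
    )
    return replace(result, marks=marks, top3=frozenset(ranked[:3]))


@dataclass
class RegressionTable:
    """The eight annotated regressions plus tabular renderings."""

    results: list[RegressionResult]
    long: pd.DataFrame
    wide: pd.DataFrame
    nobs: int


def _long_frame(results: list[RegressionResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for term in res.params.index:
            rows.append(
                {
                    "outcome": res.outcome,
                    "term": term,
                    "coef": res.params[term],
                    "se": res.bse[term],
                    "pvalue": res.pvalues[term],
                    "mark": res.marks.get(term, ""),
                    "top3": term in res.top3,
                    "rsquared": res.rsquared,
                    "nobs": res.nobs,
                }
            )
    return pd.DataFrame(rows)


def _wide_frame(results: list[RegressionResult]) -> pd.DataFrame:
    """Coefficient-over-standard-error layout, marks appended, top-3 bolded."""
    terms = (
        list(FOOD_REGRESSORS) + list(MARKET_REGRESSORS) + ["const"]
    )
    index, data = [], {res.outcome: [] for res in results}
    for term in terms:
        index += [term, f"{term}__se"]
        for res in results:
            coef = res.params[term]
            cell = f"{coef:,.1f}{res.marks.get(term, '')}"
            if term in res.top3:
                cell = f"**{cell}**"
            data[res.outcome].append(cell)
            data[res.outcome].append(f"({res.bse[term]:,.1f})")
    for res in results:
        data[res.outcome].append(f"{res.rsquared:.2f}")
        data[res.outcome].append(str(res.nobs))
    index += ["rsquared", "observations"]
    return pd.DataFrame(data, index=index)


def run_regressions(
    dataset: SurveyDataset,
    composition: FoodComposition,
    rda: RdaSet,
    trim_threshold: int = 12,
    se_flavor: str = "nonrobust",
    price_book: PriceBook | None = None,
) -> RegressionTable:
    """Classify, trim, price, compute productivity and fit the eight models."""
    classified = classify_farms(
        dataset.harvests, composition, farm_ids=list(dataset.farms["farm_id"])
    )
    retained, _ = trim_small_systems(classified, trim_threshold)
    if price_book is None:
        price_book = build_price_book(dataset)
    results = compute_productivity(dataset, composition, rda, price_book=price_book)
    Y, X = build_design_matrix(dataset, retained, composition, results)
    fitted = []
    for outcome in OUTCOMES:
        res = ols_fit(X, Y[outcome].rename(outcome), se_flavor=se_flavor)
        fitted.append(mark_significance_and_top3(res))
    return RegressionTable(
        results=fitted,
        long=_long_frame(fitted),
        wide=_wide_frame(fitted),
        nobs=fitted[0].nobs,
    )
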