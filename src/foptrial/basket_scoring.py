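"""Per-order outcome scoring.

A weekly basket is scaled to per-person-per-day intakes (divide by adult
household members and by seven days) and scored three ways:

* a modified Alternative Healthy Eating Index built from nine of the
  AHEI-2010 components (alcohol and PUFA dropped), each 0–10, maximum 90;
* the serving-weighted average Nutri-Score of the basket (A=5 … E=1);
* nutrient totals and per-serving means, total spend, and kcal per dollar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import Catalog, Category, Order, Participant
from .label_engines import (
    BeverageRuleConfig,
    NutriScoreResult,
    ScoringError,
    grade_product,
)

KCAL_PER_G_FAT = 9.0

#: (worst intake, best intake) anchors for the linearly interpolated
#: components, in per-person-per-day units.  Published AHEI-2010 anchors;
#: whole grains use the 90 g/day (male) anchor for the whole household.
AHEI_ANCHORS: dict[str, tuple[float, float]] = {
    "vegetables": (0.0, 5.0),            # servings/day
    "fruit": (0.0, 4.0),                 # servings/day
    "whole_grains": (0.0, 90.0),         # g/day
    "ssb_juice": (1.0, 0.0),             # servings/day (reversed)
    "nuts_legumes": (0.0, 1.0),          # servings/day
    "red_processed_meat": (1.5, 0.0),    # servings/day (reversed)
    "trans_fat": (4.0, 0.5),             # % of energy (reversed)
    "long_chain_n3": (0.0, 250.0),       # mg/day EPA+DHA
}

AHEI_COMPONENTS = list(AHEI_ANCHORS) + ["sodium"]

MAX_AHEI = 10 * len(AHEI_COMPONENTS)  # 90


class DomainError(ValueError):
    """An argument is outside its scientific domain (e.g. n_adults < 1)."""


@dataclass(frozen=True)
class AheiComponentScore:
    component: str
    intake: float
    score: float


@dataclass
class NutrientSummary:
    totals: dict[str, float]
    per_serving_means: dict[str, float]
    total_spend_sgd: float
    kcal_per_dollar: float
    n_servings: float


@dataclass
class BasketSummary:
    modified_ahei: Optional[float]
    ahei_components: Optional[list[AheiComponentScore]]
    avg_nutriscore: float
    totals: dict[str, float]
    per_serving_means: dict[str, float]
    total_spend_sgd: float
    kcal_per_dollar: float
    n_servings: float


NUTRIENT_FIELDS = {
    "energy_kcal": "energy_kcal_per_100g",
    "sugar_g": "sugar_g_per_100g",
    "fat_g": "fat_g_per_100g",
    "satfat_g": "satfat_g_per_100g",
    "sodium_mg": "sodium_mg_per_100g",
    "fiber_g": "fiber_g_per_100g",
    "protein_g": "protein_g_per_100g",
}


def per_day_per_person(totals: Mapping[str, float], n_adults: int) -> dict[str, float]:
    """Scale weekly household totals to per-person-per-day quantities."""
    if n_adults < 1:
        raise DomainError(f"n_adults must be >= 1, got {n_adults}")
    return {k: v / (n_adults * 7.0) for k, v in totals.items()}


def _interp_score(intake: float, worst: float, best: float) -> float:
    """Linear 0–10 between the worst and best anchors, clipped at both ends."""
    frac = (intake - worst) / (best - worst)
    return 10.0 * min(max(frac, 0.0), 1.0)


def sodium_decile_cutpoints(values: Sequence[float]) -> np.ndarray:
    """Nine decile cut points of per-person-day sodium over a cohort."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DomainError("cannot compute sodium deciles from an empty cohort")
    return np.percentile(arr, np.arange(10, 100, 10))


def sodium_decile_score(intake_mg: float, cutpoints: Sequence[float]) -> float:
    """Decile-based sodium score: lowest decile 10, highest 0, linear between."""
    cut = np.asarray(cutpoints, dtype=float)
    if cut.size != 9:
        raise DomainError(f"sodium scoring needs 9 decile cut points, got {cut.size}")
    decile = int(np.searchsorted(cut, intake_mg, side="right"))  # 0..9
    return 10.0 * (9 - decile) / 9.0


def component_intakes(order: Order, catalog: Catalog, n_adults: int) -> dict[str, float]:
    """Per-person-per-day intakes of each index component for one basket.

    Trans fat is expressed as percent of basket energy (zero-energy baskets
    score 0 % by convention); all other components come straight from the
    per-serving catalog yields.
    """
    raw = {
        "vegetables": 0.0,
        "fruit": 0.0,
        "whole_grains": 0.0,
        "ssb_juice": 0.0,
        "nuts_legumes": 0.0,
        "red_processed_meat": 0.0,
        "transfat_g": 0.0,
        "long_chain_n3": 0.0,
        "sodium": 0.0,
        "energy_kcal": 0.0,
    }
    key_map = {
        "vegetables": "vegetables_servings",
        "fruit": "fruit_servings",
        "whole_grains": "whole_grain_g",
        "ssb_juice": "ssb_juice_servings",
        "nuts_legumes": "nuts_legumes_servings",
        "red_processed_meat": "red_processed_meat_servings",
        "transfat_g": "transfat_g",
        "long_chain_n3": "long_chain_n3_mg",
        "sodium": "sodium_mg",
    }
    for line in order.lines:
        product = catalog[line.product_id]
        if product.ahei_yields is None:
            raise ScoringError(
                f"product {product.product_id!r} carries no AHEI component yields"
            )
        servings = line.quantity * product.servings_per_pack
        for comp, attr in key_map.items():
            raw[comp] += servings * getattr(product.ahei_yields, attr)
        raw["energy_kcal"] += servings * product.panel.per_serving("energy_kcal_per_100g")

    scaled = per_day_per_person(raw, n_adults)
    energy = scaled.pop("energy_kcal")
    transfat_g = scaled.pop("transfat_g")
    scaled["trans_fat"] = (
        100.0 * transfat_g * KCAL_PER_G_FAT / energy if energy > 0 else 0.0
    )
    return scaled


def modified_ahei(
    order: Order,
    catalog: Catalog,
    n_adults: int,
    sodium_deciles: Sequence[float],
) -> tuple[float, list[AheiComponentScore]]:
    """Score one basket on the nine-component modified index (0–90).

    Empty baskets are scored on zero intakes rather than rejected; the
    absence components (SSB, red meat, trans fat) then score 10 and the
    adequacy components 0.
    """
    intakes = component_intakes(order, catalog, n_adults)
    components = []
    for comp, (worst, best) in AHEI_ANCHORS.items():
        components.append(
            AheiComponentScore(comp, intakes[comp], _interp_score(intakes[comp], worst, best))
        )
    components.append(
        AheiComponentScore(
            "sodium", intakes["sodium"], sodium_decile_score(intakes["sodium"], sodium_deciles)
        )
    )
    return sum(c.score for c in components), components


def average_nutriscore(
    order: Order,
    catalog: Catalog,
    grades: Mapping[str, NutriScoreResult],
) -> float:
    """Serving-weighted mean of numeric grades (A=5 … E=1); NaN for empty baskets."""
    num = 0.0
    servings = 0.0
    for line in order.lines:
        product = catalog[line.product_id]
        if line.product_id not in grades:
            raise ScoringError(f"no grade supplied for product {line.product_id!r}")
        s = line.quantity * product.servings_per_pack
        num += s * grades[line.product_id].numeric_value
        servings += s
    if servings == 0:
        return math.nan
    return num / servings


def nutrient_summaries(order: Order, catalog: Catalog) -> NutrientSummary:
    """Totals, serving-weighted per-serving means, spend, and kcal per dollar."""
    totals = {k: 0.0 for k in NUTRIENT_FIELDS}
    servings = 0.0
    spend = 0.0
    for line in order.lines:
        product = catalog[line.product_id]
        s = line.quantity * product.servings_per_pack
        servings += s
        spend += line.quantity * product.price_sgd
        for key, panel_field in NUTRIENT_FIELDS.items():
            totals[key] += s * product.panel.per_serving(panel_field)
    spend = round(spend, 2)
    if servings > 0:
        means = {k: v / servings for k, v in totals.items()}
    else:
        means = {k: math.nan for k in totals}
    kcal_per_dollar = totals["energy_kcal"] / spend if spend > 0 else math.nan
    return NutrientSummary(totals, means, spend, kcal_per_dollar, servings)


def _filter_order(order: Order, catalog: Catalog, stratum: str) -> Order:
    if stratum == "all":
        return order
    target = Category.FOOD if stratum == "foods" else Category.BEVERAGE
    lines = [l for l in order.lines if catalog[l.product_id].category is target]
    return order.model_copy(update={"lines": lines})


def score_basket(
    order: Order,
    catalog: Catalog,
    n_adults: int,
    sodium_deciles: Sequence[float],
    grades: Mapping[str, NutriScoreResult],
    include_ahei: bool = True,
) -> BasketSummary:
    """All per-order outcomes for one validated basket."""
    summary = nutrient_summaries(order, catalog)
    if include_ahei:
        ahei, components = modified_ahei(order, catalog, n_adults, sodium_deciles)
    else:
        ahei, components = None, None
    return BasketSummary(
        modified_ahei=ahei,
        ahei_components=components,
        avg_nutriscore=average_nutriscore(order, catalog, grades),
        totals=summary.totals,
        per_serving_means=summary.per_serving_means,
        total_spend_sgd=summary.total_spend_sgd,
        kcal_per_dollar=summary.kcal_per_dollar,
        n_servings=summary.n_servings,
    )


#: column names of the scored per-order table, in output order
OUTCOME_COLUMNS = (
    ["modified_ahei", "avg_nutriscore"]
    + [f"total_{k}" for k in NUTRIENT_FIELDS]
    + [f"mean_{k}_per_serving" for k in NUTRIENT_FIELDS]
    + ["total_spend_sgd", "kcal_per_dollar"]
)


def score_orders(
    orders: Sequence[Order],
    catalog: Catalog,
    participants: Sequence[Participant],
    beverage_config: Optional[BeverageRuleConfig] = None,
    stratum: str = "all",
    sodium_deciles: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Score every order; one row per participant-shop.

    The sodium component's reference deciles are computed over all
    per-person-day basket sodium values in the cohort unless fixed cut
    points are supplied.  For the foods/beverages strata the index is
    omitted (its components span both groups and are not scored in
    isolation).
    """
    if stratum not in ("all", "foods", "beverages"):
        raise DomainError(f"unknown stratum {stratum!r}")
    include_ahei = stratum == "all"
    by_id = {p.participant_id: p for p in participants}

    grades: dict[str, NutriScoreResult] = {
        p.product_id: grade_product(p, beverage_config) for p in catalog
    }

    filtered = [_filter_order(o, catalog, stratum) for o in orders]

    if include_ahei and sodium_deciles is None:
        sodium_values = []
        for order in filtered:
            n_adults = by_id[order.participant_id].n_adults_in_household
            sodium_values.append(
                component_intakes(order, catalog, n_adults)["sodium"]
            )
        sodium_deciles = sodium_decile_cutpoints(sodium_values)

    rows = []
    for order in filtered:
        participant = by_id[order.participant_id]
        basket = score_basket(
            order,
            catalog,
            participant.n_adults_in_household,
            sodium_deciles if include_ahei else np.zeros(9),
            grades,
            include_ahei=include_ahei,
        )
        row = {
            "participant_id": order.participant_id,
            "shop_index": order.shop_index,
            "condition": order.condition.value,
            "modified_ahei": basket.modified_ahei,
            "avg_nutriscore": basket.avg_nutriscore,
            "total_spend_sgd": basket.total_spend_sgd,
            "kcal_per_dollar": basket.kcal_per_dollar,
            "n_servings": basket.n_servings,
            "post_shop_mood": order.post_shop_mood,
            "post_shop_hunger": order.post_shop_hunger,
            "high_education": None if participant.high_education is None else int(participant.high_education),
            "high_income": None if participant.high_income is None else int(participant.high_income),
        }
        row.update({f"total_{k}": v for k, v in basket.totals.items()})
        row.update({f"mean_{k}_per_serving": v for k, v in basket.per_serving_means.items()})
        rows.append(row)
    frame = pd.DataFrame(rows)
    if not include_ahei:
        frame["modified_ahei"] = math.nan
    return frame
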