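"""Synthetic store, cohort and shopping-trip generator.

Nothing from the original trial's raw data is available, so every pipeline
stage is exercised on generated inputs that reproduce the study's stated
conditions: a store of ~4,000 food and beverage products whose food
Nutri-Score distribution approximates 26/12/26/25/9.8 % A–E and whose
beverages approximate 29/11/3/3/54 % under the modified scoring; a cohort
of 168 recruits with the published demographics; six-sequence permuted-block
randomization; $50–$100 baskets; and the observed completion pattern
(14 recruits placed no order, 7 one, 2 two).

Label effects are injected through a discrete-choice utility so the label,
scoring and analysis stages are genuinely exercised end to end.  The
behavioral model itself is an artifact device — the trial observed real
shoppers and specifies none — and is documented as such.  A direct
outcome-shift helper exists for fast statistical calibration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import (
    AheiYields,
    Catalog,
    Category,
    Condition,
    NutrientPanel,
    Order,
    OrderLine,
    Participant,
    Product,
    validate_order,
)
from .label_engines import (
    BeverageRuleConfig,
    grade_product,
    mtl_colors,
    mtl_numeric,
    nutriscore_food,
)


class GenerationError(RuntimeError):
    """The generator could not satisfy its constraints (bad targets/prices)."""


SEQUENCES: tuple[tuple[Condition, Condition, Condition], ...] = (
    (Condition.CONTROL, Condition.MTL, Condition.NS),
    (Condition.CONTROL, Condition.NS, Condition.MTL),
    (Condition.MTL, Condition.CONTROL, Condition.NS),
    (Condition.MTL, Condition.NS, Condition.CONTROL),
    (Condition.NS, Condition.CONTROL, Condition.MTL),
    (Condition.NS, Condition.MTL, Condition.CONTROL),
)


@dataclass
class TrialConfig:
    """All knobs of the generated trial; defaults are the study's conditions."""

    seed: int
    n_products: int = 4175
    beverage_fraction: float = 832 / 4175
    #: target food grade shares A–E (store's food distribution)
    food_grade_targets: tuple[float, ...] = (0.26, 0.12, 0.26, 0.25, 0.098)
    #: target beverage grade shares A–E under the modified scoring
    beverage_grade_targets: tuple[float, ...] = (0.29, 0.11, 0.03, 0.03, 0.54)
    n_recruited: int = 168
    #: probability a recruit completes 0/1/2/3 shops
    completion_probs: tuple[float, ...] = (14 / 168, 7 / 168, 2 / 168, 145 / 168)
    age_mean: float = 34.69
    age_sd: float = 6.83
    bmi_mean: float = 23.31
    bmi_sd: float = 4.07
    p_female: float = 0.6871
    p_high_education: float = 0.6701
    p_high_income: float = 0.3265
    #: household adult-count distribution (counts 1..4)
    household_adult_probs: tuple[float, ...] = (0.20, 0.55, 0.15, 0.10)
    #: label-effect sizes on choice utility (healthiness taste shift)
    gamma_mtl: float = 0.05
    gamma_ns: float = 0.08
    #: price sensitivity of the choice utility
    theta_price: float = 0.08
    min_spend: float = 50.0
    max_spend: float = 100.0
    beverage_rules: BeverageRuleConfig = dataclass_field(default_factory=BeverageRuleConfig)

    def __post_init__(self):
        for p in (
            self.beverage_fraction,
            self.p_female,
            self.p_high_education,
            self.p_high_income,
            *self.completion_probs,
        ):
            if not 0 <= p <= 1:
                raise GenerationError(f"probability {p} outside [0, 1]")
        if abs(sum(self.completion_probs) - 1) > 1e-9:
            raise GenerationError("completion probabilities must sum to 1")


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators so catalog/cohort/shops are separately
    reproducible from the one trial seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# --- product archetypes ----------------------------------------------------
# Macronutrient ranges per 100 g; energy is derived from macros (4 kcal/g
# carbohydrate and protein, 9 kcal/g fat, 2 kcal/g fiber) so panels are
# internally consistent by construction.

_FOOD_ARCHETYPES: dict[str, dict] = {
    "vegetable": dict(
        sugar=(1, 4), starch=(0, 5), fat=(0, 0.5), sat_ratio=(0.1, 0.3),
        protein=(1, 3), fiber=(2, 5), sodium=(5, 80), fvnl=(85, 100),
        serving=(80, 150), price=(2.0, 7.0),
        yields=dict(vegetables_servings=1.0),
    ),
    "fruit": dict(
        sugar=(8, 14), starch=(0, 2), fat=(0, 0.5), sat_ratio=(0.1, 0.3),
        protein=(0.5, 1.5), fiber=(1.5, 4), sodium=(0, 10), fvnl=(90, 100),
        serving=(80, 150), price=(2.0, 8.0),
        yields=dict(fruit_servings=1.0),
    ),
    "fish": dict(
        sugar=(0, 0.5), starch=(0, 0.5), fat=(1, 8), sat_ratio=(0.2, 0.3),
        protein=(18, 24), fiber=(0, 0), sodium=(50, 120), fvnl=(0, 0),
        serving=(100, 150), price=(5.0, 14.0),
        yields=dict(long_chain_n3_mg=(300, 1500)),
    ),
    "legumes": dict(
        sugar=(0, 2), starch=(10, 18), fat=(0.5, 3), sat_ratio=(0.1, 0.2),
        protein=(6, 9), fiber=(4, 8), sodium=(0, 250), fvnl=(95, 100),
        serving=(80, 130), price=(2.0, 6.0),
        yields=dict(nuts_legumes_servings=1.0),
    ),
    "nuts": dict(
        sugar=(2, 6), starch=(5, 15), fat=(45, 60), sat_ratio=(0.1, 0.18),
        protein=(15, 25), fiber=(5, 10), sodium=(0, 300), fvnl=(95, 100),
        serving=(30, 50), price=(5.0, 12.0),
        yields=dict(nuts_legumes_servings=1.0),
    ),
    "plain_dairy": dict(
        sugar=(4, 6), starch=(0, 1), fat=(1, 3.5), sat_ratio=(0.6, 0.7),
        protein=(3, 5), fiber=(0, 0), sodium=(40, 70), fvnl=(0, 0),
        serving=(100, 250), price=(2.5, 7.0),
        yields=dict(),
    ),
    "bread": dict(
        sugar=(2, 5), starch=(38, 48), fat=(1, 4), sat_ratio=(0.2, 0.4),
        protein=(8, 11), fiber=(3.5, 6), sodium=(300, 450), fvnl=(0, 0),
        serving=(60, 100), price=(2.5, 6.0),
        yields=dict(whole_grain_g=(0.3, 0.7)),  # fraction of serving weight
    ),
    "cereal": dict(
        sugar=(15, 24), starch=(50, 60), fat=(1, 5), sat_ratio=(0.2, 0.4),
        protein=(7, 10), fiber=(5, 9), sodium=(150, 400), fvnl=(0, 0),
        serving=(30, 60), price=(4.0, 9.0),
        yields=dict(whole_grain_g=(0.3, 0.7)),
    ),
    "meat": dict(
        sugar=(0, 1), starch=(0, 1), fat=(8, 18), sat_ratio=(0.35, 0.45),
        protein=(18, 26), fiber=(0, 0), sodium=(60, 600), fvnl=(0, 0),
        serving=(100, 150), price=(6.0, 15.0),
        yields=dict(red_processed_meat_servings=1.0),
    ),
    "processed_meat": dict(
        sugar=(1, 4), starch=(1, 5), fat=(10, 22), sat_ratio=(0.38, 0.45),
        protein=(12, 18), fiber=(0, 0), sodium=(500, 900), fvnl=(0, 0),
        serving=(50, 100), price=(4.0, 10.0), transfat=(0.0, 0.2),
        yields=dict(red_processed_meat_servings=1.0),
    ),
    "sweet_snack": dict(
        sugar=(25, 35), starch=(25, 35), fat=(12, 22), sat_ratio=(0.3, 0.5),
        protein=(4, 7), fiber=(1, 3), sodium=(100, 300), fvnl=(0, 0),
        serving=(25, 60), price=(2.0, 6.0), transfat=(0.0, 0.3),
        yields=dict(),
    ),
    "confectionery": dict(
        sugar=(45, 60), starch=(5, 15), fat=(18, 30), sat_ratio=(0.5, 0.7),
        protein=(4, 7), fiber=(1, 3), sodium=(50, 250), fvnl=(0, 0),
        serving=(25, 50), price=(2.0, 7.0), transfat=(0.0, 0.3),
        yields=dict(),
    ),
}

#: archetypes eligible for each target food grade (rejection-sampled)
_GRADE_ARCHETYPES: dict[str, list[str]] = {
    "A": ["vegetable", "fruit", "fish", "legumes"],
    "B": ["plain_dairy", "bread", "nuts"],
    "C": ["cereal", "meat", "bread"],
    "D": ["processed_meat", "sweet_snack", "meat"],
    "E": ["confectionery", "sweet_snack"],
}

_MAX_GRADE_TRIES = 60


def _uniform(rng: np.random.Generator, bounds) -> float:
    lo, hi = bounds
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def _food_panel(rng: np.random.Generator, spec: dict) -> NutrientPanel:
    sugar = _uniform(rng, spec["sugar"])
    starch = _uniform(rng, spec["starch"])
    fat = _uniform(rng, spec["fat"])
    satfat = fat * _uniform(rng, spec["sat_ratio"])
    protein = _uniform(rng, spec["protein"])
    fiber = _uniform(rng, spec["fiber"])
    sodium = _uniform(rng, spec["sodium"])
    fvnl = _uniform(rng, spec["fvnl"])
    transfat = _uniform(rng, spec.get("transfat", (0.0, 0.0)))
    kcal = 4.0 * (sugar + starch + protein) + 9.0 * fat + 2.0 * fiber
    return NutrientPanel(
        energy_kcal_per_100g=kcal,
        sugar_g_per_100g=sugar,
        fat_g_per_100g=fat,
        satfat_g_per_100g=satfat,
        sodium_mg_per_100g=sodium,
        fiber_g_per_100g=fiber,
        protein_g_per_100g=protein,
        transfat_g_per_100g=transfat,
        fvnl_percent=fvnl,
        serving_size_g=_uniform(rng, spec["serving"]),
    )


def _food_yields(rng: np.random.Generator, spec: dict, panel: NutrientPanel) -> AheiYields:
    kwargs = {}
    for key, value in spec["yields"].items():
        if key == "whole_grain_g":
            kwargs[key] = panel.serving_size_g * _uniform(rng, value)
        elif isinstance(value, tuple):
            kwargs[key] = _uniform(rng, value)
        else:
            kwargs[key] = float(value)
    kwargs["transfat_g"] = panel.per_serving("transfat_g_per_100g")
    kwargs["sodium_mg"] = panel.per_serving("sodium_mg_per_100g")
    return AheiYields(**kwargs)


def _make_food(rng: np.random.Generator, pid: str, target_grade: str) -> Product:
    """Rejection-sample a food panel until the engine assigns the target grade."""
    archetypes = _GRADE_ARCHETYPES[target_grade]
    panel = None
    name = ""
    for _ in range(_MAX_GRADE_TRIES):
        name = archetypes[rng.integers(len(archetypes))]
        spec = _FOOD_ARCHETYPES[name]
        candidate = _food_panel(rng, spec)
        if nutriscore_food(candidate).grade == target_grade:
            panel = candidate
            break
    if panel is None:  # keep the last draw; distribution stays approximate
        panel = candidate
    spec = _FOOD_ARCHETYPES[name]
    return Product(
        product_id=pid,
        name=f"{name} {pid}",
        category=Category.FOOD,
        price_sgd=round(_uniform(rng, spec["price"]), 2),
        servings_per_pack=float(rng.integers(1, 7)),
        panel=panel,
        ahei_yields=_food_yields(rng, spec, panel),
    )


# Beverage sugar (g/100 mL) is drawn band-conditionally so the default
# grading rules reproduce the target distribution: zero-sugar drinks, then
# three low/mid bands, then regular sweetened drinks above the top band.
_BEV_BAND_SUGAR = {"B": (0.5, 3.0), "C": (3.0, 5.0), "D": (5.0, 7.0), "E": (7.0, 14.0)}


def _make_beverage(rng: np.random.Generator, pid: str, target_grade: str) -> Product:
    if target_grade == "A":
        sugar = 0.0
        name = "zero-sugar drink"
    else:
        lo, hi = _BEV_BAND_SUGAR[target_grade]
        sugar = float(rng.uniform(lo, hi))
        if target_grade != "E":
            sugar = min(sugar, hi - 1e-6)
        name = "sweetened drink"
    kcal = 4.0 * sugar + float(rng.uniform(0, 1))
    serving = float(rng.uniform(200, 330))
    panel = NutrientPanel(
        energy_kcal_per_100g=kcal,
        sugar_g_per_100g=sugar,
        sodium_mg_per_100g=float(rng.uniform(0, 40)),
        serving_size_g=serving,
    )
    yields = AheiYields(
        ssb_juice_servings=1.0 if sugar > 0 else 0.0,
        sodium_mg=panel.per_serving("sodium_mg_per_100g"),
    )
    return Product(
        product_id=pid,
        name=f"{name} {pid}",
        category=Category.BEVERAGE,
        price_sgd=round(float(rng.uniform(1.2, 5.0)), 2),
        servings_per_pack=float(rng.integers(1, 7)),
        panel=panel,
        ahei_yields=yields,
    )


def generate_catalog(config: TrialConfig, rng: Optional[np.random.Generator] = None) -> Catalog:
    """Generate the store: foods and beverages with target grade shares."""
    rng = rng or _rngs(config.seed, 3)[0]
    n_bev = int(round(config.n_products * config.beverage_fraction))
    n_food = config.n_products - n_bev
    grades = "ABCDE"

    food_targets = np.asarray(config.food_grade_targets, dtype=float)
    bev_targets = np.asarray(config.beverage_grade_targets, dtype=float)
    if food_targets.min() < 0 or bev_targets.min() < 0:
        raise GenerationError("grade targets must be nonnegative")
    food_targets = food_targets / food_targets.sum()
    bev_targets = bev_targets / bev_targets.sum()

    products = []
    food_grades = rng.choice(list(grades), size=n_food, p=food_targets)
    for i, g in enumerate(food_grades):
        products.append(_make_food(rng, f"F{i:05d}", str(g)))
    bev_grades = rng.choice(list(grades), size=n_bev, p=bev_targets)
    for i, g in enumerate(bev_grades):
        products.append(_make_beverage(rng, f"B{i:05d}", str(g)))
    return Catalog(products)


def generate_participants(
    config: TrialConfig, rng: Optional[np.random.Generator] = None
) -> list[Participant]:
    """Recruit the cohort with the published demographic mix (no sequences yet)."""
    rng = rng or _rngs(config.seed, 3)[1]
    adult_counts = np.arange(1, len(config.household_adult_probs) + 1)
    out = []
    for i in range(config.n_recruited):
        out.append(
            Participant(
                participant_id=f"P{i:04d}",
                n_adults_in_household=int(
                    rng.choice(adult_counts, p=config.household_adult_probs)
                ),
                age_years=float(np.clip(rng.normal(config.age_mean, config.age_sd), 21, 80)),
                bmi_kg_m2=float(np.clip(rng.normal(config.bmi_mean, config.bmi_sd), 15, 50)),
                female=bool(rng.random() < config.p_female),
                high_education=bool(rng.random() < config.p_high_education),
                high_income=bool(rng.random() < config.p_high_income),
            )
        )
    return out


def assign_sequences(
    participants: Sequence[Participant], seed: int | np.random.Generator
) -> list[Participant]:
    """Permuted-block randomization over the six condition orderings.

    Complete blocks contain each sequence exactly once; a final partial
    block draws sequences without replacement, so per-sequence counts never
    differ by more than one within complete block sets.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(participants)
    assignments: list[tuple[Condition, ...]] = []
    while len(assignments) + 6 <= n:
        block = list(SEQUENCES)
        rng.shuffle(block)
        assignments.extend(block)
    remainder = n - len(assignments)
    if remainder:
        idx = rng.choice(6, size=remainder, replace=False)
        assignments.extend(SEQUENCES[i] for i in idx)
    return [
        p.model_copy(update={"sequence": tuple(seq)})
        for p, seq in zip(participants, assignments)
    ]


def _product_arrays(catalog: Catalog, beverage_rules: BeverageRuleConfig):
    ids = catalog.product_ids
    price = np.array([catalog[i].price_sgd for i in ids])
    ns_health = np.array(
        [grade_product(catalog[i], beverage_rules).numeric_value for i in ids], dtype=float
    )
    mtl_health = np.array(
        [mtl_numeric(mtl_colors(catalog[i].panel, catalog[i].category)) for i in ids]
    )
    return ids, price, ns_health, mtl_health


def simulate_shops(
    catalog: Catalog,
    participants: Sequence[Participant],
    config: TrialConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[Order]:
    """Simulate every completed shopping trip.

    Choice model (artifact device, not from the trial): each item draw picks
    product p with probability ∝ exp(a_p + γ_condition·h_c(p) − θ·price_p),
    where a_p is a stable product attractiveness, h_c is the numeric
    Nutri-Score value under the NS condition and a traffic-light color score
    under MTL, and γ_Control = 0.  Items are added one pack at a time among
    those still affordable until the basket reaches the minimum spend; the
    inclusive $[min, max]$ window is then asserted via ``validate_order``.

    Each participant completes 0–3 shops per the configured completion
    pattern (shops are completed in sequence order).  Post-shop mood and
    hunger are 1–5 ordinals.
    """
    rng = rng or _rngs(config.seed, 3)[2]
    ids, price, ns_health, mtl_health = _product_arrays(catalog, config.beverage_rules)
    if price.min() > config.max_spend:
        raise GenerationError("no product is affordable within the spend window")
    attractiveness = rng.normal(0.0, 1.0, size=len(ids))

    base_logit = {
        Condition.CONTROL: attractiveness - config.theta_price * price,
        Condition.MTL: attractiveness - config.theta_price * price + config.gamma_mtl * mtl_health,
        Condition.NS: attractiveness - config.theta_price * price + config.gamma_ns * ns_health,
    }
    probs = {}
    for cond, logit in base_logit.items():
        w = np.exp(logit - logit.max())
        probs[cond] = w / w.sum()

    orders: list[Order] = []
    for participant in participants:
        if participant.sequence is None:
            raise GenerationError(f"participant {participant.participant_id} has no sequence")
        n_shops = int(rng.choice(len(config.completion_probs), p=config.completion_probs))
        for shop_index in range(1, n_shops + 1):
            condition = participant.sequence[shop_index - 1]
            p = probs[condition]
            total = 0.0
            quantities: dict[str, int] = {}
            for _ in range(10_000):
                if total >= config.min_spend:
                    break
                affordable = price <= (config.max_spend - total)
                if not affordable.any():
                    raise GenerationError(
                        "spend window unsatisfiable: no affordable product left"
                    )
                pa = np.where(affordable, p, 0.0)
                pa = pa / pa.sum()
                j = int(rng.choice(len(ids), p=pa))
                quantities[ids[j]] = quantities.get(ids[j], 0) + 1
                total += price[j]
            order = Order(
                participant_id=participant.participant_id,
                shop_index=shop_index,
                condition=condition,
                lines=[
                    OrderLine(product_id=pid, quantity=q) for pid, q in quantities.items()
                ],
                post_shop_mood=int(rng.integers(1, 6)),
                post_shop_hunger=int(rng.integers(1, 6)),
            )
            orders.append(validate_order(order, catalog, config.min_spend, config.max_spend))
    return orders


def simulate_trial(config: TrialConfig):
    """Catalog → cohort → sequences → shops, all from the one seed."""
    cat_rng, cohort_rng, shop_rng = _rngs(config.seed, 3)
    catalog = generate_catalog(config, cat_rng)
    participants = assign_sequences(generate_participants(config, cohort_rng), cohort_rng)
    orders = simulate_shops(catalog, participants, config, shop_rng)
    return catalog, participants, orders


def shift_outcomes(
    summaries: pd.DataFrame,
    outcome: str,
    mtl_shift: float,
    ns_shift: float,
) -> pd.DataFrame:
    """Add known condition effects to a scored table (direct-shift mode).

    Bypasses the choice model: useful for statistical calibration where the
    ground-truth effect on the outcome scale must be exact.
    """
    out = summaries.copy()
    out.loc[out["condition"] == Condition.MTL.value, outcome] += mtl_shift
    out.loc[out["condition"] == Condition.NS.value, outcome] += ns_shift
    return out


def simulate_null_differences(
    n_participants: int,
    rng: np.random.Generator,
    sd_participant: float = 1.0,
    sd_noise: float = 1.0,
    mtl_effect: float = 0.0,
    ns_effect: float = 0.0,
) -> list:
    """Fast generator of first-difference observations with known effects.

    Δ_is = effect(condition) + u_i + e_is with participant effect u_i shared
    by a participant's two differences (both contain the same control shop),
    inducing the within-person correlation the clustered errors must absorb.
    """
    from .crossover import DifferenceObservation

    obs = []
    for i in range(n_participants):
        u = rng.normal(0.0, sd_participant)
        for ns, eff in ((0, mtl_effect), (1, ns_effect)):
            obs.append(
                DifferenceObservation(
                    participant_id=f"S{i:04d}",
                    shop_index=ns + 2,
                    outcome_delta=eff + u + rng.normal(0.0, sd_noise),
                    ns_dummy=ns,
                )
            )
    return obs
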