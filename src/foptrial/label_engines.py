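"""Front-of-pack label engines.

Three engines operate on a :class:`~foptrial.catalog.NutrientPanel`:

* ``nutriscore_food`` — the five-grade (A–E) nutrient-profiling score for
  foods, using the published 2017 point bands of the French scheme (derived
  from the British FSA profiling system).
* ``nutriscore_beverage_modified`` — a transparent sugar-first surrogate for
  the proprietary Singapore HPB beverage scoring: zero-sugar drinks are
  always grade A, other grades come from configurable ascending sugar
  thresholds with an energy-density demotion rule.
* ``mtl_colors`` — UK Multiple Traffic Lights green/amber/red per nutrient,
  per the 2016 front-of-pack technical guidance bands, with per-portion red
  overrides and percent-of-reference-intake values.

All band tables are module constants; treat them as read-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .catalog import Category, NutrientPanel, Product, SALT_G_PER_SODIUM_MG


class ScoringError(ValueError):
    """A panel lacks a field the requested engine needs."""


class CategoryError(ValueError):
    """A product of the wrong category was passed to an engine."""


# --- Nutri-Score (foods) ---------------------------------------------------
# 2017 published point bands, per 100 g.  A value scores the number of
# thresholds it strictly exceeds (">"; boundary values stay in the lower band).

NS_ENERGY_KJ_BANDS = (335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350)
NS_SUGAR_G_BANDS = (4.5, 9.0, 13.5, 18.0, 22.5, 27.0, 31.0, 36.0, 40.0, 45.0)
NS_SATFAT_G_BANDS = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0)
NS_SODIUM_MG_BANDS = (90, 180, 270, 360, 450, 540, 630, 720, 810, 900)
NS_FIBER_G_BANDS = (0.9, 1.9, 2.8, 3.7, 4.7)  # AOAC fiber
NS_PROTEIN_G_BANDS = (1.6, 3.2, 4.8, 6.4, 8.0)

#: final-point upper bounds for grades A..D (foods); above the last is E
NS_GRADE_CUTPOINTS = ((-1, "A"), (2, "B"), (10, "C"), (18, "D"))

GRADE_TO_NUMERIC = {"A": 5, "B": 4, "C": 3, "D": 2, "E": 1}

#: points ≥ this from the negative block suppress the protein bonus unless
#: the fruit/vegetable/nut/legume score is maximal
NS_PROTEIN_EXCLUSION_THRESHOLD = 11


def _band_points(value: float, thresholds: tuple[float, ...]) -> int:
    return sum(value > t for t in thresholds)


def _fvnl_points(percent: float) -> int:
    if percent > 80:
        return 5
    if percent > 60:
        return 2
    if percent > 40:
        return 1
    return 0


def _grade_from_points(final_points: int) -> str:
    for upper, grade in NS_GRADE_CUTPOINTS:
        if final_points <= upper:
            return grade
    return "E"


@dataclass(frozen=True)
class NutriScoreResult:
    negative_points: int
    positive_points: int
    final_points: int
    grade: str

    @property
    def numeric_value(self) -> int:
        """Grade mapped A=5 down to E=1."""
        return GRADE_TO_NUMERIC[self.grade]


def nutriscore_food(panel: NutrientPanel) -> NutriScoreResult:
    """Grade a food from its per-100 g panel.

    Negative points accrue from energy, sugars, saturated fat and sodium
    (0–10 each); positive points from fruit/vegetable/nut/legume content,
    fiber and protein (0–5 each).  Protein is not counted when the negative
    block reaches 11 points without a maximal FVNL score.  The special-case
    rules for cheeses and added fats are deliberately not implemented.
    """
    for name in ("energy_kj_per_100g", "serving_size_g"):
        if getattr(panel, name) is None:
            raise ScoringError(f"panel is missing {name}")

    neg = (
        _band_points(panel.energy_kj_per_100g, NS_ENERGY_KJ_BANDS)
        + _band_points(panel.sugar_g_per_100g, NS_SUGAR_G_BANDS)
        + _band_points(panel.satfat_g_per_100g, NS_SATFAT_G_BANDS)
        + _band_points(panel.sodium_mg_per_100g, NS_SODIUM_MG_BANDS)
    )
    fvnl = _fvnl_points(panel.fvnl_percent)
    fiber = _band_points(panel.fiber_g_per_100g, NS_FIBER_G_BANDS)
    protein = _band_points(panel.protein_g_per_100g, NS_PROTEIN_G_BANDS)
    if neg >= NS_PROTEIN_EXCLUSION_THRESHOLD and fvnl < 5:
        protein = 0
    pos = fvnl + fiber + protein
    final = neg - pos
    return NutriScoreResult(neg, pos, final, _grade_from_points(final))


# --- modified beverage grading ---------------------------------------------

@dataclass(frozen=True)
class BeverageRuleConfig:
    """Sugar-first beverage grading with an energy-density demotion.

    ``sugar_thresholds_g_per_100g`` are inclusive upper bounds for grades
    B, C and D (ascending); anything above the last is E, and zero sugar is
    always A.  A drink whose energy density exceeds the cap for its sugar
    band is demoted one grade (the energy tie-breaker).  Defaults were chosen
    so the default synthetic beverage catalog approximates the trial store's
    29/11/3/3/54 % A–E distribution.
    """

    sugar_thresholds_g_per_100g: tuple[float, float, float] = (3.0, 5.0, 7.0)
    energy_caps_kj_per_100g: tuple[float, float, float] = (120.0, 160.0, 200.0)


DEFAULT_BEVERAGE_RULES = BeverageRuleConfig()

_BEV_GRADE_POINTS = {"A": -1, "B": 0, "C": 3, "D": 11, "E": 19}


def nutriscore_beverage_modified(
    panel: NutrientPanel,
    config: BeverageRuleConfig | None = None,
    category: Category = Category.BEVERAGE,
) -> NutriScoreResult:
    """Grade a beverage: A iff sugar-free, else sugar bands with energy demotion."""
    if category is Category.FOOD:
        raise CategoryError("the modified beverage score applies to beverages only")
    cfg = config or DEFAULT_BEVERAGE_RULES
    sugar = panel.sugar_g_per_100g
    if sugar == 0:
        grade = "A"
    else:
        bands = "BCD"
        grade = "E"
        for letter, upper, cap in zip(
            bands, cfg.sugar_thresholds_g_per_100g, cfg.energy_caps_kj_per_100g
        ):
            if sugar <= upper:
                if panel.energy_kj_per_100g > cap:
                    idx = min("ABCDE".index(letter) + 1, 4)
                    grade = "ABCDE"[idx]
                else:
                    grade = letter
                break
    points = _BEV_GRADE_POINTS[grade]
    return NutriScoreResult(max(points, 0), 0, points, grade)


def grade_product(
    product: Product, beverage_config: BeverageRuleConfig | None = None
) -> NutriScoreResult:
    """Dispatch to the food or beverage engine by product category."""
    if product.category is Category.BEVERAGE:
        return nutriscore_beverage_modified(product.panel, beverage_config)
    return nutriscore_food(product.panel)


# --- Multiple Traffic Lights -----------------------------------------------
# UK 2016 FoP technical guidance.  (green_max, amber_max) per 100 g/mL;
# boundary values are inclusive ("≤ green_max" is green).

MTL_FOOD_BANDS = {
    "fat": (3.0, 17.5),
    "saturates": (1.5, 5.0),
    "sugars": (5.0, 22.5),
    "salt": (0.3, 1.5),
}
MTL_DRINK_BANDS = {
    "fat": (1.5, 8.75),
    "saturates": (0.75, 2.5),
    "sugars": (2.5, 11.25),
    "salt": (0.3, 0.75),
}
#: per-portion red overrides (grams per portion) for portions above 100 g/mL
MTL_FOOD_PORTION_RED = {"fat": 21.0, "saturates": 6.0, "sugars": 27.0, "salt": 1.8}
MTL_DRINK_PORTION_RED = {"fat": 10.5, "saturates": 3.0, "sugars": 13.5, "salt": 0.9}

#: EU adult reference intakes used for the %RI figures on the label
REFERENCE_INTAKES = {
    "energy_kcal": 2000.0,
    "fat": 70.0,
    "saturates": 20.0,
    "sugars": 90.0,
    "salt": 6.0,
}

_PANEL_FIELD = {
    "fat": "fat_g_per_100g",
    "saturates": "satfat_g_per_100g",
    "sugars": "sugar_g_per_100g",
}


@dataclass(frozen=True)
class MtlResult:
    colors: dict[str, str]
    energy_kcal_per_serving: float
    percent_ri: dict[str, float] = field(default_factory=dict)


def mtl_colors(panel: NutrientPanel, category: Category = Category.FOOD) -> MtlResult:
    """Color fat, saturates, sugars and salt for one product.

    Per-100 g/mL bands decide green/amber/red; a large portion (>100 g/mL)
    whose per-portion content exceeds the portion threshold is forced red.
    Salt is derived from sodium at 2.5 g salt per 1000 mg sodium.
    """
    if panel.serving_size_g is None:
        raise ScoringError("serving size required for per-portion traffic-light rules")
    bands = MTL_DRINK_BANDS if category is Category.BEVERAGE else MTL_FOOD_BANDS
    portion_red = (
        MTL_DRINK_PORTION_RED if category is Category.BEVERAGE else MTL_FOOD_PORTION_RED
    )
    portion = panel.serving_size_g

    per100 = {k: getattr(panel, f) for k, f in _PANEL_FIELD.items()}
    per100["salt"] = panel.salt_g_per_100g

    colors = {}
    for nutrient, value in per100.items():
        green_max, amber_max = bands[nutrient]
        if value <= green_max:
            color = "green"
        elif value <= amber_max:
            color = "amber"
        else:
            color = "red"
        per_portion = value * portion / 100.0
        if portion > 100.0 and per_portion > portion_red[nutrient]:
            color = "red"
        colors[nutrient] = color

    per_serving = {k: v * portion / 100.0 for k, v in per100.items()}
    energy_serving = panel.per_serving("energy_kcal_per_100g")
    percent_ri = {
        k: 100.0 * per_serving[k] / REFERENCE_INTAKES[k] for k in per_serving
    }
    percent_ri["energy_kcal"] = 100.0 * energy_serving / REFERENCE_INTAKES["energy_kcal"]
    return MtlResult(colors=colors, energy_kcal_per_serving=energy_serving, percent_ri=percent_ri)


def mtl_numeric(result: MtlResult) -> float:
    """Summarize a traffic-light panel on the 1–5 healthiness scale.

    Greens count +1, reds −1; the net count over the four nutrients is mapped
    linearly so all-green → 5 and all-red → 1.  Used by the shopper simulator
    as the salience signal a traffic-light label conveys.
    """
    net = sum({"green": 1, "amber": 0, "red": -1}[c] for c in result.colors.values())
    return 3.0 + net / 2.0


def annotate_catalog(catalog, beverage_config: BeverageRuleConfig | None = None):
    """Return the catalog as a DataFrame with grade and color columns added."""
    from .catalog import catalog_to_frame

    frame = catalog_to_frame(catalog)
    grades, numerics, colors = [], [], {k: [] for k in MTL_FOOD_BANDS}
    for product in catalog:
        ns = grade_product(product, beverage_config)
        mtl = mtl_colors(product.panel, product.category)
        grades.append(ns.grade)
        numerics.append(ns.numeric_value)
        for k in colors:
            colors[k].append(mtl.colors[k])
    frame["nutriscore_grade"] = grades
    frame["nutriscore_numeric"] = numerics
    for k, v in colors.items():
        frame[f"mtl_{k}"] = v
    return frame
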