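"""Data model and I/O for products, participants and orders.

The store sells foods and beverages; each product carries a nutrient panel
(per 100 g, plus a serving size) and per-serving yields for the diet-quality
index components.  Orders are one participant-shop basket under one labeling
condition.  Tabular I/O is plain comma-separated text with documented
headers so every artifact is inspectable.
"""

from __future__ import annotations

import enum
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

KJ_PER_KCAL = 4.184
#: grams of salt per mg of sodium (NaCl mass ratio), used by the traffic-light engine
SALT_G_PER_SODIUM_MG = 2.5 / 1000.0

DEFAULT_MIN_SPEND = 50.0
DEFAULT_MAX_SPEND = 100.0


class Condition(str, enum.Enum):
    CONTROL = "Control"
    MTL = "MTL"
    NS = "NS"


class Category(str, enum.Enum):
    FOOD = "food"
    BEVERAGE = "beverage"


class CatalogSchemaError(ValueError):
    """A tabular input is missing a required column."""


class CatalogValidationError(ValueError):
    """A row violates a product invariant (names the offending product)."""


class UnknownProductError(KeyError):
    """An order line references a product id absent from the catalog."""


class SpendWindowError(ValueError):
    """Basket total falls outside the allowed spend window."""

    def __init__(self, total: float, min_spend: float, max_spend: float):
        self.total = total
        self.min_spend = min_spend
        self.max_spend = max_spend
        super().__init__(
            f"basket total ${total:.2f} outside spend window "
            f"[${min_spend:.2f}, ${max_spend:.2f}]"
        )


class NutrientPanel(BaseModel):
    """Per-100 g nutrient quantities plus the manufacturer serving size.

    Energy may be supplied in kJ, kcal or both; a missing unit is derived at
    4.184 kJ/kcal and supplying both requires agreement within 2 %.
    """

    energy_kj_per_100g: Optional[float] = None
    energy_kcal_per_100g: Optional[float] = None
    sugar_g_per_100g: float = 0.0
    fat_g_per_100g: float = 0.0
    satfat_g_per_100g: float = 0.0
    sodium_mg_per_100g: float = 0.0
    fiber_g_per_100g: float = 0.0
    protein_g_per_100g: float = 0.0
    transfat_g_per_100g: float = 0.0
    fvnl_percent: float = Field(0.0, le=100.0)
    serving_size_g: float = Field(..., gt=0.0)

    @field_validator(
        "energy_kj_per_100g",
        "energy_kcal_per_100g",
        "sugar_g_per_100g",
        "fat_g_per_100g",
        "satfat_g_per_100g",
        "sodium_mg_per_100g",
        "fiber_g_per_100g",
        "protein_g_per_100g",
        "transfat_g_per_100g",
        "fvnl_percent",
    )
    @classmethod
    def _nonnegative(cls, v, info):
        if v is not None and v < 0:
            raise ValueError(f"{info.field_name} must be >= 0, got {v}")
        return v

    @model_validator(mode="after")
    def _energy_and_fat(self) -> "NutrientPanel":
        kj, kcal = self.energy_kj_per_100g, self.energy_kcal_per_100g
        if kj is None and kcal is None:
            raise ValueError("panel needs energy in kJ or kcal per 100 g")
        if kj is None:
            object.__setattr__(self, "energy_kj_per_100g", kcal * KJ_PER_KCAL)
        elif kcal is None:
            object.__setattr__(self, "energy_kcal_per_100g", kj / KJ_PER_KCAL)
        elif kcal > 0:
            ratio = kj / (kcal * KJ_PER_KCAL)
            if not 0.98 <= ratio <= 1.02:
                raise ValueError(
                    f"energy units disagree: {kj} kJ vs {kcal} kcal "
                    f"(ratio to 4.184 kJ/kcal: {ratio:.3f})"
                )
        if self.satfat_g_per_100g > self.fat_g_per_100g + 1e-9:
            raise ValueError(
                f"saturated fat ({self.satfat_g_per_100g} g) exceeds "
                f"total fat ({self.fat_g_per_100g} g)"
            )
        return self

    def per_serving(self, field: str) -> float:
        """Scale a per-100 g quantity to one serving."""
        return getattr(self, field) * self.serving_size_g / 100.0

    @property
    def salt_g_per_100g(self) -> float:
        return self.sodium_mg_per_100g * SALT_G_PER_SODIUM_MG


class AheiYields(BaseModel):
    """Per-serving contributions of a product to each diet-index component.

    Mapping products to index food groups is a catalog annotation, not an
    inference from product names; the synthetic generator supplies them.
    """

    vegetables_servings: float = Field(0.0, ge=0.0)
    fruit_servings: float = Field(0.0, ge=0.0)
    whole_grain_g: float = Field(0.0, ge=0.0)
    ssb_juice_servings: float = Field(0.0, ge=0.0)
    nuts_legumes_servings: float = Field(0.0, ge=0.0)
    red_processed_meat_servings: float = Field(0.0, ge=0.0)
    transfat_g: float = Field(0.0, ge=0.0)
    long_chain_n3_mg: float = Field(0.0, ge=0.0)
    sodium_mg: float = Field(0.0, ge=0.0)


class Product(BaseModel):
    product_id: str
    name: str = ""
    category: Category
    price_sgd: float = Field(..., gt=0.0)
    servings_per_pack: float = Field(..., gt=0.0)
    panel: NutrientPanel
    ahei_yields: Optional[AheiYields] = None


class Participant(BaseModel):
    participant_id: str
    n_adults_in_household: int = Field(1, ge=1)
    age_years: Optional[float] = None
    bmi_kg_m2: Optional[float] = None
    female: Optional[bool] = None
    high_education: Optional[bool] = None
    high_income: Optional[bool] = None
    sequence: Optional[tuple[Condition, Condition, Condition]] = None

    @field_validator("sequence")
    @classmethod
    def _permutation(cls, v):
        if v is not None and set(v) != {Condition.CONTROL, Condition.MTL, Condition.NS}:
            raise ValueError(f"sequence must be a permutation of the three conditions, got {v}")
        return v


class OrderLine(BaseModel):
    product_id: str
    quantity: int = Field(..., ge=1)


class Order(BaseModel):
    participant_id: str
    shop_index: int = Field(..., ge=1, le=3)
    condition: Condition
    lines: list[OrderLine]
    post_shop_mood: Optional[int] = None
    post_shop_hunger: Optional[int] = None


class Catalog:
    """An ordered collection of products keyed by product_id."""

    def __init__(self, products: Iterable[Product]):
        self._products: dict[str, Product] = {}
        for p in products:
            if p.product_id in self._products:
                raise CatalogValidationError(f"duplicate product_id {p.product_id!r}")
            self._products[p.product_id] = p

    def __len__(self) -> int:
        return len(self._products)

    def __iter__(self) -> Iterator[Product]:
        return iter(self._products.values())

    def __contains__(self, product_id: str) -> bool:
        return product_id in self._products

    def __getitem__(self, product_id: str) -> Product:
        try:
            return self._products[product_id]
        except KeyError:
            raise UnknownProductError(f"product_id {product_id!r} not in catalog") from None

    @property
    def product_ids(self) -> list[str]:
        return list(self._products)


# --- tabular I/O -----------------------------------------------------------

PANEL_COLUMNS = [
    "energy_kcal_per_100g",
    "energy_kj_per_100g",
    "sugar_g_per_100g",
    "fat_g_per_100g",
    "satfat_g_per_100g",
    "sodium_mg_per_100g",
    "fiber_g_per_100g",
    "protein_g_per_100g",
    "transfat_g_per_100g",
    "fvnl_percent",
    "serving_size_g",
]

YIELD_COLUMNS = [
    "ahei_vegetables_servings",
    "ahei_fruit_servings",
    "ahei_whole_grain_g",
    "ahei_ssb_juice_servings",
    "ahei_nuts_legumes_servings",
    "ahei_red_processed_meat_servings",
    "ahei_transfat_g",
    "ahei_long_chain_n3_mg",
    "ahei_sodium_mg",
]

CATALOG_COLUMNS = (
    ["product_id", "name", "category", "price_sgd", "servings_per_pack"]
    + PANEL_COLUMNS
    + YIELD_COLUMNS
)

REQUIRED_CATALOG_COLUMNS = [
    "product_id",
    "category",
    "price_sgd",
    "servings_per_pack",
    "serving_size_g",
]


def catalog_to_frame(catalog: Catalog) -> pd.DataFrame:
    rows = []
    for p in catalog:
        row = {
            "product_id": p.product_id,
            "name": p.name,
            "category": p.category.value,
            "price_sgd": p.price_sgd,
            "servings_per_pack": p.servings_per_pack,
        }
        row.update({c: getattr(p.panel, c) for c in PANEL_COLUMNS})
        y = p.ahei_yields or AheiYields()
        row.update({f"ahei_{k}": getattr(y, k) for k in AheiYields.model_fields})
        rows.append(row)
    return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


def catalog_from_frame(frame: pd.DataFrame) -> Catalog:
    for col in REQUIRED_CATALOG_COLUMNS:
        if col not in frame.columns:
            raise CatalogSchemaError(f"catalog is missing required column {col!r}")
    products = []
    for _, row in frame.iterrows():
        pid = str(row["product_id"])
        panel_kwargs = {
            c: (None if pd.isna(row.get(c)) else float(row[c]))
            for c in PANEL_COLUMNS
            if c in frame.columns
        }
        yield_kwargs = {
            c.removeprefix("ahei_"): float(row[c])
            for c in YIELD_COLUMNS
            if c in frame.columns and not pd.isna(row[c])
        }
        try:
            products.append(
                Product(
                    product_id=pid,
                    name="" if pd.isna(row.get("name")) else str(row.get("name", "")),
                    category=Category(str(row["category"])),
                    price_sgd=float(row["price_sgd"]),
                    servings_per_pack=float(row["servings_per_pack"]),
                    panel=NutrientPanel(**panel_kwargs),
                    ahei_yields=AheiYields(**yield_kwargs) if yield_kwargs else AheiYields(),
                )
            )
        except ValueError as exc:
            raise CatalogValidationError(f"product {pid!r}: {exc}") from exc
    return Catalog(products)


def read_catalog(path) -> Catalog:
    """Read a comma-separated product catalog; row count is preserved."""
    return catalog_from_frame(pd.read_csv(path, dtype={"product_id": str}, float_precision="round_trip"))


def write_catalog(catalog: Catalog, path) -> None:
    catalog_to_frame(catalog).to_csv(path, index=False)


PARTICIPANT_COLUMNS = [
    "participant_id",
    "n_adults_in_household",
    "age_years",
    "bmi_kg_m2",
    "female",
    "high_education",
    "high_income",
    "sequence",
]


def participants_to_frame(participants: Sequence[Participant]) -> pd.DataFrame:
    rows = []
    for p in participants:
        rows.append(
            {
                "participant_id": p.participant_id,
                "n_adults_in_household": p.n_adults_in_household,
                "age_years": p.age_years,
                "bmi_kg_m2": p.bmi_kg_m2,
                "female": None if p.female is None else int(p.female),
                "high_education": None if p.high_education is None else int(p.high_education),
                "high_income": None if p.high_income is None else int(p.high_income),
                "sequence": "|".join(c.value for c in p.sequence) if p.sequence else None,
            }
        )
    return pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS)


def participants_from_frame(frame: pd.DataFrame) -> list[Participant]:
    if "participant_id" not in frame.columns:
        raise CatalogSchemaError("participant table is missing required column 'participant_id'")
    out = []
    for _, row in frame.iterrows():
        seq = row.get("sequence")
        sequence = (
            tuple(Condition(s) for s in str(seq).split("|")) if isinstance(seq, str) else None
        )
        def _opt_bool(key):
            v = row.get(key)
            return None if v is None or pd.isna(v) else bool(int(v))
        def _opt_float(key):
            v = row.get(key)
            return None if v is None or pd.isna(v) else float(v)
        out.append(
            Participant(
                participant_id=str(row["participant_id"]),
                n_adults_in_household=int(row.get("n_adults_in_household", 1)),
                age_years=_opt_float("age_years"),
                bmi_kg_m2=_opt_float("bmi_kg_m2"),
                female=_opt_bool("female"),
                high_education=_opt_bool("high_education"),
                high_income=_opt_bool("high_income"),
                sequence=sequence,
            )
        )
    return out


def read_participants(path) -> list[Participant]:
    return participants_from_frame(pd.read_csv(path, dtype={"participant_id": str}, float_precision="round_trip"))


def write_participants(participants: Sequence[Participant], path) -> None:
    participants_to_frame(participants).to_csv(path, index=False)


ORDER_COLUMNS = [
    "participant_id",
    "shop_index",
    "condition",
    "product_id",
    "quantity",
    "post_shop_mood",
    "post_shop_hunger",
]


def orders_to_frame(orders: Sequence[Order]) -> pd.DataFrame:
    """Long format: one row per order line; survey values repeat per line."""
    rows = []
    for o in orders:
        for line in o.lines:
            rows.append(
                {
                    "participant_id": o.participant_id,
                    "shop_index": o.shop_index,
                    "condition": o.condition.value,
                    "product_id": line.product_id,
                    "quantity": line.quantity,
                    "post_shop_mood": o.post_shop_mood,
                    "post_shop_hunger": o.post_shop_hunger,
                }
            )
    return pd.DataFrame(rows, columns=ORDER_COLUMNS)


def orders_from_frame(frame: pd.DataFrame) -> list[Order]:
    for col in ("participant_id", "shop_index", "condition", "product_id", "quantity"):
        if col not in frame.columns:
            raise CatalogSchemaError(f"orders table is missing required column {col!r}")
    out = []
    for (pid, shop), grp in frame.groupby(["participant_id", "shop_index"], sort=False):
        first = grp.iloc[0]
        def _opt_int(key):
            v = first.get(key)
            return None if v is None or pd.isna(v) else int(v)
        out.append(
            Order(
                participant_id=str(pid),
                shop_index=int(shop),
                condition=Condition(str(first["condition"])),
                lines=[
                    OrderLine(product_id=str(r["product_id"]), quantity=int(r["quantity"]))
                    for _, r in grp.iterrows()
                ],
                post_shop_mood=_opt_int("post_shop_mood"),
                post_shop_hunger=_opt_int("post_shop_hunger"),
            )
        )
    return out


def read_orders(path) -> list[Order]:
    return orders_from_frame(pd.read_csv(path, dtype={"participant_id": str, "product_id": str}, float_precision="round_trip"))


def write_orders(orders: Sequence[Order], path) -> None:
    orders_to_frame(orders).to_csv(path, index=False)


# --- order validation ------------------------------------------------------

def order_total(order: Order, catalog: Catalog) -> float:
    """Basket total in SGD, rounded to cents."""
    total = sum(catalog[line.product_id].price_sgd * line.quantity for line in order.lines)
    return round(total, 2)


def validate_order(
    order: Order,
    catalog: Catalog,
    min_spend: float = DEFAULT_MIN_SPEND,
    max_spend: float = DEFAULT_MAX_SPEND,
) -> Order:
    """Accept an order iff its total lies within the inclusive spend window.

    Raises UnknownProductError for unresolvable lines and SpendWindowError
    (carrying the computed total) for out-of-window baskets.  Idempotent and
    insensitive to line order.
    """
    total = order_total(order, catalog)
    if not (min_spend <= total <= max_spend):
        raise SpendWindowError(total, min_spend, max_spend)
    return order
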