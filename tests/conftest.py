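import numpy as np
import pytest

from foptrial.catalog import (
    AheiYields,
    Catalog,
    Category,
    Condition,
    NutrientPanel,
    Order,
    OrderLine,
    Participant,
    Product,
)


def make_panel(**overrides) -> NutrientPanel:
    base = dict(serving_size_g=100.0)
    if "energy_kj_per_100g" not in overrides and "energy_kcal_per_100g" not in overrides:
        base["energy_kcal_per_100g"] = 100.0
    base.update(overrides)
    return NutrientPanel(**base)


def make_product(
    product_id="X1",
    category=Category.FOOD,
    price=5.0,
    servings_per_pack=2.0,
    yields=None,
    **panel_overrides,
) -> Product:
    return Product(
        product_id=product_id,
        name=f"test {product_id}",
        category=category,
        price_sgd=price,
        servings_per_pack=servings_per_pack,
        panel=make_panel(**panel_overrides),
        ahei_yields=AheiYields(**(yields or {})),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_catalog():
    """Three hand-made products: a food, a zero-sugar drink, a sweet drink."""
    return Catalog(
        [
            make_product("F1", price=10.0, sugar_g_per_100g=4.0, fiber_g_per_100g=3.0,
                         protein_g_per_100g=5.0, fvnl_percent=50.0),
            make_product("B1", category=Category.BEVERAGE, price=2.5,
                         energy_kcal_per_100g=0.5, serving_size_g=250.0,
                         servings_per_pack=6.0),
            make_product("B2", category=Category.BEVERAGE, price=3.0,
                         energy_kcal_per_100g=44.0, sugar_g_per_100g=10.6,
                         serving_size_g=330.0, servings_per_pack=4.0,
                         yields={"ssb_juice_servings": 1.0}),
        ]
    )


def make_order(lines, pid="P1", shop=1, condition=Condition.CONTROL, **kw) -> Order:
    return Order(
        participant_id=pid,
        shop_index=shop,
        condition=condition,
        lines=[OrderLine(product_id=p, quantity=q) for p, q in lines],
        **kw,
    )


def make_participant(pid="P1", n_adults=1, **kw) -> Participant:
    return Participant(participant_id=pid, n_adults_in_household=n_adults, **kw)
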