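"""Independent reference implementations used only to check the package.

The tables and scans here are written from the published band definitions
directly, without importing the package's constant tables, so agreement is
a genuine cross-check rather than a tautology.
"""

import numpy as np


def nutriscore_food_oracle(energy_kj, sugar_g, satfat_g, sodium_mg,
                           fvnl_pct, fiber_g, protein_g):
    """Linear scan of the food point bands; returns (neg, pos, final, grade)."""

    def scan(value, start, step, n=10):
        pts = 0
        bound = start
        for _ in range(n):
            if value > bound:
                pts += 1
                bound += step
            else:
                break
        return pts

    neg = 0
    neg += scan(energy_kj, 335.0, 335.0)
    # sugar bands are not equally spaced past 27 g
    sugar_bounds = [4.5, 9.0, 13.5, 18.0, 22.5, 27.0, 31.0, 36.0, 40.0, 45.0]
    neg += sum(1 for b in sugar_bounds if sugar_g > b)
    neg += scan(satfat_g, 1.0, 1.0)
    neg += scan(sodium_mg, 90.0, 90.0)

    if fvnl_pct > 80:
        fvnl = 5
    elif fvnl_pct > 60:
        fvnl = 2
    elif fvnl_pct > 40:
        fvnl = 1
    else:
        fvnl = 0
    fiber_bounds = [0.9, 1.9, 2.8, 3.7, 4.7]
    fiber = sum(1 for b in fiber_bounds if fiber_g > b)
    protein_bounds = [1.6, 3.2, 4.8, 6.4, 8.0]
    protein = sum(1 for b in protein_bounds if protein_g > b)
    if neg >= 11 and fvnl < 5:
        protein = 0
    pos = fvnl + fiber + protein
    final = neg - pos
    if final <= -1:
        grade = "A"
    elif final <= 2:
        grade = "B"
    elif final <= 10:
        grade = "C"
    elif final <= 18:
        grade = "D"
    else:
        grade = "E"
    return neg, pos, final, grade


def random_panel_values(rng):
    """One random nutrient vector spanning all point bands."""
    return dict(
        energy_kj=float(rng.uniform(0, 4000)),
        sugar_g=float(rng.uniform(0, 60)),
        satfat_g=float(rng.uniform(0, 15)),
        sodium_mg=float(rng.uniform(0, 1200)),
        fvnl_pct=float(rng.uniform(0, 100)),
        fiber_g=float(rng.uniform(0, 8)),
        protein_g=float(rng.uniform(0, 12)),
    )


def group_mean_effects(deltas, ns_dummies):
    """Closed-form OLS with a single dummy regressor: group means."""
    deltas = np.asarray(deltas, dtype=float)
    ns = np.asarray(ns_dummies)
    mean0 = deltas[ns == 0].mean()
    mean1 = deltas[ns == 1].mean()
    return mean0, mean1 - mean0
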