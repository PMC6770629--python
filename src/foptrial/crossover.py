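"""Within-person first-difference estimation for the 3×3 crossover design.

Each participant shops once under each of Control, MTL (traffic-light) and
NS (Nutri-Score).  Differencing each treatment shop against the same
person's control shop removes time-invariant heterogeneity; the model

    Δy_is = α + β_NS · NS_is + ε_is

is fit by OLS with covariance clustered on participant.  α is the MTL vs
Control effect, β_NS the incremental NS-over-MTL effect, and α + β_NS the
NS vs Control contrast.  Moderator analyses interact a median-split binary
moderator with the NS dummy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .basket_scoring import DomainError, OUTCOME_COLUMNS, score_orders
from .catalog import Condition


class DataError(ValueError):
    """Input data violate a design assumption (duplicate conditions, empty)."""


class RankDeficiencyError(ValueError):
    """The design matrix is not full rank (e.g. a constant regressor)."""


class UnsupportedOutcomeError(ValueError):
    """The requested outcome is undefined for this stratum."""


MODERATORS = ("hungry", "happy", "high_income", "high_education")


@dataclass(frozen=True)
class DifferenceObservation:
    participant_id: str
    shop_index: int
    outcome_delta: float
    ns_dummy: int
    moderator_values: dict[str, Optional[int]] = field(default_factory=dict)


@dataclass
class EffectTable:
    """α, β_NS and the NS-vs-Control contrast with cluster-robust inference."""

    outcome: str
    alpha: float
    alpha_se: float
    alpha_p: float
    beta_ns: float
    beta_ns_se: float
    beta_ns_p: float
    alpha_plus_beta: float
    alpha_plus_beta_se: float
    alpha_plus_beta_p: float
    n_participants: int
    n_observations: int
    beta_m: Optional[float] = None
    beta_m_se: Optional[float] = None
    beta_m_p: Optional[float] = None
    beta_int: Optional[float] = None
    beta_int_se: Optional[float] = None
    beta_int_p: Optional[float] = None
    beta_m_plus_int: Optional[float] = None
    beta_m_plus_int_se: Optional[float] = None
    beta_m_plus_int_p: Optional[float] = None


def median_split(values: Sequence[float]) -> np.ndarray:
    """Dichotomize at the sample median; ties (== median) code as 1."""
    arr = np.asarray(values, dtype=float)
    med = np.nanmedian(arr)
    return (arr >= med).astype(int)


def build_differences(summaries: pd.DataFrame, outcome: str) -> list[DifferenceObservation]:
    """Treatment-minus-control differences from a scored per-shop table.

    ``summaries`` carries one row per participant-shop with columns
    ``participant_id``, ``condition``, the outcome, and optionally
    ``shop_index``, survey and demographic columns.  A participant yields
    one observation per treatment shop for which they also have a control
    shop; participants without a control shop (or with only one shop)
    contribute nothing.
    """
    if outcome not in summaries.columns:
        raise DataError(f"outcome column {outcome!r} not in summaries")
    def _splitter(column: str):
        if column not in summaries.columns or summaries[column].isna().all():
            return None
        med = np.nanmedian(summaries[column].astype(float))
        return lambda v, med=med: None if pd.isna(v) else int(float(v) >= med)

    hunger_split = _splitter("post_shop_hunger")
    mood_split = _splitter("post_shop_mood")

    observations: list[DifferenceObservation] = []
    for pid, grp in summaries.groupby("participant_id", sort=False):
        conditions = grp["condition"].tolist()
        if len(set(conditions)) != len(conditions):
            raise DataError(f"participant {pid!r} has duplicate conditions")
        by_cond = {row["condition"]: row for _, row in grp.iterrows()}
        control = by_cond.get(Condition.CONTROL.value)
        if control is None:
            continue
        for cond in (Condition.MTL.value, Condition.NS.value):
            row = by_cond.get(cond)
            if row is None:
                continue
            delta = row[outcome] - control[outcome]
            if pd.isna(delta):
                continue
            def _opt_int(v):
                return None if v is None or pd.isna(v) else int(v)
            moderators = {
                "hungry": hunger_split(row.get("post_shop_hunger")) if hunger_split else None,
                "happy": mood_split(row.get("post_shop_mood")) if mood_split else None,
                "high_income": _opt_int(row.get("high_income")),
                "high_education": _opt_int(row.get("high_education")),
            }
            observations.append(
                DifferenceObservation(
                    participant_id=str(pid),
                    shop_index=int(row.get("shop_index", 0) or 0),
                    outcome_delta=float(delta),
                    ns_dummy=int(cond == Condition.NS.value),
                    moderator_values=moderators,
                )
            )
    return observations


def _cluster_fit(y, X, groups, use_t_df: Optional[int] = None):
    """OLS with CR1 cluster-robust covariance; returns (params, cov, df)."""
    model = sm.OLS(y, X)
    res = model.fit(cov_type="cluster", cov_kwds={"groups": groups, "use_correction": True})
    n_groups = len(np.unique(groups))
    df = use_t_df if use_t_df is not None else max(n_groups - X.shape[1], 1)
    return res.params, res.cov_params(), df, n_groups


def _safe_sqrt(v: float) -> float:
    """Variance diagonals can round to tiny negatives when the cluster-robust
    variance is exactly zero; clamp before taking the root."""
    return math.sqrt(max(v, 0.0))


def _p_value(est: float, se: float, df: int, one_sided: bool) -> float:
    if se == 0:
        return math.nan if est == 0 else 0.0
    t = est / se
    if one_sided:
        return float(stats.t.sf(t, df))
    return float(2 * stats.t.sf(abs(t), df))


def fit_first_difference(
    observations: Sequence[DifferenceObservation],
    outcome: str = "outcome",
    one_sided: bool = False,
    df: Optional[int] = None,
) -> EffectTable:
    """Estimate Δy = α + β_NS·NS + ε with participant-clustered errors.

    P-values use a t reference with cluster-count-minus-parameters degrees
    of freedom (override with ``df``); two-sided by default, with the
    design's directional (greater-than-zero) tests available via
    ``one_sided``.
    """
    if len(observations) < 2:
        raise DataError("need at least two difference observations")
    ns = np.array([o.ns_dummy for o in observations], dtype=float)
    if len(set(ns)) < 2:
        raise RankDeficiencyError("both treatment conditions must be present")
    y = np.array([o.outcome_delta for o in observations], dtype=float)
    groups = np.array([o.participant_id for o in observations])
    X = sm.add_constant(ns)
    params, cov, dof, n_groups = _cluster_fit(y, X, groups, df)
    params = np.asarray(params)
    cov = np.asarray(cov)

    alpha, beta = params[0], params[1]
    alpha_se = _safe_sqrt(cov[0, 0])
    beta_se = _safe_sqrt(cov[1, 1])
    contrast = alpha + beta
    contrast_se = _safe_sqrt(cov[0, 0] + cov[1, 1] + 2 * cov[0, 1])
    return EffectTable(
        outcome=outcome,
        alpha=alpha,
        alpha_se=alpha_se,
        alpha_p=_p_value(alpha, alpha_se, dof, one_sided),
        beta_ns=beta,
        beta_ns_se=beta_se,
        beta_ns_p=_p_value(beta, beta_se, dof, one_sided),
        alpha_plus_beta=contrast,
        alpha_plus_beta_se=contrast_se,
        alpha_plus_beta_p=_p_value(contrast, contrast_se, dof, one_sided),
        n_participants=n_groups,
        n_observations=len(observations),
    )


def fit_moderator(
    observations: Sequence[DifferenceObservation],
    moderator: str,
    outcome: str = "outcome",
    one_sided: bool = False,
    df: Optional[int] = None,
) -> EffectTable:
    """Estimate Δy = α + β_NS·NS + β_M·M + β_int·M·NS + ε.

    The moderator must be a binary (median-split) indicator attached to the
    treatment-shop observation.  Reports β_M (does the moderator shift the
    MTL effect) and β_M + β_int (ditto for NS) alongside the usual contrasts.
    """
    obs = [o for o in observations if o.moderator_values.get(moderator) is not None]
    if len(obs) < 4:
        raise DataError(f"too few observations with moderator {moderator!r}")
    m = np.array([o.moderator_values[moderator] for o in obs], dtype=float)
    if len(set(m)) < 2:
        raise RankDeficiencyError(f"moderator {moderator!r} is constant")
    ns = np.array([o.ns_dummy for o in obs], dtype=float)
    if len(set(ns)) < 2:
        raise RankDeficiencyError("both treatment conditions must be present")
    y = np.array([o.outcome_delta for o in obs], dtype=float)
    groups = np.array([o.participant_id for o in obs])
    X = np.column_stack([np.ones_like(ns), ns, m, m * ns])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError("design matrix is rank deficient")
    params, cov, dof, n_groups = _cluster_fit(y, X, groups, df)
    params = np.asarray(params)
    cov = np.asarray(cov)

    alpha, beta, beta_m, beta_int = params
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    contrast = alpha + beta
    contrast_se = _safe_sqrt(cov[0, 0] + cov[1, 1] + 2 * cov[0, 1])
    m_plus_int = beta_m + beta_int
    m_plus_int_se = _safe_sqrt(cov[2, 2] + cov[3, 3] + 2 * cov[2, 3])
    return EffectTable(
        outcome=outcome,
        alpha=alpha,
        alpha_se=se[0],
        alpha_p=_p_value(alpha, se[0], dof, one_sided),
        beta_ns=beta,
        beta_ns_se=se[1],
        beta_ns_p=_p_value(beta, se[1], dof, one_sided),
        alpha_plus_beta=contrast,
        alpha_plus_beta_se=contrast_se,
        alpha_plus_beta_p=_p_value(contrast, contrast_se, dof, one_sided),
        n_participants=n_groups,
        n_observations=len(obs),
        beta_m=beta_m,
        beta_m_se=se[2],
        beta_m_p=_p_value(beta_m, se[2], dof, one_sided),
        beta_int=beta_int,
        beta_int_se=se[3],
        beta_int_p=_p_value(beta_int, se[3], dof, one_sided),
        beta_m_plus_int=m_plus_int,
        beta_m_plus_int_se=m_plus_int_se,
        beta_m_plus_int_p=_p_value(m_plus_int, m_plus_int_se, dof, one_sided),
    )


def stratified_runs(
    orders,
    catalog,
    participants,
    stratum: str = "all",
    outcomes: Optional[Sequence[str]] = None,
    beverage_config=None,
    one_sided: bool = False,
) -> dict[str, EffectTable]:
    """Fit the first-difference model for every outcome within one stratum.

    The diet-quality index is only defined on the full basket: its
    components span food and drink groups and are not scored in isolation,
    so requesting it for the foods or beverages stratum is an error.
    """
    if outcomes is None:
        outcomes = list(OUTCOME_COLUMNS)
        if stratum != "all":
            outcomes = [o for o in outcomes if o != "modified_ahei"]
    elif stratum != "all" and "modified_ahei" in outcomes:
        raise UnsupportedOutcomeError(
            "modified_ahei is a whole-basket index; it is not defined per stratum"
        )
    summaries = score_orders(
        orders, catalog, participants, beverage_config=beverage_config, stratum=stratum
    )
    tables = {}
    for outcome in outcomes:
        obs = build_differences(summaries, outcome)
        tables[outcome] = fit_first_difference(obs, outcome=outcome, one_sided=one_sided)
    return tables


def sample_size(
    effect_size: float,
    alpha: float = 0.05,
    power: float = 0.9,
    n_comparisons: int = 1,
) -> int:
    """Participants needed to detect a standardized within-person effect.

    Normal-approximation paired design with a Bonferroni-adjusted two-tailed
    level:  n = ceil(((z_{1−α/(2k)} + z_power) / d)²).
    """
    if not (0 < alpha < 1) or not (0 < power < 1) or effect_size <= 0 or n_comparisons < 1:
        raise DomainError("require 0<alpha<1, 0<power<1, effect_size>0, n_comparisons>=1")
    z_alpha = stats.norm.ppf(1 - alpha / (2 * n_comparisons))
    z_power = stats.norm.ppf(power)
    return math.ceil(((z_alpha + z_power) / effect_size) ** 2)


def implied_cad_reduction(delta_ahei: float, rr_per_10_points: float) -> float:
    """Linear extrapolation of an index gain to percent lower coronary-artery
    disease risk, given the published risk gradient per 10 index points.
    Reported to one decimal place.
    """
    if delta_ahei < 0 or rr_per_10_points < 0:
        raise DomainError("inputs must be nonnegative")
    return round(delta_ahei / 10.0 * rr_per_10_points, 1)
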