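"""Item pool visualization (IPV) center-distance analysis.

IPV compares two confirmatory factor models fitted to the same item pool:

* a **general factor model** — one factor over every item, representing the
  construct's common core; and
* a **correlated factor model** — one factor per sub-pool (facet or
  instrument), factors free to correlate.

For each item the center distance

    cd = (lambda_specific^2 - lambda_general^2) / lambda_general^2

is the proportional increase in explained item variance when the item is
modeled by its specific factor instead of the general one.  A cd of zero
means the specific factor adds nothing: the item sits at the construct's
core.  Pool-level summaries are the arithmetic mean of item cds and the
aggregate cd

    acd = (sum lambda_specific^2 - sum lambda_general^2) / sum lambda_general^2,

which is identically the lambda_general^2-weighted mean of raw item cds
and therefore always lies between the smallest and largest item cd.

Sampling noise can produce slightly negative raw cds; the default policy
floors them at zero and flags the item (the raw value is preserved).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cfa
from .registry import Registry

__all__ = [
    "ItemCenterDistance",
    "PoolSummary",
    "NestedIPVResult",
    "center_distance",
    "mean_center_distance",
    "aggregate_center_distance",
    "center_distance_table",
    "pool_summary",
    "fit_global_model",
    "fit_correlated_model",
    "run_nested_ipv",
    "item_table_report",
]

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 0.05


@dataclass(frozen=True)
class ItemCenterDistance:
    item_id: str
    lambda_general: float
    lambda_specific: float
    cd_raw: float
    cd: float
    negative_flag: bool


@dataclass(frozen=True)
class PoolSummary:
    pool_id: str
    mean_cd: float
    aggregate_cd: float
    n_items: int


@dataclass
class NestedIPVResult:
    item_table: pd.DataFrame  # one row per item
    facet_summaries: dict[str, PoolSummary]
    instrument_summaries: dict[str, PoolSummary]
    latent_corr: pd.DataFrame  # instrument-factor correlations
    global_fit: cfa.FittedCFA
    facet_fit: cfa.FittedCFA
    instrument_fit: cfa.FittedCFA


def center_distance(
    lambda_general: float,
    lambda_specific: float,
    item_id: str = "",
    policy: str = "floor",
    epsilon: float = DEFAULT_EPSILON,
) -> ItemCenterDistance:
    """Center distance of one item from its two standardized loadings.

    ``policy='floor'`` (default) clips negative raw values to 0 and sets
    ``negative_flag``; ``policy='keep-raw'`` reports the raw value.  A
    general loading below ``epsilon`` in magnitude makes the ratio
    numerically meaningless and raises an error naming the item.
    """
    if abs(lambda_general) <= epsilon:
        raise ValueError(
            f"center distance undefined for item {item_id or '?'}: "
            f"|lambda_general| = {abs(lambda_general):.4f} <= {epsilon}"
        )
    if policy not in ("floor", "keep-raw"):
        raise ValueError(f"unknown negative-cd policy {policy!r}")
    g2 = lambda_general**2
    cd_raw = (lambda_specific**2 - g2) / g2
    negative = cd_raw < 0
    cd = cd_raw if (cd_raw >= 0 or policy == "keep-raw") else 0.0
    if negative and policy == "floor":
        logger.warning("item %s: negative raw center distance %.4f floored to 0", item_id, cd_raw)
    return ItemCenterDistance(
        item_id=item_id,
        lambda_general=float(lambda_general),
        lambda_specific=float(lambda_specific),
        cd_raw=float(cd_raw),
        cd=float(cd),
        negative_flag=bool(negative),
    )


def mean_center_distance(items: list[ItemCenterDistance]) -> float:
    """Arithmetic mean of (policy-applied) item center distances."""
    if not items:
        raise ValueError("empty item list")
    return float(np.mean([it.cd for it in items]))


def aggregate_center_distance(items: list[ItemCenterDistance]) -> float:
    """Pooled proportional increase in explained variance across a sub-pool.

    Uses raw (pre-policy) loadings; algebraically the lambda_general^2-
    weighted mean of raw item cds.
    """
    if not items:
        raise ValueError("empty item list")
    g2 = np.array([it.lambda_general**2 for it in items])
    s2 = np.array([it.lambda_specific**2 for it in items])
    denom = g2.sum()
    if denom == 0:
        raise ValueError("sum of squared general loadings is zero")
    return float((s2.sum() - denom) / denom)


def pool_summary(pool_id: str, items: list[ItemCenterDistance]) -> PoolSummary:
    return PoolSummary(
        pool_id=pool_id,
        mean_cd=mean_center_distance(items),
        aggregate_cd=aggregate_center_distance(items),
        n_items=len(items),
    )


def center_distance_table(
    loadings: pd.DataFrame,
    policy: str = "floor",
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Vectorized center distances for a table with columns ``item_id``,
    ``lambda_general``, ``lambda_specific`` (extra columns pass through)."""
    recs = [
        center_distance(r.lambda_general, r.lambda_specific, r.item_id, policy, epsilon)
        for r in loadings.itertuples()
    ]
    out = loadings.copy()
    out["cd_raw"] = [r.cd_raw for r in recs]
    out["cd"] = [r.cd for r in recs]
    out["negative_flag"] = [r.negative_flag for r in recs]
    return out


# ---------------------------------------------------------------------------
# model fitting on data


def fit_global_model(data: pd.DataFrame, registry: Registry) -> cfa.FittedCFA:
    """Single-factor CFA over the full item pool; loadings sign-aligned so
    the general factor correlates positively with the total score."""
    cov = cfa.sample_covariance(data[registry.item_ids])
    spec = cfa.single_factor_spec(registry.item_ids, "flourishing")
    fit = cfa.fit_ml(cov, spec)
    if not fit.converged:
        logger.warning("global single-factor model did not converge (grad tolerance)")
    return fit


def fit_correlated_model(
    data: pd.DataFrame, registry: Registry, level: str = "facet"
) -> cfa.FittedCFA:
    """Correlated simple-structure CFA at ``level`` 'facet' (one factor per
    subscale; a unidimensional instrument contributes its single facet) or
    'instrument' (one factor per questionnaire)."""
    if level == "facet":
        blocks = registry.items_by_facet()
    elif level == "instrument":
        blocks = registry.items_by_instrument()
    else:
        raise ValueError(f"unknown level {level!r}")
    for name, ids in blocks.items():
        if len(ids) < 2:
            raise ValueError(f"pool {name} has {len(ids)} item(s); not identified")
    cov = cfa.sample_covariance(data[registry.item_ids])
    spec = cfa.correlated_spec(blocks)
    fit = cfa.fit_ml(cov, spec)
    if not fit.converged:
        logger.warning("correlated %s-level model did not converge", level)
    return fit


def run_nested_ipv(
    data: pd.DataFrame,
    registry: Registry,
    policy: str = "floor",
    epsilon: float = DEFAULT_EPSILON,
) -> NestedIPVResult:
    """Full nested IPV: global model, facet- and instrument-level correlated
    models, per-item center distances at both granularities, pool summaries
    and the instrument-factor latent correlation matrix.

    The general and specific loadings come from separately fitted models on
    the same sample covariance (the two-step IPV recipe), not from a joint
    bifactor estimation.
    """
    g_fit = fit_global_model(data, registry)
    f_fit = fit_correlated_model(data, registry, "facet")
    i_fit = fit_correlated_model(data, registry, "instrument")
    for name, fit in (("global", g_fit), ("facet", f_fit), ("instrument", i_fit)):
        if not fit.converged:
            raise RuntimeError(f"{name} model did not converge; refusing partial IPV result")

    rows = []
    for iid in registry.item_ids:
        lg = g_fit.lambda_std[iid]
        rec_f = center_distance(lg, f_fit.lambda_std[iid], iid, policy, epsilon)
        rec_i = center_distance(lg, i_fit.lambda_std[iid], iid, policy, epsilon)
        rows.append(
            {
                "instrument": registry.instrument_of(iid),
                "facet": registry.facet_of(iid),
                "item_id": iid,
                "lambda_general": lg,
                "lambda_facet": rec_f.lambda_specific,
                "lambda_instrument": rec_i.lambda_specific,
                "cd_facet_raw": rec_f.cd_raw,
                "cd_facet": rec_f.cd,
                "cd_instrument_raw": rec_i.cd_raw,
                "cd_instrument": rec_i.cd,
                "negative_flag": rec_f.negative_flag or rec_i.negative_flag,
            }
        )
    item_table = pd.DataFrame(rows)

    def summaries(group_col: str, lam_col: str) -> dict[str, PoolSummary]:
        out = {}
        for pool, g in item_table.groupby(group_col, sort=False):
            items = [
                center_distance(r.lambda_general, getattr(r, lam_col), r.item_id, policy, epsilon)
                for r in g.itertuples()
            ]
            out[pool] = pool_summary(pool, items)
        return out

    facet_summaries = summaries("facet", "lambda_facet")
    # instrument pools are summarized over the facet-level specific loadings
    # (the reference analysis pools sub-pool loadings per questionnaire);
    # the instrument-level fit contributes the latent correlations only
    instrument_summaries = summaries("instrument", "lambda_facet")

    return NestedIPVResult(
        item_table=item_table,
        facet_summaries=facet_summaries,
        instrument_summaries=instrument_summaries,
        latent_corr=i_fit.phi.copy(),
        global_fit=g_fit,
        facet_fit=f_fit,
        instrument_fit=i_fit,
    )


def item_table_report(result: NestedIPVResult, decimals: int = 3) -> pd.DataFrame:
    """Publication-style item table: one row per item with the general and
    facet-level standardized loadings, the center distance, and each pool's
    mean/aggregate pair on the pool's first row."""
    tbl = result.item_table
    rows = []
    for inst, g in tbl.groupby("instrument", sort=False):
        summ = result.instrument_summaries[inst]
        first = True
        for r in g.itertuples():
            rows.append(
                {
                    "pool": inst,
                    "item_id": r.item_id,
                    "lambda_general": round(r.lambda_general, decimals),
                    "lambda_specific": round(r.lambda_facet, decimals),
                    "cd": round(r.cd_facet, decimals),
                    "pool_mean_cd": round(summ.mean_cd, decimals) if first else np.nan,
                    "pool_aggregate_cd": round(summ.aggregate_cd, decimals) if first else np.nan,
                }
            )
            first = False
    return pd.DataFrame(rows)
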