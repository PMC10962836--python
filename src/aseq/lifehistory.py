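"""Derived larval-performance metrics from bottle eclosion tables.

Metrics follow standard experimental-evolution practice: egg-to-adult
survival (eclosed / eggs per bottle), developmental time summarised as an
eclosion-count-weighted bottle mean (optionally on the inverse scale, which
behaves better in linear analyses), and larval growth rate

    ln(female dry weight / egg weight) / (eclosion day - pre-larval offset)

with egg weight 5 ug and a 5-day offset for embryogenesis + metamorphosis by
default.  Group contrasts keep the bottle as the experimental unit —
bottle-level summaries plus OLS/Welch contrasts reproduce the point
estimates of a bottle-random-effect mixed model in balanced designs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

logger = logging.getLogger(__name__)


def survival(eclosed: int, eggs: int) -> float:
    """Egg-to-adult survival: eclosed adults / initial eggs."""
    if eggs <= 0:
        raise ValueError("eggs must be > 0")
    if not 0 <= eclosed <= eggs:
        raise ValueError("eclosed must be within [0, eggs] (data integrity)")
    return eclosed / eggs


def growth_rate(
    female_weight: float,
    eclosion_day: float,
    egg_weight: float = 5.0,
    pre_larval_offset: float = 5.0,
) -> float:
    """Average larval growth rate, per day.

    ln(weight / egg_weight) divided by the larval period, i.e. eclosion day
    minus the fixed pre-larval offset covering embryonal development and
    metamorphosis.
    """
    if female_weight <= 0:
        raise ValueError("weight must be > 0")
    if eclosion_day <= pre_larval_offset:
        raise ValueError("eclosion_day must exceed the pre-larval offset")
    return math.log(female_weight / egg_weight) / (eclosion_day - pre_larval_offset)


@dataclass(frozen=True)
class DevTimeSummary:
    per_bottle: pd.DataFrame  # bottle_id, mean (on the chosen scale), n_eclosed
    group_mean: float
    group_se: float  # nan when a single bottle (flagged undefined)
    n_bottles: int
    transform: str


def dev_time_summary(records: pd.DataFrame, transform: str = "identity") -> DevTimeSummary:
    """Eclosion-count-weighted developmental-time summary.

    ``records`` needs bottle_id, day, n_eclosed.  ``transform`` is
    ``identity`` (days) or ``inverse`` (1/day, applied per cohort day before
    weighting).  Bottles with zero eclosion are excluded with a warning; the
    bottle is the unit of the group SE, undefined (nan) for one bottle.
    """
    if transform not in ("identity", "inverse"):
        raise ValueError("transform must be 'identity' or 'inverse'")
    rows = []
    for bottle, grp in records.groupby("bottle_id", sort=False):
        grp = grp[grp["n_eclosed"] > 0]
        if grp.empty:
            logger.warning("bottle %s: zero eclosion, excluded from dev-time summary", bottle)
            continue
        vals = grp["day"].astype(float)
        if transform == "inverse":
            vals = 1.0 / vals
        w = grp["n_eclosed"].astype(float)
        rows.append((bottle, float(np.average(vals, weights=w)), int(w.sum())))
    if not rows:
        raise ValueError("no bottle with eclosed flies")
    per_bottle = pd.DataFrame(rows, columns=["bottle_id", "mean", "n_eclosed"])
    means = per_bottle["mean"]
    se = float(means.std(ddof=1) / math.sqrt(len(means))) if len(means) > 1 else float("nan")
    return DevTimeSummary(
        per_bottle=per_bottle,
        group_mean=float(means.mean()),
        group_se=se,
        n_bottles=len(means),
        transform=transform,
    )


@dataclass(frozen=True)
class WeightContrast:
    offset: float  # genotype_b minus genotype_a at equal eclosion day
    offset_se: float
    p: float
    quadratic: bool  # False = linear-only fallback (< 3 distinct days)
    coefficients: dict
    n_obs: int


def weight_by_devtime_contrast(
    records: pd.DataFrame,
    genotype_a: str,
    genotype_b: str,
    outlier_filter: bool = False,
) -> WeightContrast:
    """Genotype offset in weight at equal developmental time.

    Fits weight ~ day + day^2 + genotype (shared curvature, additive genotype
    offset) over per-day cohort weights of the two genotypes; the offset is
    genotype_b minus genotype_a.  With fewer than 3 distinct eclosion days in
    either genotype the quadratic term is dropped (flagged).  The optional
    studentized-residual filter removes points with |r| > 3, logged.
    """
    df = records[records["genotype"].isin([genotype_a, genotype_b])].dropna(
        subset=["day", "group_dry_weight"]
    )
    if df.empty:
        raise ValueError("no weight records for the requested genotypes")
    quadratic = all(
        df.loc[df["genotype"] == g, "day"].nunique() >= 3 for g in (genotype_a, genotype_b)
    )
    if not quadratic:
        logger.warning("fewer than 3 distinct eclosion days: linear-only fallback")

    def _fit(data: pd.DataFrame):
        day = data["day"].astype(float)
        day_c = day - day.mean()  # center to decorrelate linear/quadratic terms
        X = pd.DataFrame({"day": day_c})
        if quadratic:
            X["day_sq"] = day_c**2
        X["genotype_offset"] = (data["genotype"] == genotype_b).astype(float)
        X = sm.add_constant(X)
        return sm.OLS(data["group_dry_weight"].astype(float), X).fit()

    fit = _fit(df)
    if outlier_filter and fit.df_resid > 0:
        resid = OLSInfluence(fit).resid_studentized_external
        keep = np.abs(np.nan_to_num(resid)) <= 3
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("outlier filter removed %d point(s) (|studentized r| > 3)", n_drop)
            fit = _fit(df[keep])
    return WeightContrast(
        offset=float(fit.params["genotype_offset"]),
        offset_se=float(fit.bse["genotype_offset"]),
        p=float(fit.pvalues["genotype_offset"]),
        quadratic=quadratic,
        coefficients=dict(fit.params),
        n_obs=int(fit.nobs),
    )


def bottle_summaries(records: pd.DataFrame) -> pd.DataFrame:
    """Per-bottle survival and (weighted) mean developmental time.

    ``records`` needs bottle_id, eggs, day, n_eclosed; returns bottle_id,
    eggs, eclosed, survival, mean_dev_time, mean_inv_dev_time (nan for
    bottles with zero eclosion).
    """
    rows = []
    for bottle, grp in records.groupby("bottle_id", sort=False):
        eggs = int(grp["eggs"].iloc[0])
        eclosed = int(grp["n_eclosed"].sum())
        surv = survival(eclosed, eggs)
        if eclosed > 0:
            live = grp[grp["n_eclosed"] > 0]
            w = live["n_eclosed"].astype(float)
            mdt = float(np.average(live["day"].astype(float), weights=w))
            midt = float(np.average(1.0 / live["day"].astype(float), weights=w))
        else:
            mdt = midt = float("nan")
        rows.append((bottle, eggs, eclosed, surv, mdt, midt))
    return pd.DataFrame(
        rows,
        columns=["bottle_id", "eggs", "eclosed", "survival", "mean_dev_time", "mean_inv_dev_time"],
    )
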