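"""Cis/trans decomposition of expression divergence from F1 allele ratios.

The logic: in an F1 heterozygote both alleles share one trans environment, so
any allele imbalance is cis.  A 50:50 mass mix of the two parental cDNAs
instead reflects the *total* (cis + trans) expression difference.  Comparing
the F1 log allele ratio against zero tests for a cis component; comparing it
against the mix ratio tests for a trans component; their difference is the
trans estimate, so cis + trans = total holds by construction.

Statistics are a declared two-stage procedure: (i) average log ratios within
each pair_id x cross_type cell, (ii) t contrasts on the cell means.  For
balanced designs this gives the same point estimates as a mixed model with
pair as a random factor, without the mixed-model machinery; degrees of
freedom are #cells - 1 (one-sample) or Welch (two-sample) by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .amplicon import AlleleCount

#: |total| below this is treated as zero when forming percent_cis
_TOTAL_TOL = 1e-9


@dataclass(frozen=True)
class RatioObservation:
    """One sample's log allele ratio, tagged with its place in the design."""

    sample_id: str
    gene_id: str
    cross_type: str
    pair_id: str
    log_ratio: float  # natural log of (allele_a / allele_b)
    prop_b: float  # fraction of allele_b reads, the plotting view


@dataclass(frozen=True)
class ContrastResult:
    estimate: float
    statistic: float
    df: float
    p: float
    n_cells: int


@dataclass(frozen=True)
class CisTransResult:
    gene_id: str
    cis_estimate: float
    total_estimate: float
    trans_estimate: float
    percent_cis: float  # nan when undefined
    percent_cis_defined: bool
    cis_test: ContrastResult
    trans_test: ContrastResult
    per_direction_means: dict
    n_pairs: int


def log_allele_ratio(
    count: AlleleCount,
    cross_type: str = "F1_SC",
    pair_id: str = "pair1",
    pseudocount: float = 0.5,
) -> RatioObservation:
    """ln(n_a / n_b), with a pseudocount added to both counts only when
    either is zero (at realistic depths this never triggers)."""
    if count.depth == 0:
        raise ValueError("depth 0: no ratio defined")
    n_a, n_b = float(count.n_allele_a), float(count.n_allele_b)
    if n_a == 0 or n_b == 0:
        n_a += pseudocount
        n_b += pseudocount
    return RatioObservation(
        sample_id=count.sample_id,
        gene_id=count.gene_id,
        cross_type=cross_type,
        pair_id=pair_id,
        log_ratio=math.log(n_a / n_b),
        prop_b=n_b / (n_a + n_b),
    )


def _cell_means(obs: list[RatioObservation]) -> pd.Series:
    if not obs:
        raise ValueError("no observations")
    df = pd.DataFrame(
        {
            "pair_id": [o.pair_id for o in obs],
            "cross_type": [o.cross_type for o in obs],
            "log_ratio": [o.log_ratio for o in obs],
        }
    )
    return df.groupby(["pair_id", "cross_type"])["log_ratio"].mean()


def test_cis(f1_obs: list[RatioObservation]) -> ContrastResult:
    """One-sample t of pair x direction cell means against 0 (= 50:50).

    A nonzero mean F1 log ratio is the cis signature.  All-identical cells
    with mean 0 are reported as no deviation (p = 1); identical nonzero
    cells give an infinite statistic with p = 0.
    """
    cells = _cell_means(f1_obs)
    if len(cells) < 2:
        raise ValueError("need >= 2 pair x cross-type cells for a cis test")
    mean = float(cells.mean())
    sd = float(cells.std(ddof=1))
    df = len(cells) - 1
    if sd == 0.0:
        if mean == 0.0:
            return ContrastResult(0.0, 0.0, df, 1.0, len(cells))
        return ContrastResult(mean, math.copysign(math.inf, mean), df, 0.0, len(cells))
    t = mean / (sd / math.sqrt(len(cells)))
    p = 2.0 * stats.t.sf(abs(t), df)
    return ContrastResult(mean, t, df, p, len(cells))


def test_trans(
    f1_obs: list[RatioObservation], mix_obs: list[RatioObservation]
) -> ContrastResult:
    """Welch t of mix vs F1 cell means; estimate = mean(mix) - mean(F1).

    If the F1 ratio deviates less from 50:50 than the mix (total) ratio, the
    shortfall is the trans component.
    """
    f1_cells = _cell_means(f1_obs)
    mix_cells = _cell_means(mix_obs)
    if len(f1_cells) < 2 or len(mix_cells) < 2:
        raise ValueError("need >= 2 cells in each group for a trans test")
    est = float(mix_cells.mean() - f1_cells.mean())
    if f1_cells.std(ddof=1) == 0.0 and mix_cells.std(ddof=1) == 0.0:
        n = len(f1_cells) + len(mix_cells)
        if est == 0.0:
            return ContrastResult(0.0, 0.0, n - 2, 1.0, n)
        return ContrastResult(est, math.copysign(math.inf, est), n - 2, 0.0, n)
    res = stats.ttest_ind(mix_cells.values, f1_cells.values, equal_var=False)
    return ContrastResult(
        est, float(res.statistic), float(res.df), float(res.pvalue), len(f1_cells) + len(mix_cells)
    )


def decompose(
    f1_obs: list[RatioObservation],
    mix_obs: list[RatioObservation],
    gene_id: str | None = None,
) -> CisTransResult:
    """Full decomposition: cis = mean F1 ratio, total = mean mix ratio,
    trans = total - cis (machine-exact additivity).

    percent_cis = 100 * cis / total; undefined (nan, flagged) when total is
    numerically zero.  Per-direction F1 means are always reported so
    parent-of-origin asymmetry stays visible even though both directions are
    pooled in the cis contrast.
    """
    cis_t = test_cis(f1_obs)
    trans_t = test_trans(f1_obs, mix_obs)
    cis = cis_t.estimate
    total = float(_cell_means(mix_obs).mean())
    trans = total - cis
    defined = abs(total) > _TOTAL_TOL
    pct = 100.0 * cis / total if defined else float("nan")
    gene = gene_id or f1_obs[0].gene_id
    dir_means = {
        ct: float(np.mean([o.log_ratio for o in f1_obs if o.cross_type == ct]))
        for ct in sorted({o.cross_type for o in f1_obs})
    }
    return CisTransResult(
        gene_id=gene,
        cis_estimate=cis,
        total_estimate=total,
        trans_estimate=trans,
        percent_cis=pct,
        percent_cis_defined=defined,
        cis_test=cis_t,
        trans_test=trans_t,
        per_direction_means=dir_means,
        n_pairs=len({o.pair_id for o in f1_obs}),
    )


@dataclass(frozen=True)
class MaternalCheck:
    direction: str
    s: float  # 0 = paternal mean, 1 = maternal mean
    label: str  # maternal_like / intermediate / paternal_like


def maternal_allele_check(
    expr: pd.DataFrame,
    hi: float = 0.75,
    lo: float = 0.25,
) -> dict[str, MaternalCheck]:
    """Place each F1 male group's mean expression on the parent-parent axis.

    For X-linked genes, males carry only the maternal allele: if the
    expression difference is encoded on the X (cis, or X-linked trans), each
    F1 direction should track its maternal population.  ``expr`` needs
    columns ``group`` (PARENT_SEL, PARENT_CTL, F1_SC, F1_CS; F1_SC = Selected
    mother) and ``log2_expr`` with >= 2 replicates per group.  The score
    s = (F1 - paternal) / (maternal - paternal) classifies maternal_like
    above ``hi``, paternal_like below ``lo``, else intermediate.
    """
    needed = {"PARENT_SEL", "PARENT_CTL", "F1_SC", "F1_CS"}
    counts = expr.groupby("group")["log2_expr"].count()
    missing = needed - set(counts.index)
    if missing or (counts.reindex(sorted(needed)) < 2).any():
        raise ValueError("all four groups need >= 2 replicates")
    means = expr.groupby("group")["log2_expr"].mean()
    out = {}
    for direction, maternal in (("F1_SC", "PARENT_SEL"), ("F1_CS", "PARENT_CTL")):
        paternal = "PARENT_CTL" if maternal == "PARENT_SEL" else "PARENT_SEL"
        axis = means[maternal] - means[paternal]
        if axis == 0:
            raise ValueError("parental means equal: maternal axis undefined")
        s = float((means[direction] - means[paternal]) / axis)
        label = "maternal_like" if s > hi else "paternal_like" if s < lo else "intermediate"
        out[direction] = MaternalCheck(direction=direction, s=s, label=label)
    return out
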