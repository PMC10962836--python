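"""Efficiency-corrected relative qPCR expression.

The quantity of interest per sample is

    log2_rel = log2( (E_goi + 1)^(-Ct_goi) / GeoMean_refs[(E_ref + 1)^(-Ct_ref)] )

with primer efficiency E in (0, 1] (amplification factor E + 1; E = 1 is
perfect doubling) and an unweighted geometric mean over the reference genes.
Everything is evaluated in log space — the geometric mean becomes an
arithmetic mean of Ct_ref * log2(E_ref + 1) — so (E + 1)^(-Ct) never
underflows at Ct around 20-35.  When several measurements of the gene of
interest remain in a sample after technical replicates are collapsed, their
arithmetic mean is taken (the outer Mean; identity for a single value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _check_efficiency(gene: str, e: float) -> None:
    if not 0.0 < e <= 1.0:
        hint = ""
        if e > 1.0:
            hint = (
                " (values > 1 look like a percent or an amplification factor; "
                "supply E such that the factor is E + 1, e.g. 0.95 for 95%)"
            )
        raise ValueError(f"efficiency for {gene} outside (0, 1]{hint}")


def collapse_technical(records: pd.DataFrame) -> pd.DataFrame:
    """Median Ct over technical replicates per sample x gene.

    ``records`` is long-format with columns sample_id, gene_id, tech_rep, ct
    (missing ct allowed).  The replicate count actually used is recorded; a
    cell whose replicates are all missing is an error naming the cell.
    """
    empty = []
    rows = []
    for (sample, gene), grp in records.groupby(["sample_id", "gene_id"], sort=False):
        vals = grp["ct"].dropna()
        if vals.empty:
            empty.append((sample, gene))
            continue
        rows.append((sample, gene, float(vals.median()), int(vals.size)))
    if empty:
        raise ValueError(f"all technical replicates missing for: {empty}")
    return pd.DataFrame(rows, columns=["sample_id", "gene_id", "ct", "n_reps"])


@dataclass(frozen=True)
class RelativeExpression:
    sample_id: str
    gene_id: str
    log2_rel_expr: float
    ref_genes_used: tuple


def relative_expression(
    ct: pd.DataFrame, eff: dict, goi: str, refs: list[str]
) -> pd.DataFrame:
    """Per-sample log2 expression of ``goi`` relative to the reference genes.

    ``ct`` is a collapsed table (sample_id, gene_id, ct).  Returns a frame
    with sample_id, gene_id, log2_rel_expr, ref_genes_used.  Every sample
    must carry the gene of interest and all references.
    """
    if not refs:
        raise ValueError("need >= 1 reference gene")
    for g in [goi, *refs]:
        if g not in eff:
            raise ValueError(f"missing efficiency for {g}")
        _check_efficiency(g, eff[g])
    w = {g: np.log2(eff[g] + 1.0) for g in [goi, *refs]}
    out = []
    for sample, grp in ct.groupby("sample_id", sort=False):
        by_gene = grp.groupby("gene_id")["ct"].apply(list).to_dict()
        for g in [goi, *refs]:
            if g not in by_gene:
                raise ValueError(f"sample {sample}: missing Ct for {g}")
        # log-space geometric mean of the references = arithmetic mean of
        # Ct_ref * log2(E_ref + 1); references with several remaining
        # measurements contribute their mean Ct term
        ref_term = float(np.mean([np.mean(by_gene[r]) * w[r] for r in refs]))
        # outer arithmetic mean over remaining goi measurements
        vals = [-c * w[goi] + ref_term for c in by_gene[goi]]
        out.append((sample, goi, float(np.mean(vals)), tuple(refs)))
    return pd.DataFrame(
        out, columns=["sample_id", "gene_id", "log2_rel_expr", "ref_genes_used"]
    )


@dataclass(frozen=True)
class FoldChangeResult:
    delta_log2: float
    fold: float
    statistic: float | None
    df: float | None
    p: float | None
    n_units: tuple
    warning: str = ""


def group_fold_change(
    expr: pd.DataFrame, group_a: str, group_b: str
) -> FoldChangeResult:
    """Two-stage group contrast on relative expression.

    ``expr`` needs columns log2_rel_expr, group and unit (the biological
    unit — replicate population or bottle).  Replicates are averaged per
    unit first; the Welch t-test then runs on unit means, which reproduces a
    random-unit mixed model's point estimate in balanced designs.  A group
    with a single unit yields the estimate only, with a warning and no test.
    """
    units = expr.groupby(["group", "unit"])["log2_rel_expr"].mean()
    try:
        a = units.loc[group_a]
        b = units.loc[group_b]
    except KeyError as exc:
        raise ValueError(f"group missing from expression table: {exc}") from exc
    delta = float(a.mean() - b.mean())
    fold = float(2.0**delta)
    if len(a) < 2 or len(b) < 2:
        return FoldChangeResult(
            delta, fold, None, None, None, (len(a), len(b)),
            warning="a group has < 2 units: estimate only, no test",
        )
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        # degenerate: no within-group variance on unit means
        df = float(len(a) + len(b) - 2)
        stat, p = (0.0, 1.0) if delta == 0.0 else (np.copysign(np.inf, delta), 0.0)
        return FoldChangeResult(delta, fold, stat, df, p, (len(a), len(b)))
    res = stats.ttest_ind(a.values, b.values, equal_var=False)
    return FoldChangeResult(
        delta, fold, float(res.statistic), float(res.df), float(res.pvalue),
        (len(a), len(b)),
    )


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down (sequential Bonferroni) adjustment, input order kept."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]
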