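"""Candidate cis-regulatory SNP prioritization.

A causal cis variant should track expression across replicate populations:
populations fixed for one allele show one expression level, populations fixed
for the other show the other, intermediates fall in between.  The population
(not the individual) is the unit of correlation.  Supporting evidence:
fixation-pattern classification, ancestral/derived polarization against an
ancestral-range panel plus an outgroup base, and a two-site haplotype
exclusivity check (two derived alleles that never co-occur on one sequence
point to independent origins).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP with per-population alternate-allele frequencies."""

    chrom: str
    pos: int  # 1-based, as printed in variant tables
    ref_base: str
    alt_base: str
    freqs: dict  # population -> alt frequency

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based, must be >= 1")
        for pop, f in self.freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency for {pop} outside [0, 1]")


def correlate_freq_expression(snp: SnpRecord, expr: dict) -> tuple[float, float, int]:
    """Pearson r between per-population alt frequency and mean expression.

    ``expr`` maps population -> mean expression (replicates must already be
    averaged per population).  Returns (r, two-sided p from the t transform,
    n populations).  Needs >= 3 shared populations and non-constant vectors.
    """
    pops = sorted(set(snp.freqs) & set(expr))
    if len(pops) < 3:
        raise ValueError("need >= 3 shared populations")
    f = np.array([snp.freqs[p] for p in pops], dtype=float)
    e = np.array([expr[p] for p in pops], dtype=float)
    if np.ptp(f) == 0 or np.ptp(e) == 0:
        raise ValueError("undefined correlation: constant input vector")
    r, p = stats.pearsonr(f, e)
    return float(r), float(p), len(pops)


def classify_fixation(
    freqs: dict, hi: float = 0.95, lo: float = 0.05
) -> tuple[dict, Counter]:
    """Label each population fixed_alt (f >= hi), fixed_ref (f <= lo) or
    intermediate; "(nearly) fixed" defaults to the 0.95/0.05 operational
    thresholds.  Returns (labels, pattern summary counter)."""
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("need 0 <= lo < hi <= 1")
    labels = {}
    for pop, f in freqs.items():
        if f >= hi:
            labels[pop] = "fixed_alt"
        elif f <= lo:
            labels[pop] = "fixed_ref"
        else:
            labels[pop] = "intermediate"
    return labels, Counter(labels.values())


@dataclass(frozen=True)
class Polarization:
    ancestral: str | None
    derived: str | None
    status: str  # "resolved" or "unresolved"
    panel_major_freq: float
    outgroup_concordant: bool | None  # None when no outgroup given


def polarize_alleles(
    snp: SnpRecord,
    ancestral_panel_counts: dict,
    outgroup_base: str | None = None,
    fixed_threshold: float = 0.99,
) -> Polarization:
    """Infer the ancestral allele from an ancestral-range sequence panel.

    The allele at frequency >= ``fixed_threshold`` in the panel is called
    ancestral; an outgroup base, when given, is reported as concordant or
    discordant independent support.  A polymorphic panel with no outgroup
    (or one whose major allele is neither ref nor alt) is unresolved, not an
    error.
    """
    total = sum(ancestral_panel_counts.values())
    if total < 1:
        raise ValueError("ancestral panel needs >= 1 call")
    major, n_major = max(ancestral_panel_counts.items(), key=lambda kv: kv[1])
    major_freq = n_major / total
    if major_freq >= fixed_threshold and major in (snp.ref_base, snp.alt_base):
        derived = snp.alt_base if major == snp.ref_base else snp.ref_base
        concordant = None if outgroup_base is None else (outgroup_base == major)
        return Polarization(major, derived, "resolved", major_freq, concordant)
    if outgroup_base is not None and outgroup_base in (snp.ref_base, snp.alt_base):
        derived = snp.alt_base if outgroup_base == snp.ref_base else snp.ref_base
        return Polarization(outgroup_base, derived, "resolved", major_freq, True)
    return Polarization(None, None, "unresolved", major_freq, None)


@dataclass(frozen=True)
class HaplotypeCooccurrence:
    counts: dict  # (alleleA_state, alleleB_state) -> count, states "anc"/"der"
    n_missing: int
    exclusive: bool
    reason: str


def haplotype_cooccurrence(
    panel, derived_a: str, derived_b: str
) -> HaplotypeCooccurrence:
    """Two-site haplotype table and derived-allele exclusivity verdict.

    ``panel`` is an iterable of (base_at_A, base_at_B) per sequence (None =
    missing call; any call other than the derived allele counts as
    ancestral).  Exclusivity holds iff no sequence carries both derived
    alleles while each derived allele occurs alone in at least one sequence —
    the signature of two independent origins.
    """
    counts = {("anc", "anc"): 0, ("der", "anc"): 0, ("anc", "der"): 0, ("der", "der"): 0}
    n_missing = 0
    for call_a, call_b in panel:
        if call_a is None or call_b is None:
            n_missing += 1
            continue
        sa = "der" if call_a == derived_a else "anc"
        sb = "der" if call_b == derived_b else "anc"
        counts[(sa, sb)] += 1
    both = counts[("der", "der")]
    only_a = counts[("der", "anc")]
    only_b = counts[("anc", "der")]
    if both > 0:
        return HaplotypeCooccurrence(
            counts, n_missing, False, f"{both} sequence(s) carry both derived alleles"
        )
    if only_a == 0 or only_b == 0:
        return HaplotypeCooccurrence(
            counts, n_missing, False, "no derived alleles at one or both sites (vacuous)"
        )
    return HaplotypeCooccurrence(
        counts, n_missing, True, "derived alleles co-occur in populations but never on one sequence"
    )


def read_snp_panel_tsv(path) -> list[SnpRecord]:
    """Canonical panel input: TSV with chrom, pos, ref_base, alt_base and one
    alt-frequency column per population."""
    df = pd.read_csv(path, sep="\t")
    fixed = ["chrom", "pos", "ref_base", "alt_base"]
    pops = [c for c in df.columns if c not in fixed]
    return [
        SnpRecord(
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref_base=str(row["ref_base"]),
            alt_base=str(row["alt_base"]),
            freqs={p: float(row[p]) for p in pops},
        )
        for _, row in df.iterrows()
    ]


def read_snp_panel_vcf(path, af_prefix: str = "AF_") -> list[SnpRecord]:
    """Minimal VCF-like reader: CHROM, POS, REF, ALT plus per-population
    alternate frequencies as INFO keys ``AF_<population>``.

    Intentionally narrow (biallelic SNP rows, site-level INFO only); the TSV
    panel is the canonical format.
    """
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, pos, _id, ref, alt = fields[:5]
            info = fields[7] if len(fields) > 7 else ""
            freqs = {}
            for item in info.split(";"):
                if "=" in item:
                    key, val = item.split("=", 1)
                    if key.startswith(af_prefix):
                        freqs[key[len(af_prefix):]] = float(val)
            if len(ref) == 1 and len(alt) == 1 and "," not in alt:
                records.append(SnpRecord(chrom, int(pos), ref, alt, freqs))
    return records
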