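"""Synthetic-data generators for every pipeline input.

Each generator draws from one explicit :class:`numpy.random.Generator` seeded
per call; nothing touches global RNG state, so identical configs and seeds
give byte-identical outputs.

The read simulator emits single merged full-length amplicons (2x250 paired-end
reads fully span amplicons of 150-300 nt, so merging is lossless for the
statistic of interest) with a constant Phred symbol: per-base quality carries
no information downstream.  Sequencing error is an independent uniform
per-base miscall to each of the three other bases; no indels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_BASES = "ACGT"
_BASE_TO_IDX = {b: i for i, b in enumerate(_BASES)}
_IDX_TO_BYTE = np.frombuffer(_BASES.encode(), dtype=np.uint8)

# rows simulated per chunk; bounds the error-mask allocation
_CHUNK = 20_000


@dataclass(frozen=True)
class GeneTemplate:
    """An amplicon with one diagnostic biallelic SNP.

    ``allele_a`` is the "Control" allele, ``allele_b`` the "Selected" one.
    ``snp_offset`` is 0-based within ``amplicon_seq``; ``genomic_pos`` (when
    given) is the 1-based genomic coordinate of the SNP as printed in
    variant tables.  The first ``anchor_len`` bases serve as the
    read-to-gene assignment anchor.
    """

    gene_id: str
    amplicon_seq: str
    snp_offset: int
    allele_a: str
    allele_b: str
    anchor_len: int = 20
    genomic_pos: int | None = None

    def __post_init__(self) -> None:
        seq = self.amplicon_seq.upper()
        object.__setattr__(self, "amplicon_seq", seq)
        object.__setattr__(self, "allele_a", self.allele_a.upper())
        object.__setattr__(self, "allele_b", self.allele_b.upper())
        if not seq or any(b not in _BASE_TO_IDX for b in seq):
            raise ValueError(f"{self.gene_id}: amplicon must be non-empty A/C/G/T")
        if not (0 <= self.snp_offset < len(seq)):
            raise ValueError(f"{self.gene_id}: snp_offset outside amplicon")
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.gene_id}: alleles must differ")
        if seq[self.snp_offset] not in (self.allele_a, self.allele_b):
            raise ValueError(
                f"{self.gene_id}: base at snp_offset is neither declared allele"
            )
        if not (0 < self.anchor_len <= len(seq)):
            raise ValueError(f"{self.gene_id}: anchor_len outside amplicon")

    @property
    def anchor(self) -> str:
        return self.amplicon_seq[: self.anchor_len]


@dataclass(frozen=True)
class AmpliconSimConfig:
    """True allele proportion, depth and error model for one read pool."""

    true_prop_a: float
    depth: int
    error_rate: float = 0.0
    seed: int = 0
    quality_char: str = "I"

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_prop_a <= 1.0:
            raise ValueError("true_prop_a must be in [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0.0 <= self.error_rate < 0.75:
            raise ValueError("error_rate must be in [0, 0.75)")
        if len(self.quality_char) != 1:
            raise ValueError("quality_char must be a single character")


def simulate_amplicon_reads(
    template: GeneTemplate, cfg: AmpliconSimConfig
) -> list[SeqRecord]:
    """Simulate ``cfg.depth`` amplicon reads from one gene template.

    Each read copies the amplicon, sets the SNP base to ``allele_a`` with
    probability ``true_prop_a`` (one Binomial draw over the pool), then
    applies independent per-base miscalls at ``error_rate``.  Read ids encode
    gene, index and the *true* allele (``<gene>:<i>:a|b``) so oracle tests
    can recover the simulated truth.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.depth
    if n == 0:
        return []
    base_row = np.array([_BASE_TO_IDX[b] for b in template.amplicon_seq], dtype=np.uint8)
    is_a = rng.random(n) < cfg.true_prop_a
    a_code = _BASE_TO_IDX[template.allele_a]
    b_code = _BASE_TO_IDX[template.allele_b]

    records: list[SeqRecord] = []
    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        block = np.tile(base_row, (stop - start, 1))
        block[:, template.snp_offset] = np.where(is_a[start:stop], a_code, b_code)
        if cfg.error_rate > 0:
            err = rng.random(block.shape) < cfg.error_rate
            n_err = int(err.sum())
            if n_err:
                # uniform shift of 1..3 over the ring A->C->G->T guarantees a
                # *different* base, uniform over the other three
                shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                block[err] = (block[err] + shift) % 4
        chars = _IDX_TO_BYTE[block]
        for i in range(stop - start):
            j = start + i
            rec = SeqRecord(
                Seq(chars[i].tobytes().decode()),
                id=f"{template.gene_id}:{j}:{'a' if is_a[j] else 'b'}",
                description="",
            )
            records.append(rec)
    return records


def write_fastq(records, path, quality_char: str = "I") -> None:
    """Write reads as Sanger Phred+33 FASTQ with a constant quality symbol."""
    with open(path, "w") as fh:
        for rec in records:
            seq = str(rec.seq)
            fh.write(f"@{rec.id}\n{seq}\n+\n{quality_char * len(seq)}\n")


@dataclass(frozen=True)
class QpcrSimConfig:
    """Generative inverse of the efficiency-corrected expression formula.

    ``true_log2_expr`` maps gene -> log2 expression relative to the reference
    baseline (reference genes must map to 0); ``efficiencies`` maps gene ->
    E in (0, 1], with amplification factor E + 1 per cycle.
    """

    true_log2_expr: dict
    efficiencies: dict
    ct_noise_sd: float = 0.0
    baseline_ct: float = 25.0
    n_tech_reps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.n_tech_reps < 1:
            raise ValueError("n_tech_reps must be >= 1")
        for g, e in self.efficiencies.items():
            if not 0.0 < e <= 1.0:
                raise ValueError(f"efficiency for {g} outside (0, 1]")
        for g in self.true_log2_expr:
            if g not in self.efficiencies:
                raise ValueError(f"gene {g} has no efficiency")


def simulate_qpcr_plate(
    genes: list[str], cfg: QpcrSimConfig, sample_ids=("s1",)
) -> pd.DataFrame:
    """Simulate a long-format Ct table (sample_id, gene_id, tech_rep, ct).

    Ct(gene) = (baseline_ct - true_log2_expr) / log2(E + 1) + N(0, sd):
    a template at 2^x times the reference abundance crosses the detection
    threshold after (baseline_ct - x) perfect doublings, and a primer
    amplifying by E + 1 per cycle needs 1/log2(E + 1) cycles per doubling.
    At E = 1 this is the familiar baseline_ct - x, and a noise-free plate is
    exactly inverted by the relative-expression formula for *any* mix of
    per-gene efficiencies.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for sample in sample_ids:
        for g in genes:
            if g not in cfg.efficiencies:
                raise ValueError(f"gene {g} has no efficiency")
            expr = cfg.true_log2_expr.get(g, 0.0)
            e = cfg.efficiencies[g]
            mu = (cfg.baseline_ct - expr) / np.log2(e + 1.0)
            for rep in range(1, cfg.n_tech_reps + 1):
                ct = mu + (rng.normal(0.0, cfg.ct_noise_sd) if cfg.ct_noise_sd else 0.0)
                rows.append((sample, g, rep, ct))
    return pd.DataFrame(rows, columns=["sample_id", "gene_id", "tech_rep", "ct"])


@dataclass(frozen=True)
class PanelSimConfig:
    """Population panel where expression is a noisy linear map of frequency."""

    freqs: tuple
    intercept: float = 0.0
    slope: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", tuple(float(f) for f in self.freqs))
        if any(not 0.0 <= f <= 1.0 for f in self.freqs):
            raise ValueError("frequencies must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_populations(self) -> int:
        return len(self.freqs)


def simulate_population_panel(cfg: PanelSimConfig) -> pd.DataFrame:
    """Simulate (population, freq, expression) rows, one per population."""
    rng = np.random.default_rng(cfg.seed)
    freqs = np.asarray(cfg.freqs)
    expr = cfg.intercept + cfg.slope * freqs
    if cfg.noise_sd:
        expr = expr + rng.normal(0.0, cfg.noise_sd, size=len(freqs))
    pops = [f"P{i + 1:02d}" for i in range(len(freqs))]
    return pd.DataFrame({"population": pops, "freq": freqs, "expression": expr})


@dataclass(frozen=True)
class LifeHistorySimConfig:
    """Bottle-structured eclosion/weight tables.

    Mirrors a knockdown-style assay: each bottle starts with a fixed egg
    count, eclosion is Binomial(eggs, survival_prob), eclosion days are
    rounded Gaussian, and each day's eclosed females are weighed as a group
    whose mean weight moves linearly with eclosion day.
    """

    n_bottles: int
    eggs_per_bottle: int = 200
    survival_prob: float = 0.8
    eclosion_day_mean: float = 12.0
    eclosion_day_sd: float = 1.0
    weight_at_mean_day: float = 1000.0  # micrograms
    weight_slope: float = 0.0  # micrograms per day
    weight_noise_sd: float = 0.0
    genotype: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bottles < 1 or self.eggs_per_bottle <= 0:
            raise ValueError("need >= 1 bottle with > 0 eggs")
        if not 0.0 <= self.survival_prob <= 1.0:
            raise ValueError("survival_prob must be in [0, 1]")
        if self.eclosion_day_sd < 0 or self.weight_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")


def simulate_lifehistory(cfg: LifeHistorySimConfig) -> pd.DataFrame:
    """Simulate per-bottle, per-day eclosion counts and cohort dry weights.

    Columns: bottle_id, genotype, eggs, day, n_eclosed, group_dry_weight.
    Bottles where nothing ecloses contribute a single row with
    ``n_eclosed = 0`` and missing day/weight, so survival bookkeeping stays
    complete.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for b in range(1, cfg.n_bottles + 1):
        bottle = f"{cfg.genotype}_b{b:03d}"
        eclosed = int(rng.binomial(cfg.eggs_per_bottle, cfg.survival_prob))
        if eclosed == 0:
            rows.append((bottle, cfg.genotype, cfg.eggs_per_bottle, np.nan, 0, np.nan))
            continue
        days = np.rint(
            rng.normal(cfg.eclosion_day_mean, cfg.eclosion_day_sd, size=eclosed)
        ).astype(int)
        days = np.clip(days, 6, None)  # development + metamorphosis minimum
        for day in np.unique(days):
            n_day = int((days == day).sum())
            w = cfg.weight_at_mean_day + cfg.weight_slope * (day - cfg.eclosion_day_mean)
            if cfg.weight_noise_sd:
                w += rng.normal(0.0, cfg.weight_noise_sd)
            rows.append((bottle, cfg.genotype, cfg.eggs_per_bottle, int(day), n_day, w))
    return pd.DataFrame(
        rows,
        columns=["bottle_id", "genotype", "eggs", "day", "n_eclosed", "group_dry_weight"],
    )


def simulate_ase_experiment(
    template: GeneTemplate,
    f1_prop_a: float,
    mix_prop_a: float,
    depth: int = 20_000,
    n_pairs: int = 3,
    n_reps: int = 4,
    error_rate: float = 0.0,
    seed: int = 0,
    read_level: bool = True,
):
    """Simulate a full F1 + parental-mix allele-specific expression design.

    Produces per-sample allele counts and metadata for ``n_pairs``
    population pairs x two reciprocal F1 directions x ``n_reps`` replicates,
    plus ``n_pairs`` x ``n_reps`` 50:50 parental-mix samples.  ``f1_prop_a``
    encodes the cis component (allele-a transcript fraction in
    heterozygotes), ``mix_prop_a`` the total (cis + trans) difference.  With
    ``read_level`` the reads are simulated, assigned and counted through the
    full pipeline; otherwise counts come from the equivalent Binomial draws.
    Returns ``(counts, metas)``.
    """
    from .amplicon import SampleMeta, assign_reads_to_genes, count_alleles

    rng = np.random.default_rng(seed)
    pair_ids = [f"pair{i + 1}" for i in range(n_pairs)]
    design = []
    for pair in pair_ids:
        for cross in ("F1_SC", "F1_CS"):
            for rep in range(1, n_reps + 1):
                design.append((pair, cross, rep, f1_prop_a))
        for rep in range(1, n_reps + 1):
            design.append((pair, "MIX_5050", rep, mix_prop_a))
    counts, metas = [], []
    for pair, cross, rep, prop in design:
        sample = f"{pair}_{cross}_r{rep}"
        if read_level:
            cfg = AmpliconSimConfig(
                true_prop_a=prop,
                depth=depth,
                error_rate=error_rate,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            reads = simulate_amplicon_reads(template, cfg)
            assigned, _ = assign_reads_to_genes(reads, [template])
            count = count_alleles(assigned[template.gene_id], template, sample_id=sample)
        else:
            from .amplicon import AlleleCount

            n_a = int(rng.binomial(depth, prop))
            count = AlleleCount(sample, template.gene_id, n_a, depth - n_a, 0, depth)
        counts.append(count)
        metas.append(SampleMeta(sample_id=sample, cross_type=cross, pair_id=pair))
    return counts, metas


def simulate_allele_counts(
    true_prop_a: float,
    depth: int,
    n_samples: int,
    seed: int = 0,
    gene_id: str = "gene",
    sample_prefix: str = "s",
):
    """Count-level shortcut: Binomial allele counts without materialising reads.

    The read simulator followed by allele counting is, at error_rate 0,
    exactly a Binomial(depth, true_prop_a) draw per sample; this helper
    produces those draws directly for Monte-Carlo work where building 10^4
    reads per sample would dominate runtime.  Returns a list of
    :class:`aseq.amplicon.AlleleCount`.
    """
    from .amplicon import AlleleCount

    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_samples):
        n_a = int(rng.binomial(depth, true_prop_a))
        out.append(
            AlleleCount(
                sample_id=f"{sample_prefix}{i + 1}",
                gene_id=gene_id,
                n_allele_a=n_a,
                n_allele_b=depth - n_a,
                n_other=0,
                depth=depth,
            )
        )
    return out
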