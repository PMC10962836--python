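"""Read-to-gene assignment, diagnostic-SNP allele counting and sample QC.

Assignment uses the first ``anchor_len`` bases of each template as an anchor
and accepts up to ``max_mismatches`` substitutions; a read within tolerance
of two templates is ambiguous and goes to the unassigned pool.  This is a
declared, auditable convention for amplicon pools — not a general aligner
(no indels, no demultiplexing).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .simulate import GeneTemplate

logger = logging.getLogger(__name__)

CROSS_TYPES = ("F1_SC", "F1_CS", "MIX_5050", "PARENT_SEL", "PARENT_CTL")


@dataclass(frozen=True)
class AlleleCount:
    """Per-sample, per-gene read tallies at the diagnostic SNP."""

    sample_id: str
    gene_id: str
    n_allele_a: int
    n_allele_b: int
    n_other: int
    depth: int

    def __post_init__(self) -> None:
        if min(self.n_allele_a, self.n_allele_b, self.n_other, self.depth) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_allele_a + self.n_allele_b + self.n_other != self.depth:
            raise ValueError("allele counts must sum to depth")


@dataclass(frozen=True)
class SampleMeta:
    """Cross design and exclusion bookkeeping for one sample.

    ``cross_type`` follows the F1 design: F1_SC = Selected mother x Control
    father, F1_CS the reciprocal, MIX_5050 an equal-mass parental cDNA mix,
    plus the two parental controls.  ``excluded`` mirrors wet-lab flags such
    as Y-chromosome amplicon detection in a presumed-female pool.
    """

    sample_id: str
    cross_type: str
    pair_id: str
    material: str = "cDNA"
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.cross_type not in CROSS_TYPES:
            raise ValueError(f"unknown cross_type {self.cross_type!r}")
        if self.material not in ("cDNA", "gDNA"):
            raise ValueError(f"unknown material {self.material!r}")
        if self.excluded and not self.exclusion_reason:
            raise ValueError("excluded samples need an exclusion_reason")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def assign_reads_to_genes(
    reads, templates: list[GeneTemplate], max_mismatches: int = 2
) -> tuple[dict, int]:
    """Assign each read to at most one gene by anchor match.

    Returns ``(assigned, n_unassigned)`` where ``assigned`` maps gene_id to
    the list of its reads.  A read goes to the template whose anchor is at
    uniquely minimal Hamming distance from the read prefix, provided that
    distance is <= ``max_mismatches``; distance ties, no match within
    tolerance, and reads shorter than the anchor are unassigned.
    """
    anchors = [t.anchor for t in templates]
    if len(set(anchors)) != len(anchors):
        raise ValueError("templates must have mutually distinct anchors")
    assigned: dict[str, list] = {t.gene_id: [] for t in templates}
    n_unassigned = 0
    for read in reads:
        seq = str(read.seq)
        # fast path: an exact anchor hit is uniquely minimal (anchors distinct)
        gid = None
        for t in templates:
            if seq[: t.anchor_len] == t.anchor:
                gid = t.gene_id
                break
        if gid is not None:
            assigned[gid].append(read)
            continue
        best_d, best_gid, tie = max_mismatches + 1, None, False
        for t in templates:
            prefix = seq[: t.anchor_len]
            if len(prefix) < t.anchor_len:
                continue
            d = _hamming(prefix, t.anchor)
            if d < best_d:
                best_d, best_gid, tie = d, t.gene_id, False
            elif d == best_d:
                tie = True
        if best_gid is None or tie or best_d > max_mismatches:
            n_unassigned += 1
        else:
            assigned[best_gid].append(read)
    return assigned, n_unassigned


def count_alleles(reads, template: GeneTemplate, sample_id: str = "sample") -> AlleleCount:
    """Tally the base at the diagnostic SNP into allele_a / allele_b / other.

    Reads too short to cover the SNP count as "other" and are logged.
    """
    n_a = n_b = n_other = 0
    n_short = 0
    off = template.snp_offset
    for read in reads:
        seq = str(read.seq)
        if len(seq) <= off:
            n_other += 1
            n_short += 1
            continue
        base = seq[off]
        if base == template.allele_a:
            n_a += 1
        elif base == template.allele_b:
            n_b += 1
        else:
            n_other += 1
    if n_short:
        logger.warning(
            "%s/%s: %d reads shorter than snp_offset+1 counted as other",
            sample_id,
            template.gene_id,
            n_short,
        )
    return AlleleCount(
        sample_id=sample_id,
        gene_id=template.gene_id,
        n_allele_a=n_a,
        n_allele_b=n_b,
        n_other=n_other,
        depth=n_a + n_b + n_other,
    )


def min_nonzero_freq(n_individuals: int, ploidy_per_individual: int = 2) -> float:
    """Lowest non-zero allele frequency observable in a pooled sample.

    A pool of n diploid individuals carries 2n chromosomes, so a real
    polymorphism cannot sit below 1/(2n); anything under that is attributable
    to sequencing error (e.g. 1/14 = 7.1% for 7 diploids).
    """
    if n_individuals < 1 or ploidy_per_individual < 1:
        raise ValueError("arguments must be >= 1")
    return 1.0 / (n_individuals * ploidy_per_individual)


@dataclass(frozen=True)
class FixationVerdict:
    verdict: str  # "fixed" or "polymorphic_suspect"
    wrong_allele_freq: float
    threshold: float


def verify_fixation(
    count: AlleleCount, expected_allele: str, n_individuals: int
) -> FixationVerdict:
    """Check a parental gDNA amplicon for fixation of the expected allele.

    The opposite-allele frequency is compared with the lowest non-zero
    frequency possible in the pool; below it, "wrong" alleles are read as
    sequencing error and the sample is called fixed.
    """
    if count.depth == 0:
        raise ValueError("depth 0: uninformative sample")
    if expected_allele not in ("a", "b"):
        raise ValueError("expected_allele must be 'a' or 'b'")
    wrong = count.n_allele_b if expected_allele == "a" else count.n_allele_a
    freq = wrong / count.depth
    thr = min_nonzero_freq(n_individuals, 2)
    verdict = "fixed" if freq < thr else "polymorphic_suspect"
    return FixationVerdict(verdict=verdict, wrong_allele_freq=freq, threshold=thr)


def apply_sample_exclusions(
    counts: list[AlleleCount], meta: list[SampleMeta]
) -> list[AlleleCount]:
    """Drop counts whose sample is flagged excluded; log each removal.

    Every count must have a metadata row.  Remaining replicate counts per
    (pair_id, cross_type) are logged so downstream power is visible; an empty
    result triggers a warning that group statistics are impossible.
    """
    by_id = {m.sample_id: m for m in meta}
    retained = []
    for c in counts:
        m = by_id.get(c.sample_id)
        if m is None:
            raise ValueError(f"sample {c.sample_id} lacks metadata")
        if m.excluded:
            logger.info(
                "excluding %s (%s/%s): %s",
                c.sample_id,
                m.pair_id,
                m.cross_type,
                m.exclusion_reason,
            )
        else:
            retained.append(c)
    cells = Counter(
        (by_id[c.sample_id].pair_id, by_id[c.sample_id].cross_type) for c in retained
    )
    for (pair, cross), n in sorted(cells.items()):
        logger.info("retained %d replicate(s) for %s/%s", n, pair, cross)
    if counts and not retained:
        logger.warning("all samples excluded: downstream statistics impossible")
    return retained


def depth_filter(counts: list[AlleleCount], min_depth: int = 1000) -> list[bool]:
    """Pass/fail per count: depth >= min_depth.

    The default of 1,000 suits synthetic tests; real amplicon pools are run
    far deeper (>= 23,000x) and the threshold is fully configurable.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    return [c.depth >= min_depth for c in counts]


def counts_to_frame(counts: list[AlleleCount]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.sample_id, c.gene_id, c.n_allele_a, c.n_allele_b, c.n_other, c.depth)
            for c in counts
        ],
        columns=["sample_id", "gene_id", "n_allele_a", "n_allele_b", "n_other", "depth"],
    )
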