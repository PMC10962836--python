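"""PWM scanning of promoter windows and single-base substitution effects.

A position weight matrix is scored as summed log2 odds against a background
(uniform by default) at every offset of a query window — here a short
(default 21 bp) sequence centered on a candidate regulatory SNP, on the
strand the gene lies on.  ``substitution_effect`` rescores the window with
the SNP base replaced and classifies the change: a predicted "complete loss"
of binding is operationalized as the alternate score dropping below a
configurable fraction of the matrix's maximum attainable score (no numeric
criterion exists in the literature for "loss", so the threshold is always
echoed with the verdict).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as bio_motifs
from Bio.Seq import Seq

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Pwm:
    """Per-position base-probability matrix with background and pseudocount.

    ``matrix`` has shape (L, 4), columns A, C, G, T, rows summing to 1.
    Scores use pseudocount-regularized probabilities
    (p + c) / (1 + 4c) against the background.
    """

    motif_id: str
    matrix: np.ndarray
    pseudocount: float = 0.01
    background: tuple = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 4:
            raise ValueError("matrix must be (L >= 4) x 4")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's probabilities must sum to 1")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 probabilities summing to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        p = (self.matrix + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        return np.log2(p / np.asarray(self.background))

    @property
    def max_score(self) -> float:
        """Score of the consensus: the matrix's maximum attainable log odds."""
        return float(self.log_odds.max(axis=1).sum())

    def reverse_complement(self) -> "Pwm":
        return Pwm(
            motif_id=self.motif_id + "_rc",
            matrix=self.matrix[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            background=tuple(np.asarray(self.background)[::-1]),
        )


def read_jaspar(path, pseudocount: float = 0.01, background=(0.25,) * 4) -> Pwm:
    """Load a JASPAR plain-text PFM (count matrix) and normalise to a Pwm."""
    with open(path) as fh:
        motif = bio_motifs.read(fh, "jaspar")
    counts = np.array([motif.counts[b] for b in "ACGT"], dtype=float).T
    probs = counts / counts.sum(axis=1, keepdims=True)
    return Pwm(
        motif_id=motif.matrix_id or motif.name or "motif",
        matrix=probs,
        pseudocount=pseudocount,
        background=background,
    )


@dataclass(frozen=True)
class PromoterWindow:
    """A (2*flank + 1)-mer centered on a focal SNP, on the searched strand.

    ``sequence`` is stored as read on ``strand``: for a minus-strand gene the
    plus-strand window is reverse complemented, so the center base is the
    complement of the genomic (plus-strand) SNP base but stays in the middle.
    """

    sequence: str
    center_pos: int  # 1-based genomic position of the focal SNP
    flank: int
    strand: str = "plus"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.strand not in ("plus", "minus"):
            raise ValueError("strand must be 'plus' or 'minus'")
        if len(self.sequence) != 2 * self.flank + 1:
            raise ValueError("window length must equal 2*flank + 1")

    @property
    def center_index(self) -> int:
        return self.flank

    @property
    def center_base(self) -> str:
        return self.sequence[self.flank]


def build_query_window(
    genome_seq: str, snp_pos: int, flank: int = 10, strand: str = "plus"
) -> PromoterWindow:
    """Cut a window of 2*flank + 1 bases centered on a 1-based SNP position.

    Errors if the flanks run off either end of the supplied sequence; with
    ``strand='minus'`` the window is reverse complemented.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    start = snp_pos - 1 - flank
    stop = snp_pos + flank
    if start < 0 or stop > len(genome_seq):
        raise ValueError("window runs off the end of the sequence")
    window = genome_seq[start:stop].upper()
    if strand == "minus":
        window = str(Seq(window).reverse_complement())
    return PromoterWindow(sequence=window, center_pos=snp_pos, flank=flank, strand=strand)


@dataclass(frozen=True)
class ScanResult:
    best_score: float
    best_offset: int
    scores: np.ndarray
    n_ambiguous: int  # window bases scored at background (N etc.)


def score_window(pwm: Pwm, window: PromoterWindow) -> ScanResult:
    """Log-odds scan of the PWM over every offset of the window.

    Ambiguous bases (anything outside A/C/G/T) contribute 0 (background) and
    are counted in ``n_ambiguous``.
    """
    seq = window.sequence
    L = len(pwm)
    if len(seq) < L:
        raise ValueError("window shorter than the motif")
    lo = pwm.log_odds
    n_ambiguous = sum(1 for b in seq if b not in _BASE_IDX)
    scores = np.empty(len(seq) - L + 1)
    for off in range(len(scores)):
        s = 0.0
        for i in range(L):
            idx = _BASE_IDX.get(seq[off + i])
            if idx is not None:
                s += lo[i, idx]
        scores[off] = s
    best = int(np.argmax(scores))
    return ScanResult(float(scores[best]), best, scores, n_ambiguous)


@dataclass(frozen=True)
class SubstitutionEffect:
    score_ref: float
    score_alt: float
    delta: float
    verdict: str  # retained / weakened / lost
    loss_threshold: float
    retain_tolerance: float


def substitution_effect(
    pwm: Pwm,
    window: PromoterWindow,
    alt_base: str,
    loss_fraction: float = 0.6,
    retain_tolerance: float = 0.25,
) -> SubstitutionEffect:
    """Best-score change when the focal (center) base is substituted.

    ``alt_base`` is given on the plus (genomic) strand; for a minus-strand
    window it is complemented before substitution.  Verdict: "lost" when the
    alternate best score falls below ``loss_fraction`` of the matrix maximum,
    "retained" when |delta| <= ``retain_tolerance`` bits, else "weakened".
    """
    alt = alt_base.upper()
    if alt not in _BASE_IDX:
        raise ValueError("alt base must be one of A/C/G/T")
    if window.strand == "minus":
        alt = alt.translate(_COMPLEMENT)
    if alt == window.center_base:
        raise ValueError("alt base equals the current center base")
    ref_scan = score_window(pwm, window)
    i = window.center_index
    alt_seq = window.sequence[:i] + alt + window.sequence[i + 1 :]
    alt_window = PromoterWindow(
        sequence=alt_seq, center_pos=window.center_pos, flank=window.flank,
        strand=window.strand,
    )
    alt_scan = score_window(pwm, alt_window)
    delta = alt_scan.best_score - ref_scan.best_score
    threshold = loss_fraction * pwm.max_score
    if alt_scan.best_score < threshold:
        verdict = "lost"
    elif abs(delta) <= retain_tolerance:
        verdict = "retained"
    else:
        verdict = "weakened"
    return SubstitutionEffect(
        score_ref=ref_scan.best_score,
        score_alt=alt_scan.best_score,
        delta=delta,
        verdict=verdict,
        loss_threshold=threshold,
        retain_tolerance=retain_tolerance,
    )


def packaged_pwm() -> Pwm:
    """The shipped toy Adf1-like fixture matrix (synthetic; not the real
    Adf1 model — tests never assert real-motif scores)."""
    from importlib.resources import files

    path = files("aseq").joinpath("data/adf1_like_synthetic.jaspar")
    return read_jaspar(str(path))
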