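"""Quantitative marker utilities: qPCR domain percentages and ISR fingerprints.

qPCR copy numbers of archaeal vs bacterial 16S rRNA genes give the percent
archaea per sample, and the archaeal-16S : dsrB ratio tracks how tightly the
sulfate-reducing partner population follows the archaeon.  The 16S-23S
intergenic spacer region (ISR) distinguishes strains whose 16S genes are
identical: after global alignment, the substitution count is the strain
fingerprint (six SNPs separate the two dominant biofilm strains).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from Bio import Align

__all__ = [
    "QpcrRecord",
    "IsrPair",
    "percent_archaea",
    "gene_ratio",
    "align_pair",
    "count_snps",
    "trim_to_spacer",
]

_DNA = set("ACGTN")


@dataclass(frozen=True)
class QpcrRecord:
    """Copy numbers (per ng DNA) for one sample type, with standard deviations."""

    sample_type: str
    archaeal_16s: float
    bacterial_16s: float
    dsrb: float
    archaeal_16s_sd: float = 0.0
    bacterial_16s_sd: float = 0.0
    dsrb_sd: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.archaeal_16s, self.bacterial_16s, self.dsrb):
            if v < 0:
                raise ValueError("copy numbers must be non-negative")


@dataclass(frozen=True)
class IsrPair:
    """A pair of ISR sequences, optionally gapped after global alignment."""

    seq_a: str
    seq_b: str
    aligned: bool = False

    def __post_init__(self) -> None:
        if self.aligned and len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")


def percent_archaea(archaeal: float, bacterial: float, digits: int | None = 2) -> float:
    """100 * archaeal / (archaeal + bacterial), rounded half-up to *digits*.

    Pass ``digits=None`` for the unrounded value.
    """
    if archaeal < 0 or bacterial < 0:
        raise ValueError("copy numbers must be non-negative")
    if archaeal + bacterial == 0:
        raise ValueError("both copy numbers are zero")
    value = 100.0 * archaeal / (archaeal + bacterial)
    if digits is None:
        return value
    q = Decimal(10) ** -digits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def gene_ratio(numerator: float, denominator: float) -> float:
    """Plain copy-number quotient (e.g. archaeal 16S : dsrB)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return numerator / denominator


def align_pair(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -5.0,
) -> IsrPair:
    """Needleman-Wunsch global alignment of two sequences.

    A pairwise global alignment is the two-sequence reduction of the
    multiple alignment used on the original clone libraries.  The default
    gap penalty is deliberately stiff relative to the mismatch penalty, as
    is conventional for DNA: strain-level ISR variation is substitution-
    dominated, and a cheap gap would occasionally let a coincidental repeat
    rewrite substitutions as indels.  The first optimal alignment in the
    aligner's deterministic traversal order is returned.
    """
    for s in (seq_a, seq_b):
        if not s:
            raise ValueError("sequences must be non-empty")
        if not set(s) <= _DNA:
            raise ValueError("sequences must be uppercase ACGT (+N)")
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=match,
        mismatch_score=mismatch,
        open_gap_score=gap,
        extend_gap_score=gap,
    )
    aln = aligner.align(seq_a, seq_b)[0]
    return IsrPair(str(aln[0]), str(aln[1]), aligned=True)


def count_snps(pair: IsrPair) -> int:
    """Substitution count over aligned columns; gap columns are not SNPs."""
    if not pair.aligned:
        raise ValueError("pair must be aligned first (see align_pair)")
    return sum(
        1
        for a, b in zip(pair.seq_a, pair.seq_b)
        if a != "-" and b != "-" and a != b
    )


def trim_to_spacer(sequence: str, left_anchor: str, right_anchor: str) -> str:
    """Extract the spacer between two flanking anchor motifs.

    The anchors are user-supplied conserved motifs at the 16S 3' end and
    23S 5' end; the returned subsequence excludes both anchors.
    """
    i = sequence.find(left_anchor)
    if i < 0:
        raise ValueError("left anchor not found")
    j = sequence.find(right_anchor, i + len(left_anchor))
    if j < 0:
        raise ValueError("right anchor not found downstream of left anchor")
    return sequence[i + len(left_anchor) : j]
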