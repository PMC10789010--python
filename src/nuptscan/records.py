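"""Core domain types shared across the pipeline.

All genomic intervals are 0-based half-open ``[start, end)`` on the forward
strand; minus-strand alignments are stored as forward intervals plus a
strand flag. External 1-based inclusive conventions (BLAST tabular) are
converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "SequenceRecord",
    "AlignmentHit",
    "NuptRecord",
    "overlap_len",
    "reciprocal_overlap",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def overlap_len(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Length of the intersection of two half-open intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """min(overlap/len_a, overlap/len_b); 0 for disjoint or degenerate input."""
    la, lb = a_end - a_start, b_end - b_start
    if la <= 0 or lb <= 0:
        return 0.0
    ov = overlap_len(a_start, a_end, b_start, b_end)
    return min(ov / la, ov / lb)


@dataclass
class SequenceRecord:
    """A nucleotide sequence over {A,C,G,T,N} with a unique id."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentHit:
    """One local alignment between the plastid (query) and a nuclear subject.

    ``q_start/q_end`` and ``s_start/s_end`` are 0-based half-open forward
    intervals; ``strand`` records the orientation of the subject interval as
    encoded by the raw coordinate order.
    """

    query_id: str
    subject_id: str
    pident: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"pident {self.pident} outside [0,100]")
        if self.q_start >= self.q_end or self.s_start >= self.s_end:
            raise ValueError("intervals must satisfy start < end")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class NuptRecord:
    """A filtered nuclear integrant of plastid DNA (one surviving HSP).

    Episode posteriors/labels and the cluster id are attached by later
    pipeline stages and default to their "not yet computed" states.
    """

    id: str
    s_chrom: str
    s_start: int
    s_end: int
    q_start: int
    q_end: int
    strand: str
    pident: float
    aln_length: int
    evalue: float
    is_ir_redundant: bool = False
    episode: str = "none"
    posterior: list[float] = field(default_factory=list)
    cluster_id: str | None = None

    def copy(self) -> "NuptRecord":
        return replace(self, posterior=list(self.posterior))

    @property
    def s_interval(self) -> tuple[int, int]:
        return (self.s_start, self.s_end)

    @property
    def q_interval(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)
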