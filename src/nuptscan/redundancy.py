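"""Inverted-repeat redundancy correction and plastid genome fractions.

Plastid genomes carry two large inverted repeats (IRA/IRB) with identical
sequence content, so one nuclear integrant whose donor lies in the IR is
reported twice by local alignment — once per IR copy. Hits involving the IR
are therefore counted only once: duplicates are identified by projecting
IRB donor coordinates onto IRA (the mirror transform) and grouping hits
that share both a nuclear locus and a mirrored donor locus.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .records import NuptRecord, SequenceRecord, overlap_len, reciprocal_overlap, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "IRAnnotation",
    "FractionReport",
    "find_inverted_repeats",
    "mirror_interval",
    "flag_ir_redundant",
    "genome_fraction",
]


@dataclass
class IRAnnotation:
    """The quadripartite plastid layout as 0-based half-open intervals."""

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("region\tstart\tend\n")
            for name in ("lsc", "ira", "ssc", "irb"):
                s, e = getattr(self, name)
                fh.write(f"{name}\t{s}\t{e}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IRAnnotation":
        regions: dict[str, tuple[int, int]] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("region"):
                raise ValueError(f"{path}: expected header 'region\\tstart\\tend'")
            for line in fh:
                name, s, e = line.split("\t")
                regions[name.strip().lower()] = (int(s), int(e))
        missing = {"lsc", "ira", "ssc", "irb"} - set(regions)
        if missing:
            raise ValueError(f"{path}: missing regions {sorted(missing)}")
        return cls(regions["lsc"], regions["ira"], regions["ssc"], regions["irb"])


@dataclass
class FractionReport:
    """Plastid-derived fraction of a nuclear assembly (alignment-length sum)."""

    total_nupt_bp: int
    assembly_bp: int
    fraction_raw: float
    fraction_dedup: float
    n_redundant: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer code per k-window; windows containing N get -1."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    vals = win.astype(np.int64) @ powers
    bad = (win == 255).any(axis=1)
    vals[bad] = -1
    return vals


def find_inverted_repeats(
    plastid: SequenceRecord, min_ir_length: int = 1000, seed_k: int = 24
) -> IRAnnotation:
    """Locate the longest exact inverted-repeat pair (IRA, IRB).

    Seeds shared k-mers between the sequence and its reverse complement,
    groups them by anti-diagonal, and extends each group exactly (extension
    stops at the first mismatch on each side independently). The longer of
    the remaining single-copy segments is labelled LSC, the shorter SSC.
    """
    L = plastid.length
    if L <= 2 * min_ir_length:
        raise ValueError("plastid shorter than twice min_ir_length")
    seq = plastid.sequence
    codes = _encode(seq)
    rc_codes = _encode(revcomp(seq))
    k = seed_k

    fw = _kmer_codes(codes, k)
    rc = _kmer_codes(rc_codes, k)
    order = np.argsort(fw, kind="stable")
    sorted_fw = fw[order]
    left = np.searchsorted(sorted_fw, rc, side="left")
    right = np.searchsorted(sorted_fw, rc, side="right")
    has = (right > left) & (rc >= 0)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    # seeds grouped by anti-diagonal c = i + j + k - 1 (invariant of the
    # pairing x <-> c - x between the two copies)
    by_antidiag: dict[int, list[int]] = {}
    for p in np.nonzero(has)[0]:
        j = L - int(p) - k  # rc window p covers revcomp of seq[j:j+k]
        for idx in order[left[p] : right[p]]:
            i = int(idx)
            if j <= i:
                continue
            by_antidiag.setdefault(i + j + k - 1, []).append(i)
    if not by_antidiag:
        raise ValueError(
            "no inverted repeat found; supply an IR annotation file instead"
        )

    best: tuple[int, int, int] | None = None  # (length, a_start, b_start)
    for c, seeds in by_antidiag.items():
        seeds.sort()
        covered_end = -1
        for i in seeds:
            if i < covered_end:  # same maximal exact block already extended
                continue
            a0, a1 = i, i + k
            b0, b1 = c - a1 + 1, c - a0 + 1
            if b0 < a1:  # overlapping copies (palindrome center): not an IR pair
                continue
            # outward: new a0-1 pairs with b1; stops at first mismatch
            while a0 > 0 and b1 < L and seq[b1] == comp.get(seq[a0 - 1], "?"):
                a0 -= 1
                b1 += 1
            # inward: new a1 pairs with b0-1; keep copies disjoint
            while b0 - a1 >= 2 and seq[b0 - 1] == comp.get(seq[a1], "?"):
                a1 += 1
                b0 -= 1
            covered_end = a1
            length = a1 - a0
            if best is None or length > best[0]:
                best = (length, a0, b0)

    if best is None or best[0] < min_ir_length:
        raise ValueError(
            "no inverted repeat of at least "
            f"{min_ir_length} bp found; supply an IR annotation file instead"
        )
    length, a0, b0 = best
    ira = (a0, a0 + length)
    irb = (b0, b0 + length)
    head = (0, ira[0])
    mid = (ira[1], irb[0])
    tail = (irb[1], L)
    # single-copy segments: between the IRs, and outside them (head or tail)
    outer = head if (head[1] - head[0]) >= (tail[1] - tail[0]) else tail
    if (outer[1] - outer[0]) >= (mid[1] - mid[0]):
        lsc, ssc = outer, mid
    else:
        lsc, ssc = mid, outer
    return IRAnnotation(lsc=lsc, ira=ira, ssc=ssc, irb=irb)


def mirror_interval(interval: tuple[int, int], ir: IRAnnotation) -> tuple[int, int]:
    """Project an interval in one IR copy onto the other (an involution).

    Position ``x`` in IRA pairs with ``C - x`` in IRB where
    ``C = ira_start + irb_end - 1``; the same formula maps both directions.
    """
    c = ir.ira[0] + ir.irb[1]
    qs, qe = interval
    return (c - qe, c - qs)


def _ir_side(record: NuptRecord, ir: IRAnnotation, min_overlap_fraction: float) -> str | None:
    qlen = record.q_end - record.q_start
    if qlen <= 0:
        return None
    for side, (s, e) in (("A", ir.ira), ("B", ir.irb)):
        if overlap_len(record.q_start, record.q_end, s, e) >= min_overlap_fraction * qlen:
            return side
    return None


def flag_ir_redundant(
    records: list[NuptRecord],
    ir: IRAnnotation,
    min_overlap_fraction: float = 0.5,
    nuclear_reciprocal: float = 0.9,
    donor_tolerance: int = 50,
) -> list[NuptRecord]:
    """Flag all but one hit in each (nuclear locus, mirrored donor) group.

    IRB-side donors are projected onto IRA coordinates; hits that share a
    nuclear interval-equivalence class (reciprocal overlap >=
    ``nuclear_reciprocal``) and a mirrored donor start (within
    ``donor_tolerance`` bp) are duplicates of one integrant. The retained
    copy is the IRA-side one (tie broken by lower nuclear start, then id).
    Flags are set in place; the list is returned for chaining.
    """
    ir_hits = []
    for idx, rec in enumerate(records):
        side = _ir_side(rec, ir, min_overlap_fraction)
        rec.is_ir_redundant = False
        if side is None:
            continue
        donor = (
            mirror_interval((rec.q_start, rec.q_end), ir)
            if side == "B"
            else (rec.q_start, rec.q_end)
        )
        ir_hits.append((rec.s_chrom, rec.s_start, rec.s_end, donor[0], side, idx))

    # cluster nuclear loci per chromosome with a sorted sweep, then split by donor
    ir_hits.sort()
    n = len(ir_hits)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i in range(n):
        chrom_i, s_i, e_i, d_i, _, _ = ir_hits[i]
        for j in range(i + 1, n):
            chrom_j, s_j, e_j, d_j, _, _ = ir_hits[j]
            if chrom_j != chrom_i or s_j >= e_i:
                break
            if (
                reciprocal_overlap(s_i, e_i, s_j, e_j) >= nuclear_reciprocal
                and abs(d_i - d_j) <= donor_tolerance
            ):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    n_flagged = 0
    for members in groups.values():
        if len(members) < 2:
            continue
        def sort_key(m: int) -> tuple:
            _, s_start, _, _, side, idx = ir_hits[m]
            return (0 if side == "A" else 1, s_start, records[idx].id)
        keep = min(members, key=sort_key)
        for m in members:
            if m != keep:
                records[ir_hits[m][5]].is_ir_redundant = True
                n_flagged += 1
    logger.info("flagged %d IR-redundant records out of %d", n_flagged, len(records))
    return records


def genome_fraction(
    records: list[NuptRecord],
    nuclear: list[SequenceRecord] | int,
    dedup: bool = True,
) -> FractionReport:
    """Plastid fraction of the assembly from summed alignment lengths.

    Nuclear intervals are deliberately not union-merged: the occupied bp is
    the sum of alignment lengths, so overlapping hits double-count.
    """
    assembly_bp = nuclear if isinstance(nuclear, int) else sum(r.length for r in nuclear)
    if assembly_bp <= 0:
        raise ValueError("assembly size is zero")
    raw_bp = sum(r.aln_length for r in records)
    n_redundant = sum(1 for r in records if r.is_ir_redundant)
    dedup_bp = sum(r.aln_length for r in records if not r.is_ir_redundant)
    return FractionReport(
        total_nupt_bp=dedup_bp if dedup else raw_bp,
        assembly_bp=assembly_bp,
        fraction_raw=100.0 * raw_bp / assembly_bp,
        fraction_dedup=100.0 * dedup_bp / assembly_bp,
        n_redundant=n_redundant,
    )
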