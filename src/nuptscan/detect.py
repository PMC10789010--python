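"""NUPT detection: low-complexity masking, local alignment, filtering.

The aligner reproduces the shape of a nucleotide local-alignment search at
desk scale: exact-word seeding (default word size 9) on both strands, a
two-hit rule on diagonals, chaining across nearby diagonals, an exact core
alignment between the outermost seeds with ungapped X-drop extension of the
ends, +1/-2 match/mismatch and 5+2g affine gap rescoring, and
Karlin-Altschul e-values for the +1/-2 ungapped regime. Query-side
low-complexity masking follows the classic DUST triplet statistic. Users
with real BLAST tabular output can bypass the aligner entirely via
``io.read_blast_tab``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import edlib
import numpy as np
from scipy.optimize import brentq

from .records import AlignmentHit, NuptRecord, SequenceRecord, overlap_len, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "MaskedRegion",
    "mask_low_complexity",
    "align_plastid_to_nuclear",
    "filter_hits",
    "karlin_altschul_params",
]

#: published ungapped Karlin-Altschul K for +1/-2 scoring at uniform composition
K_UNGAPPED = 0.621


@dataclass
class MaskedRegion:
    """A low-complexity stretch of a sequence (0-based half-open)."""

    seq_id: str
    start: int
    end: int
    score: float


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def mask_low_complexity(
    seq: SequenceRecord, window: int = 64, threshold: float = 2.0
) -> list[MaskedRegion]:
    """DUST-style triplet masking.

    Per sliding window the score is sum_t c_t(c_t-1)/2 over overlapping
    trinucleotide counts c_t, divided by (window - 3); windows above
    ``threshold`` are merged into maximal regions. Triplets containing N
    are ignored.
    """
    if window < 8:
        raise ValueError("window must be >= 8")
    L = seq.length
    if L < window:
        raise ValueError("sequence shorter than the masking window")
    codes = _encode(seq.sequence)
    tri = codes[:-2].astype(np.int16) * 16 + codes[1:-1] * 4 + codes[2:]
    tri[(codes[:-2] > 3) | (codes[1:-1] > 3) | (codes[2:] > 3)] = 64

    step = max(1, window // 4)
    starts = list(range(0, L - window + 1, step))
    if starts[-1] != L - window:
        starts.append(L - window)

    flagged: list[tuple[int, int, float]] = []
    denom = window - 3
    for w0 in starts:
        t = tri[w0 : w0 + window - 2]
        t = t[t < 64]
        counts = np.bincount(t, minlength=64)
        score = float((counts * (counts - 1) // 2).sum()) / denom
        if score > threshold:
            flagged.append((w0, w0 + window, score))

    regions: list[MaskedRegion] = []
    for w0, w1, score in flagged:
        if regions and w0 <= regions[-1].end:
            regions[-1].end = max(regions[-1].end, w1)
            regions[-1].score = max(regions[-1].score, score)
        else:
            regions.append(MaskedRegion(seq.id, w0, w1, score))
    return regions


def karlin_altschul_params(match: int, mismatch: int) -> tuple[float, float]:
    """(lambda, K) for ungapped match/mismatch scoring at uniform composition.

    lambda solves (1/4)e^(lambda*match) + (3/4)e^(lambda*mismatch) = 1;
    K is the published value for +1/-2 (used for all schemes here — e-value
    exactness versus NCBI BLAST is explicitly not promised).
    """
    if mismatch >= 0:
        raise ValueError("mismatch score must be negative")

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    lam = brentq(f, 1e-6, 10.0)
    return lam, K_UNGAPPED


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    vals = win.astype(np.int64) @ powers
    vals[(win == 255).any(axis=1)] = -1
    return vals


def _seed_pairs(
    q_sorted: np.ndarray, q_pos_sorted: np.ndarray, s_kmers: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """All (q_pos, s_pos) pairs with identical words, vectorized."""
    left = np.searchsorted(q_sorted, s_kmers, side="left")
    right = np.searchsorted(q_sorted, s_kmers, side="right")
    counts = right - left
    counts[s_kmers < 0] = 0
    s_idx = np.nonzero(counts)[0]
    if len(s_idx) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    c = counts[s_idx]
    s_rep = np.repeat(s_idx, c)
    # ragged gather of query positions
    offsets = np.concatenate(([0], np.cumsum(c)))
    take = np.empty(offsets[-1], dtype=np.int64)
    starts = left[s_idx]
    idx = np.arange(offsets[-1]) - np.repeat(offsets[:-1], c) + np.repeat(starts, c)
    take = q_pos_sorted[idx]
    return take, s_rep


def _runs_from_seeds(
    q_pos: np.ndarray, s_pos: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse word seeds into maximal exact runs per diagonal.

    Returns (diag, s_first, s_last) per run, sorted by (diag, s_first).
    """
    diag = s_pos - q_pos
    order = np.lexsort((s_pos, diag))
    d, s = diag[order], s_pos[order]
    new_run = np.ones(len(d), dtype=bool)
    if len(d) > 1:
        new_run[1:] = (np.diff(d) != 0) | (np.diff(s) != 1)
    run_id = np.cumsum(new_run) - 1
    starts = np.nonzero(new_run)[0]
    ends = np.append(starts[1:], len(d)) - 1
    return d[starts], s[starts], s[ends]


@dataclass
class _Candidate:
    s_lo: int
    s_hi: int
    q_lo: int
    q_hi: int
    diag_lo: int
    diag_hi: int


def _candidates_from_runs(
    diag: np.ndarray,
    s_first: np.ndarray,
    s_last: np.ndarray,
    word: int,
    two_hit_window: int = 40,
    min_single_exact: int = 14,
    diag_merge: int = 20,
    s_merge_gap: int = 150,
) -> list[_Candidate]:
    if len(diag) == 0:
        return []
    # diagonal segments: runs on one diagonal within the two-hit window
    new_seg = np.ones(len(diag), dtype=bool)
    if len(diag) > 1:
        new_seg[1:] = (np.diff(diag) != 0) | (
            s_first[1:] - (s_last[:-1] + word) > two_hit_window
        )
    seg_idx = np.nonzero(new_seg)[0]
    seg_end = np.append(seg_idx[1:], len(diag)) - 1

    segs = []
    for a, b in zip(seg_idx, seg_end):
        n_runs = b - a + 1
        exact = s_last[b] - s_first[a] + word  # span of exact content
        if n_runs >= 2 or exact >= min_single_exact:
            segs.append(
                (int(s_first[a]), int(s_last[b] + word), int(diag[a]))
            )
    if not segs:
        return []
    segs.sort()
    out: list[_Candidate] = []
    for s_lo, s_hi, d in segs:
        target = None
        # unrelated short matches can interleave, so look back past them
        # (bounded window; candidates are not sorted by s_hi)
        for cand in reversed(out[-25:]):
            if (
                s_lo - cand.s_hi <= s_merge_gap
                and cand.diag_lo - diag_merge <= d <= cand.diag_hi + diag_merge
            ):
                target = cand
                break
        if target is not None:
            target.s_hi = max(target.s_hi, s_hi)
            target.q_lo = min(target.q_lo, s_lo - d)
            target.q_hi = max(target.q_hi, s_hi - d)
            target.diag_lo = min(target.diag_lo, d)
            target.diag_hi = max(target.diag_hi, d)
        else:
            out.append(_Candidate(s_lo, s_hi, s_lo - d, s_hi - d, d, d))
    return out


def _xdrop_extend(
    q: np.ndarray, s: np.ndarray, q_pos: int, s_pos: int,
    direction: int, match: int, mismatch: int, xdrop: int,
    max_cols: int = 4000,
) -> tuple[int, int]:
    """Ungapped extension from (q_pos, s_pos) exclusive, returning
    (columns, matches) at the score maximum. direction is +1 or -1."""
    score = best = 0
    cols = best_cols = 0
    matches = best_matches = 0
    lq, ls = len(q), len(s)
    i, j = q_pos, s_pos
    while cols < max_cols:
        i += direction
        j += direction
        if not (0 <= i < lq and 0 <= j < ls):
            break
        if q[i] == s[j] and q[i] < 4:
            score += match
            matches += 1
        else:
            score += mismatch
        cols += 1
        if score > best:
            best, best_cols, best_matches = score, cols, matches
        elif best - score > xdrop:
            break
    return best_cols, best_matches


def _gapped_hop(
    q: np.ndarray, s: np.ndarray, q_pos: int, s_pos: int, direction: int,
    match: int, mismatch: int, gap_open: int, gap_extend: int,
    window: int = 64, band: int = 8,
):
    """Small banded affine-gap DP continuing an extension across an indel.

    Aligns the tails beyond (q_pos, s_pos) and returns
    (dq, ds, cols, matches, mism, gap_opens, gap_cols) of the best
    net-positive prefix extension, or None when no extension gains score.
    """
    lq, ls = len(q), len(s)
    if direction > 0:
        qt = q[q_pos + 1 : min(lq, q_pos + 1 + window)]
        st = s[s_pos + 1 : min(ls, s_pos + 1 + window)]
    else:
        qt = q[max(0, q_pos - window) : q_pos][::-1]
        st = s[max(0, s_pos - window) : s_pos][::-1]
    n, m2 = len(qt), len(st)
    if n == 0 or m2 == 0:
        return None
    neg = -(10 ** 9)
    # three states: M (column consumes both), X (gap in subject: q only),
    # Y (gap in query: s only); affine cost open+extend*len
    M = [[neg] * (m2 + 1) for _ in range(n + 1)]
    X = [[neg] * (m2 + 1) for _ in range(n + 1)]
    Y = [[neg] * (m2 + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for i in range(1, min(n, band) + 1):
        X[i][0] = gap_open + gap_extend * i
    for j in range(1, min(m2, band) + 1):
        Y[0][j] = gap_open + gap_extend * j
    pm = {}  # parent state of M[i][j]
    px = {}  # parent state of X[i][j]
    py = {}  # parent state of Y[i][j]
    best = (0, 0, 0)
    for i in range(1, n + 1):
        jlo, jhi = max(1, i - band), min(m2, i + band)
        for j in range(jlo, jhi + 1):
            sub = match if (qt[i - 1] == st[j - 1] and qt[i - 1] < 4) else mismatch
            prev = ((M[i - 1][j - 1], "M"), (X[i - 1][j - 1], "X"), (Y[i - 1][j - 1], "Y"))
            pv, ps = max(prev)
            M[i][j] = pv + sub
            pm[(i, j)] = ps
            if M[i - 1][j] + gap_open >= X[i - 1][j]:
                X[i][j] = M[i - 1][j] + gap_open + gap_extend
                px[(i, j)] = "M"
            else:
                X[i][j] = X[i - 1][j] + gap_extend
                px[(i, j)] = "X"
            if M[i][j - 1] + gap_open >= Y[i][j - 1]:
                Y[i][j] = M[i][j - 1] + gap_open + gap_extend
                py[(i, j)] = "M"
            else:
                Y[i][j] = Y[i][j - 1] + gap_extend
                py[(i, j)] = "Y"
            v = max(M[i][j], X[i][j], Y[i][j])
            if v > best[0]:
                best = (v, i, j)
    if best[0] <= 0:
        return None
    # traceback for column accounting
    i, j = best[1], best[2]
    state = max((M[i][j], "M"), (X[i][j], "X"), (Y[i][j], "Y"))[1]
    matches = mism = gap_opens = gap_cols = 0
    while i > 0 or j > 0:
        if state == "M":
            if qt[i - 1] == st[j - 1] and qt[i - 1] < 4:
                matches += 1
            else:
                mism += 1
            state = pm[(i, j)]
            i, j = i - 1, j - 1
        elif state == "X":
            if j == 0:  # gap run from the DP boundary
                gap_cols += i
                gap_opens += 1
                break
            gap_cols += 1
            nxt = px[(i, j)]
            if nxt == "M":
                gap_opens += 1
            i -= 1
            state = nxt
        else:  # Y
            if i == 0:
                gap_cols += j
                gap_opens += 1
                break
            gap_cols += 1
            nxt = py[(i, j)]
            if nxt == "M":
                gap_opens += 1
            j -= 1
            state = nxt
    return best[1], best[2], matches + mism + gap_cols, matches, mism, gap_opens, gap_cols


def _extend_end(
    q: np.ndarray, s: np.ndarray, q_pos: int, s_pos: int, direction: int,
    match: int, mismatch: int, gap_open: int, gap_extend: int, xdrop: int,
):
    """Iterated ungapped X-drop extension with gapped hops across indels.

    (q_pos, s_pos) is the outermost aligned column; returns the new
    outermost column plus accumulated (cols, matches, mism, gap_opens,
    gap_cols).
    """
    cols = matches = mism = gap_opens = gap_cols = 0
    while True:
        c, mt = _xdrop_extend(q, s, q_pos, s_pos, direction, match, mismatch, xdrop)
        q_pos += direction * c
        s_pos += direction * c
        cols += c
        matches += mt
        mism += c - mt
        hop = _gapped_hop(
            q, s, q_pos, s_pos, direction, match, mismatch, gap_open, gap_extend
        )
        if hop is None:
            break
        dq, ds_, c2, mt2, mm2, go2, gc2 = hop
        q_pos += direction * dq
        s_pos += direction * ds_
        cols += c2
        matches += mt2
        mism += mm2
        gap_opens += go2
        gap_cols += gc2
    return q_pos, s_pos, cols, matches, mism, gap_opens, gap_cols


def _contained(a0: int, a1: int, b0: int, b1: int) -> float:
    """Overlap as a fraction of the smaller interval."""
    ov = overlap_len(a0, a1, b0, b1)
    small = min(a1 - a0, b1 - b0)
    return ov / small if small > 0 else 0.0


def _dedup_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Merge redundant overlapping HSPs, keeping the higher score.

    A hit is redundant when a higher-scoring hit on the same subject and
    strand covers >= 90% of its query and subject intervals (partial
    re-alignments of the same region). Distinct donor loci — e.g. the two
    IR copies — are never collapsed because their query intervals differ.
    """
    kept: list[AlignmentHit] = []
    for h in sorted(hits, key=lambda h: (-h.bitscore, h.s_start, h.q_start)):
        dup = any(
            k.subject_id == h.subject_id
            and k.strand == h.strand
            and _contained(h.s_start, h.s_end, k.s_start, k.s_end) >= 0.9
            and _contained(h.q_start, h.q_end, k.q_start, k.q_end) >= 0.9
            for k in kept
        )
        if not dup:
            kept.append(h)
    return kept


def _parse_cigar(cigar: str) -> tuple[int, int, int, int]:
    """(matches, mismatches, gap_opens, gap_columns) from an edlib extended cigar."""
    matches = mism = gap_opens = gap_cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            matches += n
        elif ch == "X":
            mism += n
        elif ch in "ID":
            gap_opens += 1
            gap_cols += n
    return matches, mism, gap_opens, gap_cols


def align_plastid_to_nuclear(
    plastid: SequenceRecord,
    nuclear: list[SequenceRecord],
    word_size: int = 9,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -5,
    gap_extend: int = -2,
    min_score: int | None = None,
    max_evalue: float = 1e-5,
    xdrop: int = 40,
) -> list[AlignmentHit]:
    """Seed-and-extend local alignment of the plastid against the nuclear set.

    Both strands are searched by aligning each subject against the forward
    and reverse-complemented query; reverse-orientation hits are reported
    as forward query intervals with strand '-'. HSPs sharing a diagonal are
    chained and reported once. E-values use the ungapped Karlin-Altschul
    formula with the database size equal to the summed nuclear length.
    """
    if mismatch >= 0:
        raise ValueError("degenerate scoring: mismatch must be negative")
    if plastid.length == 0 or not nuclear or any(r.length == 0 for r in nuclear):
        raise ValueError("sequences must be non-empty")
    lam, kparam = karlin_altschul_params(match, mismatch)
    m = plastid.length
    n_db = sum(r.length for r in nuclear)
    if min_score is None:
        # smallest integer score whose e-value is below the cutoff
        min_score = int(math.ceil(math.log(kparam * m * n_db / max_evalue) / lam))

    orientations = []
    for strand, qseq in (("+", plastid.sequence), ("-", revcomp(plastid.sequence))):
        q_codes = _encode(qseq)
        q_kmers = _kmer_codes(q_codes, word_size)
        order = np.argsort(q_kmers, kind="stable")
        orientations.append((strand, qseq, q_codes, q_kmers[order], order.astype(np.int64)))

    hits: list[AlignmentHit] = []
    for subject in nuclear:
        s_codes = _encode(subject.sequence)
        s_kmers = _kmer_codes(s_codes, word_size)
        for strand, qseq, q_codes, q_sorted, q_pos_sorted in orientations:
            q_pos, s_pos = _seed_pairs(q_sorted, q_pos_sorted, s_kmers)
            if len(q_pos) == 0:
                continue
            diag, s_first, s_last = _runs_from_seeds(q_pos, s_pos)
            for cand in _candidates_from_runs(diag, s_first, s_last, word_size):
                hit = _extend_candidate(
                    cand, q_codes, s_codes, qseq, subject.sequence,
                    match, mismatch, gap_open, gap_extend, xdrop,
                )
                if hit is None:
                    continue
                q0, q1, s0, s1, matches, mismatches, gap_opens, cols, score = hit
                if score < min_score:
                    continue
                evalue = kparam * m * n_db * math.exp(-lam * score)
                if evalue > max_evalue:
                    continue
                if strand == "-":
                    q0, q1 = plastid.length - q1, plastid.length - q0
                bitscore = (lam * score - math.log(kparam)) / math.log(2.0)
                hits.append(
                    AlignmentHit(
                        query_id=plastid.id, subject_id=subject.id,
                        pident=round(100.0 * matches / cols, 3),
                        aln_length=cols, mismatches=mismatches,
                        gap_opens=gap_opens, q_start=q0, q_end=q1,
                        s_start=s0, s_end=s1, strand=strand,
                        evalue=evalue, bitscore=round(bitscore, 1),
                    )
                )
    hits = _dedup_hits(hits)
    hits.sort(key=lambda h: (h.subject_id, h.s_start, h.s_end, h.strand, h.q_start))
    logger.info("aligner produced %d hits above thresholds", len(hits))
    return hits


def _extend_candidate(
    cand: _Candidate,
    q_codes: np.ndarray,
    s_codes: np.ndarray,
    qseq: str,
    sseq: str,
    match: int,
    mismatch: int,
    gap_open: int,
    gap_extend: int,
    xdrop: int,
):
    q0, q1 = cand.q_lo, cand.q_hi
    s0, s1 = cand.s_lo, cand.s_hi
    if q1 <= q0 or s1 <= s0:
        return None
    # exact core between the outermost seeds; the ungapped reading is used
    # only when the edit distance certifies it optimal (balanced indels can
    # leave lengths equal while wrecking the columnwise identity)
    ungapped = False
    if (q1 - q0) == (s1 - s0):
        a, b = q_codes[q0:q1], s_codes[s0:s1]
        eq = (a == b) & (a < 4)
        matches = int(eq.sum())
        mism = len(a) - matches
        gap_opens = gap_cols = 0
        cols = len(a)
        if mism <= edlib.align(qseq[q0:q1], sseq[s0:s1], mode="NW", task="distance")["editDistance"]:
            ungapped = True
    if not ungapped:
        res = edlib.align(qseq[q0:q1], sseq[s0:s1], mode="NW", task="path")
        cigar = res.get("cigar")
        if cigar is None:
            return None
        matches, mism, gap_opens, gap_cols = _parse_cigar(cigar)
        cols = matches + mism + gap_cols

    nq0, ns0, lcols, lmatch, lmism, lgo, lgc = _extend_end(
        q_codes, s_codes, q0, s0, -1, match, mismatch, gap_open, gap_extend, xdrop
    )
    nq1, ns1, rcols, rmatch, rmism, rgo, rgc = _extend_end(
        q_codes, s_codes, q1 - 1, s1 - 1, +1, match, mismatch, gap_open, gap_extend, xdrop
    )
    q0, s0 = nq0, ns0
    q1, s1 = nq1 + 1, ns1 + 1
    matches += lmatch + rmatch
    mism += lmism + rmism
    gap_opens += lgo + rgo
    gap_cols += lgc + rgc
    cols += lcols + rcols
    if cols <= 0 or matches == 0:
        return None
    score = match * matches + mismatch * mism + gap_opens * gap_open + gap_cols * gap_extend
    return q0, q1, s0, s1, matches, mism, gap_opens, cols, score


def filter_hits(
    hits: list[AlignmentHit],
    masks: list[MaskedRegion],
    max_masked_fraction: float = 0.5,
    min_length: int = 30,
) -> list[NuptRecord]:
    """Drop low-complexity and short hits; survivors become NuptRecords.

    A hit is dropped when its plastid (query) interval overlaps masked
    regions over at least ``max_masked_fraction`` of its length, or when
    its alignment is shorter than ``min_length``. Survivors get stable ids
    ordered by nuclear position.
    """
    merged: list[tuple[int, int]] = []
    for reg in sorted(masks, key=lambda r: (r.start, r.end)):
        if merged and reg.start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], reg.end))
        else:
            merged.append((reg.start, reg.end))

    n_masked = n_short = 0
    kept: list[AlignmentHit] = []
    for h in hits:
        if h.aln_length < min_length:
            n_short += 1
            continue
        qlen = h.q_end - h.q_start
        masked = sum(overlap_len(h.q_start, h.q_end, s, e) for s, e in merged)
        if masked >= max_masked_fraction * qlen:
            n_masked += 1
            continue
        kept.append(h)

    kept.sort(key=lambda h: (h.subject_id, h.s_start, h.s_end, h.q_start))
    records = [
        NuptRecord(
            id=f"NUPT_{i + 1}", s_chrom=h.subject_id, s_start=h.s_start,
            s_end=h.s_end, q_start=h.q_start, q_end=h.q_end, strand=h.strand,
            pident=h.pident, aln_length=h.aln_length, evalue=h.evalue,
        )
        for i, h in enumerate(kept)
    ]
    logger.info(
        "filter_hits: %d in, %d dropped low-complexity, %d dropped short, %d kept",
        len(hits), n_masked, n_short, len(records),
    )
    return records
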