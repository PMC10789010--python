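"""Scoring detected NUPTs against the simulator's ground truth."""

from __future__ import annotations

from bisect import bisect_left

import pandas as pd

from .records import NuptRecord, reciprocal_overlap

__all__ = ["match_truth", "detection_recall", "episode_accuracy"]


def match_truth(
    truth: pd.DataFrame,
    records: list[NuptRecord],
    min_reciprocal: float = 0.8,
) -> pd.DataFrame:
    """Best-overlap assignment of detected records to planted insertions.

    Adds ``matched_id``, ``matched_episode`` and ``overlap`` columns to a
    copy of the truth table; a planted row matches the record with the
    highest reciprocal overlap on its chromosome, provided it reaches
    ``min_reciprocal``.
    """
    by_chrom: dict[str, list[NuptRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.s_chrom, []).append(r)
    for lst in by_chrom.values():
        lst.sort(key=lambda r: r.s_start)

    matched_ids, matched_eps, overlaps = [], [], []
    for row in truth.itertuples(index=False):
        cands = by_chrom.get(row.chrom, [])
        starts = [c.s_start for c in cands]
        lo = bisect_left(starts, row.start - 200_000)
        best, best_ov = None, 0.0
        for c in cands[lo:]:
            if c.s_start >= row.end:
                break
            ov = reciprocal_overlap(row.start, row.end, c.s_start, c.s_end)
            if ov > best_ov:
                best, best_ov = c, ov
        if best is not None and best_ov >= min_reciprocal:
            matched_ids.append(best.id)
            matched_eps.append(best.episode)
            overlaps.append(best_ov)
        else:
            matched_ids.append(None)
            matched_eps.append(None)
            overlaps.append(best_ov)
    out = truth.copy()
    out["matched_id"] = matched_ids
    out["matched_episode"] = matched_eps
    out["overlap"] = overlaps
    return out


def _qualifying(matched: pd.DataFrame, min_size: int, min_identity: float) -> pd.DataFrame:
    return matched[
        (~matched.is_decoy)
        & (matched["size"] >= min_size)
        & (matched.realized_identity >= min_identity)
    ]


def detection_recall(
    truth: pd.DataFrame,
    records: list[NuptRecord],
    min_size: int = 100,
    min_identity: float = 75.0,
    min_reciprocal: float = 0.8,
) -> tuple[float, int]:
    """Fraction of qualifying planted insertions recovered by detection."""
    matched = match_truth(truth, records, min_reciprocal)
    q = _qualifying(matched, min_size, min_identity)
    if len(q) == 0:
        return float("nan"), 0
    return float((q.matched_id.notna()).mean()), len(q)


def episode_accuracy(
    truth: pd.DataFrame,
    records: list[NuptRecord],
    min_size: int = 100,
    min_identity: float = 75.0,
    min_reciprocal: float = 0.8,
) -> tuple[float, int]:
    """Fraction of detected qualifying insertions whose assigned episode
    equals the planted one (unassigned counts as incorrect)."""
    matched = match_truth(truth, records, min_reciprocal)
    q = _qualifying(matched, min_size, min_identity)
    det = q[q.matched_id.notna()]
    if len(det) == 0:
        return float("nan"), 0
    return float((det.matched_episode == det.episode).mean()), len(det)
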