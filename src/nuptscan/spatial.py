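"""Spatial statistics: clusters, collinearity, density tracks, flanking GC.

Clusters follow the classic definition: two or more non-overlapping NUPTs
on one chromosome whose consecutive gaps are below 5 kb. Collinearity of a
cluster with the plastid donor order is quantified by Kendall's tau
between the nuclear rank order and the donor-start rank order (|tau| = 1
means perfectly collinear in either orientation). Density tracks tile
each sequence with fixed windows and count any-overlap; donor peaks are
windows above mean + z*sd. The flanking-GC analysis compares per-NUPT
flank GC against a tiled non-NUPT background with Mann-Whitney U tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .records import NuptRecord, SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "NuptCluster",
    "DensityTrack",
    "FlankGcReport",
    "detect_clusters",
    "cluster_collinearity",
    "correlate_size_identity",
    "correlate_cluster_identity",
    "density_track",
    "find_donor_peaks",
    "flank_gc_analysis",
]


@dataclass
class NuptCluster:
    cluster_id: str
    s_chrom: str
    start: int
    end: int
    members: list[str]
    n_integrants: int
    total_bp: int
    mean_pident: float
    episode_composition: dict[str, int]
    collinearity_tau: float | None = None

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class DensityTrack:
    seq_id: str
    window_size: int
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        n = len(self.counts)
        starts = np.arange(n) * self.window_size
        return pd.DataFrame(
            {
                "seq": self.seq_id,
                "start": starts,
                "end": starts + self.window_size,
                "count": self.counts,
            }
        )


@dataclass
class FlankGcReport:
    episode: str
    mean_flank_gc: float
    background_gc: float
    u_statistic: float
    p_value: float
    n_flank: int
    n_background: int


def detect_clusters(
    records: list[NuptRecord], max_gap: int = 5000
) -> list[NuptCluster]:
    """Chain non-overlapping records whose consecutive gaps are < max_gap.

    Per chromosome, records are processed in nuclear order; a record that
    overlaps the previous chain member closes that chain and starts its
    own (cluster members must be non-overlapping). Chains with >= 2
    members become clusters and members are back-annotated with the
    cluster id.
    """
    for r in records:
        r.cluster_id = None
    by_chrom: dict[str, list[NuptRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.s_chrom, []).append(r)

    clusters: list[NuptCluster] = []
    counter = 0
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.s_start, r.s_end, r.id))
        chain: list[NuptRecord] = []

        def close(chain: list[NuptRecord]) -> None:
            nonlocal counter
            if len(chain) < 2:
                return
            counter += 1
            cid = f"CL{counter}"
            comp: dict[str, int] = {}
            for m in chain:
                m.cluster_id = cid
                comp[m.episode] = comp.get(m.episode, 0) + 1
            cluster = NuptCluster(
                cluster_id=cid,
                s_chrom=chrom,
                start=chain[0].s_start,
                end=chain[-1].s_end,
                members=[m.id for m in chain],
                n_integrants=len(chain),
                total_bp=sum(m.aln_length for m in chain),
                mean_pident=float(np.mean([m.pident for m in chain])),
                episode_composition=comp,
            )
            cluster.collinearity_tau = cluster_collinearity(chain)
            clusters.append(cluster)

        for r in recs:
            if not chain:
                chain = [r]
                continue
            gap = r.s_start - chain[-1].s_end
            if 0 <= gap < max_gap:
                chain.append(r)
            else:  # overlap (gap < 0) or break (gap >= max_gap)
                close(chain)
                chain = [r]
        close(chain)
    return clusters


def cluster_collinearity(members: list[NuptRecord]) -> float | None:
    """Kendall's tau between nuclear order and plastid donor-start order.

    Returns None when the donor starts are all identical (undefined).
    Donor coordinates are the stored forward-strand plastid intervals;
    |tau| is orientation-invariant, so an inverted but order-preserving
    cluster scores -1 and still counts as collinear by magnitude.
    """
    if len(members) < 2:
        return None
    s_starts = [m.s_start for m in members]
    q_starts = [m.q_start for m in members]
    if len(set(q_starts)) == 1:
        return None
    tau = stats.kendalltau(s_starts, q_starts).statistic
    return None if math.isnan(tau) else float(tau)


def correlate_size_identity(
    records: list[NuptRecord], method: str = "kendall"
) -> tuple[float, float]:
    """Tie-corrected rank correlation between NUPT size and identity."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    sizes = np.array([r.aln_length for r in records], dtype=float)
    idents = np.array([r.pident for r in records], dtype=float)
    if np.ptp(sizes) == 0 or np.ptp(idents) == 0:
        return (float("nan"), float("nan"))
    if method == "kendall":
        res = stats.kendalltau(sizes, idents)
    elif method == "spearman":
        res = stats.spearmanr(sizes, idents)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def correlate_cluster_identity(
    clusters: list[NuptCluster],
) -> dict[str, tuple[float, float]]:
    """Spearman rho of cluster mean identity vs integrant count, per
    episode-pure cluster class (fragmentation signal: if clusters arise
    from large integrants decaying in place, older clusters should be
    both larger and more diverged)."""
    pure: dict[str, list[NuptCluster]] = {}
    for c in clusters:
        if len(c.episode_composition) == 1:
            ep = next(iter(c.episode_composition))
            if ep != "unassigned":
                pure.setdefault(ep, []).append(c)
    out: dict[str, tuple[float, float]] = {}
    for ep, cs in sorted(pure.items()):
        if len(cs) < 3:
            logger.warning("episode %s: fewer than 3 pure clusters; undefined", ep)
            out[ep] = (float("nan"), float("nan"))
            continue
        res = stats.spearmanr(
            [c.mean_pident for c in cs], [c.n_integrants for c in cs]
        )
        out[ep] = (float(res.statistic), float(res.pvalue))
    return out


def density_track(
    records: list[NuptRecord],
    seq_lengths: dict[str, int],
    window_size: int,
    coordinate_space: str = "nuclear",
) -> list[DensityTrack]:
    """Fixed-window any-overlap counts per sequence.

    ``coordinate_space='nuclear'`` bins each record's nuclear interval on
    its chromosome; ``'plastid_donor'`` bins the plastid donor interval of
    every record onto the single plastid sequence. A record increments
    every window its interval overlaps, so window sums can exceed the
    record count.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if coordinate_space not in ("nuclear", "plastid_donor"):
        raise ValueError(f"unknown coordinate_space {coordinate_space!r}")
    tracks = {}
    for seq_id, L in seq_lengths.items():
        n_win = max(1, -(-L // window_size))
        tracks[seq_id] = np.zeros(n_win, dtype=np.int64)
    for r in records:
        if coordinate_space == "nuclear":
            seq_id, start, end = r.s_chrom, r.s_start, r.s_end
        else:
            seq_id = next(iter(seq_lengths))
            start, end = r.q_start, r.q_end
        if seq_id not in tracks or end <= start:
            continue
        w0 = start // window_size
        w1 = (end - 1) // window_size
        counts = tracks[seq_id]
        w1 = min(w1, len(counts) - 1)
        counts[w0 : w1 + 1] += 1
    return [
        DensityTrack(seq_id, window_size, counts) for seq_id, counts in tracks.items()
    ]


def find_donor_peaks(
    track: DensityTrack, records: list[NuptRecord], z: float = 3.0
) -> list[tuple[tuple[int, int], int]]:
    """Peak windows of a donor-space density track.

    Windows with count > mean + z*sd seed peaks; adjacent above-threshold
    windows merge. Each peak reports the number of records whose donor
    midpoint falls inside it. A flat track (sd = 0) has no peaks.
    """
    counts = track.counts.astype(float)
    sd = float(counts.std())
    if sd == 0:
        return []
    thr = float(counts.mean()) + z * sd
    above = counts > thr
    peaks: list[tuple[tuple[int, int], int]] = []
    w = track.window_size
    i = 0
    mids = np.array([(r.q_start + r.q_end) // 2 for r in records]) if records else np.array([])
    while i < len(above):
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(above) and above[j + 1]:
            j += 1
        lo, hi = i * w, (j + 1) * w
        n_in = int(((mids >= lo) & (mids < hi)).sum()) if len(mids) else 0
        peaks.append(((lo, hi), n_in))
        i = j + 1
    return peaks


def _gc_and_valid(seq: str) -> tuple[np.ndarray, np.ndarray]:
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    gc = (a == ord("G")) | (a == ord("C"))
    valid = gc | (a == ord("A")) | (a == ord("T"))
    return gc, valid


def flank_gc_analysis(
    records: list[NuptRecord],
    nuclear_seqs: list[SequenceRecord],
    flank: int = 100,
    background_window: int = 100,
) -> dict[str, FlankGcReport]:
    """Per-episode flanking-GC bias versus the non-NUPT genome background.

    Each record contributes the GC% of its concatenated up/downstream
    flanks, excluding positions inside any NUPT interval and N bases. The
    background sample is the GC% of every background_window-bp window
    tiling the genome that is free of NUPT intervals and their flanks.
    Two-sided Mann-Whitney U (normal approximation, tie-corrected)
    compares each episode's flank values against the background.
    """
    seqs = {s.id: s for s in nuclear_seqs}
    gc_masks, valid_masks, nupt_masks, flank_masks = {}, {}, {}, {}
    for sid, s in seqs.items():
        gc, valid = _gc_and_valid(s.sequence)
        gc_masks[sid], valid_masks[sid] = gc, valid
        nupt_masks[sid] = np.zeros(s.length, dtype=bool)
        flank_masks[sid] = np.zeros(s.length, dtype=bool)
    for r in records:
        if r.s_chrom in nupt_masks:
            nupt_masks[r.s_chrom][r.s_start : r.s_end] = True
            L = len(nupt_masks[r.s_chrom])
            flank_masks[r.s_chrom][max(0, r.s_start - flank) : r.s_start] = True
            flank_masks[r.s_chrom][r.s_end : min(L, r.s_end + flank)] = True

    flank_values: dict[str, list[float]] = {}
    for r in records:
        sid = r.s_chrom
        if sid not in seqs:
            continue
        L = seqs[sid].length
        idx = np.r_[
            max(0, r.s_start - flank) : r.s_start, r.s_end : min(L, r.s_end + flank)
        ]
        if len(idx) == 0:
            continue
        ok = ~nupt_masks[sid][idx] & valid_masks[sid][idx]
        n_ok = int(ok.sum())
        if n_ok == 0:
            continue
        gc_pct = 100.0 * float(gc_masks[sid][idx][ok].sum()) / n_ok
        flank_values.setdefault(r.episode, []).append(gc_pct)

    background: list[float] = []
    for sid, s in seqs.items():
        excluded = nupt_masks[sid] | flank_masks[sid]
        gc, valid = gc_masks[sid], valid_masks[sid]
        n_win = s.length // background_window
        if n_win == 0:
            continue
        upto = n_win * background_window
        exc = excluded[:upto].reshape(n_win, background_window)
        win_ok = ~exc.any(axis=1)
        g = gc[:upto].reshape(n_win, background_window).sum(axis=1)
        v = valid[:upto].reshape(n_win, background_window).sum(axis=1)
        usable = win_ok & (v > 0)
        background.extend((100.0 * g[usable] / v[usable]).tolist())
    if not background:
        raise ValueError("no NUPT-free background windows available")
    bg = np.asarray(background)

    reports: dict[str, FlankGcReport] = {}
    for ep, vals in sorted(flank_values.items()):
        arr = np.asarray(vals)
        res = stats.mannwhitneyu(arr, bg, alternative="two-sided", method="asymptotic")
        reports[ep] = FlankGcReport(
            episode=ep,
            mean_flank_gc=float(arr.mean()),
            background_gc=float(bg.mean()),
            u_statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n_flank=len(arr),
            n_background=len(bg),
        )
    return reports
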