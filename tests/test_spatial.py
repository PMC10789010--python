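import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nuptscan.records import NuptRecord, SequenceRecord
from nuptscan.spatial import (
    DensityTrack,
    cluster_collinearity,
    correlate_cluster_identity,
    correlate_size_identity,
    density_track,
    detect_clusters,
    find_donor_peaks,
    flank_gc_analysis,
)

from conftest import random_seq


def _rec(rid, s0, s1, q0=None, q1=None, chrom="chr1", pident=95.0, episode="none"):
    q0 = s0 if q0 is None else q0
    q1 = s1 if q1 is None else q1
    r = NuptRecord(
        id=rid, s_chrom=chrom, s_start=s0, s_end=s1, q_start=q0, q_end=q1,
        strand="+", pident=pident, aln_length=s1 - s0, evalue=1e-20,
    )
    r.episode = episode
    return r


def brute_force_chains(intervals, max_gap=5000):
    """Independent oracle: maximal runs of sorted intervals where every
    consecutive pair satisfies 0 <= gap < max_gap."""
    order = sorted(range(len(intervals)), key=lambda i: intervals[i])
    chains, current = [], []
    for idx in order:
        if not current:
            current = [idx]
            continue
        prev = intervals[current[-1]]
        cur = intervals[idx]
        gap = cur[0] - prev[1]
        if 0 <= gap < max_gap:
            current.append(idx)
        else:
            if len(current) >= 2:
                chains.append(current)
            current = [idx]
    if len(current) >= 2:
        chains.append(current)
    return chains


class TestDetectClusters:
    def test_worked_example(self):
        recs = [
            _rec("a", 1000, 1200), _rec("b", 5000, 5300), _rec("c", 12000, 12100)
        ]
        clusters = detect_clusters(recs)
        assert len(clusters) == 1
        assert clusters[0].members == ["a", "b"]
        assert recs[2].cluster_id is None

    def test_overlapping_records_break_chains(self):
        recs = [_rec("a", 0, 500), _rec("b", 400, 900)]
        assert detect_clusters(recs) == []

    def test_eleven_records_at_4999bp_gaps_form_one_cluster(self):
        recs = []
        pos = 0
        for i in range(11):
            recs.append(_rec(f"r{i}", pos, pos + 100))
            pos += 100 + 4999
        clusters = detect_clusters(recs)
        assert len(clusters) == 1
        assert clusters[0].n_integrants == 11

    def test_gap_of_exactly_5000_breaks(self):
        recs = [_rec("a", 0, 100), _rec("b", 5100, 5200)]
        assert detect_clusters(recs) == []

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(31)
        for trial in range(100):
            n = int(rng.integers(2, 50))
            starts = np.sort(rng.integers(0, 60_000, size=n))
            lens = rng.integers(50, 3000, size=n)
            intervals = [(int(s), int(s + l)) for s, l in zip(starts, lens)]
            recs = [_rec(f"r{i}", s, e) for i, (s, e) in enumerate(intervals)]
            clusters = detect_clusters(recs)
            expected = brute_force_chains(intervals)
            got = sorted(sorted(int(m[1:]) for m in c.members) for c in clusters)
            want = sorted(sorted(c) for c in expected)
            assert got == want, f"trial {trial}"

    def test_membership_count_consistency(self):
        rng = np.random.default_rng(32)
        starts = np.sort(rng.integers(0, 100_000, size=60))
        recs = [_rec(f"r{i}", int(s), int(s) + 80) for i, s in enumerate(starts)]
        clusters = detect_clusters(recs)
        n_in_clusters = sum(c.n_integrants for c in clusters)
        n_flagged = sum(1 for r in recs if r.cluster_id is not None)
        assert n_in_clusters == n_flagged


class TestCollinearity:
    def test_identity_order_gives_tau_one(self):
        # donors 100, 900, 2000 in nuclear order -> perfectly collinear
        ordered = [
            _rec("a", 0, 100, 100, 200), _rec("b", 1000, 1100, 900, 1000),
            _rec("c", 2000, 2100, 2000, 2100),
        ]
        assert cluster_collinearity(ordered) == pytest.approx(1.0)

    def test_shuffled_donor_order(self):
        # donors 2000, 100, 900: 1 concordant pair, 2 discordant -> -1/3
        recs = [
            _rec("a", 0, 100, 2000, 2100), _rec("b", 1000, 1100, 100, 200),
            _rec("c", 2000, 2100, 900, 1000),
        ]
        assert cluster_collinearity(recs) == pytest.approx(-1 / 3)

    def test_two_members_distinct_donors(self):
        recs = [_rec("a", 0, 100, 500, 600), _rec("b", 1000, 1100, 100, 200)]
        assert abs(cluster_collinearity(recs)) == pytest.approx(1.0)

    def test_identical_donor_starts_undefined(self):
        recs = [_rec("a", 0, 100, 500, 600), _rec("b", 1000, 1100, 500, 600)]
        assert cluster_collinearity(recs) is None


class TestCorrelations:
    def test_perfect_reversal(self):
        recs = [
            _rec("a", 0, 1), _rec("b", 10, 12), _rec("c", 20, 23),
        ]
        for r, (L, p) in zip(recs, [(1, 3.0), (2, 2.0), (3, 1.0)]):
            r.aln_length, r.pident = L, p
        tau, _ = correlate_size_identity(recs, "kendall")
        rho, _ = correlate_size_identity(recs, "spearman")
        assert tau == pytest.approx(-1.0)
        assert rho == pytest.approx(-1.0)

    def test_negative_dependence_recovered(self):
        rng = np.random.default_rng(33)
        recs = []
        for i in range(2000):
            size = float(rng.lognormal(6, 1))
            ident = 100 - 2.0 * np.log10(size) - rng.normal(0, 1.5)
            r = _rec(f"r{i}", i * 10, i * 10 + 5)
            r.aln_length, r.pident = int(size), float(np.clip(ident, 50, 100))
            recs.append(r)
        tau, p = correlate_size_identity(recs, "kendall")
        assert tau < 0 and p < 0.01

    def test_null_calibration_independent_draws(self):
        taus, ps = [], []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            recs = []
            for i in range(2000):
                r = _rec(f"r{i}", i * 10, i * 10 + 5)
                r.aln_length = int(rng.lognormal(6, 1))
                r.pident = float(rng.uniform(70, 100))
                recs.append(r)
            tau, p = correlate_size_identity(recs, "kendall")
            taus.append(abs(tau))
            ps.append(p)
        ok = sum(1 for t, p in zip(taus, ps) if t < 0.05 and p > 0.01)
        assert ok >= 18

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            correlate_size_identity([_rec("a", 0, 1), _rec("b", 5, 6)])

    def test_constant_vector_sentinel(self):
        recs = [_rec(f"r{i}", i * 10, i * 10 + 5) for i in range(5)]
        for r in recs:
            r.aln_length = 100
        tau, p = correlate_size_identity(recs)
        assert np.isnan(tau) and np.isnan(p)


class TestClusterIdentityCorrelation:
    def _clusters(self, recs_by_cluster):
        clusters = detect_clusters([r for grp in recs_by_cluster for r in grp])
        return clusters

    def test_monotone_example_rho_one(self):
        groups = []
        base = 0
        for n, ident in [(2, 90.0), (3, 92.0), (4, 94.0)]:
            grp = []
            for i in range(n):
                grp.append(
                    _rec(f"c{base}_{i}", base + i * 200, base + i * 200 + 100,
                         pident=ident, episode="II")
                )
            groups.append(grp)
            base += 100_000
        out = correlate_cluster_identity(self._clusters(groups))
        rho, p = out["II"]
        assert rho == pytest.approx(1.0)

    def test_fewer_than_three_pure_clusters_sentinel(self):
        groups = []
        base = 0
        for ident in (90.0, 92.0):
            groups.append([
                _rec(f"c{base}_{i}", base + i * 200, base + i * 200 + 100,
                     pident=ident, episode="I")
                for i in range(2)
            ])
            base += 100_000
        out = correlate_cluster_identity(self._clusters(groups))
        assert np.isnan(out["I"][0])


class TestDensityTrack:
    def test_overlap_counts_both_windows(self):
        recs = [_rec("a", 150, 250)]
        (track,) = density_track(recs, {"chr1": 1000}, 100)
        assert track.counts[1] == 1 and track.counts[2] == 1
        assert track.counts[0] == 0

    def test_zero_records_all_zero(self):
        (track,) = density_track([], {"chr1": 1000}, 100)
        assert track.counts.sum() == 0

    def test_records_in_one_large_window(self):
        recs = [_rec(f"r{i}", 1000 * i, 1000 * i + 100) for i in range(10)]
        (track,) = density_track(recs, {"chr1": 400_000}, 500_000)
        assert len(track.counts) == 1
        assert track.counts[0] == 10

    def test_donor_space_uses_query_intervals(self):
        recs = [_rec("a", 500_000, 500_100, q0=150, q1=250)]
        (track,) = density_track(recs, {"cp": 1000}, 100, "plastid_donor")
        assert track.counts[1] == 1 and track.counts[2] == 1


class TestDonorPeaks:
    def test_flat_track_no_peaks(self):
        track = DensityTrack("cp", 100, np.full(50, 3))
        assert find_donor_peaks(track, []) == []

    def test_single_extreme_window(self):
        counts = np.ones(50, dtype=int)
        counts[20] = 40
        track = DensityTrack("cp", 100, counts)
        recs = [_rec(f"r{i}", 0, 50, q0=2010, q1=2060) for i in range(7)]
        peaks = find_donor_peaks(track, recs)
        assert len(peaks) == 1
        (lo, hi), n = peaks[0]
        assert (lo, hi) == (2000, 2100)
        assert n == 7

    def test_adjacent_hot_windows_merge(self):
        counts = np.ones(50, dtype=int)
        counts[10:12] = 30
        track = DensityTrack("cp", 100, counts)
        peaks = find_donor_peaks(track, [])
        assert len(peaks) == 1
        assert peaks[0][0] == (1000, 1200)


class TestFlankGc:
    def test_alternating_flank_gc_is_fifty(self):
        # NUPT at [200, 400); flanks are 'ATGC' repeats -> GC 50%
        chrom = ("AT" * 50) + ("ATGC" * 25) + ("A" * 200) + ("ATGC" * 25) + ("AT" * 150)
        seqs = [SequenceRecord("chr1", chrom)]
        recs = [_rec("a", 200, 400, episode="II")]
        out = flank_gc_analysis(recs, seqs, flank=100)
        assert out["II"].mean_flank_gc == pytest.approx(50.0)

    def test_no_background_windows_raises(self):
        seqs = [SequenceRecord("chr1", "ACGT" * 100)]
        recs = [_rec("a", 0, 400, episode="II")]
        with pytest.raises(ValueError):
            flank_gc_analysis(recs, seqs, flank=100)

    def test_null_calibration_matched_distributions(self):
        """Randomly placed records on a homogeneous genome: the flank vs
        background test should be null (no p < 0.001 except rarely)."""
        n_small = 0
        for seed in range(20):
            rng = np.random.default_rng(500 + seed)
            seqs = [SequenceRecord("chr1", random_seq(rng, 200_000, gc=0.4))]
            starts = np.sort(rng.choice(np.arange(500, 195_000, 500), 80, replace=False))
            recs = [
                _rec(f"r{i}", int(s), int(s) + 120, episode="II")
                for i, s in enumerate(starts)
            ]
            out = flank_gc_analysis(recs, seqs)
            if out["II"].p_value < 0.001:
                n_small += 1
        assert n_small <= 1
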