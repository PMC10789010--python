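import numpy as np
import pytest
from Bio import Align

from nuptscan.detect import (
    MaskedRegion,
    align_plastid_to_nuclear,
    filter_hits,
    karlin_altschul_params,
    mask_low_complexity,
)
from nuptscan.records import AlignmentHit, SequenceRecord, revcomp
from nuptscan.simulate import mutate_fragment

from conftest import random_seq


class TestMaskLowComplexity:
    def test_period_four_repeat_fully_masked(self):
        seq = SequenceRecord("q", "ACGT" * 16)  # 64 bp
        regions = mask_low_complexity(seq)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 64)
        # 4 distinct triplets, counts 15/15/16/16 over 62 windows
        assert regions[0].score == pytest.approx(
            (2 * 15 * 14 / 2 + 2 * 16 * 15 / 2) / 61
        )

    def test_random_sequence_mostly_unmasked(self, rng):
        seq = SequenceRecord("q", random_seq(rng, 10_000))
        regions = mask_low_complexity(seq)
        masked = sum(r.end - r.start for r in regions)
        assert masked < 0.05 * 10_000

    def test_at_stretch_masked_as_one_region(self, rng):
        core = "".join(rng.choice(list("AT"), size=200))
        seq = SequenceRecord("q", random_seq(rng, 300) + core + random_seq(rng, 300))
        regions = mask_low_complexity(seq)
        covering = [r for r in regions if r.start <= 320 and r.end >= 480]
        assert len(covering) == 1

    def test_small_window_rejected(self):
        with pytest.raises(ValueError):
            mask_low_complexity(SequenceRecord("q", "ACGT" * 10), window=4)

    def test_sequence_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            mask_low_complexity(SequenceRecord("q", "ACGTACGT"))


class TestKarlinAltschul:
    def test_lambda_for_plus1_minus2_scoring(self):
        # exact root of x^3 - 4x^2 + 3 = 0 with x = e^lambda
        lam, _ = karlin_altschul_params(1, -2)
        assert lam == pytest.approx(np.log((3 + np.sqrt(21)) / 2), rel=1e-9)

    def test_degenerate_scoring_rejected(self):
        with pytest.raises(ValueError):
            karlin_altschul_params(1, 0)


def _sw_oracle(qseq: str, sseq: str):
    """Optimal Smith-Waterman local alignment under +1/-2, gap 5+2g."""
    aligner = Align.PairwiseAligner(
        mode="local", match_score=1, mismatch_score=-2,
        open_gap_score=-7, extend_gap_score=-2,
    )
    aln = aligner.align(qseq, sseq)[0]
    qblocks, sblocks = aln.aligned
    q0, q1 = int(qblocks[0][0]), int(qblocks[-1][1])
    s0, s1 = int(sblocks[0][0]), int(sblocks[-1][1])
    matches = cols = 0
    for (qa, qb), (sa, sb) in zip(qblocks, sblocks):
        cols += qb - qa
        matches += sum(qseq[qa + i] == sseq[sa + i] for i in range(qb - qa))
    # count gap columns between blocks
    for i in range(1, len(qblocks)):
        cols += (qblocks[i][0] - qblocks[i - 1][1]) + (sblocks[i][0] - sblocks[i - 1][1])
    return q0, q1, s0, s1, 100.0 * matches / cols, float(aln.score)


class TestAligner:
    def test_exact_planted_fragment_single_hit(self, rng):
        plastid = SequenceRecord("cp", random_seq(rng, 20_000))
        frag = plastid.sequence[5000:5500]
        nuc = random_seq(rng, 25_000) + frag + random_seq(rng, 25_000)
        hits = align_plastid_to_nuclear(plastid, [SequenceRecord("chr1", nuc)])
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "+"
        assert h.pident >= 99.0
        assert h.s_start <= 25_000 and h.s_end >= 25_500
        assert h.q_start <= 5000 and h.q_end >= 5500

    def test_reverse_complement_fragment_minus_strand(self, rng):
        plastid = SequenceRecord("cp", random_seq(rng, 20_000))
        frag = revcomp(plastid.sequence[5000:5500])
        nuc = random_seq(rng, 25_000) + frag + random_seq(rng, 25_000)
        hits = align_plastid_to_nuclear(plastid, [SequenceRecord("chr1", nuc)])
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].q_start <= 5005 and hits[0].q_end >= 5495

    def test_negative_control_no_hits(self, rng):
        plastid = SequenceRecord("cp", random_seq(rng, 20_000))
        nuclear = [SequenceRecord("chr1", random_seq(rng, 50_000))]
        assert align_plastid_to_nuclear(plastid, nuclear) == []

    def test_degenerate_scoring_rejected(self, rng):
        plastid = SequenceRecord("cp", random_seq(rng, 1000))
        with pytest.raises(ValueError):
            align_plastid_to_nuclear(plastid, [plastid], mismatch=0)

    def test_agrees_with_smith_waterman_oracle(self):
        """On planted-fragment pairs <= 2 kb, reported identity is within
        1 point and endpoints within 5 bp of the optimal local alignment."""
        rng = np.random.default_rng(2024)
        n_checked = 0
        for trial in range(50):
            qlen = int(rng.integers(1200, 2000))
            plastid = SequenceRecord("cp", random_seq(rng, qlen))
            f0 = int(rng.integers(0, qlen - 600))
            flen = int(rng.integers(200, 600))
            ident = float(rng.uniform(82, 99))
            frag = mutate_fragment(
                plastid.sequence[f0 : f0 + flen], ident, 0.001, rng
            )
            pos = int(rng.integers(100, 1000))
            nuc = random_seq(rng, pos) + frag + random_seq(rng, 1800 - pos)
            hits = align_plastid_to_nuclear(plastid, [SequenceRecord("chr1", nuc)])
            assert hits, f"trial {trial}: planted fragment not detected"
            h = max(hits, key=lambda h: h.bitscore)
            q0, q1, s0, s1, pident, score = _sw_oracle(plastid.sequence, nuc)
            assert abs(h.pident - pident) <= 1.0, f"trial {trial}"
            for got, want in ((h.q_start, q0), (h.q_end, q1), (h.s_start, s0), (h.s_end, s1)):
                assert abs(got - want) <= 5, f"trial {trial}: {got} vs {want}"
            n_checked += 1
        assert n_checked == 50


class TestFilterHits:
    def _hit(self, q0, q1, length=None, s0=1000):
        length = length if length is not None else q1 - q0
        return AlignmentHit(
            query_id="cp", subject_id="chr1", pident=95.0, aln_length=length,
            mismatches=2, gap_opens=0, q_start=q0, q_end=q1,
            s_start=s0, s_end=s0 + (q1 - q0), strand="+",
            evalue=1e-12, bitscore=80.0,
        )

    def test_fully_masked_hit_dropped(self):
        masks = [MaskedRegion("cp", 100, 300, 5.0)]
        out = filter_hits([self._hit(120, 220)], masks)
        assert out == []

    def test_lightly_masked_hit_kept(self):
        masks = [MaskedRegion("cp", 100, 110, 5.0)]
        out = filter_hits([self._hit(100, 200)], masks)  # 10% overlap
        assert len(out) == 1

    def test_joint_filters_keep_only_clean_long_hit(self):
        masks = [MaskedRegion("cp", 0, 200, 5.0)]
        hits = [
            self._hit(50, 150, s0=1000),    # masked
            self._hit(500, 525, s0=2000),   # 25 bp, too short
            self._hit(600, 700, s0=3000),   # clean
        ]
        out = filter_hits(hits, masks)
        assert len(out) == 1
        assert out[0].q_start == 600

    def test_ids_ordered_by_nuclear_position(self):
        hits = [self._hit(600, 700, s0=9000), self._hit(100, 200, s0=1000)]
        out = filter_hits(hits, [])
        assert [r.id for r in out] == ["NUPT_1", "NUPT_2"]
        assert out[0].s_start == 1000


class TestDecoyRemoval:
    def test_planted_decoy_hits_all_filtered(self, small_dataset):
        """Hits whose donor lies in an A/T decoy region are removed with
        recall 1.0 by the low-complexity filter."""
        ds = small_dataset
        masks = mask_low_complexity(ds.plastid)
        hits = align_plastid_to_nuclear(ds.plastid, ds.nuclear)
        records = filter_hits(hits, masks)
        decoy_rows = ds.truth[ds.truth.is_decoy]
        assert len(decoy_rows) > 0
        for row in decoy_rows.itertuples():
            hit_at = [
                r for r in records
                if r.s_chrom == row.chrom
                and min(r.s_end, row.end) - max(r.s_start, row.start)
                >= 0.5 * (row.end - row.start)
            ]
            assert hit_at == [], f"decoy at {row.chrom}:{row.start} survived"
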