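import numpy as np
import pytest
from scipy import stats

from nuptscan.records import revcomp
from nuptscan.simulate import (
    EpisodeSpec,
    SimulationConfig,
    default_config,
    mutate_fragment,
    simulate_dataset,
    simulate_plastid,
)

from conftest import random_seq, small_sim_config


class TestSimulatePlastid:
    def test_irb_is_exact_revcomp_of_ira(self):
        cfg = small_sim_config(seed=0)
        ps = simulate_plastid(cfg)
        seq = ps.record.sequence
        a0, a1 = ps.ir.ira
        b0, b1 = ps.ir.irb
        assert seq[b0:b1] == revcomp(seq[a0:a1])
        assert a1 - a0 == cfg.ir_length

    def test_quadripartite_tiles_the_plastid(self):
        ps = simulate_plastid(small_sim_config(seed=1))
        ir = ps.ir
        assert ir.lsc[0] == 0
        assert ir.lsc[1] == ir.ira[0]
        assert ir.ira[1] == ir.ssc[0]
        assert ir.ssc[1] == ir.irb[0]
        assert ir.irb[1] == ps.record.length

    def test_decoy_regions_have_zero_gc(self):
        ps = simulate_plastid(small_sim_config(seed=2))
        assert len(ps.decoy_intervals) == 2
        for s, e in ps.decoy_intervals:
            stretch = ps.record.sequence[s:e]
            assert set(stretch) <= {"A", "T"}

    def test_seed_determinism(self):
        a = simulate_plastid(small_sim_config(seed=5))
        b = simulate_plastid(small_sim_config(seed=5))
        c = simulate_plastid(small_sim_config(seed=6))
        assert a.record.sequence == b.record.sequence
        assert a.record.sequence != c.record.sequence

    def test_infeasible_layout_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(plastid_length=3000, ir_length=1500)


class TestMutateFragment:
    def test_identity_100_no_indels_is_identity(self, rng):
        frag = random_seq(rng, 500)
        assert mutate_fragment(frag, 100.0, 0.0, rng) == frag

    def test_zero_indel_rate_preserves_length(self, rng):
        frag = random_seq(rng, 400)
        assert len(mutate_fragment(frag, 85.0, 0.0, rng)) == 400

    def test_realized_mismatch_fraction_tracks_target(self):
        """At 80% target on 10 kb the realized mismatch fraction sits
        within the binomial 99% interval (0.20 +/- ~0.0103)."""
        rng = np.random.default_rng(77)
        frag = random_seq(rng, 10_000)
        out = mutate_fragment(frag, 80.0, 0.0, rng)
        frac = np.mean([a != b for a, b in zip(frag, out)])
        assert abs(frac - 0.20) < 0.0105

    def test_invalid_identity_rejected(self, rng):
        with pytest.raises(ValueError):
            mutate_fragment(random_seq(rng, 100), 0.0, 0.0, rng)
        with pytest.raises(ValueError):
            mutate_fragment(random_seq(rng, 100), 101.0, 0.0, rng)

    def test_short_fragment_rejected(self, rng):
        with pytest.raises(ValueError):
            mutate_fragment("ACGT", 90.0, 0.0, rng)


class TestSimulateDataset:
    def test_truth_bookkeeping_counts(self, small_dataset):
        t = small_dataset.truth
        cfg = small_dataset.config
        planted = t[~t.is_decoy]
        for ep in cfg.episodes:
            assert (planted.episode == ep.name).sum() == ep.n_insertions
        assert t.is_decoy.sum() == cfg.decoy_insertions

    def test_cluster_fraction_produces_enough_chained_rows(self):
        cfg = default_config(seed=13)
        ds = simulate_dataset(cfg)
        n_total = sum(e.n_insertions for e in cfg.episodes)
        n_chained = (ds.truth.cluster_label != ".").sum()
        assert n_chained >= 0.19 * n_total

    def test_no_overlapping_truth_intervals(self, small_dataset):
        t = small_dataset.truth
        for _, g in t.groupby("chrom"):
            g = g.sort_values("start")
            assert (g.start.values[1:] >= g.end.values[:-1]).all()

    def test_same_seed_identical_output(self):
        a = simulate_dataset(small_sim_config(seed=9))
        b = simulate_dataset(small_sim_config(seed=9))
        assert a.plastid.sequence == b.plastid.sequence
        for ra, rb in zip(a.nuclear, b.nuclear):
            assert ra.sequence == rb.sequence
        assert a.truth.equals(b.truth)

    def test_planted_copy_matches_recorded_coordinates(self, small_dataset):
        """The nuclear slice at each truth interval is the mutated donor
        fragment: its identity to the donor matches the recorded realized
        identity (checked on indel-free fragments)."""
        ds = small_dataset
        chroms = {r.id: r.sequence for r in ds.nuclear}
        checked = 0
        for row in ds.truth[~ds.truth.is_decoy].head(40).itertuples():
            donor = ds.plastid.sequence[row.donor_start : row.donor_end]
            planted = chroms[row.chrom][row.start : row.end]
            if row.strand == "-":
                planted = revcomp(planted)
            if len(planted) != len(donor):
                continue  # indel-bearing copy
            ident = 100.0 * np.mean([a == b for a, b in zip(donor, planted)])
            if abs(ident - row.realized_identity) <= 1.0:
                checked += 1
        assert checked >= 30

    def test_realized_identity_tracks_drawn_identity_on_long_fragments(self):
        """For 5 kb fragments the realized identity is within 2 points of
        the drawn one (binomial sd ~0.57 at 79%)."""
        rng = np.random.default_rng(4242)
        frag = random_seq(rng, 5000)
        from nuptscan.simulate import _mutate_codes, _str_to_codes

        for target in (79.05, 93.1):
            for _ in range(10):
                _, n_sub = _mutate_codes(_str_to_codes(frag), target, 0.0, rng)
                realized = 100.0 * (1 - n_sub / 5000)
                assert abs(realized - target) <= 2.0

    def test_planted_sizes_follow_truncated_lognormal(self):
        """KS test of planted episode-II sizes against the configured
        truncated log-normal law at alpha = 0.01."""
        ep = EpisodeSpec("II", 93.1, 2.0, float(np.log(778.0)), 1.5, 600)
        cfg = small_sim_config(
            seed=21,
            episodes=[ep],
            chromosome_lengths=[4_000_000, 4_000_000],
            cluster_fraction=0.0,
            decoy_insertions=0,
        )
        ds = simulate_dataset(cfg)
        sizes = ds.truth.loc[~ds.truth.is_decoy, "size"].to_numpy(float)
        assert len(sizes) == 600
        lo, hi = cfg.min_fragment_size, max(sizes.max(), 1)
        dist = stats.lognorm(s=ep.size_log_sd, scale=np.exp(ep.size_log_mean))
        # truncated CDF on the realised support
        z_lo, z_hi = dist.cdf(lo - 0.5), 1.0
        # upper truncation bound equals the longest clean donor region
        hi_bound = sizes.max() + 1

        def cdf(v):
            c = (dist.cdf(np.clip(v, lo, None)) - z_lo) / (
                dist.cdf(hi_bound) - z_lo
            )
            return np.clip(c, 0, 1)

        res = stats.kstest(sizes, cdf)
        assert res.pvalue > 0.01

    def test_yaml_round_trip(self, tmp_path):
        cfg = default_config(seed=3)
        p = tmp_path / "sim.yaml"
        cfg.to_yaml(p)
        back = SimulationConfig.from_yaml(p)
        assert back == cfg
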