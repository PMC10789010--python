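import numpy as np
import pytest

from nuptscan.detect import align_plastid_to_nuclear, filter_hits, mask_low_complexity
from nuptscan.episodes import assign_episodes, fit_gmm_em
from nuptscan.records import SequenceRecord
from nuptscan.redundancy import find_inverted_repeats, flag_ir_redundant
from nuptscan.simulate import (
    EpisodeSpec,
    SimulationConfig,
    default_config,
    simulate_dataset,
)

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(BASES, size=n, p=p))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def small_sim_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A fast configuration for unit tests: ~200 kb genome, 60 insertions."""
    episodes = [
        EpisodeSpec("I", 79.05, 3.0, float(np.log(127.0)), 1.0, 15),
        EpisodeSpec("II", 93.1, 2.0, float(np.log(400.0)), 1.0, 45),
    ]
    cfg = dict(
        seed=seed,
        plastid_length=20_000,
        ir_length=2_000,
        chromosome_lengths=[250_000, 150_000],
        episodes=episodes,
        cluster_fraction=0.2,
        hotspot_count=0,
        donor_hotspot_count=0,
        decoy_insertions=5,
        episode_site_gc={},
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_sim_config(seed=3))


@pytest.fixture(scope="session")
def e2e_dataset():
    """The study-condition dataset: 10 Mb nuclear genome, 1000 planted
    insertions from the two episodes, decoys, IR donors, hotspots."""
    return simulate_dataset(default_config(seed=42))


@pytest.fixture(scope="session")
def e2e_records(e2e_dataset):
    """Full detection + IR dedup on the study-condition dataset."""
    ds = e2e_dataset
    masks = mask_low_complexity(ds.plastid)
    hits = align_plastid_to_nuclear(ds.plastid, ds.nuclear)
    records = filter_hits(hits, masks)
    ir = find_inverted_repeats(ds.plastid)
    flag_ir_redundant(records, ir)
    return records


@pytest.fixture(scope="session")
def e2e_assigned(e2e_dataset, e2e_records):
    """Records with episode labels from a k=2 mixture fit."""
    active = [r for r in e2e_records if not r.is_ir_redundant]
    x = np.array([r.pident for r in active])
    model = fit_gmm_em(x, 2, rng=np.random.default_rng(99))
    assign_episodes(e2e_records, model)
    return e2e_records, model
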