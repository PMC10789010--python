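"""Synthetic plastid + nuclear genomes with planted NUPTs of known truth.

The generator emulates the study conditions the pipeline is meant to
recover: a quadripartite plastid (LSC-IRA-SSC-IRB, IRB the exact reverse
complement of IRA) carrying A/T-rich low-complexity decoy regions, and a
multi-megabase nuclear genome seeded with insertions drawn from two
divergence episodes — an older one with percent identities around 79 and a
younger one around 93, each with a right-skewed (log-normal) size law
calibrated so the episode size medians are ~127 bp and ~778 bp. Optional
features: chained insertions forming clusters (consecutive gaps < 5 kb),
nuclear hotspots, donor hotspots on the plastid, post-insertion
fragmentation (collinear cluster generator), and episode-specific GC bias
at insertion sites. Every planted insertion is recorded in a ground-truth
table so detection, redundancy correction, episode assignment and spatial
statistics can all be scored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import SequenceRecord, revcomp
from .redundancy import IRAnnotation

__all__ = [
    "EpisodeSpec",
    "SimulationConfig",
    "SimulatedPlastid",
    "SimulatedDataset",
    "default_config",
    "simulate_plastid",
    "mutate_fragment",
    "simulate_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TRUTH_COLUMNS = [
    "chrom", "start", "end", "donor_start", "donor_end", "strand", "episode",
    "size", "drawn_identity", "realized_identity", "cluster_label",
    "from_ir", "is_decoy", "donor_hotspot",
]


@dataclass
class EpisodeSpec:
    """One episodic burst of plastid-to-nucleus transfer.

    ``identity_mean``/``identity_sd`` parameterize the Gaussian percent
    identity law (the divergence-as-age proxy); ``size_log_mean`` /
    ``size_log_sd`` the log-normal size law in bp (natural log).
    """

    name: str
    identity_mean: float
    identity_sd: float
    size_log_mean: float
    size_log_sd: float
    n_insertions: int
    indel_rate: float = 5e-4

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_mean <= 100.0):
            raise ValueError("identity_mean must be in (0, 100]")
        if self.identity_sd <= 0:
            raise ValueError("identity_sd must be positive")
        if self.n_insertions < 0:
            raise ValueError("n_insertions must be >= 0")


@dataclass
class SimulationConfig:
    seed: int = 0
    plastid_length: int = 20_000
    ir_length: int = 2_000
    chromosome_lengths: list[int] = field(
        default_factory=lambda: [2_500_000, 2_500_000, 2_500_000, 2_500_000]
    )
    episodes: list[EpisodeSpec] = field(default_factory=list)
    cluster_fraction: float = 0.2
    hotspot_count: int = 2
    hotspot_mean_occupancy: int = 25
    hotspot_width: int = 300_000
    donor_hotspot_count: int = 2
    donor_hotspot_width: int = 200
    donor_hotspot_n: int = 45
    decoy_lowcomplexity_regions: list[tuple[int, str]] = field(
        default_factory=lambda: [(200, "AT"), (350, "AT")]
    )
    decoy_insertions: int = 25
    background_gc: float = 0.357
    episode_site_gc: dict[str, float] = field(default_factory=dict)
    site_gc_halo: int = 150
    fragment_fraction: float = 0.0
    min_fragment_size: int = 33

    def __post_init__(self) -> None:
        if 2 * self.ir_length >= self.plastid_length:
            raise ValueError("2*ir_length must be < plastid_length")
        if any(l <= 0 for l in self.chromosome_lengths) or self.plastid_length <= 0:
            raise ValueError("all lengths must be positive")
        if not (0.0 <= self.cluster_fraction <= 1.0):
            raise ValueError("cluster_fraction must be in [0,1]")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosome_lengths)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["episodes"] = [dataclasses.asdict(e) for e in self.episodes]
        d["decoy_lowcomplexity_regions"] = [
            list(t) for t in self.decoy_lowcomplexity_regions
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["episodes"] = [EpisodeSpec(**e) for e in d.get("episodes", [])]
        d["decoy_lowcomplexity_regions"] = [
            (int(l), str(c)) for l, c in d.get("decoy_lowcomplexity_regions", [])
        ]
        return cls(**d)


def default_config(seed: int = 0) -> SimulationConfig:
    """Study-condition defaults: two episodes at 79.05% / 93.1% identity
    with log-normal sizes whose medians match the reported 127 / 778 bp."""
    episodes = [
        EpisodeSpec(
            name="I", identity_mean=79.05, identity_sd=3.0,
            size_log_mean=float(np.log(127.0)), size_log_sd=1.37,
            n_insertions=200,
        ),
        EpisodeSpec(
            name="II", identity_mean=93.1, identity_sd=2.0,
            size_log_mean=float(np.log(778.0)), size_log_sd=1.50,
            n_insertions=800,
        ),
    ]
    return SimulationConfig(
        seed=seed,
        episodes=episodes,
        episode_site_gc={"I": 0.364, "II": 0.323},
    )


@dataclass
class SimulatedPlastid:
    record: SequenceRecord
    ir: IRAnnotation
    decoy_intervals: list[tuple[int, int]]


@dataclass
class SimulatedDataset:
    plastid: SequenceRecord
    ir: IRAnnotation
    decoy_intervals: list[tuple[int, int]]
    nuclear: list[SequenceRecord]
    truth: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        from .io import write_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([SequenceRecord(self.plastid.id, self.plastid.sequence)], outdir / "plastid.fasta")
        write_fasta(self.nuclear, outdir / "nuclear.fasta")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.ir.to_tsv(outdir / "ir_annotation.tsv")
        self.config.to_yaml(outdir / "sim_config.yaml")


def _random_seq_codes(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _str_to_codes(seq: str) -> np.ndarray:
    table = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def simulate_plastid(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedPlastid:
    """Build the quadripartite plastid: LSC-IRA-SSC-IRB, IRB = revcomp(IRA).

    Decoy low-complexity stretches are written into the LSC at recorded,
    evenly spaced loci. Deterministic for a given config seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L, ir_len = config.plastid_length, config.ir_length
    single = L - 2 * ir_len
    lsc_len = int(round(single * 0.8))
    ssc_len = single - lsc_len
    if lsc_len <= 0 or ssc_len <= 0:
        raise ValueError("plastid layout infeasible for the given lengths")

    lsc = _random_seq_codes(rng, lsc_len, config.background_gc)
    ira = _random_seq_codes(rng, ir_len, config.background_gc)
    ssc = _random_seq_codes(rng, ssc_len, config.background_gc)

    decoys: list[tuple[int, int]] = []
    specs = config.decoy_lowcomplexity_regions
    if specs:
        total_decoy = sum(l for l, _ in specs)
        if total_decoy > lsc_len // 2:
            raise ValueError("decoy regions too long for the LSC")
        # pack decoys near the LSC start so one long decoy-free donor
        # stretch remains available
        pos = max(200, lsc_len // 20)
        for length, composition in specs:
            comp_codes = _str_to_codes(composition.upper())
            lsc[pos : pos + length] = rng.choice(comp_codes, size=length)
            decoys.append((pos, pos + length))
            pos += length + 300

    irb_seq = revcomp(_codes_to_str(ira))
    sequence = _codes_to_str(lsc) + _codes_to_str(ira) + _codes_to_str(ssc) + irb_seq
    annotation = IRAnnotation(
        lsc=(0, lsc_len),
        ira=(lsc_len, lsc_len + ir_len),
        ssc=(lsc_len + ir_len, lsc_len + ir_len + ssc_len),
        irb=(L - ir_len, L),
    )
    return SimulatedPlastid(SequenceRecord("plastid", sequence), annotation, decoys)


def _mutate_codes(
    codes: np.ndarray, target_identity: float, indel_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Mutated copy plus the substitution count (on the original sites)."""
    p_sub = 1.0 - target_identity / 100.0
    out = codes.copy()
    sub_mask = rng.random(len(out)) < p_sub
    n_sub = int(sub_mask.sum())
    if n_sub:
        shifts = rng.integers(1, 4, size=n_sub).astype(np.uint8)
        out[sub_mask] = (out[sub_mask] + shifts) % 4
    if indel_rate > 0:
        n_events = rng.binomial(len(out), indel_rate)
        if n_events:
            positions = np.sort(rng.integers(0, len(out), size=n_events))[::-1]
            for pos in positions:
                length = min(int(rng.geometric(0.5)), 3)
                if rng.random() < 0.5:  # deletion
                    out = np.delete(out, slice(pos, min(pos + length, len(out))))
                else:  # insertion of random bases
                    ins = rng.integers(0, 4, size=length).astype(np.uint8)
                    out = np.insert(out, pos, ins)
    return out, n_sub


def mutate_fragment(
    fragment: str,
    target_identity: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> str:
    """Diverge a donor fragment to a target percent identity.

    Each site is substituted with probability ``1 - identity/100``
    (uniformly over the three alternative bases, so a substitution always
    changes the base); indel events occur per-site at ``indel_rate`` with
    geometric lengths truncated at 3.
    """
    if not (0.0 < target_identity <= 100.0):
        raise ValueError("target_identity must be in (0, 100]")
    if len(fragment) < 30:
        raise ValueError("fragment must be at least 30 bp")
    out, _ = _mutate_codes(_str_to_codes(fragment), target_identity, indel_rate, rng)
    return _codes_to_str(out)


def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, n: int, lo: int, hi: int
) -> np.ndarray:
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = np.round(rng.lognormal(mu, sigma, size=2 * (n - filled))).astype(np.int64)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int, lo: float, hi: float
) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        ok = draw[(draw > lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _overlaps_any(start: int, end: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s < end and start < e for s, e in intervals)


def _sample_donor(
    rng: np.random.Generator,
    size: int,
    plastid_len: int,
    ir: IRAnnotation,
    decoys: list[tuple[int, int]],
    max_tries: int = 200,
) -> tuple[int, int, bool]:
    """Donor interval avoiding decoys and snapped fully inside/outside an IR.

    Keeping donors either wholly inside or wholly outside an IR copy makes
    the planted IR-duplicate count an exact oracle for the redundancy stage.
    Returns (start, end, from_ir).
    """
    irs = [ir.ira, ir.irb]
    for _ in range(max_tries):
        start = int(rng.integers(0, plastid_len - size + 1))
        end = start + size
        if _overlaps_any(start, end, decoys):
            continue
        inside = None
        partial = False
        for s, e in irs:
            ov = max(0, min(end, e) - max(start, s))
            if ov == 0:
                continue
            if ov == size:
                inside = (s, e)
            elif size <= e - s:
                # snap fully inside this IR copy
                start = min(max(start, s), e - size)
                end = start + size
                inside = (s, e)
            else:
                partial = True
            break
        if partial:
            continue
        if inside is None and any(
            s < end and start < e for s, e in irs
        ):
            continue
        return start, end, inside is not None
    raise RuntimeError("could not sample a donor interval; plastid too crowded")


class _Placer:
    """Non-overlapping interval placement on the nuclear chromosomes."""

    def __init__(self, rng: np.random.Generator, chrom_lengths: list[int]):
        self.rng = rng
        self.lengths = chrom_lengths
        self.names = [f"chr{i + 1}" for i in range(len(chrom_lengths))]
        self.placed: list[list[tuple[int, int]]] = [[] for _ in chrom_lengths]
        self.weights = np.asarray(chrom_lengths, dtype=float)
        self.weights /= self.weights.sum()

    def _free(self, ci: int, start: int, end: int) -> bool:
        return not _overlaps_any(start, end, self.placed[ci])

    def place_span(
        self, span: int, ci: int | None = None, region: tuple[int, int] | None = None,
        max_tries: int = 500,
    ) -> tuple[int, int]:
        """Find a free [start, start+span) slot; returns (chrom_idx, start)."""
        for _ in range(max_tries):
            c = int(self.rng.choice(len(self.lengths), p=self.weights)) if ci is None else ci
            lo, hi = 0, self.lengths[c] - span
            if region is not None:
                lo, hi = region[0], min(region[1], self.lengths[c]) - span
            if hi <= lo:
                if ci is not None or region is not None:
                    continue
                continue
            start = int(self.rng.integers(lo, hi + 1))
            if self._free(c, start, start + span):
                self.placed[c].append((start, start + span))
                return c, start
        raise RuntimeError(
            "could not place insertions without overlap; "
            "use longer chromosomes or fewer/smaller insertions"
        )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full synthetic dataset with its ground-truth table.

    Nuclear background is i.i.d. at ``background_gc``; planted fragments
    replace background slices (coordinates in the truth table are final
    assembly coordinates). All randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    plastid_sim = simulate_plastid(config, rng)
    plastid_codes = _str_to_codes(plastid_sim.record.sequence)
    L_plastid = plastid_sim.record.length
    ir = plastid_sim.ir

    total_n = sum(e.n_insertions for e in config.episodes)
    genome_bp = sum(config.chromosome_lengths)

    # draw per-insertion attributes episode by episode; donors must fit
    # wholly inside one plastid region and avoid decoys (so the IR-duplicate
    # oracle is exact and decoy hits are exactly the planted decoy copies)
    lsc_segments: list[tuple[int, int]] = []
    cursor = ir.lsc[0]
    for ds_, de_ in sorted(plastid_sim.decoy_intervals):
        if ds_ > cursor:
            lsc_segments.append((cursor, ds_))
        cursor = de_
    if ir.lsc[1] > cursor:
        lsc_segments.append((cursor, ir.lsc[1]))
    max_donor = max(
        max((e - s for s, e in lsc_segments), default=0),
        ir.ssc[1] - ir.ssc[0],
        ir.ira[1] - ir.ira[0],
    )
    inserts: list[dict] = []
    for ep in config.episodes:
        sizes = _truncated_lognormal(
            rng, ep.size_log_mean, ep.size_log_sd, ep.n_insertions,
            config.min_fragment_size, min(max_donor, genome_bp // 5),
        )
        idents = _truncated_normal(
            rng, ep.identity_mean, ep.identity_sd, ep.n_insertions, 50.0, 100.0
        )
        for s, pid in zip(sizes, idents):
            inserts.append(
                {
                    "episode": ep.name, "size": int(s), "drawn_identity": float(pid),
                    "indel_rate": ep.indel_rate, "cluster_label": None,
                    "donor_hotspot": None, "is_decoy": False,
                }
            )
    if sum(i["size"] for i in inserts) >= 0.2 * genome_bp:
        raise ValueError(
            "planted bp would exceed 20% of the nuclear genome; "
            "use longer chromosomes or fewer/smaller insertions"
        )
    order = rng.permutation(len(inserts))
    inserts = [inserts[i] for i in order]

    # donor hotspot assignment (small fragments drawn from narrow plastid windows)
    hotspot_windows: list[tuple[int, int]] = []
    if config.donor_hotspot_count > 0 and inserts:
        w = config.donor_hotspot_width
        lsc_lo, lsc_hi = ir.lsc
        pool = [i for i, ins in enumerate(inserts) if ins["episode"] == config.episodes[0].name]
        per = config.donor_hotspot_n
        for h in range(config.donor_hotspot_count):
            for _ in range(50):
                ws = int(rng.integers(lsc_lo, max(lsc_lo + 1, lsc_hi - w)))
                if not _overlaps_any(ws, ws + w, plastid_sim.decoy_intervals) and not _overlaps_any(
                    ws, ws + w, hotspot_windows
                ):
                    break
            hotspot_windows.append((ws, ws + w))
            chosen, pool = pool[:per], pool[per:]
            for i in chosen:
                ins = inserts[i]
                ins["donor_hotspot"] = f"dhs{h + 1}"
                ins["size"] = int(min(ins["size"], w))

    # donor coordinates
    for ins in inserts:
        if ins["donor_hotspot"] is not None:
            ws, we = hotspot_windows[int(ins["donor_hotspot"][3:]) - 1]
            size = ins["size"]
            hi = max(ws + 1, we - size)  # keep the donor midpoint in-window
            start = min(int(rng.integers(ws, hi)), L_plastid - size)
            ins["donor_start"], ins["donor_end"] = start, start + size
            ins["from_ir"] = False
        else:
            ds, de, from_ir = _sample_donor(
                rng, ins["size"], L_plastid, ir, plastid_sim.decoy_intervals
            )
            ins["donor_start"], ins["donor_end"], ins["from_ir"] = ds, de, from_ir

    # decoy copies: near-identical copies of the plastid low-complexity regions
    for _ in range(config.decoy_insertions if plastid_sim.decoy_intervals else 0):
        ds, de = plastid_sim.decoy_intervals[
            int(rng.integers(0, len(plastid_sim.decoy_intervals)))
        ]
        inserts.append(
            {
                "episode": "decoy", "size": de - ds, "drawn_identity": 97.0,
                "indel_rate": 0.0, "cluster_label": None, "donor_hotspot": None,
                "is_decoy": True, "donor_start": ds, "donor_end": de,
                "from_ir": False,
            }
        )

    # fragmentation: split some insertions into 2-4 collinear pieces
    frag_candidates = [
        i for i, ins in enumerate(inserts)
        if not ins["is_decoy"] and ins["size"] >= 4 * config.min_fragment_size
    ]
    n_frag = int(round(config.fragment_fraction * len(frag_candidates)))
    frag_ids = list(rng.choice(frag_candidates, size=n_frag, replace=False)) if n_frag else []
    fragmented: list[list[dict]] = []
    for fi, i in enumerate(sorted(frag_ids, reverse=True)):
        ins = inserts.pop(i)
        n_pieces = int(rng.integers(2, 5))
        cuts = np.sort(
            rng.choice(
                np.arange(config.min_fragment_size, ins["size"] - config.min_fragment_size),
                size=n_pieces - 1, replace=False,
            )
        ) if ins["size"] > 2 * config.min_fragment_size + n_pieces else np.array([], dtype=int)
        bounds = [0, *cuts.tolist(), ins["size"]]
        pieces = []
        for p in range(len(bounds) - 1):
            lo, hi = bounds[p], bounds[p + 1]
            if hi - lo < config.min_fragment_size:
                continue
            piece = dict(ins)
            piece["size"] = hi - lo
            piece["donor_start"] = ins["donor_start"] + lo
            piece["donor_end"] = ins["donor_start"] + hi
            piece["cluster_label"] = f"frag{fi + 1}"
            pieces.append(piece)
        if len(pieces) >= 2:
            fragmented.append(pieces)
        else:
            ins["cluster_label"] = None
            inserts.append(ins)

    # cluster chains from the remaining single pool
    singles = [ins for ins in inserts if not ins["is_decoy"]]
    decoy_single = [ins for ins in inserts if ins["is_decoy"]]
    n_clustered_target = int(round(config.cluster_fraction * total_n))
    chains: list[list[dict]] = []
    chain_pool: list[dict] = []
    by_episode: dict[str, list[dict]] = {}
    for ins in singles:
        by_episode.setdefault(ins["episode"], []).append(ins)
    n_clustered = 0
    ci = 0
    while n_clustered < n_clustered_target:
        # episode-pure chains, episode chosen proportionally to remaining pool
        avail = [(name, lst) for name, lst in by_episode.items() if len(lst) >= 2]
        if not avail:
            break
        weights = np.array([len(lst) for _, lst in avail], dtype=float)
        name, lst = avail[int(rng.choice(len(avail), p=weights / weights.sum()))]
        want = int(rng.integers(2, 6))
        want = min(want, len(lst), n_clustered_target - n_clustered + 1)
        if want < 2:
            want = 2
        members = [lst.pop() for _ in range(min(want, len(lst)))]
        ci += 1
        for m in members:
            m["cluster_label"] = f"chain{ci}"
        chains.append(members)
        n_clustered += len(members)
    chain_pool = [ins for lst in by_episode.values() for ins in lst]

    # nuclear placement
    placer = _Placer(rng, config.chromosome_lengths)
    placements: list[dict] = []

    def place_chain(members: list[dict], region=None, ci_=None) -> None:
        gaps = [int(rng.integers(0, 5000)) for _ in range(len(members) - 1)]
        span = sum(m["size"] for m in members) + sum(gaps)
        c, start = placer.place_span(span, ci=ci_, region=region)
        pos = start
        for gi, m in enumerate(members):
            m["chrom"] = placer.names[c]
            m["start"] = pos
            m["end"] = pos + m["size"]
            placements.append(m)
            pos = m["end"] + (gaps[gi] if gi < len(gaps) else 0)

    for members in chains:
        place_chain(members)
    for pieces in fragmented:
        place_chain(pieces)

    # nuclear hotspots take from the youngest episode's single pool
    hotspot_regions: list[tuple[int, tuple[int, int]]] = []
    if config.hotspot_count > 0 and chain_pool:
        young = config.episodes[-1].name if config.episodes else None
        for _ in range(config.hotspot_count):
            c = int(rng.integers(0, len(config.chromosome_lengths)))
            width = min(config.hotspot_width, config.chromosome_lengths[c])
            rs = int(rng.integers(0, config.chromosome_lengths[c] - width + 1))
            hotspot_regions.append((c, (rs, rs + width)))
            n_extra = 1 + int(rng.geometric(1.0 / config.hotspot_mean_occupancy))
            chosen = [m for m in chain_pool if m["episode"] == young][:n_extra]
            for m in chosen:
                chain_pool.remove(m)
                c2, start = placer.place_span(m["size"], ci=c, region=(rs, rs + width))
                m["chrom"] = placer.names[c2]
                m["start"], m["end"] = start, start + m["size"]
                placements.append(m)

    for m in chain_pool + decoy_single:
        c, start = placer.place_span(m["size"])
        m["chrom"] = placer.names[c]
        m["start"], m["end"] = start, start + m["size"]
        placements.append(m)

    # mutate fragments and assemble chromosomes
    chrom_codes = {
        name: _random_seq_codes(rng, length, config.background_gc)
        for name, length in zip(placer.names, config.chromosome_lengths)
    }
    rows = []
    prepared = []
    for m in placements:
        frag = plastid_codes[m["donor_start"] : m["donor_end"]]
        mutated, n_sub = _mutate_codes(frag, m["drawn_identity"], m["indel_rate"], rng)
        realized = 100.0 * (1.0 - n_sub / len(frag))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            mutated = _str_to_codes(revcomp(_codes_to_str(mutated)))
        # never overrun the reserved slot (indels may lengthen the copy)
        if len(mutated) > m["size"]:
            mutated = mutated[: m["size"]]
        prepared.append((m, mutated, realized, strand))

    # pass 1: GC-bias halos around insertion sites (before any insert is
    # written, so a halo never clobbers a neighbouring planted copy)
    for m, mutated, _, _ in prepared:
        site_gc = config.episode_site_gc.get(m["episode"])
        if site_gc is None or config.site_gc_halo <= 0:
            continue
        target = chrom_codes[m["chrom"]]
        halo = config.site_gc_halo
        lo = max(0, m["start"] - halo)
        hi = min(len(target), m["start"] + len(mutated) + halo)
        target[lo:hi] = _random_seq_codes(rng, hi - lo, site_gc)

    # pass 2: the planted copies themselves
    for m, mutated, realized, strand in prepared:
        target = chrom_codes[m["chrom"]]
        end = min(m["start"] + len(mutated), len(target))
        mutated = mutated[: end - m["start"]]
        target[m["start"] : end] = mutated
        rows.append(
            {
                "chrom": m["chrom"], "start": m["start"], "end": end,
                "donor_start": m["donor_start"], "donor_end": m["donor_end"],
                "strand": strand, "episode": m["episode"], "size": end - m["start"],
                "drawn_identity": round(m["drawn_identity"], 4),
                "realized_identity": round(realized, 4),
                "cluster_label": m["cluster_label"] or ".",
                "from_ir": bool(m.get("from_ir", False)),
                "is_decoy": bool(m["is_decoy"]),
                "donor_hotspot": m["donor_hotspot"] or ".",
            }
        )

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS).sort_values(
        ["chrom", "start"], kind="mergesort"
    ).reset_index(drop=True)
    nuclear = [
        SequenceRecord(name, _codes_to_str(chrom_codes[name])) for name in placer.names
    ]
    return SimulatedDataset(
        plastid=plastid_sim.record,
        ir=ir,
        decoy_intervals=plastid_sim.decoy_intervals,
        nuclear=nuclear,
        truth=truth,
        config=config,
    )
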