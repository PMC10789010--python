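"""End-to-end orchestration: simulate/ingest -> detect -> dedup ->
episodes -> spatial -> consolidated report.

Every stage persists its artifacts into the output directory so any stage
can be re-run from intermediates; the whole run is deterministic given the
configured seed (report.json contains no timestamps or absolute paths).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import detect, episodes, io, redundancy, spatial
from .records import NuptRecord, SequenceRecord
from .simulate import SimulationConfig, default_config, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "check_consistency"]


@dataclass
class RunConfig:
    outdir: str = "nuptscan_run"
    seed: int = 0
    # inputs: either a simulation or real files
    simulate: bool = True
    sim_config: SimulationConfig | None = None
    plastid_path: str | None = None
    nuclear_path: str | None = None
    hits_path: str | None = None
    ir_annotation_path: str | None = None
    # detection
    word_size: int = 9
    max_evalue: float = 1e-5
    dust_window: int = 64
    dust_threshold: float = 2.0
    max_masked_fraction: float = 0.5
    min_length: int = 30
    # redundancy
    min_ir_length: int = 1000
    # episodes
    k_max: int = 9
    B: int = 200
    alpha: float = 0.01
    assign_threshold: float = 0.95
    # spatial
    max_gap: int = 5000
    nuclear_window: int = 500_000
    plastid_window: int = 100
    flank: int = 100
    background_window: int = 100
    peak_z: float = 3.0

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        if self.sim_config is not None:
            d["sim_config"] = dataclasses.asdict(self.sim_config)
            d["sim_config"]["episodes"] = [
                dataclasses.asdict(e) for e in self.sim_config.episodes
            ]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        from .simulate import EpisodeSpec

        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = d.get("sim_config")
        if sim is not None:
            sim["episodes"] = [EpisodeSpec(**e) for e in sim.get("episodes", [])]
            sim["decoy_lowcomplexity_regions"] = [
                (int(l), str(c)) for l, c in sim.get("decoy_lowcomplexity_regions", [])
            ]
            d["sim_config"] = SimulationConfig(**sim)
        return cls(**d)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
            logger.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("simulate")
def _stage_inputs(config: RunConfig, outdir: Path):
    if config.simulate:
        sim_cfg = config.sim_config or default_config(seed=config.seed)
        ds = simulate_dataset(sim_cfg)
        ds.write(outdir)
        return ds.plastid, ds.nuclear, ds.truth
    if not config.plastid_path or not config.nuclear_path:
        raise FileNotFoundError("plastid_path and nuclear_path are required")
    plastid = io.read_fasta(config.plastid_path)[0]
    nuclear = io.read_fasta(config.nuclear_path)
    return plastid, nuclear, None


@_stage("detect")
def _stage_detect(config: RunConfig, outdir: Path, plastid, nuclear):
    masks = detect.mask_low_complexity(
        plastid, window=config.dust_window, threshold=config.dust_threshold
    )
    if config.hits_path:
        hits = io.read_blast_tab(config.hits_path)
    else:
        hits = detect.align_plastid_to_nuclear(
            plastid, nuclear, word_size=config.word_size, max_evalue=config.max_evalue
        )
        io.write_blast_tab(hits, outdir / "hits.tsv")
    records = detect.filter_hits(
        hits, masks,
        max_masked_fraction=config.max_masked_fraction,
        min_length=config.min_length,
    )
    io.write_nupt_table(records, outdir / "nupts.tsv")
    return hits, masks, records


@_stage("dedup")
def _stage_dedup(config: RunConfig, outdir: Path, plastid, nuclear, records):
    if config.ir_annotation_path:
        ir = redundancy.IRAnnotation.from_tsv(config.ir_annotation_path)
    else:
        ir = redundancy.find_inverted_repeats(plastid, min_ir_length=config.min_ir_length)
    redundancy.flag_ir_redundant(records, ir)
    fractions = redundancy.genome_fraction(records, nuclear, dedup=True)
    fractions.to_json(outdir / "fractions.json")
    io.write_nupt_table(records, outdir / "nupts.dedup.tsv")
    ir.to_tsv(outdir / "ir_detected.tsv")
    return ir, fractions


@_stage("episodes")
def _stage_episodes(config: RunConfig, outdir: Path, records):
    active = [r for r in records if not r.is_ir_redundant]
    x = np.array([r.pident for r in active])
    rng = np.random.default_rng(config.seed + 1)
    k, decisions = episodes.select_k_bootstrap(
        x, k_max=config.k_max, B=config.B, alpha=config.alpha, rng=rng
    )
    model = episodes.fit_gmm_em(x, k, rng=np.random.default_rng(config.seed + 2))
    episodes.assign_episodes(records, model, threshold=config.assign_threshold)
    with open(outdir / "model.json", "w") as fh:
        json.dump(
            {
                "k_selected": k,
                "model": model.to_dict(),
                "bootstrap": [d.to_dict() for d in decisions],
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    summary = episodes.summarize_episodes(active)
    summary.to_csv(outdir / "episode_summary.tsv", sep="\t", index=False)
    io.write_nupt_table(records, outdir / "nupts.episodes.tsv")
    # histogram + per-component densities for plotting
    edges = np.arange(np.floor(x.min()), np.ceil(x.max()) + 0.5, 0.5)
    hist, _ = np.histogram(x, bins=edges)
    dens_rows = []
    for lo, hi, h in zip(edges[:-1], edges[1:], hist):
        mid = (lo + hi) / 2
        row = {"bin_start": lo, "bin_end": hi, "count": int(h)}
        for j in range(k):
            z = (mid - model.means_[j]) / model.sds_[j]
            row[f"density_{j + 1}"] = float(
                model.weights_[j] * np.exp(-0.5 * z * z)
                / (model.sds_[j] * np.sqrt(2 * np.pi))
            )
        dens_rows.append(row)
    import pandas as pd

    pd.DataFrame(dens_rows).to_csv(outdir / "identity_histogram.tsv", sep="\t", index=False)
    return k, model, decisions, summary


@_stage("spatial")
def _stage_spatial(config: RunConfig, outdir: Path, plastid, nuclear, records):
    import pandas as pd

    active = [r for r in records if not r.is_ir_redundant]
    clusters = spatial.detect_clusters(active, max_gap=config.max_gap)
    cl_rows = [
        {
            "cluster_id": c.cluster_id, "chrom": c.s_chrom, "start": c.start,
            "end": c.end, "span": c.span, "n_integrants": c.n_integrants,
            "total_bp": c.total_bp, "mean_pident": round(c.mean_pident, 3),
            "episodes": ";".join(f"{k}:{v}" for k, v in sorted(c.episode_composition.items())),
            "collinearity_tau": "" if c.collinearity_tau is None else round(c.collinearity_tau, 4),
            "members": ",".join(c.members),
        }
        for c in clusters
    ]
    pd.DataFrame(
        cl_rows,
        columns=[
            "cluster_id", "chrom", "start", "end", "span", "n_integrants",
            "total_bp", "mean_pident", "episodes", "collinearity_tau", "members",
        ],
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)

    nuc_lengths = {r.id: r.length for r in nuclear}
    nuc_tracks = spatial.density_track(active, nuc_lengths, config.nuclear_window)
    pd.concat([t.to_frame() for t in nuc_tracks]).to_csv(
        outdir / "density_nuclear.tsv", sep="\t", index=False
    )
    donor_track = spatial.density_track(
        active, {plastid.id: plastid.length}, config.plastid_window,
        coordinate_space="plastid_donor",
    )[0]
    donor_track.to_frame().to_csv(outdir / "density_plastid.tsv", sep="\t", index=False)
    # donor peaks are a feature of the older episode's track (episode I);
    # fall back to all records when no episode labels are present
    ep1 = [r for r in active if r.episode == "I"]
    peak_records = ep1 if ep1 else active
    peak_track = spatial.density_track(
        peak_records, {plastid.id: plastid.length}, config.plastid_window,
        coordinate_space="plastid_donor",
    )[0]
    peaks = spatial.find_donor_peaks(peak_track, peak_records, z=config.peak_z)
    pd.DataFrame(
        [{"start": p[0][0], "end": p[0][1], "n_records": p[1]} for p in peaks],
        columns=["start", "end", "n_records"],
    ).to_csv(outdir / "peaks.tsv", sep="\t", index=False)

    correlations = {}
    for method in ("kendall", "spearman"):
        for ep in ("I", "II"):
            sub = [r for r in active if r.episode == ep]
            if len(sub) >= 3:
                stat, p = spatial.correlate_size_identity(sub, method=method)
                correlations[f"{method}_{ep}"] = {"statistic": stat, "p_value": p}
    cluster_corr = {
        ep: {"rho": v[0], "p_value": v[1]}
        for ep, v in spatial.correlate_cluster_identity(clusters).items()
    }

    flank_reports = spatial.flank_gc_analysis(
        active, nuclear, flank=config.flank, background_window=config.background_window
    )
    with open(outdir / "flank_gc.json", "w") as fh:
        json.dump(
            {ep: dataclasses.asdict(r) for ep, r in flank_reports.items()},
            fh, indent=2, sort_keys=True, default=float,
        )
        fh.write("\n")
    io.write_nupt_table(records, outdir / "nupts.final.tsv")
    return clusters, nuc_tracks, donor_track, peaks, correlations, cluster_corr, flank_reports


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and persists) the consolidated report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "run_config.yaml")

    plastid, nuclear, truth = _stage_inputs(config, outdir)
    hits, masks, records = _stage_detect(config, outdir, plastid, nuclear)
    ir, fractions = _stage_dedup(config, outdir, plastid, nuclear, records)
    k, model, decisions, summary = _stage_episodes(config, outdir, records)
    (clusters, nuc_tracks, donor_track, peaks, correlations, cluster_corr,
     flank_reports) = _stage_spatial(config, outdir, plastid, nuclear, records)

    active = [r for r in records if not r.is_ir_redundant]
    clustered = [r for r in active if r.cluster_id is not None]
    ep_counts: dict[str, int] = {}
    ep_bp: dict[str, int] = {}
    for r in active:
        ep_counts[r.episode] = ep_counts.get(r.episode, 0) + 1
        ep_bp[r.episode] = ep_bp.get(r.episode, 0) + r.aln_length

    report = {
        "seed": config.seed,
        "counts": {
            "hits": len(hits),
            "masked_regions": len(masks),
            "nupts": len(records),
            "ir_redundant": fractions.n_redundant,
            "nupts_nonredundant": len(active),
            "clusters": len(clusters),
            "clustered_nupts": len(clustered),
            "clustered_bp": sum(r.aln_length for r in clustered),
            "total_bp": sum(r.aln_length for r in active),
        },
        "episode_counts": ep_counts,
        "episode_bp": ep_bp,
        "fractions": dataclasses.asdict(fractions),
        "mixture": {
            "k_selected": k,
            **model.to_dict(),
            "bootstrap_p_values": [d.p_value for d in decisions],
        },
        "correlations_size_identity": correlations,
        "correlations_cluster_identity": cluster_corr,
        "donor_peaks": [
            {"start": p[0][0], "end": p[0][1], "n_records": p[1]} for p in peaks
        ],
        "flank_gc": {ep: dataclasses.asdict(r) for ep, r in flank_reports.items()},
    }
    violations = check_consistency(report)
    report["consistency_violations"] = violations
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    _write_report_md(report, outdir / "report.md")
    return report


def check_consistency(report: dict) -> list[str]:
    """Cross-checks between report sections; empty list means consistent."""
    v: list[str] = []
    counts = report.get("counts", {})
    ep_n = sum(report.get("episode_counts", {}).values())
    if ep_n != counts.get("nupts_nonredundant", ep_n):
        v.append(
            f"episode counts sum to {ep_n}, expected "
            f"{counts.get('nupts_nonredundant')}"
        )
    if counts.get("clustered_bp", 0) > counts.get("total_bp", 0):
        v.append("clustered bp exceeds total bp")
    fr = report.get("fractions", {})
    if fr and fr.get("fraction_dedup", 0.0) > fr.get("fraction_raw", 0.0) + 1e-12:
        v.append("fraction_dedup exceeds fraction_raw")
    return v


def _write_report_md(report: dict, path: Path) -> None:
    c = report["counts"]
    fr = report["fractions"]
    mix = report["mixture"]
    lines = [
        "# nuptscan run report",
        "",
        f"seed: {report['seed']}",
        "",
        "## Detection",
        f"- alignments: {c['hits']}",
        f"- NUPTs after filtering: {c['nupts']}",
        f"- IR-redundant: {c['ir_redundant']}",
        "",
        "## Genome fraction",
        f"- plastid DNA fraction: {fr['fraction_raw']:.2f}% raw, "
        f"{fr['fraction_dedup']:.2f}% after IR dedup",
        "",
        "## Episodes",
        f"- selected k: {mix['k_selected']}",
        f"- component means: {', '.join(f'{m:.2f}' for m in mix['means'])}",
        f"- component weights: {', '.join(f'{w:.3f}' for w in mix['weights'])}",
        "- per-episode n: "
        + ", ".join(f"{k}={v}" for k, v in sorted(report["episode_counts"].items())),
        "",
        "## Clusters",
        f"- clusters: {c['clusters']} hosting {c['clustered_nupts']} NUPTs "
        f"({c['clustered_bp']} bp)",
        "",
        "## Flanking GC",
    ]
    for ep, r in sorted(report["flank_gc"].items()):
        lines.append(
            f"- episode {ep}: flank GC {r['mean_flank_gc']:.2f}% vs background "
            f"{r['background_gc']:.2f}% (U={r['u_statistic']:.0f}, p={r['p_value']:.3g})"
        )
    if report["consistency_violations"]:
        lines += ["", "## Consistency violations"] + [
            f"- {x}" for x in report["consistency_violations"]
        ]
    path.write_text("\n".join(lines) + "\n")
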