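"""End-to-end orchestration: simulate -> coverage -> enrichment (-> SPR).

A run is driven by one YAML config and is fully deterministic for fixed
seeds: every number in the final TSV reports is recomputable from the truth
BED files alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .coverage import (
    compute_depth,
    median_chromosome_depth,
    normalize_depth,
    average_replicates,
    write_bedgraph,
)
from .enrichment import (
    average_reports,
    build_report,
    counts_from_alignments,
    write_report_tsv,
)
from .genome import build_design, write_fasta, write_sites_bed, write_model_yaml
from .simulate import ProtectionParams, simulate_reads, truth_to_alignments
from .spr import KineticParams, fit_titrations, simulate_sensorgram, write_sensorgrams_tsv
from .stats import DiameterSummary, summarize_diameters  # re-exported CLI surface


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""


@dataclass
class PipelineConfig:
    """One packaging-analysis run: design, protection model, replicates, SPR."""

    design: str = "lacO8"
    design_seed: int = 0
    backbone_length: int = 5000
    replicates: int = 2
    seeds: list[int] = field(default_factory=lambda: [1, 2])
    packaging: dict[str, Any] = field(default_factory=dict)
    policy: str = "overlap_any"
    output_dir: str | None = None
    spr: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if len(self.seeds) != self.replicates:
            raise ValueError("len(seeds) must equal replicates")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)


def _params_for(config: PipelineConfig, seed: int) -> ProtectionParams:
    kwargs = dict(config.packaging)
    kwargs.pop("seed", None)
    return ProtectionParams(seed=seed, **kwargs)


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> Path:
    """Run all stages; returns the run directory.

    Layout: rep{i}/ holds reads.fastq, truth.bed and per-replicon bedGraph
    tracks (raw + normalized); the run root holds enrichment_summary.tsv,
    averaged normalized tracks, the model FASTA/BED/YAML and run.log.
    """
    out = Path(output_dir or config.output_dir or "pdupack_run")
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"pdupack {__version__}", f"design={config.design} design_seed={config.design_seed}"]

    try:
        model = build_design(
            config.design, backbone_length=config.backbone_length, seed=config.design_seed
        )
        write_fasta(model, out / "reference.fasta")
        write_sites_bed(model, out / "sites.bed")
        write_model_yaml(model, out / "model.yaml")
    except Exception as exc:
        raise PipelineError(f"stage genome_model: {exc}") from exc

    reports = []
    norm_by_replicon: dict[str, list] = {r.name: [] for r in model.replicons}
    for i, seed in enumerate(config.seeds, start=1):
        rep_dir = out / f"rep{i}"
        rep_dir.mkdir(exist_ok=True)
        try:
            params = _params_for(config, seed)
            sim = simulate_reads(
                model, params, rep_dir / "reads.fastq", rep_dir / "truth.bed"
            )
        except Exception as exc:
            raise PipelineError(f"stage packaging_sim (replicate {i}): {exc}") from exc
        log_lines.append(f"replicate {i}: seed={seed} n_reads={len(sim.truth)}")

        try:
            alignments = truth_to_alignments(sim.truth)
            chrom_track = compute_depth(alignments, model.chromosome)
            median = median_chromosome_depth(chrom_track)
            log_lines.append(f"replicate {i}: chromosome_median={median:g}")
            for replicon in model.replicons:
                track = (
                    chrom_track
                    if replicon.is_chromosome
                    else compute_depth(alignments, replicon)
                )
                write_bedgraph(
                    replicon.name, track.depth, rep_dir / f"{replicon.name}.raw.bedgraph", "%d"
                )
                norm = normalize_depth(track, median)
                norm_by_replicon[replicon.name].append(norm)
                write_bedgraph(
                    replicon.name,
                    np.round(norm.values, 6),
                    rep_dir / f"{replicon.name}.norm.bedgraph",
                    "%.6f",
                )
        except Exception as exc:
            raise PipelineError(f"stage coverage (replicate {i}): {exc}") from exc

        try:
            counts = counts_from_alignments(alignments, model, policy=config.policy)
            reports.append(build_report(counts, model))
            log_lines.append(
                f"replicate {i}: per_replicon={counts.per_replicon} "
                f"segment_count={counts.segment_count}"
            )
        except Exception as exc:
            raise PipelineError(f"stage enrichment (replicate {i}): {exc}") from exc

    try:
        averaged = average_reports(reports)
        write_report_tsv(reports, model, out / "enrichment_summary.tsv", averaged)
        for name, tracks in norm_by_replicon.items():
            avg = average_replicates(tracks)
            write_bedgraph(
                name, np.round(avg.values, 6), out / f"{name}.norm.avg.bedgraph", "%.6f"
            )
    except Exception as exc:
        raise PipelineError(f"stage reporting: {exc}") from exc

    if config.spr:
        try:
            _run_spr_block(config.spr, out, log_lines)
        except Exception as exc:
            raise PipelineError(f"stage spr: {exc}") from exc

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


def _run_spr_block(block: dict[str, Any], out: Path, log_lines: list[str]) -> None:
    """Simulate the configured titrations, fit them, write TSV + YAML report."""
    truth = KineticParams(
        ka=float(block["ka"]), kd=float(block["kd"]), rmax=float(block["rmax"])
    )
    concentrations = [float(c) for c in block["concentrations"]]
    noise_sd = float(block.get("noise_sd", 0.0))
    n_titrations = int(block.get("titrations", 2))
    t_assoc = float(block.get("t_assoc", 120.0))
    t_dissoc = float(block.get("t_dissoc", 80.0))
    dt = float(block.get("dt", 0.1))
    seed = int(block.get("seed", 0))
    rng = np.random.default_rng(seed)
    titrations = [
        [
            simulate_sensorgram(truth, c, t_assoc, t_dissoc, dt, noise_sd, rng)
            for c in concentrations
        ]
        for _ in range(n_titrations)
    ]
    write_sensorgrams_tsv([g for t in titrations for g in t], out / "sensorgrams.tsv")
    fit = fit_titrations(titrations)
    report = {
        "ka_per_M_s": fit.params.ka,
        "kd_per_s": fit.params.kd,
        "rmax_RU": fit.params.rmax,
        "KD_M": fit.params.KD,
        "KD_mean_M": fit.KD_mean,
        "KD_sd_M": fit.KD_sd,
        "residual_rms_RU": fit.residual_rms,
        "n_titrations": fit.n_titrations,
    }
    (out / "spr_fit.yaml").write_text(yaml.safe_dump(report, sort_keys=False))
    log_lines.append(f"spr: KD_mean={fit.KD_mean:.4g} M over {fit.n_titrations} titrations")
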