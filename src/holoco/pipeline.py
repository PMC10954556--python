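"""Configuration and the end-to-end driver.

``run_pipeline`` chains simulation (or loading) -> QC -> crossover calling
-> landscape and genetic map -> interference statistics -> feature
association, writing every intermediate as a plain-text artifact plus a
JSON manifest of parameters. All defaults are the study's printed values.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, interference, io, landscape, qc
from .calling import CallerParams, CrossoverInterval, genotype_cell
from .simulate import MeiosisModel, ObservationModel, simulate_cohort, simulate_reference

__all__ = ["PipelineConfig", "run_pipeline", "call_cohort"]


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults mirror the published thresholds."""

    # synthetic inputs
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i+1}": 2_000_000 for i in range(5)}
    )
    marker_spacing: float = 449.0
    genetic_length_cM: dict[str, float] = field(
        default_factory=lambda: {f"chr{i+1}": 60.0 for i in range(5)}
    )
    nu: float = 5.0
    distal_bias_weight: float = 0.0
    n_cells: int = 500
    markers_per_cell: dict = field(default_factory=lambda: {"kind": "lognormal", "median": 700.0, "sigma": 0.6})
    error_rate: float = 0.01
    doublet_fraction: float = 0.05
    # QC. The published read filter (>5,000 read pairs per barcode) counts
    # all reads, not marker-covering reads; synthetic observations only
    # model marker reads, so the read filter defaults off here and the
    # module-level default in holoco.qc keeps the published value.
    min_reads: int = 0
    min_markers: int = 400
    switch_threshold: float = 0.07
    min_align_rate: float = 25.0
    # caller
    min_block_markers: int = 5
    block_span_bp: int = 1_000_000
    min_double_co_sep: int = 2_000_000
    # landscape / map
    rate_window: int = 1_000_000
    rate_step: int = 100_000
    thin_window: int = 500_000
    # interference
    coc_intervals: int = 15
    coc_rounds: int = 100
    # association
    permutation_rounds: int = 5_000
    # global
    seed: int = 0

    def validate(self) -> None:
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate outside [0, 0.5)")
        if self.min_reads < 0 or self.min_markers < 0:
            raise ValueError("negative QC thresholds")
        if self.switch_threshold <= 0 or self.switch_threshold >= 1:
            raise ValueError("switch threshold outside (0, 1)")
        if self.permutation_rounds < 1 or self.coc_rounds < 1:
            raise ValueError("round counts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg


def call_cohort(cells, params: CallerParams) -> tuple[list[CrossoverInterval], dict[str, int]]:
    """Run the caller over QC-passing cells; returns all COs + per-cell counts."""
    cos: list[CrossoverInterval] = []
    counts: dict[str, int] = {}
    for cell in cells:
        _, cell_cos, n = genotype_cell(cell, params)
        cos.extend(cell_cos)
        counts[cell.cell_id] = n
    return cos, counts


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the synthetic end-to-end analysis and write all artifacts.

    Deterministic given ``config.seed``. Returns a summary dict (also
    written as ``manifest.json``).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages: dict[str, float] = {}

    def tick(name: str) -> None:
        stages[name] = round(time.time() - t0, 3)

    genome = simulate_reference(
        config.chrom_lengths,
        marker_spacing=config.marker_spacing,
        seed=config.seed,
    )
    model = MeiosisModel(
        genetic_length_cM=config.genetic_length_cM,
        nu=config.nu,
        distal_bias_weight=config.distal_bias_weight,
    )
    obs_model = ObservationModel(
        markers_per_cell=config.markers_per_cell,
        error_rate=config.error_rate,
        doublet_fraction=config.doublet_fraction,
    )
    cells, truths = simulate_cohort(genome, model, obs_model, config.n_cells, config.seed)
    io.write_observations(cells, out / "observations.tsv")
    co_truth, seg_truth = io.truth_to_bed(truths)
    io.write_bed(co_truth, out / "truth_crossovers.bed")
    io.write_bed(seg_truth, out / "truth_segments.bed")
    tick("simulate")

    kept, reports = qc.run_qc(
        cells,
        min_reads=config.min_reads,
        min_markers=config.min_markers,
        switch_threshold=config.switch_threshold,
    )
    pd.DataFrame([asdict(r) for r in reports]).to_csv(out / "qc_report.tsv", sep="\t", index=False)
    tick("qc")

    params = CallerParams(
        min_block_markers=config.min_block_markers,
        block_span_bp=config.block_span_bp,
        min_double_co_sep=config.min_double_co_sep,
    )
    cos, per_cell = call_cohort(kept, params)
    co_bed = pd.DataFrame(
        [dict(zip(("chrom", "start", "end", "name"), c.to_bed())) for c in cos],
        columns=["chrom", "start", "end", "name"],
    )
    io.write_bed(co_bed, out / "crossovers.bed")
    tick("call")

    n_cells = len(kept)
    track_frames = []
    for chrom, length in genome.chromosomes:
        track = landscape.co_rate_track(
            cos, n_cells, chrom, length, window=config.rate_window, step=config.rate_step
        )
        track_frames.append(track.to_frame())
    tracks = pd.concat(track_frames, ignore_index=True)
    io.write_bedgraph(tracks, "rate_cM_per_Mb", out / "recombination_rate.bedgraph")

    gmap = landscape.marey_map(
        cos,
        n_cells,
        {c: genome.markers[c]["pos"] for c, _ in genome.chromosomes},
        genome.chrom_lengths,
        thin_window=config.thin_window,
    )
    gmap.to_frame().to_csv(out / "marey_map.tsv", sep="\t", index=False)
    dist = landscape.co_count_distribution(
        cos, [c.cell_id for c in kept], [c for c, _ in genome.chromosomes]
    )
    tick("landscape")

    counts = dist["per_gamete_counts"]
    stats_block: dict = {
        "n_cells": n_cells,
        "n_crossovers": int(len(cos)),
        "mean_cos_per_gamete": dist["mean_per_gamete"],
        "mean_cos_per_chromatid": dist["mean_per_chromatid"],
        "total_map_length_cM": gmap.total_length_cM,
        "chrom_length_cM": gmap.chrom_length_cM,
    }
    if counts.size >= 2 and counts.mean() > 0:
        disp = interference.dispersion_test(counts)
        stats_block["dispersion"] = {
            "ratio": disp.ratio, "p_value": disp.p_value, "verdict": disp.verdict,
        }
    if counts.size >= 20:
        try:
            stat, dfree, p = interference.poisson_gof(counts)
            stats_block["poisson_gof"] = {"statistic": stat, "df": dfree, "p_value": p}
        except ValueError as exc:
            stats_block["poisson_gof"] = {"note": str(exc)}
    coc_tables = []
    for chrom, length in genome.chromosomes:
        per_cell_cos = {c.cell_id: [] for c in kept}
        for c in cos:
            if c.chrom == chrom:
                per_cell_cos[c.cell_id].append((float(c.left), float(c.right)))
        curve = interference.coc_curve(
            per_cell_cos, length, k=config.coc_intervals,
            rounds=config.coc_rounds, seed=config.seed,
        )
        tab = curve.to_frame()
        tab["chrom"] = chrom
        coc_tables.append(tab)
    pd.concat(coc_tables, ignore_index=True).to_csv(out / "coc_pairs.tsv", sep="\t", index=False)
    tick("interference")

    feature_tracks = [
        association.FeatureTrack(
            label=label,
            chrom=track["chrom"],
            start=track["start"],
            end=track["end"],
            strand=track.get("strand"),
        )
        for label, track in genome.features.items()
    ]
    nulls = association.z_scores(
        co_bed,
        feature_tracks,
        genome.chrom_lengths,
        n_rounds=config.permutation_rounds,
        seed=config.seed,
    )
    pd.DataFrame(
        [
            {"feature": n.feature, "observed": n.observed, "null_mean": n.mean,
             "null_sd": n.sd, "z": n.z}
            for n in nulls
        ]
    ).to_csv(out / "association_z.tsv", sep="\t", index=False)
    tick("association")

    manifest = {
        "parameters": asdict(config),
        "stage_seconds": stages,
        "inputs_sha256": {
            "observations.tsv": _sha256(out / "observations.tsv"),
        },
        "results": stats_block,
        "association_z": {n.feature: n.z for n in nulls},
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()
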