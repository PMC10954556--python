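"""Readers and writers for the pipeline's plain-text artifacts.

Conventions: marker-level tables are 1-based to match VCF; all genomic
interval output is BED-style 0-based half-open. Conversion happens only
here. Every writer has a matching reader and round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .markers import PhasedMarkerSet
from .simulate import GameteObservation, GameteTruth, SimulatedGenome

__all__ = [
    "write_markers_vcf",
    "write_marker_table",
    "read_marker_table",
    "write_observations",
    "read_observations",
    "write_bed",
    "read_bed",
    "truth_to_bed",
    "write_bedgraph",
    "write_json",
]


def write_markers_vcf(genome: SimulatedGenome, path: str | Path, *, seed: int = 0) -> None:
    """Write the genome's markers as a VCF against the hap1 reference.

    INFO carries MQ (mapping quality), AO (alternate coverage) and AF
    (allele frequency) drawn to sit inside the study's retention bounds, so
    selecting markers from this file recovers the simulated marker set.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCF]))
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">')
    header.add_line('##INFO=<ID=AO,Number=1,Type=Integer,Description="Alternate allele observations">')
    header.add_line('##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele frequency">')
    for chrom, length in genome.chromosomes:
        header.contigs.add(chrom, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for chrom, _ in genome.chromosomes:
            m = genome.markers[chrom]
            n = m["pos"].size
            mq = rng.uniform(51, 60, size=n)
            ao = rng.integers(5, 31, size=n)
            # keep clear of the AF bounds so float32 VCF storage cannot
            # push a value over the inclusive 0.4/0.6 thresholds
            af = rng.uniform(0.405, 0.595, size=n)
            for i in range(n):
                rec = vf.new_record(
                    contig=chrom,
                    start=int(m["pos"][i]) - 1,
                    alleles=(str(m["hap1"][i]), str(m["hap2"][i])),
                )
                rec.info["MQ"] = float(round(mq[i], 2))
                rec.info["AO"] = int(ao[i])
                rec.info["AF"] = float(round(af[i], 3))
                vf.write(rec)


def write_marker_table(markers: PhasedMarkerSet, path: str | Path) -> None:
    rows = []
    for chrom, d in markers.by_chrom.items():
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": d["pos"], "ref": d["hap1"], "alt": d["hap2"]}
            )
        )
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "pos", "ref", "alt"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_marker_table(path: str | Path) -> PhasedMarkerSet:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    by_chrom = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        by_chrom[str(chrom)] = {
            "pos": sub["pos"].to_numpy(np.int64),
            "hap1": sub["ref"].to_numpy(object),
            "hap2": sub["alt"].to_numpy(object),
        }
    ms = PhasedMarkerSet(by_chrom=by_chrom)
    ms.validate()
    return ms


def write_observations(cells: list[GameteObservation], path: str | Path) -> None:
    """Long-format TSV: cell_id, chrom, pos (1-based), hap1/hap2 reads."""
    frames = []
    for cell in cells:
        for chrom, c in cell.calls.items():
            if c["pos"].size == 0:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": cell.cell_id,
                        "chrom": chrom,
                        "pos": c["pos"],
                        "hap1_reads": c["hap1_reads"],
                        "hap2_reads": c["hap2_reads"],
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["cell_id", "chrom", "pos", "hap1_reads", "hap2_reads"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_observations(path: str | Path, chrom_names: list[str] | None = None) -> list[GameteObservation]:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "chrom": str})
    cells = []
    for cell_id, sub in df.groupby("cell_id", sort=False):
        calls = {}
        for chrom, cc in sub.groupby("chrom", sort=False):
            cc = cc.sort_values("pos")
            calls[str(chrom)] = {
                "pos": cc["pos"].to_numpy(np.int64),
                "hap1_reads": cc["hap1_reads"].to_numpy(np.int64),
                "hap2_reads": cc["hap2_reads"].to_numpy(np.int64),
            }
        empty = {"pos": np.array([], dtype=np.int64),
                 "hap1_reads": np.array([], dtype=np.int64),
                 "hap2_reads": np.array([], dtype=np.int64)}
        for chrom in chrom_names or []:
            calls.setdefault(chrom, {k: v.copy() for k, v in empty.items()})
        cells.append(GameteObservation(cell_id=str(cell_id), calls=calls))
    return cells


def write_bed(df: pd.DataFrame, path: str | Path, *, columns: list[str] | None = None) -> None:
    """Write BED (0-based half-open). Default columns chrom/start/end/name."""
    cols = columns or [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in df]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path, *, names: list[str] | None = None) -> pd.DataFrame:
    base = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    df.columns = (names or base)[: df.shape[1]]
    return df


def truth_to_bed(truths: list[GameteTruth]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """True CO points (width-1 BED) and haplotype segments, per cell."""
    co_rows, seg_rows = [], []
    for t in truths:
        for chrom, pos in t.crossovers.items():
            for p in pos:
                start = int(np.floor(p))
                co_rows.append({"chrom": chrom, "start": start, "end": start + 1, "name": t.cell_id})
        for chrom, segs in t.segments.items():
            for s, e, hap in segs:
                seg_rows.append(
                    {"chrom": chrom, "start": s, "end": e, "name": f"{t.cell_id}:H{hap}"}
                )
    cols = ["chrom", "start", "end", "name"]
    return (
        pd.DataFrame(co_rows, columns=cols),
        pd.DataFrame(seg_rows, columns=cols),
    )


def write_bedgraph(df: pd.DataFrame, value_col: str, path: str | Path) -> None:
    df[["chrom", "start", "end", value_col]].to_csv(
        path, sep="\t", index=False, header=False
    )


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
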