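"""Recombination landscapes, marker thinning, Marey maps, count tables.

The windowed rate in cM/Mb is derived by spreading each crossover's unit of
probability mass uniformly over its bracketing interval (intervals from
sparse markers are of megabase width; assigning them to midpoints creates
step artifacts), dividing by the number of gametes, and scaling to
centimorgans per megabase. Genetic positions follow directly: the genetic
position at physical coordinate x is 100 times the expected number of
crossovers to the left of x per gamete, which makes the chromosome map
length exactly 100 times the mean per-chromatid crossover count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._intervals import interval_window_mass, sliding_windows
from .calling import CrossoverInterval

__all__ = [
    "RecombinationTrack",
    "GeneticMap",
    "co_rate_track",
    "thin_markers",
    "marey_map",
    "co_count_distribution",
]


@dataclass
class RecombinationTrack:
    chrom: str
    window_start: np.ndarray  # 0-based half-open
    window_end: np.ndarray
    rate_cM_per_Mb: np.ndarray
    n_cells: int
    confident_bounds: tuple[int, int] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.window_start,
                "end": self.window_end,
                "rate_cM_per_Mb": self.rate_cM_per_Mb,
            }
        )


@dataclass
class GeneticMap:
    """Thinned markers with genetic positions plus per-chromosome lengths."""

    positions: dict[str, np.ndarray]  # physical bp, per chromosome
    genetic_cM: dict[str, np.ndarray]
    chrom_length_cM: dict[str, float]

    @property
    def total_length_cM(self) -> float:
        return float(sum(self.chrom_length_cM.values()))

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame({"chrom": c, "pos": self.positions[c], "cM": self.genetic_cM[c]})
            for c in self.positions
        ]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["chrom", "pos", "cM"]
        )


def _cos_on(cos: list[CrossoverInterval], chrom: str) -> tuple[np.ndarray, np.ndarray]:
    sel = [c for c in cos if c.chrom == chrom]
    starts = np.array([c.left for c in sel], dtype=np.float64)
    ends = np.array([c.right for c in sel], dtype=np.float64)
    return starts, ends


def co_rate_track(
    cos: list[CrossoverInterval],
    n_cells: int,
    chrom: str,
    chrom_length: int,
    *,
    window: int = 1_000_000,
    step: int = 100_000,
    confident_bounds: tuple[int, int] | None = None,
    midpoint: bool = False,
) -> RecombinationTrack:
    """Windowed crossover rate in cM/Mb (1 Mb window, 100 kb step default).

    rate(w) = 100 * [sum of per-CO overlap fractions with w] / n_cells
    / (window width in Mb). With ``confident_bounds`` only windows fully
    inside the bounds are emitted (rates outside the marker-covered region
    are not meaningful); ``midpoint`` assigns each CO to its midpoint
    instead of spreading its mass.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    lo, hi = (0, chrom_length) if confident_bounds is None else confident_bounds
    ws, we = sliding_windows(lo, hi, window, step, full_only=confident_bounds is not None)
    starts, ends = _cos_on(cos, chrom)
    if midpoint:
        mids = (starts + ends) / 2.0
        starts = ends = mids
    mass = interval_window_mass(starts, ends, ws, we)
    width_mb = (we - ws) / 1e6
    rate = np.zeros(mass.shape)
    nz = width_mb > 0
    rate[nz] = 100.0 * mass[nz] / n_cells / width_mb[nz]
    return RecombinationTrack(
        chrom=chrom,
        window_start=ws,
        window_end=we,
        rate_cM_per_Mb=rate,
        n_cells=n_cells,
        confident_bounds=confident_bounds,
    )


def thin_markers(positions: np.ndarray, *, window: int = 500_000) -> np.ndarray:
    """One marker per non-empty window: the median by index (lower median).

    Windows step by their own width from the first present marker to the
    last, so thinning adapts to the covered span rather than the assembly
    coordinates.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size == 0:
        return pos.copy()
    out = []
    start = int(pos[0])
    last = int(pos[-1])
    while start <= last:
        in_win = pos[(pos >= start) & (pos < start + window)]
        if in_win.size:
            out.append(in_win[(in_win.size - 1) // 2])
        start += window
    return np.array(out, dtype=np.int64)


def marey_map(
    cos: list[CrossoverInterval],
    n_cells: int,
    marker_positions: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    *,
    thin_window: int | None = 500_000,
) -> GeneticMap:
    """Genetic position (cM) against physical position per chromosome.

    The genetic position at x is 100 x (expected per-gamete CO count left
    of x), each CO contributing the probability that a uniform point of its
    interval lies left of x. Map length is the value at the chromosome end,
    i.e. 100 x (COs on the chromosome) / n_cells.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    positions, genetic, lengths = {}, {}, {}
    for chrom, L in chrom_lengths.items():
        pos = np.asarray(marker_positions.get(chrom, np.array([], dtype=np.int64)))
        if thin_window is not None:
            pos = thin_markers(pos, window=thin_window)
        starts, ends = _cos_on(cos, chrom)
        widths = np.maximum(ends - starts, 1e-12)

        def cm_at(x: np.ndarray) -> np.ndarray:
            if starts.size == 0:
                return np.zeros(np.asarray(x, dtype=np.float64).shape)
            x = np.asarray(x, dtype=np.float64)[:, None]
            p = np.clip((x - starts[None, :]) / widths[None, :], 0.0, 1.0)
            return 100.0 * p.sum(axis=1) / n_cells

        positions[chrom] = pos
        genetic[chrom] = cm_at(pos.astype(np.float64)) if pos.size else np.array([])
        lengths[chrom] = float(cm_at(np.array([float(L)]))[0])
    return GeneticMap(positions=positions, genetic_cM=genetic, chrom_length_cM=lengths)


def co_count_distribution(
    cos: list[CrossoverInterval],
    cell_ids: list[str],
    chrom_names: list[str],
) -> dict:
    """Per-gamete and per-chromatid crossover count histograms.

    ``cell_ids`` must include zero-CO cells so their counts enter the
    histograms. Returns exact count tables plus the fraction of chromatids
    carrying 0, 1 and 2+ crossovers.
    """
    per_cell = {cid: 0 for cid in cell_ids}
    per_chromatid = {(cid, ch): 0 for cid in cell_ids for ch in chrom_names}
    for c in cos:
        per_cell[c.cell_id] += 1
        per_chromatid[(c.cell_id, c.chrom)] += 1
    gam = np.array(list(per_cell.values()), dtype=np.int64)
    chrom_counts = {
        ch: np.array([per_chromatid[(cid, ch)] for cid in cell_ids], dtype=np.int64)
        for ch in chrom_names
    }
    all_chromatids = np.concatenate(list(chrom_counts.values())) if chrom_counts else np.array([], dtype=np.int64)
    def hist(a: np.ndarray) -> dict[int, int]:
        vals, cnts = np.unique(a, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, cnts)}

    return {
        "per_gamete_counts": gam,
        "per_gamete_hist": hist(gam),
        "per_chromatid_counts": chrom_counts,
        "mean_per_gamete": float(gam.mean()) if gam.size else 0.0,
        "mean_per_chromatid": float(all_chromatids.mean()) if all_chromatids.size else 0.0,
        "chromatid_fractions": {
            "0": float((all_chromatids == 0).mean()) if all_chromatids.size else 0.0,
            "1": float((all_chromatids == 1).mean()) if all_chromatids.size else 0.0,
            "2+": float((all_chromatids >= 2).mean()) if all_chromatids.size else 0.0,
        },
        "total": int(len(cos)),
    }
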