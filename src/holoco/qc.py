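"""Cell-level quality control for single-gamete observations.

Three screens applied before crossover calling: read/marker count filters,
species assignment from dual-reference alignment rates (the sequencing
library multiplexes two species), and doublet detection via the genotype
switch rate — a barcode covering two gametes alternates haplotypes far more
often than a singleton, whose switches are limited to true crossovers plus
sporadic errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import GameteObservation

__all__ = [
    "CellQCReport",
    "raw_genotypes",
    "switch_rate",
    "filter_cells",
    "assign_species",
    "run_qc",
]

SWITCH_RATE_THRESHOLD = 0.07
MIN_READS = 5_000
MIN_MARKERS = 400
MIN_ALIGN_RATE = 25.0


@dataclass
class CellQCReport:
    cell_id: str
    n_reads: int = 0
    n_markers: int = 0
    switch_rate: float = float("nan")
    species_call: str = "A"
    pass_reads: bool = True
    pass_markers: bool = True
    pass_species: bool = True
    is_doublet: bool = False

    @property
    def passed(self) -> bool:
        return self.pass_reads and self.pass_markers and self.pass_species and not self.is_doublet


def raw_genotypes(cell: GameteObservation, chrom: str) -> np.ndarray:
    """Per-marker raw call on one chromosome: 1, 2 or 0 (NA on read ties)."""
    c = cell.calls.get(chrom)
    if c is None:
        return np.array([], dtype=np.int8)
    h1, h2 = c["hap1_reads"], c["hap2_reads"]
    out = np.zeros(h1.shape, dtype=np.int8)
    out[h1 > h2] = 1
    out[h2 > h1] = 2
    return out


def switch_rate(cell: GameteObservation) -> float:
    """Genotype switches per observed marker, within chromosomes.

    Switches are counted between consecutive non-NA raw calls along each
    chromosome (never across chromosome ends); the denominator is the total
    number of observed markers. For a noiseless singleton this equals
    (true CO count) / (marker count). Returns NaN for < 2 markers.
    """
    n_markers = cell.n_markers
    if n_markers < 2:
        return float("nan")
    switches = 0
    for chrom in cell.calls:
        g = raw_genotypes(cell, chrom)
        g = g[g != 0]
        if g.size >= 2:
            switches += int(np.sum(g[1:] != g[:-1]))
    return switches / n_markers


def filter_cells(
    cells: list[GameteObservation],
    *,
    min_reads: int = MIN_READS,
    min_markers: int = MIN_MARKERS,
) -> tuple[list[GameteObservation], list[GameteObservation], list[CellQCReport]]:
    """Partition cells by count filters.

    A cell is kept iff n_reads > min_reads (strict, matching the barcode
    occurrence cut) and n_markers >= min_markers (inclusive: "fewer than
    400 markers" are discarded, 400 itself is kept).
    """
    if min_reads < 0 or min_markers < 0:
        raise ValueError("count thresholds must be non-negative")
    kept, discarded, reports = [], [], []
    for cell in cells:
        r = CellQCReport(
            cell_id=cell.cell_id,
            n_reads=cell.n_reads,
            n_markers=cell.n_markers,
            pass_reads=cell.n_reads > min_reads,
            pass_markers=cell.n_markers >= min_markers,
        )
        reports.append(r)
        (kept if r.pass_reads and r.pass_markers else discarded).append(cell)
    return kept, discarded, reports


def assign_species(
    rates: dict[str, tuple[float, float]],
    *,
    min_rate: float = MIN_ALIGN_RATE,
    ambiguity_delta: float = 10.0,
) -> dict[str, str]:
    """Call species per cell from (rate_A, rate_B) alignment percentages.

    ``ambiguous`` when the two rates differ by less than ``ambiguity_delta``
    percentage points (a cell aligning equally well to both genomes is a
    candidate cross-species doublet); otherwise the winner, downgraded to
    ``low_rate`` when even the winning rate is below ``min_rate``.
    """
    out = {}
    for cell_id, (ra, rb) in rates.items():
        if not (0 <= ra <= 100 and 0 <= rb <= 100):
            raise ValueError(f"alignment rates outside [0,100] for {cell_id}: {(ra, rb)}")
        if abs(ra - rb) < ambiguity_delta:
            out[cell_id] = "ambiguous"
            continue
        winner, rate = ("A", ra) if ra > rb else ("B", rb)
        out[cell_id] = "low_rate" if rate < min_rate else winner
    return out


def run_qc(
    cells: list[GameteObservation],
    *,
    min_reads: int = MIN_READS,
    min_markers: int = MIN_MARKERS,
    switch_threshold: float = SWITCH_RATE_THRESHOLD,
    species_rates: dict[str, tuple[float, float]] | None = None,
    min_align_rate: float = MIN_ALIGN_RATE,
    ambiguity_delta: float = 10.0,
) -> tuple[list[GameteObservation], list[CellQCReport]]:
    """Full QC: count filters, optional species screen, doublet screen.

    Doublets are cells whose switch rate strictly exceeds
    ``switch_threshold`` (default 0.07); cells with an undefined switch
    rate fail the marker filter anyway. Returns passing cells and a report
    for every input cell.
    """
    species = {}
    if species_rates is not None:
        species = assign_species(
            species_rates, min_rate=min_align_rate, ambiguity_delta=ambiguity_delta
        )
    kept, reports = [], []
    for cell in cells:
        r = CellQCReport(
            cell_id=cell.cell_id,
            n_reads=cell.n_reads,
            n_markers=cell.n_markers,
            pass_reads=cell.n_reads > min_reads,
            pass_markers=cell.n_markers >= min_markers,
        )
        if species:
            r.species_call = species.get(cell.cell_id, "A")
            r.pass_species = r.species_call == "A"
        if r.pass_reads and r.pass_markers:
            sr = switch_rate(cell)
            r.switch_rate = sr
            # undefined switch rate fails open: treated as singleton
            r.is_doublet = bool(sr > switch_threshold) if np.isfinite(sr) else False
        reports.append(r)
        if r.passed:
            kept.append(cell)
    return kept, reports
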