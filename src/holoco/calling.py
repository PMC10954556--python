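"""Crossover calling from sparse per-cell haplotype markers.

A gamete inherits one recombined chromatid per chromosome, so along each
chromosome its markers should read as long runs of one haplotype with a
switch at every crossover. With one-or-few reads per marker and a
percent-level error rate, raw per-marker calls are noisy; calling proceeds
in two smoothing stages followed by segmentation:

1. each marker's haplotype-2 allele frequency is replaced by the mean over
   the five-marker window centred on it (two ahead, two behind, truncated
   at chromosome ends) and converted to a genotype (H1 below 0.5, H2 above,
   undecided at exactly 0.5);
2. genotypes are then majority-smoothed over the same window (undecided
   neighbours excluded; ties keep the marker's own call);
3. maximal runs of one genotype become blocks; a block is *qualified* to
   carry genotype state when at least five of its markers fall within 1 Mb
   (any five consecutive member markers spanning <= 1 Mb);
4. every genotype conversion between adjacent qualified blocks is emitted
   as a crossover interval bracketed by the flanking block-edge markers.

Close double crossovers — adjacent calls nearer than a separation floor —
are flagged and, by default, dropped unless the blocks flanking the pair
are well supported; this replaces the study's manual review of double-CO
cells with a deterministic rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import GameteObservation

__all__ = [
    "CallerParams",
    "GenotypeBlock",
    "CrossoverInterval",
    "smooth_allele_frequencies",
    "smooth_genotypes",
    "build_blocks",
    "call_crossovers",
    "genotype_cell",
]

H1, H2, NA = 1, 2, 0


@dataclass
class CallerParams:
    smoothing_window: int = 2  # markers ahead and behind
    min_block_markers: int = 5
    block_span_bp: int = 1_000_000
    min_double_co_sep: int = 2_000_000
    rescue_block_markers: int = 10  # flanking support that keeps a close pair
    drop_close_doubles: bool = True


@dataclass
class GenotypeBlock:
    chrom: str
    start_pos: int  # 1-based first marker
    end_pos: int  # 1-based last marker
    genotype: int  # H1 or H2
    n_markers: int
    qualified: bool


@dataclass
class CrossoverInterval:
    """One genotype conversion in one cell.

    ``left``/``right`` are the 1-based positions of the last marker of the
    upstream qualified block and the first marker of the downstream one;
    the true exchange point lies between them.
    """

    cell_id: str
    chrom: str
    left: int
    right: int
    flags: tuple[str, ...] = ()

    @property
    def width(self) -> int:
        return self.right - self.left

    def to_bed(self) -> tuple[str, int, int, str]:
        # 0-based half-open, spanning both bracketing marker bases
        return (self.chrom, self.left - 1, self.right, self.cell_id)


def _window_bounds(n: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(n)
    return np.maximum(idx - w, 0), np.minimum(idx + w + 1, n)


def smooth_allele_frequencies(af: np.ndarray, window: int = 2) -> np.ndarray:
    """Sliding mean of allele frequencies over [i-window, i+window].

    The window is truncated at chromosome ends; a single isolated read
    error is absorbed (e.g. 0,0,1,0,0 smooths the middle marker to 0.2).
    """
    af = np.asarray(af, dtype=np.float64)
    n = af.size
    if n == 0:
        return af.copy()
    lo, hi = _window_bounds(n, window)
    c = np.concatenate([[0.0], np.cumsum(af)])
    return (c[hi] - c[lo]) / (hi - lo)


def genotype_from_af(af: np.ndarray) -> np.ndarray:
    """H1 below 0.5, H2 above, NA at exactly 0.5 (deterministic tie rule)."""
    af = np.asarray(af, dtype=np.float64)
    out = np.full(af.shape, NA, dtype=np.int8)
    out[af < 0.5] = H1
    out[af > 0.5] = H2
    return out


def smooth_genotypes(genotypes: np.ndarray, window: int = 2) -> np.ndarray:
    """Majority vote over [i-window, i+window], NA excluded, ties self-keep."""
    g = np.asarray(genotypes, dtype=np.int8)
    n = g.size
    if n == 0:
        return g.copy()
    lo, hi = _window_bounds(n, window)
    c1 = np.concatenate([[0], np.cumsum(g == H1)])
    c2 = np.concatenate([[0], np.cumsum(g == H2)])
    n1 = c1[hi] - c1[lo]
    n2 = c2[hi] - c2[lo]
    out = g.copy()
    out[n1 > n2] = H1
    out[n2 > n1] = H2
    return out


def build_blocks(
    chrom: str,
    pos: np.ndarray,
    genotypes: np.ndarray,
    *,
    min_block_markers: int = 5,
    block_span_bp: int = 1_000_000,
) -> list[GenotypeBlock]:
    """Maximal runs of one non-NA genotype, with the qualification rule.

    A block qualifies when some ``min_block_markers`` consecutive member
    markers span at most ``block_span_bp`` — dense support somewhere in the
    block, however long the block is overall.
    """
    pos = np.asarray(pos, dtype=np.int64)
    g = np.asarray(genotypes, dtype=np.int8)
    blocks: list[GenotypeBlock] = []
    i = 0
    n = g.size
    while i < n:
        if g[i] == NA:
            i += 1
            continue
        j = i
        while j + 1 < n and g[j + 1] == g[i]:
            j += 1
        k = min_block_markers
        run_pos = pos[i : j + 1]
        qualified = False
        if run_pos.size >= k:
            spans = run_pos[k - 1 :] - run_pos[: run_pos.size - k + 1]
            qualified = bool(np.min(spans) <= block_span_bp)
        blocks.append(
            GenotypeBlock(
                chrom=chrom,
                start_pos=int(run_pos[0]),
                end_pos=int(run_pos[-1]),
                genotype=int(g[i]),
                n_markers=int(run_pos.size),
                qualified=qualified,
            )
        )
        i = j + 1
    return blocks


def call_crossovers(
    blocks: list[GenotypeBlock],
    cell_id: str = "",
    *,
    min_double_co_sep: int = 2_000_000,
    rescue_block_markers: int = 10,
    drop_close_doubles: bool = True,
) -> list[CrossoverInterval]:
    """Emit one crossover per genotype conversion between qualified blocks.

    Unqualified blocks carry no genotype state: two same-genotype qualified
    blocks separated only by unqualified markers merge logically, while a
    conversion spans the unqualified gap. Adjacent calls with midpoint
    separation below ``min_double_co_sep`` are flagged ``close_double_co``
    and (by default) both dropped, unless every block the pair touches
    (upstream, shared middle, downstream) holds at least
    ``rescue_block_markers`` markers.
    """
    qual = [b for b in blocks if b.qualified]
    cos: list[CrossoverInterval] = []
    support: list[tuple[int, int]] = []  # (upstream, downstream) block marker counts
    for up, down in zip(qual[:-1], qual[1:]):
        if up.genotype != down.genotype:
            cos.append(
                CrossoverInterval(cell_id=cell_id, chrom=up.chrom, left=up.end_pos, right=down.start_pos)
            )
            support.append((up.n_markers, down.n_markers))
    if len(cos) < 2:
        return cos
    drop = np.zeros(len(cos), dtype=bool)
    mids = np.array([(c.left + c.right) / 2.0 for c in cos])
    for k in range(len(cos) - 1):
        if mids[k + 1] - mids[k] >= min_double_co_sep:
            continue
        cos[k].flags = tuple(set(cos[k].flags) | {"close_double_co"})
        cos[k + 1].flags = tuple(set(cos[k + 1].flags) | {"close_double_co"})
        # a pair survives only when every block it touches (upstream,
        # shared middle, downstream) is well supported; otherwise both go
        rescued = (
            support[k][0] >= rescue_block_markers
            and support[k][1] >= rescue_block_markers
            and support[k + 1][1] >= rescue_block_markers
        )
        if drop_close_doubles and not rescued:
            drop[k] = drop[k + 1] = True
    return [c for c, d in zip(cos, drop) if not d]


def genotype_cell(
    cell: GameteObservation,
    params: CallerParams | None = None,
) -> tuple[dict[str, list[GenotypeBlock]], list[CrossoverInterval], int]:
    """Run the full caller on one QC-passing cell.

    Returns per-chromosome genotype blocks, the cell's crossover intervals
    and their count. Deterministic; chromosomes with no qualified block
    contribute no calls.
    """
    p = params or CallerParams()
    blocks_by_chrom: dict[str, list[GenotypeBlock]] = {}
    cos: list[CrossoverInterval] = []
    for chrom, c in cell.calls.items():
        pos = c["pos"]
        if pos.size == 0:
            blocks_by_chrom[chrom] = []
            continue
        h1 = c["hap1_reads"].astype(np.float64)
        h2 = c["hap2_reads"].astype(np.float64)
        af = h2 / (h1 + h2)
        g = genotype_from_af(smooth_allele_frequencies(af, p.smoothing_window))
        g = smooth_genotypes(g, p.smoothing_window)
        blocks = build_blocks(
            chrom,
            pos,
            g,
            min_block_markers=p.min_block_markers,
            block_span_bp=p.block_span_bp,
        )
        blocks_by_chrom[chrom] = blocks
        cos.extend(
            call_crossovers(
                blocks,
                cell.cell_id,
                min_double_co_sep=p.min_double_co_sep,
                rescue_block_markers=p.rescue_block_markers,
                drop_close_doubles=p.drop_close_doubles,
            )
        )
    return blocks_by_chrom, cos, len(cos)
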