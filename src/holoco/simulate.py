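"""Synthetic gametes: reference, meiosis, sparse observation, doublets.

This module generates data with the statistical structure the downstream
analyses assume, so the whole pipeline is testable without sequencing data:

* a multi-chromosome reference carrying haplotype-diagnostic SNP markers at
  a configurable density and feature tracks (centromeric tandem-repeat
  arrays, CENH3 domains, genes, TEs) with realistic geometry;
* crossovers placed by a stationary gamma-renewal process on the genetic
  scale (shape ``nu``; ``nu = 1`` is the no-interference Poisson limit,
  larger ``nu`` gives underdispersed, interfering COs), with an optional
  U-shaped distal bias when mapping genetic to physical coordinates;
* sparse per-cell marker observations with genotyping error, mimicking the
  low transcript abundance of single pollen nuclei;
* barcode doublets (two gametes merged under one barcode) and selfed
  offspring whose CO set unions two independent gametes.

All randomness flows from one integer seed; per-cell sub-streams are derived
by counter via :class:`numpy.random.SeedSequence` so outputs are reproducible
and independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special

__all__ = [
    "SimulatedGenome",
    "MeiosisModel",
    "GameteTruth",
    "ObservationModel",
    "GameteObservation",
    "simulate_reference",
    "simulate_meiosis",
    "observe_gamete",
    "make_doublet",
    "simulate_cohort",
    "simulate_selfed_offspring",
]

_BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """Raised for invalid simulation or pipeline parameters."""


# --------------------------------------------------------------------------
# domain types


@dataclass
class SimulatedGenome:
    """Phased reference at reduced scale: chromosomes, markers, features.

    ``markers[chrom]`` is a dict with sorted 1-based ``pos`` and per-marker
    ``hap1``/``hap2`` alleles (always different). ``features[label]`` is a
    dict of arrays ``chrom``, ``start``, ``end`` (0-based half-open) and,
    for genes, ``strand``.
    """

    chromosomes: list[tuple[str, int]]
    markers: dict[str, dict[str, np.ndarray]]
    features: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def n_markers(self) -> int:
        return sum(m["pos"].size for m in self.markers.values())

    def validate(self) -> None:
        lengths = self.chrom_lengths
        for chrom, m in self.markers.items():
            pos = m["pos"]
            if pos.size and not np.all(np.diff(pos) > 0):
                raise ValueError(f"marker positions not strictly increasing on {chrom}")
            if pos.size and (pos[0] < 1 or pos[-1] > lengths[chrom]):
                raise ValueError(f"marker outside chromosome {chrom}")
        for label, track in self.features.items():
            for chrom in np.unique(track["chrom"]):
                sel = track["chrom"] == chrom
                s, e = track["start"][sel], track["end"][sel]
                if np.any(s < 0) or np.any(e > lengths[str(chrom)]):
                    raise ValueError(f"{label} feature outside chromosome {chrom}")
                if s.size > 1 and np.any(np.diff(s) < 0):
                    raise ValueError(f"{label} features unsorted on {chrom}")


@dataclass
class MeiosisModel:
    """Per-chromosome genetic lengths plus interference and bias knobs.

    Parameters
    ----------
    genetic_length_cM : mapping chrom -> map length in centimorgans. The
        expected CO count per chromatid is length/100.
    nu : gamma-renewal shape; 1 = Poisson (no interference), >1 =
        interference (underdispersed counts, CoC < 1 at short range).
    distal_bias_weight : exponent >= 0. 0 = uniform genetic-to-physical
        intensity; larger values pile recombination toward chromosome ends
        through a symmetric-beta intensity.
    p_obligate : if True, chromatids are rejection-sampled until they carry
        at least one CO (obligate-CO enforcement per chromatid).
    """

    genetic_length_cM: dict[str, float]
    nu: float = 1.0
    distal_bias_weight: float = 0.0
    p_obligate: bool = False

    def __post_init__(self) -> None:
        if self.nu < 0.1:
            raise ConfigurationError(f"nu must be >= 0.1, got {self.nu}")
        if self.distal_bias_weight < 0:
            raise ConfigurationError("distal_bias_weight must be >= 0")
        for chrom, length in self.genetic_length_cM.items():
            if length < 0:
                raise ConfigurationError(f"negative genetic length on {chrom}")


@dataclass
class GameteTruth:
    """Ground truth for one simulated gamete.

    ``crossovers[chrom]``: sorted true CO point positions (bp, float).
    ``segments[chrom]``: list of (start, end, hap) 0-based half-open tiles,
    hap in {1, 2}, alternating and covering the chromosome exactly.
    """

    cell_id: str
    crossovers: dict[str, np.ndarray]
    segments: dict[str, list[tuple[int, int, int]]]

    def n_crossovers(self) -> int:
        return sum(v.size for v in self.crossovers.values())

    def haplotype_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Inherited haplotype (1/2) at 1-based positions ``pos``."""
        segs = self.segments[chrom]
        bounds = np.array([s[1] for s in segs[:-1]], dtype=np.float64)
        haps = np.array([s[2] for s in segs], dtype=np.int8)
        idx = np.searchsorted(bounds, np.asarray(pos, dtype=np.float64) - 1, side="right")
        return haps[idx]


@dataclass
class ObservationModel:
    """Sparse-capture model for single-cell marker observations.

    ``markers_per_cell`` is a spec dict: ``{"kind": "all"}``,
    ``{"kind": "fixed", "n": int}`` or ``{"kind": "lognormal",
    "median": float, "sigma": float}`` (cell totals; capture is uniform over
    the genome's markers without replacement).
    ``reads_per_marker`` is ``{"kind": "fixed", "n": int}`` or
    ``{"kind": "geometric", "mean": float}`` (support >= 1). Default one
    read per captured marker, reflecting transcript sparsity.
    """

    markers_per_cell: dict = field(default_factory=lambda: {"kind": "lognormal", "median": 700.0, "sigma": 0.6})
    reads_per_marker: dict = field(default_factory=lambda: {"kind": "fixed", "n": 1})
    error_rate: float = 0.01
    doublet_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.5:
            raise ConfigurationError("error_rate must be in [0, 0.5)")
        if not 0 <= self.doublet_fraction < 1:
            raise ConfigurationError("doublet_fraction must be in [0, 1)")


@dataclass
class GameteObservation:
    """Per-cell sparse marker read counts.

    ``calls[chrom]`` holds sorted observed 1-based ``pos`` with
    ``hap1_reads``/``hap2_reads`` (sum >= 1 at every kept marker).
    ``provenance`` lists the source cell ids ( > 1 entry for a doublet).
    """

    cell_id: str
    calls: dict[str, dict[str, np.ndarray]]
    provenance: tuple[str, ...] = ()

    @property
    def n_markers(self) -> int:
        return sum(c["pos"].size for c in self.calls.values())

    @property
    def n_reads(self) -> int:
        return int(
            sum((c["hap1_reads"].sum() + c["hap2_reads"].sum()) for c in self.calls.values())
        )

    @property
    def is_doublet(self) -> bool:
        return len(self.provenance) > 1


# --------------------------------------------------------------------------
# reference simulation


def _place_arrays(
    rng: np.random.Generator, length: int, mean_size: float, mean_spacing: float
) -> tuple[np.ndarray, np.ndarray]:
    """Tile a chromosome with repeat arrays: exponential gaps, lognormal-ish sizes."""
    starts, ends = [], []
    pos = rng.exponential(mean_spacing / 2.0)
    while pos < length:
        size = max(1.0, rng.normal(mean_size, mean_size * 0.25))
        end = min(length, pos + size)
        if end > pos:
            starts.append(int(pos))
            ends.append(int(end))
        pos = end + rng.exponential(max(mean_spacing - mean_size, 1.0))
    return np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64)


def simulate_reference(
    chrom_lengths: Sequence[int] | dict[str, int],
    *,
    marker_spacing: float = 449.0,
    tyba_mean_size: float = 20_000.0,
    tyba_mean_spacing: float = 400_000.0,
    n_genes_per_mb: float = 20.0,
    gene_mean_size: float = 3_000.0,
    n_tes_per_mb: float = 30.0,
    te_mean_size: float = 2_000.0,
    seed: int = 0,
) -> SimulatedGenome:
    """Simulate a phased reference with markers and feature tracks.

    Markers are placed by a Poisson process at mean spacing
    ``marker_spacing`` bp (the study density is ~1 SNP per 449 bp);
    centromeric repeat arrays default to ~20 kb size spaced ~400 kb, the
    holocentromere geometry. CENH3 domains are the Tyba arrays jittered at
    the edges, mimicking ChIP peak boundaries.
    """
    if isinstance(chrom_lengths, dict):
        chroms = list(chrom_lengths.items())
    else:
        chroms = [(f"chr{i + 1}", int(l)) for i, l in enumerate(chrom_lengths)]
    if any(l <= 0 for _, l in chroms):
        raise ConfigurationError("chromosome lengths must be positive")
    if marker_spacing <= 0:
        raise ConfigurationError("marker spacing must be positive")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    markers: dict[str, dict[str, np.ndarray]] = {}
    feat: dict[str, dict[str, list]] = {
        lbl: {"chrom": [], "start": [], "end": [], "strand": []}
        for lbl in ("tyba_monomers", "cenh3_peaks", "genes", "TEs")
    }
    for chrom, length in chroms:
        n = rng.poisson(length / marker_spacing)
        pos = np.sort(rng.choice(np.int64(length), size=min(n, length), replace=False)) + 1
        hap1 = rng.integers(0, 4, size=pos.size)
        shift = rng.integers(1, 4, size=pos.size)
        hap2 = (hap1 + shift) % 4
        markers[chrom] = {
            "pos": pos.astype(np.int64),
            "hap1": _BASES[hap1],
            "hap2": _BASES[hap2],
        }
        ts, te = _place_arrays(rng, length, tyba_mean_size, tyba_mean_spacing)
        feat["tyba_monomers"]["chrom"] += [chrom] * ts.size
        feat["tyba_monomers"]["start"] += list(ts)
        feat["tyba_monomers"]["end"] += list(te)
        feat["tyba_monomers"]["strand"] += ["."] * ts.size
        # CENH3 occupancy tracks the repeat arrays with ragged edges
        jit = rng.integers(-2000, 2000, size=2 * ts.size)
        cs = np.clip(ts + jit[: ts.size], 0, length - 1)
        ce = np.clip(te + jit[ts.size :], cs + 1, length)
        feat["cenh3_peaks"]["chrom"] += [chrom] * ts.size
        feat["cenh3_peaks"]["start"] += list(cs)
        feat["cenh3_peaks"]["end"] += list(ce)
        feat["cenh3_peaks"]["strand"] += ["."] * ts.size
        for lbl, per_mb, mean_size in (
            ("genes", n_genes_per_mb, gene_mean_size),
            ("TEs", n_tes_per_mb, te_mean_size),
        ):
            k = rng.poisson(per_mb * length / 1e6)
            s = np.sort(rng.integers(0, max(1, length - int(mean_size)), size=k))
            w = np.maximum(200, rng.exponential(mean_size, size=k)).astype(np.int64)
            e = np.minimum(length, s + w)
            feat[lbl]["chrom"] += [chrom] * k
            feat[lbl]["start"] += list(s)
            feat[lbl]["end"] += list(e)
            feat[lbl]["strand"] += list(rng.choice(["+", "-"], size=k))

    features = {
        lbl: {
            "chrom": np.array(d["chrom"], dtype=object),
            "start": np.array(d["start"], dtype=np.int64),
            "end": np.array(d["end"], dtype=np.int64),
            "strand": np.array(d["strand"], dtype=object),
        }
        for lbl, d in feat.items()
    }
    genome = SimulatedGenome(chromosomes=chroms, markers=markers, features=features)
    genome.validate()
    return genome


# --------------------------------------------------------------------------
# meiosis


def _genetic_to_physical(u: np.ndarray, length: int, w: float) -> np.ndarray:
    """Map genetic fractions u in [0,1] to bp through the bias intensity.

    The genetic-per-physical intensity is a symmetric beta(a, a) density
    with a = 1/(1+w): w = 0 gives the identity (uniform intensity), w > 0
    a U shape concentrating COs distally.
    """
    if w == 0:
        return u * length
    a = 1.0 / (1.0 + w)
    return special.betaincinv(a, a, u) * length


def _chromatid_cos(
    rng: np.random.Generator, map_morgans: float, nu: float, obligate: bool
) -> np.ndarray:
    """CO positions (genetic fraction of one chromatid) on [0, 1].

    Chiasmata on the bivalent follow a stationary gamma renewal process
    with shape nu and rate 2*nu per Morgan (mean inter-event distance
    0.5 Morgan), then are thinned to one chromatid with probability 1/2,
    giving the expected map_morgans COs per chromatid.
    """
    if map_morgans <= 0:
        return np.array([], dtype=np.float64)
    rate = 2.0 * nu
    while True:
        events = []
        # stationary delay: U times a length-biased (shape nu+1) interval
        x = rng.uniform() * rng.gamma(nu + 1.0, 1.0 / rate)
        while x < map_morgans:
            events.append(x)
            x += rng.gamma(nu, 1.0 / rate)
        if events:
            keep = rng.uniform(size=len(events)) < 0.5
            got = np.array(events, dtype=np.float64)[keep]
        else:
            got = np.array([], dtype=np.float64)
        if got.size or not obligate:
            return got / map_morgans


def simulate_meiosis(
    genome: SimulatedGenome,
    model: MeiosisModel,
    n_gametes: int,
    seed: int = 0,
    *,
    id_prefix: str = "cell",
) -> list[GameteTruth]:
    """Simulate gametes: per chromosome one recombined chromatid.

    Per-chromatid CO counts have mean ``genetic_length_cM/100``; their
    dispersion is governed by ``nu``. Haplotype segments alternate from a
    fair random starting haplotype and tile each chromosome exactly.
    """
    if n_gametes < 1:
        raise ConfigurationError("n_gametes must be >= 1")
    root = np.random.SeedSequence(seed)
    streams = root.spawn(n_gametes)
    out = []
    for i in range(n_gametes):
        rng = np.random.default_rng(streams[i])
        cos: dict[str, np.ndarray] = {}
        segments: dict[str, list[tuple[int, int, int]]] = {}
        for chrom, length in genome.chromosomes:
            cm = model.genetic_length_cM.get(chrom, 0.0)
            u = np.sort(_chromatid_cos(rng, cm / 100.0, model.nu, model.p_obligate))
            pos = _genetic_to_physical(u, length, model.distal_bias_weight)
            cos[chrom] = pos
            start_hap = int(rng.integers(1, 3))
            bounds = [0] + [int(round(p)) for p in pos] + [length]
            # collapse zero-width tiles from COs rounding onto a boundary
            segs = []
            hap = start_hap
            for a, b in zip(bounds[:-1], bounds[1:]):
                if b > a:
                    segs.append((a, b, hap))
                hap = 3 - hap
            # merge neighbours that ended up with equal haplotype
            merged = [segs[0]]
            for s in segs[1:]:
                if s[2] == merged[-1][2]:
                    merged[-1] = (merged[-1][0], s[1], s[2])
                else:
                    merged.append(s)
            segments[chrom] = merged
        out.append(GameteTruth(cell_id=f"{id_prefix}{i:05d}", crossovers=cos, segments=segments))
    return out


# --------------------------------------------------------------------------
# observation


def _draw_n_markers(rng: np.random.Generator, spec: dict, total: int) -> int:
    kind = spec.get("kind", "lognormal")
    if kind == "all":
        return total
    if kind == "fixed":
        return min(int(spec["n"]), total)
    if kind == "lognormal":
        n = rng.lognormal(mean=np.log(spec["median"]), sigma=spec.get("sigma", 0.6))
        return int(min(max(round(n), 0), total))
    raise ConfigurationError(f"unknown markers_per_cell kind {kind!r}")


def _draw_reads(rng: np.random.Generator, spec: dict, n: int) -> np.ndarray:
    kind = spec.get("kind", "fixed")
    if kind == "fixed":
        return np.full(n, int(spec.get("n", 1)), dtype=np.int64)
    if kind == "geometric":
        mean = float(spec["mean"])
        if mean < 1:
            raise ConfigurationError("geometric reads mean must be >= 1")
        return rng.geometric(1.0 / mean, size=n).astype(np.int64)
    raise ConfigurationError(f"unknown reads_per_marker kind {kind!r}")


def observe_gamete(
    truth: GameteTruth,
    genome: SimulatedGenome,
    obs: ObservationModel,
    seed: int = 0,
) -> GameteObservation:
    """Emit a sparse, noisy observation of one gamete.

    A subset of reference markers is captured uniformly; each captured
    marker receives >= 1 reads, each read reporting the inherited haplotype
    except with probability ``error_rate``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    total = genome.n_markers()
    n_obs = _draw_n_markers(rng, obs.markers_per_cell, total)
    # uniform capture without replacement across the genome-wide marker index
    chosen = rng.choice(total, size=n_obs, replace=False) if n_obs else np.array([], dtype=np.int64)
    chosen = np.sort(chosen)
    calls: dict[str, dict[str, np.ndarray]] = {}
    offset = 0
    for chrom, _ in genome.chromosomes:
        pos_all = genome.markers[chrom]["pos"]
        lo, hi = offset, offset + pos_all.size
        local = chosen[(chosen >= lo) & (chosen < hi)] - lo
        offset = hi
        if local.size == 0:
            calls[chrom] = {
                "pos": np.array([], dtype=np.int64),
                "hap1_reads": np.array([], dtype=np.int64),
                "hap2_reads": np.array([], dtype=np.int64),
            }
            continue
        pos = pos_all[local]
        true_hap = truth.haplotype_at(chrom, pos)
        reads = _draw_reads(rng, obs.reads_per_marker, pos.size)
        wrong = rng.binomial(reads, obs.error_rate)
        right = reads - wrong
        hap1 = np.where(true_hap == 1, right, wrong)
        hap2 = np.where(true_hap == 2, right, wrong)
        calls[chrom] = {
            "pos": pos.astype(np.int64),
            "hap1_reads": hap1.astype(np.int64),
            "hap2_reads": hap2.astype(np.int64),
        }
    return GameteObservation(cell_id=truth.cell_id, calls=calls, provenance=(truth.cell_id,))


def make_doublet(a: GameteObservation, b: GameteObservation) -> GameteObservation:
    """Merge two observations as one barcode: union markers, sum counts."""
    chroms_a, chroms_b = set(a.calls), set(b.calls)
    if chroms_a != chroms_b:
        raise ValueError("observations come from different genomes (chromosome sets differ)")
    calls = {}
    for chrom in a.calls:
        pa, pb = a.calls[chrom]["pos"], b.calls[chrom]["pos"]
        pos = np.union1d(pa, pb)
        h1 = np.zeros(pos.size, dtype=np.int64)
        h2 = np.zeros(pos.size, dtype=np.int64)
        for src, p in ((a, pa), (b, pb)):
            idx = np.searchsorted(pos, p)
            h1[idx] += src.calls[chrom]["hap1_reads"]
            h2[idx] += src.calls[chrom]["hap2_reads"]
        calls[chrom] = {"pos": pos, "hap1_reads": h1, "hap2_reads": h2}
    return GameteObservation(
        cell_id=f"{a.cell_id}+{b.cell_id}",
        calls=calls,
        provenance=tuple(a.provenance) + tuple(b.provenance),
    )


def simulate_cohort(
    genome: SimulatedGenome,
    model: MeiosisModel,
    obs: ObservationModel,
    n_cells: int,
    seed: int = 0,
) -> tuple[list[GameteObservation], list[GameteTruth]]:
    """Simulate an observed cohort including a doublet fraction.

    Returns ``n_cells`` emitted observations (singletons plus doublets made
    from extra gametes) and the underlying single-gamete truths.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5A]))
    n_doublets = int(round(n_cells * obs.doublet_fraction))
    n_singletons = n_cells - n_doublets
    n_gametes = n_singletons + 2 * n_doublets
    truths = simulate_meiosis(genome, model, n_gametes, seed)
    obs_seeds = np.random.SeedSequence([seed, 0xA5]).spawn(n_gametes)
    observations = []
    for i, t in enumerate(truths):
        sub = np.random.default_rng(obs_seeds[i])
        observations.append(observe_gamete(t, genome, obs, seed=int(sub.integers(2**31))))
    cells = observations[:n_singletons]
    for j in range(n_doublets):
        a = observations[n_singletons + 2 * j]
        b = observations[n_singletons + 2 * j + 1]
        cells.append(make_doublet(a, b))
    order = rng.permutation(len(cells))
    return [cells[i] for i in order], truths


def simulate_selfed_offspring(
    genome: SimulatedGenome,
    model: MeiosisModel,
    n_offspring: int,
    seed: int = 0,
    *,
    resolution_median_bp: float = 334.0,
    resolution_sigma: float = 1.0,
) -> tuple[list[dict], list[tuple[GameteTruth, GameteTruth]]]:
    """Selfed-offspring CO sets: union of two independent gametes per plant.

    Each true CO point is reported as an interval whose width is log-normal
    with the given median (the study's offspring COs resolve to a median of
    a few hundred bp), clipped to the chromosome. Returns BED-like records
    (dicts with chrom/start/end/offspring) and the gamete-truth pairs.
    """
    if n_offspring < 1:
        raise ConfigurationError("n_offspring must be >= 1")
    truths = simulate_meiosis(genome, model, 2 * n_offspring, seed, id_prefix="gamete")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1]))
    lengths = genome.chrom_lengths
    records: list[dict] = []
    pairs = []
    for k in range(n_offspring):
        t1, t2 = truths[2 * k], truths[2 * k + 1]
        pairs.append((t1, t2))
        for t in (t1, t2):
            for chrom, pos in t.crossovers.items():
                L = lengths[chrom]
                for p in pos:
                    w = rng.lognormal(np.log(resolution_median_bp), resolution_sigma)
                    half = max(0.5, w / 2.0)
                    start = int(max(0, np.floor(p - half)))
                    end = int(min(L, np.ceil(p + half)))
                    records.append(
                        {"chrom": chrom, "start": start, "end": max(end, start + 1),
                         "offspring": f"F1_{k:03d}"}
                    )
    return records, pairs
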