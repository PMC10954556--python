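"""Association of crossovers with (epi)genomic features.

The central tool is a permutation null: pseudo-crossovers are re-placed
uniformly at random, chromosome by chromosome, keeping the observed
per-chromosome counts and drawing each interval's width from the empirical
pool of real crossover widths. Overlap counts of the real set against a
feature track are then converted to Z-scores against the simulated
distribution (positive = enrichment). Supporting analyses: the relative
position of crossovers between flanking centromeric units (a centromere
effect would drain the neighbourhood of the units), strand-aware metagene
profiles over feature bodies, and Pearson correlation matrices of windowed
feature densities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._intervals import merge_intervals, overlaps_any, sliding_windows, interval_window_mass

__all__ = [
    "FeatureTrack",
    "NullDistribution",
    "RelativeDistanceProfile",
    "overlap_count",
    "permute_pseudo_cos",
    "z_scores",
    "relative_distance_profile",
    "metagene_profile",
    "windowed_track",
    "window_correlation_matrix",
]


@dataclass
class FeatureTrack:
    """Sorted intervals (0-based half-open) of one genomic feature class."""

    label: str
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    strand: np.ndarray | None = None

    @classmethod
    def from_frame(cls, label: str, df: pd.DataFrame) -> "FeatureTrack":
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        return cls(
            label=label,
            chrom=df["chrom"].to_numpy(dtype=object),
            start=df["start"].to_numpy(dtype=np.int64),
            end=df["end"].to_numpy(dtype=np.int64),
            strand=df["strand"].to_numpy(dtype=object) if "strand" in df else None,
        )

    def on(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        sel = self.chrom == chrom
        return self.start[sel], self.end[sel]

    def merged_on(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        s, e = self.on(chrom)
        order = np.argsort(s, kind="stable")
        return merge_intervals(s[order], e[order], gap=-1, inclusive=False)


@dataclass
class NullDistribution:
    feature: str
    observed: int
    simulated: np.ndarray
    mean: float
    sd: float
    z: float  # NaN when sd == 0


@dataclass
class RelativeDistanceProfile:
    r: np.ndarray  # per-CO relative position in [0, 1]
    n_excluded_inside: int
    n_excluded_outside: int
    bin_edges: np.ndarray
    bin_density: np.ndarray
    smooth_x: np.ndarray
    smooth_y: np.ndarray
    smooth_se: np.ndarray


def overlap_count(cos: pd.DataFrame, track: FeatureTrack) -> int:
    """Crossover intervals intersecting >= 1 bp of the track, each once."""
    total = 0
    for chrom in np.unique(cos["chrom"].to_numpy()):
        sub = cos[cos["chrom"] == chrom]
        ts, te = track.merged_on(str(chrom))
        total += int(
            overlaps_any(
                sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64), ts, te
            ).sum()
        )
    return total


def permute_pseudo_cos(
    per_chrom_counts: dict[str, int],
    gap_pool: np.ndarray,
    chrom_lengths: dict[str, int],
    *,
    n_rounds: int = 5000,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Random pseudo-crossover sets with the observed configuration.

    Per round and chromosome, exactly ``per_chrom_counts[chrom]`` intervals
    are placed; each draws a width from ``gap_pool`` (the real CO interval
    widths, with replacement) and a start uniform on [0, L - width].
    Pseudo-crossovers may overlap one another.
    """
    gap_pool = np.asarray(gap_pool, dtype=np.int64)
    if gap_pool.size == 0:
        raise ValueError("empty gap pool")
    if not per_chrom_counts:
        raise ValueError("empty per-chromosome counts")
    for chrom, L in chrom_lengths.items():
        too_long = gap_pool[gap_pool > L]
        if per_chrom_counts.get(chrom, 0) > 0 and too_long.size:
            raise ValueError(
                f"gap of {int(too_long.max())} bp exceeds chromosome {chrom} ({L} bp)"
            )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rounds = []
    chroms = [c for c, n in per_chrom_counts.items() if n > 0]
    for _ in range(n_rounds):
        rows_chrom, rows_start, rows_end = [], [], []
        for chrom in chroms:
            n = per_chrom_counts[chrom]
            L = chrom_lengths[chrom]
            widths = gap_pool[rng.integers(0, gap_pool.size, size=n)]
            starts = (rng.uniform(size=n) * (L - widths + 1)).astype(np.int64)
            rows_chrom += [chrom] * n
            rows_start.append(starts)
            rows_end.append(starts + widths)
        rounds.append(
            pd.DataFrame(
                {
                    "chrom": np.array(rows_chrom, dtype=object),
                    "start": np.concatenate(rows_start) if rows_start else np.array([], dtype=np.int64),
                    "end": np.concatenate(rows_end) if rows_end else np.array([], dtype=np.int64),
                }
            )
        )
    return rounds


def z_scores(
    cos: pd.DataFrame,
    tracks: list[FeatureTrack],
    chrom_lengths: dict[str, int],
    *,
    gap_pool: np.ndarray | None = None,
    n_rounds: int = 5000,
    seed: int = 0,
) -> list[NullDistribution]:
    """Overlap enrichment Z-score per feature track.

    The null keeps per-chromosome CO counts and re-draws positions; widths
    come from the observed intervals unless ``gap_pool`` overrides them.
    Z = (observed - null mean) / null sd; NaN (with zero sd) when the null
    is degenerate.
    """
    if n_rounds < 100:
        raise ValueError("need at least 100 permutation rounds")
    counts = cos.groupby("chrom").size().to_dict()
    widths = (cos["end"] - cos["start"]).to_numpy(np.int64)
    pool = widths if gap_pool is None else np.asarray(gap_pool, dtype=np.int64)
    rounds = permute_pseudo_cos(
        counts, pool, chrom_lengths, n_rounds=n_rounds, seed=seed
    )
    out = []
    for track in tracks:
        observed = overlap_count(cos, track)
        sim = np.array([overlap_count(r, track) for r in rounds], dtype=np.float64)
        mean, sd = float(sim.mean()), float(sim.std(ddof=0))
        z = (observed - mean) / sd if sd > 0 else float("nan")
        out.append(
            NullDistribution(
                feature=track.label, observed=observed, simulated=sim,
                mean=mean, sd=sd, z=z,
            )
        )
    return out


def _tricube_local_linear(
    x: np.ndarray, y: np.ndarray, grid: np.ndarray, span: float = 0.75
) -> tuple[np.ndarray, np.ndarray]:
    """Loess-style smoother: tri-cube-weighted local linear fit plus SE."""
    n = x.size
    w_n = max(int(np.ceil(span * n)), 3)
    fit = np.full(grid.shape, np.nan)
    se = np.full(grid.shape, np.nan)
    for gi, g in enumerate(grid):
        d = np.abs(x - g)
        h = np.partition(d, w_n - 1)[w_n - 1]
        if h == 0:
            fit[gi] = y[d == 0].mean()
            se[gi] = 0.0
            continue
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        sw = w.sum()
        if sw == 0:
            continue
        X = np.column_stack([np.ones(n), x - g])
        WX = X * w[:, None]
        A = X.T @ WX
        b = WX.T @ y
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta = np.array([np.average(y, weights=w), 0.0])
        fit[gi] = beta[0]
        resid = y - X @ beta
        dof = max(sw**2 / (w**2).sum() - 2, 1.0)
        s2 = float((w * resid**2).sum() / w.sum()) / dof
        # variance of the weighted intercept
        e1 = np.zeros(2)
        e1[0] = 1.0
        try:
            Ainv = np.linalg.inv(A)
            var = s2 * float(e1 @ Ainv @ (X.T @ (X * (w**2)[:, None])) @ Ainv @ e1) * w.sum()
            se[gi] = np.sqrt(max(var, 0.0))
        except np.linalg.LinAlgError:
            se[gi] = np.nan
    return fit, se


def relative_distance_profile(
    cos: pd.DataFrame,
    units: FeatureTrack,
    *,
    n_bins: int = 20,
    grid_points: int = 50,
    span: float = 0.75,
) -> RelativeDistanceProfile:
    """Relative crossover position between flanking centromeric units.

    For a crossover midpoint p with nearest unit ending at e_left on the
    left and next unit starting at s_right on the right,
    r = (p - e_left) / (s_right - e_left) in [0, 1]. Crossovers inside a
    unit, or before the first / after the last unit of a chromosome, are
    excluded and counted. Chromosomes with fewer than two units are
    skipped. A uniform CO placement between units yields a flat profile.
    """
    rs = []
    n_inside = 0
    n_outside = 0
    for chrom in np.unique(cos["chrom"].to_numpy()):
        us, ue = units.merged_on(str(chrom))
        sub = cos[cos["chrom"] == chrom]
        mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) / 2.0).astype(np.float64)
        if us.size < 2:
            continue
        for p in mids:
            k = np.searchsorted(ue, p, side="right")  # first unit ending after p
            if k < us.size and us[k] <= p:  # inside unit k
                n_inside += 1
                continue
            if k == 0 or k >= us.size:
                n_outside += 1
                continue
            e_left, s_right = ue[k - 1], us[k]
            rs.append((p - e_left) / (s_right - e_left))
    r = np.array(rs, dtype=np.float64)
    edges = np.linspace(0, 1, n_bins + 1)
    density, _ = np.histogram(r, bins=edges, density=True) if r.size else (
        np.zeros(n_bins), edges)
    grid = np.linspace(0, 1, grid_points)
    if r.size >= 10:
        # smooth the binned density against bin centres
        centers = (edges[:-1] + edges[1:]) / 2
        fit, se = _tricube_local_linear(centers, density, grid, span=span)
    else:
        fit = np.full(grid.shape, np.nan)
        se = np.full(grid.shape, np.nan)
    return RelativeDistanceProfile(
        r=r,
        n_excluded_inside=n_inside,
        n_excluded_outside=n_outside,
        bin_edges=edges,
        bin_density=density,
        smooth_x=grid,
        smooth_y=fit,
        smooth_se=se,
    )


def metagene_profile(
    points: pd.DataFrame,
    features: FeatureTrack,
    *,
    n_bins: int = 50,
    flank_bp: int = 2500,
    flank_bins: int = 10,
) -> pd.DataFrame:
    """Binned point counts over scaled feature bodies with absolute flanks.

    Feature bodies are scaled to [0, 1] and split into ``n_bins`` bins;
    each flank spans ``flank_bp`` in ``flank_bins`` absolute-width bins.
    For stranded features (genes) the profile is oriented 5'->3' (TSS on
    the left). ``points`` needs chrom/start/end; the midpoint is used.
    Returns a tidy frame with bin index, zone (upstream/body/downstream)
    and count.
    """
    if np.any(features.end <= features.start):
        raise ValueError("degenerate feature (end <= start)")
    counts = np.zeros(2 * flank_bins + n_bins, dtype=np.int64)
    mids_by_chrom = {}
    for chrom in np.unique(points["chrom"].to_numpy()):
        sub = points[points["chrom"] == chrom]
        mids_by_chrom[str(chrom)] = np.sort(
            (sub["start"].to_numpy() + sub["end"].to_numpy()) / 2.0
        )
    for fi in range(features.start.size):
        chrom = str(features.chrom[fi])
        mids = mids_by_chrom.get(chrom)
        if mids is None or mids.size == 0:
            continue
        s, e = features.start[fi], features.end[fi]
        strand = features.strand[fi] if features.strand is not None else "+"
        lo, hi = s - flank_bp, e + flank_bp
        inside = mids[(mids >= lo) & (mids < hi)]
        for p in inside:
            if p < s:
                off = (p - lo) / flank_bp  # [0,1) upstream in + orientation
                b = int(off * flank_bins)
                zone = 0
            elif p >= e:
                off = (p - e) / flank_bp
                b = int(off * flank_bins)
                zone = 2
            else:
                off = (p - s) / (e - s)
                b = min(int(off * n_bins), n_bins - 1)
                zone = 1
            if strand == "-":
                if zone == 1:
                    b = n_bins - 1 - b
                else:
                    zone = 2 - zone
                    b = flank_bins - 1 - b
            base = 0 if zone == 0 else (flank_bins if zone == 1 else flank_bins + n_bins)
            counts[base + b] += 1
    zones = (
        ["upstream"] * flank_bins + ["body"] * n_bins + ["downstream"] * flank_bins
    )
    return pd.DataFrame(
        {"bin": np.arange(counts.size), "zone": zones, "count": counts}
    )


def windowed_track(
    intervals: pd.DataFrame,
    chrom: str,
    chrom_length: int,
    *,
    window: int = 1_000_000,
    step: int = 250_000,
) -> pd.DataFrame:
    """Per-window interval mass (density) for correlation analyses."""
    ws, we = sliding_windows(0, chrom_length, window, step)
    sub = intervals[intervals["chrom"] == chrom]
    mass = interval_window_mass(
        sub["start"].to_numpy(np.float64), sub["end"].to_numpy(np.float64), ws, we
    )
    return pd.DataFrame({"chrom": chrom, "start": ws, "end": we, "value": mass})


def window_correlation_matrix(tracks: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pearson correlation matrix of aligned per-window feature values.

    Tracks must share the same window grid (equal lengths, >= 3 windows).
    Zero-variance tracks get NaN rows/columns; the diagonal stays 1 where
    defined.
    """
    lengths = {len(v) for v in tracks.values()}
    if len(lengths) != 1:
        raise ValueError("tracks are not aligned on identical windows")
    (n,) = lengths
    if n < 3:
        raise ValueError("need at least 3 windows")
    df = pd.DataFrame(tracks)
    corr = df.corr(method="pearson")
    for name in df.columns:
        if df[name].std(ddof=0) == 0:
            corr.loc[name, :] = np.nan
            corr.loc[:, name] = np.nan
    return corr
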