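"""Crossover interference statistics.

Under no interference, per-gamete crossover counts are Poisson and
crossovers in disjoint genomic intervals occur independently. Interference
shows up as (i) underdispersion of CO counts (variance below the mean) and
(ii) a coefficient of coincidence (CoC) below 1 for nearby interval pairs:
CoC(i,j) = f_ij / (f_i * f_j), the observed co-occurrence frequency of COs
in intervals i and j across gametes relative to the independence
expectation. Because each crossover is localised only to a bracketing
marker interval, the CoC is averaged over resampling rounds that place each
CO at a uniform random point of its interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DispersionResult",
    "CoCCurve",
    "poisson_gof",
    "dispersion_test",
    "coc_curve",
]


@dataclass
class DispersionResult:
    n: int
    mean: float
    variance: float
    ratio: float
    statistic: float
    p_value: float
    verdict: str  # under | over | consistent


@dataclass
class CoCCurve:
    chrom: str
    k: int
    rounds: int
    pair_i: np.ndarray
    pair_j: np.ndarray
    separation_bp: np.ndarray  # interval midpoint distance
    coc: np.ndarray  # mean over usable rounds; NaN if never defined
    n_undefined_pairs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "i": self.pair_i,
                "j": self.pair_j,
                "separation_bp": self.separation_bp,
                "coc": self.coc,
            }
        )

    def by_separation(self) -> pd.DataFrame:
        """Mean CoC per distinct midpoint separation (the CoC curve)."""
        df = self.to_frame().dropna(subset=["coc"])
        return df.groupby("separation_bp", as_index=False)["coc"].mean()


def poisson_gof(counts: np.ndarray, *, min_expected: float = 5.0) -> tuple[float, int, float]:
    """Chi-squared goodness of fit of CO counts to Poisson(sample mean).

    Count bins with expectation below ``min_expected`` are merged into the
    tails; one degree of freedom is spent on the estimated mean, so
    df = bins - 2. Returns (statistic, df, p).
    """
    counts = np.asarray(counts, dtype=np.int64)
    n = counts.size
    if n < 20:
        raise ValueError("need at least 20 observations")
    lam = counts.mean()
    kmax = int(counts.max())
    support = np.arange(kmax + 1)
    probs = stats.poisson.pmf(support, lam)
    probs = np.append(probs, stats.poisson.sf(kmax, lam))  # open tail
    obs = np.append(np.bincount(counts, minlength=kmax + 1), 0).astype(np.float64)
    exp = probs * n
    # merge right tail, then left tail, until every bin carries min_expected
    while exp.size > 2 and exp[-1] < min_expected:
        exp[-2] += exp[-1]
        obs[-2] += obs[-1]
        exp, obs = exp[:-1], obs[:-1]
    while exp.size > 2 and exp[0] < min_expected:
        exp[1] += exp[0]
        obs[1] += obs[0]
        exp, obs = exp[1:], obs[1:]
    if exp.size < 2:
        raise ValueError("fewer than 2 bins after merging; counts too concentrated")
    stat = float(np.sum((obs - exp) ** 2 / exp))
    df = int(exp.size - 2)
    df = max(df, 1)
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def dispersion_test(counts: np.ndarray, *, alpha: float = 0.05) -> DispersionResult:
    """Variance-ratio test of Poisson dispersion.

    Under Poisson, (n-1) * variance / mean ~ chi-squared with n-1 df; the
    two-sided p doubles the smaller tail. Verdict 'under' requires both
    ratio < 1 and significance (interference), 'over' the reverse.
    """
    counts = np.asarray(counts, dtype=np.float64)
    n = counts.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("mean count is zero; dispersion undefined")
    var = counts.var(ddof=1)
    ratio = var / mean
    statistic = (n - 1) * ratio
    lower = stats.chi2.cdf(statistic, n - 1)
    p = float(2 * min(lower, 1 - lower))
    if ratio < 1 and p < alpha:
        verdict = "under"
    elif ratio > 1 and p < alpha:
        verdict = "over"
    else:
        verdict = "consistent"
    return DispersionResult(
        n=n, mean=float(mean), variance=float(var), ratio=float(ratio),
        statistic=float(statistic), p_value=p, verdict=verdict,
    )


def coc_curve(
    cos_per_cell: dict[str, list[tuple[float, float]]],
    chrom_length: int,
    *,
    k: int = 15,
    rounds: int = 100,
    seed: int = 0,
) -> CoCCurve:
    """Coefficient of coincidence for every pair of k equal intervals.

    ``cos_per_cell`` maps cell id -> list of (left, right) CO intervals on
    one chromosome; cells without COs must still appear (empty lists) since
    they enter the frequency denominators. Per round each CO is placed at a
    uniform point of its interval and binned; CoC(i,j) = f_ij / (f_i f_j)
    with per-cell presence frequencies f. Rounds where a pair's expectation
    is zero are excluded for that pair; pairs undefined in all rounds are
    reported NaN and counted.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cells = list(cos_per_cell)
    n_cells = len(cells)
    if n_cells == 0:
        raise ValueError("no cells supplied")
    flat_cell = []
    flat_left = []
    flat_width = []
    for ci, cid in enumerate(cells):
        for left, right in cos_per_cell[cid]:
            flat_cell.append(ci)
            flat_left.append(left)
            flat_width.append(max(right - left, 0.0))
    cell_idx = np.array(flat_cell, dtype=np.int64)
    left = np.array(flat_left, dtype=np.float64)
    width = np.array(flat_width, dtype=np.float64)
    bin_width = chrom_length / k

    iu, ju = np.triu_indices(k, 1)
    coc_sum = np.zeros(iu.size)
    coc_n = np.zeros(iu.size, dtype=np.int64)
    for _ in range(rounds):
        pts = left + rng.uniform(size=left.size) * width
        bins = np.minimum((pts / bin_width).astype(np.int64), k - 1)
        presence = np.zeros((n_cells, k), dtype=np.float64)
        presence[cell_idx, bins] = 1.0
        f = presence.mean(axis=0)
        fij = (presence.T @ presence) / n_cells
        denom = f[iu] * f[ju]
        ok = denom > 0
        coc_sum[ok] += fij[iu[ok], ju[ok]] / denom[ok]
        coc_n[ok] += 1
    coc = np.full(iu.size, np.nan)
    defined = coc_n > 0
    coc[defined] = coc_sum[defined] / coc_n[defined]
    separation = np.abs(ju - iu) * bin_width
    return CoCCurve(
        chrom="",
        k=k,
        rounds=rounds,
        pair_i=iu,
        pair_j=ju,
        separation_bp=separation,
        coc=coc,
        n_undefined_pairs=int((~defined).sum()),
    )
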