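"""Centromeric-unit annotation merging and cross-haplotype comparison.

Holocentric chromosomes carry hundreds of repeat-based centromeric units:
tandem-repeat (Tyba) arrays of ~20 kb spaced ~400 kb, each covered by a
CENH3 occupancy domain. Raw monomer/peak annotations are fragmented; the
merging rules here consolidate them into arrays/domains. The comparison
half scales array midpoints into syntenic blocks shared by the two
haplotypes, pairs arrays at the closest relative syntenic position, and
runs the statistical battery comparing the two haplotypes' arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._intervals import merge_intervals

__all__ = [
    "ArraySet",
    "SyntenicBlockMap",
    "merge_tyba",
    "merge_cenh3",
    "pair_arrays",
    "compare_array_stats",
]


@dataclass
class ArraySet:
    """Sorted disjoint arrays per chromosome (0-based half-open)."""

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]]

    @property
    def n_arrays(self) -> int:
        return sum(s.size for s, _ in self.by_chrom.values())

    def sizes(self) -> np.ndarray:
        parts = [e - s for s, e in self.by_chrom.values()]
        return np.concatenate(parts) if parts else np.array([], dtype=np.int64)

    def counts_per_chrom(self) -> dict[str, int]:
        return {c: int(s.size) for c, (s, _) in self.by_chrom.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, (s, e) in self.by_chrom.items():
            rows.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["chrom", "start", "end"]
        )


@dataclass
class SyntenicBlockMap:
    """Colinear block pairs between haplotypes.

    Frames need chrom/start/end; row i of ``hap1`` corresponds to row i of
    ``hap2``. Blocks must not overlap within a haplotype.
    """

    hap1: pd.DataFrame
    hap2: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.hap1) != len(self.hap2):
            raise ValueError("block lists differ in length")
        for name, df in (("hap1", self.hap1), ("hap2", self.hap2)):
            if np.any(df["end"].to_numpy() <= df["start"].to_numpy()):
                raise ValueError(f"degenerate block in {name}")
            for chrom, sub in df.groupby("chrom"):
                sub = sub.sort_values("start")
                if np.any(sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]):
                    raise ValueError(f"overlapping blocks in {name} on {chrom}")


def _merge_rule(
    intervals: pd.DataFrame,
    *,
    min_input: int,
    gap: int,
    gap_inclusive: bool,
    min_output: int,
) -> ArraySet:
    out = {}
    for chrom, sub in intervals.groupby("chrom"):
        s = sub["start"].to_numpy(np.int64)
        e = sub["end"].to_numpy(np.int64)
        order = np.argsort(s, kind="stable")
        s, e = s[order], e[order]
        keep = e - s >= min_input
        ms, me = merge_intervals(s[keep], e[keep], gap=gap, inclusive=gap_inclusive)
        big = me - ms >= min_output
        if big.any():
            out[str(chrom)] = (ms[big], me[big])
    return ArraySet(by_chrom=out)


def merge_tyba(
    monomers: pd.DataFrame,
    *,
    min_monomer: int = 500,
    merge_gap: int = 25_000,
    min_array: int = 2_000,
) -> ArraySet:
    """Consolidate repeat monomers into arrays.

    In order: drop monomers shorter than ``min_monomer``; merge neighbours
    whose gap is at most ``merge_gap`` (inclusive — "a maximum distance of
    25 kb"); drop merged arrays smaller than ``min_array``.
    """
    return _merge_rule(
        monomers,
        min_input=min_monomer,
        gap=merge_gap,
        gap_inclusive=True,
        min_output=min_array,
    )


def merge_cenh3(
    peaks: pd.DataFrame,
    *,
    merge_gap: int = 25_000,
    min_domain: int = 1_000,
) -> ArraySet:
    """Consolidate occupancy peaks into domains.

    Merge peaks whose gap is strictly less than ``merge_gap``, then drop
    domains smaller than ``min_domain``. A gap of exactly 25 kb does NOT
    merge (the rule is "less than").
    """
    return _merge_rule(
        peaks,
        min_input=0,
        gap=merge_gap,
        gap_inclusive=False,
        min_output=min_domain,
    )


def _relative_positions(arrays: ArraySet, blocks: pd.DataFrame) -> pd.DataFrame:
    """Assign each array to the block containing its midpoint.

    Returns a frame with block index, array interval, midpoint and the
    midpoint's relative position within the block ([0, 1]); arrays outside
    every block are omitted.
    """
    rows = []
    for chrom, (s, e) in arrays.by_chrom.items():
        mids = (s + e) / 2.0
        sub = blocks[blocks["chrom"] == chrom]
        for ai in range(s.size):
            hit = sub[(sub["start"] <= mids[ai]) & (mids[ai] < sub["end"])]
            if len(hit) == 0:
                continue
            row = hit.iloc[0]
            rel = (mids[ai] - row["start"]) / (row["end"] - row["start"])
            rows.append(
                {
                    "block": int(row.name),
                    "chrom": chrom,
                    "start": int(s[ai]),
                    "end": int(e[ai]),
                    "mid": float(mids[ai]),
                    "rel": float(rel),
                }
            )
    return pd.DataFrame(rows, columns=["block", "chrom", "start", "end", "mid", "rel"])


def pair_arrays(
    h1: ArraySet, h2: ArraySet, blocks: SyntenicBlockMap
) -> pd.DataFrame:
    """One-to-one pairing of arrays across haplotypes by syntenic position.

    Each array's midpoint is scaled to [0, 1] within its syntenic block;
    within corresponding blocks, pairs are formed greedily by increasing
    relative-position difference |Δrel|, each array used at most once.
    Returns one row per pair with both intervals, rel positions and drel.
    """
    if len(blocks.hap1) == 0:
        raise ValueError("empty syntenic block map")
    b1 = blocks.hap1.reset_index(drop=True)
    b2 = blocks.hap2.reset_index(drop=True)
    r1 = _relative_positions(h1, b1)
    r2 = _relative_positions(h2, b2)
    pairs = []
    for block in sorted(set(r1["block"]) & set(r2["block"])):
        a = r1[r1["block"] == block].reset_index(drop=True)
        b = r2[r2["block"] == block].reset_index(drop=True)
        cand = [
            (abs(a["rel"][i] - b["rel"][j]), i, j)
            for i in range(len(a))
            for j in range(len(b))
        ]
        cand.sort(key=lambda t: (t[0], t[1], t[2]))
        used_a: set[int] = set()
        used_b: set[int] = set()
        for d, i, j in cand:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            pairs.append(
                {
                    "block": block,
                    "chrom1": a["chrom"][i], "start1": a["start"][i], "end1": a["end"][i],
                    "chrom2": b["chrom"][j], "start2": b["start"][j], "end2": b["end"][j],
                    "rel1": a["rel"][i], "rel2": b["rel"][j],
                    "drel": a["rel"][i] - b["rel"][j],
                }
            )
    return pd.DataFrame(
        pairs,
        columns=[
            "block", "chrom1", "start1", "end1", "chrom2", "start2", "end2",
            "rel1", "rel2", "drel",
        ],
    )


def compare_array_stats(
    h1: ArraySet, h2: ArraySet, pairs: pd.DataFrame | None = None
) -> dict:
    """Statistical battery comparing the two haplotypes' arrays.

    Shapiro normality of per-chromosome array counts (each haplotype),
    F-test of count variances, two-sided t-test of count means,
    Mann-Whitney U on array sizes, two-sample Kolmogorov-Smirnov on
    paired relative positions, and a linear regression of drel on rel1
    (no haplotype bias shows slope and intercept near 0). Tests without
    enough data report NA with a reason.
    """
    results: dict[str, dict] = {}

    c1 = np.array(list(h1.counts_per_chrom().values()), dtype=np.float64)
    c2 = np.array(list(h2.counts_per_chrom().values()), dtype=np.float64)

    def na(reason: str) -> dict:
        return {"statistic": float("nan"), "p_value": float("nan"), "note": reason}

    for name, c in (("shapiro_hap1", c1), ("shapiro_hap2", c2)):
        if c.size >= 3 and np.ptp(c) > 0:
            w, p = stats.shapiro(c)
            results[name] = {"statistic": float(w), "p_value": float(p)}
        else:
            results[name] = na("need >= 3 distinct per-chromosome counts")

    if c1.size >= 3 and c2.size >= 3 and c1.var(ddof=1) > 0 and c2.var(ddof=1) > 0:
        f = c1.var(ddof=1) / c2.var(ddof=1)
        d1, d2 = c1.size - 1, c2.size - 1
        lower = stats.f.cdf(f, d1, d2)
        results["f_test_counts"] = {
            "statistic": float(f), "p_value": float(2 * min(lower, 1 - lower)),
        }
        t, p = stats.ttest_ind(c1, c2, equal_var=True)
        results["t_test_counts"] = {"statistic": float(t), "p_value": float(p)}
    else:
        results["f_test_counts"] = na("need >= 3 counts with variance per haplotype")
        results["t_test_counts"] = na("need >= 3 counts with variance per haplotype")

    s1, s2 = h1.sizes(), h2.sizes()
    if s1.size >= 3 and s2.size >= 3:
        u, p = stats.mannwhitneyu(s1, s2, alternative="two-sided")
        results["mannwhitney_sizes"] = {"statistic": float(u), "p_value": float(p)}
    else:
        results["mannwhitney_sizes"] = na("need >= 3 array sizes per haplotype")

    if pairs is not None and len(pairs) >= 3:
        d, p = stats.ks_2samp(pairs["rel1"], pairs["rel2"])
        results["ks_rel_positions"] = {"statistic": float(d), "p_value": float(p)}
        reg = stats.linregress(pairs["rel1"], pairs["drel"])
        results["regression_drel"] = {
            "slope": float(reg.slope),
            "intercept": float(reg.intercept),
            "p_value": float(reg.pvalue),
            "r": float(reg.rvalue),
        }
    else:
        results["ks_rel_positions"] = na("need >= 3 pairs")
        results["regression_drel"] = na("need >= 3 pairs")
    return results
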