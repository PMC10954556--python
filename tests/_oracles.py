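"""Independent brute-force oracles used by unit and acceptance tests.

Each function re-derives a pipeline quantity by direct enumeration,
deliberately ignoring the implementation's vectorised path.
"""

from __future__ import annotations

import numpy as np


def sliding_mean(values, window):
    """Mean over [i-window, i+window] truncated at the ends, per index."""
    n = len(values)
    out = []
    for i in range(n):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        out.append(sum(values[lo:hi]) / (hi - lo))
    return out


def majority_smooth(genotypes, window, na=0):
    """Window majority vote excluding NA; ties keep the own value."""
    n = len(genotypes)
    out = []
    for i in range(n):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        votes = [g for g in genotypes[lo:hi] if g != na]
        n1 = votes.count(1)
        n2 = votes.count(2)
        if n1 > n2:
            out.append(1)
        elif n2 > n1:
            out.append(2)
        else:
            out.append(genotypes[i])
    return out


def runs_with_qualification(pos, genotypes, min_markers, span_bp, na=0):
    """Maximal non-NA runs -> (start, end, genotype, n, qualified)."""
    blocks = []
    i, n = 0, len(genotypes)
    while i < n:
        if genotypes[i] == na:
            i += 1
            continue
        j = i
        while j + 1 < n and genotypes[j + 1] == genotypes[i]:
            j += 1
        run = pos[i : j + 1]
        qualified = any(
            run[t + min_markers - 1] - run[t] <= span_bp
            for t in range(len(run) - min_markers + 1)
        )
        blocks.append((run[0], run[-1], genotypes[i], len(run), qualified))
        i = j + 1
    return blocks


def count_intersecting(q_intervals, t_intervals):
    """Queries touching >= 1 bp of any target (half-open), each once."""
    total = 0
    for qs, qe in q_intervals:
        if any(qs < te and ts < qe for ts, te in t_intervals):
            total += 1
    return total


def window_median_thin(positions, window):
    """Lower-median marker per non-empty window from first to last marker."""
    positions = sorted(positions)
    if not positions:
        return []
    out = []
    start = positions[0]
    while start <= positions[-1]:
        inside = [p for p in positions if start <= p < start + window]
        if inside:
            out.append(inside[(len(inside) - 1) // 2])
        start += window
    return out


def merge_rule(intervals, min_input, gap, gap_inclusive, min_output):
    """Three-step annotation merge: size filter, gap merge, size filter."""
    kept = sorted((s, e) for s, e in intervals if e - s >= min_input)
    merged = []
    for s, e in kept:
        if merged:
            g = s - merged[-1][1]
            if (g <= gap) if gap_inclusive else (g < gap):
                merged[-1][1] = max(merged[-1][1], e)
                continue
        merged.append([s, e])
    return [(s, e) for s, e in merged if e - s >= min_output]


def marker_filter(records, min_mq, lo_cov, hi_cov, lo_af, hi_af, snps_only=True):
    """Exhaustive per-record retention predicate."""
    out = []
    for r in records:
        if snps_only and r.is_indel:
            continue
        if r.mapping_quality <= min_mq:
            continue
        if not (lo_cov <= r.alt_coverage <= hi_cov):
            continue
        if not (lo_af <= r.allele_frequency <= hi_af):
            continue
        out.append(r)
    return out


def dispersion_closed_form(counts):
    """(n-1) * s^2 / xbar computed with explicit sums."""
    n = len(counts)
    xbar = sum(counts) / n
    s2 = sum((x - xbar) ** 2 for x in counts) / (n - 1)
    return (n - 1) * s2 / xbar


def random_intervals(rng, n, length, max_width=50_000):
    starts = rng.integers(0, length - max_width, size=n)
    widths = rng.integers(1, max_width, size=n)
    return np.sort(starts), np.sort(starts) + widths[np.argsort(starts)]
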