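"""Crossover caller: smoothing oracles, block building, truth recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from holoco.calling import (
    CallerParams,
    GenotypeBlock,
    build_blocks,
    call_crossovers,
    genotype_cell,
    genotype_from_af,
    smooth_allele_frequencies,
    smooth_genotypes,
)
from holoco.simulate import (
    GameteObservation,
    MeiosisModel,
    ObservationModel,
    observe_gamete,
    simulate_meiosis,
)

import _oracles


class TestAfSmoothing:
    def test_isolated_error_absorbed(self):
        sm = smooth_allele_frequencies(np.array([0, 0, 1, 0, 0.0]))
        assert sm[2] == pytest.approx(0.2)
        assert np.all(genotype_from_af(sm) == 1)

    def test_constant_sequence_fixed_point(self):
        af = np.zeros(50)
        np.testing.assert_array_equal(smooth_allele_frequencies(af), af)

    def test_empty_input(self):
        assert smooth_allele_frequencies(np.array([])).size == 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60),
        st.integers(min_value=1, max_value=4),
    )
    def test_matches_sliding_mean_oracle(self, values, window):
        ours = smooth_allele_frequencies(np.array(values), window)
        np.testing.assert_allclose(ours, _oracles.sliding_mean(values, window), atol=1e-12)


class TestGenotypeSmoothing:
    def test_majority_flips_center(self):
        g = np.array([1, 1, 2, 1, 1], dtype=np.int8)
        assert smooth_genotypes(g)[2] == 1

    def test_all_na_stays_na(self):
        g = np.zeros(10, dtype=np.int8)
        np.testing.assert_array_equal(smooth_genotypes(g), g)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=60),
        st.integers(min_value=1, max_value=4),
    )
    def test_matches_majority_oracle(self, genotypes, window):
        ours = smooth_genotypes(np.array(genotypes, dtype=np.int8), window)
        np.testing.assert_array_equal(ours, _oracles.majority_smooth(genotypes, window))


class TestBuildBlocks:
    def test_qualified_block(self):
        pos = np.array([0, 200_000, 400_000, 600_000, 800_000]) + 1
        blocks = build_blocks("chr1", pos, np.ones(5, dtype=np.int8))
        assert len(blocks) == 1 and blocks[0].qualified

    def test_four_markers_unqualified(self):
        pos = np.arange(1, 5) * 1000
        blocks = build_blocks("chr1", pos, np.ones(4, dtype=np.int8))
        assert len(blocks) == 1 and not blocks[0].qualified

    def test_sparse_block_qualifies_through_dense_core(self):
        # 1,000 markers over 10 Mb would fail a whole-block span rule, but
        # five consecutive markers within 1 Mb qualify it
        pos = np.concatenate([[1], np.arange(5_000_000, 5_000_500, 100), [10_000_000]])
        blocks = build_blocks("chr1", pos, np.ones(pos.size, dtype=np.int8))
        assert blocks[0].qualified

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=50), st.randoms())
    def test_matches_run_length_oracle(self, genotypes, rnd):
        pos = np.cumsum([rnd.randint(1, 400_000) for _ in genotypes])
        blocks = build_blocks("chr1", pos, np.array(genotypes, dtype=np.int8))
        expected = _oracles.runs_with_qualification(list(pos), genotypes, 5, 1_000_000)
        assert [
            (b.start_pos, b.end_pos, b.genotype, b.n_markers, b.qualified) for b in blocks
        ] == expected


def qblock(chrom, start, end, genotype, n=20, qualified=True):
    return GenotypeBlock(chrom, start, end, genotype, n, qualified)


class TestCallCrossovers:
    def test_single_conversion(self):
        blocks = [qblock("chr1", 1, 500_000, 1), qblock("chr1", 700_000, 1_200_000, 2)]
        cos = call_crossovers(blocks, "c")
        assert len(cos) == 1
        assert (cos[0].left, cos[0].right) == (500_000, 700_000)

    def test_single_block_no_calls(self):
        assert call_crossovers([qblock("chr1", 1, 9, 1)]) == []

    def test_unqualified_blocks_carry_no_state(self):
        blocks = [
            qblock("chr1", 1, 500_000, 1),
            qblock("chr1", 600_000, 650_000, 2, n=3, qualified=False),
            qblock("chr1", 700_000, 1_200_000, 1),
        ]
        assert call_crossovers(blocks) == []  # same genotype: logical merge
        blocks[2] = qblock("chr1", 700_000, 1_200_000, 2)
        cos = call_crossovers(blocks)
        assert len(cos) == 1 and (cos[0].left, cos[0].right) == (500_000, 700_000)

    def test_close_double_co_dropped_by_default(self):
        blocks = [
            qblock("chr1", 1, 1_000_000, 1, n=20),
            qblock("chr1", 1_100_000, 1_500_000, 2, n=6),
            qblock("chr1", 1_600_000, 3_000_000, 1, n=20),
        ]
        assert call_crossovers(blocks) == []
        far = [
            qblock("chr1", 1, 1_000_000, 1),
            qblock("chr1", 1_100_000, 4_000_000, 2),
            qblock("chr1", 4_100_000, 8_000_000, 1),
        ]
        assert len(call_crossovers(far)) == 2

    def test_close_double_co_rescued_by_support(self):
        blocks = [
            qblock("chr1", 1, 1_000_000, 1, n=30),
            qblock("chr1", 1_100_000, 1_500_000, 2, n=12),
            qblock("chr1", 1_600_000, 3_000_000, 1, n=30),
        ]
        cos = call_crossovers(blocks, rescue_block_markers=10)
        assert len(cos) == 2
        assert all("close_double_co" in c.flags for c in cos)


class TestGenotypeCell:
    def test_noiseless_exact_recovery(self, noiseless_cells, dense_genome):
        cells, truths = noiseless_cells
        exact = 0
        for cell, truth in zip(cells, truths):
            _, cos, n = genotype_cell(cell)
            for chrom, _ in dense_genome.chromosomes:
                for c in (c for c in cos if c.chrom == chrom):
                    inside = np.sum(
                        (truth.crossovers[chrom] >= c.left) & (truth.crossovers[chrom] <= c.right)
                    )
                    assert inside >= 1  # every call brackets a true CO
            exact += n == truth.n_crossovers()
        assert exact >= 0.95 * len(cells)

    def test_empty_cell_yields_no_calls(self, dense_genome):
        empty = GameteObservation(
            cell_id="x",
            calls={
                c: {
                    "pos": np.array([], dtype=np.int64),
                    "hap1_reads": np.array([], dtype=np.int64),
                    "hap2_reads": np.array([], dtype=np.int64),
                }
                for c, _ in dense_genome.chromosomes
            },
        )
        _, cos, n = genotype_cell(empty)
        assert n == 0 and cos == []

    def test_translation_invariance(self, noiseless_cells):
        cells, _ = noiseless_cells
        cell = cells[0]
        shift = 123_456
        shifted = GameteObservation(
            cell_id=cell.cell_id,
            calls={
                c: {
                    "pos": d["pos"] + shift,
                    "hap1_reads": d["hap1_reads"],
                    "hap2_reads": d["hap2_reads"],
                }
                for c, d in cell.calls.items()
            },
        )
        _, cos_a, _ = genotype_cell(cell)
        _, cos_b, _ = genotype_cell(shifted)
        assert [(c.chrom, c.left + shift, c.right + shift) for c in cos_a] == [
            (c.chrom, c.left, c.right) for c in cos_b
        ]

    def test_recall_degrades_monotonically_with_error(self, dense_genome, meiosis_300cM):
        truths = simulate_meiosis(dense_genome, meiosis_300cM, 120, seed=77)
        recalls = []
        for eps in (0.0, 0.02, 0.05, 0.10):
            obs = ObservationModel(markers_per_cell={"kind": "all"}, error_rate=eps)
            tp = fn = 0
            for i, t in enumerate(truths):
                cell = observe_gamete(t, dense_genome, obs, seed=3_000 + i)
                _, cos, _ = genotype_cell(cell)
                for chrom, _ in dense_genome.chromosomes:
                    called = [(c.left, c.right) for c in cos if c.chrom == chrom]
                    used = set()
                    for p in t.crossovers[chrom]:
                        hit = [
                            j
                            for j, (l, r) in enumerate(called)
                            if j not in used and l - 50_000 <= p <= r + 50_000
                        ]
                        if hit:
                            used.add(hit[0])
                            tp += 1
                        else:
                            fn += 1
            recalls.append(tp / (tp + fn))
        assert all(a >= b - 0.01 for a, b in zip(recalls, recalls[1:]))
        assert recalls[0] > recalls[-1]

    def test_intervals_inside_chromosome(self, noiseless_cells, dense_genome):
        cells, _ = noiseless_cells
        lengths = dense_genome.chrom_lengths
        for cell in cells[:10]:
            _, cos, _ = genotype_cell(cell)
            for c in cos:
                assert 1 <= c.left < c.right <= lengths[c.chrom]
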