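"""Generator statistics: tiling, densities, interference, sparsity, doublets."""

import numpy as np
import pytest

from holoco.qc import switch_rate
from holoco.simulate import (
    ConfigurationError,
    MeiosisModel,
    ObservationModel,
    make_doublet,
    observe_gamete,
    simulate_meiosis,
    simulate_reference,
    simulate_selfed_offspring,
)

from conftest import bare_genome


def chromatid_counts(genome, nu, n, seed, cm=60.0, **kw):
    model = MeiosisModel(
        genetic_length_cM={c: cm for c, _ in genome.chromosomes}, nu=nu, **kw
    )
    truths = simulate_meiosis(genome, model, n, seed=seed)
    return np.array(
        [t.crossovers[c].size for t in truths for c, _ in genome.chromosomes]
    ), truths


class TestReference:
    def test_marker_density_matches_config(self, small_genome):
        # requested 1 marker per 449 bp on 2 Mb -> ~4454 per chromosome
        for _, m in small_genome.markers.items():
            assert m["pos"].size == pytest.approx(2_000_000 / 449, rel=0.10)

    def test_marker_positions_strictly_increasing_and_alleles_differ(self, small_genome):
        for m in small_genome.markers.values():
            assert np.all(np.diff(m["pos"]) > 0)
            assert np.all(m["hap1"] != m["hap2"])

    def test_tyba_geometry(self, small_genome):
        # ~20 kb arrays spaced ~400 kb -> about 5 per 2 Mb chromosome
        t = small_genome.features["tyba_monomers"]
        counts = [np.sum(t["chrom"] == c) for c, _ in small_genome.chromosomes]
        assert 3.0 <= np.mean(counts) <= 7.0
        sizes = t["end"] - t["start"]
        assert np.mean(sizes) == pytest.approx(20_000, rel=0.25)

    def test_zero_genes_requested(self):
        g = simulate_reference([1_000_000], n_genes_per_mb=0.0, seed=1)
        assert g.features["genes"]["start"].size == 0

    def test_deterministic_given_seed(self):
        a = simulate_reference([500_000] * 2, seed=7)
        b = simulate_reference([500_000] * 2, seed=7)
        for c, _ in a.chromosomes:
            np.testing.assert_array_equal(a.markers[c]["pos"], b.markers[c]["pos"])
            np.testing.assert_array_equal(a.markers[c]["hap1"], b.markers[c]["hap1"])

    @pytest.mark.parametrize("bad", [{"chrom_lengths": [0]}, {"chrom_lengths": [1000], "marker_spacing": -1}])
    def test_invalid_config_rejected(self, bad):
        lengths = bad.pop("chrom_lengths")
        with pytest.raises(ConfigurationError):
            simulate_reference(lengths, **bad)


class TestMeiosis:
    def test_segments_tile_chromosomes_exactly(self, dense_genome, meiosis_300cM):
        truths = simulate_meiosis(dense_genome, meiosis_300cM, 25, seed=11)
        for t in truths:
            for chrom, L in dense_genome.chromosomes:
                segs = t.segments[chrom]
                assert segs[0][0] == 0 and segs[-1][1] == L
                for (s0, e0, h0), (s1, e1, h1) in zip(segs, segs[1:]):
                    assert e0 == s1  # no gaps, no overlaps
                    assert h0 != h1  # alternating haplotypes

    def test_zero_map_gives_zero_crossovers(self, dense_genome):
        model = MeiosisModel(genetic_length_cM={c: 0.0 for c, _ in dense_genome.chromosomes})
        truths = simulate_meiosis(dense_genome, model, 20, seed=3)
        assert all(t.n_crossovers() == 0 for t in truths)

    def test_poisson_limit_variance_over_mean(self):
        g = bare_genome({"chr1": 90_000_000})
        counts, _ = chromatid_counts(g, nu=1.0, n=20_000, seed=5)
        ratio = counts.var(ddof=1) / counts.mean()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_interference_strictly_reduces_dispersion(self):
        g = bare_genome({"chr1": 90_000_000})
        ratios = []
        for nu in (1.0, 2.0, 5.0, 10.0):
            counts, _ = chromatid_counts(g, nu=nu, n=20_000, seed=5)
            ratios.append(counts.var(ddof=1) / counts.mean())
        assert all(a > b for a, b in zip(ratios, ratios[1:]))

    def test_distal_bias_concentrates_crossovers(self):
        g = bare_genome({"chr1": 10_000_000})
        model = MeiosisModel(genetic_length_cM={"chr1": 60.0}, distal_bias_weight=2.0)
        truths = simulate_meiosis(g, model, 4_000, seed=6)
        pos = np.concatenate([t.crossovers["chr1"] for t in truths])
        L = 10_000_000
        outer = np.mean((pos < 0.2 * L) | (pos > 0.8 * L)) / 0.4
        inner = np.mean((pos > 0.4 * L) & (pos < 0.6 * L)) / 0.2
        assert outer > inner

    def test_obligate_crossover(self):
        g = bare_genome({"chr1": 10_000_000})
        model = MeiosisModel(genetic_length_cM={"chr1": 30.0}, p_obligate=True)
        truths = simulate_meiosis(g, model, 300, seed=8)
        assert all(t.crossovers["chr1"].size >= 1 for t in truths)

    def test_reproducible(self, dense_genome, meiosis_300cM):
        a = simulate_meiosis(dense_genome, meiosis_300cM, 5, seed=42)
        b = simulate_meiosis(dense_genome, meiosis_300cM, 5, seed=42)
        for x, y in zip(a, b):
            assert x.segments == y.segments
            for c in x.crossovers:
                np.testing.assert_array_equal(x.crossovers[c], y.crossovers[c])

    def test_invalid_nu_rejected(self):
        with pytest.raises(ConfigurationError):
            MeiosisModel(genetic_length_cM={"chr1": 60.0}, nu=0.0)


class TestObservation:
    def test_noiseless_full_capture_is_identity(self, dense_genome, meiosis_300cM):
        truth = simulate_meiosis(dense_genome, meiosis_300cM, 1, seed=21)[0]
        obs = ObservationModel(markers_per_cell={"kind": "all"}, error_rate=0.0)
        cell = observe_gamete(truth, dense_genome, obs, seed=22)
        assert cell.n_markers == dense_genome.n_markers()
        for chrom, _ in dense_genome.chromosomes:
            c = cell.calls[chrom]
            hap = truth.haplotype_at(chrom, c["pos"])
            np.testing.assert_array_equal(c["hap1_reads"] > 0, hap == 1)
            np.testing.assert_array_equal(c["hap2_reads"] > 0, hap == 2)

    def test_error_rate_sets_discordance(self, dense_genome):
        model = MeiosisModel(genetic_length_cM={c: 0.0 for c, _ in dense_genome.chromosomes})
        truth = simulate_meiosis(dense_genome, model, 1, seed=23)[0]
        obs = ObservationModel(markers_per_cell={"kind": "all"}, error_rate=0.05)
        cell = observe_gamete(truth, dense_genome, obs, seed=24)
        discordant = 0
        for chrom, _ in dense_genome.chromosomes:
            c = cell.calls[chrom]
            hap = truth.haplotype_at(chrom, c["pos"])
            maj = np.where(c["hap1_reads"] > c["hap2_reads"], 1, 2)
            discordant += int(np.sum(maj != hap))
        n = cell.n_markers  # 5,000 single-read markers -> ~250 discordant
        assert discordant == pytest.approx(0.05 * n, rel=0.25)

    def test_marker_count_straddles_qc_cut(self, dense_genome, meiosis_300cM):
        truths = simulate_meiosis(dense_genome, meiosis_300cM, 60, seed=25)
        obs = ObservationModel(markers_per_cell={"kind": "lognormal", "median": 400, "sigma": 0.5})
        ns = [observe_gamete(t, dense_genome, obs, seed=30 + i).n_markers for i, t in enumerate(truths)]
        assert any(n < 400 for n in ns) and any(n >= 400 for n in ns)

    def test_observed_positions_subset_of_reference(self, dense_genome, meiosis_300cM):
        truth = simulate_meiosis(dense_genome, meiosis_300cM, 1, seed=26)[0]
        obs = ObservationModel(markers_per_cell={"kind": "fixed", "n": 500})
        cell = observe_gamete(truth, dense_genome, obs, seed=27)
        assert cell.n_markers == 500
        for chrom, _ in dense_genome.chromosomes:
            ref = dense_genome.markers[chrom]["pos"]
            assert np.all(np.isin(cell.calls[chrom]["pos"], ref))


class TestDoublets:
    def test_self_union_doubles_counts(self, noiseless_cells):
        cells, _ = noiseless_cells
        d = make_doublet(cells[0], cells[0])
        for chrom, c in cells[0].calls.items():
            np.testing.assert_array_equal(d.calls[chrom]["pos"], c["pos"])
            np.testing.assert_array_equal(d.calls[chrom]["hap1_reads"], 2 * c["hap1_reads"])
        assert d.is_doublet

    def test_doublet_switch_rate_exceeds_singletons(self, dense_genome, meiosis_300cM):
        # sparse capture: the two gametes observe mostly disjoint markers,
        # so the union alternates haplotypes far more than either input
        truths = simulate_meiosis(dense_genome, meiosis_300cM, 200, seed=55)
        obs = ObservationModel(markers_per_cell={"kind": "fixed", "n": 500})
        cells = [
            observe_gamete(t, dense_genome, obs, seed=700 + i)
            for i, t in enumerate(truths)
        ]
        exceeds = 0
        pairs = list(zip(cells[:100], cells[100:200]))
        for a, b in pairs:
            d = make_doublet(a, b)
            exceeds += switch_rate(d) > max(switch_rate(a), switch_rate(b))
        assert exceeds == len(pairs)

    def test_union_of_marker_sets(self, dense_genome, meiosis_300cM):
        truths = simulate_meiosis(dense_genome, meiosis_300cM, 2, seed=31)
        obs = ObservationModel(markers_per_cell={"kind": "fixed", "n": 300})
        a = observe_gamete(truths[0], dense_genome, obs, seed=32)
        b = observe_gamete(truths[1], dense_genome, obs, seed=33)
        d = make_doublet(a, b)
        for chrom, _ in dense_genome.chromosomes:
            expected = np.union1d(a.calls[chrom]["pos"], b.calls[chrom]["pos"])
            np.testing.assert_array_equal(d.calls[chrom]["pos"], expected)
        assert d.provenance == (a.cell_id, b.cell_id)


class TestSelfedOffspring:
    def test_zero_map_zero_crossovers(self, dense_genome):
        model = MeiosisModel(genetic_length_cM={c: 0.0 for c, _ in dense_genome.chromosomes})
        records, _ = simulate_selfed_offspring(dense_genome, model, 10, seed=41)
        assert records == []

    def test_mean_crossovers_doubles_gamete_rate(self, dense_genome, meiosis_300cM):
        # two gametes per offspring: 2 x 3 expected COs under a 300 cM map
        records, _ = simulate_selfed_offspring(dense_genome, meiosis_300cM, 200, seed=42)
        assert len(records) / 200 == pytest.approx(6.0, rel=0.10)

    def test_interval_width_median(self, dense_genome, meiosis_300cM):
        records, _ = simulate_selfed_offspring(
            dense_genome, meiosis_300cM, 300, seed=43, resolution_sigma=0.5
        )
        widths = np.array([r["end"] - r["start"] for r in records])
        assert np.median(widths) == pytest.approx(334, rel=0.15)
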