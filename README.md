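# holoco

Crossover detection and recombination-landscape analysis from sparse
single-gamete haplotype markers, built for holocentric plants whose
centromeric units (CENH3-binding tandem-repeat arrays) are distributed
along the whole chromosome.

## The problem

Measuring meiotic recombination normally requires a segregating
population. For self-incompatible species that is expensive or impossible;
an alternative is to sequence many individual gametes (pollen nuclei) of a
single heterozygous plant with single-cell RNA-seq. Each cell then yields
a sparse, noisy readout of haplotype-specific SNP markers — hundreds to a
few thousand markers per cell, usually one read each — and every crossover
(CO) appears as a haplotype switch along a chromosome. `holoco` implements
the full analysis for this design:

* **marker selection** from a variant table against the phased haplotype-1
  reference (SNPs with MQ > 50, 5 ≤ alt coverage ≤ 30, 0.4 ≤ AF ≤ 0.6);
* **cell QC**: read/marker count filters (≥ 400 markers), species
  assignment by dual-reference alignment rates, and doublet removal by the
  genotype switch rate (alternations per marker > 0.07);
* **CO calling** by two-stage smoothing (window mean of allele
  frequencies, then genotype majority vote), qualified genotype blocks
  (five markers within 1 Mb), and crossover intervals at genotype
  conversions;
* **landscape and maps**: sliding-window cM/Mb tracks (1 Mb / 100 kb),
  marker thinning (500 kb window medians), Marey maps and genetic lengths
  (`cM(x) = 100 · E[COs left of x] / n_cells`);
* **interference**: Poisson goodness of fit, variance-ratio dispersion
  test, and coefficient-of-coincidence curves
  (`CoC(i,j) = f_ij / f_i f_j` over k equal intervals with interval-
  resampling of CO positions);
* **feature association**: permutation null with fixed per-chromosome CO
  counts and empirical interval widths, overlap Z-scores, relative
  distance of COs to flanking centromeric units, strand-aware metagene
  profiles, windowed Pearson correlation matrices;
* **centromeric-unit annotation**: the monomer/peak merging rules for
  repeat arrays and CENH3 domains, plus the cross-haplotype syntenic
  pairing and statistical comparison of arrays;
* **synthetic data**: a gamma-renewal meiosis simulator (interference
  shape ν, optional distal bias and obligate CO), sparse noisy
  observation model, doublets and selfed offspring — so the entire
  pipeline is testable without any sequencing data.

See `docs/methods.md` for the models, parameter defaults and their
rationale, and known limitations.

## Worked example

Run the end-to-end synthetic analysis (simulate → QC → call → landscape →
interference → association) from Python:

```python
from holoco.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    chrom_lengths={f"chr{i+1}": 5_000_000 for i in range(5)},
    marker_spacing=2_000,                      # 1 SNP per 2 kb
    genetic_length_cM={f"chr{i+1}": 60.0 for i in range(5)},  # 300 cM total
    n_cells=300,
    markers_per_cell={"kind": "lognormal", "median": 900, "sigma": 0.4},
    error_rate=0.01,
    doublet_fraction=0.05,
    permutation_rounds=1000,
    seed=7,
)
manifest = run_pipeline(cfg, "demo_run")

r = manifest["results"]
print("cells passing QC:", r["n_cells"])
print("crossovers:", r["n_crossovers"])
print("mean COs/gamete:", round(r["mean_cos_per_gamete"], 3))
print("mean COs/chromatid:", round(r["mean_cos_per_chromatid"], 3))
print("total map length (cM):", round(r["total_map_length_cM"], 1))
print("dispersion:", {k: (round(v, 3) if isinstance(v, float) else v)
                      for k, v in r["dispersion"].items()})
print("association Z:", {k: round(v, 2) for k, v in manifest["association_z"].items()})
```

which prints (all artifacts are also written to `demo_run/`):

```
cells passing QC: 280
crossovers: 807
mean COs/gamete: 2.882
mean COs/chromatid: 0.576
total map length (cM): 288.2
dispersion: {'ratio': 0.683, 'p_value': 0.0, 'verdict': 'under'}
association Z: {'tyba_monomers': 0.97, 'cenh3_peaks': 0.82, 'genes': 0.52, 'TEs': -0.02}
```

Reading these numbers: of 300 emitted cells, the QC stage removed the
simulated doublets and the cells under 400 markers, leaving 280. The
caller found 807 crossovers, i.e. ~2.9 per gamete and ~0.58 per chromatid
— close to, but ~4% under, the simulated 3.0, because crossovers within
two markers of a chromosome end cannot be bracketed by a qualified block;
the Marey-map total (288 cM, identically 100 × mean COs/gamete) reflects
the same calling loss relative to the true 300 cM. The dispersion ratio
0.68 with a tiny p-value correctly flags the simulated interference
(ν = 5): per-gamete CO counts are underdispersed relative to Poisson. The
association Z-scores are all within ±1 of zero, as they must be here —
the simulator places crossovers independently of the feature tracks.

The same stages are available as CLI subcommands (`holoco simulate`,
`markers`, `qc`, `callco`, `landscape`, `genmap`, `coc`, `assoc`,
`annot`, `run`); artifacts are plain TSV/BED/bedgraph/JSON, with marker
tables 1-based (VCF convention) and all interval output 0-based half-open
(BED convention).

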