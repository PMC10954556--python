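# Methods

`holoco` re-implements, as a tested library, a pipeline for detecting
meiotic crossovers (COs) in individual gametes of a heterozygous,
holocentric plant from sparse haplotype-specific markers, together with the
downstream analyses that characterise the recombination landscape: windowed
cM/Mb tracks, Marey maps, crossover-interference statistics, permutation
tests of CO association with (epi)genomic features, and the annotation and
cross-haplotype comparison of repeat-based centromeric units. Because the
original sequencing data are not required, a first-class synthetic-data
module generates gametes with the statistical structure the analyses
assume; every stage is validated against ground truth or an independent
brute-force oracle.

## The measurement model

A haploid gamete inherits one recombined chromatid per chromosome. Against
a phased haplotype-1 reference, each heterozygous SNP is a haplotype
diagnostic: reads covering it vote for haplotype 1 or 2. Single-cell RNA
of pollen nuclei is shallow — hundreds to a few thousand markers observed
per cell, mostly at one read each, with a percent-scale error rate — so a
gamete's genome reads as a sparse, noisy binary string per chromosome, and
every true crossover appears as a single switch point in that string.

## Marker selection

Variants called against the hap1 assembly are retained as markers when
they are biallelic SNPs with mapping quality strictly above 50, alternate
allele coverage in [5, 30] and pooled allele frequency in [0.4, 0.6]
(heterozygous sites in a single individual should sit near 0.5). The
mapping-quality bound is strict and the interval bounds inclusive,
following the printed inequality symbols. Multiallelic sites are dropped by
default (only allelic SNPs are haplotype-diagnostic); a flag expands them
instead. Mean marker spacing is defined as chromosome length divided by
marker count.

## Cell QC

Three screens run before calling:

* **counts** — cells are kept when total reads exceed the barcode-count
  threshold (default 5,000, strict) and the marker count is at least 400
  (inclusive: "fewer than 400" is discarded, 400 itself kept);
* **species** — for the two-species multiplexed library, a cell is called
  for the genome with the higher alignment rate, `ambiguous` when the two
  rates differ by fewer than 10 percentage points, and `low_rate` (and
  discarded) when even the winning rate is below 25%;
* **doublets** — the switch rate is the number of genotype alternations
  between consecutive decided raw calls within chromosomes divided by the
  total observed marker count. Raw calls take the read-majority haplotype;
  read ties are undecided and skipped; switches are never counted across
  chromosome boundaries. Cells above 0.07 (strict) are doublets. The rate
  is computed on raw, unsmoothed calls, since the screen runs before CO
  calling; for a noiseless singleton it equals true COs / markers.

The synthetic cohort confirms the screen's design point: at ~800 observed
markers and 1% error, singleton rates concentrate near 2 x error plus the
CO rate (~0.03) while doublets — two sparse marker sets interleaved, so
adjacent markers frequently come from different chromatids — concentrate
far above 0.07, giving >= 95% sensitivity and specificity in the test
suite.

## Crossover calling

Two smoothing stages, then segmentation:

1. per-marker allele frequency `af = hap2_reads / (hap1 + hap2)` is
   replaced by its mean over the five-marker window centred on the marker
   (two ahead, two behind; truncated at chromosome ends), then thresholded
   at 0.5 into H1/H2 (exactly 0.5 is undecided — ties resolve
   deterministically, never randomly);
2. genotypes are majority-smoothed over the same window, undecided
   neighbours excluded, voting ties keeping the marker's own call;
3. maximal same-genotype runs become blocks. A block is *qualified* to
   carry genotype state when any five consecutive member markers span at
   most 1 Mb. The published rule ("at least five markers within 1 Mb") does
   not say whether the span is measured over the whole block or a window;
   the windowed reading was chosen because it rejects sparse spurious
   blocks while still qualifying long dense blocks, whose total span is
   legitimately much larger than 1 Mb.
4. each adjacent pair of qualified blocks with different genotypes yields
   one crossover interval, bracketed by the last marker of the upstream
   block and the first of the downstream one. Unqualified blocks carry no
   state: same-genotype qualified neighbours merge logically across them,
   and a conversion spans the unqualified gap.

The study manually reviewed cells with double COs; here that review is a
deterministic rule. Adjacent calls whose interval midpoints lie closer
than 2 Mb are flagged `close_double_co` and dropped, unless every block
the pair touches (upstream, shared middle, downstream) holds at least 10
markers — the middle block is precisely the evidence that a close double
crossover is real, so its support is required for rescue. Both the
separation and the support threshold are exposed parameters.

With full error-free marker capture the caller recovers >= 95% of true COs
exactly (losses are crossovers within two markers of a chromosome end,
where no five-marker flanking block exists); at 1,000 markers per
chromosome and 2% allele error, recall and precision both stay >= 0.95, and
recall degrades monotonically as error grows.

## Landscape, thinning and Marey maps

The windowed recombination rate over window `w` is
`rate(w) = 100 * M(w) / n_cells / |w|_Mb`, where `M(w)` sums each CO's
overlap fraction with `w`, the CO's unit mass spread uniformly over its
bracketing interval (default 1 Mb window, 100 kb step). Spreading rather
than midpointing was chosen because gamete CO intervals are of megabase
width and midpoint assignment creates step artifacts; a midpoint mode
remains available. With tiling windows the rate track conserves total CO
count exactly, a tested identity. Rates are reported only for windows
fully inside the confident region (first to last observed marker) when
bounds are supplied.

Marker thinning selects the lower-median marker (by index) in each 500 kb
window, windows stepping by their own width from the first marker to the
last. The genetic position at physical `x` is
`100 * E[#COs left of x] / n_cells`, each CO contributing the probability
that a uniform point of its interval falls left of `x`; the chromosome map
length is therefore exactly `100 * (COs on chromosome) / n_cells`, and the
genome total equals `100 *` mean COs per gamete — a construction-level
identity the tests assert to float precision. Under a 300 cM synthetic map
(five chromosomes of 60 cM), 2,000 dense error-free gametes pushed through
the full caller recover the total within 5% (the ~2% shortfall is the
terminal-CO loss above, not an estimator bias).

## Interference statistics

* **Poisson goodness of fit** — observed per-gamete CO count histogram
  against Poisson(sample mean); bins with expectation below 5 are merged
  into the tails; df = bins − 2 (one for the estimated mean).
* **Dispersion** — the variance ratio `(n−1) s² / x̄` is chi-squared with
  n−1 df under Poisson; the two-sided p doubles the smaller tail. A
  significantly small ratio ("under") is the signature of CO interference.
* **Coefficient of coincidence** — the chromosome is divided into `k`
  equal intervals (default 15, configurable per chromosome; the study used
  18 on its longest chromosome and 15 elsewhere, and both are honoured via
  the parameter rather than either being treated as canonical). Because a
  CO is only localised to a marker interval, each resampling round places
  it at a uniform point of that interval; per round,
  `CoC(i,j) = f_ij / (f_i f_j)` from per-cell presence frequencies, and
  pairs average over the rounds in which their expectation is non-zero
  (rounds default to 100; the value is a numerical-smoothing choice and
  two independent 100-round runs agree within 0.05 on a fixed cohort).
  Pair separation is the interval-midpoint distance.

## Feature association

The permutation null re-places "pseudo-COs" chromosome by chromosome: per
round, exactly the observed per-chromosome CO counts, each interval width
drawn with replacement from the empirical pool of real CO widths, each
start uniform on `[0, L − width]` (placement is clamped by construction;
pseudo-COs may overlap each other — no exclusion rule is imposed). Overlap
counts (>= 1 bp, each CO once) against each feature track across 5,000
default rounds give `Z = (observed − mean) / sd`, positive meaning
enrichment; no multiple-testing correction is applied, matching the
original presentation of per-feature Z-scores. Calibration is tested by
drawing the "observed" set from the null itself: pooled over four feature
tracks, 200 replicate Z-values have |mean| < 0.1 and sd within [0.9, 1.1].

The relative-distance profile asks whether crossovers avoid the
neighbourhood of centromeric units: each CO midpoint between two units
maps to `r = (p − e_left)/(s_right − e_left)` in [0, 1]; COs inside units
or beyond a chromosome's first/last unit are excluded and counted. The
profile is reported as binned densities plus a loess-style smoother
(tri-cube-weighted local linear regression, span 0.75) with a pointwise
standard-error band. The CO representative point is the interval midpoint
(configurable to a uniform random point); with the offspring data's
few-hundred-bp resolution the midpoint is faithful.

Metagene profiles scale feature bodies to [0, 1] (strand-aware for genes,
TSS on the left) with absolute-bp flanks, counting CO and marker midpoints
per bin; marker profiles provide the density normalisation. Window-level
Pearson correlation matrices operate on aligned per-window feature values
(default 1 Mb window, 250 kb step), with zero-variance tracks reported NA.

## Centromeric-unit annotation and haplotype comparison

Tyba monomer annotations: drop monomers < 500 bp, merge neighbours with
gaps <= 25 kb (inclusive, "a maximum distance of 25 kb"), then drop merged
arrays < 2 kb — in that order. CENH3 peaks: merge gaps strictly < 25 kb,
then drop domains < 1 kb. The two rules' different boundary conventions
follow the respective sentences literally; both merges are idempotent and
output sorted, disjoint intervals (tested exactly).

For cross-haplotype comparison, each array's midpoint is scaled to [0, 1]
within the syntenic block containing it; within corresponding blocks,
arrays pair greedily by increasing |Δrel| under a one-to-one constraint
(the original matching algorithm is not described; greedy nearest-position
matching is deterministic and recovers the true correspondence exactly on
jittered synthetic annotations). The comparison battery mirrors the
published tests: Shapiro normality of per-chromosome array counts, an
F-test of count variances, a two-sided t-test of count means,
Mann–Whitney U on array sizes, a two-sample Kolmogorov–Smirnov test on
relative positions, and a linear regression of Δrel on rel (no haplotype
bias shows slope and intercept near zero).

## The synthetic generator

The generator emulates the study's data structure, not its sequences:

* **reference** — five chromosomes (study scale ~70–90 Mb; tests and the
  bundled configurations run at 2–10 Mb, which preserves every
  per-marker statistic), markers as a Poisson process at 1 per 449 bp,
  Tyba arrays ~20 kb spaced ~400 kb with CENH3 domains jittered around
  them, plus stranded gene and TE tracks.
* **meiosis** — chiasmata on the genetic scale follow a stationary gamma
  renewal process with shape `nu` and rate `2 nu` per Morgan (stationary
  first-event delay sampled as Uniform × length-biased interval), thinned
  to one chromatid with probability 1/2, so per-chromatid counts have mean
  map-length/100, are exactly Poisson at `nu = 1`, and grow underdispersed
  as `nu` rises. The study reports strong interference but no generative
  model or interference strength; the gamma renewal process is the
  standard interference model and `nu` is a free parameter (default 5,
  qualitatively matching the observed CoC suppression out to tens of Mb).
  Genetic positions map to physical ones through the inverse CDF of a
  symmetric beta density with `a = 1/(1 + w)`; `w = 0` is uniform, larger
  `w` concentrates COs distally (the observed landscape is distally
  biased). An optional obligate-CO flag rejection-samples chromatids until
  at least one CO.
* **observation** — a log-normal marker count per cell (default median
  700, straddling the 400-marker QC cut), uniform capture without
  replacement, one read per captured marker by default (transcript
  sparsity; configurable), each read flipping haplotype with the error
  rate; doublets merge two gametes' observations (union of markers,
  summed counts); selfed offspring union two independent gametes' COs and
  report each as an interval with log-normal width (median 334 bp,
  matching the offspring CO resolution).

All randomness descends from one integer seed; per-cell sub-streams are
spawned by counter, so outputs are byte-reproducible and independent of
evaluation order.

What the generator does **not** model: real expression variation
(capture is uniform, not transcript-weighted), barcode chemistry and
ambient RNA, mapping bias near structural variants, segmental
marker deserts, or linkage between error and coverage. Passing tests
therefore demonstrate the correctness and calibration of the algorithms
under the stated statistical assumptions, not the end-to-end accuracy on
any particular sequencing run.

## Problem sizes and numerical choices

The bundled analyses run at reduced scale chosen to keep Monte-Carlo error
well inside the tolerances they are checked against: 10,000 gametes for
count means (±2%), 2,000 fully observed cells for map-length recovery
(±5%), 20,000 chromatids for dispersion and CoC curves, 500 cells for
recall/precision, and 1,000–5,000 permutation rounds for Z-scores.
Deterministic tie rules throughout (af exactly 0.5 → undecided; majority
ties → self-keep; lower median on even counts); degenerate inputs (empty
cells, zero markers, zero-length maps, chromosomes without qualified
blocks) return empty results or explicit NA rather than raising, except
where a quantity is mathematically undefined (zero-mean dispersion,
zero-cell rates), which raises.

## Known limitations

* The caller cannot place crossovers within two markers of a chromosome
  end (no qualified flanking block), a ~2% count shortfall at the bundled
  densities; real data share this edge blindness.
* Genetic lengths are derived directly from CO counts with no mapping
  function, as gamete data permit; no correction for undetected double
  crossovers within one marker interval is applied.
* The switch-rate doublet screen assumes sparse capture; two gametes
  observed at every marker would instead produce read-tied markers and is
  detected poorly (the read-count filter catches such cells in practice).
* The loess-style smoother is a presentation device; its internals are not
  matched to any particular reference implementation.
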