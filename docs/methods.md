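# Methods

## The scan statistic

The pipeline detects local depletion of polymorphism — the footprint of a
selective sweep or of strong drift — in small resequencing panels. The
unit of analysis is the 300 Kb bin: for each individual the number of
heterozygous genotype calls falling in the bin is divided by the bin width
(trailing bins shorter than 300 Kb are normalized by their actual width and
flagged), and the population value is the arithmetic mean of the
individuals' rates. Large bins are deliberate: with 2–7× coverage and a
genotype-quality cutoff the per-site SNP detection rate is low, and small
windows fluctuate too much to scan. Homozygous non-reference counts are
computed and reported per bin but do not enter the sweep statistic, which
uses heterozygous calls only.

Filtering is per call: depth within an inclusive band (default 5–10×) and
genotype quality ≥ 20. The depth ceiling is a repeat proxy — collapsed
repeats attract excess coverage. Missing genotypes in a VCF sample column
are neither heterozygous nor homozygous non-reference and are ignored; a
non-reference call without DP or GQ is treated as missing.

## Threshold calibration by permutation

A sweep requires ≥ 5 consecutive bins at or below a threshold *t*
("at or below" is the comparison throughout). *t* is chosen to control the
genome-wide probability of seeing any qualifying run by chance at
α = 0.05, separately for each population:

1. Pool all bin values of the genome and shuffle them uniformly into the
   fixed per-chromosome bin structure ("permuted across the genome":
   pooled, not within-chromosome).
2. For the shuffled genome record the **minimax run threshold**:
   min over all windows of 5 consecutive within-chromosome bins of the
   window maximum. This is the smallest *t* admitting a qualifying run;
   as *t* rises through it the count of significant regions passes 0 → 1,
   so absent ties it is "the threshold yielding exactly one significant
   region". With tied values several regions can appear simultaneously;
   the minimax is still returned.
3. Repeat for `n_reps` replicates (default 7,000) and take the lower
   empirical α-quantile (order statistic of rank ⌈α·n⌉) of the replicate
   thresholds.

By construction a fresh permutation contains a qualifying run iff its own
minimax is ≤ *t*, so the fraction flagged estimates α; the calibration
test and acceptance script verify this on an iid exponential null genome
of 3,000 bins over 30 chromosomes.

Runs never span chromosome boundaries. Partial trailing bins participate
in the permutation like full bins (their rates are already
width-normalized). Replicate *r* draws from a seed-derived independent
substream, making results reproducible and order-independent; the pooled
values are sorted before shuffling so the replicate stream depends only on
the value multiset and the seed, not on the input track's ordering.

## Sweep calling and overlap analysis

Sweeps are maximal runs (≥ `run_len` bins at/below *t*), reported as
genomic intervals from the first bin start to the last bin end — hence a
minimum length of 1.5 Mb on full bins. Bins with no retained calls have
rate 0 and qualify; `min_informative_sites` can optionally mask them.

Overlaps are computed at bp resolution with a boundary-event sweep. The
chromosome decomposes into atoms on which the covering-population set is
constant; atoms with ≥ 2 covering populations qualify; touching qualifying
atoms are merged into one record when they share at least two populations
(published tables list one interval and one population list per region;
a region's population list is exactly the set of populations whose sweeps
intersect it, and its span is the union extent of those sweeps). A sweep
intersecting no overlap region is population-specific, so every sweep is
classified exactly once. Summaries count records by minimum population
number, by class composition (e.g. commercial lines vs heritage
varieties), by chromosome and by population.

## Synthetic data

The generator emulates the product of mapping + genotype calling, not the
sequencing itself: per individual, heterozygous sites are a homogeneous
Poisson process at rate θ per bp (default 1.07×10⁻³, the observed domestic
turkey average of ~1.07 het SNPs/Kb), multiplied inside planted sweep
intervals by a reduction factor in [0,1]; `"shared"` sweeps are planted in
every population to exercise overlap detection. Homozygous non-reference
sites are an independent Poisson process (default 2×10⁻⁴ per bp — below
the heterozygous rate, as expected when the reference genome is itself a
domestic bird; not reduced inside sweeps since the statistic ignores
them). Depth is uniform on {2,…,12} and GQ places 85% of its mass at ≥ 20,
so both retention and rejection branches of the filters occur. Default
panel structure is 3 individuals per population. Output is one VCFv4.2
file per population (FORMAT GT:DP:GQ; only polymorphic sites; `./.` for
individuals without a call), byte-identical under a fixed seed.

Deliberately absent realism: no linkage disequilibrium, recombination,
coalescent ancestry, allele-frequency spectrum or genotyping-error model —
sites and individuals are independent. Passing tests therefore demonstrate
the pipeline's behaviour under its own null and under planted signal of
known location and strength; they do not certify power or error rates on
real data, where LD makes neighbouring bins correlated and the permutation
null conservative or liberal depending on the diversity landscape.

## Numerical and design choices

- Bins are half-open `[start, end)` 0-based internally; reports print
  1-based inclusive coordinates. Position *p* (1-based) maps to bin
  `(p−1)//300000`, so position 300,000 is the last bp of bin 0.
- Depth bounds are inclusive (5 ≤ DP ≤ 10), the conventional reading of
  "5–10 fold".
- Population averaging is the mean of individual *rates* (identical to
  summed counts over summed width when individuals share the binning).
- Quantile convention: lower empirical order statistic; with all-equal
  bin values the threshold equals that value for any α and `n_reps`.
- Ties in bin values can make "exactly one region" unattainable; the
  minimax is returned regardless (see above).
- Heat maps color cells by a white→red ramp applied to √heterozygosity,
  normalized to the per-figure maximum (the square root stretches the
  low-diversity end where sweeps live); rendering is an exact-pixel
  raster, deterministic for fixed input, with optional interval outlines
  and an SVG axes variant.
- The pipeline manifest records parameters, seed, versions and SHA-256
  checksums of every artifact; identical config + seed reproduces
  identical checksums.

## Problem sizes in the test suite

Stochastic checks run at desk scale, chosen once: threshold calibration
uses a 3,000-bin null genome with 20,000 estimation replicates and 2,000
fresh scans (the acceptance script uses 20,000 fresh scans, putting the
reported percentage's standard error near 0.2 points); single-population
planted-sweep recovery uses 100 simulations of a 30 Mb genome (5
chromosomes, θ = 1.07×10⁻³, a 2.1 Mb sweep at reduction 0.02, 3
individuals, 200 permutation replicates each); the end-to-end overlap
check runs the full pipeline 20 times on a 13.5 Mb genome with 10
populations sharing one planted sweep. At these sizes the planted signal
(2% of background heterozygosity) sits far below any plausible threshold,
so recovery failures indicate pipeline defects rather than statistical
noise.

## Known limitations

- The permutation null assumes exchangeable bins; real genomes have
  spatially structured diversity (recombination-rate and mutation-rate
  variation), which the synthetic generator does not reproduce.
- With 2–3 individuals per population, "population" heterozygosity is a
  small-sample mean; thresholds double as diversity measures and are not
  comparable across panels with different coverage.
- Very low-coverage chromosomes or masked regions appear as zero-rate
  bins and, without `min_informative_sites`, can qualify as sweeps.
- The overlap merge rule can join adjacent regions whose population lists
  differ; the alternative (emitting every constant-coverage atom) is
  recoverable from the per-population sweep BEDs.
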