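# Methods

`sweepscan` implements a genome-wide scan for recent positive selection
from phased SNP-chip haplotypes, the long-range-haplotype approach used
to map selection signatures in livestock lines: haplotype blocks ("core
regions") are detected from the confidence bounds of pairwise |D′|,
extended haplotype homozygosity (EHH) and relative EHH (REHH) are
evaluated 1 Mb to either side of each core haplotype, and outliers are
called by empirical rank within core-haplotype frequency bins.  A
coalescent-initialized forward Wright–Fisher generator produces the
chip-like phased panels the pipeline is tested on.

## The scan

**Input contract.** Phased, complete, biallelic haplotypes (phased VCF
or IMPUTE-style `.hap`/`.legend`), alleles coded 0/1.  Phasing and
imputation are upstream concerns; unphased or missing genotypes are hard
errors.  Markers with unknown position, monomorphic markers, and markers
with minor allele frequency below 0.05 are removed, in that order, with
a reconciled filter report.  All coordinates are 1-based inclusive; BED
feature files are converted from 0-based half-open on read.

**Core regions.** For each marker pair (span ≤ 2.5 Mb, a cap chosen
above the largest block length we expect at chip scale), the multinomial
likelihood of the four phased haplotype counts is evaluated on a
101-point grid of |D′| ∈ [0, 1], with allele frequencies fixed at their
sample estimates, reconstructed haplotype probabilities floored at 1e-10
before logs, and the normalized likelihood accumulated to a two-sided
90% interval (5th and 95th cumulative grid points).  A pair is *strong
LD* when ci_low ≥ 0.70 and ci_high ≥ 0.98, *strong recombination* when
ci_high < 0.90, otherwise *inconclusive*; monomorphic pairs are
uninformative.  A candidate interval qualifies as a core region when at
least 95% of its conclusive pairs (strong LD + strong recombination;
inconclusive pairs carry no evidence either way and enter neither count)
are strong LD and its end pair is itself strong.  Qualifying intervals
are selected greedily by descending bp length, leftmost first on ties,
never overlapping, with ≥ 2 SNPs each.  All thresholds are configurable.

A note on the denominator: scoring intervals by strong/(strong +
recombination) rather than strong/(all informative) is what makes the
rule behave correctly in the no-recombination limit — repulsion-phase
pairs (derived alleles on different genealogical branches, |D′| = 1 with
n11 = 0) have wide likelihood intervals and would otherwise dilute every
long block below the 95% bar.

**EHH, EHH̄, REHH.** For a core haplotype with c ≥ 2 carriers among H
chromosomes, EHH at a locus is the probability that two randomly chosen
carriers are identical over the whole interval from the core boundary to
that locus: Σᵢ C(eᵢ,2)/C(c,2) over extension-group sizes eᵢ.  EHH̄ pools
all H−c non-carriers, with the interval including the core region itself
(so chromosomes with different core haplotypes are never homozygous).
REHH = EHH_t / EHH̄ at the first marker at distance ≥ 1 Mb from the
region boundary in the direction of travel (no interpolation: the
statistic stays a pure function of observed haplotypes; a midpoint
anchor is available as an option).  When the chromosome ends before
1 Mb, the terminal marker is used and the record is flagged
`truncated_end` but retained.  EHH̄ = 0 gives `undefined_bar` and the
record is excluded from testing; undefined records never raise in batch
mode.  Identity is exact string equality — the I/O contract forbids
missing data.

**Significance.** Each testable record (every qualifying core haplotype
× two directions) is assigned to one of 20 equal-width right-closed
frequency bins over (0, 1] (a record with frequency f goes to bin
⌈20f⌉−1; equal-count bins are available).  The empirical p-value is the
within-bin upper-tail rank, ties inclusive, self included: p ≥ 1/n_bin
by construction.  Significance is raw p < α = 0.01; a Benjamini–Hochberg
column is emitted for convenience but never drives the flag.  A
log-normal fit per bin is offered as an alternative p-mode.  Reporting
tables (per-chromosome counts, significant regions) are restricted to
core haplotypes with frequency ≥ 0.25; the full record table is not.
Binning is per scan (per line), not pooled across lines.

**Annotation and contrast.** Significant regions are intersected with
user-supplied BED features (≥ 1 bp overlap, all-pairs semantics; "/" for
no feature).  Between-line divergence at a region is tested by a
chi-square test of homogeneity on the core-haplotype × line count table,
pooling rare haplotypes smallest-first into "other" until all expected
counts reach 1 (configurable); the test statistic is invariant to line
relabeling, and pooling never changes the grand total.  A chi-square
test was chosen as the standard k×2 haplotype-table test; exact tests
are out of scope.

## The synthetic-data generator

The generator emulates a 60K-chip study of two broiler lines divergently
selected for abdominal fat: one or more chromosomes, ~22 kb mean marker
spacing, MAF spectrum truncated at 0.05, block-forming background LD,
100 phased haplotypes per line, and optionally a selective sweep or a
divergent two-line split.

**Model.** A haploid Wright–Fisher population of 2N chromosomes with
per-generation recombination (crossover count ~ Poisson(rL), uniform
breakpoints) and infinite-sites mutation (ancestral allele 0, one flip
per site, fresh uniform integer positions, de-duplicated).  Standing
variation is initialized at exact neutral equilibrium by a seeded
coalescent simulation (msprime, binary 0/1 mutations, discrete genome)
of the matching model — the coalescent is the stationary distribution of
this Wright–Fisher process, so initialization adds no truncation bias —
and every scenario generation then runs forward: drift, selection
(parent-sampling weight 1+s for carriers of the focal derived allele, or
for non-carriers in the down-selected line), and the two-line split are
exact.  A pure-forward burn-in from a monomorphic population is
available via `burn_in_generations`.  Fixed and lost sites are purged
each generation; fixation is tracked so it is never confused with loss.
All randomness flows from one integer seed through one NumPy generator
(msprime seeds are drawn from it), so (params, seed) determines the
panel bit-for-bit.

**Default parameters and why.**

| parameter | default | rationale |
|---|---|---|
| N (diploids) | 500 | desk-scale population that still yields chip-like diversity |
| L | 5 Mb | one chromosome arm; ≥ 2×1 Mb flanks around a central sweep |
| H | 100 haplotypes | tens-to-hundreds per line, as in chip studies of selected lines |
| μ | 1e-8 /bp/gen | vertebrate point-mutation scale; with thinning sets chip density |
| r | 1e-8 /bp/gen | at this N reproduces the block-rich LD regime of small-Nₑ selected lines (ρ ≈ 0.4 between adjacent markers) |
| marker target | L / 22,090 | the reference study's mean marker spacing |
| MAF floor | 0.05 | the chip QC filter; the focal site is exempt (truth must survive) |
| sweep | s = 0.10, start 0.02, G = 45 | a young low-frequency variant (carriers share a recent haplotype) driven to ≈ 0.4–0.7 — the regime the REHH test targets |

With these defaults one neutral chromosome yields ≈ 226 markers,
≈ 35 core regions of ≈ 100 kb mean length with ≈ 0.85 of SNPs inside
blocks and ≈ 9 EHH tests per region — close to the published chip-scale
bookkeeping (22.09 kb spacing, 86–103 kb mean region length, ≈ 8.4
tests per region) that the generator is meant to emulate.

If the focal allele is lost, the simulation retries with sub-seeds
derived from (seed, attempt), preserving determinism, up to 10 times.
The two-line mode shares one marker map (pooled-sample MAF floor; a site
lost in one line is an all-ancestral column there, a site fixed in one
line an all-derived column).

**What the generator does not emulate.** Real chicken demography
(bottlenecks, growth, family structure), varying recombination maps,
ascertainment bias of chip marker selection beyond the MAF floor,
genotyping or phasing error, gene conversion, and background selection.
Passing tests therefore demonstrate correctness and calibration of the
statistics under the model's assumptions, not robustness to artifacts
of real chip data.

## Study designs for calibration and power

Empirical within-bin p-values are discrete: a bin with n members cannot
produce p < 0.01 unless n > 100.  Calibration and power genomes
therefore use 24 independent 5 Mb chromosomes (≈ 5,400 markers, ≈ 7,000
tests, every bin > 100 members), the desk-scale counterpart of a
genome-wide chip scan.  The problem sizes here are the package's chosen
study design, stated so results are interpretable:

* **Type-I error** — one neutral 24-chromosome genome.  Because
  empirical p is a within-bin rank, the number of records below α is a
  deterministic function of bin sizes (ties can only lower it): the
  attainable expectation Σ_bins (⌈αn⌉−1) is reported next to the
  realized count, and the realized rate sits at α within binomial
  tolerance.
* **Sweep recovery** — 20 replicate genomes, one selected chromosome
  each (s = 0.1 from 2% standing frequency, 45 generations).  A
  replicate is recovered when the significant-region table (p < 0.01,
  frequency ≥ 0.25) holds a region within 1 Mb of the realized focal
  position: blocks often form in the swept flanks rather than on top of
  the focal site, so recovery is defined on the sweep's neighborhood.
  Misses are dominated by sweeps that stall at low frequency — an
  honest property of selection from standing variation, and of the
  frequency-≥ 0.25 reporting cut.
* **Two-line null** — both lines sampled from one population (zero
  scenario generations): the exact null of the homogeneity test, under
  which the chi-square p-values across regions are approximately
  uniform.  With generations of independent drift after the split the
  contrast is *not* null-calibrated (drift divergence inflates χ²,
  F_ST ≈ G/2N); the worked analysis therefore reads between-line
  contrasts as a ranking, with the swept region expected at the top.

## Numerical choices and degenerate inputs

* |D′| CI: grid resolution 101, likelihood floor 1e-10, frequencies
  fixed at sample values — chosen for determinism and
  oracle-checkability; D = 0 maps to D′ = 0 and the sign of observed D
  selects the D_max branch.
* Greedy block selection breaks bp-length ties leftmost; regions never
  overlap; a chromosome with fewer markers than `min_snps` yields none.
* Duplicate marker positions are rejected (EHH needs a strict marker
  order); position ties are not arbitrated.
* Report rounding: EHH/REHH to 2 decimals, p to 4, numpy round-half-even
  (3.994999 → 3.99), so TSVs diff stably across runs.
* Singleton bins give p = 1 with a flag; empty scans produce header-only
  tables and a warning, never an exception.

## Known limitations

* The |D′| CI recipe matches this package's documented construction and
  its independent test oracle; equivalence with any particular legacy
  implementation of the block rule cannot be asserted.
* High-frequency sweeps (core haplotype > 0.8) land in sparse frequency
  bins where the attainable empirical p rarely clears 0.01 — a known
  blind spot of frequency-binned REHH, visible in the worked example.
* The chi-square contrast relies on asymptotics; with heavy pooling the
  test is conservative.
* Single-threaded throughout; a 24-chromosome genome scans in ~10 s.
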