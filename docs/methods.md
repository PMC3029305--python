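# Methods

## Populations and meiosis

Individuals are simulated marker-by-marker along a multi-chromosome
genetic map. Crossovers follow the Haldane model (a Poisson crossover
process, hence no interference): between markers `d` cM apart the
per-meiosis recombination fraction is `r = (1 − e^(−2d/100))/2`. An F2
individual is the union of two independent gametes, each a Markov chain
of parental alleles along the chromosome. RILs are modelled at the
infinite-selfing limit as fully homozygous mosaics whose
adjacent-marker recombination fraction is `R = 2r/(1 + 2r)`, the
standard selfed-RIL expectation. Both closed forms double as test
oracles (recombinant fractions at 10⁵ meioses are checked against them
to 3 standard errors).

The default map has five chromosomes of 135, 88, 101, 125 and 139 cM —
an Arabidopsis-like classical map, chosen because the method was
developed for Arabidopsis SNP arrays; the source designs state no map —
with markers every 0.5 cM. Both are configurable. QTL positions are
snapped to the nearest marker, since pool signals are only observable
at markers.

## Genetic models

A QTL with additive effect `a` and dominance `d` contributes `+a`, `d`,
`−a` to the genetic value of AA / AB / BB genotypes (A = reference
parent allele); multiple loci add. A two-locus model may instead supply
a 3×3 epistasis table giving the value of each genotype combination
outright. Phenotypes add the mean of `n` independent
Normal(0, `env_sd`) measurement errors per individual (default
`n = 3`, `env_sd = 1`), so the noise variance of a line mean is
`env_sd²/n`.

Eight catalogued presets cover: major/moderate single additive QTL,
major dominant, major overdominant, a telomeric major QTL, two unlinked
moderate QTL, two major QTL linked in repulsion (opposite-sign effects
20 cM apart), and two unlinked epistatic loci. "Major" scales the locus
to explain 75% of single-measurement phenotypic variance in an F2,
"moderate" 30%; with `env_sd = 1` this gives `a = √6 ≈ 2.45` (additive
major), `a = √(6/7) ≈ 0.93` (additive moderate), `a = d = 2` (dominant
major), `d = 2√3 ≈ 3.46` (overdominant major), via the F2 segregation
variances `a²/2`, `(a²+d²)/2 − d²/4`, `d²/4`. The epistatic preset uses
a dominant-complementary table (`+e` iff both loci carry at least one
reference allele, else `−e`, with `e ≈ 1.75` at the major scale) — a
classic two-locus architecture whose marginal allele effects are
nonzero at both loci, so both linked chromosomes carry signal. The
variance calibration is defined on F2 segregation frequencies; RIL runs
reuse the same effect sizes.

## Signal banks

Per-marker array signals are drawn from a *signal bank*: one pool of
allele-difference values per genotype class plus a control pool. The
synthetic generator emulates the shape of real parental hybridizations:
AA ~ Normal(+1.5, 0.8), BB ~ Normal(−1.5, 0.8) (signal units), controls
~ Normal(0, 0.5), and the heterozygote pool is the elementwise mean of
paired AA/BB draws — the same "pseudo-F1" construction used for real
parent arrays, and therefore distributed about zero. The defaults were
fixed once so that the marker and control densities overlap while the
modes separate clearly; all headline results (failure rates, orderings)
are structural and do not depend on this calibration, whereas absolute
threshold and confidence-interval values do and are reported only in
the bank's own signal units. An empirical bank can be loaded from two
parental intensity tables plus a polymorphic-marker list; simulations
use sense-strand signals only (real sense/antisense signals are highly
correlated).

Signals are assigned to simulated genotypes by uniform resampling with
replacement from the class pool, independently per (individual,
marker) cell — pooled across markers rather than tied to each marker's
own probes, which reproduces marginal noise but no probe-specific
affinity. Only the selected pool members are assigned signals, since
only they are hybridized.

## The scan

The BSA statistic per marker is the difference of pool mean signals
(high − low). Each chromosome is smoothed by loess with span 0.25:
a degree-2 local polynomial fitted by weighted least squares over the
`ceil(span·m)` nearest markers with tricube weights
`w = (1 − (|Δx|/max|Δx|)³)³`, evaluated at each marker, no robustness
iterations — the defaults of the R `loess()` this class of analysis
traditionally relies on (verified to machine precision against
`loess(..., degree = 2, surface = "direct")` and against an independent
brute-force WLS oracle in the tests). Because the furthest neighbour
carries weight exactly 0, the neighbourhood is floored at `degree + 2`
points. For a fixed map the smoother is linear, so replicate batches
precompute one hat matrix per chromosome and smooth by matrix-vector
product. Simulations smooth on cM positions; the real-data pipeline on
bp; traces record their unit and never mix them.

## Aggregation

Per replicate, the smoothed maximum and minimum (value and position)
are recorded per chromosome. Thresholds pool every unlinked
chromosome's maxima and |minima| — symmetric treatment, the natural
reading for a sign-free detector — and take nearest-rank 95th/99th
percentiles (the `ceil(q·n)`-th sorted value). A replicate is a
*failure* when the linked chromosome's extreme, taken in the direction
implied by the model (the marginal effect of the reference allele at
the locus, table-marginalised for epistasis; maxima when the marginal
effect is zero, as under pure overdominance), does not exceed the 95%
threshold. One-sided judgement is used because the simulator knows
which allele raises the phenotype.

The positional confidence interval is the smallest window centred on
the true locus, intersected with the chromosome, that contains the peak
position in ≥95% of replicates (locus-centred rather than
peak-median-centred; the alternative reading of "central width" was
considered and rejected as harder to interpret when the peak
distribution is skewed by chromosome ends). Under a no-signal null with
the locus at the chromosome centre this converges to ~0.95× the
chromosome length (uniform order statistics), slightly inflated because
loess edge variance biases null peaks toward the chromosome ends.

Multi-scenario reports average thresholds across genetic models within
each population/selection group (they are equal in expectation, since
unlinked chromosomes carry no signal) before judging failures.

## Real-data pipeline

Inputs are already-extracted intensity TSVs (one row per SNP × strand
with both allele intensities); CEL parsing and spatial correction are
upstream of this package. The scan restricts to the supplied
polymorphic-marker list, takes the per-SNP allele difference in each
bulk, subtracts bulk B from bulk A, smooths per chromosome and strand,
and averages the two strands into a combined trace. Region calls are
maximal contiguous runs of markers with |smoothed| ≥ threshold₉₅, one
call per run, peak at the run's largest magnitude. Thresholds must come
from a simulation matched to the experimental design; they are not
recomputed from the two experimental arrays.

The fixture generator emulates such an experiment: SNPs uniformly
placed on bp coordinates, bulk compositions drawn per SNP under
Hardy–Weinberg at a skewed (inside the planted region) or balanced
allele frequency, signals resampled from a bank, intensities written as
`base ± diff/2`. Each SNP's bulk composition is drawn independently —
there is no linkage along the chromosome — so fixtures test
planted-region recovery, not linkage-disequilibrium structure; passing
them shows the scan recovers a sustained allele-frequency skew, not
that it reproduces any particular real hybridization.

## Numerical choices and problem sizes

* Pool selection takes the top/bottom `round(fraction·N)` phenotypes,
  ties broken by ascending individual index (stable sort) —
  deterministic, and invariant to positive affine phenotype transforms.
* All randomness flows from one master seed through
  `numpy.random.SeedSequence` spawns: one stream per replicate plus one
  for the bank, so batches are bitwise reproducible and
  embarrassingly parallel in principle.
* Extremes tie-break to the smallest position.
* Replicate counts: the test suite and acceptance script use 200–1000
  replicates per scenario at 0.5 cM marker spacing, the package's
  desk-scale default profile; all checked quantities are rates and
  orderings whose Monte-Carlo error at those counts is well inside the
  asserted tolerances.

## Known limitations

* No crossover interference, no backcross or outbred designs, at most
  two QTL.
* Signal draws ignore probe-specific affinity, spatial artifacts and
  sense/antisense correlation; the bank is pooled across markers.
* Effect-size presets are calibrated to variance-explained targets, not
  to any external catalogue of effect sizes.
* Threshold and CI magnitudes are meaningful only relative to the bank
  calibration; transfer to real arrays requires an empirical bank from
  the actual cross parents.
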