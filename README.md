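# snpbsa

Bulk segregant analysis (BSA) and eXtreme Array Mapping (XAM) on SNP
genotyping arrays, with the simulation machinery needed to calibrate
them.

## The problem

BSA maps the genomic location of a trait by pooling individuals from
the two phenotypic extremes of a biparental cross and asking where the
pools differ in allele frequency. On a SNP genotyping array each SNP is
probed for both alleles, and the working signal is the allele
difference

    s = I_ref − I_alt

(reference-parent probe intensity minus alternate-allele probe
intensity), so preferential hybridization to the reference allele is
positive. A locus linked to the trait drags the high pool toward one
parental allele and the low pool toward the other, so the per-SNP
difference of pool means, loess-smoothed along each chromosome
(span = 0.25), peaks at the locus. XAM is the same idea applied to
quantitative traits by selecting the extreme 10% or 30% of a
continuously varying population.

Array noise makes "how big a peak is real?" and "how precisely is the
peak placed?" empirical questions. This package answers them by
simulation: it simulates F2 or recombinant-inbred (RIL) populations on
a genetic map (Haldane meioses), phenotypes them under one- or
two-locus QTL models (additive, dominant, overdominant, linked in
repulsion, epistatic), selects extreme pools, assigns per-marker
allele-difference signals by genotype class from a signal bank, and
runs the BSA scan on each replicate. Aggregating replicates yields

* **detection thresholds** — nearest-rank 95th/99th percentiles of the
  pooled smoothed extremes (maxima and |minima|) on chromosomes
  unlinked to any QTL;
* **failure rates** — how often the linked chromosome fails to clear
  the 95% threshold;
* **positional confidence intervals** — the smallest locus-centred
  window containing the peak in 95% of replicates.

The same scan runs on real data: per-SNP intensity tables from two bulk
hybridizations, restricted to SNPs polymorphic between the cross
parents, difference-of-differences per strand, smoothing, and region
calls against simulation-derived thresholds.

## Worked example

```python
from snpbsa import (ScenarioConfig, run_batch, detection_thresholds,
                    failure_rate, confidence_interval)

cfg = ScenarioConfig.from_preset(
    1,                      # major additive QTL at 36 cM on chromosome 2
    population_type="F2", population_size=200,
    selection_fraction=0.10, n_replicates=200, seed=7)
summary = run_batch(cfg)
thr = detection_thresholds(summary)
print(f"95% detection threshold: {thr.threshold_95:.3f} signal units")
print(f"failure rate: {failure_rate(summary, thr):.1f}%")
print(f"95% confidence interval for the peak position: "
      f"{confidence_interval(summary):.1f} cM")
```

prints (seed 7):

```
95% detection threshold: 0.818 signal units
failure rate: 0.0%
95% confidence interval for the peak position: 6.0 cM
```

meaning: on unlinked chromosomes the smoothed scan exceeds 0.818 signal
units only 5% of the time; a major additive QTL was detected in every
one of 200 replicate experiments; and across replicates the peak fell
within a 6 cM window around the true locus 95% of the time. The
`examples/` directory holds one short script per capability (power
simulation, the overdominance failure mode, signal banks, bulk-array
mapping), each printing the numbers it computes.

The same functionality is exposed on the command line:

```bash
snpbsa simulate examples/scenario.yaml --reps 500 --out sim/
snpbsa fixture  --region 1:8000000-18000000 --out fx/
snpbsa map fx/bulkA.tsv fx/bulkB.tsv fx/markers.tsv \
        --thresholds sim/thresholds.json --out mapped/
snpbsa bank --out bank.tsv
```

Every run writes a `manifest.json` with parameters, seed and version.

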