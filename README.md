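# peakshift

Comparative analysis of two-condition ChIP-seq peak landscapes, built for
the question of how a chromatin regulator's loss redistributes a
DNA-binding complex (the motivating case: cohesin occupancy in mouse
embryonic stem cells after loss of regulators such as WIZ, WAPL or G9a).
Given peak calls and signal tracks for a wildtype (WT) and a perturbation
condition, the package:

- builds analysis-ready peaks: MACS2-style summits extended ±50 bp to
  100-bp windows, repeat-filtered, optionally input-subtracted;
- **classifies** every peak as *shared* (called in both conditions),
  *ectopic* (perturbation-only with positive log2 signal ratio),
  *removed* (perturbation-only, ratio ≤ 0 — a call whose signal did not
  actually increase), or *orphaned* (WT-only);
- compares ectopic landscapes across perturbations (overlap within 2 kb,
  distance-to-nearest distributions under the `bedtools closest -d`
  convention: overlap = 0, bookended = 1, else gap + 1);
- annotates each class against cis-regulatory elements (CTCF sites, loop
  anchors, enhancers, promoters) as overlap fractions;
- tests **differential occupancy** at retained (shared) sites: fixed-width
  consensus windows, spike-in normalized replicate counts, per-site Welch
  t-test on log2 counts with Benjamini–Hochberg correction;
- ranks known TF motifs by **differential enrichment** in ectopic vs
  shared peak sequences (100-bp summit-centered windows, both-strand PWM
  log-odds scanning, one-sided Fisher exact + BH);
- computes the accompanying closed forms: population doubling time,
  cell-cycle phase lengths, immunoblot fold changes, ChIP-qPCR percent
  input;
- and ships a fully seeded **synthetic-data generator** that emulates all
  of the above with known ground truth, so every stage is testable
  without external data.

## Core quantities

For a perturbation peak window \(w\) with signal tracks \(s_{pert}, s_{wt}\)
and pseudocount \(\varepsilon\):

```
log2 ratio(w) = log2( (mean_w(s_pert) + ε) / (mean_w(s_wt) + ε) )
```

A perturbation-only peak is ectopic iff its log2 ratio is > 0. At retained
sites with spike-in factors \(f_j = G / \text{spike}_j\) (G the geometric
mean of spike-in read counts), per-site differential occupancy uses
\(y_{ij} = \log_2(c_{ij} f_j + 1)\), Welch's t between conditions,
\(\log_2 FC = \bar y_{PERT} - \bar y_{WT}\), and BH-adjusted FDR < 0.05.
Motif enrichment tests, per PWM, the 2×2 table of hit/miss counts in
foreground vs background sequences with a one-sided Fisher exact test,
where a hit is a best both-strand window score ≥ 0.8 × the maximum
achievable log2-odds score.

## Worked example

Simulate a small landscape and classify it:

```
peakshift simulate --seed 5 --out data
peakshift classify --dataset data --out classes
```

prints:

```
{"n_peaks": 2900, "classes": {"shared": 2000, "ectopic": 500, "orphaned": 300, "decoy": 100}}
{"shared": 1979, "ectopic": 495, "orphaned": 298, "removed": 98}
```

i.e. of 2572 analysis-ready perturbation peaks, 1979 overlap a WT peak
(shared), 495 are new with a genuine signal gain (ectopic), and 98
perturbation-only calls had non-positive log2 ratio and are removed —
exactly the generator's planted structure (2000/500/300/100 minus the 30
deliberately repeat-masked peaks dropped by filtering). Then:

```
peakshift annotate --dataset data --classes classes --out annot
peakshift diffocc  --dataset data --classes classes --out docc
peakshift motifs   --dataset data --classes classes --out mot
peakshift report   --classes classes --annotate-dir annot \
                   --diffocc-dir docc --motifs-dir mot --out report.json
```

`annot/cre_fractions.tsv` recovers the planted class-dependent CRE
structure (shared peaks ~70% on CTCF sites, ectopic ~10%); the diffocc
summary reports the percentage of differentially occupied retained sites
and the fraction of those with increased signal (≈99% increased under the
default uniform-gain generator); the motif table ranks the planted SP1-type
GC-box first with FDR ≪ 0.05. The same operations are available as a
library (`peakshift.classify.classify_peaks`, `peakshift.diffocc`,
`peakshift.motifs`, ...), which is the surface the tests exercise.

Doubling time from a two-point growth measurement:

```
peakshift cellcycle --t1 52 --n1 1000 --t2 64 --n2 1830 \
    --fraction G1 0.35 --fraction S 0.45 --fraction G2/M 0.15
{"doubling_time_h": 13.763935793439172, "phase_lengths_h": {"G1": 4.81737752770371, "S": 6.193771107047628, "G2/M": 2.0645903690158756}}
```

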