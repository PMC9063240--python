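# Methods

## Scope and data model

The package compares the genomic landscape of a DNA-binding factor
between a wildtype (WT) and a perturbation condition. All coordinates are
0-based half-open (BED convention). Peaks live in a `PeakSet` —
coordinate-sorted, name-unique intervals with optional summit offsets on
an explicit genome (chromosome → length) — and signal lives in a
`SignalTrack`, a per-chromosome piecewise-constant function with implicit
value 0 over uncovered bases (bedGraph semantics). Strand is carried but
ignored by all overlap and distance logic, since protein-occupancy peaks
are unstranded.

## Analysis-ready peak definition

Raw peak calls are reduced to 100-bp summit windows: the summit extended
by `flank = 50` bp on either side, clipped at chromosome ends. Repeat
filtering and input-peak subtraction are applied to these windows, in that
order, so a window touching a repetitive element (at 0 bp slack) is
discarded. Every downstream signal quantity — log2 ratios for
classification, heatmap anchors, motif windows — is computed on these
windows, which makes the classification insensitive to the width of the
original calls.

## Classification

A perturbation peak overlapping ≥ 1 WT peak within `within_slack`
(default 0 bp, the most conservative direct-overlap reading) is *shared*;
otherwise it is *ectopic* if

    log2((mean_pert + ε) / (mean_wt + ε)) > 0

on its window (ε = 1 coverage unit, the default of common track-comparison
tools) and *removed* otherwise. WT peaks with no perturbation partner are
*orphaned*. The removed class implements the rule that a
perturbation-only call without an actual signal increase is excluded from
the ectopic set. The 2-kb slack (`cross_slack`) is reserved for
cross-perturbation comparisons of ectopic sets, where overlap is
deliberately liberal. Peaks on chromosomes absent from the other
condition are classified normally as non-overlapping.

Distances to nearest features follow the `bedtools closest -d`
convention — overlapping 0, bookended 1, otherwise gap + 1 — which
reproduces "median distance 0 due to peak overlap" for self-comparisons
and is cross-checked against bedtools itself in the tests. Ties are
broken by leftmost subject start, then name, for determinism.

## Differential occupancy at retained sites

Shared peaks become fixed-width consensus windows (default 400 bp,
midpoint-centered; overlapping windows merged). Replicate counts over the
windows are scaled by spike-in factors `f_j = G / spike_j` with `G` the
geometric mean of exogenous-genome read counts — symmetric and invariant
to a common rescaling; fixed-reference and reads-per-spike-million
variants are selectable. The per-site test is Welch's t on
`log2(normalized + 1)` between conditions with BH adjustment across
sites (FDR threshold 0.05). This is a deliberately self-contained,
simulation-verified substitute for external differential-binding
packages: it is calibrated (null fraction of raw p < 0.05 ≈ 0.033–0.036
at n = 3 vs 3 on negative-binomial counts) and directional, at the cost
of lower power than shrinkage-based NB GLMs at very small n. Sites where
both groups have zero variance are flagged degenerate with p = 1. The
published-style summary percentages (percent differential, percent
increased among differential) are emergent properties of the data and the
test, not targets.

## Motif enrichment

Known-motif scanning stands in for de novo discovery, which is out of
scope: each PWM (JASPAR PFM input, or the built-in consensus-derived
library of GC-box/TFAP2A/NRF1/TP53/ZFX/CTCF motifs) is scanned over both
strands of 100-bp summit-centered sequences with log2-odds scores
(pseudocount 0.01; ambiguous bases contribute 0). A sequence is a hit
when its best window reaches `threshold_frac = 0.8` of the motif's
maximum achievable score. Per motif, hits in ectopic (foreground) vs
shared (background) sequences enter a one-sided Fisher exact test; BH
across motifs; ranking by p, then odds ratio, then id — deterministic for
fixed inputs.

## Cell-cycle closed forms

Doubling time uses the exponential two-point form
`Td = Δt · ln2 / ln(n2/n1)` (two timepoints are the intended design, so a
regression over more points is not attempted); phase lengths are
`fraction × Td`, conserving `Σ fractions × Td` exactly. Immunoblot folds
are loading-normalized ratios to WT, with optional phospho/total second
normalization; ChIP-qPCR percent input is
`100 · 2^(ct_input − log2(1/input_fraction) − ct_ip)`, invariant to a
common Ct shift.

## Synthetic landscape generator

The generator provides ground truth for every stage on a desk-scale
genome (default 3 × 10 Mb, 2900 peaks ≥ 3 kb apart):

- **Amplitudes.** WT amplitudes are log-normal (μ = 2.0, σ = 0.5 on the
  natural-log scale; median ≈ 7.4 coverage units over a background of
  0.2). Shared peaks get a perturbation amplitude of WT × a log-normal
  multiplier (μ = 0.4, σ = 0.25; median ≈ 1.5), emulating a uniform
  occupancy increase at retained sites. Ectopic peaks have WT amplitude 0;
  orphaned peaks have perturbation amplitude 0; decoys are
  perturbation-called peaks whose true perturbation signal is background
  only, so their log2 ratio is negative and a correct classifier removes
  them.
- **Tracks.** Background is piecewise-constant noise in 1-kb bins
  (truncated normal, CV 0.25); each peak adds a triangular bump
  (half-width 150 bp, 10-bp steps). The shape is immaterial to
  classification; it only needs a summit-centered maximum.
- **Counts.** Replicate counts at any window are negative binomial with
  mean `depth_j × count_scale × (Σ amplitudes + background)` and shape
  `nb_size = 50` (dispersion α = 0.02, typical of well-behaved cell-line
  ChIP/RNA-seq replicates; at substantially higher dispersion an n = 3
  Welch test is underpowered, which would be a statement about the test,
  not the pipeline). Per-replicate depths are log-normal (σ = 0.15), and
  spike-in read counts are Poisson around `spike_depth × depth_j`, so
  spike-derived factors invert depth as they do in real spike-in designs.
- **Annotation.** CRE elements (200 bp) are placed under an exact quota
  of `round(p × n_class)` peaks per class/category — Bernoulli placement
  would make "recovering the configured probability" a 16-way joint coin
  flip — plus background elements ≥ 2 kb from every peak. Repeats cover a
  configurable quota of peaks (default 30) to exercise filtering, with
  the remainder placed away from peaks; repeat-masked peaks are flagged
  in the truth table since filtering removes them by design.
- **Sequence.** The genome is i.i.d. uniform ACGT with the configured PWM
  consensus (default SP1-type GC box) inserted at summit-centered
  positions of 40% of ectopic and 5% of shared peaks.

All randomness flows from the single mandatory seed through spawned
`numpy` SeedSequences; no global state is touched, and regenerating with
the same seed is byte-identical down to the written files.

What the generator does **not** emulate: mappability and GC biases,
chromatin-state spatial correlation, fragment-level read placement,
peak-width heterogeneity, and shared/ectopic amplitude confounding.
Passing tests therefore demonstrate the correctness and calibration of
the pipeline's operations under a clean generative model, not end-to-end
performance on real sequencing data.

## Numerical choices and degenerate inputs

Region means are exact base-weighted integrals of the piecewise track
(cumulative-sum lookup, no binning error). Subtractive tracks are
computed over the union of breakpoints and keep explicit zero segments
over either input's footprint. Heatmap matrices default to summit anchor,
flank 2000 bp, bin 50 bp (the common practice for such tools; the choice
is configuration, not a claim about any particular study), with rows
clipped at chromosome edges zero-padded and flagged. Correlation over
bins with zero variance is reported as NaN rather than raised. Fisher
odds ratios use the sample convention with 0 and ∞ reported explicitly.
Empty peak classes yield NaN annotation rows; an empty shared set is an
error for consensus-site construction because the analysis is undefined.

## Problem sizes

Defaults were chosen so the full study — simulation, classification,
annotation, differential testing at ~2000 sites, 5000-site calibration
runs, and 400 + 400 motif scans against 6 PWMs — completes in seconds on
one CPU, while keeping every per-class count large enough for stable
fractions (≥ 100 peaks per class).
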