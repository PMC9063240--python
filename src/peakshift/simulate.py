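"""Seeded synthetic two-condition peak landscapes with known truth.

The generator emulates the statistical structure of a wildtype (WT) vs
perturbation cohesin ChIP-seq comparison without any external data:

* peak loci spaced at least ``min_spacing`` apart on a small multi-
  chromosome genome, assigned to four truth classes — *shared* (called in
  both conditions, log-normal WT amplitude times a perturbation
  multiplier centered above 1, mimicking a genome-wide occupancy
  increase), *ectopic* (perturbation-only with real signal gain),
  *orphaned* (WT-only), and *decoy* (perturbation-only peak call whose
  signal did not increase; true perturbation amplitude is background, so
  its log2 ratio is negative and the classifier should discard it);
* piecewise-constant coverage tracks: noisy background plus a triangular
  bump of the true amplitude at each peak (10-bp steps, half-width
  ``bump_halfwidth``);
* per-replicate sequencing depths, spike-in read counts proportional to
  depth, and negative-binomial replicate counts at arbitrary site sets;
* cis-regulatory elements placed under an exact quota of peaks per
  (class, category) — round(p × n_class) peaks get the element — plus
  background elements away from all peaks, so configured placement
  probabilities are recovered exactly up to rounding;
* a random-uniform genome sequence with the configured PWM consensus
  inserted at the summits of a quota of ectopic (and a few shared) peaks;
* repeat elements placed away from peaks, plus a configurable number
  deliberately covering peak summits to exercise repeat filtering.

All randomness flows from the single mandatory config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .diffocc import CountMatrix
from .intervals import (
    PeakSet,
    write_bed,
    write_chrom_sizes,
    write_narrowpeak,
)
from .motifs import PWM, pwm_from_consensus, write_jaspar
from .peakproc import spike_in_factors, write_spikein_table
from .signal import SignalTrack, write_bedgraph

__all__ = [
    "SimConfig",
    "Landscape",
    "SimTracks",
    "simulate_landscape",
    "simulate_tracks",
    "simulate_site_counts",
    "simulate_count_matrix",
    "write_dataset",
]

CRE_CATEGORIES = ("ctcf", "loop_anchor", "enhancer", "promoter")
TRUTH_CLASSES = ("shared", "ectopic", "orphaned", "decoy")


def _default_cre_probs() -> dict[str, dict[str, float]]:
    # class-dependent CRE overlap structure: shared cohesin sits on CTCF
    # sites and loop anchors, ectopic cohesin mostly does not; enhancer and
    # promoter overlap is similar between the two classes.
    return {
        "shared": {"ctcf": 0.70, "loop_anchor": 0.50, "enhancer": 0.35, "promoter": 0.30},
        "ectopic": {"ctcf": 0.10, "loop_anchor": 0.05, "enhancer": 0.35, "promoter": 0.25},
        "orphaned": {"ctcf": 0.50, "loop_anchor": 0.30, "enhancer": 0.30, "promoter": 0.25},
        "decoy": {"ctcf": 0.05, "loop_anchor": 0.05, "enhancer": 0.05, "promoter": 0.05},
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic two-condition landscape.

    Amplitudes are in arbitrary coverage units; the defaults give
    well-separated peak signal (log-normal median ~7.4) over a background
    of 0.2, a perturbation multiplier at shared peaks with median ~1.5
    (uniform occupancy increase), and negative-binomial replicate counts
    with dispersion alpha = 1/nb_size = 0.02.
    """

    seed: int
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}
    )
    n_shared: int = 2000
    n_ectopic: int = 500
    n_orphaned: int = 300
    n_decoy: int = 100
    min_spacing: int = 3000
    edge_margin: int = 5000
    raw_peak_halfwidth: int = 150
    # amplitude model (log-normal parameters, natural-log scale)
    wt_amp_mu: float = 2.0
    wt_amp_sigma: float = 0.5
    shared_mult_mu: float = 0.4
    shared_mult_sigma: float = 0.25
    ectopic_amp_mu: float = 2.0
    ectopic_amp_sigma: float = 0.5
    # track shape / noise
    background: float = 0.2
    noise_bin: int = 1000
    noise_sd_frac: float = 0.25
    bump_halfwidth: int = 150
    bump_step: int = 10
    # replicates / counting
    replicates: int = 3
    nb_size: float = 50.0
    count_scale: float = 40.0
    depth_sigma: float = 0.15
    spike_depth: int = 1_000_000
    # annotation
    cre_probs: dict[str, dict[str, float]] = field(default_factory=_default_cre_probs)
    cre_width: int = 200
    n_background_cre: int = 200
    repeat_fraction: float = 0.03
    repeat_mean_length: int = 600
    n_repeat_overlap: int = 30
    # motifs
    motif_rates: dict[str, float] = field(
        default_factory=lambda: {"shared": 0.05, "ectopic": 0.40, "orphaned": 0.0, "decoy": 0.0}
    )
    motif_consensus: str = "GGGGCGGGGC"  # SP1-style GC box
    motif_id: str = "SP1"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("n_shared", "n_ectopic", "n_orphaned", "n_decoy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nb_size <= 0:
            raise ValueError("nb_size (NB shape) must be > 0")
        for cls, cats in self.cre_probs.items():
            for cat, p in cats.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"cre_probs[{cls}][{cat}] outside [0, 1]")
        for cls, r in self.motif_rates.items():
            if not 0 <= r <= 1:
                raise ValueError(f"motif_rates[{cls}] outside [0, 1]")

    @property
    def pwm(self) -> PWM:
        return pwm_from_consensus(self.motif_id, self.motif_consensus)

    @property
    def n_peaks(self) -> int:
        return self.n_shared + self.n_ectopic + self.n_orphaned + self.n_decoy


@dataclass
class Landscape:
    wt: PeakSet
    pert: PeakSet
    repeats: PeakSet
    cre: dict[str, PeakSet]
    truth: pd.DataFrame
    genome: dict[str, int]
    sequences: dict[str, str]


@dataclass
class SimTracks:
    wt: SignalTrack
    pert: SignalTrack
    replicates: dict[str, SignalTrack]
    conditions: dict[str, str]
    depth_factors: dict[str, float]
    spike_table: dict[str, int]


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def _place_loci(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Peak summits per chromosome, >= min_spacing apart, away from edges."""
    chroms = sorted(config.chrom_lengths)
    total_len = sum(config.chrom_lengths.values())
    n = config.n_peaks
    # proportional allocation with remainder to the largest chromosomes
    alloc = {c: int(n * config.chrom_lengths[c] / total_len) for c in chroms}
    for c in sorted(chroms, key=lambda c: -config.chrom_lengths[c]):
        if sum(alloc.values()) < n:
            alloc[c] += 1
    rows = []
    for chrom in chroms:
        k = alloc[chrom]
        if k == 0:
            continue
        length = config.chrom_lengths[chrom]
        usable = length - 2 * config.edge_margin - (k - 1) * config.min_spacing
        if usable <= 0:
            raise ValueError(
                f"cannot pack {k} peaks with spacing {config.min_spacing} on "
                f"{chrom} ({length} bp)"
            )
        u = np.sort(rng.uniform(0, usable, size=k))
        pos = (
            config.edge_margin
            + np.floor(u).astype(np.int64)
            + np.arange(k) * config.min_spacing
        )
        rows.extend((chrom, int(p)) for p in pos)
    return pd.DataFrame(rows, columns=["chrom", "summit"])


def _quota_choice(rng: np.random.Generator, index: np.ndarray, p: float) -> np.ndarray:
    """Exactly round(p * n) elements of ``index``, chosen uniformly."""
    k = int(round(p * len(index)))
    if k == 0:
        return np.array([], dtype=index.dtype)
    return rng.choice(index, size=k, replace=False)


def simulate_landscape(config: SimConfig) -> Landscape:
    """Generate peak sets, repeats, CREs, truth table and genome sequence."""
    root = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(6)]
    rng_pos, rng_class, rng_amp, rng_cre, rng_rep, rng_seq = rngs

    loci = _place_loci(config, rng_pos)
    n = len(loci)
    loci["name"] = [f"peak_{i:05d}" for i in range(n)]

    labels = np.repeat(
        TRUTH_CLASSES,
        [config.n_shared, config.n_ectopic, config.n_orphaned, config.n_decoy],
    )
    rng_class.shuffle(labels)
    loci["true_class"] = labels

    # amplitudes
    wt_amp = np.zeros(n)
    pert_amp = np.zeros(n)
    is_shared = labels == "shared"
    is_ectopic = labels == "ectopic"
    is_orphaned = labels == "orphaned"
    is_decoy = labels == "decoy"
    wt_amp[is_shared] = rng_amp.lognormal(config.wt_amp_mu, config.wt_amp_sigma, is_shared.sum())
    pert_amp[is_shared] = wt_amp[is_shared] * rng_amp.lognormal(
        config.shared_mult_mu, config.shared_mult_sigma, is_shared.sum()
    )
    pert_amp[is_ectopic] = rng_amp.lognormal(
        config.ectopic_amp_mu, config.ectopic_amp_sigma, is_ectopic.sum()
    )
    wt_amp[is_orphaned] = rng_amp.lognormal(
        config.wt_amp_mu, config.wt_amp_sigma, is_orphaned.sum()
    )
    wt_amp[is_decoy] = rng_amp.lognormal(
        config.wt_amp_mu, config.wt_amp_sigma, is_decoy.sum()
    )
    # decoy perturbation signal stays at background: negative log2 ratio
    loci["wt_amp"] = wt_amp
    loci["pert_amp"] = pert_amp

    # repeat masking: a quota of deliberately repeat-covered peaks
    masked_idx = (
        rng_rep.choice(n, size=min(config.n_repeat_overlap, n), replace=False)
        if config.n_repeat_overlap
        else np.array([], dtype=int)
    )
    repeat_masked = np.zeros(n, dtype=bool)
    repeat_masked[masked_idx] = True
    loci["repeat_masked"] = repeat_masked

    # CRE quota placement
    hw = config.cre_width // 2
    cre_sets: dict[str, PeakSet] = {}
    cre_flags = {cat: np.zeros(n, dtype=bool) for cat in CRE_CATEGORIES}
    summits = loci["summit"].to_numpy()
    chrom_arr = loci["chrom"].to_numpy()
    for cat in CRE_CATEGORIES:
        rows = []
        for cls in TRUTH_CLASSES:
            idx = np.flatnonzero(labels == cls)
            p = config.cre_probs.get(cls, {}).get(cat, 0.0)
            chosen = _quota_choice(rng_cre, idx, p)
            cre_flags[cat][chosen] = True
            for i in sorted(chosen):
                jitter = int(rng_cre.integers(-40, 41))
                c = summits[i] + jitter
                rows.append((chrom_arr[i], max(c - hw, 0), c + hw))
        # background elements far from every peak
        rows.extend(
            _background_elements(config, rng_cre, summits, chrom_arr, hw)
        )
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df["name"] = [f"{cat}_{i}" for i in range(len(df))]
        df["score"] = 0.0
        df["strand"] = "."
        df["summit_offset"] = None
        cre_sets[cat] = PeakSet(df, config.chrom_lengths)
    for cat in CRE_CATEGORIES:
        loci[f"cre_{cat}"] = cre_flags[cat]

    # repeats
    repeats = _simulate_repeats(config, rng_rep, loci, masked_idx)

    # genome sequence with planted motifs
    sequences, motif_flags = _simulate_sequence(config, rng_seq, loci)
    loci["motif_planted"] = motif_flags

    # condition peak sets (raw calls: summit +/- raw_peak_halfwidth)
    rhw = config.raw_peak_halfwidth
    def _peakset(mask: np.ndarray) -> PeakSet:
        sub = loci[mask]
        df = pd.DataFrame(
            {
                "chrom": sub["chrom"],
                "start": sub["summit"] - rhw,
                "end": sub["summit"] + rhw,
                "name": sub["name"],
                "score": 0.0,
                "strand": ".",
                "summit_offset": rhw,
            }
        )
        return PeakSet(df, config.chrom_lengths)

    wt = _peakset(is_shared | is_orphaned)
    pert = _peakset(is_shared | is_ectopic | is_decoy)

    return Landscape(
        wt=wt,
        pert=pert,
        repeats=repeats,
        cre=cre_sets,
        truth=loci,
        genome=dict(config.chrom_lengths),
        sequences=sequences,
    )


def _background_elements(config, rng, summits, chrom_arr, hw):
    """Elements >= 2 kb from every peak summit (rejection sampling)."""
    by_chrom = {
        c: np.sort(summits[chrom_arr == c]) for c in config.chrom_lengths
    }
    rows = []
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    pchrom = lengths / lengths.sum()
    tries = 0
    while len(rows) < config.n_background_cre and tries < config.n_background_cre * 50:
        tries += 1
        chrom = chroms[rng.choice(len(chroms), p=pchrom)]
        pos = int(rng.integers(hw, config.chrom_lengths[chrom] - hw))
        s = by_chrom[chrom]
        j = np.searchsorted(s, pos)
        near = min(
            abs(pos - s[j - 1]) if j > 0 else np.inf,
            abs(s[j] - pos) if j < len(s) else np.inf,
        )
        if near >= 2000:
            rows.append((chrom, pos - hw, pos + hw))
    return rows


def _simulate_repeats(config, rng, loci, masked_idx) -> PeakSet:
    """Repeat elements away from peaks plus quota covering masked summits."""
    genome_len = sum(config.chrom_lengths.values())
    n_rep = int(config.repeat_fraction * genome_len / config.repeat_mean_length)
    summits = loci["summit"].to_numpy()
    chrom_arr = loci["chrom"].to_numpy()
    by_chrom = {c: np.sort(summits[chrom_arr == c]) for c in config.chrom_lengths}
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    pchrom = lengths / lengths.sum()
    rows = []
    tries = 0
    while len(rows) < n_rep and tries < n_rep * 50:
        tries += 1
        chrom = chroms[rng.choice(len(chroms), p=pchrom)]
        size = max(50, int(rng.exponential(config.repeat_mean_length)))
        pos = int(rng.integers(0, config.chrom_lengths[chrom] - size))
        s = by_chrom[chrom]
        j = np.searchsorted(s, pos + size // 2)
        near = min(
            abs(pos + size // 2 - s[j - 1]) if j > 0 else np.inf,
            abs(s[j] - pos - size // 2) if j < len(s) else np.inf,
        )
        if near >= 1500 + size // 2:
            rows.append((chrom, pos, pos + size))
    # deliberate overlaps: cover the masked peaks' summits
    for i in masked_idx:
        c = int(summits[i])
        rows.append((chrom_arr[i], max(c - 100, 0), c + 100))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"repeat_{i}" for i in range(len(df))]
    df["score"] = 0.0
    df["strand"] = "."
    df["summit_offset"] = None
    return PeakSet(df, config.chrom_lengths)


_BASE_LOOKUP = np.frombuffer(b"ACGT", dtype=np.uint8)


def _simulate_sequence(config, rng, loci) -> tuple[dict[str, str], np.ndarray]:
    """i.i.d. uniform ACGT genome with motif consensus planted at summits."""
    consensus = config.motif_consensus.replace("N", "A").upper()
    mlen = len(consensus)
    n = len(loci)
    planted = np.zeros(n, dtype=bool)
    labels = loci["true_class"].to_numpy()
    for cls, rate in config.motif_rates.items():
        idx = np.flatnonzero(labels == cls)
        chosen = _quota_choice(rng, idx, rate)
        planted[chosen] = True
    sequences = {}
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        codes = rng.integers(0, 4, size=length, dtype=np.int64)
        arr = _BASE_LOOKUP[codes]
        sub = loci[(loci["chrom"] == chrom) & planted[loci.index]]
        for summit in sub["summit"]:
            a = int(summit) - mlen // 2
            arr[a : a + mlen] = np.frombuffer(consensus.encode(), dtype=np.uint8)
        sequences[chrom] = arr.tobytes().decode("ascii")
    return sequences, planted


# ---------------------------------------------------------------------------
# tracks and counts
# ---------------------------------------------------------------------------

def _condition_track(
    config: SimConfig,
    loci: pd.DataFrame,
    amps: np.ndarray,
    rng: np.random.Generator,
) -> SignalTrack:
    """Noisy background plus triangular bumps of the given amplitudes."""
    seg: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    hw, step = config.bump_halfwidth, config.bump_step
    offs = np.arange(-hw, hw, step)
    tri = np.maximum(0.0, 1.0 - np.abs(offs + step / 2) / hw)
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        edges = np.arange(0, length + config.noise_bin, config.noise_bin)
        edges[-1] = min(edges[-1], length)
        if edges[-1] == edges[-2]:
            edges = edges[:-1]
        nbins = len(edges) - 1
        bg = np.maximum(
            rng.normal(config.background, config.background * config.noise_sd_frac, nbins),
            0.0,
        )
        mask = (loci["chrom"] == chrom).to_numpy()
        summits = loci["summit"].to_numpy()[mask]
        amp = amps[mask]
        keep = amp > 0
        summits, amp = summits[keep], amp[keep]
        # breakpoints: noise-bin edges plus bump step edges
        bump_edges = (summits[:, None] + np.concatenate([offs, [hw]])[None, :]).ravel()
        allb = np.unique(np.concatenate([edges, bump_edges]))
        allb = allb[(allb >= 0) & (allb <= length)]
        lo, hi = allb[:-1], allb[1:]
        mid = (lo + hi) // 2
        vals = bg[np.minimum(mid // config.noise_bin, nbins - 1)]
        if len(summits):
            j = np.searchsorted(summits, mid)
            jn = np.clip(j, 0, len(summits) - 1)
            jp = np.clip(j - 1, 0, len(summits) - 1)
            for cand in (jn, jp):
                d = mid - summits[cand]
                within = np.abs(d) < hw
                if within.any():
                    k = ((d[within] + hw) // step).astype(int)
                    vals[within] = np.where(
                        tri[k] > 0,
                        bg[np.minimum(mid[within] // config.noise_bin, nbins - 1)]
                        + amp[cand[within]] * tri[k],
                        vals[within],
                    )
        seg[chrom] = (lo, hi, vals)
    return SignalTrack(seg, config.chrom_lengths)


def simulate_tracks(landscape: Landscape, config: SimConfig) -> SimTracks:
    """Merged per-condition tracks, replicate tracks, depths, spike counts."""
    root = np.random.SeedSequence([config.seed, 1])
    rng_wt, rng_pert, rng_depth = (
        np.random.default_rng(s) for s in root.spawn(3)
    )
    truth = landscape.truth
    wt = _condition_track(config, truth, truth["wt_amp"].to_numpy(), rng_wt)
    pert = _condition_track(config, truth, truth["pert_amp"].to_numpy(), rng_pert)
    replicates: dict[str, SignalTrack] = {}
    conditions: dict[str, str] = {}
    depth_factors: dict[str, float] = {}
    spike: dict[str, int] = {}
    for cond, base in (("WT", wt), ("PERT", pert)):
        for r in range(1, config.replicates + 1):
            sample = f"{cond}_rep{r}"
            depth = float(np.exp(rng_depth.normal(0.0, config.depth_sigma)))
            depth_factors[sample] = depth
            conditions[sample] = cond
            replicates[sample] = base.scale(depth)
            spike[sample] = int(rng_depth.poisson(config.spike_depth * depth))
    return SimTracks(
        wt=wt,
        pert=pert,
        replicates=replicates,
        conditions=conditions,
        depth_factors=depth_factors,
        spike_table=spike,
    )


def simulate_site_counts(
    sites: PeakSet, landscape: Landscape, tracks: SimTracks, config: SimConfig
) -> CountMatrix:
    """Negative-binomial replicate counts over an arbitrary site set.

    The expected count of sample j at site i is
    ``depth_j × count_scale × (sum of true condition amplitudes of peaks
    whose summit falls in the site, + background)``; counts are NB with
    shape ``nb_size``. Spike-in derived factors are attached.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    truth = landscape.truth
    sdf = sites.df
    amp_wt = np.full(len(sdf), config.background)
    amp_pert = np.full(len(sdf), config.background)
    by_chrom = {
        c: g.sort_values("summit") for c, g in truth.groupby("chrom", sort=False)
    }
    for chrom, g in sdf.groupby("chrom", sort=False):
        t = by_chrom.get(chrom)
        if t is None:
            continue
        s = t["summit"].to_numpy()
        lo = np.searchsorted(s, g["start"].to_numpy())
        hi = np.searchsorted(s, g["end"].to_numpy())
        wt_cum = np.concatenate([[0.0], np.cumsum(t["wt_amp"].to_numpy())])
        pe_cum = np.concatenate([[0.0], np.cumsum(t["pert_amp"].to_numpy())])
        rows = g.index.to_numpy()
        amp_wt[rows] += wt_cum[hi] - wt_cum[lo]
        amp_pert[rows] += pe_cum[hi] - pe_cum[lo]
    counts = {}
    for sample in tracks.replicates:
        cond = tracks.conditions[sample]
        base = amp_wt if cond == "WT" else amp_pert
        mean = tracks.depth_factors[sample] * config.count_scale * base
        p = config.nb_size / (config.nb_size + mean)
        counts[sample] = rng.negative_binomial(config.nb_size, p)
    cdf = pd.DataFrame(counts, index=sites.names)
    cdf.index.name = "site"
    factors = pd.Series(spike_in_factors(tracks.spike_table))
    return CountMatrix(sites, cdf, dict(tracks.conditions), factors)


def simulate_count_matrix(
    n_sites: int = 5000,
    n_rep: int = 3,
    baseline_mean: float = 300.0,
    nb_size: float = 50.0,
    planted_frac: float = 0.0,
    planted_lfc: float = 0.0,
    depth_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[CountMatrix, np.ndarray]:
    """Stand-alone NB count matrix for calibration and power studies.

    The first ``round(planted_frac * n_sites)`` sites carry a true
    perturbation log2 fold change of ``planted_lfc``; the rest are null.
    Returns the :class:`CountMatrix` (unit genome plumbing, spike factors
    inverse to depths) and the boolean planted-truth mask.
    """
    rng = np.random.default_rng(seed)
    k = int(round(planted_frac * n_sites))
    truth = np.zeros(n_sites, dtype=bool)
    truth[:k] = True
    base = np.full(n_sites, baseline_mean)
    mean_pert = base * np.where(truth, 2.0 ** planted_lfc, 1.0)
    genome = {"sim": (n_sites + 1) * 1000}
    sdf = pd.DataFrame(
        {
            "chrom": "sim",
            "start": np.arange(n_sites) * 1000,
            "end": np.arange(n_sites) * 1000 + 400,
            "name": [f"site_{i}" for i in range(n_sites)],
            "score": 0.0,
            "strand": ".",
            "summit_offset": None,
        }
    )
    sites = PeakSet(sdf, genome)
    counts = {}
    conditions = {}
    factors = {}
    for cond, mu in (("WT", base), ("PERT", mean_pert)):
        for r in range(1, n_rep + 1):
            sample = f"{cond}_rep{r}"
            depth = float(np.exp(rng.normal(0.0, depth_sigma))) if depth_sigma else 1.0
            m = mu * depth
            p = nb_size / (nb_size + m)
            counts[sample] = rng.negative_binomial(nb_size, p)
            conditions[sample] = cond
            factors[sample] = 1.0 / depth
    cdf = pd.DataFrame(counts, index=sites.names)
    cdf.index.name = "site"
    return CountMatrix(sites, cdf, conditions, pd.Series(factors)), truth


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def write_dataset(
    landscape: Landscape,
    tracks: SimTracks,
    directory,
    write_fasta: bool = True,
) -> dict[str, str]:
    """Write the landscape + tracks as the standard text formats.

    Produces chrom.sizes, genome FASTA, narrowPeak per condition, bedGraph
    per condition and replicate, repeat and CRE BEDs, the spike-in TSV and
    the truth table. Returns a manifest of logical name -> path.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def reg(key: str, fname: str) -> Path:
        manifest[key] = fname  # relative to the dataset directory
        return d / fname

    write_chrom_sizes(landscape.genome, reg("chrom_sizes", "genome.chrom.sizes"))
    if write_fasta:
        with open(reg("genome_fasta", "genome.fa"), "w") as fh:
            for chrom in sorted(landscape.sequences):
                fh.write(f">{chrom}\n")
                seq = landscape.sequences[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
    write_narrowpeak(landscape.wt, reg("wt_peaks", "wt_peaks.narrowPeak"))
    write_narrowpeak(landscape.pert, reg("pert_peaks", "pert_peaks.narrowPeak"))
    write_bed(landscape.repeats, reg("repeats", "repeats.bed"))
    for cat, ps in landscape.cre.items():
        write_bed(ps, reg(f"cre_{cat}", f"cre_{cat}.bed"))
    landscape.truth.to_csv(reg("truth", "truth.tsv"), sep="\t", index=False)
    write_bedgraph(tracks.wt, reg("wt_track", "wt.bedGraph"))
    write_bedgraph(tracks.pert, reg("pert_track", "pert.bedGraph"))
    for sample, tr in tracks.replicates.items():
        write_bedgraph(tr, reg(f"track_{sample}", f"{sample}.bedGraph"))
    write_spikein_table(tracks.spike_table, reg("spike", "spike_counts.tsv"))
    pd.Series(tracks.depth_factors, name="depth").rename_axis("sample").to_csv(
        reg("depths", "depth_factors.tsv"), sep="\t"
    )
    return manifest
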