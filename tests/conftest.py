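import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from peakshift.intervals import GenomicInterval, PeakSet
from peakshift.signal import SignalTrack
from peakshift.simulate import SimConfig, simulate_landscape, simulate_tracks

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

GENOME = {"chr1": 100_000, "chr2": 50_000}


def make_peaks(rows, genome=None):
    """rows: (chrom, start, end[, name[, summit_offset]]) tuples."""
    ivs = []
    for i, r in enumerate(rows):
        chrom, start, end = r[:3]
        name = r[3] if len(r) > 3 else f"p{i}"
        so = r[4] if len(r) > 4 else None
        ivs.append(GenomicInterval(chrom, start, end, name, summit_offset=so))
    return PeakSet.from_intervals(ivs, genome or GENOME)


def random_peaks(rng, n, genome=None, name_prefix="r", max_width=500):
    genome = genome or GENOME
    chroms = sorted(genome)
    rows = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        width = int(rng.integers(1, max_width))
        start = int(rng.integers(0, genome[chrom] - width))
        rows.append((chrom, start, start + width, f"{name_prefix}{i}"))
    return make_peaks(rows, genome)


def random_track(rng, genome=None, n_segments=30, max_value=10.0):
    """Random sparse piecewise-constant track (may leave gaps)."""
    genome = genome or GENOME
    seg = {}
    for chrom, length in genome.items():
        cuts = np.sort(rng.choice(length, size=2 * n_segments, replace=False))
        starts, ends, vals = [], [], []
        for a, b in zip(cuts[::2], cuts[1::2]):
            if rng.random() < 0.8:  # leave some gaps uncovered
                starts.append(int(a))
                ends.append(int(b))
                vals.append(float(rng.uniform(0, max_value)))
        seg[chrom] = (np.array(starts), np.array(ends), np.array(vals))
    return SignalTrack(seg, genome)


def dense_values(track, chrom):
    """Per-base value array for a track chromosome (oracle helper)."""
    out = np.zeros(track.genome[chrom])
    s, e, v = track.segments(chrom)
    for a, b, val in zip(s, e, v):
        out[a:b] = val
    return out


def tiny_sim_config(seed=11, **overrides):
    defaults = dict(
        chrom_lengths={"chrA": 500_000, "chrB": 400_000},
        n_shared=120,
        n_ectopic=40,
        n_orphaned=25,
        n_decoy=15,
        min_spacing=2500,
        edge_margin=2000,
        n_background_cre=30,
        repeat_fraction=0.02,
        n_repeat_overlap=6,
        spike_depth=200_000,
    )
    defaults.update(overrides)
    return SimConfig(seed=seed, **defaults)


@pytest.fixture(scope="session")
def tiny_landscape():
    cfg = tiny_sim_config()
    return cfg, simulate_landscape(cfg)


@pytest.fixture(scope="session")
def tiny_tracks(tiny_landscape):
    cfg, landscape = tiny_landscape
    return simulate_tracks(landscape, cfg)
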