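"""Analysis-ready peak definition and spike-in scale factors.

Raw peak calls become analysis-ready peaks by (1) extending each summit by
a fixed flank (default 50 bp, giving the 100-bp summit windows used for
every downstream signal computation), (2) removing windows that touch a
repetitive element, and (3) removing windows that overlap peaks called in
the input (non-immunoprecipitated) samples when no spike-in is available.

Spike-in normalization converts exogenous-genome read counts into
per-sample scale factors so ChIP signal is quantitatively comparable
between conditions.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import PeakSet, intersect

__all__ = [
    "extend_summits",
    "filter_repeats",
    "subtract_input_peaks",
    "spike_in_factors",
    "read_spikein_table",
    "write_spikein_table",
]


def extend_summits(peaks: PeakSet, flank: int = 50) -> PeakSet:
    """Replace each peak by ``[summit - flank, summit + flank)``.

    Windows are clipped to chromosome bounds, so width is exactly
    ``2 * flank`` except at chromosome edges. Every peak must carry a
    summit; ``flank`` must be >= 1 (a zero flank would yield empty
    intervals).
    """
    if flank < 1:
        raise ValueError(f"flank must be >= 1 bp, got {flank}")
    df = peaks.df
    missing = df["summit_offset"].isna()
    if missing.any():
        bad = df.loc[missing, "name"].iloc[0]
        raise ValueError(f"peak {bad!r} has no summit; cannot extend")
    summit = (df["start"] + df["summit_offset"].astype(np.int64)).to_numpy()
    lengths = df["chrom"].map(peaks.genome).to_numpy()
    start = np.maximum(summit - flank, 0)
    end = np.minimum(summit + flank, lengths)
    out = df.copy()
    out["start"] = start
    out["end"] = end
    out["summit_offset"] = summit - start
    return PeakSet(out, peaks.genome)


def _drop_overlapping(peaks: PeakSet, blacklist: PeakSet) -> PeakSet:
    hits = intersect(peaks, blacklist, slack=0)
    keep = np.array([len(h) == 0 for h in hits], dtype=bool)
    return peaks.subset(keep)


def filter_repeats(peaks: PeakSet, repeats: PeakSet) -> PeakSet:
    """Remove peaks with any bp overlap against repetitive elements."""
    if not peaks.same_genome(repeats):
        raise ValueError("peaks and repeats are on different genomes")
    return _drop_overlapping(peaks, repeats)


def subtract_input_peaks(chip: PeakSet, input_peaks: PeakSet) -> PeakSet:
    """Remove ChIP peaks overlapping any peak called in the input sample."""
    if not chip.same_genome(input_peaks):
        raise ValueError("chip and input peaks are on different genomes")
    return _drop_overlapping(chip, input_peaks)


def spike_in_factors(
    table: Mapping[str, int], method: str = "geometric"
) -> dict[str, float]:
    """Per-sample scale factors from exogenous spike-in read counts.

    ``method="geometric"`` (default): ``factor_i = G / spike_i`` with G the
    geometric mean of all spike counts — symmetric and invariant to a
    common rescaling of the counts. Alternatives: ``"reference:<sample>"``
    scales to a fixed sample, ``"per_million"`` is reads-per-spike-million
    (``1e6 / spike_i``). Multiplying each sample's signal by its factor
    equalizes spike-in totals (up to the per-million constant).
    """
    if len(table) == 0:
        raise ValueError("spike-in table is empty")
    counts = {k: float(v) for k, v in table.items()}
    for k, v in counts.items():
        if v <= 0:
            raise ValueError(f"spike-in count for {k!r} must be > 0, got {v}")
    if method == "geometric":
        logs = np.log([counts[k] for k in counts])
        ref = float(np.exp(logs.mean()))
    elif method.startswith("reference:"):
        sample = method.split(":", 1)[1]
        if sample not in counts:
            raise ValueError(f"reference sample {sample!r} not in table")
        ref = counts[sample]
    elif method == "per_million":
        ref = 1e6
    else:
        raise ValueError(f"unknown spike-in method {method!r}")
    return {k: ref / v for k, v in counts.items()}


def read_spikein_table(path) -> dict[str, int]:
    """Read a two-column TSV (sample, spike_reads); header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 0] == "sample":
        df = df.iloc[1:]
    return {str(r[0]): int(r[1]) for r in df.itertuples(index=False)}


def write_spikein_table(table: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tspike_reads\n")
        for k in table:
            fh.write(f"{k}\t{int(table[k])}\n")
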