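"""Closed-form cell-biology arithmetic: growth, phases, blots, qPCR.

Small deterministic computations that accompany the genomic analysis:
exponential-growth population doubling time from two timepoints, cell
cycle phase durations from flow-cytometry fractions, loading-controlled
immunoblot fold changes, and ChIP-qPCR percent input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "GrowthObservation",
    "doubling_time",
    "phase_lengths",
    "immunoblot_relative",
    "percent_input",
    "compare_phase_fractions",
]

PHASES = ("G1", "S", "G2/M")


@dataclass(frozen=True)
class GrowthObservation:
    """Two-timepoint growth measurement: times in hours, relative counts."""

    t1: float
    t2: float
    n1: float
    n2: float

    def __post_init__(self) -> None:
        if self.t2 <= self.t1:
            raise ValueError("t2 must be > t1")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("cell numbers must be > 0")


def doubling_time(obs: GrowthObservation) -> float:
    """Population doubling time under exponential growth (hours).

    Td = (t2 - t1) * ln 2 / ln(n2 / n1). Requires net growth (n2 > n1).
    """
    if obs.n2 <= obs.n1:
        raise ValueError("no growth between timepoints (n2 <= n1)")
    return (obs.t2 - obs.t1) * np.log(2) / np.log(obs.n2 / obs.n1)


def phase_lengths(fractions: Mapping[str, float], td: float) -> dict[str, float]:
    """Hours per cell cycle phase: fraction x doubling time.

    Fractions (from flow cytometry) must each lie in [0, 1] and sum to at
    most 1 (sub-G1 / unclassified events are excluded).
    """
    if td <= 0:
        raise ValueError("doubling time must be > 0")
    for phase, f in fractions.items():
        if not 0 <= f <= 1:
            raise ValueError(f"fraction for {phase!r} outside [0, 1]: {f}")
    if sum(fractions.values()) > 1 + 1e-9:
        raise ValueError("phase fractions sum to more than 1")
    return {phase: f * td for phase, f in fractions.items()}


def immunoblot_relative(
    target: float,
    loading: float,
    wt_target: float,
    wt_loading: float,
    phospho_over_total: tuple[float, float] | None = None,
) -> float:
    """Loading-normalized fold change of a protein signal vs wildtype.

    fold = (target/loading) / (wt_target/wt_loading). When
    ``phospho_over_total = (phospho_fold, total_fold)`` is given the
    result is additionally divided by the matched total-protein fold
    (phospho-specific change).
    """
    for v in (target, loading, wt_target, wt_loading):
        if v <= 0:
            raise ValueError("immunoblot signals must be > 0")
    fold = (target / loading) / (wt_target / wt_loading)
    if phospho_over_total is not None:
        phospho_fold, total_fold = phospho_over_total
        if total_fold <= 0:
            raise ValueError("total-protein fold must be > 0")
        fold = phospho_fold / total_fold
    return fold


def percent_input(ct_ip: float, ct_input: float, input_fraction: float) -> float:
    """ChIP-qPCR signal as percent of (dilution-adjusted) input chromatin.

    The input Ct is first adjusted for the fraction of chromatin used:
    adjusted = ct_input - log2(1/input_fraction); the result is
    100 * 2^(adjusted - ct_ip). Invariant to adding a constant to both Ct
    values (same qPCR efficiency assumption).
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    adjusted = ct_input - np.log2(1.0 / input_fraction)
    return float(100.0 * 2.0 ** (adjusted - ct_ip))


def compare_phase_fractions(wt: np.ndarray, mut: np.ndarray) -> dict:
    """Unpaired two-sample t-test on per-replicate phase fractions."""
    t, p = stats.ttest_ind(np.asarray(wt, float), np.asarray(mut, float))
    return {"t": float(t), "p": float(p)}
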