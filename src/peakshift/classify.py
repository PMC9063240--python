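"""Shared / ectopic / orphaned / removed peak classification.

The central comparative operation: a perturbation-condition peak that
overlaps any wildtype peak is *shared*; a perturbation-only peak is
*ectopic* when its log2 signal ratio (perturbation/WT, pseudocounted) is
positive and *removed* otherwise (spurious calls whose signal did not
actually increase); a wildtype peak with no perturbation partner is
*orphaned*. Downstream utilities compare ectopic sets across perturbations
(2-kb overlap), summarize distance-to-nearest distributions, and annotate
peak classes against cis-regulatory element categories (CTCF sites, loop
anchors, enhancers, promoters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import PeakSet, closest, intersect
from .signal import SignalTrack, log2_ratio

__all__ = [
    "ClassifyParams",
    "ClassifiedPeaks",
    "classify_peaks",
    "cross_condition_overlap",
    "distance_distribution",
    "overlap_fraction",
    "annotate_classes",
]

CLASSES = ("shared", "ectopic", "orphaned", "removed")


@dataclass(frozen=True)
class ClassifyParams:
    """Slacks and pseudocount for peak classification.

    within_slack: bp allowed between WT and perturbation peaks for the
    shared call (default 0 = direct overlap of the 100-bp windows).
    cross_slack: bp for ectopic-vs-ectopic comparison across perturbations
    (default 2000, the "within 2 kb" definition).
    pseudocount: coverage units added to both region means in the log2
    ratio.
    """

    within_slack: int = 0
    cross_slack: int = 2000
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.within_slack < 0 or self.cross_slack < 0:
            raise ValueError("slacks must be >= 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass
class ClassifiedPeaks:
    """Partition of a WT/perturbation peak-set pair.

    shared ∪ ectopic ∪ removed partitions the perturbation peaks;
    orphaned is the WT-only remainder. ``ratios`` maps every perturbation
    peak name (and orphaned WT peak name) to its log2 signal ratio;
    ``shared_partners`` records, per shared peak, the overlapping WT peak
    names.
    """

    shared: PeakSet
    ectopic: PeakSet
    orphaned: PeakSet
    removed: PeakSet
    ratios: pd.Series
    shared_partners: dict[str, list[str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {c: len(getattr(self, c)) for c in CLASSES}

    def class_of(self) -> pd.Series:
        """Peak name -> class label for all classified peaks."""
        out = {}
        for c in CLASSES:
            for n in getattr(self, c).names:
                out[n] = c
        return pd.Series(out, name="class")

    def table(self) -> pd.DataFrame:
        """Per-peak class + log2 ratio table (TSV-ready)."""
        cls = self.class_of()
        df = pd.DataFrame({"class": cls})
        df["log2_ratio"] = self.ratios.reindex(df.index)
        df.index.name = "name"
        return df.reset_index()


def classify_peaks(
    wt: PeakSet,
    pert: PeakSet,
    wt_track: SignalTrack,
    pert_track: SignalTrack,
    params: ClassifyParams = ClassifyParams(),
) -> ClassifiedPeaks:
    """Partition perturbation and WT peaks into the four classes.

    A perturbation peak overlapping >= 1 WT peak at ``within_slack`` is
    shared; otherwise it is ectopic when
    ``log2((mean_pert + eps)/(mean_wt + eps)) > 0`` on the peak window and
    removed when the ratio is <= 0. WT peaks with no perturbation overlap
    are orphaned. Signal ratios are computed on the peak's own interval
    (the 100-bp analysis window for summit-extended peaks).
    """
    if not wt.same_genome(pert):
        raise ValueError("WT and perturbation peak sets are on different genomes")
    if wt_track.genome != pert_track.genome:
        raise ValueError("tracks are on different genomes")

    hits = intersect(pert, wt, slack=params.within_slack)
    wt_names = wt.df["name"]
    is_shared = np.array([len(h) > 0 for h in hits], dtype=bool)
    partners = {
        name: wt_names.iloc[h].tolist()
        for name, h in zip(pert.df["name"], hits)
        if len(h)
    }

    ratios: dict[str, float] = {}
    for iv in pert:
        ratios[iv.name] = log2_ratio(
            pert_track, wt_track, iv, params.pseudocount
        )
    pos = np.array([ratios[n] > 0 for n in pert.df["name"]], dtype=bool)

    shared = pert.subset(is_shared)
    ectopic = pert.subset(~is_shared & pos)
    removed = pert.subset(~is_shared & ~pos)

    back = intersect(wt, pert, slack=params.within_slack)
    orphan_mask = np.array([len(h) == 0 for h in back], dtype=bool)
    orphaned = wt.subset(orphan_mask)
    for iv in orphaned:
        ratios[iv.name] = log2_ratio(
            pert_track, wt_track, iv, params.pseudocount
        )

    return ClassifiedPeaks(
        shared=shared,
        ectopic=ectopic,
        orphaned=orphaned,
        removed=removed,
        ratios=pd.Series(ratios, name="log2_ratio"),
        shared_partners=partners,
    )


def cross_condition_overlap(
    ectopic_a: PeakSet, ectopic_b: PeakSet, cross_slack: int = 2000
) -> dict:
    """Overlap of two ectopic peak sets at ``cross_slack`` bp.

    A peak is counted "both" when it lies within ``cross_slack`` of any
    peak of the other set; counts are per-set (A_only + both_a == |A|).
    Returns counts plus per-set boolean membership Series.
    """
    if not ectopic_a.same_genome(ectopic_b):
        raise ValueError("peak sets are on different genomes")
    both_a = np.array(
        [len(h) > 0 for h in intersect(ectopic_a, ectopic_b, cross_slack)],
        dtype=bool,
    )
    both_b = np.array(
        [len(h) > 0 for h in intersect(ectopic_b, ectopic_a, cross_slack)],
        dtype=bool,
    )
    return {
        "a_only": int((~both_a).sum()),
        "b_only": int((~both_b).sum()),
        "both_a": int(both_a.sum()),
        "both_b": int(both_b.sum()),
        "membership_a": pd.Series(both_a, index=ectopic_a.names),
        "membership_b": pd.Series(both_b, index=ectopic_b.names),
    }


def distance_distribution(query: PeakSet, subject: PeakSet) -> dict:
    """Distance from each query peak to its nearest subject peak.

    Uses the closest-feature convention (overlap 0, bookended 1, else
    gap + 1). Mean and median summarize queries that have a
    same-chromosome subject; others are excluded and counted.
    """
    res = closest(query, subject)
    d = res["distance"].to_numpy(dtype=float)
    ok = ~np.isnan(d)
    return {
        "distances": res,
        "n": int(ok.sum()),
        "n_no_subject_chrom": int((~ok).sum()),
        "mean": float(np.mean(d[ok])) if ok.any() else float("nan"),
        "median": float(np.median(d[ok])) if ok.any() else float("nan"),
    }


def distance_histogram(
    distances: np.ndarray, bin_width: float = 1000.0, max_distance: float | None = None
) -> pd.DataFrame:
    """Histogram (bin edges + counts) of a distance vector, TSV-ready."""
    d = np.asarray(distances, dtype=float)
    d = d[~np.isnan(d)]
    hi = float(max_distance) if max_distance is not None else (d.max() if len(d) else bin_width)
    edges = np.arange(0, hi + bin_width, bin_width)
    counts, edges = np.histogram(np.minimum(d, hi), bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )


def overlap_fraction(query: PeakSet, subject: PeakSet, slack: int = 0) -> float:
    """Fraction of query peaks overlapping >= 1 subject interval at slack."""
    if len(query) == 0:
        raise ValueError("overlap_fraction: query peak set is empty")
    hits = intersect(query, subject, slack=slack)
    return sum(1 for h in hits if len(h)) / len(query)


def annotate_classes(
    classes: ClassifiedPeaks,
    cre: Mapping[str, PeakSet],
    slack: int = 0,
    which: tuple[str, ...] = CLASSES,
) -> pd.DataFrame:
    """Class × CRE-category table of overlap fractions.

    Each cell is the fraction of peaks of that class overlapping at least
    one element of that category; cells are independent (categories may
    overlap each other). Empty classes yield NaN rows.
    """
    if not cre:
        raise ValueError("no CRE categories supplied")
    rows = {}
    for cls in which:
        ps: PeakSet = getattr(classes, cls)
        vals = {}
        for cat, elements in cre.items():
            if len(ps) == 0:
                vals[cat] = float("nan")
            else:
                vals[cat] = overlap_fraction(ps, elements, slack=slack)
        rows[cls] = vals
    out = pd.DataFrame(rows).T
    out.index.name = "class"
    return out
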