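"""Differential occupancy at retained (shared) cohesin sites.

Shared peaks become fixed-width consensus windows; per-replicate read
counts over those windows are scaled by spike-in factors, log2
transformed, and tested per site with a Welch two-sample t between
conditions, followed by Benjamini-Hochberg adjustment across sites. The
summary reports the percentage of differentially occupied sites and, among
those, the percentage with increased signal in the perturbation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classify import ClassifiedPeaks
from .intervals import PeakSet, merge
from .signal import SignalTrack

__all__ = [
    "DiffOccParams",
    "CountMatrix",
    "consensus_sites",
    "count_sites",
    "normalize_counts",
    "differential_test",
    "summarize_differential",
]


@dataclass(frozen=True)
class DiffOccParams:
    site_width: int = 400
    alpha: float = 0.05
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.site_width <= 0:
            raise ValueError("site_width must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass
class CountMatrix:
    """Consensus sites × replicate raw counts with condition labels.

    counts: DataFrame indexed by site name, one integer column per sample.
    conditions: sample id -> "WT" or "PERT".
    factors: per-sample scale factor (spike-in derived), > 0.
    """

    sites: PeakSet
    counts: pd.DataFrame
    conditions: dict[str, str]
    factors: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        for s in self.counts.columns:
            if s not in self.conditions:
                raise ValueError(f"sample {s!r} has no condition label")
        bad = set(self.conditions.values()) - {"WT", "PERT"}
        if bad:
            raise ValueError(f"unknown condition labels {bad}")
        self.factors = pd.Series(self.factors).reindex(self.counts.columns)
        if self.factors.isna().any() or (self.factors <= 0).any():
            raise ValueError("every sample needs a scale factor > 0")

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]


def consensus_sites(
    classes: ClassifiedPeaks, params: DiffOccParams = DiffOccParams()
) -> PeakSet:
    """Fixed-width windows centered on shared-peak midpoints, merged.

    One ``site_width`` window per shared peak, clipped to chromosome
    bounds; overlapping windows are merged (so the number of sites can be
    smaller than the number of shared peaks). Site names are
    ``site_<k>`` in coordinate order.
    """
    shared = classes.shared
    if len(shared) == 0:
        raise ValueError("no shared peaks: cannot build consensus sites")
    df = shared.df
    mid = ((df["start"] + df["end"]) // 2).to_numpy()
    half = params.site_width // 2
    lengths = df["chrom"].map(shared.genome).to_numpy()
    start = np.maximum(mid - half, 0)
    end = np.minimum(mid + (params.site_width - half), lengths)
    out = df.copy()
    out["start"] = start
    out["end"] = end
    out["summit_offset"] = None
    windows = PeakSet(out, shared.genome)
    merged = merge(windows, gap=0)
    mdf = merged.df
    mdf["name"] = [f"site_{i}" for i in range(len(mdf))]
    return PeakSet(mdf, shared.genome)


def count_sites(
    sites: PeakSet,
    replicate_data: Mapping[str, SignalTrack | Mapping[str, int] | pd.Series],
    conditions: Mapping[str, str],
    factors: Mapping[str, float] | pd.Series | None = None,
) -> CountMatrix:
    """Build the site × sample count matrix.

    Each sample may supply either a :class:`SignalTrack` (counts are the
    rounded signal totals over each site) or a precomputed per-site count
    mapping keyed by site name. Factors default to 1.
    """
    cols = {}
    for sample, data in replicate_data.items():
        if isinstance(data, SignalTrack):
            vals = np.zeros(len(sites), dtype=np.int64)
            df = sites.df
            for chrom, g in df.groupby("chrom", sort=False):
                tot = data.integral(
                    chrom, g["start"].to_numpy(), g["end"].to_numpy()
                )
                vals[g.index.to_numpy()] = np.rint(tot).astype(np.int64)
            cols[sample] = pd.Series(vals, index=sites.names)
        else:
            s = pd.Series(data).reindex(sites.names)
            if s.isna().any():
                missing = s.index[s.isna()][0]
                raise ValueError(f"sample {sample!r} lacks a count for {missing!r}")
            cols[sample] = s.astype(np.int64)
    counts = pd.DataFrame(cols)
    counts.index.name = "site"
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    return CountMatrix(sites, counts, dict(conditions), pd.Series(factors))


def normalize_counts(cm: CountMatrix) -> pd.DataFrame:
    """Scale-factor normalized counts: ``normalized[i, j] = counts * factor_j``."""
    if (cm.factors <= 0).any():
        raise ValueError("factors must be > 0")
    return cm.counts.astype(float) * cm.factors


def differential_test(
    cm: CountMatrix, params: DiffOccParams = DiffOccParams()
) -> pd.DataFrame:
    """Per-site Welch t-test on log2 normalized counts, BH-adjusted.

    ``y = log2(normalized + pseudocount)``; ``log2FC`` is
    ``mean(y_PERT) - mean(y_WT)``. Sites where both groups have zero
    within-group variance are flagged degenerate with p = 1. The
    ``differential`` flag is ``FDR < alpha``; direction is the sign of
    log2FC.
    """
    wt_samples = cm.samples("WT")
    pert_samples = cm.samples("PERT")
    if len(wt_samples) < 2 or len(pert_samples) < 2:
        raise ValueError("need >= 2 replicates per condition")
    norm = normalize_counts(cm)
    y_wt = np.log2(norm[wt_samples].to_numpy() + params.pseudocount)
    y_pert = np.log2(norm[pert_samples].to_numpy() + params.pseudocount)
    lfc = y_pert.mean(axis=1) - y_wt.mean(axis=1)
    var_wt = y_wt.var(axis=1, ddof=1)
    var_pert = y_pert.var(axis=1, ddof=1)
    degenerate = (var_wt == 0) & (var_pert == 0)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant rows trigger a scipy precision warning; they are flagged
        # degenerate and overridden below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(y_pert, y_wt, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    t = np.asarray(t, dtype=float)
    p[degenerate] = 1.0
    t[degenerate] = 0.0
    p[np.isnan(p)] = 1.0
    rej, fdr, _, _ = multipletests(p, alpha=params.alpha, method="fdr_bh")
    out = pd.DataFrame(
        {
            "log2FC": lfc,
            "t": t,
            "p": p,
            "FDR": fdr,
            "differential": fdr < params.alpha,
            "direction": np.sign(lfc).astype(int),
            "degenerate": degenerate,
        },
        index=norm.index,
    )
    out.index.name = "site"
    return out


def summarize_differential(
    results: pd.DataFrame, params: DiffOccParams = DiffOccParams()
) -> dict:
    """Percent differential sites and percent increased among them.

    Mirrors the headline summary of quantitative retained-site analysis:
    total percentage of differentially occupied sites and, among those,
    the percentage with increased signal in the perturbation. With zero
    differential sites the increased percentage is None (undefined).
    """
    if len(results) == 0:
        raise ValueError("empty results")
    diff = results["differential"]
    n_diff = int(diff.sum())
    pct_diff = 100.0 * n_diff / len(results)
    if n_diff == 0:
        pct_up = None
    else:
        pct_up = 100.0 * float((results.loc[diff, "log2FC"] > 0).sum()) / n_diff
    return {
        "n_sites": int(len(results)),
        "n_differential": n_diff,
        "percent_differential": pct_diff,
        "percent_increased_among_differential": pct_up,
    }
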