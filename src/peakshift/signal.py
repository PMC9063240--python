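"""Piecewise-constant coverage tracks and track algebra.

A :class:`SignalTrack` holds, per chromosome, sorted non-overlapping
``[start, end)`` segments with float values (bedGraph semantics); bases not
covered by any segment have implicit value 0. On top of it sit the
quantification primitives of the pipeline: base-weighted region means,
log2 ratios with a pseudocount, subtractive tracks over the union of
breakpoints, summit-anchored binned matrices for heatmaps, and genome-wide
binned Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, ParseError, PeakSet

__all__ = [
    "SignalTrack",
    "MatrixSpec",
    "read_bedgraph",
    "write_bedgraph",
    "region_mean",
    "log2_ratio",
    "subtract_tracks",
    "signal_matrix",
    "sort_rows_by_ratio",
    "track_correlation",
]


class SignalTrack:
    """Per-chromosome piecewise-constant signal (bedGraph semantics)."""

    def __init__(
        self,
        segments: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        genome: Mapping[str, int],
    ):
        self.genome = dict(genome)
        self._seg: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cum: dict[str, np.ndarray] = {}
        for chrom, (s, e, v) in segments.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=float)
            if chrom not in self.genome:
                raise ValueError(f"chromosome {chrom!r} absent from genome")
            if len(s):
                if (s >= e).any():
                    raise ValueError(f"{chrom}: empty or inverted segment")
                if (s[1:] < e[:-1]).any():
                    raise ValueError(f"{chrom}: overlapping or unsorted segments")
                if s[0] < 0 or e[-1] > self.genome[chrom]:
                    raise ValueError(f"{chrom}: segment outside chromosome")
            self._seg[chrom] = (s, e, v)
            cum = np.zeros(len(s) + 1)
            if len(s):
                np.cumsum(v * (e - s), out=cum[1:])
            self._cum[chrom] = cum

    @classmethod
    def from_dict(
        cls,
        d: Mapping[str, Sequence[tuple[int, int, float]]],
        genome: Mapping[str, int],
    ) -> "SignalTrack":
        seg = {}
        for chrom, rows in d.items():
            rows = sorted(rows)
            s = np.array([r[0] for r in rows], dtype=np.int64)
            e = np.array([r[1] for r in rows], dtype=np.int64)
            v = np.array([r[2] for r in rows], dtype=float)
            seg[chrom] = (s, e, v)
        return cls(seg, genome)

    def chroms(self) -> list[str]:
        return sorted(self._seg)

    def segments(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        s, e, v = self._seg.get(
            chrom, (np.array([], np.int64), np.array([], np.int64), np.array([]))
        )
        return s.copy(), e.copy(), v.copy()

    def n_segments(self) -> int:
        return sum(len(s) for s, _, _ in self._seg.values())

    # -- quantification ---------------------------------------------------
    def integral(self, chrom: str, a, b) -> np.ndarray:
        """Vectorized ∫ value d(base) over half-open windows [a, b).

        ``a`` and ``b`` may be scalars or arrays; windows are clipped to the
        covered part of the chromosome implicitly (uncovered bases add 0).
        """
        a = np.atleast_1d(np.asarray(a, dtype=np.int64))
        b = np.atleast_1d(np.asarray(b, dtype=np.int64))
        if chrom not in self._seg:
            return np.zeros(len(a))
        s, e, v = self._seg[chrom]
        if len(s) == 0:
            return np.zeros(len(a))
        cum = self._cum[chrom]
        ia = np.searchsorted(e, a, side="right")
        ib = np.searchsorted(s, b, side="left")
        total = cum[ib] - cum[ia]
        has = ib > ia
        # trim partial overlap of the first segment (before a)
        left = np.zeros(len(a))
        idx = ia[has]
        left[has] = np.maximum(a[has] - s[idx], 0) * v[idx]
        # trim partial overlap of the last segment (after b)
        right = np.zeros(len(a))
        idx = ib[has] - 1
        right[has] = np.maximum(e[idx] - b[has], 0) * v[idx]
        return total - left - right

    def value_at(self, chrom: str, pos) -> np.ndarray:
        """Track value at single base positions (0 where uncovered)."""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if chrom not in self._seg:
            return np.zeros(len(pos))
        s, e, v = self._seg[chrom]
        if len(s) == 0:
            return np.zeros(len(pos))
        i = np.searchsorted(e, pos, side="right")
        ok = (i < len(s)) & (s[np.minimum(i, len(s) - 1)] <= pos)
        out = np.zeros(len(pos))
        out[ok] = v[i[ok]]
        return out

    def scale(self, factor: float) -> "SignalTrack":
        """New track with every value multiplied by ``factor``."""
        return SignalTrack(
            {c: (s, e, v * factor) for c, (s, e, v) in self._seg.items()},
            self.genome,
        )


@dataclass(frozen=True)
class MatrixSpec:
    """Window geometry for summit-anchored heatmap matrices.

    flank bp on each side of the anchor, bin bp per column, anchored on the
    peak summit (falling back to the interval midpoint when no summit is
    recorded) or always on the midpoint.
    """

    flank: int = 2000
    bin: int = 50
    anchor: str = "summit"

    def __post_init__(self) -> None:
        if self.flank <= 0 or self.bin <= 0:
            raise ValueError("flank and bin must be > 0")
        if self.flank % self.bin:
            raise ValueError(
                f"flank ({self.flank}) must be divisible by bin ({self.bin})"
            )
        if self.anchor not in ("summit", "midpoint"):
            raise ValueError(f"anchor must be summit|midpoint, got {self.anchor!r}")

    @property
    def n_bins(self) -> int:
        return 2 * self.flank // self.bin


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bedgraph(path, genome: Mapping[str, int] | None = None) -> SignalTrack:
    """Read a 4-column bedGraph into a validated :class:`SignalTrack`.

    Records must be non-overlapping; adjacent equal-value runs are kept
    as-is so write/read round-trips preserve segment boundaries.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            p = line.split()
            if len(p) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                s, e, v = int(p[1]), int(p[2]), float(p[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if s >= e:
                raise ParseError(f"{path}:{lineno}: start >= end")
            per_chrom.setdefault(p[0], []).append((s, e, v))
    if genome is None:
        genome = {c: max(e for _, e, _ in rows) for c, rows in per_chrom.items()}
    try:
        return SignalTrack.from_dict(per_chrom, genome)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            s, e, v = track.segments(chrom)
            for a, b, val in zip(s, e, v):
                fh.write(f"{chrom}\t{a}\t{b}\t{val:.10g}\n")


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def _check_bounds(track: SignalTrack, iv: GenomicInterval) -> None:
    if iv.chrom not in track.genome:
        raise ValueError(f"chromosome {iv.chrom!r} absent from track genome")
    if iv.start < 0 or iv.end > track.genome[iv.chrom]:
        raise ValueError(
            f"interval {iv.chrom}:{iv.start}-{iv.end} outside chromosome"
        )


def region_mean(track: SignalTrack, iv: GenomicInterval) -> float:
    """Base-weighted mean of the track over ``[start, end)``.

    Uncovered bases contribute 0, so the mean is the coverage integral
    divided by the interval width.
    """
    _check_bounds(track, iv)
    return float(track.integral(iv.chrom, iv.start, iv.end)[0]) / iv.width


def log2_ratio(
    pert: SignalTrack,
    wt: SignalTrack,
    iv: GenomicInterval,
    pseudocount: float = 1.0,
) -> float:
    """log2((mean_pert + eps) / (mean_wt + eps)) over one interval."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    mp = region_mean(pert, iv)
    mw = region_mean(wt, iv)
    return float(np.log2((mp + pseudocount) / (mw + pseudocount)))


def subtract_tracks(pert: SignalTrack, wt: SignalTrack) -> SignalTrack:
    """Piecewise difference pert − wt over the union of breakpoints.

    The result covers every base covered by either input (zero-valued
    segments are kept, so x − x is an explicit zero track over x's
    footprint); adjacent equal-value pieces are coalesced.
    """
    if pert.genome != wt.genome:
        raise ValueError("tracks are on different genomes")
    out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in sorted(set(pert.chroms()) | set(wt.chroms())):
        ps, pe, _ = pert.segments(chrom)
        ws, we, _ = wt.segments(chrom)
        edges = np.unique(np.concatenate([ps, pe, ws, we]))
        if len(edges) < 2:
            continue
        lo, hi = edges[:-1], edges[1:]
        pv = pert.value_at(chrom, lo)
        wv = wt.value_at(chrom, lo)
        # keep only pieces covered by at least one input
        cov_p = _covered(ps, pe, lo)
        cov_w = _covered(ws, we, lo)
        keep = cov_p | cov_w
        lo, hi, val = lo[keep], hi[keep], (pv - wv)[keep]
        if len(lo) == 0:
            continue
        out[chrom] = _coalesce(lo, hi, val)
    return SignalTrack(out, pert.genome)


def _covered(s: np.ndarray, e: np.ndarray, pos: np.ndarray) -> np.ndarray:
    if len(s) == 0:
        return np.zeros(len(pos), dtype=bool)
    i = np.searchsorted(e, pos, side="right")
    return (i < len(s)) & (s[np.minimum(i, len(s) - 1)] <= pos)


def _coalesce(lo, hi, val):
    """Merge adjacent touching segments with identical values."""
    keep_s, keep_e, keep_v = [lo[0]], [hi[0]], [val[0]]
    for a, b, v in zip(lo[1:], hi[1:], val[1:]):
        if a == keep_e[-1] and v == keep_v[-1]:
            keep_e[-1] = b
        else:
            keep_s.append(a)
            keep_e.append(b)
            keep_v.append(v)
    return (
        np.array(keep_s, np.int64),
        np.array(keep_e, np.int64),
        np.array(keep_v, float),
    )


def signal_matrix(
    track: SignalTrack, peaks: PeakSet, spec: MatrixSpec = MatrixSpec()
) -> tuple[pd.DataFrame, np.ndarray]:
    """Binned signal around each peak's anchor.

    Row i, column j holds the base-weighted mean of the track over
    ``[anchor - flank + j*bin, anchor - flank + (j+1)*bin)``. Bins reaching
    beyond the chromosome are padded with implicit zeros; such rows are
    flagged. Returns ``(matrix, edge_flags)`` where the matrix is indexed
    by peak name.
    """
    df = peaks.df
    if spec.anchor == "summit" and df["summit_offset"].isna().any():
        missing = df.loc[df["summit_offset"].isna(), "name"].iloc[0]
        raise ValueError(f"peak {missing!r} has no summit for summit anchoring")
    if spec.anchor == "summit":
        anchors = (df["start"] + df["summit_offset"].astype(np.int64)).to_numpy()
    else:
        anchors = ((df["start"] + df["end"]) // 2).to_numpy()
    n = len(df)
    mat = np.zeros((n, spec.n_bins))
    flags = np.zeros(n, dtype=bool)
    offsets = np.arange(spec.n_bins + 1) * spec.bin - spec.flank
    for chrom, g in df.groupby("chrom", sort=False):
        rows = g.index.to_numpy()
        a = anchors[rows]
        length = peaks.genome[chrom]
        edges = a[:, None] + offsets[None, :]
        flags[rows] = (edges[:, 0] < 0) | (edges[:, -1] > length)
        clipped = np.clip(edges, 0, length)
        lo = clipped[:, :-1].ravel()
        hi = clipped[:, 1:].ravel()
        vals = track.integral(chrom, lo, hi) / spec.bin
        mat[rows] = vals.reshape(len(rows), spec.n_bins)
    out = pd.DataFrame(mat, index=df["name"].tolist())
    return out, flags


def sort_rows_by_ratio(
    matrix: pd.DataFrame, ratios: pd.Series | Mapping[str, float]
) -> pd.DataFrame:
    """Rows in non-increasing log2-ratio order; ties broken by peak name."""
    ratios = pd.Series(ratios)
    missing = [n for n in matrix.index if n not in ratios.index]
    if missing or len(ratios) != len(matrix):
        raise ValueError("ratios must provide exactly one value per matrix row")
    key = pd.DataFrame(
        {"r": -ratios.loc[matrix.index].to_numpy(), "n": matrix.index}
    )
    order = key.sort_values(["r", "n"], kind="mergesort").index
    return matrix.iloc[order]


def track_correlation(a: SignalTrack, b: SignalTrack, bin: int) -> float:
    """Genome-wide Pearson correlation of per-bin mean signal.

    Bins of ``bin`` bp tile every chromosome of the shared genome (the last
    bin of a chromosome may be shorter). Returns NaN when either binned
    vector has zero variance.
    """
    if a.genome != b.genome:
        raise ValueError("tracks are on different genomes")
    if bin <= 0:
        raise ValueError("bin must be > 0")
    va, vb = [], []
    for chrom in sorted(a.genome):
        length = a.genome[chrom]
        edges = np.arange(0, length + bin, bin)
        edges[-1] = min(edges[-1], length)
        if edges[-1] == edges[-2]:
            edges = edges[:-1]
        widths = np.diff(edges)
        va.append(a.integral(chrom, edges[:-1], edges[1:]) / widths)
        vb.append(b.integral(chrom, edges[:-1], edges[1:]) / widths)
    x = np.concatenate(va)
    y = np.concatenate(vb)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
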