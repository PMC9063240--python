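"""Genomic-interval data model and interval arithmetic.

Coordinates are 0-based half-open (BED convention) throughout. The two
central containers are :class:`GenomicInterval`, a single validated
interval with an optional summit, and :class:`PeakSet`, a coordinate-sorted
collection backed by a :class:`pandas.DataFrame` with a genome (chromosome
size) mapping.

Distance conventions follow the closest-feature tool lineage used in
ChIP-seq work: overlapping intervals are at distance 0, bookended intervals
at distance 1, and otherwise gap + 1. Strand is carried through readers and
writers but ignored by all overlap and distance logic: cohesin ChIP peaks
are unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_narrowpeak",
    "read_bed",
    "write_bed",
    "write_narrowpeak",
    "overlaps",
    "interval_distance",
    "intersect",
    "closest",
    "merge",
]

_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "summit_offset"]


class ParseError(ValueError):
    """Raised when a text-format genomic file cannot be parsed."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with optional summit.

    Parameters
    ----------
    chrom :
        Chromosome name.
    start, end :
        0-based half-open coordinates in bp; ``0 <= start < end``.
    name :
        Identifier; unique within a :class:`PeakSet`.
    score :
        Unitless score (narrowPeak column 5 or free-form).
    strand :
        One of ``+``, ``-``, ``.``; ignored by overlap/distance logic.
    summit_offset :
        Optional offset of the point of maximum enrichment from ``start``;
        must satisfy ``0 <= summit_offset < end - start``.
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: str = "."
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside interval "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def summit(self) -> int | None:
        """Absolute summit position, or None when no summit was recorded."""
        if self.summit_offset is None:
            return None
        return self.start + self.summit_offset

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class PeakSet:
    """Coordinate-sorted, name-unique collection of intervals on a genome.

    The canonical in-memory peak container of the pipeline. Internally a
    :class:`pandas.DataFrame` with columns
    ``chrom, start, end, name, score, strand, summit_offset`` sorted by
    ``(chrom, start, end)``, plus ``genome`` mapping chromosome name to
    length (bp). Every interval must lie within its chromosome.
    """

    def __init__(self, df: pd.DataFrame, genome: Mapping[str, int]):
        df = df.loc[:, _COLUMNS].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["score"] = df["score"].astype(float)
        df = df.sort_values(["chrom", "start", "end", "name"], kind="mergesort")
        df = df.reset_index(drop=True)
        self._df = df
        self.genome = dict(genome)
        self._validate()

    def _validate(self) -> None:
        df = self._df
        if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
            bad = df[(df["start"] < 0) | (df["start"] >= df["end"])].iloc[0]
            raise ValueError(
                f"invalid interval {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        if df["name"].duplicated().any():
            dup = df.loc[df["name"].duplicated(), "name"].iloc[0]
            raise ValueError(f"duplicate interval name {dup!r}")
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in self.genome:
                raise ValueError(f"chromosome {chrom!r} absent from genome")
            if int(sub["end"].max()) > self.genome[chrom]:
                raise ValueError(
                    f"interval beyond end of {chrom} "
                    f"({int(sub['end'].max())} > {self.genome[chrom]})"
                )
        so = df["summit_offset"]
        has = so.notna()
        if has.any():
            off = so[has].astype(float)
            w = (df.loc[has, "end"] - df.loc[has, "start"]).astype(float)
            if ((off < 0) | (off >= w)).any():
                raise ValueError("summit_offset outside its interval")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_intervals(
        cls, intervals: Iterable[GenomicInterval], genome: Mapping[str, int]
    ) -> "PeakSet":
        rows = [
            (
                iv.chrom,
                iv.start,
                iv.end,
                iv.name,
                iv.score,
                iv.strand,
                iv.summit_offset,
            )
            for iv in intervals
        ]
        df = pd.DataFrame(rows, columns=_COLUMNS)
        if df.empty:
            df = pd.DataFrame(columns=_COLUMNS)
        return cls(df, genome)

    # -- container protocol ----------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self._df.itertuples(index=False):
            so = row.summit_offset
            so = None if so is None or (isinstance(so, float) and np.isnan(so)) else int(so)
            yield GenomicInterval(
                row.chrom, int(row.start), int(row.end), row.name,
                float(row.score), row.strand, so,
            )

    def __getitem__(self, i: int) -> GenomicInterval:
        return list(self)[i] if isinstance(i, slice) else self._row(i)

    def _row(self, i: int) -> GenomicInterval:
        row = self._df.iloc[i]
        so = row["summit_offset"]
        so = None if pd.isna(so) else int(so)
        return GenomicInterval(
            row["chrom"], int(row["start"]), int(row["end"]), row["name"],
            float(row["score"]), row["strand"], so,
        )

    @property
    def df(self) -> pd.DataFrame:
        """Read-only view of the underlying frame (copy)."""
        return self._df.copy()

    @property
    def names(self) -> list[str]:
        return self._df["name"].tolist()

    def subset(self, mask) -> "PeakSet":
        """Sub-PeakSet selected by a boolean mask or a list of names."""
        if isinstance(mask, (list, set, frozenset, pd.Index)):
            keep = self._df["name"].isin(set(mask))
        else:
            keep = np.asarray(mask, dtype=bool)
        return PeakSet(self._df[keep], self.genome)

    def same_genome(self, other: "PeakSet") -> bool:
        return self.genome == other.genome

    def _chrom_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends, row-index) arrays, coordinate order."""
        out = {}
        for chrom, sub in self._df.groupby("chrom", sort=False):
            out[chrom] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub.index.to_numpy(),
            )
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> dict[str, int]:
    """Read a UCSC chrom.sizes file (two-column TSV: name, length)."""
    genome: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns")
            try:
                genome[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
    return genome


def write_chrom_sizes(genome: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f"{chrom}\t{genome[chrom]}\n")


def _parse_line(line: str, lineno: int, path, min_fields: int) -> list[str]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) == 1:
        parts = line.split()
    if len(parts) < min_fields:
        raise ParseError(
            f"{path}:{lineno}: expected >= {min_fields} fields, got {len(parts)}"
        )
    return parts


def read_narrowpeak(path, genome: Mapping[str, int] | None = None) -> PeakSet:
    """Read an ENCODE narrowPeak (BED6+4) file into a :class:`PeakSet`.

    Field 10 is the summit offset from ``start``; ``-1`` means no summit.
    When ``genome`` is None chromosome lengths are inferred as the maximum
    ``end`` seen per chromosome.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            p = _parse_line(line, lineno, path, 10)
            try:
                start, end = int(p[1]), int(p[2])
                score = float(p[4])
                summit = int(p[9])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            rows.append(
                (p[0], start, end, p[3], score, p[5],
                 None if summit == -1 else summit)
            )
    df = pd.DataFrame(rows, columns=_COLUMNS)
    if genome is None:
        genome = {} if df.empty else df.groupby("chrom")["end"].max().astype(int).to_dict()
    return PeakSet(df, genome)


def read_bed(path, genome: Mapping[str, int] | None = None) -> PeakSet:
    """Read a BED3/BED6 file. Missing name/score/strand get defaults."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            p = _parse_line(line, lineno, path, 3)
            try:
                start, end = int(p[1]), int(p[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            name = p[3] if len(p) > 3 else f"iv_{lineno}"
            score = float(p[4]) if len(p) > 4 and p[4] != "." else 0.0
            strand = p[5] if len(p) > 5 else "."
            rows.append((p[0], start, end, name, score, strand, None))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    if genome is None:
        genome = {} if df.empty else df.groupby("chrom")["end"].max().astype(int).to_dict()
    return PeakSet(df, genome)


def write_bed(peaks: PeakSet, path) -> None:
    """Write BED6. Round-trips coordinates, names, scores and strands."""
    with open(path, "w") as fh:
        for iv in peaks:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                f"{iv.score:g}\t{iv.strand}\n"
            )


def write_narrowpeak(peaks: PeakSet, path) -> None:
    """Write ENCODE narrowPeak; summit offset -1 when absent."""
    with open(path, "w") as fh:
        for iv in peaks:
            so = -1 if iv.summit_offset is None else iv.summit_offset
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t"
                f"{iv.strand}\t0\t-1\t-1\t{so}\n"
            )


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------

def overlaps(a: GenomicInterval, b: GenomicInterval, slack: int = 0) -> bool:
    """True iff a and b are on the same chromosome within ``slack`` bp.

    ``slack=0`` is plain half-open overlap; positive slack additionally
    counts intervals whose gap is strictly less than ``slack`` bp.
    """
    if slack < 0:
        raise ValueError(f"slack must be >= 0, got {slack}")
    return (
        a.chrom == b.chrom
        and a.start < b.end + slack
        and b.start < a.end + slack
    )


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Distance between two intervals under the closest-feature convention.

    0 when overlapping, 1 when bookended, otherwise gap + 1 (matching
    ``bedtools closest -d``). None when on different chromosomes.
    """
    if a.chrom != b.chrom:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    gap = max(a.start - b.end, b.start - a.end)
    return gap + 1


def intersect(
    query: PeakSet, subject: PeakSet, slack: int = 0
) -> list[np.ndarray]:
    """For every query interval, indices of subject intervals within slack.

    Returns one :class:`numpy.ndarray` of subject row indices (into
    ``subject.df``) per query row, in subject coordinate order. The total
    pair count equals the brute-force all-pairs count.
    """
    if slack < 0:
        raise ValueError(f"slack must be >= 0, got {slack}")
    if not query.same_genome(subject):
        raise ValueError("query and subject are on different genomes")
    sub = subject._chrom_arrays()
    out: list[np.ndarray] = []
    empty = np.array([], dtype=np.int64)
    for chrom, qs, qe in zip(
        query._df["chrom"], query._df["start"], query._df["end"]
    ):
        if chrom not in sub:
            out.append(empty)
            continue
        ss, se, idx = sub[chrom]
        # starts are sorted: candidates have s.start < q.end + slack
        hi = np.searchsorted(ss, qe + slack, side="left")
        mask = se[:hi] + slack > qs
        out.append(idx[:hi][mask])
    return out


def closest(query: PeakSet, subject: PeakSet) -> pd.DataFrame:
    """Nearest subject interval and distance for every query interval.

    Distance follows :func:`interval_distance`. Ties are broken by the
    leftmost subject start, then lexicographic subject name. Queries on
    chromosomes with no subject interval get ``subject_name = None`` and
    ``distance = NaN``.

    Returns a DataFrame with columns ``query_name, subject_name, distance``
    in query coordinate order.
    """
    if len(subject) == 0:
        raise ValueError("closest: subject peak set is empty")
    sdf = subject._df
    by_chrom: dict[str, pd.DataFrame] = {
        c: g for c, g in sdf.groupby("chrom", sort=False)
    }
    rows = []
    for row in query._df.itertuples(index=False):
        g = by_chrom.get(row.chrom)
        if g is None:
            rows.append((row.name, None, np.nan))
            continue
        ss = g["start"].to_numpy()
        se = g["end"].to_numpy()
        ov = (ss < row.end) & (se > row.start)
        gap = np.maximum(row.start - se, ss - row.end)
        dist = np.where(ov, 0, gap + 1)
        best = dist.min()
        cand = np.flatnonzero(dist == best)
        if len(cand) > 1:
            order = sorted(
                cand, key=lambda i: (ss[i], g["name"].iloc[i])
            )
            pick = order[0]
        else:
            pick = cand[0]
        rows.append((row.name, g["name"].iloc[pick], float(best)))
    return pd.DataFrame(rows, columns=["query_name", "subject_name", "distance"])


def merge(peaks: PeakSet, gap: int = 0) -> PeakSet:
    """Merge intervals closer than ``gap`` bp into single intervals.

    With ``gap=0`` only touching/overlapping intervals are merged; covered
    bases are preserved and the operation is idempotent. Merged intervals
    are renamed ``merged_<k>`` and lose summits/scores.
    """
    if gap < 0:
        raise ValueError(f"gap must be >= 0, got {gap}")
    rows = []
    k = 0
    for chrom, g in peaks._df.groupby("chrom", sort=False):
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e + gap:
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e, f"merged_{k}", 0.0, ".", None))
                k += 1
                cur_s, cur_e = int(s), int(e)
        rows.append((chrom, cur_s, cur_e, f"merged_{k}", 0.0, ".", None))
        k += 1
    df = pd.DataFrame(rows, columns=_COLUMNS)
    if df.empty:
        df = pd.DataFrame(columns=_COLUMNS)
    return PeakSet(df, peaks.genome)
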