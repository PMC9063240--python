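"""Known-motif differential enrichment: ectopic vs shared peak sequences.

Sequences are fixed-width windows centered on peak summits (default
100 bp). Each position weight matrix is scanned over both strands with a
log2-odds score; a sequence is a "hit" when its best window reaches a
configurable fraction of the motif's maximum achievable score. Per motif,
hit counts in foreground (ectopic) vs background (shared) sequences enter
a one-sided Fisher exact test for enrichment, BH-adjusted across motifs,
yielding a ranked table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import PeakSet

__all__ = [
    "PWM",
    "ScanResult",
    "pwm_from_counts",
    "pwm_from_consensus",
    "read_jaspar",
    "write_jaspar",
    "default_motif_library",
    "extract_sequences",
    "pwm_scan",
    "fisher_exact",
    "differential_enrichment",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class PWM:
    """Position probability matrix with background frequencies.

    matrix: (length, 4) probabilities over A, C, G, T; each row sums to 1
    within 1e-6 and every entry is strictly positive (apply a pseudocount
    before construction). background: 4 probabilities, default uniform.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        bg = (
            np.full(4, 0.25)
            if self.background is None
            else np.asarray(self.background, dtype=float)
        )
        object.__setattr__(self, "background", bg)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 4:
            raise ValueError("PWM matrix must be (length >= 4, 4)")
        if (m <= 0).any():
            raise ValueError("PWM probabilities must be > 0 (use a pseudocount)")
        if np.abs(m.sum(axis=1) - 1).max() > 1e-6:
            raise ValueError("PWM rows must each sum to 1")
        if bg.shape != (4,) or (bg <= 0).any():
            raise ValueError("background must be 4 positive probabilities")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def score_matrix(self) -> np.ndarray:
        """(length, 5) log2-odds scores; the 5th column (N) scores 0."""
        lo = np.log2(self.matrix / self.background)
        return np.column_stack([lo, np.zeros(len(self))])

    @property
    def max_score(self) -> float:
        """Best achievable log2-odds score (bits)."""
        return float(np.log2(self.matrix / self.background).max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.motif_id, self.matrix[::-1, ::-1].copy(), self.background[::-1].copy()
        )


def pwm_from_counts(
    motif_id: str,
    counts: np.ndarray,
    pseudocount: float = 0.01,
    background: np.ndarray | None = None,
) -> PWM:
    """Probability PWM from a (length, 4) count/frequency matrix."""
    c = np.asarray(counts, dtype=float) + pseudocount
    return PWM(motif_id, c / c.sum(axis=1, keepdims=True), background)


def pwm_from_consensus(
    motif_id: str, consensus: str, strength: float = 0.91, pseudocount: float = 0.01
) -> PWM:
    """Near-deterministic PWM for a consensus string (N = uniform)."""
    rows = []
    off = (1 - strength) / 3
    for base in consensus.upper():
        if base == "N":
            rows.append([0.25] * 4)
        else:
            row = [off] * 4
            row[_BASE_INDEX[base]] = strength
            rows.append(row)
    return pwm_from_counts(motif_id, np.array(rows), pseudocount)


def default_motif_library() -> list[PWM]:
    """Small built-in library of mESC-relevant TF motifs (consensus-derived).

    Covers the GC-box family (SP1/SP2), TFAP2A, NRF1, TP53 half-site, ZFX
    and the CTCF core — the motif classes reported at ectopic vs shared
    cohesin sites.
    """
    consensi = {
        "SP1": "GGGGCGGGGC",
        "TFAP2A": "GCCNNNGGC",
        "NRF1": "GCGCATGCGC",
        "TP53": "GGACATGTCC",
        "ZFX": "AGGCCTAG",
        "CTCF": "CCACCAGGGGGCGC",
    }
    return [pwm_from_consensus(k, v) for k, v in consensi.items()]


# ---------------------------------------------------------------------------
# JASPAR I/O (via Biopython)
# ---------------------------------------------------------------------------

def read_jaspar(path, pseudocount: float = 0.01) -> list[PWM]:
    """Read motifs from a JASPAR-format PFM file."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array(
                [[m.counts[b][i] for b in _BASES] for i in range(m.length)]
            )
            name = m.matrix_id or m.name
            out.append(pwm_from_counts(name, counts, pseudocount))
    return out


def write_jaspar(pwms: Iterable[PWM], path, scale: int = 100) -> None:
    """Write motifs as JASPAR PFMs (probabilities scaled to counts)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\t{pwm.motif_id}\n")
            counts = np.rint(pwm.matrix * scale).astype(int)
            for i, base in enumerate(_BASES):
                row = "  ".join(str(c) for c in counts[:, i])
                fh.write(f"{base}  [ {row} ]\n")


# ---------------------------------------------------------------------------
# sequence extraction
# ---------------------------------------------------------------------------

def extract_sequences(
    peaks: PeakSet, genome_fasta, width: int = 100
) -> tuple[dict[str, str], set[str]]:
    """Summit-centered uppercase sequences of ``width`` bp per peak.

    ``genome_fasta`` may be a FASTA path (read through pyfaidx) or an
    in-memory mapping chromosome -> sequence string. Sequences truncated
    by a chromosome edge are returned shorter and their names collected in
    the flagged set.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    if isinstance(genome_fasta, (str, bytes)) or hasattr(genome_fasta, "__fspath__"):
        from pyfaidx import Fasta

        fa = Fasta(str(genome_fasta))
        get = lambda c, a, b: str(fa[c][a:b])
        has = lambda c: c in fa
    else:
        get = lambda c, a, b: genome_fasta[c][a:b]
        has = lambda c: c in genome_fasta
    seqs: dict[str, str] = {}
    flagged: set[str] = set()
    half = width // 2
    for iv in peaks:
        if iv.summit is None:
            raise ValueError(f"peak {iv.name!r} has no summit")
        if not has(iv.chrom):
            raise ValueError(f"chromosome {iv.chrom!r} missing from FASTA")
        length = peaks.genome[iv.chrom]
        a = iv.summit - half
        b = iv.summit + (width - half)
        if a < 0 or b > length:
            flagged.add(iv.name)
        a, b = max(a, 0), min(b, length)
        seqs[iv.name] = get(iv.chrom, a, b).upper()
    return seqs, flagged


# ---------------------------------------------------------------------------
# scanning and testing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanResult:
    hit: bool
    best_score: float
    too_short: bool = False


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(arr), 4, dtype=np.int8)  # default: N bucket
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _best_strand_score(codes: np.ndarray, score_matrix: np.ndarray) -> float:
    L = score_matrix.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return float("-inf")
    tot = np.zeros(n)
    for j in range(L):
        tot += score_matrix[j, codes[j : j + n]]
    return float(tot.max())


def pwm_scan(seq: str, pwm: PWM, threshold_frac: float = 0.8) -> ScanResult:
    """Best both-strand log2-odds score and hit call for one sequence.

    A window scores ``sum log2(p_pos(base)/bg(base))`` with ambiguous
    bases (N) contributing 0; the sequence is a hit when the best window
    on either strand reaches ``threshold_frac × max achievable score``.
    Sequences shorter than the motif are flagged and never hit.
    """
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must be in (0, 1]")
    if len(seq) < len(pwm):
        return ScanResult(False, float("-inf"), too_short=True)
    codes = _encode(seq)
    fwd = _best_strand_score(codes, pwm.score_matrix)
    rc_codes = _encode(seq.translate(_COMPLEMENT)[::-1])
    rev = _best_strand_score(rc_codes, pwm.score_matrix)
    best = max(fwd, rev)
    return ScanResult(best >= threshold_frac * pwm.max_score, best)


def fisher_exact(a: int, b: int, c: int, d: int) -> dict:
    """Fisher exact test on the 2×2 table [[a, b], [c, d]].

    Returns the sample odds ratio (a*d)/(b*c) — 0 when a*d == 0, inf when
    only b*c == 0 — plus one-sided (enrichment of a relative to c) and
    two-sided hypergeometric p-values.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    table = [[a, b], [c, d]]
    _, p_two = stats.fisher_exact(table, alternative="two-sided")
    _, p_greater = stats.fisher_exact(table, alternative="greater")
    if a * d == 0:
        oddsratio = 0.0 if (b * c or not a * d) else float("inf")
    elif b * c == 0:
        oddsratio = float("inf")
    else:
        oddsratio = (a * d) / (b * c)
    return {
        "odds_ratio": oddsratio,
        "p_greater": float(p_greater),
        "p_two_sided": float(p_two),
    }


def differential_enrichment(
    fg_seqs: Mapping[str, str],
    bg_seqs: Mapping[str, str],
    pwms: Iterable[PWM],
    threshold_frac: float = 0.8,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Ranked per-motif enrichment of foreground vs background sequences.

    For each motif: hit counts via :func:`pwm_scan` in both sets, a
    one-sided Fisher exact test for enrichment in the foreground, then BH
    adjustment across motifs. Rows are sorted by p ascending with ties
    broken by odds ratio descending, then motif id — a deterministic
    ranking for fixed inputs.
    """
    pwms = list(pwms)
    if not fg_seqs or not bg_seqs:
        raise ValueError("foreground and background sequence sets must be nonempty")
    if not pwms:
        raise ValueError("need at least one PWM")
    rows = []
    for pwm in pwms:
        hits_fg = sum(
            pwm_scan(s, pwm, threshold_frac).hit for s in fg_seqs.values()
        )
        hits_bg = sum(
            pwm_scan(s, pwm, threshold_frac).hit for s in bg_seqs.values()
        )
        n_fg, n_bg = len(fg_seqs), len(bg_seqs)
        ft = fisher_exact(hits_fg, n_fg - hits_fg, hits_bg, n_bg - hits_bg)
        rows.append(
            {
                "motif": pwm.motif_id,
                "hits_fg": hits_fg,
                "n_fg": n_fg,
                "hits_bg": hits_bg,
                "n_bg": n_bg,
                "odds_ratio": ft["odds_ratio"],
                "p": ft["p_greater"],
            }
        )
    out = pd.DataFrame(rows)
    _, fdr, _, _ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
    out["FDR"] = fdr
    out["significant"] = out["FDR"] < alpha
    out = out.sort_values(
        ["p", "odds_ratio", "motif"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out
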