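"""Interval model, BED/narrowPeak I/O and interval arithmetic."""

import subprocess

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from peakshift.intervals import (
    GenomicInterval,
    PeakSet,
    closest,
    interval_distance,
    intersect,
    merge,
    overlaps,
    read_chrom_sizes,
    read_narrowpeak,
    read_bed,
    write_bed,
    write_chrom_sizes,
    write_narrowpeak,
)

from conftest import GENOME, make_peaks, random_peaks


class TestGenomicInterval:
    def test_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 100, strand="x")
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 100, summit_offset=100)
        iv = GenomicInterval("chr1", 100, 600, summit_offset=250)
        assert iv.summit == 350
        assert iv.width == 500

    def test_peakset_invariants(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_peaks([("chr1", 0, 10, "a"), ("chr1", 20, 30, "a")])
        with pytest.raises(ValueError, match="beyond end"):
            make_peaks([("chr1", 0, GENOME["chr1"] + 1)])
        with pytest.raises(ValueError, match="absent from genome"):
            make_peaks([("chrX", 0, 10)])

    def test_peakset_sorted(self):
        ps = make_peaks([("chr2", 5, 10), ("chr1", 50, 60), ("chr1", 5, 10)])
        coords = [(iv.chrom, iv.start) for iv in ps]
        assert coords == sorted(coords)


class TestNarrowPeakIO:
    def test_summit_parsing(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text(
            "chr1\t100\t600\tp1\t250\t.\t5.2\t10.1\t8.3\t250\n"
            "chr1\t700\t900\tp2\t1\t.\t0\t-1\t-1\t-1\n"
        )
        ps = read_narrowpeak(p, GENOME)
        ivs = list(ps)
        assert (ivs[0].start, ivs[0].end) == (100, 600)
        assert ivs[0].summit == 350
        assert ivs[1].summit_offset is None

    def test_unsorted_input_sorted(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text(
            "chr2\t10\t20\tb\t0\t.\t0\t-1\t-1\t-1\n"
            "chr1\t10\t20\ta\t0\t.\t0\t-1\t-1\t-1\n"
        )
        ps = read_narrowpeak(p, GENOME)
        assert [iv.chrom for iv in ps] == ["chr1", "chr2"]

    def test_malformed_line_reports_lineno(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t100\t600\tp1\t250\t.\t5.2\t10.1\t8.3\t250\nchr1\t5\n")
        with pytest.raises(ValueError, match=":2"):
            read_narrowpeak(p, GENOME)

    def test_start_ge_end_rejected(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t600\t100\tp1\t0\t.\t0\t-1\t-1\t-1\n")
        with pytest.raises(ValueError):
            read_narrowpeak(p, GENOME)

    def test_narrowpeak_round_trip(self, tmp_path):
        ps = make_peaks(
            [("chr1", 100, 600, "p1", 250), ("chr2", 5, 105, "p2", None)]
        )
        f = tmp_path / "rt.narrowPeak"
        write_narrowpeak(ps, f)
        back = read_narrowpeak(f, GENOME)
        assert back.df[["chrom", "start", "end", "name"]].equals(
            ps.df[["chrom", "start", "end", "name"]]
        )
        assert list(back)[0].summit == list(ps)[0].summit


class TestBedIO:
    def test_round_trip(self, tmp_path):
        ps = make_peaks([("chr1", 0, 10, "a"), ("chr1", 20, 30, "b"),
                         ("chr2", 5, 9, "c")])
        f = tmp_path / "x.bed"
        write_bed(ps, f)
        back = read_bed(f, GENOME)
        assert back.df[["chrom", "start", "end", "name", "strand"]].equals(
            ps.df[["chrom", "start", "end", "name", "strand"]]
        )

    def test_empty_set(self, tmp_path):
        ps = PeakSet.from_intervals([], GENOME)
        f = tmp_path / "empty.bed"
        write_bed(ps, f)
        assert f.read_text() == ""
        assert len(read_bed(f, GENOME)) == 0

    def test_unstranded_dot_column(self, tmp_path):
        f = tmp_path / "x.bed"
        write_bed(make_peaks([("chr1", 0, 10, "a")]), f)
        assert f.read_text().split("\t")[5].strip() == "."

    def test_chrom_sizes_round_trip(self, tmp_path):
        f = tmp_path / "g.chrom.sizes"
        write_chrom_sizes(GENOME, f)
        assert read_chrom_sizes(f) == GENOME


class TestOverlaps:
    def test_examples(self):
        a = GenomicInterval("chr1", 100, 200)
        assert overlaps(a, GenomicInterval("chr1", 150, 250))
        # gap of 1900 bp: counted within 2 kb but not within 1.8 kb
        far = GenomicInterval("chr1", 2100, 2200)
        assert overlaps(a, far, slack=2000)
        assert not overlaps(a, far, slack=1800)
        assert not overlaps(a, GenomicInterval("chr2", 100, 200), slack=10**9)
        with pytest.raises(ValueError):
            overlaps(a, far, slack=-1)

    @given(
        s1=st.integers(0, 5000), w1=st.integers(1, 500),
        s2=st.integers(0, 5000), w2=st.integers(1, 500),
        slack=st.integers(0, 3000),
    )
    def test_symmetric(self, s1, w1, s2, w2, slack):
        a = GenomicInterval("chr1", s1, s1 + w1)
        b = GenomicInterval("chr1", s2, s2 + w2)
        assert overlaps(a, b, slack) == overlaps(b, a, slack)


def brute_force_pairs(query, subject, slack):
    pairs = set()
    for qi, q in enumerate(query):
        for si, s in enumerate(subject):
            if overlaps(q, s, slack):
                pairs.add((qi, si))
    return pairs


class TestIntersect:
    def test_self_intersection(self):
        ps = make_peaks([("chr1", i * 100, i * 100 + 50) for i in range(5)])
        hits = intersect(ps, ps, slack=0)
        for i, h in enumerate(hits):
            assert i in h

    def test_disjoint_chromosomes(self):
        a = make_peaks([("chr1", 0, 10)])
        b = make_peaks([("chr2", 0, 10)])
        assert all(len(h) == 0 for h in intersect(a, b, slack=10**6))

    def test_genome_mismatch(self):
        a = make_peaks([("chr1", 0, 10)])
        b = make_peaks([("chr1", 0, 10)], genome={"chr1": 1000})
        with pytest.raises(ValueError, match="genome"):
            intersect(a, b)

    @pytest.mark.parametrize("slack", [0, 100, 2000])
    def test_matches_brute_force(self, slack):
        rng = np.random.default_rng(42)
        q = random_peaks(rng, 200, name_prefix="q")
        s = random_peaks(rng, 200, name_prefix="s")
        hits = intersect(q, s, slack=slack)
        got = {(qi, si) for qi, h in enumerate(hits) for si in h}
        assert got == brute_force_pairs(q, s, slack)


def brute_force_closest(query, subject):
    out = []
    for q in query:
        best = None
        for s in subject:
            d = interval_distance(q, s)
            if d is None:
                continue
            key = (d, s.start, s.name)
            if best is None or key < best:
                best = key
        out.append(None if best is None else (best[2], best[0]))
    return out


class TestClosest:
    def test_overlap_distance_zero(self):
        q = make_peaks([("chr1", 100, 200, "q")])
        s = make_peaks([("chr1", 150, 250, "s")])
        assert closest(q, s)["distance"].iloc[0] == 0

    def test_bookended_matches_bedtools(self, tmp_path):
        """Bookended intervals report distance 1, as bedtools closest -d."""
        qf, sf = tmp_path / "q.bed", tmp_path / "s.bed"
        qf.write_text("chr1\t100\t200\tq\t0\t.\n")
        sf.write_text("chr1\t200\t300\ts\t0\t.\n")
        out = subprocess.run(
            ["bedtools", "closest", "-d", "-a", qf, "-b", sf],
            capture_output=True, text=True, check=True,
        ).stdout
        bedtools_distance = int(out.split()[-1])
        q = read_bed(qf, GENOME)
        s = read_bed(sf, GENOME)
        assert closest(q, s)["distance"].iloc[0] == bedtools_distance == 1

    def test_empty_subject_errors(self):
        q = make_peaks([("chr1", 0, 10)])
        with pytest.raises(ValueError, match="empty"):
            closest(q, PeakSet.from_intervals([], GENOME))

    def test_absent_chromosome_is_nan(self):
        q = make_peaks([("chr1", 0, 10, "a"), ("chr2", 0, 10, "b")])
        s = make_peaks([("chr1", 50, 60, "s")])
        res = closest(q, s)
        assert res.loc[res.query_name == "b", "distance"].isna().all()

    def test_tie_breaks_leftmost_then_name(self):
        q = make_peaks([("chr1", 500, 600, "q")])
        s = make_peaks([("chr1", 300, 400, "left"), ("chr1", 700, 800, "right")])
        res = closest(q, s)  # both at distance 101
        assert res["subject_name"].iloc[0] == "left"

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        q = random_peaks(rng, 500, name_prefix="q")
        s = random_peaks(rng, 500, name_prefix="s")
        res = closest(q, s)
        oracle = brute_force_closest(q, s)
        for (_, row), expect in zip(res.iterrows(), oracle):
            assert (row.subject_name, row.distance) == (expect[0], expect[1])


class TestMerge:
    def test_overlap_merged(self):
        ps = make_peaks([("chr1", 100, 200), ("chr1", 150, 300)])
        m = merge(ps)
        assert [(iv.start, iv.end) for iv in m] == [(100, 300)]

    def test_disjoint_unchanged_and_idempotent(self):
        ps = make_peaks([("chr1", 0, 10), ("chr1", 50, 60)])
        m = merge(ps)
        assert len(m) == 2
        m2 = merge(m)
        assert m2.df[["chrom", "start", "end"]].equals(m.df[["chrom", "start", "end"]])

    def test_gap_parameter(self):
        ps = make_peaks([("chr1", 0, 10), ("chr1", 50, 60)])
        assert len(merge(ps, gap=40)) == 1
        assert len(merge(ps, gap=39)) == 2

    def test_coverage_matches_bitmap_oracle(self):
        rng = np.random.default_rng(3)
        ps = random_peaks(rng, 300)
        m = merge(ps)
        for chrom in GENOME:
            bitmap = np.zeros(GENOME[chrom], dtype=bool)
            for iv in ps:
                if iv.chrom == chrom:
                    bitmap[iv.start:iv.end] = True
            merged_cov = np.zeros(GENOME[chrom], dtype=bool)
            for iv in m:
                if iv.chrom == chrom:
                    merged_cov[iv.start:iv.end] = True
            assert (bitmap == merged_cov).all()
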