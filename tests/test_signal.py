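"""Signal tracks: quantification, track algebra, matrices, correlation."""

import numpy as np
import pandas as pd
import pytest

from peakshift.intervals import GenomicInterval
from peakshift.signal import (
    MatrixSpec,
    SignalTrack,
    log2_ratio,
    read_bedgraph,
    region_mean,
    signal_matrix,
    sort_rows_by_ratio,
    subtract_tracks,
    track_correlation,
    write_bedgraph,
)

from conftest import GENOME, dense_values, make_peaks, random_track


class TestBedGraphIO:
    def test_basic_parse(self, tmp_path):
        f = tmp_path / "a.bedGraph"
        f.write_text("chr1\t0\t100\t2.5\n")
        t = read_bedgraph(f, GENOME)
        s, e, v = t.segments("chr1")
        assert (s[0], e[0], v[0]) == (0, 100, 2.5)

    def test_overlapping_records_rejected(self, tmp_path):
        f = tmp_path / "a.bedGraph"
        f.write_text("chr1\t0\t100\t1\nchr1\t50\t150\t2\n")
        with pytest.raises(ValueError, match="overlap"):
            read_bedgraph(f, GENOME)

    def test_round_trip_preserves_segments(self, tmp_path):
        rng = np.random.default_rng(1)
        t = random_track(rng)
        f = tmp_path / "rt.bedGraph"
        write_bedgraph(t, f)
        back = read_bedgraph(f, GENOME)
        for chrom in GENOME:
            s1, e1, v1 = t.segments(chrom)
            s2, e2, v2 = back.segments(chrom)
            np.testing.assert_array_equal(s1, s2)
            np.testing.assert_array_equal(e1, e2)
            np.testing.assert_allclose(v1, v2, rtol=1e-9)

    def test_malformed_line_reports_lineno(self, tmp_path):
        f = tmp_path / "a.bedGraph"
        f.write_text("chr1\t0\t100\t1\nchr1\tx\t200\t2\n")
        with pytest.raises(ValueError, match=":2"):
            read_bedgraph(f, GENOME)


class TestRegionMean:
    def test_constant_track(self):
        t = SignalTrack.from_dict({"chr1": [(0, 1000, 3.5)]}, GENOME)
        assert region_mean(t, GenomicInterval("chr1", 100, 200)) == 3.5

    def test_half_covered(self):
        t = SignalTrack.from_dict({"chr1": [(0, 50, 2.0)]}, GENOME)
        assert region_mean(t, GenomicInterval("chr1", 0, 100)) == 1.0

    def test_out_of_bounds_rejected(self):
        t = SignalTrack.from_dict({"chr1": [(0, 50, 2.0)]}, GENOME)
        with pytest.raises(ValueError):
            region_mean(t, GenomicInterval("chr1", 0, GENOME["chr1"] + 10))

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            t = random_track(rng)
            dense = dense_values(t, "chr1")
            for _ in range(10):
                a = int(rng.integers(0, GENOME["chr1"] - 1000))
                b = a + int(rng.integers(1, 1000))
                got = region_mean(t, GenomicInterval("chr1", a, b))
                assert got == pytest.approx(dense[a:b].mean(), abs=1e-9)

    def test_linear_in_signal(self):
        rng = np.random.default_rng(3)
        t = random_track(rng)
        iv = GenomicInterval("chr1", 1000, 5000)
        assert region_mean(t.scale(3.0), iv) == pytest.approx(
            3.0 * region_mean(t, iv), rel=1e-12
        )


class TestLog2Ratio:
    def test_equal_means_zero(self):
        t = SignalTrack.from_dict({"chr1": [(0, 1000, 4.0)]}, GENOME)
        assert log2_ratio(t, t, GenomicInterval("chr1", 0, 100)) == 0.0

    def test_doubling_gives_one(self):
        wt = SignalTrack.from_dict({"chr1": [(0, 1000, 1.0)]}, GENOME)
        pert = SignalTrack.from_dict({"chr1": [(0, 1000, 3.0)]}, GENOME)
        # (3 + 1) / (1 + 1) = 2
        assert log2_ratio(pert, wt, GenomicInterval("chr1", 0, 100), 1.0) == 1.0

    def test_zero_wt_coverage(self):
        wt = SignalTrack.from_dict({"chr1": []}, GENOME)
        pert = SignalTrack.from_dict({"chr1": [(0, 1000, 1.0)]}, GENOME)
        assert log2_ratio(pert, wt, GenomicInterval("chr1", 0, 100), 1.0) == 1.0


class TestSubtractTracks:
    def test_self_subtraction_is_zero_track(self):
        rng = np.random.default_rng(4)
        t = random_track(rng)
        z = subtract_tracks(t, t)
        for chrom in GENOME:
            _, _, v = z.segments(chrom)
            assert (v == 0).all()
            np.testing.assert_array_equal(
                dense_values(z, chrom), np.zeros(GENOME[chrom])
            )

    def test_constants(self):
        a = SignalTrack.from_dict({"chr1": [(0, 100, 3.0)]}, GENOME)
        b = SignalTrack.from_dict({"chr1": [(0, 100, 1.0)]}, GENOME)
        d = subtract_tracks(a, b)
        s, e, v = d.segments("chr1")
        assert (s[0], e[0], v[0]) == (0, 100, 2.0)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = random_track(rng)
            b = random_track(rng)
            d = subtract_tracks(a, b)
            for chrom in GENOME:
                np.testing.assert_allclose(
                    dense_values(d, chrom),
                    dense_values(a, chrom) - dense_values(b, chrom),
                    atol=1e-12,
                )

    def test_subtracting_zero_is_identity(self):
        rng = np.random.default_rng(6)
        a = random_track(rng)
        zero = SignalTrack({}, GENOME)
        d = subtract_tracks(a, zero)
        for chrom in GENOME:
            np.testing.assert_allclose(
                dense_values(d, chrom), dense_values(a, chrom), atol=1e-12
            )

    def test_genome_mismatch(self):
        a = SignalTrack({}, GENOME)
        b = SignalTrack({}, {"chr1": 10})
        with pytest.raises(ValueError):
            subtract_tracks(a, b)


class TestSignalMatrix:
    def test_constant_track_fills_matrix(self):
        t = SignalTrack.from_dict({"chr1": [(0, GENOME["chr1"], 2.0)]}, GENOME)
        peaks = make_peaks([("chr1", 5000, 5100, "p", 50)])
        mat, flags = signal_matrix(t, peaks, MatrixSpec(flank=500, bin=50))
        assert mat.shape == (1, 20)
        assert (mat.to_numpy() == 2.0).all()
        assert not flags.any()

    def test_two_columns_when_flank_equals_bin(self):
        t = SignalTrack({}, GENOME)
        peaks = make_peaks([("chr1", 5000, 5100, "p", 50)])
        mat, _ = signal_matrix(t, peaks, MatrixSpec(flank=50, bin=50))
        assert mat.shape == (1, 2)

    def test_edge_rows_flagged_and_zero_padded(self):
        t = SignalTrack.from_dict({"chr1": [(0, GENOME["chr1"], 1.0)]}, GENOME)
        peaks = make_peaks([("chr1", 0, 100, "edge", 10)])
        mat, flags = signal_matrix(t, peaks, MatrixSpec(flank=500, bin=100))
        assert flags[0]
        assert mat.to_numpy()[0, 0] == 0.0  # fully outside chromosome

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            MatrixSpec(flank=100, bin=33)
        with pytest.raises(ValueError):
            MatrixSpec(flank=0)

    def test_matches_region_mean_oracle(self):
        rng = np.random.default_rng(7)
        t = random_track(rng)
        rows = [("chr1", p, p + 100, f"p{i}", 50)
                for i, p in enumerate(range(2000, 30_000, 3000))]
        peaks = make_peaks(rows)
        spec = MatrixSpec(flank=400, bin=100)
        mat, _ = signal_matrix(t, peaks, spec)
        for iv in peaks:
            for j in range(spec.n_bins):
                a = iv.summit - spec.flank + j * spec.bin
                b = a + spec.bin
                expect = region_mean(t, GenomicInterval("chr1", a, b))
                assert mat.loc[iv.name][j] == pytest.approx(expect, abs=1e-9)

    def test_row_mean_equals_window_mean(self):
        rng = np.random.default_rng(8)
        t = random_track(rng)
        peaks = make_peaks([("chr1", 10_000, 10_100, "p", 50)])
        spec = MatrixSpec(flank=1000, bin=50)
        mat, _ = signal_matrix(t, peaks, spec)
        window = GenomicInterval("chr1", 10_050 - 1000, 10_050 + 1000)
        assert mat.iloc[0].mean() == pytest.approx(region_mean(t, window), abs=1e-9)


class TestSortRowsByRatio:
    def test_descending_order(self):
        mat = pd.DataFrame(np.eye(3), index=["a", "b", "c"])
        out = sort_rows_by_ratio(mat, {"a": 0.1, "b": 2.0, "c": 1.0})
        assert list(out.index) == ["b", "c", "a"]

    def test_ties_broken_by_name(self):
        mat = pd.DataFrame(np.zeros((3, 2)), index=["c", "a", "b"])
        out = sort_rows_by_ratio(mat, {"a": 1.0, "b": 1.0, "c": 1.0})
        assert list(out.index) == ["a", "b", "c"]

    def test_matches_argsort_oracle(self):
        rng = np.random.default_rng(9)
        names = [f"p{i}" for i in range(200)]
        ratios = pd.Series(rng.normal(size=200), index=names)
        mat = pd.DataFrame(rng.normal(size=(200, 4)), index=names)
        out = sort_rows_by_ratio(mat, ratios)
        expect = sorted(names, key=lambda n: (-ratios[n], n))
        assert list(out.index) == expect

    def test_length_mismatch_rejected(self):
        mat = pd.DataFrame(np.zeros((2, 2)), index=["a", "b"])
        with pytest.raises(ValueError):
            sort_rows_by_ratio(mat, {"a": 1.0})


class TestTrackCorrelation:
    def test_identity_is_one(self):
        rng = np.random.default_rng(10)
        t = random_track(rng)
        assert track_correlation(t, t, bin=1000) == pytest.approx(1.0)

    def test_negated_is_minus_one(self):
        rng = np.random.default_rng(11)
        t = random_track(rng)
        assert track_correlation(t, t.scale(-1.0), bin=1000) == pytest.approx(-1.0)

    def test_zero_variance_is_nan(self):
        flat = SignalTrack.from_dict(
            {c: [(0, GENOME[c], 1.0)] for c in GENOME}, GENOME
        )
        rng = np.random.default_rng(12)
        assert np.isnan(track_correlation(flat, random_track(rng), bin=1000))

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(13)
        a = random_track(rng)
        b = random_track(rng)
        bin_ = 500
        xs, ys = [], []
        for chrom in sorted(GENOME):
            da = dense_values(a, chrom)
            db = dense_values(b, chrom)
            for lo in range(0, GENOME[chrom], bin_):
                hi = min(lo + bin_, GENOME[chrom])
                xs.append(da[lo:hi].mean())
                ys.append(db[lo:hi].mean())
        x, y = np.array(xs), np.array(ys)
        expect = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert track_correlation(a, b, bin=bin_) == pytest.approx(expect, abs=1e-12)
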