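"""Track/interval data model, file I/O round trips and circular statistics."""

import numpy as np
import pytest

from ipodhr.tracks import (
    FeatureSet,
    GenomeTrack,
    GenomicInterval,
    interval_overlap_fraction,
    mask_to_intervals,
    read_features,
    read_track,
    rolling_mean_circular,
    rotation_permutation_test,
    write_features,
    write_track,
)

from conftest import make_track


class TestTrackIO:
    def test_bedgraph_maps_onto_bin_grid(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chrom\t0\t10\t2.0\n")
        t = read_track(p, genome_length=20, resolution=5)
        assert t.values[0] == 2.0 and t.values[1] == 2.0
        assert np.isnan(t.values[2]) and np.isnan(t.values[3])

    def test_empty_file_gives_all_missing(self, tmp_path):
        p = tmp_path / "empty.bedgraph"
        p.write_text("")
        t = read_track(p, genome_length=100, resolution=5)
        assert t.n_bins == 20 and np.isnan(t.values).all()

    def test_overlapping_records_error_names_collision(self, tmp_path):
        p = tmp_path / "bad.bedgraph"
        p.write_text("chrom\t0\t10\t1.0\nchrom\t5\t15\t2.0\n")
        with pytest.raises(ValueError, match=r"\[0,10\).*\[5,15\)"):
            read_track(p, genome_length=100, resolution=5)

    def test_record_beyond_genome_errors(self, tmp_path):
        p = tmp_path / "bad.bedgraph"
        p.write_text("chrom\t95\t110\t1.0\n")
        with pytest.raises(ValueError, match="outside genome"):
            read_track(p, genome_length=100, resolution=5)

    def test_write_merges_equal_adjacent_bins(self, tmp_path):
        t = make_track([1.0, 1.0, 2.0])
        p = tmp_path / "t.bedgraph"
        write_track(t, p)
        lines = p.read_text().strip().split("\n")
        assert lines == ["chrom\t0\t10\t1", "chrom\t10\t15\t2"]

    def test_constant_track_single_record(self, tmp_path):
        t = make_track([3.0] * 10)
        p = tmp_path / "t.bedgraph"
        write_track(t, p)
        assert p.read_text().strip() == "chrom\t0\t50\t3"

    def test_roundtrip_random_tracks(self, tmp_path, rng):
        for i in range(100):
            n = int(rng.integers(5, 60))
            vals = rng.integers(0, 4, size=n).astype(float)  # ties force merging
            if rng.random() < 0.3:
                vals[rng.integers(0, n)] = np.nan
            t = make_track(vals)
            p = tmp_path / f"rt_{i}.bedgraph"
            write_track(t, p)
            back = read_track(p, t.genome_length, t.resolution)
            np.testing.assert_array_equal(back.values, t.values)


class TestFeatureIO:
    def test_gff_coordinate_conversion(self, tmp_path):
        p = tmp_path / "f.gff"
        p.write_text("##gff-version 3\nchrom\tsrc\tpeak\t101\t200\t4\t.\t.\tID=p1\n")
        fs = read_features(p, "gff3")
        assert fs.intervals[0] == GenomicInterval("chrom", 100, 200)
        assert fs.scores[0] == 4.0

    def test_bed_kept_half_open(self, tmp_path):
        p = tmp_path / "f.bed"
        p.write_text("chrom\t100\t200\tx\t1\t+\n")
        fs = read_features(p, "bed")
        assert fs.intervals[0] == GenomicInterval("chrom", 100, 200)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "f.gff"
        p.write_text("chrom\tsrc\tpeak\t101\tnot_a_number\t4\t.\t.\t\n")
        with pytest.raises(ValueError, match=":1"):
            read_features(p, "gff3")

    @pytest.mark.parametrize("fmt", ["gff3", "bed", "tsv"])
    def test_roundtrip_identity(self, tmp_path, rng, fmt):
        for i in range(20):
            n = int(rng.integers(1, 10))
            starts = np.sort(rng.choice(1000, size=n, replace=False))
            fs = FeatureSet(
                intervals=[GenomicInterval("chrom", int(s), int(s) + int(rng.integers(1, 50))) for s in starts],
                scores=[float(s) for s in rng.integers(0, 10, n)],
                names=[f"f{j}" for j in range(n)],
            )
            p = tmp_path / f"rt_{fmt}_{i}"
            write_features(fs, p, fmt)
            back = read_features(p, fmt)
            assert [iv for iv in back.intervals] == [iv for iv in fs.intervals]
            assert back.scores == fs.scores
            assert back.names == fs.names


class TestRollingMean:
    def test_hand_computed_example_with_wrap(self):
        t = make_track([0, 0, 10, 0, 0])
        out = rolling_mean_circular(t, 15)
        np.testing.assert_allclose(out.values, [0, 10 / 3, 10 / 3, 10 / 3, 0])

    def test_constant_track_unchanged(self):
        t = make_track([2.5] * 40)
        out = rolling_mean_circular(t, 35)
        np.testing.assert_allclose(out.values, 2.5)

    def test_mean_conserved(self, rng):
        t = make_track(rng.standard_normal(200))
        out = rolling_mean_circular(t, 55)
        assert out.values.mean() == pytest.approx(t.values.mean())

    def test_even_window_forced_odd(self):
        # window of 2 bins becomes 3; symmetric operator
        t = make_track([0, 0, 6, 0, 0, 0])
        out = rolling_mean_circular(t, 10)
        np.testing.assert_allclose(out.values, [0, 2, 2, 2, 0, 0])

    def test_translation_equivariance(self, rng):
        vals = rng.standard_normal(120)
        t = make_track(vals)
        shifted = make_track(np.roll(vals, 17))
        out = rolling_mean_circular(t, 45).values
        out_shifted = rolling_mean_circular(shifted, 45).values
        np.testing.assert_allclose(np.roll(out, 17), out_shifted)

    def test_missing_bins_excluded(self):
        t = make_track([1.0, np.nan, 3.0])
        out = rolling_mean_circular(t, 15)
        np.testing.assert_allclose(out.values, [2.0, 2.0, 2.0])

    def test_window_larger_than_genome_errors(self):
        with pytest.raises(ValueError, match="window larger"):
            rolling_mean_circular(make_track([1.0, 2.0]), 100)


class TestOverlapFraction:
    def test_identical_sets(self):
        fs = FeatureSet(intervals=[GenomicInterval("c", 0, 100)])
        assert interval_overlap_fraction(fs, fs, 1000).symmetric == 1.0

    def test_disjoint_sets(self):
        a = FeatureSet(intervals=[GenomicInterval("c", 0, 100)])
        b = FeatureSet(intervals=[GenomicInterval("c", 200, 300)])
        assert interval_overlap_fraction(a, b, 1000).symmetric == 0.0

    def test_half_overlap(self):
        a = FeatureSet(intervals=[GenomicInterval("c", 0, 100)])
        b = FeatureSet(intervals=[GenomicInterval("c", 50, 150)])
        ov = interval_overlap_fraction(a, b, 1000)
        assert ov.symmetric == 0.5
        assert ov.frac_a_in_b == 0.5 and ov.frac_b_in_a == 0.5

    def test_empty_set_flagged(self):
        a = FeatureSet()
        b = FeatureSet(intervals=[GenomicInterval("c", 0, 100)])
        ov = interval_overlap_fraction(a, b, 1000)
        assert ov.a_empty and ov.frac_a_in_b == 0.0

    def test_wrapping_interval(self):
        a = FeatureSet(intervals=[GenomicInterval("c", 950, 50)])  # wraps origin
        b = FeatureSet(intervals=[GenomicInterval("c", 0, 50)])
        ov = interval_overlap_fraction(a, b, 1000)
        assert ov.frac_b_in_a == 1.0
        assert ov.frac_a_in_b == 0.5


class TestRotationPermutationTest:
    def test_constant_statistic_gives_p_one(self):
        fs = FeatureSet(intervals=[GenomicInterval("c", 10, 20)])
        obs, p, _ = rotation_permutation_test(fs, lambda f: 1.0, 1000, n_perm=50, seed=0)
        assert p == 1.0

    def test_zero_offset_reproduces_statistic(self):
        fs = FeatureSet(intervals=[GenomicInterval("c", 10, 20), GenomicInterval("c", 40, 60)])
        stat = lambda f: sum(iv.start for iv in f.intervals)
        assert stat(fs.shifted(0, 1000)) == stat(fs)

    def test_whole_genome_feature_invariant(self):
        fs = FeatureSet(intervals=[GenomicInterval("c", 0, 1000)])
        stat = lambda f: f.total_bp(1000)
        obs, p, perm = rotation_permutation_test(fs, stat, 1000, n_perm=30, seed=1)
        assert p == 1.0 and np.all(perm == obs)

    def test_rotation_preserves_count_and_lengths(self, rng):
        ivs = [GenomicInterval("c", int(s), int(s) + int(rng.integers(1, 30)))
               for s in rng.choice(900, 10, replace=False)]
        fs = FeatureSet(intervals=ivs)
        for off in [0, 1, 500, 999]:
            shifted = fs.shifted(off, 1000)
            assert len(shifted) == len(fs)
            assert sorted(iv.length(1000) for iv in shifted.intervals) == sorted(
                iv.length(1000) for iv in fs.intervals
            )

    def test_addone_pvalue_never_zero(self):
        fs = FeatureSet(intervals=[GenomicInterval("c", 10, 20)])
        # statistic maximal at the observed placement
        stat = lambda f: -abs(f.intervals[0].start - 10)
        _, p, _ = rotation_permutation_test(fs, stat, 1000, n_perm=20, seed=2)
        assert 0 < p <= 1


class TestMaskIntervals:
    def test_wrap_run_reassembled(self):
        mask = np.zeros(100, dtype=bool)
        mask[95:] = True
        mask[:5] = True
        ivs = mask_to_intervals(mask, "c")
        assert ivs == [GenomicInterval("c", 95, 5)]

    def test_interval_shift_wraps(self):
        iv = GenomicInterval("c", 90, 99)
        sh = iv.shifted(5, 100)
        assert sh == GenomicInterval("c", 95, 4)
        assert sh.length(100) == iv.length(100)
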