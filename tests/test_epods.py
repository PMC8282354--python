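"""EPOD seed-and-extend calling against an independent brute-force oracle."""

import numpy as np
import pytest

from ipodhr.chipsub import robust_z
from ipodhr.epods import (
    EpodParams,
    call_epods,
    call_epods_both,
    epod_containment,
    epod_feature_enrichment,
    epod_overlap_matrix,
    epods_to_featureset,
)
from ipodhr.synthetic import planted_z_track
from ipodhr.tracks import FeatureSet, GenomeTrack, GenomicInterval

from conftest import make_track


# ---------------------------------------------------------------------------
# brute-force oracle: literal, loop-based restatement of the calling rules
# ---------------------------------------------------------------------------


def oracle_epods(values, res, k, seed_window=512, thresh_window=256, min_seed=1024, floor=0.0):
    values = np.asarray(values, dtype=float)
    n = len(values)

    def rmean(window_bp):
        w = int(round(window_bp / res))
        if w % 2 == 0:
            w += 1
        h = w // 2
        out = np.empty(n)
        for i in range(n):
            acc = [values[(i + j) % n] for j in range(-h, h + 1)]
            acc = [v for v in acc if np.isfinite(v)]
            out[i] = np.mean(acc) if acc else np.nan
        return out

    rm_t = rmean(thresh_window)
    rm_s = rmean(seed_window)
    T = np.nanpercentile(rm_t, k)
    above = [bool(np.isfinite(rm_s[i]) and rm_s[i] > T) for i in range(n)]
    w = int(round(seed_window / res))
    if w % 2 == 0:
        w += 1
    h = w // 2
    eroded = [all(above[(i + j) % n] for j in range(-h, h + 1)) for i in range(n)]

    # circular runs of eroded
    runs = []
    if all(eroded):
        runs = [(0, n)]
    elif any(eroded):
        start = None
        first_false = eroded.index(False)
        order = [(first_false + i) % n for i in range(n)]
        for i in order:
            if eroded[i] and start is None:
                start = i
                ln = 1
            elif eroded[i]:
                ln += 1
            elif start is not None:
                runs.append((start, ln))
                start = None
        if start is not None:
            runs.append((start, ln))
    runs = [r for r in runs if r[1] * res >= min_seed]

    epods = []
    for start, ln in runs:
        s = start
        while ln < n:
            idx = [(s + j) % n for j in range(ln)]
            zl = values[(s - 1) % n]
            zr = values[(s + ln) % n]
            zl = zl if np.isfinite(zl) else -np.inf
            zr = zr if np.isfinite(zr) else -np.inf
            options = []
            if zl > floor:
                ml = np.mean([values[i] for i in idx] + [zl])
                if ml > T:
                    options.append(("L", ml))
            if zr > floor:
                mr = np.mean([values[i] for i in idx] + [zr])
                if mr > T:
                    options.append(("R", mr))
            if not options:
                break
            options.sort(key=lambda o: (o[1], o[0] == "L"))
            side = options[-1][0]
            if side == "L":
                s -= 1
            ln += 1
        epods.append((s % n, ln))
    return sorted(epods)


def called_to_bins(epods, res, n):
    out = []
    for e in epods:
        start_bin = e.interval.start // res
        length = e.interval.length(n * res) // res
        out.append((start_bin, length))
    return sorted(out)


def random_structured_track(seed, n_bins=2000, res=5):
    """Noise plus occasional plateaus so EPODs actually occur."""
    r = np.random.default_rng(seed)
    vals = r.standard_normal(n_bins)
    for _ in range(int(r.integers(0, 3))):
        start = int(r.integers(0, n_bins))
        length = int(r.integers(150, 500))
        amp = float(r.uniform(1.0, 4.0))
        idx = (start + np.arange(length)) % n_bins
        vals[idx] += amp
    return GenomeTrack("c", n_bins * res, res, vals)


class TestCallEpodsOracle:
    def test_constant_track_no_epods(self):
        t = make_track(np.full(3000, 2.0))
        assert call_epods(t, EpodParams()) == []

    def test_two_kb_plateau_recovered(self):
        jaccards = []
        for seed in range(20):
            z = robust_z(planted_z_track(100_000, plateaus=[(40_000, 42_000, 3.0)], seed=seed))
            eps = call_epods(z, EpodParams(k_percentile=90))
            assert len(eps) >= 1
            best = 0.0
            for e in eps:
                iv = e.interval
                inter = max(0, min(iv.end, 42_000) - max(iv.start, 40_000))
                union = iv.length(100_000) + 2000 - inter
                best = max(best, inter / union)
            jaccards.append(best)
        assert np.mean(jaccards) >= 0.8

    def test_900bp_plateau_rejected(self):
        for seed in range(5):
            z = robust_z(planted_z_track(100_000, plateaus=[(40_000, 40_900, 5.0)], seed=seed))
            assert call_epods(z, EpodParams(k_percentile=90)) == []

    def test_plateau_on_zero_background_extends_less_than_one_window(self):
        vals = np.zeros(20_000)
        vals[8000:8400] = 5.0  # 2,000 bp plateau at 5-bp bins
        t = GenomeTrack("c", 100_000, 5, vals)
        eps = call_epods(t, EpodParams(k_percentile=90))
        assert len(eps) == 1
        iv = eps[0].interval
        assert iv.start <= 40_000 and iv.end >= 42_000
        assert 40_000 - iv.start < 512 and iv.end - 42_000 < 512

    @pytest.mark.parametrize("k", [90, 75])
    def test_matches_brute_force_oracle(self, k):
        for seed in range(50):
            t = random_structured_track(seed)
            called = call_epods(t, EpodParams(k_percentile=float(k)))
            expected = oracle_epods(t.values, t.resolution, k)
            assert called_to_bins(called, t.resolution, t.n_bins) == expected, f"seed={seed}"

    def test_strict_subset_of_relaxed(self):
        for seed in range(20):
            t = random_structured_track(seed + 100)
            both = call_epods_both(t)
            strict = epods_to_featureset(both["strict"])
            relaxed = epods_to_featureset(both["relaxed"])
            if len(strict) == 0:
                continue
            containment = epod_containment(strict, relaxed, t.genome_length)
            assert containment == pytest.approx(1.0)

    def test_all_missing_track_errors(self):
        t = make_track(np.full(1000, np.nan))
        with pytest.raises(ValueError, match="missing"):
            call_epods(t)


class TestEpodComparisons:
    def test_overlap_matrix_identical_and_disjoint(self):
        a = FeatureSet(intervals=[GenomicInterval("c", 0, 2000)])
        b = FeatureSet(intervals=[GenomicInterval("c", 0, 2000)])
        c = FeatureSet(intervals=[GenomicInterval("c", 5000, 7000)])
        mat, order = epod_overlap_matrix({"a": a, "b": b, "c": c}, 10_000)
        ia, ib, ic = order.index("a"), order.index("b"), order.index("c")
        assert mat[ia, ib] == 1.0
        assert mat[ia, ic] == 0.0
        assert np.allclose(np.diag(mat), 1.0)
        assert np.allclose(mat, mat.T)

    def test_half_overlap_value(self):
        a = FeatureSet(intervals=[GenomicInterval("c", 0, 1000)])
        b = FeatureSet(intervals=[GenomicInterval("c", 500, 1500)])
        mat, _ = epod_overlap_matrix({"a": a, "b": b}, 10_000)
        assert mat[0, 1] == pytest.approx(0.5)

    def test_containment_identical_sets(self):
        a = FeatureSet(intervals=[GenomicInterval("c", 100, 300)])
        assert epod_containment(a, a, 1000) == 1.0

    def test_containment_empty_strict_flagged_zero(self):
        b = FeatureSet(intervals=[GenomicInterval("c", 100, 300)])
        assert epod_containment(FeatureSet(), b, 1000) == 0.0


class TestEpodEnrichment:
    def test_indicator_of_epods_is_maximal(self):
        # indicator achieves the maximal median difference of 1; rotations
        # only tie when they realign >= 50% with the original location
        epods = FeatureSet(intervals=[GenomicInterval("c", 100_000, 105_000)])
        vals = np.zeros(100_000)
        vals[20_000:21_000] = 1.0  # indicator of the EPOD bins
        track = GenomeTrack("c", 500_000, 5, vals)
        diff, p = epod_feature_enrichment(epods, track, n_perm=200, seed=0)
        assert diff == pytest.approx(1.0)
        assert p < 0.1

    def test_constant_feature_no_difference(self):
        epods = FeatureSet(intervals=[GenomicInterval("c", 10_000, 15_000)])
        track = GenomeTrack("c", 50_000, 5, np.full(10_000, 3.0))
        diff, p = epod_feature_enrichment(epods, track, n_perm=50, seed=0)
        assert diff == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_random_feature_pvalues_not_degenerate(self, rng):
        # p should be spread out over repeated random features, not stuck at 0/1
        epods = FeatureSet(intervals=[GenomicInterval("c", 10_000, 15_000)])
        ps = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            track = GenomeTrack("c", 50_000, 5, r.standard_normal(10_000))
            _, p = epod_feature_enrichment(epods, track, n_perm=50, seed=seed)
            ps.append(p)
        assert np.std(ps) > 0.1
        assert min(ps) < 0.5 < max(ps)
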