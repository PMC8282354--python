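"""Quantile normalization, periodic spline correction and ratio tracks."""

import numpy as np
import pytest

from ipodhr.normalize import (
    ConditionBundle,
    average_replicates,
    copy_number_correct,
    fit_periodic_spline,
    log2_ratio,
    match_means,
    normalize_condition,
    quantile_normalize,
)
from ipodhr.tracks import GenomeTrack

from conftest import make_track


def gradient_track(n_bins=2000, res=5, fold=2.0, phase=0.0, noise=None):
    L = n_bins * res
    x = (np.arange(n_bins) + 0.5) * res
    vals = 1 + (fold - 1) * (np.cos(2 * np.pi * x / L + phase) + 1) / 2
    if noise is not None:
        vals = vals * noise
    return GenomeTrack("chrom", L, res, vals)


class TestQuantileNormalize:
    def test_worked_example(self):
        a, b = quantile_normalize([make_track([1, 2, 3]), make_track([2, 4, 6])])
        np.testing.assert_allclose(a.values, [1.5, 3, 4.5])
        np.testing.assert_allclose(b.values, [1.5, 3, 4.5])

    def test_identical_tracks_unchanged(self):
        t = make_track([5, 1, 3, 2])
        outs = quantile_normalize([t, t])
        for o in outs:
            np.testing.assert_allclose(o.values, t.values)

    def test_sorted_outputs_identical(self, rng):
        tracks = [make_track(rng.gamma(2, 1, size=50)) for _ in range(3)]
        outs = quantile_normalize(tracks)
        ref = np.sort(outs[0].values)
        for o in outs[1:]:
            np.testing.assert_allclose(np.sort(o.values), ref)

    def test_ties_get_mean_of_reference_span(self):
        # track a has a tie at ranks 1-2; reference is mean of sorted inputs
        a, b = quantile_normalize([make_track([1, 1, 5]), make_track([2, 4, 6])])
        # reference = mean of ([1,1,5],[2,4,6]) sorted = [1.5, 2.5, 5.5]
        np.testing.assert_allclose(a.values, [2.0, 2.0, 5.5])
        np.testing.assert_allclose(b.values, [1.5, 2.5, 5.5])

    def test_misaligned_tracks_error(self):
        with pytest.raises(ValueError, match="not aligned"):
            quantile_normalize([make_track([1, 2]), make_track([1, 2, 3])])

    def test_single_track_returned_unchanged(self):
        t = make_track([3, 1])
        (out,) = quantile_normalize([t])
        np.testing.assert_allclose(out.values, t.values)


class TestPeriodicSpline:
    def test_constant_track_gives_constant_spline(self):
        t = make_track([4.2] * 400)
        s = fit_periodic_spline(t)
        np.testing.assert_allclose(s.values, 4.2, rtol=1e-8)

    def test_recovers_cosine_within_one_percent(self):
        n, res = 4000, 5
        L = n * res
        x = (np.arange(n) + 0.5) * res
        t = GenomeTrack("c", L, res, 2 + np.cos(2 * np.pi * x / L))
        s = fit_periodic_spline(t)
        rmse = np.sqrt(np.mean((s.values - t.values) ** 2))
        assert rmse < 0.01  # 1% of the unit amplitude

    def test_rotation_equivariance(self):
        n, res = 1000, 5
        L = n * res
        x = (np.arange(n) + 0.5) * res
        vals = 2 + np.cos(2 * np.pi * x / L) + 0.3 * np.sin(4 * np.pi * x / L)
        shift = 137  # bins; knots rotate with the data
        s1 = fit_periodic_spline(GenomeTrack("c", L, res, vals)).values
        s2 = fit_periodic_spline(
            GenomeTrack("c", L, res, np.roll(vals, shift)), knot_offset=shift * res
        ).values
        np.testing.assert_allclose(np.roll(s1, shift), s2, atol=1e-6)

    def test_missing_bins_imputed(self):
        vals = np.full(500, 3.0)
        vals[10:20] = np.nan
        s = fit_periodic_spline(make_track(vals))
        np.testing.assert_allclose(s.values, 3.0, rtol=1e-6)


class TestCopyNumberCorrect:
    def _bundle(self, fold=2.0):
        tracks = {st: [gradient_track(fold=fold)] for st in ("input", "ipod", "chip")}
        return ConditionBundle("c", tracks["input"], tracks["ipod"], tracks["chip"])

    def test_input_equal_to_spline_becomes_flat(self):
        b = copy_number_correct(self._bundle())
        corrected = b.corrected["input"][0].values
        np.testing.assert_allclose(corrected, 1.0, atol=0.02)

    def test_gradient_amplitude_invariance(self):
        b1 = copy_number_correct(self._bundle(fold=2.0))
        b2 = copy_number_correct(self._bundle(fold=4.0))
        np.testing.assert_allclose(
            b1.corrected["ipod"][0].values, b2.corrected["ipod"][0].values, atol=0.03
        )

    def test_flat_tracks_unchanged(self):
        tracks = {st: [make_track([2.0] * 500)] for st in ("input", "ipod", "chip")}
        b = copy_number_correct(
            ConditionBundle("c", tracks["input"], tracks["ipod"], tracks["chip"])
        )
        np.testing.assert_allclose(b.corrected["ipod"][0].values, 1.0, rtol=1e-6)


class TestMatchMeansAverage:
    def test_means_rescaled_to_grand_mean(self):
        a, b = match_means([make_track([1.0] * 4), make_track([3.0] * 4)])
        assert a.values.mean() == pytest.approx(2.0)
        assert b.values.mean() == pytest.approx(2.0)

    def test_single_track_unchanged(self):
        (out,) = match_means([make_track([2.0, 4.0])])
        np.testing.assert_allclose(out.values, [2.0, 4.0])

    def test_output_means_identical(self, rng):
        tracks = [make_track(rng.gamma(3, 1, 30)) for _ in range(4)]
        outs = match_means(tracks)
        means = [np.nanmean(o.values) for o in outs]
        np.testing.assert_allclose(means, means[0], rtol=1e-9)

    def test_nonpositive_mean_errors(self):
        with pytest.raises(ValueError, match="positive"):
            match_means([make_track([-1.0, 0.5])])

    def test_average_duplicate_is_identity(self):
        t = make_track([1, 5, 2])
        np.testing.assert_allclose(average_replicates([t, t]).values, t.values)

    def test_average_elementwise(self):
        out = average_replicates([make_track([0, 2]), make_track([2, 0])])
        np.testing.assert_allclose(out.values, [1, 1])

    def test_average_mean_identity(self, rng):
        tracks = [make_track(rng.standard_normal(40)) for _ in range(3)]
        out = average_replicates(tracks)
        assert out.values.mean() == pytest.approx(
            np.mean([t.values.mean() for t in tracks])
        )


class TestLog2Ratio:
    def test_equal_tracks_zero(self):
        t = make_track([1.0, 2.0, 3.0])
        np.testing.assert_allclose(log2_ratio(t, t).values, 0.0)

    def test_fourfold_gives_two(self):
        a = make_track([4.0, 8.0])
        b = make_track([1.0, 2.0])
        np.testing.assert_allclose(log2_ratio(a, b).values, 2.0)

    def test_antisymmetric_under_swap(self, rng):
        a = make_track(rng.gamma(3, 1, 30))
        b = make_track(rng.gamma(3, 1, 30))
        np.testing.assert_allclose(
            log2_ratio(a, b).values, -log2_ratio(b, a).values, atol=1e-12
        )

    def test_missing_input_propagates(self):
        a = make_track([1.0, 2.0])
        b = make_track([1.0, np.nan])
        out = log2_ratio(a, b)
        assert out.values[0] == 0.0 and np.isnan(out.values[1])


class TestFullChain:
    def _noisy_bundle(self, seed=0, n_rep=2, sigma=0.0, fold=2.0, n_bins=4000):
        rng = np.random.default_rng(seed)
        mk = lambda: gradient_track(
            n_bins=n_bins,
            fold=fold,
            noise=np.exp(sigma * rng.standard_normal(n_bins)) if sigma else None,
        )
        return ConditionBundle(
            "c", [mk() for _ in range(n_rep)], [mk() for _ in range(n_rep)], [mk() for _ in range(n_rep)]
        )

    def test_pure_gradient_yields_flat_log2(self):
        b = normalize_condition(self._noisy_bundle())
        frac = np.mean(np.abs(b.ipod_log2.values) < 0.05)
        assert frac >= 0.99

    def test_chain_idempotent(self):
        b = normalize_condition(self._noisy_bundle(sigma=0.05, seed=3))
        once = {st: [t.values.copy() for t in b.corrected[st]] for st in b.corrected}
        b2 = ConditionBundle(
            "c",
            [t.with_values(v) for t, v in zip(b.input, once["input"])],
            [t.with_values(v) for t, v in zip(b.ipod, once["ipod"])],
            [t.with_values(v) for t, v in zip(b.chip, once["chip"])],
        )
        b2 = normalize_condition(b2)
        for st in ("input", "ipod", "chip"):
            for t1, t2 in zip(once[st], b2.corrected[st]):
                np.testing.assert_allclose(t1, t2.values, rtol=0.02, atol=0.02)

    def test_missing_replicate_rejected(self):
        with pytest.raises(ValueError, match="no chip replicates"):
            ConditionBundle("c", [make_track([1.0])], [make_track([1.0])], [])
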