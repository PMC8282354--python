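"""Continuous-wavelet-transform peak calling for TFBS-scale occupancy.

Binding-site footprints appear in the robust-z occupancy track as peaks a
few tens to ~150 bp wide. They are detected by ridge-line CWT peak
finding: the track is convolved (circularly) with Mexican-hat (ricker)
wavelets over a ladder of widths; local maxima of the coefficient matrix
are linked into ridges across adjacent widths; ridges that persist across
enough scales and whose maximal coefficient stands sufficiently above a
local noise floor become peak calls. Peaks are stratified by the
signal-to-noise threshold they survive, and each call is padded by a fixed
margin on each side to define the region used downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .tracks import (
    FeatureSet,
    GenomeTrack,
    GenomicInterval,
    mask_to_intervals,
    rotation_permutation_test,
)

__all__ = [
    "PeakCall",
    "CwtParams",
    "DEFAULT_WIDTHS_BP",
    "call_peaks_cwt",
    "peaks_at_threshold",
    "score_peaks",
    "peaks_to_featureset",
    "peak_site_overlap",
]

DEFAULT_WIDTHS_BP = tuple(range(25, 130, 5))


@dataclass
class CwtParams:
    """Knobs of the ridge-line CWT peak finder.

    gap_tolerance:
        A ridge may skip this many consecutive scales without a matched
        maximum before it is terminated.
    min_ridge_frac:
        Minimum ridge length as a fraction of the width ladder.
    noise_window_bins:
        Centered window (in bins) over which the local noise floor is
        estimated.
    noise_percentile:
        Percentile of |smallest-width coefficients| in that window used as
        the noise floor. A high quantile makes the SNR a contrast against
        typical local fluctuation; low quantiles inflate every ridge's SNR
        and flood low thresholds with noise calls.
    max_distance_frac:
        Matching tolerance when linking maxima across scales, as a fraction
        of the width (in bins) at each scale.
    """

    gap_tolerance: int = 2
    min_ridge_frac: float = 0.25
    noise_window_bins: int = 1000
    noise_percentile: float = 90.0
    max_distance_frac: float = 0.25


@dataclass
class PeakCall:
    """One called occupancy peak.

    ``interval`` is the padded region used downstream; ``raw_interval`` is
    the unpadded span of the detected width around the apex.
    ``min_snr_threshold`` records the strictest signal-to-noise cutoff in
    the requested ladder that the peak still survives (the score written to
    GFF output); ``snr`` is the continuous value.
    """

    interval: GenomicInterval
    raw_interval: GenomicInterval
    snr: float
    min_snr_threshold: float
    apex_bp: int
    width_bp: int
    mean_z: float = float("nan")
    discrete_score: int | None = None


def _ricker(points: int, a: float) -> np.ndarray:
    """Mexican-hat wavelet, unit L2 norm, ``points`` samples wide."""
    A = 2.0 / (np.sqrt(3.0 * a) * np.pi**0.25)
    x = np.arange(points) - (points - 1) / 2.0
    xsq = (x / a) ** 2
    return A * (1 - xsq) * np.exp(-xsq / 2.0)


def _cwt_matrix(values: np.ndarray, widths_bins: np.ndarray, circular: bool) -> np.ndarray:
    mode = "wrap" if circular else "nearest"
    n = len(values)
    out = np.empty((len(widths_bins), n))
    for i, w in enumerate(widths_bins):
        kernel = _ricker(min(10 * int(w), n), float(w))
        out[i] = ndimage.convolve1d(values, kernel, mode=mode)
    return out


def _local_maxima(row: np.ndarray) -> np.ndarray:
    """Indices of strict circular local maxima (left-strict, right-nonstrict)."""
    left = np.roll(row, 1)
    right = np.roll(row, -1)
    return np.flatnonzero((row > left) & (row >= right))


def _circ_dist(a: int, b: int, n: int) -> int:
    d = abs(a - b) % n
    return min(d, n - d)


def _identify_ridges(
    cwt: np.ndarray, widths_bins: np.ndarray, params: CwtParams, n: int
) -> list[list[tuple[int, int, float]]]:
    """Link per-scale maxima into ridges, scanning from largest width down.

    Each ridge is a list of (scale_index, position, coefficient) triples for
    the scales at which a maximum was matched.
    """
    n_scales = len(widths_bins)
    maxima = [_local_maxima(cwt[s]) for s in range(n_scales)]
    ridges: list[dict] = []
    finished: list[list[tuple[int, int, float]]] = []
    for s in range(n_scales - 1, -1, -1):
        max_dist = max(1, int(round(params.max_distance_frac * widths_bins[s])))
        available = list(maxima[s])
        claimed = set()
        for ridge in ridges:
            best = None
            best_d = max_dist + 1
            for pos in available:
                if pos in claimed:
                    continue
                d = _circ_dist(pos, ridge["pos"], n)
                if d < best_d:
                    best_d = d
                    best = pos
            if best is not None and best_d <= max_dist:
                ridge["points"].append((s, int(best), float(cwt[s, best])))
                ridge["pos"] = int(best)
                ridge["gap"] = 0
                claimed.add(best)
            else:
                ridge["gap"] += 1
        still = []
        for ridge in ridges:
            if ridge["gap"] > params.gap_tolerance:
                finished.append(ridge["points"])
            else:
                still.append(ridge)
        ridges = still
        for pos in available:
            if pos not in claimed:
                ridges.append(
                    {"pos": int(pos), "gap": 0, "points": [(s, int(pos), float(cwt[s, pos]))]}
                )
    finished.extend(r["points"] for r in ridges)
    return finished


def _noise_floor(row0_abs: np.ndarray, params: CwtParams) -> np.ndarray:
    """Per-bin noise floor from |smallest-width coefficients| in a window."""
    n = len(row0_abs)
    w = min(params.noise_window_bins, n)
    if w % 2 == 0:
        w += 1
    noise = ndimage.percentile_filter(
        row0_abs, percentile=params.noise_percentile, size=w, mode="wrap"
    )
    tiny = max(1e-12, 1e-6 * float(np.max(row0_abs, initial=0.0)))
    return np.maximum(noise, tiny)


def call_peaks_cwt(
    z: GenomeTrack,
    widths_bp: tuple[int, ...] = DEFAULT_WIDTHS_BP,
    snr_thresholds: tuple[float, ...] = (2, 3, 4, 6, 8, 10),
    pad_bp: int = 30,
    params: CwtParams | None = None,
) -> list[PeakCall]:
    """Ridge-line CWT peak detection on a robust-z track.

    Returns one :class:`PeakCall` per surviving ridge apex whose SNR
    reaches at least the lowest requested threshold. A ridge "appears" in
    the peak set at threshold t whenever its SNR >= t, so the per-threshold
    sets are nested; ``min_snr_threshold`` on each call records the
    strictest threshold in the ladder the peak survives. Use
    :func:`peaks_at_threshold` to materialize the (merged) set at one
    threshold.

    Missing bins are treated as zero signal for the transform.
    """
    if params is None:
        params = CwtParams()
    thresholds = sorted(float(t) for t in snr_thresholds)
    res = z.resolution
    widths_bins = np.unique(np.maximum(1, np.round(np.array(widths_bp) / res))).astype(int)
    vals = np.nan_to_num(z.values, nan=0.0)
    n = len(vals)
    cwt = _cwt_matrix(vals, widths_bins, z.circular)
    ridges = _identify_ridges(cwt, widths_bins, params, n)
    min_len = math.ceil(params.min_ridge_frac * len(widths_bins))
    noise = _noise_floor(np.abs(cwt[0]), params)
    calls: list[PeakCall] = []
    L = z.genome_length
    for points in ridges:
        if len(points) < min_len:
            continue
        scales, positions, coeffs = zip(*points)
        best = int(np.argmax(coeffs))
        max_coeff = coeffs[best]
        if max_coeff <= 0:
            continue
        # apex: ridge position at the smallest matched scale
        smallest = int(np.argmin(scales))
        apex_bin = positions[smallest]
        snr = float(max_coeff / noise[apex_bin])
        passed = [t for t in thresholds if snr >= t]
        if not passed:
            continue
        width_bp = int(widths_bins[scales[best]] * res)
        apex_bp = int(apex_bin * res + res // 2)
        half = width_bp // 2
        raw = _make_interval(z.chrom_id, apex_bp - half, apex_bp - half + width_bp, L)
        padded = _make_interval(z.chrom_id, apex_bp - half - pad_bp, apex_bp - half + width_bp + pad_bp, L)
        calls.append(
            PeakCall(
                interval=padded,
                raw_interval=raw,
                snr=snr,
                min_snr_threshold=max(passed),
                apex_bp=apex_bp % L,
                width_bp=width_bp,
            )
        )
    calls.sort(key=lambda c: c.interval.start)
    return calls


def _make_interval(chrom: str, start: int, end: int, L: int) -> GenomicInterval:
    """Wrap an unwrapped [start, end) onto the circular chromosome."""
    length = end - start
    if length >= L:
        return GenomicInterval(chrom, 0, L)
    s = start % L
    e = s + length
    if e > L:
        e -= L
    return GenomicInterval(chrom, s, e)


def peaks_at_threshold(
    calls: list[PeakCall], threshold: float, genome_length: int, merge: bool = True
) -> list[PeakCall]:
    """Peak set at one SNR threshold; overlapping padded calls are merged.

    A merged call keeps the minimum ``min_snr_threshold`` of its members
    and the apex/SNR of the strongest member.
    """
    selected = [c for c in calls if c.snr >= threshold]
    if not merge or not selected:
        return selected
    merged: list[PeakCall] = []
    mask = np.zeros(genome_length, dtype=bool)
    for c in selected:
        for s, e in c.interval.segments(genome_length):
            mask[s:e] = True
    regions = mask_to_intervals(mask, selected[0].interval.chrom_id, circular=True)
    for region in regions:
        rmask = np.zeros(genome_length, dtype=bool)
        for s, e in region.segments(genome_length):
            rmask[s:e] = True
        members = [c for c in selected if rmask[c.apex_bp]]
        if not members:
            continue
        top = max(members, key=lambda c: c.snr)
        merged.append(
            replace(
                top,
                interval=region,
                min_snr_threshold=min(c.min_snr_threshold for c in members),
            )
        )
    merged.sort(key=lambda c: c.interval.start)
    return merged


def score_peaks(
    peaks: list[PeakCall],
    z: GenomeTrack,
    drop_negative: bool = False,
) -> list[PeakCall]:
    """Attach mean robust z over the raw interval and its floor as score.

    ``discrete_score = floor(mean_z)``. With ``drop_negative`` (used for
    motif-dataset export) peaks with negative mean occupancy are removed.
    """
    res = z.resolution
    out: list[PeakCall] = []
    for pk in peaks:
        bins: list[int] = []
        for s, e in pk.raw_interval.segments(z.genome_length):
            bins.extend(range(s // res, min((e - 1) // res + 1, z.n_bins)))
        vals = z.values[np.array(bins, dtype=int)]
        mean_z = float(np.nanmean(vals))
        scored = replace(pk, mean_z=mean_z, discrete_score=math.floor(mean_z))
        if drop_negative and scored.discrete_score < 0:
            continue
        out.append(scored)
    return out


def peaks_to_featureset(peaks: list[PeakCall], padded: bool = True) -> FeatureSet:
    """Export calls as a FeatureSet; score column = min SNR threshold."""
    return FeatureSet(
        intervals=[p.interval if padded else p.raw_interval for p in peaks],
        scores=[float(p.min_snr_threshold) for p in peaks],
        names=[f"peak_{i}" for i in range(len(peaks))],
        sources=["ipodhr_cwt"] * len(peaks),
    )


def peak_site_overlap(
    peaks: FeatureSet,
    sites: FeatureSet,
    genome_length: int,
    n_perm: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Enrichment of annotated sites overlapping peaks vs. rotation null.

    The statistic is the fraction of sites overlapping at least one peak;
    the null rotates the sites by uniform random offsets. Returns
    ``(enrichment, p)`` where enrichment is the observed fraction divided
    by the mean permuted fraction.
    """
    if len(peaks) == 0 or len(sites) == 0:
        raise ValueError("both peak and site sets must be non-empty")
    peak_mask = peaks.to_mask(genome_length)

    def frac_overlapping(fs: FeatureSet) -> float:
        hits = 0
        for iv in fs.intervals:
            if any(peak_mask[s:e].any() for s, e in iv.segments(genome_length)):
                hits += 1
        return hits / len(fs)

    observed, p, perm = rotation_permutation_test(
        sites, frac_overlapping, genome_length, n_perm, seed
    )
    mean_perm = float(np.mean(perm))
    enrichment = observed / mean_perm if mean_perm > 0 else float("inf")
    return enrichment, p
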