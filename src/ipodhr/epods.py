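"""Extended protein occupancy domain (EPOD) detection and comparison.

EPODs are kilobase-scale regions of dense non-polymerase protein
occupancy, typically transcriptionally silent. They are called on the
robust-z occupancy track by seed-and-extend:

1. the threshold T is the k-th percentile of a 256-bp rolling mean over
   the whole chromosome (k = 90 for strict calls, 75 for relaxed);
2. seeds are maximal regions of at least 1,024 bp over which the 512-bp
   rolling mean exceeds T at every window overlapping the region (the run
   of above-threshold window centers eroded by half a window — otherwise
   window spillover at the edges would promote sub-minimum plateaus past
   the length cutoff); among overlapping seeds only the one with the
   highest mean is retained;
3. each seed is expanded outward bin by bin, choosing at each step the
   side that maximizes the running mean (ties to the left), as long as the
   mean over the whole call stays above T and the next bin's z-score stays
   above the floor (0): an EPOD never crosses a position with z <= 0.

Calls that come to abut after extension are reported separately, never
merged, preserving seed identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .tracks import (
    FeatureSet,
    GenomeTrack,
    GenomicInterval,
    interval_overlap_fraction,
    rolling_mean_circular,
    rotation_permutation_test,
)

__all__ = [
    "EpodParams",
    "Epod",
    "call_epods",
    "call_epods_both",
    "epods_to_featureset",
    "epod_overlap_matrix",
    "epod_containment",
    "epod_feature_enrichment",
]


@dataclass
class EpodParams:
    """EPOD calling parameters (strict: k=90; relaxed: k=75)."""

    k_percentile: float = 90.0
    seed_window_bp: int = 512
    threshold_window_bp: int = 256
    min_seed_bp: int = 1024
    floor_z: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.k_percentile < 100):
            raise ValueError("k_percentile must be in (0, 100)")
        if self.min_seed_bp < self.seed_window_bp:
            raise ValueError("min_seed_bp must be >= seed_window_bp")

    @property
    def mode(self) -> str:
        return "strict" if self.k_percentile >= 90 else "relaxed"


@dataclass
class Epod:
    """One called domain with its mean robust z."""

    interval: GenomicInterval
    mean_z: float
    mode: str


def _circular_true_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start_bin, length) on a circular array."""
    n = len(above)
    if above.all():
        return [(0, n)]
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.where(diff == 1)[0]
    ends = np.where(diff == -1)[0]
    runs = [(int(s), int(e - s)) for s, e in zip(starts, ends)]
    if len(runs) >= 2 and runs[0][0] == 0 and runs[-1][0] + runs[-1][1] == n:
        first, last = runs[0], runs[-1]
        runs = runs[1:-1] + [(last[0], last[1] + first[1])]
    return runs


def call_epods(z: GenomeTrack, params: EpodParams | None = None) -> list[Epod]:
    """Seed-and-extend EPOD calling on a robust-z track.

    Missing bins are treated as z <= 0: they block extension and are
    excluded from the rolling means. The percentile threshold is computed
    once, up front, over all non-missing bins.
    """
    if params is None:
        params = EpodParams()
    vals = z.values
    if not np.isfinite(vals).any():
        raise ValueError("all-missing track")
    res = z.resolution
    n = z.n_bins
    rm_thresh = rolling_mean_circular(z, params.threshold_window_bp).values
    rm_seed = rolling_mean_circular(z, params.seed_window_bp).values
    T = float(np.nanpercentile(rm_thresh, params.k_percentile))
    above = np.where(np.isfinite(rm_seed), rm_seed > T, False)
    w = int(round(params.seed_window_bp / res))
    if w % 2 == 0:
        w += 1
    mode = "wrap" if z.circular else "nearest"
    eroded = ndimage.minimum_filter(above.astype(np.uint8), size=w, mode=mode) > 0
    runs = [(s, ln) for s, ln in _circular_true_runs(eroded) if ln * res >= params.min_seed_bp]
    # maximal runs are disjoint by construction, but resolve defensively
    runs = _resolve_overlapping_seeds(runs, vals, n)
    zsafe = np.where(np.isfinite(vals), vals, -np.inf)
    epods: list[Epod] = []
    for start, length in runs:
        s, ln = _extend_seed(zsafe, start, length, T, params.floor_z, n)
        idx = (np.arange(s, s + ln)) % n
        mean_z = float(np.nanmean(vals[idx]))
        if ln >= n:
            iv = GenomicInterval(z.chrom_id, 0, z.genome_length)
        else:
            bp_start = s * res
            last_bin = (s + ln - 1) % n
            bp_end = min((last_bin + 1) * res, z.genome_length)
            iv = GenomicInterval(z.chrom_id, bp_start, bp_end)
        epods.append(Epod(iv, mean_z, params.mode))
    epods.sort(key=lambda e: e.interval.start)
    return epods


def _resolve_overlapping_seeds(
    runs: list[tuple[int, int]], vals: np.ndarray, n: int
) -> list[tuple[int, int]]:
    """Iteratively drop the lower-mean seed of any overlapping pair."""

    def covered(run: tuple[int, int]) -> set[int]:
        return {(run[0] + i) % n for i in range(run[1])}

    def mean(run: tuple[int, int]) -> float:
        idx = (run[0] + np.arange(run[1])) % n
        return float(np.nanmean(vals[idx]))

    runs = list(runs)
    changed = True
    while changed:
        changed = False
        for i in range(len(runs)):
            for j in range(i + 1, len(runs)):
                if covered(runs[i]) & covered(runs[j]):
                    drop = i if mean(runs[i]) < mean(runs[j]) else j
                    runs.pop(drop)
                    changed = True
                    break
            if changed:
                break
    return runs


def _extend_seed(
    zsafe: np.ndarray, start: int, length: int, T: float, floor_z: float, n: int
) -> tuple[int, int]:
    """Greedy bilateral extension; returns (start_bin, length_bins).

    ``start`` may go negative during extension (interpreted modulo n).
    At each step the side yielding the higher candidate mean is taken
    (ties to the left), subject to: the whole-call mean stays above T and
    the added bin's z stays above the floor.
    """
    idx = (start + np.arange(length)) % n
    total = float(np.sum(zsafe[idx]))
    s, ln = start, length
    while ln < n:
        left_bin = (s - 1) % n
        right_bin = (s + ln) % n
        zl = zsafe[left_bin]
        zr = zsafe[right_bin]
        cand = []
        if zl > floor_z:
            mean_l = (total + zl) / (ln + 1)
            if mean_l > T:
                cand.append(("L", mean_l, zl))
        if zr > floor_z:
            mean_r = (total + zr) / (ln + 1)
            if mean_r > T:
                cand.append(("R", mean_r, zr))
        if not cand:
            break
        # higher candidate mean wins; tie goes left (cand is in L,R order)
        side, _, zadd = max(cand, key=lambda c: (c[1], c[0] == "L"))
        if side == "L":
            s -= 1
        ln += 1
        total += zadd
    return s % n, ln


def call_epods_both(
    z: GenomeTrack,
    strict_k: float = 90.0,
    relaxed_k: float = 75.0,
) -> dict[str, list[Epod]]:
    """Strict (k=90) and relaxed (k=75) EPOD calls on one track."""
    return {
        "strict": call_epods(z, EpodParams(k_percentile=strict_k)),
        "relaxed": call_epods(z, EpodParams(k_percentile=relaxed_k)),
    }


def epods_to_featureset(epods: list[Epod]) -> FeatureSet:
    return FeatureSet(
        intervals=[e.interval for e in epods],
        scores=[e.mean_z for e in epods],
        names=[f"epod_{i}" for i in range(len(epods))],
        sources=[f"ipodhr_epod_{e.mode}" for e in epods],
    )


def epod_overlap_matrix(
    epod_sets: dict[str, FeatureSet], genome_length: int
) -> tuple[np.ndarray, list[str]]:
    """Symmetrized pairwise bp-overlap fractions between condition EPOD sets."""
    conditions = list(epod_sets)
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    k = len(conditions)
    mat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ov = interval_overlap_fraction(
                epod_sets[conditions[i]], epod_sets[conditions[j]], genome_length
            )
            mat[i, j] = mat[j, i] = ov.symmetric
    return mat, conditions


def epod_containment(
    strict_a: FeatureSet, relaxed_b: FeatureSet, genome_length: int
) -> float:
    """Fraction of strict-set base pairs contained in the relaxed set.

    Returns 0 for an empty strict set (degenerate, nothing to contain).
    """
    mask_a = strict_a.to_mask(genome_length)
    na = int(mask_a.sum())
    if na == 0:
        return 0.0
    mask_b = relaxed_b.to_mask(genome_length)
    return float((mask_a & mask_b).sum() / na)


def epod_feature_enrichment(
    epods: FeatureSet,
    feature_track: GenomeTrack,
    n_perm: int = 1000,
    seed: int = 0,
    smooth_bp: int = 500,
) -> tuple[float, float]:
    """Median difference of a genomic feature inside vs. outside EPODs.

    The feature track is smoothed with a 500-bp rolling mean first. The
    statistic is median(inside) - median(outside); significance comes from
    circularly permuting (rotating) the EPOD locations, which preserves the
    correlation structure of both the feature track and the domain set.
    """
    smoothed = rolling_mean_circular(feature_track, smooth_bp)
    vals = smoothed.values
    res = feature_track.resolution
    n_bins = feature_track.n_bins
    L = feature_track.genome_length

    def median_diff(fs: FeatureSet) -> float:
        inside = np.zeros(n_bins, dtype=bool)
        for iv in fs.intervals:
            for s, e in iv.segments(L):
                inside[s // res : min((e - 1) // res + 1, n_bins)] = True
        vin = vals[inside]
        vout = vals[~inside]
        if len(vin) == 0 or len(vout) == 0:
            return 0.0
        return float(np.nanmedian(vin) - np.nanmedian(vout))

    observed, p, _ = rotation_permutation_test(epods, median_diff, L, n_perm, seed)
    return observed, p
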