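"""Within-condition normalization of occupancy tracks.

The chain applied to each biological condition, in order:

1. quantile normalization across replicates, separately for each sample
   type (input, interphase/IPOD, RNAP ChIP);
2. copy-number correction: divide every track by a periodic smoothing
   spline (4 evenly spaced knots) fitted to the replicate-averaged input,
   removing the ori-to-ter DNA abundance gradient of replicating cells;
3. rescaling of all tracks to a common mean;
4. replicate averaging per sample type;
5. log2 extracted:input ratio tracks for the IPOD and ChIP signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .tracks import GenomeTrack

__all__ = [
    "ConditionBundle",
    "quantile_normalize",
    "fit_periodic_spline",
    "copy_number_correct",
    "match_means",
    "average_replicates",
    "log2_ratio",
    "normalize_condition",
]

SAMPLE_TYPES = ("input", "ipod", "chip")


@dataclass
class ConditionBundle:
    """Replicate tracks and derived profiles for one biological condition."""

    condition: str
    input: list[GenomeTrack]
    ipod: list[GenomeTrack]
    chip: list[GenomeTrack]
    spline_track: GenomeTrack | None = None
    averaged: dict[str, GenomeTrack] = field(default_factory=dict)
    ipod_log2: GenomeTrack | None = None
    chip_log2: GenomeTrack | None = None
    corrected: dict[str, list[GenomeTrack]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in SAMPLE_TYPES:
            reps = getattr(self, name)
            if not reps:
                raise ValueError(f"condition {self.condition!r}: no {name} replicates")
        ref = self.input[0]
        for name in SAMPLE_TYPES:
            for track in getattr(self, name):
                ref.require_aligned(track)

    def replicates(self, sample_type: str) -> list[GenomeTrack]:
        return getattr(self, sample_type)


# ---------------------------------------------------------------------------


def quantile_normalize(tracks: list[GenomeTrack]) -> list[GenomeTrack]:
    """Quantile-normalize aligned tracks to their across-track mean quantiles.

    After normalization every output track has the same sorted value
    vector: the element-wise mean of the inputs' sorted values. Tied values
    within a track receive the mean of the reference values their ranks
    span. Missing bins must coincide across tracks and stay missing.

    A single track is returned unchanged.
    """
    if len(tracks) == 1:
        return [tracks[0].with_values(tracks[0].values.copy())]
    ref_track = tracks[0]
    for t in tracks[1:]:
        ref_track.require_aligned(t)
    finite0 = np.isfinite(ref_track.values)
    for t in tracks[1:]:
        if not np.array_equal(np.isfinite(t.values), finite0):
            raise ValueError("quantile normalization requires identical missing-bin patterns")
    data = np.stack([t.values[finite0] for t in tracks])
    reference = np.sort(data, axis=1).mean(axis=0)
    out = []
    for t, row in zip(tracks, data):
        normed = _map_to_reference(row, reference)
        vals = np.full(t.n_bins, np.nan)
        vals[finite0] = normed
        out.append(t.with_values(vals))
    return out


def _map_to_reference(x: np.ndarray, reference: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    out = np.empty_like(x)
    out[order] = reference
    # ties: average the reference values over each tied run
    xs = x[order]
    boundaries = np.flatnonzero(np.diff(xs) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(xs)]])
    for s, e in zip(starts, ends):
        if e - s > 1:
            out[order[s:e]] = reference[s:e].mean()
    return out


# ---------------------------------------------------------------------------


def _periodic_spline_design(
    x: np.ndarray, n_knots: int, L: float, knot_offset: float = 0.0
) -> np.ndarray:
    """Design matrix of periodic cubic B-splines with evenly spaced knots.

    The basis has exactly ``n_knots`` degrees of freedom per period; each
    basis function is a cubic B-spline on knots ``(j-2)h .. (j+2)h`` with
    ``h = L / n_knots``, wrapped modulo ``L``. The basis forms a partition
    of unity.
    """
    h = L / n_knots
    xr = (x - knot_offset) % L
    X = np.zeros((len(x), n_knots))
    for j in range(n_knots):
        t = (np.arange(5) + j - 2) * h
        b = BSpline.basis_element(t, extrapolate=False)
        for shift in (-L, 0.0, L):
            v = b(xr + shift)
            X[:, j] += np.nan_to_num(v)
    return X


def fit_periodic_spline(
    input_avg: GenomeTrack,
    n_knots: int = 4,
    floor_eps: float = 1e-9,
    knot_offset: float = 0.0,
) -> GenomeTrack:
    """Low-pass DNA-abundance model: periodic cubic spline, 4 even knots.

    Knots sit at 0, L/4, L/2 and 3L/4 so inflection points can fall at the
    replication origin, terminus and the points halfway between them.
    Missing bins are imputed as the track median before fitting. The fitted
    curve is floored at a small positive epsilon; if more than 1% of bins
    hit the floor the fit is considered degenerate and an error is raised.

    With so few knots the spline space has only ``n_knots`` degrees of
    freedom, so an unpenalized least-squares fit is already maximally
    smooth at genomic scale; no roughness penalty is applied.
    """
    vals = input_avg.values.copy()
    missing = ~np.isfinite(vals)
    if missing.all():
        raise ValueError("cannot fit spline: all bins missing")
    if missing.any():
        vals[missing] = np.nanmedian(input_avg.values)
    x = input_avg.bin_centers()
    X = _periodic_spline_design(x, n_knots, float(input_avg.genome_length), knot_offset)
    coef, *_ = np.linalg.lstsq(X, vals, rcond=None)
    fitted = X @ coef
    floored = fitted < floor_eps
    if floored.mean() > 0.01:
        raise ValueError(
            f"periodic spline non-positive on {floored.mean():.1%} of bins; "
            "input track is unsuitable for copy-number correction"
        )
    fitted = np.maximum(fitted, floor_eps)
    return input_avg.with_values(fitted)


def copy_number_correct(bundle: ConditionBundle, n_knots: int = 4) -> ConditionBundle:
    """Divide every replicate track by the input-derived abundance spline.

    The spline is fitted to the replicate-averaged input track of the
    condition and stored on the bundle; corrected replicate tracks replace
    the originals in ``bundle.corrected``.
    """
    if bundle.spline_track is None:
        input_avg = average_replicates(bundle.input)
        bundle.spline_track = fit_periodic_spline(input_avg, n_knots=n_knots)
    spline = bundle.spline_track.values
    if np.any(spline == 0):
        raise ValueError("spline track contains zeros")
    for name in SAMPLE_TYPES:
        bundle.corrected[name] = [
            t.with_values(t.values / spline) for t in bundle.replicates(name)
        ]
    return bundle


def match_means(tracks: list[GenomeTrack]) -> list[GenomeTrack]:
    """Rescale each track so all means equal the grand mean of track means.

    Missing bins are excluded from means and propagate unchanged.
    """
    means = np.array([np.nanmean(t.values) for t in tracks])
    if np.any(means <= 0):
        raise ValueError("match_means requires strictly positive track means")
    target = means.mean()
    return [t.with_values(t.values * (target / m)) for t, m in zip(tracks, means)]


def average_replicates(tracks: list[GenomeTrack]) -> GenomeTrack:
    """Bin-wise arithmetic mean across replicates, missing-aware."""
    ref = tracks[0]
    for t in tracks[1:]:
        ref.require_aligned(t)
    stacked = np.stack([t.values for t in tracks])
    with np.errstate(invalid="ignore"):
        out = np.nanmean(stacked, axis=0)
    return ref.with_values(out)


def log2_ratio(
    extracted: GenomeTrack, input_track: GenomeTrack, pseudocount: float = 0.0
) -> GenomeTrack:
    """log2((extracted + pc) / (input + pc)); missing input yields missing."""
    extracted.require_aligned(input_track)
    num = extracted.values + pseudocount
    den = input_track.values + pseudocount
    if np.any(num[np.isfinite(num)] < 0) or np.any(den[np.isfinite(den)] < 0):
        raise ValueError("negative values after normalization; check pseudocount")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(num / den)
    out[~np.isfinite(input_track.values)] = np.nan
    return extracted.with_values(out)


def normalize_condition(
    bundle: ConditionBundle,
    n_knots: int = 4,
    pseudocount: float = 0.0,
) -> ConditionBundle:
    """Run the full normalization chain for one condition.

    quantile normalize (per sample type) -> spline copy-number correction
    -> mean matching across all tracks -> replicate averaging -> log2
    extracted:input ratios.
    """
    for name in SAMPLE_TYPES:
        setattr(bundle, name, quantile_normalize(bundle.replicates(name)))
    copy_number_correct(bundle, n_knots=n_knots)
    flat = [t for name in SAMPLE_TYPES for t in bundle.corrected[name]]
    matched = match_means(flat)
    i = 0
    for name in SAMPLE_TYPES:
        k = len(bundle.corrected[name])
        bundle.corrected[name] = matched[i : i + k]
        i += k
    for name in SAMPLE_TYPES:
        bundle.averaged[name] = average_replicates(bundle.corrected[name])
    bundle.ipod_log2 = log2_ratio(bundle.averaged["ipod"], bundle.averaged["input"], pseudocount)
    bundle.chip_log2 = log2_ratio(bundle.averaged["chip"], bundle.averaged["input"], pseudocount)
    return bundle
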