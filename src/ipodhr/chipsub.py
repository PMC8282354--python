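"""RNA-polymerase occupancy subtraction and occupancy scoring.

Interphase extraction captures all crosslinked protein, including RNA
polymerase. To isolate non-polymerase occupancy, the contribution of RNAP
is estimated from the RNAP ChIP signal with a deliberately conservative
zero-intercept line: among the bins with the very highest ChIP signal
(taken to be occupied by RNAP alone), the line with the lowest possible
slope that still keeps ``cover_frac`` of those points at or below it. The
predicted RNAP contribution (slope x ChIP) is then subtracted wherever the
ChIP signal is positive, so subtraction can only lower, never raise,
occupancy.

The corrected signal is standardized as robust z-scores
``z_i = (x_i - median(X)) / mad(X)`` with the plain (unscaled) median
absolute deviation, and converted to -log10 upper-tail p-values under a
standard-normal null.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .normalize import ConditionBundle, log2_ratio
from .tracks import GenomeTrack

__all__ = [
    "ChipSubModel",
    "ScoredProfile",
    "fit_subtraction_slope",
    "subtract_rnap",
    "robust_z",
    "neglog10_pvalues",
    "score_profile",
    "replicate_extreme_interval",
]

_LN10 = math.log(10.0)


@dataclass
class ChipSubModel:
    """Fitted zero-intercept RNAP subtraction line."""

    slope: float
    top_frac: float = 0.02
    cover_frac: float = 0.95
    n_fit_points: int = 0


@dataclass
class ScoredProfile:
    """ChIP-subtracted occupancy with robust z and -log10 p per bin."""

    chipsub: GenomeTrack
    robust_z: GenomeTrack
    neglog10p: GenomeTrack
    model: ChipSubModel
    replicate_lo: GenomeTrack | None = None
    replicate_hi: GenomeTrack | None = None


def fit_subtraction_slope(
    ipod_log2: GenomeTrack,
    chip_log2: GenomeTrack,
    top_frac: float = 0.02,
    cover_frac: float = 0.95,
    min_points: int = 20,
) -> ChipSubModel:
    """Fit the minimal zero-intercept line covering the high-ChIP bins.

    The top ``top_frac`` of usable bins ranked by ChIP signal are selected;
    bins with non-positive ChIP inside that set are excluded from the ratio
    computation. The slope is the smallest ratio ``r = ipod/chip`` in the
    selected set such that at least ``ceil(cover_frac * n)`` ratios are
    <= r (an order statistic, no interpolation) — the lowest slope
    sufficient to keep that fraction of points on or below the line. The
    slope is clamped at 0 so that subtraction can only remove occupancy.
    """
    ipod_log2.require_aligned(chip_log2)
    usable = np.isfinite(ipod_log2.values) & np.isfinite(chip_log2.values)
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("no usable bins")
    n_top = max(1, math.ceil(top_frac * n_usable))
    chip = chip_log2.values[usable]
    ipod = ipod_log2.values[usable]
    top_idx = np.argsort(chip)[-n_top:]
    chip_top = chip[top_idx]
    ipod_top = ipod[top_idx]
    pos = chip_top > 0
    if int(pos.sum()) < min_points:
        raise ValueError(
            f"only {int(pos.sum())} positive-ChIP bins in the top {top_frac:.1%}; "
            f"need at least {min_points}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = ipod_top[pos] / chip_top[pos]
    ratios = ratios[np.isfinite(ratios)]
    m = len(ratios)
    k = math.ceil(cover_frac * m)
    slope = float(np.sort(ratios)[k - 1])
    return ChipSubModel(max(slope, 0.0), top_frac, cover_frac, n_fit_points=n_top)


def subtract_rnap(
    ipod_log2: GenomeTrack, chip_log2: GenomeTrack, model: ChipSubModel
) -> GenomeTrack:
    """Remove predicted RNAP contribution where ChIP occupancy is positive.

    ``out = ipod - slope * chip`` where ``chip > 0``; no subtraction where
    the observed RNAP occupancy is negative, so the output never exceeds
    the input signal.
    """
    ipod_log2.require_aligned(chip_log2)
    ipod = ipod_log2.values
    chip = chip_log2.values
    out = ipod.copy()
    sub = np.isfinite(chip) & (chip > 0)
    out[sub] = ipod[sub] - model.slope * chip[sub]
    return ipod_log2.with_values(out)


def robust_z(track: GenomeTrack) -> GenomeTrack:
    """Robust z-scores: (x - median(X)) / mad(X), plain MAD (no 1.4826)."""
    vals = track.values
    finite = np.isfinite(vals)
    med = np.median(vals[finite])
    mad = np.median(np.abs(vals[finite] - med))
    if mad == 0:
        raise ValueError("MAD is zero; robust z undefined")
    return track.with_values((vals - med) / mad)


def neglog10_pvalues(z: GenomeTrack) -> GenomeTrack:
    """-log10 of the one-sided upper-tail standard-normal p-value.

    Computed through the log survival function so large z-scores retain
    full precision instead of underflowing to p = 0.
    """
    vals = z.values
    out = np.full_like(vals, np.nan)
    finite = np.isfinite(vals)
    out[finite] = -stats.norm.logsf(vals[finite]) / _LN10
    return z.with_values(out)


def score_profile(
    ipod_log2: GenomeTrack,
    chip_log2: GenomeTrack,
    top_frac: float = 0.02,
    cover_frac: float = 0.95,
    model: ChipSubModel | None = None,
) -> ScoredProfile:
    """Full scoring chain: fit slope, subtract, robust z, -log10 p."""
    if model is None:
        model = fit_subtraction_slope(ipod_log2, chip_log2, top_frac, cover_frac)
    sub = subtract_rnap(ipod_log2, chip_log2, model)
    z = robust_z(sub)
    p = neglog10_pvalues(z)
    return ScoredProfile(chipsub=sub, robust_z=z, neglog10p=p, model=model)


def replicate_extreme_interval(
    bundle: ConditionBundle,
    top_frac: float = 0.02,
    cover_frac: float = 0.95,
    pseudocount: float = 0.0,
    max_combinations: int = 64,
) -> tuple[GenomeTrack, GenomeTrack]:
    """Pessimistic per-bin occupancy bounds over replicate combinations.

    The full scoring pipeline (log2 ratios, slope fit, subtraction, robust
    z, -log10 p) is recomputed for every combination of one IPOD, one ChIP
    and one input replicate — potentially different replicates for each
    sample type, to obtain the widest possible range. Returns the bin-wise
    minimum and maximum of the resulting -log10 p tracks.

    Requires ``bundle.corrected`` (normalized replicate tracks); run
    :func:`ipodhr.normalize.normalize_condition` first.
    """
    if not bundle.corrected:
        raise ValueError("bundle has no corrected replicate tracks; normalize first")
    ipods = bundle.corrected["ipod"]
    chips = bundle.corrected["chip"]
    inputs = bundle.corrected["input"]
    n_comb = len(ipods) * len(chips) * len(inputs)
    if n_comb > max_combinations:
        raise ValueError(
            f"{n_comb} replicate combinations exceed the cap of {max_combinations}; "
            "subsample replicates or raise the cap"
        )
    lo = None
    hi = None
    for ipod_t, chip_t, input_t in itertools.product(ipods, chips, inputs):
        il2 = log2_ratio(ipod_t, input_t, pseudocount)
        cl2 = log2_ratio(chip_t, input_t, pseudocount)
        prof = score_profile(il2, cl2, top_frac, cover_frac)
        vals = prof.neglog10p.values
        if lo is None:
            lo = vals.copy()
            hi = vals.copy()
        else:
            lo = np.fmin(lo, vals)
            hi = np.fmax(hi, vals)
    ref = bundle.input[0]
    return ref.with_values(lo), ref.with_values(hi)
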