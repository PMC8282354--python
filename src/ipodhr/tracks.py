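"""Core data model for signal tracks and interval sets on a circular chromosome.

Everything downstream (normalization, RNAP subtraction, peak and EPOD
calling) operates on :class:`GenomeTrack` objects: fixed-resolution binned
signal on a single circular chromosome. Genomic features (peaks, EPODs,
TFBSs, TSSs) are carried as :class:`FeatureSet` collections of
:class:`GenomicInterval`.

Conventions
-----------
* Internal coordinates are 0-based half-open base-pair positions. GFF3
  (1-based inclusive) is converted at the I/O boundary; bedGraph and BED
  are already 0-based half-open.
* Missing signal is ``NaN``; arithmetic propagates it and every operation
  states its missing policy.
* Intervals on a circular chromosome may wrap the origin; a wrapping
  interval is stored with ``start > end`` and covers
  ``[start, genome_length) ∪ [0, end)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "GenomeTrack",
    "GenomicInterval",
    "FeatureSet",
    "OverlapFractions",
    "read_track",
    "write_track",
    "read_features",
    "write_features",
    "rolling_mean_circular",
    "interval_overlap_fraction",
    "rotation_permutation_test",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeTrack:
    """Per-bin real-valued signal on a (usually circular) chromosome.

    Parameters
    ----------
    chrom_id : str
        Chromosome name, carried through file I/O.
    genome_length : int
        Chromosome length in bp.
    resolution : int
        Bin width in bp (default 5). The number of bins is
        ``ceil(genome_length / resolution)``; the last bin may be partial.
    values : numpy.ndarray
        One float per bin; ``NaN`` marks missing bins.
    circular : bool
        Whether windowed operators wrap across the origin.
    """

    chrom_id: str
    genome_length: int
    resolution: int = 5
    values: np.ndarray = None  # type: ignore[assignment]
    circular: bool = True

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.values is None:
            self.values = np.full(self.n_bins, np.nan)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_bins,):
            raise ValueError(
                f"expected {self.n_bins} bins for genome_length="
                f"{self.genome_length} at resolution {self.resolution}, "
                f"got {self.values.shape}"
            )

    @property
    def n_bins(self) -> int:
        return math.ceil(self.genome_length / self.resolution)

    def aligned_with(self, other: "GenomeTrack") -> bool:
        return (
            self.chrom_id == other.chrom_id
            and self.genome_length == other.genome_length
            and self.resolution == other.resolution
        )

    def require_aligned(self, other: "GenomeTrack") -> None:
        if not self.aligned_with(other):
            raise ValueError(
                f"tracks are not aligned: ({self.chrom_id}, {self.genome_length},"
                f" {self.resolution}) vs ({other.chrom_id}, {other.genome_length},"
                f" {other.resolution})"
            )

    def with_values(self, values: np.ndarray) -> "GenomeTrack":
        """New track sharing this track's grid with different values."""
        return replace(self, values=np.asarray(values, dtype=float))

    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins, dtype=np.int64) * self.resolution

    def bin_centers(self) -> np.ndarray:
        starts = self.bin_starts()
        ends = np.minimum(starts + self.resolution, self.genome_length)
        return (starts + ends) / 2.0

    def bp_to_bin(self, pos: int) -> int:
        return int(pos) // self.resolution


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval; ``start > end`` wraps the origin."""

    chrom_id: str
    start: int
    end: int

    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, genome_length: int) -> int:
        if self.wraps():
            return genome_length - self.start + self.end
        return self.end - self.start

    def segments(self, genome_length: int) -> list[tuple[int, int]]:
        """Non-wrapping [start, end) pieces covering this interval."""
        if self.wraps():
            return [(self.start, genome_length), (0, self.end)]
        return [(self.start, self.end)]

    def shifted(self, offset: int, genome_length: int) -> "GenomicInterval":
        """Rotate by ``offset`` bp around the circular chromosome."""
        length = self.length(genome_length)
        if length >= genome_length:
            return GenomicInterval(self.chrom_id, 0, genome_length)
        new_start = (self.start + offset) % genome_length
        new_end = new_start + length
        if new_end > genome_length:
            new_end -= genome_length
        return GenomicInterval(self.chrom_id, new_start, new_end)

    def validate(self, genome_length: int) -> None:
        if not (0 <= self.start < genome_length):
            raise ValueError(f"start {self.start} outside [0, {genome_length})")
        if not (0 < self.end <= genome_length):
            raise ValueError(f"end {self.end} outside (0, {genome_length}]")
        if self.length(genome_length) <= 0:
            raise ValueError(f"interval {self} has non-positive length")


@dataclass
class FeatureSet:
    """Sorted genomic intervals with per-interval score/name/source."""

    intervals: list[GenomicInterval] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)
    names: list[str] = field(default_factory=list)
    sources: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.intervals)
        if not self.scores:
            self.scores = [0.0] * n
        if not self.names:
            self.names = [f"feature_{i}" for i in range(n)]
        if not self.sources:
            self.sources = ["."] * n
        if not (len(self.scores) == len(self.names) == len(self.sources) == n):
            raise ValueError("attribute lists must match interval count")
        self._sort()

    def _sort(self) -> None:
        order = sorted(range(len(self.intervals)), key=lambda i: (self.intervals[i].start, self.intervals[i].end))
        self.intervals = [self.intervals[i] for i in order]
        self.scores = [self.scores[i] for i in order]
        self.names = [self.names[i] for i in order]
        self.sources = [self.sources[i] for i in order]

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def to_mask(self, genome_length: int) -> np.ndarray:
        """Boolean bp-level coverage mask."""
        mask = np.zeros(genome_length, dtype=bool)
        for iv in self.intervals:
            for s, e in iv.segments(genome_length):
                mask[s:e] = True
        return mask

    def total_bp(self, genome_length: int) -> int:
        return int(self.to_mask(genome_length).sum())

    def shifted(self, offset: int, genome_length: int) -> "FeatureSet":
        return FeatureSet(
            intervals=[iv.shifted(offset, genome_length) for iv in self.intervals],
            scores=list(self.scores),
            names=list(self.names),
            sources=list(self.sources),
        )

    def subset(self, indices: Sequence[int]) -> "FeatureSet":
        return FeatureSet(
            intervals=[self.intervals[i] for i in indices],
            scores=[self.scores[i] for i in indices],
            names=[self.names[i] for i in indices],
            sources=[self.sources[i] for i in indices],
        )


# ---------------------------------------------------------------------------
# track I/O (bedGraph)
# ---------------------------------------------------------------------------


def read_track(
    path: str | Path,
    genome_length: int,
    resolution: int = 5,
    chrom_id: str | None = None,
    circular: bool = True,
) -> GenomeTrack:
    """Read a 4-column bedGraph onto a fixed bin grid.

    Records must be non-overlapping and lie within ``genome_length``.
    Bins not covered by any record are left missing (NaN); a bin covered
    by records with different values receives the coverage-weighted mean.
    """
    n_bins = math.ceil(genome_length / resolution)
    wsum = np.zeros(n_bins)
    wbp = np.zeros(n_bins)
    records: list[tuple[int, int]] = []
    chrom_seen = chrom_id
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom_seen is None:
                chrom_seen = chrom
            if chrom_id is not None and chrom != chrom_id:
                raise ValueError(f"{path}:{lineno}: unexpected chromosome {chrom!r}")
            if e > genome_length or s < 0 or s >= e:
                raise ValueError(
                    f"{path}:{lineno}: record [{s},{e}) outside genome of length {genome_length}"
                )
            records.append((s, e))
            _accumulate_interval(wsum, wbp, s, e, v, resolution, genome_length)
    records.sort()
    for (s1, e1), (s2, e2) in zip(records, records[1:]):
        if s2 < e1:
            raise ValueError(
                f"{path}: overlapping bedGraph records [{s1},{e1}) and [{s2},{e2})"
            )
    values = np.full(n_bins, np.nan)
    covered = wbp > 0
    values[covered] = wsum[covered] / wbp[covered]
    return GenomeTrack(chrom_seen or "chrom", genome_length, resolution, values, circular)


def _accumulate_interval(
    wsum: np.ndarray,
    wbp: np.ndarray,
    s: int,
    e: int,
    value: float,
    resolution: int,
    genome_length: int,
) -> None:
    first = s // resolution
    last = (e - 1) // resolution
    for b in range(first, last + 1):
        bs = b * resolution
        be = min(bs + resolution, genome_length)
        ov = min(e, be) - max(s, bs)
        wsum[b] += value * ov
        wbp[b] += ov


def write_track(track: GenomeTrack, path: str | Path) -> None:
    """Write bedGraph, run-length merging adjacent equal-valued bins.

    Missing bins are omitted (bedGraph gaps).
    """
    vals = track.values
    res = track.resolution
    L = track.genome_length
    with open(path, "w") as fh:
        run_start: int | None = None
        run_val = 0.0
        for i in range(track.n_bins + 1):
            v = vals[i] if i < track.n_bins else np.nan
            if run_start is not None and (i == track.n_bins or np.isnan(v) or v != run_val):
                fh.write(
                    f"{track.chrom_id}\t{run_start * res}\t{min(i * res, L)}\t{run_val:.8g}\n"
                )
                run_start = None
            if i < track.n_bins and not np.isnan(v) and run_start is None:
                run_start = i
                run_val = v


# ---------------------------------------------------------------------------
# feature I/O (GFF3 / BED / TSV)
# ---------------------------------------------------------------------------


def read_features(path: str | Path, fmt: str, genome_length: int | None = None) -> FeatureSet:
    """Read a FeatureSet from ``gff3``, ``bed`` or ``tsv``.

    GFF3 coordinates (1-based inclusive) are converted to internal 0-based
    half-open; BED and TSV are taken as already 0-based half-open.
    """
    fmt = fmt.lower()
    intervals: list[GenomicInterval] = []
    scores: list[float] = []
    names: list[str] = []
    sources: list[str] = []
    with open(path) as fh:
        header_skipped = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if fmt == "gff3":
                    chrom, source, ftype, start, end, score = (
                        parts[0], parts[1], parts[2], int(parts[3]), int(parts[4]), parts[5],
                    )
                    attrs = parts[8] if len(parts) > 8 else ""
                    name = _gff_attr(attrs, "Name") or _gff_attr(attrs, "ID") or ftype
                    intervals.append(GenomicInterval(chrom, start - 1, end))
                    scores.append(float(score) if score not in (".", "") else 0.0)
                    names.append(name)
                    sources.append(source)
                elif fmt == "bed":
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
                    score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
                    intervals.append(GenomicInterval(chrom, start, end))
                    scores.append(score)
                    names.append(name)
                    sources.append(".")
                elif fmt == "tsv":
                    if not header_skipped:
                        header_skipped = True
                        if not parts[1].lstrip("-").isdigit():
                            continue
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    names.append(parts[3] if len(parts) > 3 else f"feature_{lineno}")
                    scores.append(float(parts[4]) if len(parts) > 4 else 0.0)
                    sources.append(parts[5] if len(parts) > 5 else ".")
                    intervals.append(GenomicInterval(chrom, start, end))
                else:
                    raise ValueError(f"unknown feature format {fmt!r}")
            except (IndexError, ValueError) as exc:
                if isinstance(exc, ValueError) and "unknown feature format" in str(exc):
                    raise
                raise ValueError(f"{path}:{lineno}: malformed {fmt} line: {exc}") from exc
    if genome_length is not None:
        for iv in intervals:
            iv.validate(genome_length)
    return FeatureSet(intervals, scores, names, sources)


def _gff_attr(attrs: str, key: str) -> str | None:
    for item in attrs.split(";"):
        item = item.strip()
        if item.startswith(key + "="):
            return item[len(key) + 1 :]
    return None


def write_features(
    features: FeatureSet,
    path: str | Path,
    fmt: str,
    feature_type: str = "region",
) -> None:
    """Write a FeatureSet as GFF3, BED6 or TSV (internal coordinates)."""
    fmt = fmt.lower()
    with open(path, "w") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
            for iv, score, name, source in zip(
                features.intervals, features.scores, features.names, features.sources
            ):
                fh.write(
                    f"{iv.chrom_id}\t{source}\t{feature_type}\t{iv.start + 1}\t{iv.end}\t"
                    f"{score:.8g}\t.\t.\tID={name};Name={name}\n"
                )
        elif fmt == "bed":
            for iv, score, name in zip(features.intervals, features.scores, features.names):
                fh.write(f"{iv.chrom_id}\t{iv.start}\t{iv.end}\t{name}\t{score:.8g}\t.\n")
        elif fmt == "tsv":
            fh.write("chrom\tstart\tend\tname\tscore\tsource\n")
            for iv, score, name, source in zip(
                features.intervals, features.scores, features.names, features.sources
            ):
                fh.write(f"{iv.chrom_id}\t{iv.start}\t{iv.end}\t{name}\t{score:.8g}\t{source}\n")
        else:
            raise ValueError(f"unknown feature format {fmt!r}")


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------


def rolling_mean_circular(track: GenomeTrack, window_bp: int) -> GenomeTrack:
    """Centered rolling mean over ``window_bp``, wrapping across the origin.

    The window is converted to bins with ``round(window_bp / resolution)``
    and forced odd (+1 if even) so the operator is symmetric. Missing bins
    are excluded from each window's mean; a window with no data yields NaN.
    """
    if window_bp < track.resolution:
        raise ValueError("window_bp must be at least one bin")
    w = int(round(window_bp / track.resolution))
    if w % 2 == 0:
        w += 1
    if w > track.n_bins:
        raise ValueError("window larger than genome")
    mode = "wrap" if track.circular else "nearest"
    vals = track.values
    finite = np.isfinite(vals)
    filled = np.where(finite, vals, 0.0)
    kernel = np.ones(w)
    sums = ndimage.convolve1d(filled, kernel, mode=mode)
    counts = ndimage.convolve1d(finite.astype(float), kernel, mode=mode)
    out = np.full(track.n_bins, np.nan)
    ok = counts > 0.5
    out[ok] = sums[ok] / counts[ok]
    return track.with_values(out)


@dataclass(frozen=True)
class OverlapFractions:
    """Base-pair overlap fractions between two interval sets."""

    symmetric: float
    frac_a_in_b: float
    frac_b_in_a: float
    a_empty: bool = False
    b_empty: bool = False


def interval_overlap_fraction(
    a: FeatureSet, b: FeatureSet, genome_length: int
) -> OverlapFractions:
    """Symmetrized bp-level overlap: mean of frac(a in b) and frac(b in a).

    An empty set contributes a one-directional fraction of 0 and is flagged.
    """
    mask_a = a.to_mask(genome_length)
    mask_b = b.to_mask(genome_length)
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    inter = int((mask_a & mask_b).sum())
    fa = inter / na if na else 0.0
    fb = inter / nb if nb else 0.0
    return OverlapFractions((fa + fb) / 2.0, fa, fb, a_empty=na == 0, b_empty=nb == 0)


def rotation_permutation_test(
    features: FeatureSet,
    statistic: Callable[[FeatureSet], float],
    genome_length: int,
    n_perm: int,
    seed: int,
) -> tuple[float, float, np.ndarray]:
    """Circular-rotation permutation test for a feature-set statistic.

    Each permutation rotates all feature coordinates by one uniform random
    offset modulo the genome length, preserving internal spacing and every
    feature's length, so the correlation structure of both the data and the
    features is conserved. The p-value uses the add-one estimator
    ``(1 + #{perm >= observed}) / (1 + n_perm)`` for the greater-is-extreme
    direction.

    Returns ``(observed, p, permuted_statistics)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = float(statistic(features))
    if not np.isfinite(observed):
        raise ValueError("statistic is not finite on the observed features")
    rng = np.random.default_rng(seed)
    offsets = rng.integers(0, genome_length, size=n_perm)
    perm_stats = np.empty(n_perm)
    for i, off in enumerate(offsets):
        stat = float(statistic(features.shifted(int(off), genome_length)))
        if not np.isfinite(stat):
            raise ValueError(f"statistic not finite on permutation {i} (offset {off})")
        perm_stats[i] = stat
    p = (1.0 + float(np.sum(perm_stats >= observed))) / (1.0 + n_perm)
    return observed, p, perm_stats


def merge_overlapping(
    intervals: Iterable[GenomicInterval],
    genome_length: int,
    bookended: bool = True,
) -> list[GenomicInterval]:
    """Merge overlapping (and, optionally, bookended) intervals circularly."""
    ivs = list(intervals)
    if not ivs:
        return []
    chrom = ivs[0].chrom_id
    mask = np.zeros(genome_length, dtype=bool)
    for iv in ivs:
        for s, e in iv.segments(genome_length):
            mask[s:e] = True
    if not bookended:
        # bp-mask merging is inherently bookend-merging; callers wanting
        # strict-overlap-only semantics should not use the mask route
        raise NotImplementedError("mask-based merging always merges bookended intervals")
    return mask_to_intervals(mask, chrom, circular=True)


def mask_to_intervals(
    mask: np.ndarray, chrom_id: str, circular: bool = True
) -> list[GenomicInterval]:
    """Convert a boolean bp mask into intervals, wrapping across the origin."""
    n = len(mask)
    if mask.all():
        return [GenomicInterval(chrom_id, 0, n)]
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.where(diff == 1)[0]
    ends = np.where(diff == -1)[0]
    out = [GenomicInterval(chrom_id, int(s), int(e)) for s, e in zip(starts, ends)]
    if circular and len(out) >= 2 and out[0].start == 0 and out[-1].end == n:
        first, last = out[0], out[-1]
        out = out[1:-1] + [GenomicInterval(chrom_id, last.start, first.end)]
    return out
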