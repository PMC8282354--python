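"""Motif-discovery dataset construction, decoys and regulon assignment.

Motif discovery itself (FIRE-style mutual-information search, motif
comparison, genome scanning) is performed by external tools; this module
builds their inputs and consumes their outputs:

* a scored sequence dataset: peak sequences labeled with their discrete
  occupancy score, plus 3x as many length-matched background sequences
  drawn from the unbound portion of the genome, scored 0;
* decoy datasets in which the peak coordinates are circularly rotated by a
  random offset relative to the genome sequence, preserving the
  correlation structure of the peaks while destroying their sequence
  association — the count of motifs "discovered" in decoys bounds the
  false-discovery rate;
* assignment of motif hits to regulons: a transcriptional unit is counted
  as regulated by a motif iff a predicted site lies within 100 bp of its
  annotated transcription start site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .peaks import PeakCall
from .tracks import FeatureSet, GenomicInterval

__all__ = [
    "FireRecord",
    "FireDataset",
    "DecoySet",
    "extract_sequence",
    "build_fire_dataset",
    "make_decoys",
    "motif_fdr",
    "assign_regulons",
]


@dataclass
class FireRecord:
    name: str
    sequence: str
    score: int
    interval: GenomicInterval | None = None


@dataclass
class FireDataset:
    """Scored peak sequences plus score-0 background records."""

    peak_records: list[FireRecord]
    background_records: list[FireRecord]

    def write(self, path: str | Path) -> None:
        """FIRE-style two-column text: sequence name/sequence and score."""
        with open(path, "w") as fh:
            fh.write("seq\tscore\n")
            for rec in self.peak_records + self.background_records:
                fh.write(f"{rec.sequence}\t{rec.score}\n")


@dataclass
class DecoySet:
    offsets: list[int]
    datasets: list[FireDataset] = field(default_factory=list)
    peak_sets: list[list[PeakCall]] = field(default_factory=list)


def extract_sequence(genome: str, interval: GenomicInterval) -> str:
    """Sequence of an interval, wrapping across the origin if needed."""
    L = len(genome)
    return "".join(genome[s:e] for s, e in interval.segments(L))


def build_fire_dataset(
    peaks: list[PeakCall],
    genome: str,
    bg_multiple: int = 3,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> FireDataset:
    """Peak sequences with discrete scores and length-matched background.

    Background sampling draws uniform random start positions and rejects
    any candidate overlapping a peak, producing ``bg_multiple`` background
    records per peak with exactly the peak's length (the background length
    distribution is the peak length multiset repeated ``bg_multiple``
    times). Peaks must be scored (run ``score_peaks`` first); peaks with
    negative discrete scores are assumed to have been dropped already.
    """
    L = len(genome)
    rng = np.random.default_rng(seed)
    peak_mask = np.zeros(L, dtype=bool)
    for pk in peaks:
        if pk.discrete_score is None:
            raise ValueError("peaks must be scored before dataset construction")
        for s, e in pk.interval.segments(L):
            peak_mask[s:e] = True
    peak_records = [
        FireRecord(
            name=f"peak_{i}",
            sequence=extract_sequence(genome, pk.interval),
            score=int(pk.discrete_score),
            interval=pk.interval,
        )
        for i, pk in enumerate(peaks)
    ]
    background_records: list[FireRecord] = []
    for i, pk in enumerate(peaks):
        length = pk.interval.length(L)
        for j in range(bg_multiple):
            iv = _sample_background(rng, peak_mask, length, L, pk.interval.chrom_id, max_attempts)
            background_records.append(
                FireRecord(
                    name=f"bg_{i}_{j}",
                    sequence=extract_sequence(genome, iv),
                    score=0,
                    interval=iv,
                )
            )
    return FireDataset(peak_records, background_records)


def _sample_background(
    rng: np.random.Generator,
    peak_mask: np.ndarray,
    length: int,
    L: int,
    chrom: str,
    max_attempts: int,
) -> GenomicInterval:
    for _ in range(max_attempts):
        start = int(rng.integers(0, L))
        end = start + length
        iv = GenomicInterval(chrom, start, end if end <= L else end - L)
        if not any(peak_mask[s:e].any() for s, e in iv.segments(L)):
            return iv
    raise RuntimeError(
        f"could not place a {length}-bp background region outside peaks "
        f"after {max_attempts} attempts; peak coverage too dense"
    )


def make_decoys(
    peaks: list[PeakCall],
    genome_length: int,
    n: int = 20,
    seed: int = 0,
    genome: str | None = None,
    bg_multiple: int = 3,
) -> DecoySet:
    """Circular-permutation decoy peak sets (and datasets, given a genome).

    Each decoy shifts every peak coordinate by one uniform random offset
    modulo the genome length — equivalently, the genome sequence is rotated
    relative to the peak calls — preserving peak count, lengths and spacing
    while scrambling the underlying sequence. When ``genome`` is provided,
    a full scored dataset (with fresh background sampling) is rebuilt for
    each decoy.
    """
    if n < 1:
        raise ValueError("need at least one decoy")
    rng = np.random.default_rng(seed)
    offsets = [int(o) for o in rng.integers(0, genome_length, size=n)]
    decoys = DecoySet(offsets=offsets)
    from dataclasses import replace

    for i, off in enumerate(offsets):
        shifted = [
            replace(
                pk,
                interval=pk.interval.shifted(off, genome_length),
                raw_interval=pk.raw_interval.shifted(off, genome_length),
                apex_bp=(pk.apex_bp + off) % genome_length,
            )
            for pk in peaks
        ]
        decoys.peak_sets.append(shifted)
        if genome is not None:
            decoys.datasets.append(
                build_fire_dataset(
                    shifted, genome, bg_multiple=bg_multiple, seed=seed + 1 + i
                )
            )
    return decoys


def motif_fdr(real_count: int, decoy_counts: list[int]) -> float:
    """FDR estimate: worst decoy motif count over the real motif count.

    ``max(decoy_counts) / max(real_count, 1)``; with no real discoveries
    the denominator is clamped to 1 (degenerate, flagged by callers).
    """
    if real_count < 0:
        raise ValueError("real_count must be >= 0")
    if not decoy_counts:
        raise ValueError("need at least one decoy count")
    return max(decoy_counts) / max(real_count, 1)


def _circular_gap(iv: GenomicInterval, pos: int, L: int) -> int:
    """Minimum bp separation between an interval and a point (0 if inside)."""
    for s, e in iv.segments(L):
        if s <= pos < e:
            return 0
    best = L
    for s, e in iv.segments(L):
        for edge in (s, e - 1):
            d = abs(edge - pos) % L
            best = min(best, d, L - d)
    return best


def assign_regulons(
    motif_hits: FeatureSet,
    tss: FeatureSet,
    genome_length: int,
    window_bp: int = 100,
    tss_genes: dict[str, set[str]] | None = None,
) -> dict[str, set[str]]:
    """Map each motif to the genes of TUs whose TSS lies within 100 bp.

    ``motif_hits`` names identify motifs; ``tss`` names identify
    transcriptional units, with TSS position taken as the interval start.
    ``tss_genes`` maps TU name -> gene set (defaults to the TU name
    itself). Distance is the minimum circular bp separation between the hit
    interval and the TSS position, 0 if the hit overlaps the TSS; a TU is
    included iff distance <= window_bp.
    """
    if tss_genes is None:
        tss_genes = {name: {name} for name in tss.names}
    regulons: dict[str, set[str]] = {}
    for hit_iv, motif in zip(motif_hits.intervals, motif_hits.names):
        genes = regulons.setdefault(motif, set())
        for tss_iv, tu in zip(tss.intervals, tss.names):
            d = _circular_gap(hit_iv, tss_iv.start, genome_length)
            if d <= window_bp:
                genes |= tss_genes.get(tu, {tu})
    return regulons
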