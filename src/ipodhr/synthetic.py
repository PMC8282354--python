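"""Synthetic occupancy-profiling conditions with planted ground truth.

The generator emulates the statistical structure the pipeline assumes on a
circular bacterial chromosome, so every stage is testable without real
sequencing data:

* a smooth ori-to-ter DNA copy-number gradient (more DNA near the
  replication origin in growing cells);
* log-normal, bin-independent replicate noise;
* narrow RNA-polymerase peaks present in both the interphase (IPOD) and
  RNAP ChIP tracks, coupled through a slope ``s_true``;
* narrow transcription-factor peaks and kilobase-scale high-occupancy
  plateaus (EPODs) present in the interphase track only.

In the (chip_log2, ipod_log2) plane this reproduces the three-population
geometry the subtraction model relies on: RNAP-bound bins fall on a line
through the origin, TF/EPOD bins lie above it, background sits at the
origin.

Per-bin tracks for one condition::

    input = gradient * noise
    chip  = gradient * (1 + rnap(x)) * noise
    ipod  = gradient * (1 + s_true * rnap(x) + tf(x) + epod(x)) * noise

where ``rnap``, ``tf`` and ``epod`` are flat-topped profiles: each planted
feature contributes its amplitude uniformly across its footprint (protein
contact is modeled as saturated within a bound site or transcription
unit), and each replicate draws independent log-normal noise of scale
``noise_sigma``. Fragment-level output draws Poisson fragment counts with
intensity proportional to the track and fragment lengths uniform in
50-200 bp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .normalize import ConditionBundle
from .quantify import FragmentSet
from .tracks import FeatureSet, GenomeTrack, GenomicInterval, write_features

__all__ = [
    "PlantedFeature",
    "SyntheticTruth",
    "default_truth",
    "generate_condition",
    "planted_z_track",
    "random_genome_sequence",
    "truth_vs_called",
]

DEFAULT_NOISE_SIGMA = 0.05  # log-scale; ~5% CV, typical of deep coverage at 5-bp bins


@dataclass
class PlantedFeature:
    """One planted signal feature with a multiplicative amplitude.

    ``start``/``end`` delimit the occupancy footprint; the amplitude is
    applied uniformly across it. ``on_conditions`` empty means the feature
    is active in every condition.
    """

    start: int
    end: int
    amplitude: float
    kind: str  # {"tf", "rnap", "epod"}
    on_conditions: frozenset[str] = frozenset()

    def active_in(self, condition: str) -> bool:
        return not self.on_conditions or condition in self.on_conditions


@dataclass
class SyntheticTruth:
    """Complete description of one synthetic study design."""

    genome_length: int = 500_000
    resolution: int = 5
    ori_position: int = 0
    gradient_fold: float = 2.0
    coupling_slope: float = 1.0
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    features: list[PlantedFeature] = field(default_factory=list)
    chrom_id: str = "synthetic_chrom"

    def __post_init__(self) -> None:
        if self.gradient_fold < 1:
            raise ValueError("gradient_fold must be >= 1")
        self._check_disjoint()

    def _check_disjoint(self) -> None:
        mask = np.zeros(self.genome_length, dtype=np.uint8)
        for f in self.features:
            iv = GenomicInterval(self.chrom_id, f.start % self.genome_length, f.end % self.genome_length or self.genome_length)
            for s, e in iv.segments(self.genome_length):
                mask[s:e] += 1
        if (mask > 1).any():
            pos = int(np.argmax(mask > 1))
            raise ValueError(f"planted features overlap near bp {pos}")

    def bin_mask(self, kind: str, condition: str | None = None) -> np.ndarray:
        """Boolean per-bin mask of planted features, by bin center.

        Matches the generator's own rule: a bin carries a feature's
        amplitude iff its center lies inside the footprint.
        """
        n_bins = -(-self.genome_length // self.resolution)
        x = (np.arange(n_bins) + 0.5) * self.resolution
        mask = np.zeros(n_bins, dtype=bool)
        for f in self.features:
            if f.kind != kind or (condition is not None and not f.active_in(condition)):
                continue
            mask |= (x >= f.start) & (x < f.end)
        return mask

    def feature_set(self, kind: str, condition: str | None = None) -> FeatureSet:
        chosen = [
            f
            for f in self.features
            if f.kind == kind and (condition is None or f.active_in(condition))
        ]
        return FeatureSet(
            intervals=[GenomicInterval(self.chrom_id, f.start, f.end) for f in chosen],
            scores=[f.amplitude for f in chosen],
            names=[f"{kind}_{i}" for i in range(len(chosen))],
            sources=["truth"] * len(chosen),
        )

    def write(self, out_dir: str | Path, condition: str | None = None) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {
            "genome_length": self.genome_length,
            "resolution": self.resolution,
            "ori_position": self.ori_position,
            "gradient_fold": self.gradient_fold,
            "coupling_slope": self.coupling_slope,
            "noise_sigma": self.noise_sigma,
            "n_features": len(self.features),
        }
        (out / "truth.json").write_text(json.dumps(meta, indent=2))
        for kind in ("tf", "rnap", "epod"):
            fs = self.feature_set(kind, condition)
            if len(fs):
                write_features(fs, out / f"truth_{kind}.gff", "gff3", feature_type=kind)


def default_truth(
    seed: int = 0,
    genome_length: int = 500_000,
    n_tf: int = 30,
    n_rnap: int = 40,
    n_epod: int = 6,
    tf_amplitude: float = 3.0,
    rnap_amplitude: float = 4.0,
    epod_amplitude: float = 1.5,
    conditions: tuple[str, ...] = (),
    condition_specific_tf_frac: float = 0.5,
    **kwargs,
) -> SyntheticTruth:
    """Scatter non-overlapping TF peaks, RNAP peaks and EPOD plateaus.

    TF and RNAP footprints are 100-200 bp; plateaus are 1.5-3 kb. With
    ``conditions`` given, a fraction of TF peaks is switched on in a random
    subset of conditions (occupancy dynamics); everything else is always on.
    """
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(genome_length=genome_length, **kwargs)
    occupied = np.zeros(genome_length, dtype=bool)

    def place(length: int, margin: int = 500) -> int | None:
        for _ in range(1000):
            start = int(rng.integers(margin, genome_length - length - margin))
            if not occupied[start - margin : start + length + margin].any():
                occupied[start : start + length] = True
                return start
        return None

    feats: list[PlantedFeature] = []
    for _ in range(n_epod):
        length = int(rng.integers(1500, 3001))
        s = place(length)
        if s is not None:
            feats.append(PlantedFeature(s, s + length, epod_amplitude, "epod"))
    for _ in range(n_rnap):
        length = int(rng.integers(100, 201))
        s = place(length)
        if s is not None:
            feats.append(PlantedFeature(s, s + length, rnap_amplitude, "rnap"))
    for _ in range(n_tf):
        length = int(rng.integers(100, 201))
        s = place(length)
        if s is None:
            continue
        on: frozenset[str] = frozenset()
        if len(conditions) > 1 and rng.random() < condition_specific_tf_frac:
            k = int(rng.integers(1, len(conditions)))
            on = frozenset(rng.choice(conditions, size=k, replace=False).tolist())
        feats.append(PlantedFeature(s, s + length, tf_amplitude, "tf", on))
    truth.features = feats
    return truth


def _gradient(truth: SyntheticTruth, x: np.ndarray) -> np.ndarray:
    theta = 2.0 * np.pi * (x - truth.ori_position) / truth.genome_length
    return 1.0 + (truth.gradient_fold - 1.0) * (np.cos(theta) + 1.0) / 2.0


def _bump_profile(truth: SyntheticTruth, x: np.ndarray, kind: str, condition: str) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    for f in truth.features:
        if f.kind != kind or not f.active_in(condition):
            continue
        out[(x >= f.start) & (x < f.end)] += f.amplitude
    return out


def _expected_tracks(truth: SyntheticTruth, condition: str) -> dict[str, np.ndarray]:
    n_bins = -(-truth.genome_length // truth.resolution)
    x = (np.arange(n_bins) + 0.5) * truth.resolution
    grad = _gradient(truth, x)
    rnap = _bump_profile(truth, x, "rnap", condition)
    tf = _bump_profile(truth, x, "tf", condition)
    epod = _bump_profile(truth, x, "epod", condition)
    return {
        "input": grad,
        "chip": grad * (1.0 + rnap),
        "ipod": grad * (1.0 + truth.coupling_slope * rnap + tf + epod),
    }


def generate_condition(
    truth: SyntheticTruth,
    condition: str = "cond",
    n_replicates: int | dict[str, int] = 2,
    output: str = "tracks",
    seed: int = 0,
    mean_fragments: int = 200_000,
) -> ConditionBundle | tuple[ConditionBundle, dict[str, list[FragmentSet]]]:
    """Generate raw replicate tracks (or fragments) for one condition.

    With ``output="tracks"`` returns a :class:`ConditionBundle` of raw
    (unnormalized) replicate tracks. With ``output="fragments"`` also
    returns per-type fragment sets whose Poisson sampling intensity is
    proportional to the expected track, with fragment lengths uniform in
    50-200 bp; the bundle then holds tracks quantified from those
    fragments. Fixed seeds give bit-identical output.
    """
    rng = np.random.default_rng(seed)
    expected = _expected_tracks(truth, condition)
    if isinstance(n_replicates, int):
        n_replicates = {t: n_replicates for t in ("input", "ipod", "chip")}
    tracks: dict[str, list[GenomeTrack]] = {}
    fragments: dict[str, list[FragmentSet]] = {}
    for sample_type in ("input", "ipod", "chip"):
        tracks[sample_type] = []
        fragments[sample_type] = []
        for _ in range(n_replicates[sample_type]):
            if output == "tracks":
                noise = np.exp(truth.noise_sigma * rng.standard_normal(len(expected[sample_type]))) if truth.noise_sigma > 0 else 1.0
                vals = expected[sample_type] * noise
                tracks[sample_type].append(
                    GenomeTrack(truth.chrom_id, truth.genome_length, truth.resolution, vals)
                )
            elif output == "fragments":
                frags = _sample_fragments(truth, expected[sample_type], mean_fragments, rng)
                fragments[sample_type].append(frags)
                from .quantify import fragment_occupancy

                tracks[sample_type].append(fragment_occupancy(frags, truth.resolution))
            else:
                raise ValueError(f"unknown output mode {output!r}")
    bundle = ConditionBundle(
        condition=condition,
        input=tracks["input"],
        ipod=tracks["ipod"],
        chip=tracks["chip"],
    )
    if output == "fragments":
        return bundle, fragments
    return bundle


def _sample_fragments(
    truth: SyntheticTruth,
    intensity: np.ndarray,
    mean_fragments: int,
    rng: np.random.Generator,
) -> FragmentSet:
    n_frag = int(rng.poisson(mean_fragments))
    p = intensity / intensity.sum()
    centers_bin = rng.choice(len(intensity), size=n_frag, p=p)
    centers = centers_bin * truth.resolution + rng.integers(0, truth.resolution, size=n_frag)
    lengths = rng.integers(50, 201, size=n_frag)
    L = truth.genome_length
    frags = []
    for c, ln in zip(centers, lengths):
        start = int((c - ln // 2) % L)
        end = start + int(ln)
        frags.append(GenomicInterval(truth.chrom_id, start, end if end <= L else end - L))
    return FragmentSet(frags, L, truth.chrom_id)


def planted_z_track(
    genome_length: int,
    resolution: int = 5,
    peaks: list[tuple[int, int, float]] | None = None,
    plateaus: list[tuple[int, int, float]] | None = None,
    seed: int = 0,
    chrom_id: str = "synthetic_chrom",
) -> GenomeTrack:
    """Unit-normal noise track with planted Gaussian bumps and plateaus.

    ``peaks`` entries are (center_bp, width_bp, amplitude) with the width
    taken as the 4-sigma footprint; ``plateaus`` entries are
    (start_bp, end_bp, amplitude) boxes. Used to exercise the peak and
    EPOD callers directly on the robust-z scale.
    """
    rng = np.random.default_rng(seed)
    n_bins = -(-genome_length // resolution)
    vals = rng.standard_normal(n_bins)
    x = (np.arange(n_bins) + 0.5) * resolution
    for center, width_bp, amp in peaks or []:
        sigma = width_bp / 4.0
        d = x - center
        half = genome_length / 2.0
        d = np.where(d > half, d - genome_length, d)
        d = np.where(d < -half, d + genome_length, d)
        vals += amp * np.exp(-0.5 * (d / sigma) ** 2)
    for s, e, amp in plateaus or []:
        vals[(x >= s) & (x < e)] += amp
    return GenomeTrack(chrom_id, genome_length, resolution, vals)


def random_genome_sequence(genome_length: int, seed: int = 0) -> str:
    """Uniform-random ACGT sequence for motif dataset tests."""
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=genome_length)])


def truth_vs_called(
    truth_features: FeatureSet,
    called: FeatureSet,
    genome_length: int,
    min_reciprocal_overlap: float = 0.5,
) -> tuple[float, float, float]:
    """Interval-level recall/precision and bp-level Jaccard vs. truth.

    A truth feature is recovered (and a call correct) when some
    truth/called pair overlaps by at least ``min_reciprocal_overlap`` of
    BOTH intervals' lengths. Precision for an empty call set is reported
    as 0.0 (degenerate).
    """
    t_mask = truth_features.to_mask(genome_length)
    c_mask = called.to_mask(genome_length)
    union = (t_mask | c_mask).sum()
    jaccard = float((t_mask & c_mask).sum() / union) if union else 1.0

    def matched(a: GenomicInterval, bs: FeatureSet) -> bool:
        la = a.length(genome_length)
        amask = np.zeros(genome_length, dtype=bool)
        for s, e in a.segments(genome_length):
            amask[s:e] = True
        for b in bs.intervals:
            lb = b.length(genome_length)
            inter = sum(int(amask[s:e].sum()) for s, e in b.segments(genome_length))
            if inter >= min_reciprocal_overlap * la and inter >= min_reciprocal_overlap * lb:
                return True
        return False

    recall = (
        sum(matched(t, called) for t in truth_features.intervals) / len(truth_features)
        if len(truth_features)
        else 1.0
    )
    precision = (
        sum(matched(c, truth_features) for c in called.intervals) / len(called)
        if len(called)
        else 0.0
    )
    return float(recall), float(precision), jaccard
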