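"""End-to-end per-condition workflow and multi-condition analyses.

`run_condition` executes quantify -> normalize -> RNAP subtraction ->
peak calling -> EPOD calling for one condition and writes every track,
feature file and a JSON run report. `run_multi` adds the cross-condition
analyses: TF occupancy matrix with consensus clustering, EPOD overlap and
containment matrices, and motif-discovery exports.

All randomness flows from explicit seeds in the config; reruns with the
same config are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import epods as epods_mod
from . import peaks as peaks_mod
from .chipsub import ScoredProfile, replicate_extreme_interval, score_profile
from .normalize import ConditionBundle, normalize_condition
from .quantify import fragment_occupancy, read_fragments_bed
from .tracks import FeatureSet, read_features, read_track, write_features, write_track

__all__ = ["RunConfig", "StageError", "run_condition", "run_multi", "DEFAULT_PARAMS"]

DEFAULT_PARAMS: dict[str, Any] = {
    "resolution": 5,
    "n_knots": 4,
    "pseudocount": 0.0,
    "top_frac": 0.02,
    "cover_frac": 0.95,
    "widths_bp": list(peaks_mod.DEFAULT_WIDTHS_BP),
    "snr_thresholds": [2, 3, 4, 6, 8, 10],
    "pad_bp": 30,
    "epod_strict_k": 90.0,
    "epod_relaxed_k": 75.0,
    "tf_score_floor": 0.01,
    "detectability_z": 3.0,
    "n_boot": 1000,
    "cluster_n_runs": 100,
    "cluster_k_range": [8, 9, 10, 11, 12],
    "cluster_n_final": 10,
    "n_decoys": 20,
    "bg_multiple": 3,
    "tss_window_bp": 100,
    "seed": 0,
}


class StageError(RuntimeError):
    """Pipeline failure tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Structured run configuration.

    ``conditions`` maps condition name -> {"input": [paths], "ipod": [...],
    "chip": [...], "format": "bedgraph"|"fragments"}. Every parameter has
    an explicit default in :data:`DEFAULT_PARAMS`; seeds are always
    explicit (no wall-clock seeding).
    """

    genome_length: int
    conditions: dict[str, dict]
    output_dir: str = "ipodhr_out"
    chrom_id: str = "chrom"
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged
        for cond, manifest in self.conditions.items():
            for st in ("input", "ipod", "chip"):
                for path in manifest.get(st, []):
                    if not Path(path).exists():
                        raise FileNotFoundError(f"condition {cond!r}: missing file {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            genome_length=int(doc["genome_length"]),
            conditions=doc["conditions"],
            output_dir=doc.get("output_dir", "ipodhr_out"),
            chrom_id=doc.get("chrom_id", "chrom"),
            params=doc.get("params", {}),
        )


def _load_replicates(
    manifest: dict, sample_type: str, config: RunConfig
) -> list:
    paths = manifest.get(sample_type, [])
    fmt = manifest.get("format", "bedgraph")
    res = config.params["resolution"]
    tracks = []
    for path in paths:
        if fmt == "bedgraph":
            tracks.append(
                read_track(path, config.genome_length, res, chrom_id=None)
            )
        elif fmt == "fragments":
            frags = read_fragments_bed(path, config.genome_length)
            tracks.append(fragment_occupancy(frags, res))
        else:
            raise ValueError(f"unknown input format {fmt!r}")
    return tracks


def run_condition(
    config: RunConfig,
    condition: str,
    write_outputs: bool = True,
    keep_intermediates: bool = False,
    replicate_intervals: bool = False,
) -> tuple[ScoredProfile, dict]:
    """Full single-condition chain; returns the scored profile and report."""
    if condition not in config.conditions:
        raise StageError("manifest", f"unknown condition {condition!r}")
    manifest = config.conditions[condition]
    p = config.params
    out_dir = Path(config.output_dir) / condition
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)

    try:
        bundle = ConditionBundle(
            condition=condition,
            input=_load_replicates(manifest, "input", config),
            ipod=_load_replicates(manifest, "ipod", config),
            chip=_load_replicates(manifest, "chip", config),
        )
    except Exception as exc:
        raise StageError("quantify", str(exc)) from exc

    try:
        bundle = normalize_condition(
            bundle, n_knots=p["n_knots"], pseudocount=p["pseudocount"]
        )
    except Exception as exc:
        raise StageError("normalize", str(exc)) from exc

    try:
        profile = score_profile(
            bundle.ipod_log2, bundle.chip_log2, p["top_frac"], p["cover_frac"]
        )
        if replicate_intervals:
            lo, hi = replicate_extreme_interval(
                bundle, p["top_frac"], p["cover_frac"], p["pseudocount"]
            )
            profile.replicate_lo = lo
            profile.replicate_hi = hi
    except Exception as exc:
        raise StageError("chipsub", str(exc)) from exc

    try:
        calls = peaks_mod.call_peaks_cwt(
            profile.robust_z,
            widths_bp=tuple(p["widths_bp"]),
            snr_thresholds=tuple(p["snr_thresholds"]),
            pad_bp=p["pad_bp"],
        )
        calls = peaks_mod.score_peaks(calls, profile.robust_z)
    except Exception as exc:
        raise StageError("peaks", str(exc)) from exc

    try:
        epod_sets = epods_mod.call_epods_both(
            profile.robust_z, p["epod_strict_k"], p["epod_relaxed_k"]
        )
    except Exception as exc:
        raise StageError("epods", str(exc)) from exc

    report = {
        "condition": condition,
        "genome_length": config.genome_length,
        "resolution": p["resolution"],
        "chipsub_slope": profile.model.slope,
        "chipsub_n_fit_points": profile.model.n_fit_points,
        "n_peaks": len(calls),
        "n_peaks_by_threshold": {
            str(t): len(peaks_mod.peaks_at_threshold(calls, t, config.genome_length))
            for t in p["snr_thresholds"]
        },
        "n_epods_strict": len(epod_sets["strict"]),
        "n_epods_relaxed": len(epod_sets["relaxed"]),
        "seed": p["seed"],
    }

    if write_outputs:
        write_track(profile.chipsub, out_dir / "chipsub.bedgraph")
        write_track(profile.robust_z, out_dir / "robust_z.bedgraph")
        write_track(profile.neglog10p, out_dir / "neglog10p.bedgraph")
        if keep_intermediates:
            for name, track in bundle.averaged.items():
                write_track(track, out_dir / f"averaged_{name}.bedgraph")
            write_track(bundle.spline_track, out_dir / "input_spline.bedgraph")
            write_track(bundle.ipod_log2, out_dir / "ipod_log2.bedgraph")
            write_track(bundle.chip_log2, out_dir / "chip_log2.bedgraph")
        for t in p["snr_thresholds"]:
            tset = peaks_mod.peaks_at_threshold(calls, t, config.genome_length)
            write_features(
                peaks_mod.peaks_to_featureset(tset),
                out_dir / f"peaks_snr{t}.gff",
                "gff3",
                feature_type="occupancy_peak",
            )
        for mode, eps in epod_sets.items():
            write_features(
                epods_mod.epods_to_featureset(eps),
                out_dir / f"epods_{mode}.gff",
                "gff3",
                feature_type="EPOD",
            )
        (out_dir / "run_report.json").write_text(json.dumps(report, indent=2))

    return profile, {"report": report, "bundle": bundle, "peaks": calls, "epods": epod_sets}


def run_multi(
    config: RunConfig,
    conditions: list[str] | None = None,
    sites: FeatureSet | None = None,
    sites_path: str | None = None,
    write_outputs: bool = True,
) -> dict:
    """Score all conditions and run the cross-condition analyses."""
    from . import tf_dynamics as tfd

    if conditions is None:
        conditions = list(config.conditions)
    for c in conditions:
        if c not in config.conditions:
            raise StageError("manifest", f"unknown condition {c!r}")
    if len(conditions) < 2:
        raise StageError("multi", "need at least two conditions")
    p = config.params
    profiles: dict[str, ScoredProfile] = {}
    epod_feature_sets: dict[str, FeatureSet] = {}
    relaxed_sets: dict[str, FeatureSet] = {}
    for cond in conditions:
        profile, extras = run_condition(config, cond, write_outputs=write_outputs)
        profiles[cond] = profile
        epod_feature_sets[cond] = epods_mod.epods_to_featureset(extras["epods"]["strict"])
        relaxed_sets[cond] = epods_mod.epods_to_featureset(extras["epods"]["relaxed"])

    overlap, order = epods_mod.epod_overlap_matrix(epod_feature_sets, config.genome_length)
    containment = np.ones((len(order), len(order)))
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            if i != j:
                containment[i, j] = epods_mod.epod_containment(
                    epod_feature_sets[a], relaxed_sets[b], config.genome_length
                )

    results: dict[str, Any] = {
        "profiles": profiles,
        "epod_overlap": (overlap, order),
        "epod_containment": (containment, order),
    }

    if sites is None and sites_path is not None:
        sites = read_features(sites_path, "tsv", genome_length=config.genome_length)
    if sites is not None:
        merged = tfd.merge_tf_sites(sites, config.genome_length)
        table = tfd.site_occupancy(profiles, merged, config.genome_length)
        matrix = tfd.tf_condition_score(
            table, floor=p["tf_score_floor"], z_threshold=p["detectability_z"]
        )
        clustering = None
        if len(matrix.normalized.dropna()) >= p["cluster_n_final"]:
            clustering = tfd.consensus_cluster(
                matrix,
                n_runs=p["cluster_n_runs"],
                k_range=tuple(p["cluster_k_range"]),
                n_final=p["cluster_n_final"],
                seed=p["seed"],
            )
        results["site_table"] = table
        results["tf_matrix"] = matrix
        results["clustering"] = clustering
        if write_outputs:
            out = Path(config.output_dir)
            matrix.scores.to_csv(out / "tf_scores.tsv", sep="\t")
            matrix.normalized.to_csv(out / "tf_scores_normalized.tsv", sep="\t")
            if clustering is not None:
                clustering.kappa.to_csv(out / "tf_kappa.tsv", sep="\t")
                clustering.labels.to_csv(out / "tf_clusters.tsv", sep="\t")
    return results
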