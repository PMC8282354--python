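"""Condition-resolved transcription-factor occupancy dynamics.

Annotated binding sites (RegulonDB-style tables) are summarized per site
and condition by the maximum occupancy (-log10 p) within the site — the
peak of the binding signal. A TF's condition score is the geometric mean
of its site-level occupancies (floored at 0.01); dividing each TF's row by
its maximum across conditions yields a normalized activity profile on
(0, 1]. Profiles are grouped by consensus clustering: repeated seeded
K-means runs over a range of cluster counts define a co-clustering
frequency kappa per TF pair, and 1-kappa is the distance for a final
agglomerative clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans

from .chipsub import ScoredProfile
from .tracks import FeatureSet, GenomicInterval, mask_to_intervals

__all__ = [
    "TFSiteTable",
    "TFOccupancyMatrix",
    "ConsensusClustering",
    "merge_tf_sites",
    "site_occupancy",
    "tf_condition_score",
    "bootstrap_site_ci",
    "consensus_cluster",
    "jaccard_regulons",
    "DETECTABILITY_Z",
]

DETECTABILITY_Z = 3.0


@dataclass
class TFSiteTable:
    """Per-site occupancy across conditions.

    ``table`` columns: tf, start, end, then ``occ_<cond>`` (-log10 p) and
    ``z_<cond>`` (robust z) per condition. Overlapping or bookended sites
    of the same TF must be merged beforehand (see :func:`merge_tf_sites`).
    """

    table: pd.DataFrame
    conditions: list[str] = field(default_factory=list)

    def detectable(self, z_threshold: float = DETECTABILITY_Z) -> pd.Series:
        """Site is detectable iff its max robust z over conditions exceeds z_threshold."""
        zcols = [f"z_{c}" for c in self.conditions]
        return self.table[zcols].max(axis=1) > z_threshold


@dataclass
class TFOccupancyMatrix:
    """TF x condition geometric-mean scores and normalized profiles."""

    scores: pd.DataFrame
    normalized: pd.DataFrame
    detectable_sites: pd.Series


@dataclass
class ConsensusClustering:
    """Co-clustering frequencies and final cluster labels."""

    kappa: pd.DataFrame
    labels: pd.Series
    n_runs_total: int


def merge_tf_sites(sites: FeatureSet, genome_length: int) -> FeatureSet:
    """Merge overlapping or bookended sites of the same TF (by name)."""
    by_tf: dict[str, list[GenomicInterval]] = {}
    for iv, name in zip(sites.intervals, sites.names):
        by_tf.setdefault(name, []).append(iv)
    intervals: list[GenomicInterval] = []
    names: list[str] = []
    for tf, ivs in by_tf.items():
        mask = np.zeros(genome_length, dtype=bool)
        for iv in ivs:
            for s, e in iv.segments(genome_length):
                mask[s:e] = True
        for merged in mask_to_intervals(mask, ivs[0].chrom_id, circular=True):
            intervals.append(merged)
            names.append(tf)
    return FeatureSet(intervals=intervals, names=names)


def _site_max(track_values: np.ndarray, iv: GenomicInterval, genome_length: int, res: int) -> float:
    bins: list[int] = []
    n_bins = len(track_values)
    for s, e in iv.segments(genome_length):
        bins.extend(range(s // res, min((e - 1) // res + 1, n_bins)))
    vals = track_values[np.asarray(bins, dtype=int)]
    if not np.isfinite(vals).any():
        return float("nan")
    return float(np.nanmax(vals))


def site_occupancy(
    profiles: dict[str, ScoredProfile], sites: FeatureSet, genome_length: int
) -> TFSiteTable:
    """Summarize each merged site by its maximum occupancy per condition.

    Occupancy is the maximum -log10 p within the site; the per-condition
    maximum robust z is kept alongside for detectability calls. Sites that
    are entirely missing in a condition get NaN there and are excluded from
    downstream scores.
    """
    conditions = list(profiles)
    rows = []
    for iv, name in zip(sites.intervals, sites.names):
        row: dict = {"tf": name, "start": iv.start, "end": iv.end}
        for cond, prof in profiles.items():
            res = prof.neglog10p.resolution
            row[f"occ_{cond}"] = _site_max(prof.neglog10p.values, iv, genome_length, res)
            row[f"z_{cond}"] = _site_max(prof.robust_z.values, iv, genome_length, res)
        rows.append(row)
    return TFSiteTable(pd.DataFrame(rows), conditions)


def tf_condition_score(
    table: TFSiteTable,
    floor: float = 0.01,
    detectable_only: bool = True,
    z_threshold: float = DETECTABILITY_Z,
) -> TFOccupancyMatrix:
    """Geometric-mean TF scores per condition and row-normalized profiles.

    Each site-level occupancy is floored at ``floor`` before the geometric
    mean, so a TF's score is strictly positive. Normalization divides each
    TF row by its maximum across conditions (row maxima = 1).
    """
    df = table.table
    detectable = table.detectable(z_threshold)
    used = df[detectable] if detectable_only else df
    if used.empty:
        raise ValueError("no usable sites after detectability filtering")
    records = {}
    for tf, grp in used.groupby("tf"):
        scores = []
        for cond in table.conditions:
            occ = grp[f"occ_{cond}"].to_numpy(dtype=float)
            occ = occ[np.isfinite(occ)]
            if len(occ) == 0:
                scores.append(np.nan)
                continue
            floored = np.maximum(occ, floor)
            scores.append(float(np.exp(np.mean(np.log(floored)))))
        records[tf] = scores
    scores_df = pd.DataFrame.from_dict(records, orient="index", columns=table.conditions)
    scores_df.index.name = "tf"
    row_max = scores_df.max(axis=1)
    normalized = scores_df.div(row_max, axis=0)
    return TFOccupancyMatrix(scores_df, normalized, detectable)


def bootstrap_site_ci(
    site_values: np.ndarray,
    site_ranges: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    floor: float = 0.01,
    log_scale_normal: bool = False,
) -> tuple[float, float]:
    """Parametric-bootstrap 95% CI for a TF's mean site occupancy.

    Each site's occupancy is resampled from a log-normal distribution whose
    arithmetic mean equals the observed value and whose arithmetic standard
    deviation equals one quarter of the replicate-extreme range (the
    pessimistic replicate interval is treated as spanning roughly 95% of
    plausible values). The TF-level geometric mean (with floor) is
    recomputed per bootstrap replicate; the 2.5 and 97.5 percentiles are
    returned. Zero ranges give degenerate (zero-width) contributions.

    With ``log_scale_normal`` the observed mean/sd are instead placed on the
    log scale directly (a documented alternative parameterization).
    """
    values = np.asarray(site_values, dtype=float)
    ranges = np.asarray(site_ranges, dtype=float)
    if values.shape != ranges.shape:
        raise ValueError("site_values and site_ranges must have equal shape")
    if np.any(ranges < 0):
        raise ValueError("ranges must be non-negative")
    m = np.maximum(values, floor)
    s = ranges / 4.0
    rng = np.random.default_rng(seed)
    n_sites = len(values)
    if log_scale_normal:
        mu = np.log(m)
        sigma = np.where(m > 0, s / m, 0.0)
    else:
        sigma2 = np.log1p((s / m) ** 2)
        sigma = np.sqrt(sigma2)
        mu = np.log(m) - sigma2 / 2.0
    draws = np.exp(mu + sigma * rng.standard_normal(size=(n_boot, n_sites)))
    draws = np.maximum(draws, floor)
    boot_means = np.exp(np.mean(np.log(draws), axis=1))
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    return float(lo), float(hi)


def consensus_cluster(
    matrix: TFOccupancyMatrix,
    n_runs: int = 100,
    k_range: tuple[int, ...] = (8, 9, 10, 11, 12),
    n_final: int = 10,
    seed: int = 0,
    linkage: str = "average",
) -> ConsensusClustering:
    """Consensus clustering of normalized TF occupancy profiles.

    The profiles are clustered ``n_runs`` times with seeded random-init
    K-means at every k in ``k_range``; kappa(i, j) is the fraction of all
    those runs in which TFs i and j share a cluster (runs pooled across k).
    The final partition is agglomerative clustering on 1-kappa cut at
    ``n_final`` clusters.
    """
    data = matrix.normalized.dropna(axis=0)
    tfs = list(data.index)
    n_tf = len(tfs)
    if n_tf < n_final:
        raise ValueError(f"need at least {n_final} TFs, got {n_tf}")
    X = data.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    co = np.zeros((n_tf, n_tf))
    total = 0
    for k in k_range:
        for _ in range(n_runs):
            km = KMeans(
                n_clusters=k,
                init="random",
                n_init=1,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            labels = km.fit_predict(X)
            same = labels[:, None] == labels[None, :]
            co += same
            total += 1
    kappa = co / total
    np.fill_diagonal(kappa, 1.0)
    agg = AgglomerativeClustering(
        n_clusters=n_final, metric="precomputed", linkage=linkage
    )
    final = agg.fit_predict(1.0 - kappa)
    return ConsensusClustering(
        kappa=pd.DataFrame(kappa, index=tfs, columns=tfs),
        labels=pd.Series(final, index=tfs, name="cluster"),
        n_runs_total=total,
    )


def jaccard_regulons(a: set, b: set) -> float:
    """|a ∩ b| / |a ∪ b|; defined as 0.0 when both sets are empty."""
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)
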