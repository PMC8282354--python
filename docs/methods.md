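# Methods

This note documents the models and procedures implemented in `ipodhr`,
their assumptions, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about behavior on real data.

## Data model

All signal lives on a single circular chromosome, binned at a fixed
resolution (default 5 bp; the last bin may be partial). Missing signal is
NaN and every operation states its missing policy. Internal coordinates
are 0-based half-open; GFF3 (1-based inclusive) is converted only at the
I/O boundary; bedGraph and BED are taken as 0-based half-open. Intervals
may wrap the replication origin and are stored unwrapped as
`start > end`.

Windowed operators (rolling means, the CWT) wrap across the origin.
Window widths in bp are converted to bins with `round()` and forced odd
(+1 if even) so centered windows are symmetric; the canonical
512/256/500-bp windows are not integer multiples of an odd bin count, and
a one-bin widening changes their means negligibly while keeping the
operator translation-equivariant on the circle.

## Quantitation

Each sequenced template fragment contributes total weight 1, spread as
1/length per covered bp; bins partially covered by a fragment receive
weight proportional to the bp overlap. Total track mass therefore equals
the fragment count exactly, and the implementation (difference-array +
cumulative sum) is bit-equivalent to a per-bp loop.

## Normalization

Per condition, in fixed order:

1. **Quantile normalization** across replicates, separately within each
   sample type (input, IPOD, ChIP). The reference distribution is the
   across-track mean of sorted values; ties receive the mean of the
   reference values their ranks span. Scope is within-condition — the
   per-condition reading of the normalization contract — so conditions
   remain independently processable.
2. **Copy-number correction.** A periodic cubic smoothing spline with 4
   evenly spaced knots (at 0, L/4, L/2, 3L/4 — allowing inflections at
   the origin, terminus and midpoints) is fitted to the replicate-averaged
   input track and divided out of every track. With 4 periodic knots the
   spline space has exactly 4 degrees of freedom, so an unpenalized
   least-squares fit is already a maximally smooth low-pass model at
   genomic n; no roughness penalty is applied. The fit is floored at a
   tiny positive epsilon and declared degenerate (error) if more than 1%
   of bins hit the floor. The spline is fitted to the averaged input
   rather than per replicate: the gradient is a property of the culture's
   replication state, not of library noise.
3. **Mean matching** across all tracks of the condition (every track
   scaled to the grand mean of track means).
4. **Replicate averaging** per sample type (missing-aware arithmetic
   mean).
5. **log2 extracted:input ratios** for IPOD and ChIP. The default
   pseudocount is 0: after quantile normalization and mean matching the
   values are strictly positive in practice; a configurable pseudocount
   is available for pathological inputs.

Note that the spline divides the extracted and input tracks identically
and therefore cancels in the log2 ratios; its purpose is to keep the
absolute per-track values (and anything derived from them before the
ratio) free of the ori–ter trend. When the interphase track carries
substantial planted (or real) occupancy mass, mean matching introduces a
small global offset into the log2 ratios; the robust-z standardization
downstream absorbs it.

## RNAP subtraction and scoring

The interphase signal contains RNA polymerase occupancy. The subtraction
model assumes the bins with the very highest ChIP signal are occupied by
RNAP alone, so the IPOD-vs-ChIP relation there calibrates how much
interphase signal one unit of ChIP signal explains.

* Selection: the top `top_frac` (default 0.02) of usable bins ranked by
  ChIP log2 signal; bins with non-positive ChIP inside the selection are
  excluded from the ratio computation (at least 20 must remain).
* Slope: the smallest ratio `r = ipod/chip` in the selection such that at
  least `ceil(cover_frac × n)` ratios are ≤ r — an order statistic, no
  interpolation — i.e. the lowest zero-intercept slope keeping
  `cover_frac` (default 0.95) of the high-ChIP points on or below the
  line. The slope is clamped at ≥ 0.
* Subtraction: `ipod − slope × chip` wherever `chip > 0`; no subtraction
  where observed RNAP occupancy is negative, so correction can only lower
  occupancy. `cover_frac` is deliberately conservative: values near 0.5
  would approximate a direct fit and risk leaving RNAP-driven peaks in
  the signal, values near 1.0 risk erasing genuine protein occupancy.
* Standardization: robust z with the **unscaled** MAD (no 1.4826
  normal-consistency factor), then −log10 one-sided upper-tail p-values
  under a standard-normal null, computed through the log survival
  function so large z-scores keep full precision. The upper tail is used
  because only occupancy enrichment is of interest.
* Replicate-extreme intervals: the full scoring chain is recomputed for
  every combination of one IPOD, one ChIP and one input replicate
  (capped, default 64 combinations) and the per-bin min/max of the
  −log10 p tracks is reported — the scale on which occupancy uncertainty
  is consumed downstream. Only `lo ≤ hi` is guaranteed; the point
  estimate uses replicate-averaged tracks, which no single-replicate
  combination reproduces, so containment is typical but not a theorem.

## Peak calling

Ridge-line CWT detection with Mexican-hat (ricker) wavelets, widths 25 to
125 bp in 5-bp steps (converted to bins at track resolution), circular
convolution. Local maxima per scale are linked from the largest scale
down, with a matching tolerance of a quarter of the current width and a
gap tolerance of 2 skipped scales; ridges shorter than a quarter of the
width ladder are discarded. The apex is the ridge position at the
smallest matched scale; the reported width is the scale of the maximal
ridge coefficient.

The signal-to-noise ratio is the maximal ridge coefficient divided by a
local noise floor: the 90th percentile of |smallest-width coefficients|
in a centered 1,000-bin window. The noise floor quantile is the one knob
whose value was fixed by measurement: a high quantile makes the SNR a
contrast against typical local fluctuation, and on planted-peak tracks
separates genuine binding sites (SNR ≳ 10) from pure-noise ridges
(SNR < 4); low quantiles (e.g. the 10th percentile some CWT peak finders
default to) inflate every ridge's SNR and flood low thresholds with noise
calls. All knobs are exposed on `CwtParams`.

Peak sets are materialized per SNR threshold and are nested by
construction; each call records the strictest ladder threshold its SNR
reaches, and that value is written to the GFF score column. Overlapping
padded peaks within one threshold set are merged (the merged call keeps
the minimum threshold label). Every call is padded 30 bp per side; the
padded interval defines the region used downstream. For motif-dataset
export each peak gets `floor(mean robust-z over the raw interval)` as its
discrete score and negative-score peaks are dropped (they are kept in raw
GFF output).

## EPOD calling

Threshold T is the k-th percentile (linear interpolation, all non-missing
bins) of the 256-bp rolling mean; k = 90 for strict calls, k = 75 for
relaxed. Seeds are maximal regions, at least 1,024 bp long, over which
the 512-bp rolling mean exceeds T at **every overlapping window** — the
run of above-threshold window centers eroded by half a window. Without
the erosion, window spillover at plateau edges would promote sub-minimum
(e.g. 900-bp) plateaus past the length cutoff and systematically inflate
every call by up to half a window per side. Overlapping seeds keep the
highest-mean member (with disjoint maximal runs this is a defensive
no-op).

Each seed is extended bin by bin: at each step the side (left/right)
whose addition yields the higher whole-call mean is taken, ties to the
left; a bin is only added if the whole-call mean stays above T and the
bin's z exceeds 0. Missing bins count as z ≤ 0 and block extension.
Abutting or overlapping calls after extension are reported separately,
never merged, preserving seed identity. Strict calls are in practice a
base-pair subset of relaxed calls; the suite asserts this on random
tracks.

The caller is verified bin-for-bin against an independent brute-force
oracle (explicit-loop rolling means, erosion and extension) on random
structured tracks.

## TF occupancy dynamics

Annotated binding sites are merged per TF when overlapping or bookended.
Each site × condition is summarized by the **maximum** −log10 p within
the site (the peak of the binding footprint); a site is detectable when
its maximum robust z across conditions exceeds 3. A TF's condition score
is the geometric mean of site occupancies floored at 0.01; dividing each
TF's row by its across-condition maximum yields a profile on (0, 1].

Consensus clustering: profiles are clustered `n_runs` = 100 times with
random-initialization K-means at every k in 8–12; κ(i, j) is the fraction
of all 500 runs in which TFs i and j share a cluster (runs pooled across
k — pooling uses every run's evidence and makes κ a single coherent
similarity). The final partition is agglomerative clustering on 1 − κ cut
at 10 clusters, with average linkage (the common choice for consensus
matrices; configurable). All K-means seeds derive from one master seed,
so results are reproducible bit for bit.

Bootstrap CIs: each site's occupancy is resampled from a log-normal whose
**arithmetic** mean equals the observed value and whose arithmetic sd is
a quarter of the replicate-extreme range (treating that pessimistic range
as spanning ~95% of plausible values); moment matching gives
σ² = ln(1 + (s/m)²), μ = ln m − σ²/2. The TF-level geometric mean is
recomputed per bootstrap replicate (1,000 by default) and the 2.5/97.5
percentiles reported. A flag switches to the alternative parameterization
that places the mean/sd on the log scale directly.

## Motif dataset preparation

Peak records carry their discrete occupancy score; background records are
drawn uniformly from the non-peak genome with rejection (10,000 attempts
per record before erroring), exactly 3 per peak and exactly matching each
peak's length, all scored 0. Decoy datasets rotate all peak coordinates
by one uniform random offset per decoy (20 by default), preserving peak
count, lengths and spacing while scrambling sequence association; the FDR
estimate is `max(decoy motif counts) / max(real count, 1)`. A
transcriptional unit belongs to a motif's predicted regulon iff a motif
hit lies within 100 bp (inclusive, minimum circular separation between
the hit interval and the TSS position) of its annotated TSS. External
discovery/comparison/scanning tools consume these files; their internals
are out of scope here.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:

* circular genome, default 500 kb desk scale (full pipeline in seconds;
  a 4.64-Mb preset mirrors a full-size enterobacterial chromosome);
* ori–ter copy-number gradient shaped as a cosine of angular distance
  from the origin, scaled so ori/ter abundance = `gradient_fold`
  (default 2.0) — smooth and periodic, the regime a 4-knot periodic
  spline can capture;
* flat-topped occupancy footprints: TF sites and RNAP-bound regions
  (100–200 bp) and EPOD plateaus (1.5–3 kb) add their amplitude uniformly
  across the footprint, modeling saturated protein contact within a
  bound site or transcription unit; RNAP bumps appear in both the ChIP
  and interphase tracks, coupled by `coupling_slope` (default 1.0), TF
  and EPOD signal in the interphase track only — reproducing the
  three-subpopulation geometry (background at the origin of the
  (chip, ipod) plane, an RNAP line through it, non-RNAP occupancy above);
* independent per-bin log-normal replicate noise, σ = 0.05 on the log
  scale (~5% CV per 5-bp bin, the shot-noise regime of deeply sequenced
  libraries);
* optional fragment-level output: Poisson fragment counts with intensity
  proportional to the expected track, lengths uniform in 50–200 bp.

What the synthetic tests do **not** establish: behavior under
autocorrelated noise (real coverage noise is locally correlated),
GC-driven coverage bias, mappability artifacts, partial RNAP/TF
co-occupancy at the same locus, or graded (non-saturated) footprints.
Passing the suite demonstrates the algorithms implement their contracts
and recover planted structure under the stated noise model, not that
biological discovery quality on real libraries matches these numbers.

## Numerical choices and degenerate inputs

* Permutation p-values use the add-one estimator
  `(1 + #{perm ≥ obs}) / (1 + n_perm)` and are never 0.
* Robust z errors on MAD = 0 (constant tracks are meaningless to score);
  quantile normalization requires identical missing-bin patterns; mean
  matching requires positive means.
* The slope fit errors when fewer than 20 positive-ChIP bins survive in
  the selection.
* Empty feature sets: one-directional overlap fractions are defined as 0
  and flagged; containment of an empty strict set is 0; the Jaccard of
  two empty regulons is 0.
* EPOD extension ties break left; the percentile threshold is computed
  once, up front, not recomputed after seed resolution.
* All seeds are explicit; no wall-clock seeding anywhere.

## Problem sizes used in the shipped analyses

The test suite and `scripts/acceptance.py` run on 100–500-kb synthetic
chromosomes (20k–100k bins), 10–50 random tracks per property, 20 seeds
for recovery statistics, 200 cases × 500 bootstrap replicates for CI
coverage, and 100 K-means runs per k for clustering demonstrations at
20 runs per k. These sizes were chosen so the complete validation runs in
minutes on one CPU while keeping every estimate's Monte-Carlo error well
below the asserted margins; the algorithms themselves are linear or
n log n in genome length and run comfortably at full 4.6-Mb scale.
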