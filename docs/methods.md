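# Methods

This note documents the models, estimators and numerical choices behind
`synconn`, and what the synthetic sessions do and do not establish about
real recordings.

## Recording model

A session is a set of sorted single-unit spike trains from a single-shaft
linear probe (16 contacts, 50 µm pitch, first contact 200 µm below the
pia, so the array spans putative layers 2/3–5), together with a stimulus
train. Two stimulation protocols are modelled: passive ramp-and-hold
whisker deflection (200 ms stimuli delivered at 0.5 Hz, optionally cycling
8 deflection angles in blocked-randomized order) and artificial whisking
(10 protraction–retraction cycles at 5.5 Hz, ≈1.818 s, against one of 5
surface coarseness grades). Pair distance is the absolute depth
difference — a vertical probe provides no lateral information — and layer
membership defaults to depth bands L2/3 = [200, 550), L4 = [550, 750),
L5 = [750, 1050] µm (configurable).

## State segmentation and synchrony estimation

Each trial contributes a *spontaneous* window (the 600 ms ending at
stimulus onset, truncated at the previous offset if trials are close) and
an *evoked* window (onset to offset). Windows of the same state are pooled
across trials.

**Binned-count correlation.** Counts are formed in half-open bins tiling
each window (partial trailing bins dropped) and concatenated per state.
The bin size defaults to 10 ms: wide enough that counts are non-degenerate
at cortical rates, narrow enough to be sensitive to the few-ms synchrony
the correlogram criterion targets. Significance uses the exact *t*
transform t = r√((n−2)/(1−r²)); at the session's bin counts the 0.2
threshold corresponds to p « 0.05, and at n = 100 bins it marks p ≈ 0.046 —
the calibration that motivates the threshold.

**Cross-correlogram.** Spike-time differences t_j − t_i with both spikes
inside state windows are histogrammed at 1 ms resolution over ±50 ms lags.
The peak score is (peak − mean)/SD with mean and SD over all lag bins,
peak included (the simplest reading; flank-only normalization would change
values little at these lag counts). Note that this score is the
studentized maximum of ~101 bins: its null distribution concentrates near
2.3–3, so the 2-SD rule is permissive by construction and edge selectivity
comes from the joint requirement with r ≥ 0.2 (under independence the
joint pass rate is ≈0; see the test suite). The optimized histogram is
verified exactly against a brute-force double loop.

**Classification.** A pair is connected in a state iff r ≥ 0.2 (inclusive)
in that state, peak score > 2 (strict), each unit's session total > 3,000
spikes (strict) and each unit has ≥ 1,000 spikes (inclusive) in *both*
states. The r criterion applies to the state being classified — the two
states legitimately have different edge sets — while the count floors are
state-symmetric, so a unit's eligibility never differs between graphs.
Undefined correlations (a unit silent in a state) classify as not
connected rather than erroring.

**Connectivity index.** 100·degree/(N−1) per node, with N the accepted
units of the session; the unit itself is excluded from its own
denominator.

## Network statistics

* **Common-neighbor analysis.** All unordered pairs are partitioned by
  whether they share ≥ 1 connected neighbor in the same graph being
  scored; the random baseline is the Erdős–Rényi expectation = graph
  density. A degree-preserving rewiring null (seeded double-edge swaps)
  is available as an alternative baseline.
* **Distance profile.** Per-50 µm-bin connection probability per state;
  bin 0 holds same-contact pairs. Weighted by per-bin pair counts these
  probabilities average exactly back to graph density (tested).
* **Congruence.** Observed fraction of edges whose endpoints share a
  preferred angle/texture vs the finite-sample expectation
  Σ_k n_k(n_k−1)/(N(N−1)) computed from the same node set — not 1/k,
  which is biased when preference counts are uneven.

## Tuning estimation

The response metric is the baseline-subtracted spike count per stimulus:
count in the response window (defaulting to the full stimulus duration)
minus the pooled pre-stimulus rate times the window length. Preferred
category is the argmax of the per-category mean; exact ties are broken to
the first category in canonical order and flagged, because the congruence
analysis requires a single label per unit. No circular statistics are
fitted — the congruence analysis is categorical.

## Recovery dynamics

The connectivity index is recomputed in 500 ms latency windows stepped by
100 ms relative to stimulus onset, pooling the matched-latency window of
every trial (pooling keeps the per-window bin count high enough for a
stable r even in short windows). Unit eligibility (count floors) is
session-level; r and the correlogram criterion are evaluated per latency.
The post-offset limb is fit by least squares with
CI(t) = CI_∞ − (CI_∞ − CI_0)·exp(−(t − t₀)/τ), τ initialized at 1 s and
bounded to (0.01, 30] s, standard errors from the fit covariance; only
windows entirely after stimulus offset enter the fit. Non-convergence and
flat series return diagnostic results rather than exceptions.

Sessions intended for recovery analysis use an 8 s inter-trial period:
resolving a τ ≈ 1.2 s exponential requires observing several time
constants of the limb, which the standard 2 s period cannot provide. This
is an experiment-design choice of the analysis, made on conditioning
grounds, and is independent of the estimator itself.

## Unit quality control

Gates and defaults: rate > 0.5 Hz; minimum ISI > 2 ms; ISI histogram
(2–500 ms, 10 ms bins) log-linear exponential fit with R² ≥ 0.8
("smooth exponential-like" operationalized; < 3 nonzero bins scores 0);
waveform stability via one-way ANOVA on the first vs last 20% of the
amplitude and half-width series at α = 0.05 (no multiplicity correction,
matching the stated procedure; missing series are not-evaluable and do not
reject); MANOVA (Wilks' lambda, Rao's F) separation p < 0.05 over the
session's feature space; and the validity battery — Dunn 1 ≥ 2 / ≥ 1,
Davies–Bouldin ≤ 0.3 / ≤ 0.5, pseudo-F (Calinski–Harabasz) ≥ 100,000 /
≥ 50,000, J3 ≥ 2 / ≥ 1 for well-sorted / intermediate — requiring at
least two indices in the well-sorted range and none below intermediate.
Davies–Bouldin uses the standard dispersion (mean distance to centroid)
and is cross-checked against scikit-learn in the tests. The pseudo-F and
J3 magnitudes are unit-dependent; the absolute thresholds are applied to
raw feature values as the vendor convention does, and are configurable.
Duplicates are pairs whose zero-lag 1 ms-bin count correlation exceeds
0.9 (read as the zero-lag coefficient; a peak-over-lags variant would be
stricter); the lower-count member is excluded.

## Synthetic-session generator

**Correlation structure.** Each assembly has a latent homogeneous Poisson
mother process (λ_m = 12 Hz default); member u copies each mother spike
with probability p_u, jitters it by N(0, σ_j) (σ_j = 1 ms default), and
superimposes independent Poisson background b_u. For bins ≫ σ_j the pair
correlation has the closed form ρ = p_i p_j λ_m / √((p_iλ_m+b_i)(p_jλ_m+b_j)),
the oracle used throughout testing. A 2 ms dead-time is applied per unit,
as sorted single units exhibit; at these rates it removes ~2% of spikes
and negligibly perturbs the oracle.

**Default study conditions.** 16 units, one per contact; two spatially
contiguous assemblies of 8; copy probabilities spread evenly over
[0.5, 0.75] and background rates over [2.5, 7.5] Hz (assigned with
decorrelated strides), so baseline pair correlations span ≈0.22–0.6 —
from just above the connectivity threshold upward, as recorded populations
show. This heterogeneity matters: it spreads threshold-crossing times
during recovery so the population index relaxes smoothly rather than
stepping. 480 ramp-and-hold trials (8 angles × 60 blocked repetitions)
give ≈96 s of evoked time, the amount needed for all units to clear the
1,000-evoked-spike floor with margin at these rates; whisking sessions
reach the floors with fewer trials because the stimulus is 9× longer.

**State modulation.** During stimulation each unit's copy probability is
multiplied by γ_eff = γ · max(0, 1 − distance_penalty·d/100 µm) ·
(1 − incongruence_penalty·[pref ≠ assembly pref]); after offset the factor
relaxes as 1 − (1 − γ_eff)e^(−t/τ) in 100 ms piecewise-constant steps.
Crucially, modulation is pure decorrelation: the copy rate lost to the
factor, p_u λ_m (1 − f(t)), is returned as independent Poisson firing, and
a tuned evoked component (10 Hz at the preferred angle, Gaussian falloff
of 40°; full/0.2 gain for preferred/other textures) adds rate on top. Thus
evoked firing rates stay level or rise while pairwise synchrony falls —
the dissociation the analysis is designed to detect — and the spike-count
floors stay meaningful under strong desynchronization. γ defaults to 0.9,
which yields a ~30–40% mean connectivity-index reduction under the default
conditions; τ defaults to 1.2 s.

**Tuning assignment.** Each assembly has a preferred angle and texture;
members inherit it with probability 0.75 (else a random other category).
This alignment is what produces above-chance congruence among connected
pairs already in the spontaneous state; the incongruence penalty deepens
it in the evoked state.

**What the generator does not emulate.** No biophysics (spikes are point
events from thinned Poisson processes, with none of the bursting,
adaptation or oscillatory structure of real cortex); no laminar rate or
connectivity asymmetries beyond the spatial assembly layout; no
stimulus-locked PSTH shape within the evoked window (rates are flat within
a state); waveform features are synthetic Gaussian clouds standing in for
a real sorting space, so QC pass rates on synthetic sessions say nothing
about real sorting quality. Passing tests therefore establish the
*estimators'* correctness and sensitivity under known ground truth — not
that real recordings satisfy the generator's assumptions.

## Numerical choices and edge cases

* Bin assignment is half-open: a spike exactly on a boundary belongs to
  the bin starting there.
* Correlogram lag bins are centered on integer multiples of the bin width
  (edges at ±bin/2); the (i, j) histogram reversed equals (j, i) exactly.
* Constant count vectors, edgeless graphs, empty partitions, zero-spont
  indices and silent-state units are all reported as not-evaluable (NaN)
  rather than raised, so one degenerate pair never aborts a session.
* Edge lists are written with unit_id_a < unit_id_b so graph files are
  canonical; all tables are CSV with headers, times printed at 6 decimals
  (write → read is the identity, property-tested).
* Determinism: every stochastic component draws from
  `numpy.random.default_rng(seed)`; identical (config, seed) reruns are
  byte-identical including the pipeline's `summary.json`.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script runs use 16-unit sessions with 480
trials (≈960 s at 0.5 Hz; ≈3,840 s for the 8 s-period recovery protocol),
20-seed replications for directional claims, 100-seed replications for
graph-null calibrations, and 500-replicate type-I calibrations of the
stability and MANOVA tests — sizes at which every directional and
calibration claim is stable across seeds while a full run of everything
stays in the minutes range on one CPU.
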