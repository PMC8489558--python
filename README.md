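# synconn

State-dependent synchrony and functional-connectivity analysis of
multi-unit cortical spike trains.

Sensory stimulation does not simply excite a cortical network — it
*desynchronizes* it. In whisker somatosensory cortex, pairs of neurons that
fire together during quiet spontaneous activity transiently decouple when
the whiskers are stimulated, and the coupling recovers over seconds after
the stimulus ends. `synconn` is a library for quantifying this phenomenon
in sorted extracellular recordings from linear multi-contact probes: it
takes spike times, stimulus events and unit metadata, and produces
per-state functional-connectivity graphs together with their topology,
laminar, distance, tuning-congruence and recovery statistics. A seeded
synthetic-session generator with a closed-form correlation oracle makes the
whole pipeline testable without any recording.

## The method

For every pair of accepted units *i, j* and each behavioural state —
*spontaneous* (the 600 ms window preceding each stimulus) and *evoked* (the
stimulation window) — two synchrony measures are computed on the pooled
state windows:

* the Pearson correlation *r<sub>ij</sub>* of binned spike counts
  (10 ms bins by default), and
* the cross-correlogram peak score
  *z<sub>ij</sub>* = (peak − mean) / SD over the ±50 ms lag histogram.

A pair is **functionally connected** in a state when all three criteria
hold:

1. *r<sub>ij</sub>* ≥ 0.2 (the value that yields p < 0.05 at these bin
   counts),
2. the correlogram peak exceeds 2 SD above the correlogram mean,
3. both units fired > 3,000 spikes in the session and ≥ 1,000 spikes in
   each of the two states.

Each neuron's **connectivity index** is the percentage of the other
recorded neurons it is connected to; per-state graphs over the accepted
units support the derived statistics: relative desynchronization
(evoked − spont)/spont, evoked-edge overlap, common-neighbor connection
probabilities vs the Erdős–Rényi expectation 2|E|/N(N−1), depth-distance
and laminar profiles, tuning-congruence fractions vs the finite-sample
expectation Σ<sub>k</sub> n<sub>k</sub>(n<sub>k</sub>−1)/N(N−1), and a
mono-exponential fit CI(t) = CI<sub>∞</sub> − (CI<sub>∞</sub> − CI<sub>0</sub>)·e^(−t/τ)
to the post-stimulus recovery of the index.

Upstream of all this, a unit-acceptance battery implements the spike-sorting
quality gates: firing rate > 0.5 Hz, no inter-spike interval < 2 ms, an
exponential-like ISI distribution, waveform stability (ANOVA on the first
vs last 20% of spikes), MANOVA separation of the feature-space clusters,
the four cluster-validity indices (Dunn 1, Davies–Bouldin, pseudo-F, J3)
and duplicate-unit exclusion (> 0.9 zero-lag correlation at 1 ms bins).

The synthetic generator produces sessions with known structure: each cell
assembly owns a latent Poisson mother process (rate λ<sub>m</sub>) thinned
independently into its member units (copy probability p<sub>u</sub>, plus
background rate b<sub>u</sub>), giving the closed-form pair correlation

ρ<sub>ij</sub> = p<sub>i</sub>p<sub>j</sub>λ<sub>m</sub> / √((p<sub>i</sub>λ<sub>m</sub>+b<sub>i</sub>)(p<sub>j</sub>λ<sub>m</sub>+b<sub>j</sub>))

against which every downstream estimate is validated. Stimulation scales
the copy probability by γ ≤ 1 (with optional distance and
tuning-incongruence penalties) while compensating the lost rate with
independent firing, and the factor relaxes back to baseline with time
constant τ after stimulus offset.

## Worked example

```python
import numpy as np
import synconn as sc

assembly, modulation, tuning = sc.default_configs(seed=3)
trains, events, meta, truth = sc.generate_session(assembly, modulation, tuning, seed=3)

windows = sc.make_state_windows(events)          # 600 ms spont / evoked per trial
metrics = sc.pair_metrics(trains, windows)       # r and peak_z per pair per state
g_spont  = sc.build_graph(metrics, "spontaneous")
g_evoked = sc.build_graph(metrics, "evoked")

print(g_spont.mean_index(), g_evoked.mean_index())
print(np.nanmean(sc.connectivity_index_table(g_spont, g_evoked).relative_change))
print(sc.overlap_fraction(g_evoked, g_spont))
```

prints

```
46.666666666666664 33.333333333333336
-0.2857142857142857
1.0
```

i.e. the mean connectivity index drops from 46.7% to 33.3% during
stimulation — a 29% relative desynchronization — and every evoked-state
edge already existed in the spontaneous graph: stimulation disconnects
pairs, it does not create new couplings. The `examples/` directory walks
through each capability (simulation, quality control, connectivity,
topology, tuning, recovery dynamics) as a short narrative script, e.g.

```bash
python examples/06_recovery_dynamics.py   # fits tau = 1.10 +- 0.11 s (truth 1.2 s)
```

A thin command-line interface mirrors the library:

```bash
synconn run --n-trials 480 --seed 7 --out session_out/   # full pipeline + summary.json
synconn simulate --gamma 0.3 --tau 1.2 --seed 1 --out sim/
synconn pairs --spikes sim/spike_table.csv --events sim/events.csv --out pairs.csv
```

All artifacts are plain CSV/JSON with documented columns.

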