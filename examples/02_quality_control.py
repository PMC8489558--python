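"""Run the unit-acceptance battery on a synthetic session.

Checks firing rate (> 0.5 Hz), refractory violations (no ISI < 2 ms), the
exponential shape of the ISI distribution, waveform stability (first vs last
20% of spikes), MANOVA cluster separation, the four cluster-validity indices
(Dunn, Davies-Bouldin, pseudo-F, J3), spike-count floors and duplicate
exclusion.
"""

import synconn as sc

assembly, modulation, tuning = sc.default_configs(seed=2)
trains, events, meta, _ = sc.generate_session(assembly, modulation, tuning, seed=2)
windows = sc.make_state_windows(events)
features = sc.generate_session_features(trains, seed=2)

accepted, report = sc.apply_qc(trains, windows, features=features)

print(f"accepted {accepted.n_units}/{trains.n_units} units")
row = report.per_unit.iloc[0]
print(f"example unit {row.unit_id}: rate {row.rate_hz:.1f} Hz, "
      f"min ISI {row.min_isi_ms:.2f} ms, ISI exp-fit R2 {row.isi_exp_fit_r2:.2f}")
print(f"sorting-space indices: Dunn {row.dunn_value:.2f} "
      f"({row.dunn_grade}), DB {row.davies_bouldin_value:.3f} ({row.davies_bouldin_grade}), "
      f"pseudo-F {row.pseudo_f_value:.0f} ({row.pseudo_f_grade}), "
      f"J3 {row.j3_value:.1f} ({row.j3_grade})")
print(f"MANOVA separation p = {row.manova_p:.2e} (< 0.05 required)")
print(f"duplicate pairs flagged: {len(report.duplicates)}")
rejected = report.per_unit[~report.per_unit.accept]
if len(rejected):
    print("rejected units and their failing gates:")
    for _, r in rejected.iterrows():
        gates = [c for c in ("rate_ok", "isi_ok", "isi_shape_ok", "stability_ok",
                             "total_count_ok", "state_count_ok") if r[c] is False]
        print(f"  {r.unit_id}: {', '.join(gates) or 'duplicate'}")
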