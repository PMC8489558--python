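"""Time-resolved connectivity index and post-stimulus recovery.

Generates a deep-desynchronization session (gamma = 0.3) with an 8 s
inter-trial period so several time constants of the recovery limb are
observable, recomputes the connectivity index in 500 ms latency windows
pooled across trials, and fits the mono-exponential recovery.
"""

import synconn as sc

TAU_TRUE = 1.2  # generator recovery time constant, seconds

assembly, modulation, tuning = sc.default_configs(gamma=0.3, tau_s=TAU_TRUE, seed=6)
trains, events, _, _ = sc.generate_session(
    assembly, modulation, tuning, n_trials=480, period_s=8.0, seed=6
)

series = sc.time_resolved_index(trains, events, t_start=-1.0, t_end=7.0)
print("latency (s) -> mean connectivity index (%):")
for t, v in zip(series.times_s[::6], series.mean_index[::6]):
    bar = "#" * int(v / 2)
    print(f"  {t:+5.2f}  {v:5.1f}  {bar}")

fit = sc.fit_recovery(series, t_offset=0.45)
print(f"\nmono-exponential recovery fit: tau = {fit.tau_s:.2f} +- {fit.tau_se:.2f} s "
      f"(generator truth {TAU_TRUE} s)")
print(f"baseline asymptote {fit.ci_inf:.1f}%, residual RMS {fit.residual_rms:.1f}")
print("-> the network reconnects to its pre-stimulus state within a few seconds")
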