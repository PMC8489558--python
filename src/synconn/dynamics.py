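"""Time-resolved connectivity index and post-stimulus recovery fitting.

The connectivity index is recomputed in short latency windows locked to
stimulus onset: for each latency, the same window of every trial is pooled
(so even 500 ms windows accumulate enough count bins for a stable Pearson
r), pair metrics and the per-state graph are rebuilt, and the mean index
over units is reported.  The post-offset limb is then fit with a
mono-exponential recovery toward the pre-stimulus level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import curve_fit

from .connectivity import ConnectivityCriteria
from .pairwise import (
    EVOKED,
    SPONTANEOUS,
    _bin_unit,
    cross_correlogram,
    make_state_windows,
    state_spike_counts,
)
from .types import SessionEvents, SpikeTrainSet, ValidationError


@dataclass
class ConnectivityTimeSeries:
    """Mean connectivity index (percent) on a latency grid locked to onset."""

    times_s: np.ndarray  # window centers, seconds relative to stimulus onset
    mean_index: np.ndarray
    sem_index: np.ndarray
    window_s: float
    step_s: float
    n_units: int


@dataclass
class RecoveryFit:
    """Mono-exponential recovery CI(t) = CI_inf - (CI_inf - CI_0) e^{-(t-t0)/tau}."""

    tau_s: float
    tau_se: float
    ci_inf: float
    ci_0: float
    residual_rms: float
    n_points: int
    success: bool
    message: str = ""


def time_resolved_index(
    trains: SpikeTrainSet,
    events: SessionEvents,
    criteria: ConnectivityCriteria | None = None,
    window_s: float = 0.5,
    step_s: float = 0.1,
    t_start: float = -1.0,
    t_end: float | None = None,
    bin_s: float = 0.01,
    max_lag_ms: float = 50.0,
    ccg_bin_ms: float = 1.0,
    unit_ids: list[str] | None = None,
) -> ConnectivityTimeSeries:
    """Connectivity-index dynamics around stimulation.

    Latency windows ``[onset + l, onset + l + window_s)`` are pooled across
    trials at matched latency ``l``; windows that would run past the session
    end are dropped with a warning.  The spike-count eligibility floors are
    session-level (a unit's eligibility does not flicker between latency
    windows); the correlation and correlogram criteria are evaluated per
    latency.
    """
    if events.n_events < 2:
        raise ValidationError("need at least 2 trials to pool latency windows")
    c = criteria or ConnectivityCriteria()
    units = sorted(unit_ids if unit_ids is not None else trains.unit_ids)
    n_units = len(units)
    if n_units < 2:
        raise ValidationError("need at least 2 units")

    state_windows = make_state_windows(events)
    counts_tbl = state_spike_counts(trains, state_windows, units)
    eligible = {
        u: (
            counts_tbl.loc[u, "total"] > c.min_total_spikes
            and counts_tbl.loc[u, SPONTANEOUS] >= c.min_state_spikes
            and counts_tbl.loc[u, EVOKED] >= c.min_state_spikes
        )
        for u in units
    }

    if t_end is None:
        t_end = float(np.min(np.diff(events.onsets)))
    latencies = np.arange(t_start, t_end - window_s + 1e-9, step_s)
    if latencies.size == 0:
        raise ValidationError("empty latency grid")
    n_per = int(np.floor(window_s / bin_s + 1e-9))

    times, means, sems = [], [], []
    warned = False
    for lat in latencies:
        starts = events.onsets + lat
        ok = (starts >= 0) & (starts + window_s <= trains.session_duration)
        if not np.all(ok) and not warned:
            warnings.warn("latency windows past the session bounds dropped", stacklevel=2)
            warned = True
        starts = starts[ok]
        if starts.size < 2:
            continue
        wins = np.column_stack([starts, starts + window_s])
        n_per_arr = np.full(starts.size, n_per, dtype=np.int64)
        mat = np.vstack(
            [_bin_unit(trains.spike_times[u], starts, n_per_arr, bin_s) for u in units]
        ).astype(float)
        with np.errstate(invalid="ignore"):
            cmat = np.corrcoef(mat)
        degree = dict.fromkeys(units, 0)
        for (i, a), (j, b) in combinations(enumerate(units), 2):
            if not (eligible[a] and eligible[b]):
                continue
            r = cmat[i, j]
            if not np.isfinite(r) or r < c.r_min:
                continue
            try:
                ccg = cross_correlogram(
                    trains.spike_times[a], trains.spike_times[b], wins, max_lag_ms, ccg_bin_ms
                )
            except ValidationError:
                continue
            if ccg.peak_z > c.peak_z_min:
                degree[a] += 1
                degree[b] += 1
        idx = 100.0 * np.array([degree[u] for u in units]) / (n_units - 1)
        times.append(lat + window_s / 2.0)
        means.append(float(idx.mean()))
        sems.append(float(idx.std(ddof=1) / np.sqrt(n_units)))
    return ConnectivityTimeSeries(
        np.asarray(times), np.asarray(means), np.asarray(sems), window_s, step_s, n_units
    )


def fit_recovery(series: ConnectivityTimeSeries, t_offset: float) -> RecoveryFit:
    """Least-squares mono-exponential fit to the post-offset recovery limb.

    Only grid points at ``t >= t_offset`` enter the fit; tau is initialized
    at 1 s and bounded to (0.01, 30] s; the tau standard error comes from
    the fit's covariance.  Non-convergence returns a diagnostic result, not
    an exception.
    """
    sel = series.times_s >= t_offset
    t = series.times_s[sel]
    y = series.mean_index[sel]
    if t.size < 5:
        raise ValidationError("need at least 5 grid points after t_offset")
    if np.ptp(y) == 0:
        raise ValidationError("series constant after t_offset; nothing to fit")

    def model(tt, ci_inf, ci_0, tau):
        return ci_inf - (ci_inf - ci_0) * np.exp(-(tt - t_offset) / tau)

    p0 = (float(np.mean(y[-max(3, t.size // 5):])), float(y[0]), 1.0)
    try:
        popt, pcov = curve_fit(
            model,
            t,
            y,
            p0=p0,
            bounds=([-np.inf, -np.inf, 0.01], [np.inf, np.inf, 30.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        return RecoveryFit(
            float("nan"), float("nan"), float("nan"), float("nan"),
            float("nan"), int(t.size), False, f"fit failed: {exc}",
        )
    resid = y - model(t, *popt)
    tau_se = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else float("nan")
    return RecoveryFit(
        tau_s=float(popt[2]),
        tau_se=tau_se,
        ci_inf=float(popt[0]),
        ci_0=float(popt[1]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=int(t.size),
        success=True,
    )
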