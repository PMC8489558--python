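"""Per-pair, per-state synchrony metrics.

The session is segmented into *states* — the 600 ms spontaneous window
preceding each stimulus, the evoked (stimulation) window, and optionally a
post-stimulus window — and for every unit pair two synchrony measures are
computed per state: the Pearson correlation of binned spike counts (10 ms
bins by default; pooled across all same-state windows of the session) and
the cross-correlogram peak expressed in SDs above the correlogram mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import canonical_pair
from .types import SessionEvents, SpikeTrainSet, ValidationError

SPONTANEOUS = "spontaneous"
EVOKED = "evoked"
POST = "post"


@dataclass
class StateWindows:
    """Non-overlapping (start, end) intervals per state label."""

    windows: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, w in self.windows.items():
            w = np.asarray(w, dtype=float).reshape(-1, 2)
            if w.size and (np.any(w[:, 1] <= w[:, 0]) or np.any(w[1:, 0] < w[:-1, 1])):
                raise ValidationError(f"{label} windows overlap or are empty")
            self.windows[label] = w

    def __getitem__(self, label: str) -> np.ndarray:
        return self.windows.get(label, np.empty((0, 2)))

    def total_duration(self, label: str) -> float:
        w = self[label]
        return float(np.sum(w[:, 1] - w[:, 0])) if w.size else 0.0

    @property
    def labels(self) -> list[str]:
        return list(self.windows)


def make_state_windows(
    events: SessionEvents, spont_s: float = 0.6, post_s: float | None = None
) -> StateWindows:
    """Per-trial state windows: spontaneous = the ``spont_s`` (600 ms) window
    ending at each onset, evoked = onset..offset, post = offset..offset+post_s.

    Spontaneous windows are truncated at the previous offset (and at 0) with
    a warning when trials are too closely spaced; post windows are truncated
    at the next onset.
    """
    if spont_s <= 0:
        raise ValidationError("spont_s must be > 0")
    if events.n_events == 0:
        return StateWindows({})
    on, off = events.onsets, events.offsets
    floor = np.concatenate([[0.0], off[:-1]])
    spont_start = np.maximum(on - spont_s, floor)
    if np.any(spont_start > on - spont_s + 1e-12):
        warnings.warn("spontaneous windows truncated by preceding events", stacklevel=2)
    keep = spont_start < on
    out = {
        SPONTANEOUS: np.column_stack([spont_start[keep], on[keep]]),
        EVOKED: np.column_stack([on, off]),
    }
    if post_s is not None:
        ceil = np.concatenate([on[1:], [np.inf]])
        post_end = np.minimum(off + post_s, ceil)
        out[POST] = np.column_stack([off, post_end])
    return StateWindows(out)


def spikes_in_windows(t: np.ndarray, windows: np.ndarray) -> np.ndarray:
    """Spikes falling inside the union of half-open [start, end) windows."""
    if windows.size == 0 or t.size == 0:
        return np.empty(0)
    i0 = np.searchsorted(t, windows[:, 0], side="left")
    i1 = np.searchsorted(t, windows[:, 1], side="left")
    lens = i1 - i0
    total = int(lens.sum())
    if total == 0:
        return np.empty(0)
    starts = i0 - np.concatenate([[0], np.cumsum(lens)[:-1]])
    idx = np.repeat(starts, lens) + np.arange(total)
    return t[idx]


@dataclass
class BinnedCounts:
    """Pooled per-state count matrix: one row per unit, one column per bin."""

    unit_ids: list[str]
    counts: np.ndarray  # (n_units, n_bins) int
    bin_size_s: float
    label: str
    window_index: np.ndarray  # provenance: source window of each bin

    def vector(self, unit_id: str) -> np.ndarray:
        return self.counts[self.unit_ids.index(unit_id)]


def _bin_unit(
    t: np.ndarray, starts: np.ndarray, n_per: np.ndarray, bin_s: float
) -> np.ndarray:
    """Counts of one unit over tiled bins of (possibly unequal) windows."""
    offsets = np.concatenate([[0], np.cumsum(n_per)])
    out = np.zeros(offsets[-1], dtype=np.int64)
    ends = starts + n_per * bin_s
    i0 = np.searchsorted(t, starts, side="left")
    i1 = np.searchsorted(t, ends, side="left")
    lens = i1 - i0
    total = int(lens.sum())
    if total == 0:
        return out
    first = i0 - np.concatenate([[0], np.cumsum(lens)[:-1]])
    sidx = np.repeat(first, lens) + np.arange(total)
    widx = np.repeat(np.arange(starts.size), lens)
    rel = t[sidx] - starts[widx]
    b = np.minimum((rel / bin_s).astype(np.int64), np.repeat(n_per, lens) - 1)
    np.add.at(out, offsets[widx] + b, 1)
    return out


def bin_counts(
    trains: SpikeTrainSet,
    windows: StateWindows | np.ndarray,
    bin_s: float = 0.01,
    label: str = SPONTANEOUS,
    unit_ids: list[str] | None = None,
) -> BinnedCounts:
    """Tile each state window with half-open bins of ``bin_s`` seconds.

    Bins cover ``[start, start + floor(len/bin) * bin)`` per window (partial
    trailing bins are dropped) and are concatenated across the windows of the
    state.  A spike exactly on a bin boundary belongs to the bin starting
    there.
    """
    if bin_s <= 0:
        raise ValidationError("bin_s must be > 0")
    w = windows[label] if isinstance(windows, StateWindows) else np.asarray(windows, float).reshape(-1, 2)
    if w.size == 0:
        raise ValidationError(f"no windows for state {label!r}")
    n_per = np.floor((w[:, 1] - w[:, 0]) / bin_s + 1e-9).astype(np.int64)
    keep = n_per > 0
    w, n_per = w[keep], n_per[keep]
    if not w.size:
        raise ValidationError("all windows shorter than one bin")
    units = unit_ids if unit_ids is not None else trains.unit_ids
    counts = np.vstack([_bin_unit(trains.spike_times[u], w[:, 0], n_per, bin_s) for u in units])
    window_index = np.repeat(np.arange(w.shape[0]), n_per)
    return BinnedCounts(list(units), counts, bin_s, label, window_index)


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with a Student-t two-sided p-value.

    Constant vectors make the correlation undefined: ``(nan, nan)`` is
    returned and the pair is downstream treated as not connected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    r_ = min(max(r, -1.0), 1.0)
    if abs(r_) == 1.0:
        return (r_, 0.0)
    t = r_ * np.sqrt((n - 2) / (1.0 - r_**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return (r_, float(p))


@dataclass
class Correlogram:
    """Cross-correlogram of lagged coincidences (t_j - t_i)."""

    lags_ms: np.ndarray
    counts: np.ndarray
    mean: float
    sd: float
    peak: float
    peak_lag_ms: float
    peak_z: float


def cross_correlogram(
    train_i: np.ndarray,
    train_j: np.ndarray,
    windows: np.ndarray | StateWindows | None = None,
    max_lag_ms: float = 50.0,
    bin_ms: float = 1.0,
    label: str = SPONTANEOUS,
) -> Correlogram:
    """Histogram of spike-time differences ``t_j - t_i`` within +-max_lag.

    Both spikes must fall inside the state windows.  The peak is scored as
    ``(peak - mean) / SD`` with mean and SD taken over all lag bins
    (including the peak bin).
    """
    if windows is not None:
        w = windows[label] if isinstance(windows, StateWindows) else np.asarray(windows, float).reshape(-1, 2)
        ti = spikes_in_windows(np.asarray(train_i, float), w)
        tj = spikes_in_windows(np.asarray(train_j, float), w)
    else:
        ti, tj = np.asarray(train_i, float), np.asarray(train_j, float)
    if ti.size == 0 or tj.size == 0:
        raise ValidationError("no spikes inside the requested windows")
    max_lag_s = max_lag_ms / 1000.0
    bin_s = bin_ms / 1000.0
    k = int(round(max_lag_ms / bin_ms))
    lags_ms = (np.arange(-k, k + 1)) * bin_ms
    counts = np.zeros(2 * k + 1, dtype=np.int64)
    # for each i-spike gather j-spikes within the lag horizon
    lo = np.searchsorted(tj, ti - max_lag_s - bin_s / 2, side="left")
    hi = np.searchsorted(tj, ti + max_lag_s + bin_s / 2, side="right")
    lens = hi - lo
    total = int(lens.sum())
    if total:
        first = lo - np.concatenate([[0], np.cumsum(lens)[:-1]])
        jidx = np.repeat(first, lens) + np.arange(total)
        iidx = np.repeat(np.arange(ti.size), lens)
        d = tj[jidx] - ti[iidx]
        b = np.rint(d / bin_s).astype(np.int64) + k
        valid = (b >= 0) & (b <= 2 * k)
        np.add.at(counts, b[valid], 1)
    mean = float(counts.mean())
    sd = float(counts.std())
    peak_idx = int(np.argmax(counts))
    peak = float(counts[peak_idx])
    peak_z = (peak - mean) / sd if sd > 0 else 0.0
    return Correlogram(lags_ms, counts, mean, sd, peak, float(lags_ms[peak_idx]), float(peak_z))


def cross_correlogram_bruteforce(
    train_i, train_j, windows=None, max_lag_ms: float = 50.0, bin_ms: float = 1.0, label: str = SPONTANEOUS
) -> Correlogram:
    """Reference double-loop correlogram (test oracle for small trains)."""
    if windows is not None:
        w = windows[label] if isinstance(windows, StateWindows) else np.asarray(windows, float).reshape(-1, 2)
        ti = spikes_in_windows(np.asarray(train_i, float), w)
        tj = spikes_in_windows(np.asarray(train_j, float), w)
    else:
        ti, tj = np.asarray(train_i, float), np.asarray(train_j, float)
    if ti.size == 0 or tj.size == 0:
        raise ValidationError("no spikes inside the requested windows")
    bin_s = bin_ms / 1000.0
    k = int(round(max_lag_ms / bin_ms))
    lags_ms = (np.arange(-k, k + 1)) * bin_ms
    counts = np.zeros(2 * k + 1, dtype=np.int64)
    for a in ti:
        for b_ in tj:
            idx = int(np.rint((b_ - a) / bin_s)) + k
            if 0 <= idx <= 2 * k:
                counts[idx] += 1
    mean = float(counts.mean())
    sd = float(counts.std())
    peak_idx = int(np.argmax(counts))
    peak = float(counts[peak_idx])
    peak_z = (peak - mean) / sd if sd > 0 else 0.0
    return Correlogram(lags_ms, counts, mean, sd, peak, float(lags_ms[peak_idx]), float(peak_z))


def state_spike_counts(
    trains: SpikeTrainSet, windows: StateWindows, unit_ids: list[str]
) -> pd.DataFrame:
    """Per-unit spike counts per state plus the whole-session total."""
    rows = {}
    for u in unit_ids:
        t = trains.spike_times[u]
        rows[u] = {"total": t.size}
        for label in windows.labels:
            rows[u][label] = int(spikes_in_windows(t, windows[label]).size)
    return pd.DataFrame(rows).T.rename_axis("unit_id")


def pair_metrics(
    trains: SpikeTrainSet,
    windows: StateWindows,
    unit_ids: list[str] | None = None,
    bin_s: float = 0.01,
    max_lag_ms: float = 50.0,
    ccg_bin_ms: float = 1.0,
    states: tuple[str, ...] = (SPONTANEOUS, EVOKED),
    skip_ccg_below_r: float | None = None,
) -> pd.DataFrame:
    """Per-pair, per-state synchrony table for all unordered unit pairs.

    Returns one row per (pair, state) with columns ``pearson_r``,
    ``pearson_p``, ``n_bins``, ``peak_z``, per-state spike counts of both
    units, and whole-session totals.  ``skip_ccg_below_r`` skips the (more
    expensive) correlogram for pairs whose correlation is already below the
    connectivity threshold; their ``peak_z`` is reported as NaN.
    """
    units = sorted(unit_ids if unit_ids is not None else trains.unit_ids)
    if len(units) < 2:
        raise ValidationError("need at least two units")
    counts_tbl = state_spike_counts(trains, windows, units)
    rows = []
    for state in states:
        binned = bin_counts(trains, windows, bin_s=bin_s, label=state, unit_ids=units)
        with np.errstate(invalid="ignore"):
            cmat = np.corrcoef(binned.counts.astype(float))
        n = binned.counts.shape[1]
        for (i, a), (j, b) in combinations(enumerate(units), 2):
            ua, ub = canonical_pair(a, b)
            r = float(cmat[i, j])
            if np.ptp(binned.counts[i]) == 0 or np.ptp(binned.counts[j]) == 0:
                r, p = float("nan"), float("nan")
            elif abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r**2))
                p = 2.0 * stats.t.sf(abs(t), df=n - 2)
            peak_z = float("nan")
            if not (skip_ccg_below_r is not None and (np.isnan(r) or r < skip_ccg_below_r)):
                try:
                    ccg = cross_correlogram(
                        trains.spike_times[a], trains.spike_times[b],
                        windows, max_lag_ms, ccg_bin_ms, label=state,
                    )
                    peak_z = ccg.peak_z
                except ValidationError:
                    peak_z = float("nan")
            rows.append(
                {
                    "unit_id_a": ua,
                    "unit_id_b": ub,
                    "state": state,
                    "pearson_r": r,
                    "pearson_p": float(p) if not np.isnan(r) else float("nan"),
                    "n_bins": n,
                    "peak_z": peak_z,
                    "total_spikes_a": int(counts_tbl.loc[ua, "total"]),
                    "total_spikes_b": int(counts_tbl.loc[ub, "total"]),
                    "spont_spikes_a": int(counts_tbl.loc[ua].get(SPONTANEOUS, 0)),
                    "spont_spikes_b": int(counts_tbl.loc[ub].get(SPONTANEOUS, 0)),
                    "evoked_spikes_a": int(counts_tbl.loc[ua].get(EVOKED, 0)),
                    "evoked_spikes_b": int(counts_tbl.loc[ub].get(EVOKED, 0)),
                }
            )
    return pd.DataFrame(rows)
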