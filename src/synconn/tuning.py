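"""Per-unit stimulus tuning: angular (8 directions) and coarseness (5 textures).

The response metric is the baseline-subtracted spike count per stimulus:
mean over trials of the count in the response window minus the expected
count from the pre-stimulus baseline rate.  The preferred category is the
argmax of the mean response; exact ties are broken deterministically (first
category in canonical order) and flagged, because the congruence analysis
downstream needs a single category per unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ANGLES, TEXTURES, SessionEvents, ValidationError


@dataclass
class TuningCurve:
    categories: list
    mean_response: np.ndarray  # spikes/stimulus above baseline, per category
    sem_response: np.ndarray
    n_trials: np.ndarray
    preferred: object
    tie: bool
    selectivity: float  # (max - mean of others) / (max + mean of others)


def _per_event_responses(
    spike_times: np.ndarray,
    onsets: np.ndarray,
    offsets: np.ndarray,
    response_window_s: float | None,
    baseline_window_s: float,
) -> np.ndarray:
    t = np.asarray(spike_times, dtype=float)
    if response_window_s is None:
        ends = offsets
        win = offsets - onsets
    else:
        ends = onsets + response_window_s
        win = np.full(onsets.size, response_window_s)
    counts = np.searchsorted(t, ends) - np.searchsorted(t, onsets)
    base_lo = np.maximum(onsets - baseline_window_s, 0.0)
    base_counts = np.searchsorted(t, onsets) - np.searchsorted(t, base_lo)
    base_time = float(np.sum(onsets - base_lo))
    baseline_rate = base_counts.sum() / base_time if base_time > 0 else 0.0
    return counts - baseline_rate * win


def evoked_response(
    spike_times: np.ndarray,
    events: SessionEvents,
    response_window_s: float | None = None,
    baseline_window_s: float = 0.6,
) -> float:
    """Mean spikes/stimulus above the pre-stimulus baseline.

    The response window defaults to the full stimulus duration; the baseline
    rate is pooled over the 600 ms pre-stimulus windows of the same events.
    """
    if events.n_events == 0:
        raise ValidationError("no events")
    if baseline_window_s <= 0 or (response_window_s is not None and response_window_s <= 0):
        raise ValidationError("windows must be positive")
    resp = _per_event_responses(
        spike_times, events.onsets, events.offsets, response_window_s, baseline_window_s
    )
    return float(resp.mean())


def _tuning_curve(
    spike_times: np.ndarray,
    events: SessionEvents,
    condition: np.ndarray,
    categories: list,
    response_window_s: float | None,
    baseline_window_s: float,
) -> TuningCurve:
    resp = _per_event_responses(
        spike_times, events.onsets, events.offsets, response_window_s, baseline_window_s
    )
    means, sems, ns = [], [], []
    for c in categories:
        sel = condition == c
        ns.append(int(sel.sum()))
        if sel.any():
            means.append(float(resp[sel].mean()))
            sems.append(float(resp[sel].std(ddof=1) / np.sqrt(sel.sum())) if sel.sum() > 1 else 0.0)
        else:
            means.append(float("nan"))
            sems.append(float("nan"))
    means_arr = np.asarray(means)
    valid = ~np.isnan(means_arr)
    if valid.sum() < 2:
        raise ValidationError("need responses for at least 2 categories")
    best = int(np.nanargmax(means_arr))
    tie = bool(np.sum(means_arr[valid] == means_arr[best]) > 1)
    others = means_arr[valid & (np.arange(means_arr.size) != best)]
    denom = means_arr[best] + others.mean()
    selectivity = float((means_arr[best] - others.mean()) / denom) if denom != 0 else float("nan")
    return TuningCurve(
        categories=list(categories),
        mean_response=means_arr,
        sem_response=np.asarray(sems),
        n_trials=np.asarray(ns),
        preferred=categories[best],
        tie=tie,
        selectivity=selectivity,
    )


def angular_tuning(
    spike_times: np.ndarray,
    events: SessionEvents,
    response_window_s: float | None = None,
    baseline_window_s: float = 0.6,
) -> TuningCurve:
    """Tuning curve over the 8 deflection directions of ramp-and-hold trials."""
    if events.angle_deg is None:
        raise ValidationError("events carry no angle labels")
    present = np.unique(events.angle_deg)
    if present.size < 2:
        raise ValidationError("need at least 2 distinct angles")
    unknown = set(present) - {float(a) for a in ANGLES}
    if unknown:
        raise ValidationError(f"unknown angles {sorted(unknown)}")
    return _tuning_curve(
        spike_times, events, events.angle_deg, [float(a) for a in ANGLES],
        response_window_s, baseline_window_s,
    )


def coarseness_preference(
    spike_times: np.ndarray,
    events: SessionEvents,
    response_window_s: float | None = None,
    baseline_window_s: float = 0.6,
) -> TuningCurve:
    """Tuning curve over the 5 surface coarseness grades of whisking trials.

    The response window defaults to the whole whisking train."""
    if events.texture is None:
        raise ValidationError("events carry no texture labels")
    present = set(events.texture.tolist())
    unknown = present - set(TEXTURES)
    if unknown:
        raise ValidationError(f"unknown textures {sorted(map(str, unknown))}")
    if len(present) < 2:
        raise ValidationError("need at least 2 distinct textures")
    return _tuning_curve(
        spike_times, events, events.texture, list(TEXTURES),
        response_window_s, baseline_window_s,
    )
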