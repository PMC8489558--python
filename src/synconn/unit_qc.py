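"""Unit-acceptance battery for sorted single units.

A sorted cluster is accepted as a single unit only if it clears every gate:

* firing rate above 0.5 Hz (lower rates lack the statistical power for
  cross-correlograms);
* no inter-spike interval below 2 ms, and a smooth exponential-like ISI
  distribution (operationalized as R^2 >= 0.8 of a log-linear fit to the
  2-500 ms ISI histogram);
* stable waveform: amplitude and half-width do not differ significantly
  (one-way ANOVA) between the first and last 20% of recorded spikes;
* significant multivariate separation of the unit clusters in waveform
  feature space (MANOVA, Wilks' lambda);
* cluster-validity battery: of the four indices (Dunn 1, Davies-Bouldin,
  pseudo-F / Calinski-Harabasz, J3) at least two in the well-sorted range
  and the rest at least intermediate;
* spike-count floors (3,000 per session; 1,000 per state);
* not a duplicate of a better-sampled unit (zero-lag 1 ms-bin correlation
  above 0.9 marks duplicate pairs; the lower-count member is excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist, pdist

from .io_formats import canonical_pair
from .pairwise import SPONTANEOUS, EVOKED, StateWindows, spikes_in_windows
from .types import SpikeTrainSet, ValidationError


class InsufficientDataError(ValueError):
    pass


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class QCConfig:
    min_rate_hz: float = 0.5
    min_isi_ms: float = 2.0
    min_total_spikes: int = 3000
    min_state_spikes: int = 1000
    duplicate_ccg_threshold: float = 0.9
    stability_alpha: float = 0.05
    manova_alpha: float = 0.05
    isi_fit_r2_min: float = 0.8
    dunn_good: float = 2.0
    dunn_ok: float = 1.0
    db_good: float = 0.3
    db_ok: float = 0.5
    pseudof_good: float = 100_000.0
    pseudof_ok: float = 50_000.0
    j3_good: float = 2.0
    j3_ok: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.stability_alpha < 1 and 0 < self.manova_alpha < 1):
            raise ValidationError("alpha values must be in (0, 1)")


# --------------------------------------------------------------------------
# per-unit statistics


def isi_statistics(
    spike_times: np.ndarray,
    min_isi_ms: float = 2.0,
    hist_range_ms: tuple[float, float] = (2.0, 500.0),
    hist_bin_ms: float = 10.0,
) -> tuple[float, float, float]:
    """(min ISI in ms, fraction of ISIs below ``min_isi_ms``, R^2 of a
    single-exponential fit to the supra-refractory ISI histogram).

    The fit is log-linear least squares on the nonzero 10 ms bins of the
    2-500 ms histogram; fewer than three nonzero bins (a delta-like,
    clearly non-exponential distribution) scores 0.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size < 2:
        raise InsufficientDataError("need at least 2 spikes for ISI statistics")
    isi_ms = np.diff(t) * 1000.0
    min_isi = float(isi_ms.min())
    violations = float(np.mean(isi_ms < min_isi_ms))
    lo, hi = hist_range_ms
    edges = np.arange(lo, hi + hist_bin_ms, hist_bin_ms)
    counts, _ = np.histogram(isi_ms, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    nz = counts > 0
    if nz.sum() < 3:
        return (min_isi, violations, 0.0)
    x, y = centers[nz], np.log(counts[nz].astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return (min_isi, violations, float(r2))


def waveform_stability(
    amplitudes: np.ndarray | None,
    half_widths: np.ndarray | None,
    alpha: float = 0.05,
) -> tuple[float | None, float | None, bool | None]:
    """Compare the first vs last 20% of each waveform series (one-way ANOVA).

    Returns (p_amplitude, p_halfwidth, stable); ``stable`` is None when a
    series is missing or too short to evaluate (fewer than 50 spikes).
    """
    ps: list[float] = []
    for series in (amplitudes, half_widths):
        if series is None:
            return (None, None, None)
        series = np.asarray(series, dtype=float)
        if series.size < 50:
            return (None, None, None)
        k = max(int(0.2 * series.size), 2)
        first, last = series[:k], series[-k:]
        if np.array_equal(first, last) or (np.ptp(first) == 0 and np.ptp(last) == 0 and first[0] == last[0]):
            ps.append(1.0)
            continue
        _, p = stats.f_oneway(first, last)
        ps.append(float(p))
    stable = bool(ps[0] >= alpha and ps[1] >= alpha)
    return (ps[0], ps[1], stable)


# --------------------------------------------------------------------------
# cluster-separation statistics on the waveform feature space


def _features_labels(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cols = [c for c in features.columns if c.startswith("f")]
    return features[cols].to_numpy(dtype=float), features["unit_id"].to_numpy()


def cluster_separation_p(features: np.ndarray, labels: np.ndarray) -> float:
    """One-way MANOVA p-value (Wilks' lambda, Rao's F approximation) for
    separation of the unit clusters in the full feature space."""
    from statsmodels.multivariate.manova import MANOVA

    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValidationError("need at least 2 clusters")
    d = X.shape[1]
    for g in groups:
        if np.sum(labels == g) <= d:
            raise ValidationError("each cluster needs more points than feature dimensions")
    df = pd.DataFrame(X, columns=[f"f{i + 1}" for i in range(d)])
    df["grp"] = labels.astype(str)
    formula = " + ".join(df.columns[:-1]) + " ~ C(grp)"
    try:
        res = MANOVA.from_formula(formula, data=df).mv_test()
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError("singular within-cluster scatter") from exc
    table = res.results["C(grp)"]["stat"]
    return float(table.loc["Wilks' lambda", "Pr > F"])


def dunn_index(features: np.ndarray, labels: np.ndarray) -> float:
    """Dunn 1 index: (min inter-cluster point distance) / (max cluster diameter)."""
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValidationError("need at least 2 clusters")
    clouds = [X[labels == g] for g in groups]
    diameters = [float(pdist(c).max()) if c.shape[0] > 1 else 0.0 for c in clouds]
    max_diam = max(diameters)
    if max_diam == 0:
        raise DegenerateGeometryError("all clusters have zero diameter")
    min_inter = min(
        float(cdist(clouds[i], clouds[j]).min()) for i, j in combinations(range(len(clouds)), 2)
    )
    return min_inter / max_diam


def _scatter_sums(X: np.ndarray, labels: np.ndarray):
    groups = np.unique(labels)
    grand = X.mean(axis=0)
    j1 = 0.0  # within-cluster sum of squared distances to centroids
    j2 = 0.0  # between: sum n_k ||centroid_k - grand||^2
    centroids = {}
    for g in groups:
        c = X[labels == g]
        mu = c.mean(axis=0)
        centroids[g] = mu
        j1 += float(np.sum((c - mu) ** 2))
        j2 += c.shape[0] * float(np.sum((mu - grand) ** 2))
    return j1, j2, centroids, groups


def pseudo_f(features: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz statistic: (J2/(k-1)) / (J1/(n-k))."""
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    j1, j2, _, groups = _scatter_sums(X, labels)
    n, k = X.shape[0], groups.size
    if k < 2:
        raise ValidationError("need at least 2 clusters")
    if n == k:
        raise DegenerateGeometryError("pseudo-F undefined when n == k")
    if j1 == 0:
        raise DegenerateGeometryError("zero within-cluster scatter")
    return (j2 / (k - 1)) / (j1 / (n - k))


def j3(features: np.ndarray, labels: np.ndarray) -> float:
    """J3 = J2 / J1 (between- over within-cluster scatter)."""
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    j1, j2, _, groups = _scatter_sums(X, labels)
    if groups.size < 2:
        raise ValidationError("need at least 2 clusters")
    if j1 == 0:
        raise DegenerateGeometryError("zero within-cluster scatter")
    return j2 / j1


def davies_bouldin(features: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of the worst
    (s_i + s_j) / d_ij, with s the mean distance to the centroid and d the
    centroid separation (lower is better)."""
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    _, _, centroids, groups = _scatter_sums(X, labels)
    if groups.size < 2:
        raise ValidationError("need at least 2 clusters")
    s = {
        g: float(np.mean(np.linalg.norm(X[labels == g] - centroids[g], axis=1))) for g in groups
    }
    worst = []
    for i, gi in enumerate(groups):
        ratios = []
        for gj in groups:
            if gi is gj or gi == gj:
                continue
            d = float(np.linalg.norm(centroids[gi] - centroids[gj]))
            if d == 0:
                raise DegenerateGeometryError("coincident centroids")
            ratios.append((s[gi] + s[gj]) / d)
        worst.append(max(ratios))
    return float(np.mean(worst))


# --------------------------------------------------------------------------
# duplicate-unit exclusion


def duplicate_pairs(
    trains: SpikeTrainSet, threshold: float = 0.9, bin_s: float = 0.001
) -> pd.DataFrame:
    """Pairs whose zero-lag 1 ms binned-count correlation exceeds the
    duplicate threshold; the lower-count unit of each pair is marked for
    exclusion."""
    units = sorted(trains.unit_ids)
    if len(units) < 2:
        return pd.DataFrame(columns=["unit_id_a", "unit_id_b", "r", "excluded_unit"])
    n_bins = int(np.ceil(trains.session_duration / bin_s))
    mat = np.zeros((len(units), n_bins), dtype=np.float32)
    for i, u in enumerate(units):
        idx = np.minimum((trains.spike_times[u] / bin_s).astype(np.int64), n_bins - 1)
        np.add.at(mat[i], idx, 1.0)
    with np.errstate(invalid="ignore"):
        cmat = np.corrcoef(mat)
    rows = []
    for (i, a), (j, b) in combinations(enumerate(units), 2):
        r = float(cmat[i, j])
        if np.isfinite(r) and r > threshold:
            smaller = a if trains.spike_times[a].size <= trains.spike_times[b].size else b
            ua, ub = canonical_pair(a, b)
            rows.append({"unit_id_a": ua, "unit_id_b": ub, "r": r, "excluded_unit": smaller})
    return pd.DataFrame(rows, columns=["unit_id_a", "unit_id_b", "r", "excluded_unit"])


# --------------------------------------------------------------------------
# the full battery


@dataclass
class QCReport:
    """Per-unit criterion flags/values, duplicate pairs, and the verdicts."""

    per_unit: pd.DataFrame
    duplicates: pd.DataFrame
    accepted: list[str] = field(default_factory=list)


def _index_grade(value: float, good: float, ok: float, lower_is_better: bool = False) -> str:
    if lower_is_better:
        return "good" if value <= good else ("ok" if value <= ok else "poor")
    return "good" if value >= good else ("ok" if value >= ok else "poor")


def apply_qc(
    trains: SpikeTrainSet,
    windows: StateWindows | None = None,
    config: QCConfig | None = None,
    features: pd.DataFrame | None = None,
) -> tuple[SpikeTrainSet, QCReport]:
    """Run the acceptance battery and return the surviving units.

    ``features`` (unit_id, spike_index, f1..f3) feeds the MANOVA and the
    validity indices, which are evaluated once over the session's sorting
    space; criteria whose inputs are absent are reported not-evaluable and
    do not reject a unit.
    """
    cfg = config or QCConfig()
    units = sorted(trains.unit_ids)

    manova_p = None
    grades: dict[str, str] = {}
    index_values: dict[str, float] = {}
    if features is not None and features["unit_id"].nunique() >= 2:
        X, labels = _features_labels(features)
        manova_p = cluster_separation_p(X, labels)
        index_values = {
            "dunn": dunn_index(X, labels),
            "davies_bouldin": davies_bouldin(X, labels),
            "pseudo_f": pseudo_f(X, labels),
            "j3": j3(X, labels),
        }
        grades = {
            "dunn": _index_grade(index_values["dunn"], cfg.dunn_good, cfg.dunn_ok),
            "davies_bouldin": _index_grade(
                index_values["davies_bouldin"], cfg.db_good, cfg.db_ok, lower_is_better=True
            ),
            "pseudo_f": _index_grade(index_values["pseudo_f"], cfg.pseudof_good, cfg.pseudof_ok),
            "j3": _index_grade(index_values["j3"], cfg.j3_good, cfg.j3_ok),
        }

    dup = duplicate_pairs(trains, cfg.duplicate_ccg_threshold)
    dup_excluded = set(dup["excluded_unit"]) if not dup.empty else set()

    rows = []
    for u in units:
        t = trains.spike_times[u]
        rec: dict[str, object] = {"unit_id": u, "n_spikes": int(t.size)}
        rec["rate_hz"] = trains.rate_hz(u)
        rec["rate_ok"] = rec["rate_hz"] > cfg.min_rate_hz
        try:
            min_isi, viol, r2 = isi_statistics(t, cfg.min_isi_ms)
            rec.update(min_isi_ms=min_isi, isi_violation_fraction=viol, isi_exp_fit_r2=r2)
            rec["isi_ok"] = min_isi > cfg.min_isi_ms
            rec["isi_shape_ok"] = r2 >= cfg.isi_fit_r2_min
        except InsufficientDataError:
            rec.update(min_isi_ms=np.nan, isi_violation_fraction=np.nan, isi_exp_fit_r2=np.nan)
            rec["isi_ok"] = False
            rec["isi_shape_ok"] = False
        p_amp, p_hw, stable = waveform_stability(
            trains.amplitudes.get(u), trains.half_widths.get(u), cfg.stability_alpha
        )
        rec.update(stability_p_amplitude=p_amp, stability_p_halfwidth=p_hw)
        rec["stability_ok"] = stable  # None = not evaluable, does not reject
        rec["total_count_ok"] = t.size > cfg.min_total_spikes
        if windows is not None:
            n_sp = int(spikes_in_windows(t, windows[SPONTANEOUS]).size)
            n_ev = int(spikes_in_windows(t, windows[EVOKED]).size)
            rec.update(spont_spikes=n_sp, evoked_spikes=n_ev)
            rec["state_count_ok"] = n_sp >= cfg.min_state_spikes and n_ev >= cfg.min_state_spikes
        else:
            rec["state_count_ok"] = None
        rec["manova_p"] = manova_p
        rec["separation_ok"] = None if manova_p is None else manova_p < cfg.manova_alpha
        if grades:
            rec.update({f"{k}_value": v for k, v in index_values.items()})
            rec.update({f"{k}_grade": g for k, g in grades.items()})
            n_good = sum(g == "good" for g in grades.values())
            n_poor = sum(g == "poor" for g in grades.values())
            rec["validity_ok"] = n_good >= 2 and n_poor == 0
        else:
            rec["validity_ok"] = None
        rec["duplicate"] = u in dup_excluded
        required = [
            rec["rate_ok"],
            rec["isi_ok"],
            rec["isi_shape_ok"],
            rec["total_count_ok"],
        ]
        optional = [rec["stability_ok"], rec["state_count_ok"], rec["separation_ok"], rec["validity_ok"]]
        rec["accept"] = (
            all(required)
            and all(v for v in optional if v is not None)
            and not rec["duplicate"]
        )
        rows.append(rec)
    per_unit = pd.DataFrame(rows)
    accepted = per_unit.loc[per_unit["accept"], "unit_id"].tolist()
    report = QCReport(per_unit=per_unit, duplicates=dup, accepted=accepted)
    return trains.subset(accepted), report
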