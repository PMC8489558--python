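"""One-call orchestration: simulate -> qc -> pairs -> connect -> topology ->
tuning -> dynamics, with every stage output written as plain CSV/JSON and a
summary of the headline statistics.

Each numeric in ``summary.json`` is reproducible by invoking the
corresponding stage on the stage inputs; the summary also records the seed,
package version and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import (
    ConnectivityCriteria,
    build_graph,
    connectivity_index_table,
    overlap_fraction,
)
from .dynamics import fit_recovery, time_resolved_index
from .io_formats import (
    read_events,
    read_spike_table,
    read_unit_meta,
    write_edge_list,
    write_events,
    write_spike_table,
    write_unit_meta,
)
from .network_structure import (
    common_neighbor_stats,
    congruence_stats,
    distance_profile,
    layer_stats,
    mean_connected_distance,
)
from .pairwise import EVOKED, SPONTANEOUS, make_state_windows, pair_metrics
from .synthetic import (
    default_configs,
    generate_session,
    generate_session_features,
)
from .tuning import angular_tuning, coarseness_preference
from .types import ValidationError
from .unit_qc import QCConfig, apply_qc

STAGES = ("simulate", "qc", "pairs", "connect", "topology", "tuning", "dynamics")


@dataclass
class PipelineConfig:
    out_dir: str = "synconn_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    input_dir: str | None = None  # read spike/events/meta here instead of simulating
    # generator
    protocol: str = "ramp_hold"
    n_units: int = 16
    n_assemblies: int = 2
    n_trials: int = 480
    gamma: float = 0.9
    tau_s: float = 1.2
    distance_penalty: float = 0.0
    incongruence_penalty: float = 0.0
    period_s: float | None = None
    # analysis
    spont_s: float = 0.6
    bin_s: float = 0.01
    max_lag_ms: float = 50.0
    ccg_bin_ms: float = 1.0
    dynamics_window_s: float = 0.5
    dynamics_step_s: float = 0.1
    criteria: ConnectivityCriteria = field(default_factory=ConnectivityCriteria)
    qc: QCConfig = field(default_factory=QCConfig)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stage(s) {sorted(unknown)}")
        if "simulate" not in self.stages and self.input_dir is None:
            raise ValidationError("without the simulate stage, input_dir is required")

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # identical analyses hash equal wherever written
        d.pop("input_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the summary dict (also written to
    ``summary.json``).  A stage failure aborts with the stage named while
    earlier outputs are retained on disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"synconn {__version__} seed={config.seed} config={config.hash()}"]
    summary: dict = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "version": __version__,
    }

    def _log(msg: str) -> None:
        log.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    stage = "simulate"
    try:
        if "simulate" in config.stages:
            assembly, modulation, tuning_cfg = default_configs(
                n_units=config.n_units,
                n_assemblies=config.n_assemblies,
                gamma=config.gamma,
                tau_s=config.tau_s,
                distance_penalty=config.distance_penalty,
                incongruence_penalty=config.incongruence_penalty,
                seed=config.seed,
            )
            trains, events, meta, gt = generate_session(
                assembly, modulation, tuning_cfg,
                protocol=config.protocol, n_trials=config.n_trials,
                seed=config.seed, period_s=config.period_s,
            )
            write_spike_table(trains, out / "spike_table.csv")
            write_events(events, out / "events.csv")
            write_unit_meta(meta, out / "unit_meta.csv")
            gt.to_json(out / "ground_truth.json")
            features = generate_session_features(trains, seed=config.seed)
            features.to_csv(out / "features.csv", index=False)
            _log(f"simulate: {trains.n_units} units, {events.n_events} trials, "
                 f"{sum(trains.counts().values())} spikes")
        else:
            src = Path(config.input_dir)
            trains = read_spike_table(src / "spike_table.csv")
            events = read_events(src / "events.csv")
            meta = read_unit_meta(src / "unit_meta.csv")
            fpath = src / "features.csv"
            features = pd.read_csv(fpath, dtype={"unit_id": str}) if fpath.exists() else None
            _log(f"load: {trains.n_units} units from {src}")

        windows = make_state_windows(events, spont_s=config.spont_s)

        stage = "qc"
        if "qc" in config.stages:
            trains_qc, report = apply_qc(trains, windows, config.qc, features)
            report.per_unit.to_csv(out / "qc_report.csv", index=False)
            _log(f"qc: accepted {len(report.accepted)}/{trains.n_units} units, "
                 f"{len(report.duplicates)} duplicate pairs")
            trains = trains_qc
            if trains.n_units < 2:
                raise ValidationError("fewer than 2 units survived QC")
            summary["n_units_accepted"] = trains.n_units

        stage = "pairs"
        metrics = None
        if "pairs" in config.stages:
            metrics = pair_metrics(
                trains, windows,
                bin_s=config.bin_s, max_lag_ms=config.max_lag_ms,
                ccg_bin_ms=config.ccg_bin_ms,
            )
            metrics.to_csv(out / "pair_metrics.csv", index=False)
            for state in (SPONTANEOUS, EVOKED):
                sub = metrics[metrics["state"] == state]["pearson_r"]
                summary[f"mean_pearson_r_{state}"] = float(np.nanmean(sub))
            _log(f"pairs: {metrics.shape[0] // 2} pairs x 2 states")

        stage = "connect"
        graphs = {}
        if "connect" in config.stages:
            if metrics is None:
                raise ValidationError("connect stage needs the pairs stage")
            for state in (SPONTANEOUS, EVOKED):
                graphs[state] = build_graph(metrics, state, config.criteria)
                write_edge_list(graphs[state].edges, out / f"edges_{state}.csv")
                summary[f"mean_connectivity_index_{state}"] = graphs[state].mean_index()
                summary[f"n_edges_{state}"] = graphs[state].n_edges
            idx_tbl = connectivity_index_table(graphs[SPONTANEOUS], graphs[EVOKED])
            idx_tbl.to_csv(out / "connectivity_index.csv", index=False)
            rel = idx_tbl["relative_change"]
            summary["mean_relative_change"] = (
                float(np.nanmean(rel)) if rel.notna().any() else float("nan")
            )
            summary["overlap_fraction"] = overlap_fraction(graphs[EVOKED], graphs[SPONTANEOUS])
            _log(
                "connect: edges spont=%d evoked=%d overlap=%.3f"
                % (graphs[SPONTANEOUS].n_edges, graphs[EVOKED].n_edges,
                   summary["overlap_fraction"] if np.isfinite(summary["overlap_fraction"]) else -1)
            )

        stage = "topology"
        if "topology" in config.stages and graphs:
            topo_rows = []
            for state, g in graphs.items():
                ts = common_neighbor_stats(g)
                topo_rows.append(dataclasses.asdict(ts))
                summary[f"p_common_{state}"] = ts.p_common
                summary[f"p_nocommon_{state}"] = ts.p_nocommon
                summary[f"p_expected_{state}"] = ts.p_expected
                summary[f"mean_connected_distance_um_{state}"] = mean_connected_distance(g, meta)
            pd.DataFrame(topo_rows).to_csv(out / "topology_report.csv", index=False)
            distance_profile(graphs, meta).to_csv(out / "distance_profile.csv", index=False)
            layer_stats(graphs[SPONTANEOUS], graphs[EVOKED], meta).to_csv(
                out / "layer_stats.csv", index=False
            )
            prefs = (
                {m.unit_id: m.preferred_angle for m in meta}
                if config.protocol == "ramp_hold"
                else {m.unit_id: m.preferred_coarseness for m in meta}
            )
            if all(v is not None for v in prefs.values()):
                for state, g in graphs.items():
                    cs = congruence_stats(g, {u: prefs[u] for u in g.nodes})
                    summary[f"congruence_observed_{state}"] = cs.observed
                    summary[f"congruence_expected_{state}"] = cs.expected
            _log("topology: done")

        stage = "tuning"
        if "tuning" in config.stages:
            rows = []
            for u in sorted(trains.unit_ids):
                try:
                    curve = (
                        angular_tuning(trains.spike_times[u], events)
                        if config.protocol == "ramp_hold"
                        else coarseness_preference(trains.spike_times[u], events)
                    )
                except ValidationError:
                    continue
                rows.append(
                    {
                        "unit_id": u,
                        "preferred": curve.preferred,
                        "selectivity": curve.selectivity,
                        "tie": curve.tie,
                        "max_response": float(np.nanmax(curve.mean_response)),
                    }
                )
            if rows:
                pd.DataFrame(rows).to_csv(out / "tuning.csv", index=False)
                _log(f"tuning: {len(rows)} units")

        stage = "dynamics"
        if "dynamics" in config.stages:
            series = time_resolved_index(
                trains, events, config.criteria,
                window_s=config.dynamics_window_s, step_s=config.dynamics_step_s,
                bin_s=config.bin_s, max_lag_ms=config.max_lag_ms,
                ccg_bin_ms=config.ccg_bin_ms,
            )
            pd.DataFrame(
                {"time_s": series.times_s, "mean_index": series.mean_index,
                 "sem_index": series.sem_index}
            ).to_csv(out / "ci_timeseries.csv", index=False)
            stim_dur = float(np.median(events.offsets - events.onsets))
            try:
                fit = fit_recovery(series, t_offset=stim_dur + config.dynamics_window_s / 2)
                (out / "recovery_fit.json").write_text(
                    json.dumps(dataclasses.asdict(fit), indent=2)
                )
                summary["recovery_tau_s"] = fit.tau_s
                summary["recovery_tau_se"] = fit.tau_se
                _log(f"dynamics: tau={fit.tau_s:.3f}s over {fit.n_points} points")
            except ValidationError as exc:
                # e.g. the index never left its baseline within the latency
                # grid: recovery is not evaluable for this session
                summary["recovery_tau_s"] = float("nan")
                _log(f"dynamics: recovery not evaluable ({exc})")
    except Exception as exc:
        (out / "run_log.txt").write_text("\n".join(log + [f"FAILED at stage {stage}: {exc}"]))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "run_log.txt").write_text("\n".join(log))
    return summary
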