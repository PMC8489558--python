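"""Plain-text (CSV) readers and writers for every pipeline artifact.

Dialect: comma-separated UTF-8 with a mandatory header row; times are written
in seconds with six decimal places so a write -> read roundtrip reproduces a
session exactly.  Edge lists are written with ``unit_id_a < unit_id_b``
(lexicographically) so graph files are canonical and diffable.

Columns
-------
``spike_table.csv``  unit_id, spike_time_s[, amplitude_uV, half_width_ms]
``events.csv``       onset_s, offset_s, stim_type[, angle_deg, texture]
``unit_meta.csv``    unit_id, contact_index, depth_um, layer[, preferred_angle,
                     preferred_coarseness]
``features.csv``     unit_id, spike_index, f1, f2[, f3]
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import STIM_TYPES, SessionEvents, SpikeTrainSet, UnitMeta, ValidationError

_TIME_FMT = "%.6f"


class FormatError(ValueError):
    """A table is missing required columns or contains unparseable values."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, column: str, path) -> np.ndarray:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.isna() & df[column].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{path}: non-numeric value {df[column].iloc[row]!r} in column "
            f"{column!r} at data row {row + 1}"
        )
    return values.to_numpy(dtype=float)


def read_spike_table(path, session_duration: float | None = None) -> SpikeTrainSet:
    """Load a spike table; spikes are sorted per unit on load.

    Duplicate (unit, time) rows are retained with a warning — refractory
    violations are a quality-control concern, not an I/O one.  When
    ``session_duration`` is not given it is taken as the last spike time.
    """
    df = pd.read_csv(path, dtype={"unit_id": str})
    _require_columns(df, ["unit_id", "spike_time_s"], path)
    times = _numeric(df, "spike_time_s", path)
    df = df.assign(spike_time_s=times)

    if df.duplicated(subset=["unit_id", "spike_time_s"]).any():
        warnings.warn(f"{path}: duplicate (unit, time) rows retained", stacklevel=2)

    spike_times: dict[str, np.ndarray] = {}
    amplitudes: dict[str, np.ndarray] = {}
    half_widths: dict[str, np.ndarray] = {}
    for unit_id, grp in df.groupby("unit_id", sort=True):
        order = np.argsort(grp["spike_time_s"].to_numpy(), kind="stable")
        spike_times[unit_id] = grp["spike_time_s"].to_numpy()[order]
        if "amplitude_uV" in df.columns and grp["amplitude_uV"].notna().all():
            amplitudes[unit_id] = _numeric(grp, "amplitude_uV", path)[order]
        if "half_width_ms" in df.columns and grp["half_width_ms"].notna().all():
            half_widths[unit_id] = _numeric(grp, "half_width_ms", path)[order]

    if session_duration is None:
        session_duration = float(times.max()) if times.size else 1.0
    return SpikeTrainSet(spike_times, session_duration, amplitudes, half_widths)


def write_spike_table(trains: SpikeTrainSet, path) -> Path:
    path = Path(path)
    rows = []
    has_amp = bool(trains.amplitudes)
    has_hw = bool(trains.half_widths)
    for u in sorted(trains.unit_ids):
        t = trains.spike_times[u]
        rec = {"unit_id": np.repeat(u, t.size), "spike_time_s": t}
        if has_amp:
            rec["amplitude_uV"] = trains.amplitudes.get(u, np.full(t.size, np.nan))
        if has_hw:
            rec["half_width_ms"] = trains.half_widths.get(u, np.full(t.size, np.nan))
        rows.append(pd.DataFrame(rec))
    columns = ["unit_id", "spike_time_s"] + (["amplitude_uV"] if has_amp else []) + (
        ["half_width_ms"] if has_hw else []
    )
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=columns)
    df.to_csv(path, index=False, float_format=_TIME_FMT)
    return path


def read_events(path) -> SessionEvents:
    df = pd.read_csv(path)
    _require_columns(df, ["onset_s", "offset_s", "stim_type"], path)
    if df.empty:
        raise FormatError(f"{path}: events table is empty")
    stim_types = set(df["stim_type"].astype(str))
    if not stim_types <= set(STIM_TYPES):
        raise ValidationError(f"{path}: unknown stim_type {stim_types - set(STIM_TYPES)}")
    if len(stim_types) > 1:
        raise ValidationError(f"{path}: mixed stim_type values in one session")
    angle = None
    if "angle_deg" in df.columns and df["angle_deg"].notna().any():
        angle = _numeric(df, "angle_deg", path)
    texture = None
    if "texture" in df.columns and df["texture"].notna().any():
        texture = df["texture"].to_numpy(dtype=object)
    return SessionEvents(
        onsets=_numeric(df, "onset_s", path),
        offsets=_numeric(df, "offset_s", path),
        stim_type=stim_types.pop(),
        angle_deg=angle,
        texture=texture,
    )


def write_events(events: SessionEvents, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "onset_s": events.onsets,
        "offset_s": events.offsets,
        "stim_type": events.stim_type,
    })
    if events.angle_deg is not None:
        df["angle_deg"] = events.angle_deg
    if events.texture is not None:
        df["texture"] = events.texture
    df.to_csv(path, index=False, float_format=_TIME_FMT)
    return path


def read_unit_meta(path) -> list[UnitMeta]:
    df = pd.read_csv(path, dtype={"unit_id": str})
    _require_columns(df, ["unit_id", "contact_index", "depth_um"], path)
    meta = []
    for _, row in df.iterrows():
        angle = row.get("preferred_angle")
        coarse = row.get("preferred_coarseness")
        meta.append(
            UnitMeta(
                unit_id=str(row["unit_id"]),
                contact_index=int(row["contact_index"]),
                depth_um=float(row["depth_um"]),
                layer=str(row["layer"]) if "layer" in df.columns and pd.notna(row.get("layer")) else "",
                preferred_angle=None if pd.isna(angle) else int(angle),
                preferred_coarseness=None if (coarse is None or pd.isna(coarse)) else str(coarse),
            )
        )
    return meta


def write_unit_meta(meta: list[UnitMeta], path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "unit_id": [m.unit_id for m in meta],
            "contact_index": [m.contact_index for m in meta],
            "depth_um": [m.depth_um for m in meta],
            "layer": [m.layer for m in meta],
            "preferred_angle": [m.preferred_angle for m in meta],
            "preferred_coarseness": [m.preferred_coarseness for m in meta],
        }
    )
    df.to_csv(path, index=False)
    return path


def read_features(path) -> pd.DataFrame:
    """Waveform feature cloud: one row per spike, labelled by unit."""
    df = pd.read_csv(path, dtype={"unit_id": str})
    _require_columns(df, ["unit_id", "spike_index", "f1", "f2"], path)
    return df


def write_features(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographic) ordering of an unordered unit pair."""
    return (a, b) if a <= b else (b, a)


def write_edge_list(edges: list[tuple[str, str]], path, attrs: pd.DataFrame | None = None) -> Path:
    path = Path(path)
    canon = sorted(canonical_pair(a, b) for a, b in edges)
    df = pd.DataFrame(canon, columns=["unit_id_a", "unit_id_b"])
    if attrs is not None:
        df = df.merge(attrs, on=["unit_id_a", "unit_id_b"], how="left")
    df.to_csv(path, index=False)
    return path


def read_edge_list(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["unit_id_a", "unit_id_b"], path)
    return [canonical_pair(a, b) for a, b in zip(df["unit_id_a"], df["unit_id_b"])]


def write_results(tables: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write a dict of result tables (pair metrics, per-unit indices, edges)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    return paths
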