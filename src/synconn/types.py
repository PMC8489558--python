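"""Core domain containers shared across the pipeline.

A recording session is represented by three small objects: the sorted spike
trains (:class:`SpikeTrainSet`), the probe/unit metadata (:class:`UnitMeta`)
and the stimulus protocol (:class:`SessionEvents`).  All downstream stages
(quality control, pairwise synchrony, connectivity graphs, tuning, recovery
dynamics) consume these and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Deflection directions used for angular tuning (degrees).
ANGLES: tuple[int, ...] = (0, 45, 90, 135, 180, 225, 270, 315)

#: Sandpaper grades (plus smooth surface) used for coarseness tuning.
TEXTURES: tuple[str, ...] = ("P120", "P320", "P600", "P1000", "smooth")

#: Putative cortical layers spanned by the 16-contact probe.
LAYERS: tuple[str, ...] = ("L2/3", "L4", "L5")

#: Valid stimulation protocols.
STIM_TYPES: tuple[str, ...] = ("ramp_hold", "artificial_whisking")

#: Probe geometry: 16 contacts at 50 um pitch, first contact 200 um below pia.
N_CONTACTS = 16
CONTACT_PITCH_UM = 50.0
FIRST_CONTACT_DEPTH_UM = 200.0

#: Depth ranges (um below pia) used to assign putative layers when only the
#: contact depth is known.  Configurable in the functions that use them.
LAYER_BOUNDS_UM: dict[str, tuple[float, float]] = {
    "L2/3": (200.0, 550.0),
    "L4": (550.0, 750.0),
    "L5": (750.0, 1050.0),
}


class ValidationError(ValueError):
    """An input table or container violates a structural invariant."""


def layer_from_depth(depth_um: float, bounds: dict[str, tuple[float, float]] | None = None) -> str:
    """Assign a putative layer from recording depth (um below pia)."""
    bounds = bounds or LAYER_BOUNDS_UM
    for layer, (lo, hi) in bounds.items():
        if lo <= depth_um < hi or (hi == max(h for _, h in bounds.values()) and depth_um == hi):
            return layer
    raise ValidationError(f"depth {depth_um} um outside probe span")


@dataclass
class SpikeTrainSet:
    """Sorted single-unit spike trains for one session.

    Parameters
    ----------
    spike_times
        Mapping unit id -> strictly increasing spike times in seconds from
        session start.
    session_duration
        Session length in seconds; all spikes lie in ``[0, session_duration]``.
    amplitudes, half_widths
        Optional per-spike waveform summaries (uV / ms), parallel to
        ``spike_times`` for the units that carry them.
    """

    spike_times: dict[str, np.ndarray]
    session_duration: float
    amplitudes: dict[str, np.ndarray] = field(default_factory=dict)
    half_widths: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times = {u: np.asarray(t, dtype=float) for u, t in self.spike_times.items()}
        self.amplitudes = {u: np.asarray(a, dtype=float) for u, a in self.amplitudes.items()}
        self.half_widths = {u: np.asarray(h, dtype=float) for u, h in self.half_widths.items()}
        self.validate()

    @property
    def unit_ids(self) -> list[str]:
        return list(self.spike_times)

    @property
    def n_units(self) -> int:
        return len(self.spike_times)

    def counts(self) -> dict[str, int]:
        return {u: t.size for u, t in self.spike_times.items()}

    def rate_hz(self, unit_id: str) -> float:
        return self.spike_times[unit_id].size / self.session_duration

    def subset(self, unit_ids) -> "SpikeTrainSet":
        keep = [u for u in self.unit_ids if u in set(unit_ids)]
        return SpikeTrainSet(
            spike_times={u: self.spike_times[u] for u in keep},
            session_duration=self.session_duration,
            amplitudes={u: self.amplitudes[u] for u in keep if u in self.amplitudes},
            half_widths={u: self.half_widths[u] for u in keep if u in self.half_widths},
        )

    def validate(self) -> None:
        if self.session_duration <= 0:
            raise ValidationError("session_duration must be positive")
        for u, t in self.spike_times.items():
            if t.size and (np.any(np.diff(t) < 0)):
                raise ValidationError(f"unit {u}: spike times not sorted")
            if t.size and (t[0] < 0 or t[-1] > self.session_duration):
                raise ValidationError(f"unit {u}: spike times outside [0, duration]")
            for name, extra in (("amplitudes", self.amplitudes), ("half_widths", self.half_widths)):
                if u in extra and extra[u].size != t.size:
                    raise ValidationError(f"unit {u}: {name} not parallel to spike times")


@dataclass
class UnitMeta:
    """Probe placement and tuning metadata for one unit."""

    unit_id: str
    contact_index: int
    depth_um: float
    layer: str = ""
    preferred_angle: int | None = None
    preferred_coarseness: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= int(self.contact_index) < N_CONTACTS):
            raise ValidationError(f"contact_index {self.contact_index} outside 0..{N_CONTACTS - 1}")
        if not (FIRST_CONTACT_DEPTH_UM <= self.depth_um <= 1050.0):
            raise ValidationError(f"depth_um {self.depth_um} outside [200, 1050]")
        if not self.layer:
            self.layer = layer_from_depth(self.depth_um)
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}")
        if self.preferred_angle is not None and int(self.preferred_angle) not in ANGLES:
            raise ValidationError(f"preferred_angle {self.preferred_angle} not one of {ANGLES}")
        if self.preferred_coarseness is not None and self.preferred_coarseness not in TEXTURES:
            raise ValidationError(f"preferred_coarseness {self.preferred_coarseness!r} unknown")


def validate_probe_geometry(meta: list[UnitMeta]) -> None:
    """Check that unit depths are consistent with the 50 um contact pitch.

    All units must satisfy ``depth_um = base + 50 * contact_index`` for a
    single session-wide base depth (the depth of contact 0).
    """
    if not meta:
        return
    bases = {m.depth_um - CONTACT_PITCH_UM * m.contact_index for m in meta}
    if len(bases) > 1:
        raise ValidationError(f"inconsistent contact pitch: inferred base depths {sorted(bases)}")


@dataclass
class SessionEvents:
    """Stimulus events of one session.

    ``stim_type`` applies to all events of the session (a session uses one
    protocol).  ``angle_deg`` / ``texture`` are per-event condition labels
    and may be None when the protocol does not vary that dimension.
    """

    onsets: np.ndarray
    offsets: np.ndarray
    stim_type: str
    angle_deg: np.ndarray | None = None
    texture: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.angle_deg is not None:
            self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        if self.texture is not None:
            self.texture = np.asarray(self.texture, dtype=object)
        self.validate()

    @property
    def n_events(self) -> int:
        return int(self.onsets.size)

    def validate(self) -> None:
        if self.stim_type not in STIM_TYPES:
            raise ValidationError(f"unknown stim_type {self.stim_type!r}")
        if self.onsets.size != self.offsets.size:
            raise ValidationError("onsets and offsets differ in length")
        if self.onsets.size:
            if np.any(np.diff(self.onsets) <= 0):
                raise ValidationError("onsets must be strictly increasing")
            if np.any(self.offsets <= self.onsets):
                raise ValidationError("every offset must exceed its onset")
            if np.any(self.onsets[1:] < self.offsets[:-1]):
                raise ValidationError("events overlap")
        for name, arr in (("angle_deg", self.angle_deg), ("texture", self.texture)):
            if arr is not None and arr.size != self.onsets.size:
                raise ValidationError(f"{name} not parallel to onsets")

    def select(self, mask: np.ndarray) -> "SessionEvents":
        return SessionEvents(
            onsets=self.onsets[mask],
            offsets=self.offsets[mask],
            stim_type=self.stim_type,
            angle_deg=None if self.angle_deg is None else self.angle_deg[mask],
            texture=None if self.texture is None else self.texture[mask],
        )
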