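"""Synthetic recording sessions with known correlation structure.

The generator emulates the statistical structure of multi-unit barrel-cortex
recordings: Poisson-like background firing, assembly-structured pairwise
count correlations, a 16-contact linear probe at 50 um pitch, angular and
coarseness tuning, stimulus-evoked desynchronization and post-stimulus
exponential recovery of correlations.

Correlation mechanism
---------------------
Each assembly owns a latent homogeneous Poisson "mother" process with rate
``lambda_m``.  Member unit *u* independently copies each mother spike with
probability ``p_u`` (multiple-interaction-process style thinning), jitters
the copy by a zero-mean Gaussian (``jitter_sd_ms``), and superimposes an
independent Poisson background at ``b_u``.  For count bins much wider than
the jitter this yields the closed-form pairwise count correlation

    rho_ij = p_i p_j lambda_m / sqrt((p_i lambda_m + b_i)(p_j lambda_m + b_j))

which is the oracle every downstream synchrony estimate is checked against.

State modulation
----------------
During each evoked window the copy probability of unit *u* is multiplied by
an effective factor ``gamma_eff(u) <= 1``, and after stimulus offset the
factor relaxes back to 1 as ``1 - (1 - gamma_eff) * exp(-t / tau)`` applied
in 100 ms piecewise-constant steps.  Desynchronization is pure
decorrelation, not rate suppression: the copy rate lost to the factor,
``p_u * lambda_m * (1 - f(t))``, is replaced by independent Poisson firing,
and an independent tuned rate component adds spikes during stimulation —
so evoked firing rates stay level or rise while pairwise correlations
fall, the dissociation the recordings show.  ``gamma_eff`` is reduced further with the unit's depth distance from
its assembly center and when the unit's tuning preference disagrees with its
assembly's, which is what makes distant and incongruent pairs preferentially
"disconnect" during stimulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ANGLES,
    CONTACT_PITCH_UM,
    FIRST_CONTACT_DEPTH_UM,
    N_CONTACTS,
    TEXTURES,
    SessionEvents,
    SpikeTrainSet,
    UnitMeta,
    ValidationError,
    layer_from_depth,
)

RAMP_HOLD_DURATION_S = 0.2  # 200 ms ramp-and-hold deflection
RAMP_HOLD_PERIOD_S = 2.0  # stimuli delivered at 0.5 Hz
WHISKING_CYCLES = 10
WHISKING_RATE_HZ = 5.5  # 10 protraction-retraction cycles at 5.5 Hz
WHISKING_DURATION_S = WHISKING_CYCLES / WHISKING_RATE_HZ
WHISKING_PERIOD_S = 4.0
RELAX_STEP_S = 0.1  # piecewise-constant recovery steps


class UndefinedCorrelationError(ValueError):
    """Both units have zero expected rate; the correlation is undefined."""


# --------------------------------------------------------------------------
# configuration containers


@dataclass
class AssemblyConfig:
    """Mother-process / thinning parameters of the correlation structure.

    ``membership`` maps unit id -> assembly index (-1 for background-only
    units); ``copy_prob`` maps unit id -> per-spike inheritance probability.
    """

    membership: dict[str, int]
    copy_prob: dict[str, float]
    mother_rate_hz: float = 12.0
    background_rate_hz: float | dict[str, float] = 3.0
    jitter_sd_ms: float = 1.0
    refractory_ms: float = 2.0  # per-unit dead time, as sorted single units show

    def __post_init__(self) -> None:
        bg = (
            self.background_rate_hz.values()
            if isinstance(self.background_rate_hz, dict)
            else [self.background_rate_hz]
        )
        if self.mother_rate_hz < 0 or min(bg) < 0:
            raise ValidationError("rates must be >= 0")
        if self.jitter_sd_ms < 0:
            raise ValidationError("jitter_sd_ms must be >= 0")
        if self.refractory_ms < 0:
            raise ValidationError("refractory_ms must be >= 0")
        for u, p in self.copy_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"copy_prob[{u}] = {p} outside [0, 1]")

    @property
    def unit_ids(self) -> list[str]:
        return list(self.membership)

    def background_of(self, unit_id: str) -> float:
        if isinstance(self.background_rate_hz, dict):
            return self.background_rate_hz[unit_id]
        return self.background_rate_hz

    def assemblies(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for u, a in self.membership.items():
            if a >= 0:
                out.setdefault(a, []).append(u)
        return out


@dataclass
class StateModulation:
    """Evoked desynchronization and post-stimulus recovery parameters."""

    evoked_copy_factor: float = 0.9  # gamma: multiplier on copy_prob while stimulated
    distance_penalty: float = 0.0  # extra reduction per 100 um from assembly center
    incongruence_penalty: float = 0.0  # extra reduction when unit pref != assembly pref
    recovery_tau_s: float = 1.2  # time constant of relaxation back to baseline

    def __post_init__(self) -> None:
        for name in ("evoked_copy_factor", "distance_penalty", "incongruence_penalty"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} = {v} outside [0, 1]")
        if self.recovery_tau_s <= 0:
            raise ValidationError("recovery_tau_s must be > 0")


@dataclass
class TuningConfig:
    """Per-unit stimulus preferences and the evoked rate component."""

    preferred_angle: dict[str, int] = field(default_factory=dict)
    preferred_coarseness: dict[str, str] = field(default_factory=dict)
    assembly_preferred_angle: dict[int, int] = field(default_factory=dict)
    assembly_preferred_coarseness: dict[int, str] = field(default_factory=dict)
    evoked_gain_hz: float = 10.0  # added rate at the preferred condition
    tuning_width_deg: float = 40.0  # Gaussian falloff scale for angles
    texture_falloff: float = 0.2  # gain fraction at non-preferred textures

    def __post_init__(self) -> None:
        if self.evoked_gain_hz < 0:
            raise ValidationError("evoked_gain_hz must be >= 0")
        for u, a in self.preferred_angle.items():
            if int(a) not in ANGLES:
                raise ValidationError(f"preferred_angle[{u}] = {a} not in {ANGLES}")
        for u, t in self.preferred_coarseness.items():
            if t not in TEXTURES:
                raise ValidationError(f"preferred_coarseness[{u}] = {t!r} unknown")


@dataclass
class SyntheticGroundTruth:
    """Everything the pipeline's estimates can be checked against."""

    assembly: AssemblyConfig
    modulation: StateModulation
    tuning: TuningConfig
    seed: int
    expected_spont_corr: dict[tuple[str, str], float]
    same_assembly_pairs: list[tuple[str, str]]

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "seed": self.seed,
            "mother_rate_hz": self.assembly.mother_rate_hz,
            "background_rate_hz": self.assembly.background_rate_hz,
            "jitter_sd_ms": self.assembly.jitter_sd_ms,
            "membership": self.assembly.membership,
            "copy_prob": self.assembly.copy_prob,
            "evoked_copy_factor": self.modulation.evoked_copy_factor,
            "distance_penalty": self.modulation.distance_penalty,
            "incongruence_penalty": self.modulation.incongruence_penalty,
            "recovery_tau_s": self.modulation.recovery_tau_s,
            "preferred_angle": self.tuning.preferred_angle,
            "preferred_coarseness": self.tuning.preferred_coarseness,
            "expected_spont_corr": {f"{a}|{b}": r for (a, b), r in self.expected_spont_corr.items()},
            "same_assembly_pairs": [list(p) for p in self.same_assembly_pairs],
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


# --------------------------------------------------------------------------
# closed-form oracle


def expected_pair_correlation(
    p_i: float, p_j: float, mother_rate_hz: float, b_i: float, b_j: float
) -> float:
    """Expected binned-count Pearson correlation of two thinned-mother units.

    Valid when the count bin is much wider than the copy jitter.  Raises
    :class:`UndefinedCorrelationError` when both units have zero rate.
    """
    if min(p_i, p_j) < 0 or max(p_i, p_j) > 1 or mother_rate_hz < 0 or min(b_i, b_j) < 0:
        raise ValidationError("invalid thinning parameters")
    var_i = p_i * mother_rate_hz + b_i
    var_j = p_j * mother_rate_hz + b_j
    if var_i == 0 and var_j == 0:
        raise UndefinedCorrelationError("both units have zero expected rate")
    if var_i == 0 or var_j == 0:
        return 0.0
    return p_i * p_j * mother_rate_hz / float(np.sqrt(var_i * var_j))


# --------------------------------------------------------------------------
# default study configuration


def default_configs(
    n_units: int = 16,
    n_assemblies: int = 2,
    gamma: float = 0.9,
    tau_s: float = 1.2,
    distance_penalty: float = 0.0,
    incongruence_penalty: float = 0.0,
    tuning_alignment: float = 0.75,
    seed: int = 0,
) -> tuple[AssemblyConfig, StateModulation, TuningConfig]:
    """Build the default study conditions.

    Units are laid out one per contact (round-robin past 16); assemblies are
    contiguous blocks of contacts so connectivity is spatially structured.
    Copy probabilities are spread evenly over [0.5, 0.75] so pair
    correlations straddle the connectivity threshold, and each unit shares
    its assembly's preferred angle/texture with probability
    ``tuning_alignment`` (else a random other preference).
    """
    rng = np.random.default_rng(seed)
    unit_ids = [f"u{i:02d}" for i in range(n_units)]
    block = int(np.ceil(n_units / n_assemblies))
    membership = {u: min(i // block, n_assemblies - 1) for i, u in enumerate(unit_ids)}
    # heterogeneous copy probabilities, interleaved so every assembly spans the
    # range, plus heterogeneous background rates decorrelated from copy prob:
    # together these spread baseline pair correlations from just above the
    # connectivity threshold up to ~0.6, as recorded populations show
    ps = np.linspace(0.5, 0.75, max(block, 2))
    copy_prob = {u: float(ps[i % block]) for i, u in enumerate(unit_ids)}
    bgs = np.linspace(2.5, 7.5, n_units)
    stride = 5 if n_units % 5 else 3
    background = {u: float(bgs[(i * stride) % n_units]) for i, u in enumerate(unit_ids)}
    assembly = AssemblyConfig(
        membership=membership, copy_prob=copy_prob, background_rate_hz=background
    )

    modulation = StateModulation(
        evoked_copy_factor=gamma,
        distance_penalty=distance_penalty,
        incongruence_penalty=incongruence_penalty,
        recovery_tau_s=tau_s,
    )

    asm_angle = {a: ANGLES[a % len(ANGLES)] for a in range(n_assemblies)}
    asm_tex = {a: TEXTURES[a % len(TEXTURES)] for a in range(n_assemblies)}
    pref_angle: dict[str, int] = {}
    pref_tex: dict[str, str] = {}
    for u in unit_ids:
        a = membership[u]
        if rng.random() < tuning_alignment:
            pref_angle[u] = asm_angle[a]
        else:
            pref_angle[u] = int(rng.choice([x for x in ANGLES if x != asm_angle[a]]))
        if rng.random() < tuning_alignment:
            pref_tex[u] = asm_tex[a]
        else:
            pref_tex[u] = str(rng.choice([x for x in TEXTURES if x != asm_tex[a]]))
    tuning = TuningConfig(
        preferred_angle=pref_angle,
        preferred_coarseness=pref_tex,
        assembly_preferred_angle=asm_angle,
        assembly_preferred_coarseness=asm_tex,
    )
    return assembly, modulation, tuning


def default_unit_meta(config: AssemblyConfig, tuning: TuningConfig | None = None) -> list[UnitMeta]:
    """One unit per contact (round-robin past 16) on the 50 um probe."""
    meta = []
    for i, u in enumerate(config.unit_ids):
        contact = i % N_CONTACTS
        depth = FIRST_CONTACT_DEPTH_UM + CONTACT_PITCH_UM * contact
        meta.append(
            UnitMeta(
                unit_id=u,
                contact_index=contact,
                depth_um=depth,
                layer=layer_from_depth(depth),
                preferred_angle=tuning.preferred_angle.get(u) if tuning else None,
                preferred_coarseness=tuning.preferred_coarseness.get(u) if tuning else None,
            )
        )
    return meta


# --------------------------------------------------------------------------
# spike-train generation


def _ground_truth(
    config: AssemblyConfig,
    modulation: StateModulation,
    tuning: TuningConfig,
    seed: int,
) -> SyntheticGroundTruth:
    units = config.unit_ids
    expected: dict[tuple[str, str], float] = {}
    same_assembly: list[tuple[str, str]] = []
    for i, a in enumerate(units):
        for b in units[i + 1 :]:
            pair = (a, b) if a <= b else (b, a)
            if config.membership[a] == config.membership[b] and config.membership[a] >= 0:
                same_assembly.append(pair)
                expected[pair] = expected_pair_correlation(
                    config.copy_prob[a],
                    config.copy_prob[b],
                    config.mother_rate_hz,
                    config.background_of(a),
                    config.background_of(b),
                )
            else:
                expected[pair] = 0.0
    return SyntheticGroundTruth(config, modulation, tuning, seed, expected, same_assembly)


def _enforce_refractory(t: np.ndarray, refractory_s: float) -> np.ndarray:
    """Greedy dead-time: drop any spike closer than ``refractory_s`` to the
    previously kept one (sorted single units show no sub-refractory ISIs)."""
    if refractory_s <= 0 or t.size < 2:
        return t
    keep = np.ones(t.size, dtype=bool)
    last = t[0]
    for i in range(1, t.size):
        if t[i] - last < refractory_s:
            keep[i] = False
        else:
            last = t[i]
    return t[keep]


def _poisson_times(rng: np.random.Generator, rate_hz: float, duration_s: float) -> np.ndarray:
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def generate_correlated_trains(
    config: AssemblyConfig, duration_s: float, seed: int
) -> tuple[SpikeTrainSet, SyntheticGroundTruth]:
    """Stationary (no stimulation) correlated trains via mother-process thinning."""
    if duration_s <= 0:
        raise ValidationError("duration_s must be > 0")
    rng = np.random.default_rng(seed)
    mothers = {a: _poisson_times(rng, config.mother_rate_hz, duration_s) for a in config.assemblies()}
    sigma_s = config.jitter_sd_ms / 1000.0
    spike_times: dict[str, np.ndarray] = {}
    for u in config.unit_ids:
        a = config.membership[u]
        copied = np.empty(0)
        if a >= 0 and mothers.get(a) is not None and mothers[a].size:
            m = mothers[a]
            keep = rng.random(m.size) < config.copy_prob[u]
            copied = m[keep]
            if sigma_s > 0 and copied.size:
                copied = copied + rng.normal(0.0, sigma_s, size=copied.size)
        background = _poisson_times(rng, config.background_of(u), duration_s)
        t = np.sort(np.concatenate([copied, background]))
        t = _enforce_refractory(np.clip(t, 0.0, duration_s), config.refractory_ms / 1000.0)
        spike_times[u] = t
    trains = SpikeTrainSet(spike_times, duration_s)
    gt = _ground_truth(config, StateModulation(), TuningConfig(), seed)
    return trains, gt


def build_events(
    protocol: str,
    n_trials: int,
    tuning: TuningConfig | None = None,
    start_s: float = 5.0,
    period_s: float | None = None,
    seed: int = 0,
) -> SessionEvents:
    """Stimulus train for one protocol.

    Ramp-and-hold: 200 ms deflections at 0.5 Hz (2 s spacing), optionally
    cycling the 8 deflection angles; artificial whisking: 10-cycle 5.5 Hz
    trains (~1.818 s), cycling the 5 textures.  Conditions are applied in
    per-condition blocks of two halves whose order is drawn from the seed,
    mirroring a blocked-randomized protocol.
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    if protocol == "ramp_hold":
        duration = RAMP_HOLD_DURATION_S
        period = RAMP_HOLD_PERIOD_S if period_s is None else period_s
        conditions = list(ANGLES) if (tuning and tuning.preferred_angle) else None
        label = "angle_deg"
    elif protocol == "artificial_whisking":
        duration = WHISKING_DURATION_S
        period = WHISKING_PERIOD_S if period_s is None else period_s
        conditions = list(TEXTURES) if (tuning and tuning.preferred_coarseness) else None
        label = "texture"
    else:
        raise ValidationError(f"unknown protocol {protocol!r}")
    if period <= duration:
        raise ValidationError("inter-trial period must exceed stimulus duration")

    onsets = start_s + period * np.arange(n_trials)
    offsets = onsets + duration

    angle = texture = None
    if conditions is not None:
        reps = int(np.ceil(n_trials / len(conditions)))
        half = max(reps // 2, 1)
        blocks = []
        for c in conditions:
            blocks.append([c] * half)
            if reps - half:
                blocks.append([c] * (reps - half))
        order = rng.permutation(len(blocks))
        seq = [c for k in order for c in blocks[k]][:n_trials]
        while len(seq) < n_trials:  # n_trials smaller than one full block set
            seq.append(conditions[len(seq) % len(conditions)])
        if label == "angle_deg":
            angle = np.asarray(seq, dtype=float)
        else:
            texture = np.asarray(seq, dtype=object)
    return SessionEvents(onsets, offsets, protocol, angle_deg=angle, texture=texture)


def _gamma_eff(
    unit: str,
    config: AssemblyConfig,
    modulation: StateModulation,
    tuning: TuningConfig,
    meta_depth: dict[str, float],
    centers: dict[int, float],
    protocol: str,
) -> float:
    """Per-unit effective evoked copy factor with distance/congruence penalties."""
    g = modulation.evoked_copy_factor
    a = config.membership[unit]
    if a < 0:
        return g
    if modulation.distance_penalty > 0 and unit in meta_depth and a in centers:
        d_um = abs(meta_depth[unit] - centers[a])
        g *= max(0.0, 1.0 - modulation.distance_penalty * d_um / 100.0)
    if modulation.incongruence_penalty > 0:
        if protocol == "ramp_hold":
            pref, asm_pref = tuning.preferred_angle.get(unit), tuning.assembly_preferred_angle.get(a)
        else:
            pref, asm_pref = (
                tuning.preferred_coarseness.get(unit),
                tuning.assembly_preferred_coarseness.get(a),
            )
        if pref is not None and asm_pref is not None and pref != asm_pref:
            g *= 1.0 - modulation.incongruence_penalty
    return g


def _copy_factor_at(
    times: np.ndarray,
    onsets: np.ndarray,
    offsets: np.ndarray,
    gamma_eff: float,
    tau_s: float,
) -> np.ndarray:
    """Piecewise effective copy factor f(t): 1 baseline, gamma_eff while
    stimulated, then 1 - (1 - gamma_eff) exp(-dt/tau) in 100 ms steps."""
    f = np.ones_like(times)
    if not onsets.size:
        return f
    idx = np.searchsorted(onsets, times, side="right") - 1
    inside = idx >= 0
    if not np.any(inside):
        return f
    last_on = onsets[np.clip(idx, 0, None)]
    last_off = offsets[np.clip(idx, 0, None)]
    evoked = inside & (times >= last_on) & (times <= last_off)
    f[evoked] = gamma_eff
    post = inside & (times > last_off)
    dt = np.floor((times[post] - last_off[post]) / RELAX_STEP_S) * RELAX_STEP_S
    f[post] = 1.0 - (1.0 - gamma_eff) * np.exp(-dt / tau_s)
    return f


def _tuning_weight(tuning: TuningConfig, protocol: str, pref, condition) -> float:
    if condition is None or pref is None:
        return 1.0  # unconditioned stimulation drives every unit fully
    if protocol == "ramp_hold":
        d = abs(float(pref) - float(condition)) % 360.0
        d = min(d, 360.0 - d)
        return float(np.exp(-(d**2) / (2.0 * tuning.tuning_width_deg**2)))
    return 1.0 if pref == condition else tuning.texture_falloff


def generate_session(
    assembly: AssemblyConfig,
    modulation: StateModulation,
    tuning: TuningConfig,
    protocol: str = "ramp_hold",
    n_trials: int = 480,
    seed: int = 0,
    period_s: float | None = None,
    start_s: float = 5.0,
    tail_s: float = 5.0,
    waveform_streams: bool = True,
) -> tuple[SpikeTrainSet, SessionEvents, list[UnitMeta], SyntheticGroundTruth]:
    """Full synthetic session: events, modulated correlated trains, metadata.

    The default 480 trials mirrors 8 deflection angles x 60 repetitions; at
    ~10 Hz unit rates this is also what makes the absolute spike-count
    acceptance floors (3,000 per session / 1,000 per state) attainable.
    """
    if protocol == "artificial_whisking" and tuning.preferred_angle and not tuning.preferred_coarseness:
        raise ValidationError("angle tuning given for a whisking protocol")
    rng = np.random.default_rng(seed)
    events = build_events(protocol, n_trials, tuning, start_s, period_s, seed=rng.integers(2**31))
    duration_s = float(events.offsets[-1] + tail_s)
    meta = default_unit_meta(assembly, tuning)
    depth = {m.unit_id: m.depth_um for m in meta}
    centers = {
        a: float(np.mean([depth[u] for u in members]))
        for a, members in assembly.assemblies().items()
    }

    mothers = {a: _poisson_times(rng, assembly.mother_rate_hz, duration_s) for a in assembly.assemblies()}
    sigma_s = assembly.jitter_sd_ms / 1000.0

    conditions = (
        events.angle_deg
        if protocol == "ramp_hold"
        else (events.texture if events.texture is not None else None)
    )
    spike_times: dict[str, np.ndarray] = {}
    amplitudes: dict[str, np.ndarray] = {}
    half_widths: dict[str, np.ndarray] = {}
    for u in assembly.unit_ids:
        a = assembly.membership[u]
        g_eff = _gamma_eff(u, assembly, modulation, tuning, depth, centers, protocol)
        copied = np.empty(0)
        if a >= 0 and mothers[a].size:
            m = mothers[a]
            f = _copy_factor_at(m, events.onsets, events.offsets, g_eff, modulation.recovery_tau_s)
            keep = rng.random(m.size) < assembly.copy_prob[u] * f
            copied = m[keep]
            if sigma_s > 0 and copied.size:
                copied = copied + rng.normal(0.0, sigma_s, size=copied.size)
        background = _poisson_times(rng, assembly.background_of(u), duration_s)
        # rate compensation: copy rate lost to desynchronization returns as
        # independent firing, so modulation decorrelates without rate loss
        comp = np.empty(0)
        if a >= 0 and g_eff < 1.0:
            cand = _poisson_times(rng, assembly.copy_prob[u] * assembly.mother_rate_hz, duration_s)
            if cand.size:
                fc = _copy_factor_at(
                    cand, events.onsets, events.offsets, g_eff, modulation.recovery_tau_s
                )
                comp = cand[rng.random(cand.size) < (1.0 - fc)]
        pref = (
            tuning.preferred_angle.get(u)
            if protocol == "ramp_hold"
            else tuning.preferred_coarseness.get(u)
        )
        evoked_extra = []
        if tuning.evoked_gain_hz > 0:
            for k in range(events.n_events):
                cond = None if conditions is None else conditions[k]
                gain = tuning.evoked_gain_hz * _tuning_weight(tuning, protocol, pref, cond)
                ev_len = events.offsets[k] - events.onsets[k]
                n_extra = rng.poisson(gain * ev_len)
                if n_extra:
                    evoked_extra.append(events.onsets[k] + rng.uniform(0, ev_len, size=n_extra))
        parts = [copied, background, comp] + evoked_extra
        t = np.sort(np.concatenate(parts))
        t = _enforce_refractory(np.clip(t, 0.0, duration_s), assembly.refractory_ms / 1000.0)
        spike_times[u] = t
        if waveform_streams:
            amp_mean = 60.0 + 60.0 * rng.random()
            amplitudes[u] = rng.normal(amp_mean, 0.08 * amp_mean, size=t.size)
            half_widths[u] = rng.normal(0.30, 0.03, size=t.size)

    trains = SpikeTrainSet(spike_times, duration_s, amplitudes, half_widths)
    gt = _ground_truth(assembly, modulation, tuning, seed)
    return trains, events, meta, gt


# --------------------------------------------------------------------------
# feature clouds for spike-sorting quality control


def generate_feature_clusters(
    n_clusters: int,
    n_per_cluster: int,
    centers: np.ndarray,
    covariances: np.ndarray,
    seed: int = 0,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Gaussian feature clouds with known cluster labels.

    ``centers``: (k, d) array; ``covariances``: (k, d, d) or (d, d) shared.
    Returns a features table (unit_id, spike_index, f1..fd).
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[0] != n_clusters:
        raise ValidationError("centers must have one row per cluster")
    d = centers.shape[1]
    if d not in (2, 3):
        raise ValidationError("feature space must be 2- or 3-dimensional")
    if n_per_cluster < 2:
        raise ValidationError("n_per_cluster must be >= 2")
    cov = np.asarray(covariances, dtype=float)
    if cov.ndim == 2:
        cov = np.repeat(cov[None], n_clusters, axis=0)
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_clusters):
        if np.any(np.diag(cov[k]) > 0):
            eigs = np.linalg.eigvalsh(cov[k])
            if eigs.min() <= 1e-10 * max(eigs.max(), 1.0):
                raise ValidationError(f"covariance of cluster {k} is singular")
            pts = rng.multivariate_normal(centers[k], cov[k], size=n_per_cluster, method="cholesky")
        else:
            pts = np.repeat(centers[k][None], n_per_cluster, axis=0)
        name = labels[k] if labels else f"u{k:02d}"
        df = pd.DataFrame(pts, columns=[f"f{i + 1}" for i in range(d)])
        df.insert(0, "spike_index", np.arange(n_per_cluster))
        df.insert(0, "unit_id", name)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def generate_session_features(
    trains: SpikeTrainSet, seed: int = 0, separation: float = 25.0, max_spikes: int = 1000
) -> pd.DataFrame:
    """Well-separated 3-D feature clouds for the units of a session.

    Stands in for the sorted waveform feature space; unit centers are placed
    on a jittered grid ``separation`` apart with unit-variance clouds, so a
    correctly sorted session passes the cluster-validity battery.
    """
    rng = np.random.default_rng(seed)
    units = sorted(trains.unit_ids)
    side = int(np.ceil(len(units) ** (1 / 3)))
    rows = []
    for i, u in enumerate(units):
        center = separation * np.array(
            [i % side, (i // side) % side, i // (side * side)], dtype=float
        ) + rng.normal(0, 0.5, size=3)
        n = min(trains.spike_times[u].size, max_spikes)
        n = max(n, 8)
        pts = center + rng.normal(0, 1.0, size=(n, 3))
        df = pd.DataFrame(pts, columns=["f1", "f2", "f3"])
        df.insert(0, "spike_index", np.arange(n))
        df.insert(0, "unit_id", u)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)
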