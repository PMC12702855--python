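"""Synthetic hand-to-mouth (HTM) cohort generator.

Emulates the *outputs* of a wearable-sensor + musculoskeletal-modelling
pipeline — wrist/sternum trajectories, joint angles/velocities/torques and
muscle force / fiber-velocity time series — for a stroke cohort and healthy
controls, with a scalar impairment level ``s`` in [0, 1] driving five
biomarker families in known directions:

* mechanical work |W|  decreases (effort amplitudes scaled by ``1 - work*s``),
* smoothness SPARC     decreases (band-limited 4-10 Hz noise grows with s),
* co-contraction CCI   increases (a common antagonist baseline force grows),
* coordination IC      decreases (elbow-angle noise variance grows),
* trunk displacement   increases (forward-lean excursion grows).

Ground-truth FMA-UL labels come from a known sparse linear map over the
extracted biomarkers, so that downstream feature selection and model
validation can be tested against a known answer.

The wrist trajectory is four concatenated straight-line minimum-jerk
sub-movements (start -> marker -> mouth -> marker -> start) separated by
dwell pauses; each trial also records the analytically known segmentation
events so recovery can be scored without circularity.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import schema
from ._rng import substream
from .errors import ConfigurationError, InvalidIntervalError

__all__ = [
    "GeneratorConfig",
    "SubjectProfile",
    "TrialRecording",
    "CohortData",
    "minimum_jerk",
    "generate_trial",
    "assign_fma",
    "generate_cohort",
]

# ---------------------------------------------------------------------------
# task geometry (metres, subject-local frame: x forward, y left, z up)

_START = np.array([0.25, 0.00, 0.70])
_MARKER = np.array([0.50, 0.00, 0.72])  # 30 cm beyond table edge, midline
_MOUTH = np.array([0.28, 0.00, 1.05])
_WRIST_WAYPOINTS = (_START, _MARKER, _MOUTH, _MARKER, _START)

_STERNUM_BASE = np.array([0.0, 0.0, 1.20])
_LEAN_DIR = np.array([0.8, 0.0, -0.6])  # forward and slightly down (unit norm)

# joint-angle waypoints (degrees) at the 5 task landmarks
_ELV_WAYPOINTS = (15.0, 45.0, 70.0, 45.0, 15.0)
_FLE_WAYPOINTS = (10.0, 35.0, 55.0, 35.0, 10.0)
_ROT_WAYPOINTS = (0.0, 15.0, 30.0, 15.0, 0.0)
_ELB_OFFSET, _ELB_SLOPE = 75.0, 0.8  # elbow = offset + slope * elevation

# trunk excursion amplitude per phase: a0 + a1 * trunk_effect * s   (metres)
_TRUNK_A0 = np.array([0.010, 0.054, 0.070, 0.031])
_TRUNK_A1 = np.array([0.015, 0.070, 0.090, 0.100])

# peak effort amplitudes of the clean (healthy, s=0) profiles
_TAU_BASELINE = 0.3  # small constant torque offset (N*m) so no window is all-zero
#: distinct tonic baseline per muscle (N); distinctness keeps healthy CCI
#: well below 1 even in phases where neither pair member is task-active
_FORCE_TONIC = {"BR": 1.0, "BB": 1.4, "TRL": 1.9, "AD": 1.2, "MD": 1.6, "PD": 1.1, "PM": 1.3}

# fiber-velocity gains: v_muscle = gain * joint angular velocity (rad/s),
# shortening positive.  BB/BR shorten when the elbow flexes, TRL lengthens;
# AD shortens with elevation, PD with depression.
_FIBER_GAIN = {
    "BR": ("elb", 0.24),
    "BB": ("elb", 0.30),
    "TRL": ("elb", -0.20),
    "AD": ("elv", 0.20),
    "PD": ("elv", -0.20),
    "MD": ("elv", 0.16),
    "PM": ("fle", 0.18),
}

_DEFAULT_EFFECTS = {
    # fractional reduction of effort amplitude at s=1
    "work": 0.7,
    # 4-10 Hz motor-noise RMS at s=1: fraction of the local signal level for
    # muscle forces (signal-dependent noise), of peak amplitude for torques
    "smoothness": 0.18,
    # added common antagonist baseline force at s=1 (N)
    "cocontraction": 1.5,
    # elbow coordination-noise SD at s=1 (degrees)
    "coordination": 8.0,
    # multiplier on the default extra trunk excursion at s=1
    "trunk": 1.0,
}

_DEFAULT_FMA_WEIGHTS = {
    "TD_2": -3.5,
    "IC_elb_elv_3": 2.5,
    "TD_3": -2.0,
}


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic cohort.

    Defaults reproduce the study layout: 47 development + 18 independent-test
    patients, 20 healthy controls, five trials each, and an FMA-UL label
    distribution centred on 26 points.
    """

    n_dev_patients: int = 47
    n_test_patients: int = 18
    n_controls: int = 20
    fs: float = 100.0
    phase_durations: tuple[float, float, float, float] = (1.2, 1.2, 1.2, 1.2)
    dwell: float = 0.3
    lead: float = 0.5
    tail: float = 0.5
    impairment_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EFFECTS)
    )
    fma_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FMA_WEIGHTS)
    )
    fma_intercept: float = 26.0
    fma_noise_sd: float = 1.5
    seed: int = 0
    #: global multiplier on all within-trial stochastic components
    #: (4-10 Hz channel noise, wrist tremor, coordination noise); 0 disables.
    noise_scale: float = 1.0
    #: SD of the per-subject log-normal heterogeneity of effect amplitudes.
    subject_var: float = 0.2
    #: speed-threshold fraction used for the analytic ground-truth events.
    onset_threshold_frac: float = 0.10

    def __post_init__(self):
        if self.n_dev_patients < 1 or self.n_test_patients < 1:
            raise ConfigurationError("patient counts must be >= 1")
        if self.n_controls < 0:
            raise ConfigurationError("n_controls must be >= 0")
        if self.fs < 50.0:
            raise ConfigurationError("sampling rate must be >= 50 Hz")
        if len(self.phase_durations) != 4 or any(d <= 0 for d in self.phase_durations):
            raise ConfigurationError("phase_durations must be 4 positive values")
        if self.dwell <= 0 or self.lead < 0 or self.tail < 0:
            raise ConfigurationError("dwell must be > 0 and lead/tail >= 0")
        nonzero = [k for k, w in self.fma_weights.items() if w != 0.0]
        if not 3 <= len(nonzero) <= 15:
            raise ConfigurationError("fma_weights needs 3..15 nonzero entries")
        unknown = sorted(set(self.fma_weights) - set(schema.FEATURE_NAMES))
        if unknown:
            raise ConfigurationError(f"fma_weights reference unknown features: {unknown}")
        if not 0.0 < self.onset_threshold_frac < 1.0:
            raise ConfigurationError("onset_threshold_frac must be in (0, 1)")

    # -- YAML round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phase_durations"] = list(self.phase_durations)
        d["impairment_effects"] = dict(self.impairment_effects)
        d["fma_weights"] = dict(self.fma_weights)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "phase_durations" in d:
            d["phase_durations"] = tuple(d["phase_durations"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    group: str  # "patient" | "control"
    cohort: str  # "development" | "test" | "control"
    impairment: float  # s in [0, 1]; 0 for controls
    fma_ul: int | None = None  # assigned after feature extraction; patients only
    arm_length: float = 0.62  # m
    body_mass: float = 70.0  # kg

    def __post_init__(self):
        if self.group not in ("patient", "control"):
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.group == "control" and self.impairment != 0.0:
            raise ConfigurationError("controls must have impairment 0")
        if not 0.0 <= self.impairment <= 1.0:
            raise ConfigurationError("impairment must lie in [0, 1]")
        if self.fma_ul is not None and not 0 <= self.fma_ul <= 66:
            raise ConfigurationError("FMA-UL must lie in [0, 66]")


@dataclass
class TrialRecording:
    """One HTM trial's synchronized multichannel time series."""

    subject_id: str
    trial_index: int  # 1..5
    fs: float
    t: np.ndarray  # (N,) seconds, uniform
    wrist_pos: np.ndarray  # (N, 3) m
    sternum_pos: np.ndarray  # (N, 3) m
    joint_angle: np.ndarray  # (N, 4) deg, columns in schema.JOINTS order
    joint_ang_vel: np.ndarray  # (N, 4) deg/s
    joint_torque: np.ndarray  # (N, 4) N*m
    muscle_force: np.ndarray  # (N, 7) N, columns in schema.MUSCLES order
    muscle_fiber_vel: np.ndarray  # (N, 7) m/s, shortening positive
    ground_truth: dict | None = None  # analytic segmentation events, generator-only

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"t": self.t}
        for i, ax in enumerate("xyz"):
            cols[f"wrist_{ax}"] = self.wrist_pos[:, i]
            cols[f"sternum_{ax}"] = self.sternum_pos[:, i]
        for i, j in enumerate(schema.JOINTS):
            cols[f"ang_{j}"] = self.joint_angle[:, i]
        for i, j in enumerate(schema.JOINTS):
            cols[f"vel_{j}"] = self.joint_ang_vel[:, i]
        for i, j in enumerate(schema.JOINTS):
            cols[f"tau_{j}"] = self.joint_torque[:, i]
        for i, m in enumerate(schema.MUSCLES):
            cols[f"F_{m}"] = self.muscle_force[:, i]
        for i, m in enumerate(schema.MUSCLES):
            cols[f"v_{m}"] = self.muscle_fiber_vel[:, i]
        return pd.DataFrame(cols, columns=list(schema.TRIAL_COLUMNS))

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, subject_id: str = "", trial_index: int = 0
    ) -> "TrialRecording":
        t = frame["t"].to_numpy(float)
        dt = np.diff(t)
        fs = 1.0 / dt[0] if len(dt) else math.nan
        get = lambda names: frame[list(names)].to_numpy(float)  # noqa: E731
        return cls(
            subject_id=subject_id,
            trial_index=trial_index,
            fs=fs,
            t=t,
            wrist_pos=get([f"wrist_{ax}" for ax in "xyz"]),
            sternum_pos=get([f"sternum_{ax}" for ax in "xyz"]),
            joint_angle=get([f"ang_{j}" for j in schema.JOINTS]),
            joint_ang_vel=get([f"vel_{j}" for j in schema.JOINTS]),
            joint_torque=get([f"tau_{j}" for j in schema.JOINTS]),
            muscle_force=get([f"F_{m}" for m in schema.MUSCLES]),
            muscle_fiber_vel=get([f"v_{m}" for m in schema.MUSCLES]),
        )


# ---------------------------------------------------------------------------
# primitives


def minimum_jerk(t0: float, t1: float, x0: float, x1: float, t: np.ndarray):
    """Quintic minimum-jerk trajectory from (t0, x0) at rest to (t1, x1) at rest.

    Returns ``(position, velocity)`` evaluated at ``t``; position is constant
    ``x0`` before ``t0`` and ``x1`` after ``t1``.
    """
    if t1 <= t0:
        raise InvalidIntervalError(f"t1={t1} must exceed t0={t0}")
    t = np.asarray(t, dtype=float)
    T = t1 - t0
    tau = np.clip((t - t0) / T, 0.0, 1.0)
    s = tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)
    ds = 30.0 * tau**2 * (1.0 - tau) ** 2 / T
    return x0 + (x1 - x0) * s, (x1 - x0) * ds


def _minjerk_threshold_tau(frac: float) -> float:
    """Phase fraction tau at which minimum-jerk speed first reaches
    ``frac`` times its own peak: solves 16 tau^2 (1-tau)^2 = frac."""
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must lie in (0, 1)")
    return 0.5 * (1.0 - math.sqrt(1.0 - math.sqrt(frac)))


def _bandlimited_noise(
    n: int, fs: float, rng: np.random.Generator, f_lo: float, f_hi: float
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [f_lo, f_hi] Hz via FFT masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < f_lo) | (freqs > f_hi)] = 0.0
    out = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(out**2))
    return out / rms if rms > 0 else out


def _bump(t: np.ndarray, a: float, b: float) -> np.ndarray:
    """sin^2 envelope supported on [a, b]: 0 at the edges, 1 at the middle."""
    x = np.zeros_like(t)
    inside = (t >= a) & (t <= b)
    x[inside] = np.sin(np.pi * (t[inside] - a) / (b - a)) ** 2
    return x


# ---------------------------------------------------------------------------
# trial synthesis


def _timeline(config: GeneratorConfig):
    """Integer-sample layout: returns (N, sub-movement index bounds)."""
    fs = config.fs
    n_lead = round(config.lead * fs)
    n_tail = round(config.tail * fs)
    n_dwell = round(config.dwell * fs)
    if n_dwell < 1:
        raise ConfigurationError("dwell shorter than one sample")
    bounds = []
    i0 = n_lead
    for d in config.phase_durations:
        n_k = round(d * fs)
        if n_k < 8:
            raise ConfigurationError("phase duration shorter than 8 samples")
        bounds.append((i0, i0 + n_k))
        i0 = i0 + n_k + n_dwell
    n_total = bounds[-1][1] + n_tail + 1
    return n_total, bounds


def _subject_multipliers(profile: SubjectProfile, config: GeneratorConfig):
    """Per-subject log-normal heterogeneity, fixed across the subject's trials."""
    rng = substream(config.seed, "subject", profile.subject_id)
    trunk = np.exp(config.subject_var * rng.standard_normal(4))
    coord = np.exp(config.subject_var * rng.standard_normal(4))  # per phase
    effort = float(np.exp(0.5 * config.subject_var * rng.standard_normal()))
    return trunk, coord, effort


def generate_trial(
    profile: SubjectProfile,
    config: GeneratorConfig,
    trial_index: int,
    rng: np.random.Generator | None = None,
) -> TrialRecording:
    """Synthesize one HTM trial for a subject.

    ``rng`` drives the within-trial noise; when omitted it is derived from
    ``(config.seed, subject_id, trial_index)`` so repeated calls are
    bit-identical.  All noise draws are made unconditionally and scaled
    afterwards, so trials generated with the same rng but different
    impairment differ only through the impairment-dependent amplitudes.
    """
    if rng is None:
        rng = substream(config.seed, "trial", profile.subject_id, trial_index)
    eff = {**_DEFAULT_EFFECTS, **dict(config.impairment_effects)}
    s = profile.impairment
    nz = config.noise_scale
    trunk_mult, coord_mult, effort_mult = _subject_multipliers(profile, config)

    n, bounds = _timeline(config)
    fs = config.fs
    t = np.arange(n) / fs
    seg_times = [(i0 / fs, i1 / fs) for i0, i1 in bounds]

    # ---- wrist: 4 concatenated minimum-jerk sub-movements ------------------
    wrist = np.tile(_WRIST_WAYPOINTS[0], (n, 1)).astype(float)
    seg_lengths = []
    for k, (ta, tb) in enumerate(seg_times):
        delta = _WRIST_WAYPOINTS[k + 1] - _WRIST_WAYPOINTS[k]
        seg_lengths.append(float(np.linalg.norm(delta)))
        prog, _ = minimum_jerk(ta, tb, 0.0, 1.0, t)
        wrist += np.outer(prog, delta)
    # impairment tremor on the wrist (small, 4-10 Hz)
    wrist_noise_rms = 0.0002 * s * nz
    for ax in range(3):
        wrist[:, ax] += wrist_noise_rms * _bandlimited_noise(n, fs, rng, 4.0, 10.0)

    # ---- analytic ground-truth segmentation events --------------------------
    thr = config.onset_threshold_frac
    peak_speeds = [1.875 * L / (tb - ta) for L, (ta, tb) in zip(seg_lengths, seg_times)]
    v_max = max(peak_speeds)
    tau_on = _minjerk_threshold_tau(thr * v_max / peak_speeds[0])
    tau_off = _minjerk_threshold_tau(thr * v_max / peak_speeds[-1])
    on_idx = bounds[0][0] + tau_on * (bounds[0][1] - bounds[0][0])
    off_idx = bounds[-1][1] - tau_off * (bounds[-1][1] - bounds[-1][0])
    truth_idx = [on_idx, bounds[0][1] + 1.0, bounds[1][1] + 1.0, bounds[2][1] + 1.0, off_idx]
    ground_truth = {
        "events_idx": truth_idx,
        "events_s": [i / fs for i in truth_idx],
        "threshold_frac": thr,
        "submovement_bounds_idx": [list(b) for b in bounds],
    }

    # ---- trunk: forward-lean excursions peaking mid-sub-movement ------------
    sternum = np.tile(_STERNUM_BASE, (n, 1)).astype(float)
    lean = _LEAN_DIR / np.linalg.norm(_LEAN_DIR)
    for k, (ta, tb) in enumerate(seg_times):
        amp = (_TRUNK_A0[k] + _TRUNK_A1[k] * eff["trunk"] * s) * trunk_mult[k]
        sternum += amp * np.outer(_bump(t, ta, tb), lean)

    # ---- joint angles --------------------------------------------------------
    def waypoint_channel(waypoints):
        x = np.full(n, waypoints[0], dtype=float)
        for k, (ta, tb) in enumerate(seg_times):
            prog, _ = minimum_jerk(ta, tb, 0.0, 1.0, t)
            x += (waypoints[k + 1] - waypoints[k]) * prog
        return x

    elv = waypoint_channel(_ELV_WAYPOINTS)
    fle = waypoint_channel(_FLE_WAYPOINTS)
    rot = waypoint_channel(_ROT_WAYPOINTS)
    elb_clean = _ELB_OFFSET + _ELB_SLOPE * elv
    # coordination-noise amplitude is piecewise per sub-movement (edges at the
    # dwell midpoints) so per-phase coordination varies independently between
    # subjects instead of through one shared severity channel
    edges = [0.0]
    for (_, t1a), (t0b, _) in zip(seg_times[:-1], seg_times[1:]):
        edges.append(0.5 * (t1a + t0b))
    edges.append(t[-1] + 1.0 / fs)
    coord_amp = np.zeros(n)
    for k in range(4):
        inside = (t >= edges[k]) & (t < edges[k + 1])
        coord_amp[inside] = eff["coordination"] * s * coord_mult[k] * nz
    elb = elb_clean + coord_amp * _bandlimited_noise(n, fs, rng, 1.0, 4.0)

    angle = np.column_stack([elb, elv, rot, fle])  # schema.JOINTS order
    dt = 1.0 / fs
    ang_vel = np.gradient(angle, dt, axis=0)

    # clean angular velocities (rad/s) used for torque/force conjugates
    om = {
        "elb": np.gradient(elb_clean, dt) * math.pi / 180.0,
        "elv": np.gradient(elv, dt) * math.pi / 180.0,
        "rot": np.gradient(rot, dt) * math.pi / 180.0,
        "fle": np.gradient(fle, dt) * math.pi / 180.0,
    }

    # ---- torques and muscle forces ------------------------------------------
    scale_w = max(1.0 - eff["work"] * s, 0.15) * effort_mult
    noise_frac = eff["smoothness"] * s * nz
    b = [_bump(t, ta, tb) for ta, tb in seg_times]
    span23 = _bump(t, seg_times[1][0], seg_times[2][1])  # elbow load, phases 2-3

    def noisy(x, peak):
        return x + noise_frac * peak * _bandlimited_noise(n, fs, rng, 4.0, 10.0)

    torque = np.column_stack(
        [
            noisy(_TAU_BASELINE + 8.0 * scale_w * span23 + 1.5 * scale_w * (b[0] + b[3]), 8.0),
            noisy(_TAU_BASELINE + 6.0 * scale_w * (b[0] + b[1]) - 4.0 * scale_w * (b[2] + b[3]), 6.0),
            noisy(_TAU_BASELINE + 2.0 * scale_w * (b[0] + b[1] + b[2] + b[3]), 2.0),
            noisy(_TAU_BASELINE + 3.0 * scale_w * (b[0] + b[1]) - 2.0 * scale_w * (b[2] + b[3]), 3.0),
        ]
    )

    cci_extra = eff["cocontraction"] * s  # common antagonist baseline offset
    all_b = b[0] + b[1] + b[2] + b[3]
    # task-specific bursts plus a nonspecific postural-stabilization component
    # (no muscle is silent during movement), so every phase window carries
    # signal whose roughness can degrade with impairment
    force_shapes = {
        "BR": 15.0 * span23 + 3.0 * all_b,
        "BB": 25.0 * span23 + 4.0 * all_b,
        "TRL": 50.0 * (b[0] + b[2]) + 6.0 * all_b,
        "AD": 20.0 * (b[0] + b[1]) + 5.0 * all_b,
        "MD": 10.0 * (b[0] + b[3]) + 6.0 * all_b,
        "PD": 18.0 * (b[2] + b[3]) + 5.0 * all_b,
        "PM": 22.0 * (b[0] + b[1]) + 2.0 * all_b,
    }
    force = np.empty((n, len(schema.MUSCLES)))
    fiber_vel = np.empty_like(force)
    for i, m in enumerate(schema.MUSCLES):
        clean = _FORCE_TONIC[m] + cci_extra + scale_w * force_shapes[m]
        # signal-dependent motor noise: amplitude tracks the local force level
        raw = clean * (1.0 + noise_frac * _bandlimited_noise(n, fs, rng, 4.0, 10.0))
        force[:, i] = np.maximum(raw, 0.0)  # physical guard; rarely binds
        joint, gain = _FIBER_GAIN[m]
        fiber_vel[:, i] = gain * om[joint]

    return TrialRecording(
        subject_id=profile.subject_id,
        trial_index=trial_index,
        fs=fs,
        t=t,
        wrist_pos=wrist,
        sternum_pos=sternum,
        joint_angle=angle,
        joint_ang_vel=ang_vel,
        joint_torque=torque,
        muscle_force=force,
        muscle_fiber_vel=fiber_vel,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# labels


def assign_fma(
    features: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Assign integer FMA-UL scores from the known sparse linear map.

    score = round(clip(intercept + sum_f w_f * z_f + eps, 0, 66)) with z_f the
    feature standardized over the supplied cohort (the patient table) and
    eps ~ Normal(0, fma_noise_sd).  Trunk-displacement weights are negative by
    default: more compensation predicts a lower score.
    """
    if rng is None:
        rng = substream(config.seed, "fma")
    missing = sorted(set(config.fma_weights) - set(features.columns))
    if missing:
        raise ConfigurationError(f"weighted features absent from table: {missing}")
    lin = np.full(len(features), float(config.fma_intercept))
    for name, w in config.fma_weights.items():
        if w == 0.0:
            continue
        col = features[name].to_numpy(float)
        sd = col.std(ddof=1) if len(col) > 1 else 0.0
        if sd == 0.0:
            continue  # constant feature: every z-score is 0, no contribution
        lin += w * (col - col.mean()) / sd
    eps = config.fma_noise_sd * rng.standard_normal(len(features))
    scores = np.clip(np.rint(lin + eps), 0, 66).astype(int)
    return pd.Series(scores, index=features.index, name="fma_ul")


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortData:
    """In-memory result of :func:`generate_cohort`."""

    config: GeneratorConfig
    profiles: list[SubjectProfile]
    trials: dict[tuple[str, int], TrialRecording]  # (subject_id, trial_index)
    features: pd.DataFrame  # per-subject table: meta columns + 112 biomarkers
    manifest: pd.DataFrame

    def subject_trials(self, subject_id: str) -> list[TrialRecording]:
        return [self.trials[(subject_id, k)] for k in range(1, 6)]


def _draw_profiles(config: GeneratorConfig) -> list[SubjectProfile]:
    rng = substream(config.seed, "profiles")
    profiles = []
    n_pat = config.n_dev_patients + config.n_test_patients
    s_values = rng.beta(2.0, 2.0, size=n_pat)  # impairment spread across severities
    arm = rng.normal(0.62, 0.03, size=n_pat + config.n_controls)
    mass = rng.normal(70.0, 10.0, size=n_pat + config.n_controls)
    for i in range(n_pat):
        cohort = "development" if i < config.n_dev_patients else "test"
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:03d}",
                group="patient",
                cohort=cohort,
                impairment=float(s_values[i]),
                arm_length=float(arm[i]),
                body_mass=float(mass[i]),
            )
        )
    for j in range(config.n_controls):
        profiles.append(
            SubjectProfile(
                subject_id=f"H{j + 1:03d}",
                group="control",
                cohort="control",
                impairment=0.0,
                arm_length=float(arm[n_pat + j]),
                body_mass=float(mass[n_pat + j]),
            )
        )
    return profiles


def generate_cohort(
    config: GeneratorConfig, out_dir: str | Path | None = None
) -> CohortData:
    """Generate the full cohort: profiles, 5 trials each, biomarkers and labels.

    FMA-UL labels are assigned from the extracted biomarkers (not from the
    latent impairment directly), so the sparse linear ground truth lives in
    exactly the feature space the downstream models see.  When ``out_dir`` is
    given, per-trial CSVs and the manifest are written there.
    """
    from .biomarkers import aggregate_subject, extract_features
    from .segmentation import compute_speed, segment_htm

    profiles = _draw_profiles(config)
    trials: dict[tuple[str, int], TrialRecording] = {}
    rows = []
    for prof in profiles:
        per_trial = []
        for k in range(1, 6):
            trial = generate_trial(prof, config, k)
            trials[(prof.subject_id, k)] = trial
            boundaries = segment_htm(compute_speed(trial))
            per_trial.append(extract_features(trial, boundaries))
        rows.append(aggregate_subject(per_trial))
    features = pd.DataFrame(rows, columns=list(schema.FEATURE_NAMES))
    features.insert(0, "subject_id", [p.subject_id for p in profiles])
    features.insert(1, "group", [p.group for p in profiles])
    features.insert(2, "cohort", [p.cohort for p in profiles])

    is_patient = features["group"] == "patient"
    fma = assign_fma(features.loc[is_patient], config)
    features.insert(3, "fma_ul", pd.Series(pd.NA, index=features.index, dtype="Int64"))
    features.loc[is_patient, "fma_ul"] = fma
    profiles = [
        dataclasses.replace(
            p, fma_ul=int(fma.loc[i]) if p.group == "patient" else None
        )
        for i, p in enumerate(profiles)
    ]

    trial_path = lambda sid, k: f"trials/{sid}_t{k}.csv"  # noqa: E731
    manifest = pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in profiles],
            "group": [p.group for p in profiles],
            "cohort": [p.cohort for p in profiles],
            "impairment": [p.impairment for p in profiles],
            "fma_ul": pd.array(
                [p.fma_ul for p in profiles], dtype="Int64"
            ),
            **{
                f"trial_{k}": [trial_path(p.subject_id, k) for p in profiles]
                for k in range(1, 6)
            },
        },
        columns=list(schema.MANIFEST_COLUMNS),
    )

    if out_dir is not None:
        from .io import write_manifest, write_trial

        out = Path(out_dir)
        (out / "trials").mkdir(parents=True, exist_ok=True)
        for (sid, k), trial in trials.items():
            write_trial(trial, out / trial_path(sid, k))
        write_manifest(manifest, out / "manifest.csv")

    return CohortData(
        config=config,
        profiles=profiles,
        trials=trials,
        features=features,
        manifest=manifest,
    )
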