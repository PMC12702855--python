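"""Phase-specific biomarker computation.

Five feature families are computed on each of the four HTM phases:

* mechanical work ``W`` (J): signed time integral of power, effort times its
  conjugate rate (joint torque x angular velocity in rad/s, or muscle force x
  fiber velocity with shortening positive).  Concentric work is positive,
  eccentric negative.
* smoothness ``S`` (dimensionless, <= 0): spectral arc length (SPARC) of the
  effort time series; values nearer 0 are smoother.
* co-contraction ``CCI`` in [0, 1]: normalized temporal overlap integral
  ``2 * int min(f_a, f_b) / int (f_a + f_b)`` of an antagonist force pair.
* inter-joint coordination ``IC`` in [-1, 1]: Pearson correlation between the
  elbow and shoulder-elevation angle trajectories.
* trunk displacement ``TD`` (cm): peak norm of the sternum excursion from the
  trial-start position, a compensatory-movement proxy.

``extract_features`` assembles the full 112-entry vector per trial and
``aggregate_subject`` averages the middle three of five trials.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from . import schema
from .errors import (
    DomainError,
    InsufficientDataError,
    SamplingError,
    StrokekinError,
    UndefinedMetricError,
    WindowError,
)
from .segmentation import PhaseBoundaries
from .synthetic import TrialRecording

__all__ = [
    "mechanical_work",
    "sparc",
    "cci",
    "interjoint_coordination",
    "trunk_displacement",
    "extract_features",
    "aggregate_subject",
]

DEG2RAD = math.pi / 180.0


def _window_slice(t: np.ndarray, window) -> slice:
    """Resolve a window given as a slice or an (t_start, t_end) pair into an
    inclusive sample slice.  Adjacent windows sharing a boundary time share
    that boundary sample, which makes integral features additive."""
    if isinstance(window, slice):
        start = 0 if window.start is None else int(window.start)
        stop = len(t) if window.stop is None else int(window.stop)
        if start < 0 or stop > len(t) or stop - start < 2:
            raise WindowError(f"window {window} outside the recorded span")
        return slice(start, stop)
    t_a, t_b = float(window[0]), float(window[1])
    if t_a < t[0] - 1e-12 or t_b > t[-1] + 1e-12 or t_b <= t_a:
        raise WindowError(f"window [{t_a}, {t_b}] outside the recorded span")
    i0 = int(np.searchsorted(t, t_a, side="left"))
    i1 = int(np.searchsorted(t, t_b, side="right"))
    if i1 - i0 < 2:
        raise WindowError("window contains fewer than 2 samples")
    return slice(i0, i1)


def mechanical_work(effort, rate, t, window) -> float:
    """Signed work (J): trapezoidal integral of effort(t) * rate(t) over the window.

    ``effort`` is a torque (N*m) with ``rate`` in rad/s, or a force (N) with
    ``rate`` a fiber velocity in m/s (shortening positive).
    """
    t = np.asarray(t, float)
    effort = np.asarray(effort, float)
    rate = np.asarray(rate, float)
    if effort.shape != t.shape or rate.shape != t.shape:
        raise WindowError("effort/rate series must align with the time vector")
    sl = _window_slice(t, window)
    return float(np.trapezoid(effort[sl] * rate[sl], t[sl]))


def sparc(
    signal,
    fs: float,
    padlevel: int = 4,
    fc_max: float = 10.0,
    amp_threshold: float = 0.05,
) -> float:
    """Spectral arc length smoothness of a 1-D signal (<= 0; nearer 0 is smoother).

    The magnitude spectrum of the zero-padded signal (next power of two times
    ``2**padlevel``) is normalized by its zero-frequency magnitude; the
    adaptive cutoff ``f_c`` is the largest frequency <= ``fc_max`` where the
    normalized magnitude still reaches ``amp_threshold``; the result is the
    negated arc length of the normalized spectrum over [0, f_c], with the
    frequency axis scaled by 1/f_c.
    """
    x = np.asarray(signal, float)
    if x.ndim != 1 or x.size < 8:
        raise InsufficientDataError("SPARC needs a 1-D signal with >= 8 samples")
    if fs <= 2.0 * fc_max:
        raise SamplingError(f"fs={fs} too low for fc_max={fc_max}")
    if not np.any(x != 0.0):
        raise UndefinedMetricError("SPARC undefined for an all-zero signal")

    nfft = int(2 ** (math.ceil(math.log2(x.size)) + padlevel))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    mag = np.abs(np.fft.rfft(x, nfft))
    if mag[0] == 0.0:
        raise UndefinedMetricError("zero-frequency magnitude is zero")
    vhat = mag / mag[0]

    in_band = freqs <= fc_max
    above = np.flatnonzero(in_band & (vhat >= amp_threshold))
    i_c = int(above[-1])
    if i_c == 0:
        return 0.0  # spectrum collapses onto DC: perfectly smooth
    f_c = freqs[i_c]
    f_sel = freqs[: i_c + 1]
    v_sel = vhat[: i_c + 1]
    return float(-np.sum(np.sqrt((np.diff(f_sel) / f_c) ** 2 + np.diff(v_sel) ** 2)))


def cci(f_a, f_b, t, window) -> float:
    """Co-contraction index in [0, 1]: 2 * int min(f_a, f_b) / int (f_a + f_b)."""
    t = np.asarray(t, float)
    f_a = np.asarray(f_a, float)
    f_b = np.asarray(f_b, float)
    sl = _window_slice(t, window)
    a, b = f_a[sl], f_b[sl]
    if np.any(a < 0) or np.any(b < 0):
        raise DomainError("CCI requires non-negative force series")
    denom = float(np.trapezoid(a + b, t[sl]))
    if denom == 0.0:
        raise UndefinedMetricError("CCI undefined: both forces zero on the window")
    return float(2.0 * np.trapezoid(np.minimum(a, b), t[sl]) / denom)


def interjoint_coordination(angle_a, angle_b, t, window) -> float:
    """Pearson correlation between two joint-angle series over the window."""
    t = np.asarray(t, float)
    sl = _window_slice(t, window)
    a = np.asarray(angle_a, float)[sl]
    b = np.asarray(angle_b, float)[sl]
    if a.size < 3:
        raise InsufficientDataError("IC needs >= 3 samples in the window")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise UndefinedMetricError("IC undefined for a constant angle series")
    return float(stats.pearsonr(a, b).statistic)


def trunk_displacement(sternum_pos, t, window, reference=None) -> float:
    """Peak trunk excursion (cm): max over the window of the Euclidean distance
    of the sternum from the reference (trial-start) position."""
    t = np.asarray(t, float)
    pos = np.asarray(sternum_pos, float)
    sl = _window_slice(t, window)
    ref = pos[0] if reference is None else np.asarray(reference, float)
    return float(100.0 * np.max(np.linalg.norm(pos[sl] - ref, axis=1)))


# ---------------------------------------------------------------------------


def _named(feature: str, exc: StrokekinError) -> StrokekinError:
    exc.args = (f"{feature}: {exc.args[0] if exc.args else ''}",) + exc.args[1:]
    return exc


def extract_features(
    trial: TrialRecording,
    boundaries: PhaseBoundaries,
    padlevel: int = 4,
    fc_max: float = 10.0,
    amp_threshold: float = 0.05,
    normalize_mass: float | None = None,
) -> dict[str, float]:
    """Compute the full 112-feature vector of one trial.

    Angle channels stay in degrees (matching the trial schema); the deg->rad
    conversion happens inside the work computation only.  When
    ``normalize_mass`` is given (kg), work features are divided by it.
    """
    t = trial.t
    out: dict[str, float] = {}
    muscle_idx = {m: i for i, m in enumerate(schema.MUSCLES)}

    for p in schema.PHASES:
        sl = boundaries.phase_slice(p)
        for j, joint in enumerate(schema.JOINTS):
            torque = trial.joint_torque[:, j]
            omega = trial.joint_ang_vel[:, j] * DEG2RAD
            try:
                w = mechanical_work(torque, omega, t, sl)
                out[f"W_{joint}_{p}"] = w / normalize_mass if normalize_mass else w
                out[f"S_{joint}_{p}"] = sparc(
                    torque[sl], trial.fs, padlevel, fc_max, amp_threshold
                )
            except StrokekinError as exc:
                raise _named(f"W/S_{joint}_{p}", exc)
        for m, i in muscle_idx.items():
            force = trial.muscle_force[:, i]
            vel = trial.muscle_fiber_vel[:, i]
            try:
                w = mechanical_work(force, vel, t, sl)
                out[f"W_{m}_{p}"] = w / normalize_mass if normalize_mass else w
                out[f"S_{m}_{p}"] = sparc(
                    force[sl], trial.fs, padlevel, fc_max, amp_threshold
                )
            except StrokekinError as exc:
                raise _named(f"W/S_{m}_{p}", exc)
        for a, b in schema.CCI_PAIRS:
            try:
                out[f"CCI_{a}_{b}_{p}"] = cci(
                    trial.muscle_force[:, muscle_idx[a]],
                    trial.muscle_force[:, muscle_idx[b]],
                    t,
                    sl,
                )
            except StrokekinError as exc:
                raise _named(f"CCI_{a}_{b}_{p}", exc)
        try:
            out[f"IC_elb_elv_{p}"] = interjoint_coordination(
                trial.joint_angle[:, schema.JOINTS.index("elb")],
                trial.joint_angle[:, schema.JOINTS.index("elv")],
                t,
                sl,
            )
        except StrokekinError as exc:
            raise _named(f"IC_elb_elv_{p}", exc)
        try:
            out[f"TD_{p}"] = trunk_displacement(trial.sternum_pos, t, sl)
        except StrokekinError as exc:
            raise _named(f"TD_{p}", exc)

    return {name: out[name] for name in schema.FEATURE_NAMES}


def aggregate_subject(trial_vectors: list[dict[str, float]]) -> dict[str, float]:
    """Element-wise mean of the middle three of five chronologically ordered
    trial feature vectors (trials 2, 3 and 4)."""
    if len(trial_vectors) != 5:
        raise InsufficientDataError(
            f"exactly 5 trial vectors required, got {len(trial_vectors)}"
        )
    keys = set(trial_vectors[0])
    if any(set(v) != keys for v in trial_vectors[1:]):
        raise InsufficientDataError("trial vectors have differing key sets")
    middle = trial_vectors[1:4]
    return {k: float(np.mean([v[k] for v in middle])) for k in trial_vectors[0]}
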