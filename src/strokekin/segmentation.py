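"""Phase segmentation of a hand-to-mouth trial from the wrist speed profile.

The HTM task decomposes into four consecutive sub-movements (reach to
object, transfer to mouth, transfer to object, return to start).  Each
produces a bell-shaped speed pulse; segmentation finds movement onset and
offset by a threshold on peak speed, keeps the four largest speed peaks,
and places the interior boundaries at the deepest speed minimum between
consecutive peaks (earliest sample on ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import NoMovementError, SamplingError, SegmentationError
from .synthetic import TrialRecording

__all__ = [
    "SpeedProfile",
    "PhaseBoundaries",
    "compute_speed",
    "detect_onset_offset",
    "segment_htm",
]

_UNIFORMITY_TOL = 1e-9  # seconds


@dataclass
class SpeedProfile:
    t: np.ndarray  # (N,) s
    speed: np.ndarray  # (N,) m/s, >= 0

    @property
    def fs(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])


@dataclass
class PhaseBoundaries:
    """Five event timestamps delimiting the four phases.

    ``events_s = [t_on, t_12, t_23, t_34, t_off]``; phase p covers
    ``[events[p-1], events[p])`` for p = 1..4.  ``diagnostics`` carries the
    retained peak locations and prominences so a reviewer can audit the
    segmentation without a human-in-the-loop verification step.
    """

    events_s: np.ndarray  # (5,)
    events_idx: np.ndarray  # (5,) int
    diagnostics: dict

    def __post_init__(self):
        if not np.all(np.diff(self.events_idx) > 0):
            raise SegmentationError("phase events must be strictly increasing", 4)

    def phase_slice(self, phase: int) -> slice:
        """Inclusive index window of phase p (1..4); adjacent phases share
        their boundary sample so integral features are additive."""
        if phase not in (1, 2, 3, 4):
            raise ValueError("phase must be 1..4")
        return slice(int(self.events_idx[phase - 1]), int(self.events_idx[phase]) + 1)

    def to_dict(self, subject_id: str = "", trial_index: int = 0) -> dict:
        return {
            "subject_id": subject_id,
            "trial_index": trial_index,
            "events_s": [float(x) for x in self.events_s],
            "events_idx": [int(i) for i in self.events_idx],
            "diagnostics": self.diagnostics,
        }


def compute_speed(trial: TrialRecording) -> SpeedProfile:
    """Wrist speed as the Euclidean norm of the central-difference derivative
    of the wrist position (one-sided differences at the end points)."""
    t = np.asarray(trial.t, float)
    if t.size < 5:
        raise SamplingError("need at least 5 samples")
    dt = np.diff(t)
    if np.ptp(dt) > _UNIFORMITY_TOL:
        raise SamplingError("time base is not uniform")
    vel = np.gradient(trial.wrist_pos, t[1] - t[0], axis=0)
    return SpeedProfile(t=t, speed=np.linalg.norm(vel, axis=1))


def detect_onset_offset(
    profile: SpeedProfile, threshold_frac: float = 0.10
) -> tuple[float, float]:
    """Movement onset/offset: first crossing above and last crossing below
    ``threshold_frac * max(speed)``.  Returns times in seconds."""
    v = profile.speed
    vmax = float(v.max())
    if vmax <= 0.0:
        raise NoMovementError("speed profile is identically zero")
    thr = threshold_frac * vmax
    above = np.flatnonzero(v > thr) if threshold_frac > 0 else np.flatnonzero(v > 0)
    if above.size == 0:
        raise NoMovementError("speed never exceeds the detection threshold")
    return float(profile.t[above[0]]), float(profile.t[above[-1]])


def segment_htm(
    profile: SpeedProfile,
    n_phases: int = 4,
    threshold_frac: float = 0.10,
    min_peak_gap: float = 0.3,
) -> PhaseBoundaries:
    """Segment one HTM trial into ``n_phases`` phases.

    Within [onset, offset], the ``n_phases`` largest speed peaks separated by
    at least ``min_peak_gap`` seconds are retained; each interior boundary is
    the deepest speed minimum between consecutive peaks (earliest on ties).

    Raises
    ------
    SegmentationError
        If fewer than ``n_phases`` qualifying peaks exist; the error carries
        the number found in ``n_peaks_found``.
    """
    t, v = profile.t, profile.speed
    t_on, t_off = detect_onset_offset(profile, threshold_frac)
    i_on = int(np.searchsorted(t, t_on))
    i_off = int(np.searchsorted(t, t_off))

    fs = profile.fs
    distance = max(int(round(min_peak_gap * fs)), 1)
    peaks, props = find_peaks(v[i_on : i_off + 1], distance=distance, prominence=0.0)
    peaks = peaks + i_on
    if peaks.size < n_phases:
        raise SegmentationError(
            f"found {peaks.size} qualifying speed peaks, need {n_phases}",
            n_peaks_found=int(peaks.size),
        )
    prominences = props["prominences"]
    keep = np.sort(np.argsort(v[peaks])[::-1][:n_phases])
    peaks_kept = peaks[keep]

    interior = []
    for a, b in zip(peaks_kept[:-1], peaks_kept[1:]):
        valley = a + int(np.argmin(v[a : b + 1]))  # argmin takes earliest on ties
        interior.append(valley)

    events_idx = np.array([i_on, *interior, i_off], dtype=int)
    events_s = t[events_idx]
    diagnostics = {
        "peaks_idx": [int(p) for p in peaks_kept],
        "peaks_s": [float(t[p]) for p in peaks_kept],
        "peak_speeds": [float(v[p]) for p in peaks_kept],
        "prominences": [float(prominences[k]) for k in keep],
        "valley_depths": [float(v[i]) for i in interior],
        "threshold_frac": threshold_frac,
        "min_peak_gap": min_peak_gap,
    }
    return PhaseBoundaries(events_s=events_s, events_idx=events_idx, diagnostics=diagnostics)
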