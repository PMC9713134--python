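"""Zero-velocity-update (ZUPT) dead reckoning for foot-mounted IMUs.

Stationary (foot-flat) periods are detected on the raw body-frame signals:
a sample is stationary iff the acceleration norm is within ``accel_tol`` of
g AND the angular-rate norm is below ``gyro_tol``. Each surviving stationary
run contributes one footfall anchor (its midpoint). Gravity is removed,
acceleration is integrated to velocity, and — under the assumptions that the
foot does not slip during footfalls (v = 0 there) and that integration drift
between consecutive footfalls is linear in time — the line through the
integrated velocity at the two bounding anchors is subtracted from each
inter-anchor interval, pinning velocity to exactly zero at every anchor.
Stride length/time, stride frequency and foot speed follow from the
corrected velocity.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy import integrate

from .constants import G

log = logging.getLogger(__name__)


class NoFootfallsError(ValueError):
    """No stationary run survived the thresholds."""


class InsufficientFootfallsError(ValueError):
    """Fewer than two anchors; the ZUPT correction is undefined."""


@dataclass(frozen=True)
class StationaryThresholds:
    """Stationary-period detection thresholds.

    The detection kinds (acceleration, angular velocity, stride time) are
    fixed; the default values were tuned on the synthetic generator and are
    fully configurable.
    """

    accel_tol: float = 0.8  # m/s^2 bound on | ||a|| - g |
    gyro_tol: float = 0.6  # rad/s bound on ||omega||
    min_stationary: float = 0.08  # s, shorter runs discarded
    min_stride_time: float = 0.4  # s, closer runs merged

    def __post_init__(self) -> None:
        if min(self.accel_tol, self.gyro_tol, self.min_stationary,
               self.min_stride_time) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass
class FootfallEvents:
    """Boolean stationary mask plus one anchor index per stance."""

    stationary: np.ndarray
    anchors: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.anchors) <= 0):
            raise ValueError("anchors must be strictly increasing")


@dataclass
class StrideTable:
    """Per-stride spatiotemporal parameters and their trial summaries."""

    lengths: np.ndarray  # m, one per stride
    times: np.ndarray  # s, one per stride
    stride_length_mean: float
    stride_length_var: float
    stride_time_mean: float
    stride_time_var: float
    stride_frequency_mean: float  # Hz, mean of 1/stride time
    foot_speed_mean: float  # m/s, planar path length / elapsed time
    v_footfall: float = 0.0  # the zero-velocity constraint value

    @property
    def n_strides(self) -> int:
        return len(self.lengths)

    def summary(self) -> dict[str, float]:
        return {
            "stride_length_mean": self.stride_length_mean,
            "stride_length_var": self.stride_length_var,
            "stride_time_mean": self.stride_time_mean,
            "stride_time_var": self.stride_time_var,
            "stride_frequency_mean": self.stride_frequency_mean,
            "foot_speed_mean": self.foot_speed_mean,
        }

    @classmethod
    def empty(cls) -> "StrideTable":
        return cls(lengths=np.empty(0), times=np.empty(0),
                   stride_length_mean=0.0, stride_length_var=0.0,
                   stride_time_mean=0.0, stride_time_var=0.0,
                   stride_frequency_mean=0.0, foot_speed_mean=0.0)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs of True in a boolean mask."""
    padded = np.diff(np.concatenate([[0], mask.astype(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts, ends))


def detect_stationary(accel: np.ndarray, gyro: np.ndarray, fs: float,
                      thresholds: StationaryThresholds | None = None) -> FootfallEvents:
    """Detect stationary runs and footfall anchors on raw body-frame signals.

    Runs shorter than ``min_stationary`` are discarded, runs separated by
    less than ``min_stride_time`` are merged, and each surviving run's
    midpoint sample becomes a footfall anchor.
    """
    thr = thresholds or StationaryThresholds()
    accel = np.asarray(accel, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    a_norm = np.linalg.norm(accel, axis=1)
    w_norm = np.linalg.norm(gyro, axis=1)
    mask = (np.abs(a_norm - G) < thr.accel_tol) & (w_norm < thr.gyro_tol)

    min_len = max(1, int(round(thr.min_stationary * fs)))
    runs = [(s, e) for s, e in _runs(mask) if e - s >= min_len]
    if not runs:
        raise NoFootfallsError("no stationary run passed the thresholds")

    gap = int(round(thr.min_stride_time * fs))
    merged = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    clean = np.zeros_like(mask)
    for s, e in merged:
        clean[s:e] = True
    anchors = np.array([(s + e - 1) // 2 for s, e in merged], dtype=int)
    return FootfallEvents(stationary=clean, anchors=anchors)


def zupt_correct(accel_body: np.ndarray, events: FootfallEvents,
                 fs: float, g: float = G) -> np.ndarray:
    """Drift-corrected foot velocity from body-frame acceleration.

    Gravity (g along body z) is subtracted and acceleration integrated to a
    raw velocity. For each inter-anchor interval the accumulated error is —
    by the linear-drift assumption — linear in time, so the line through the
    raw velocities at the two bounding anchors is subtracted; any linear
    acceleration error between anchors therefore cancels exactly. Outside
    the first/last anchor the adjacent interval's line is extrapolated.
    """
    anchors = np.asarray(events.anchors, dtype=int)
    if anchors.size < 2:
        raise InsufficientFootfallsError(
            f"{anchors.size} anchor(s); need at least 2 for the ZUPT correction")
    accel = np.asarray(accel_body, dtype=float) - np.array([0.0, 0.0, g])
    velocity = integrate.cumulative_trapezoid(accel, dx=1.0 / fs, initial=0.0, axis=0)

    n = velocity.shape[0]
    idx = np.arange(n, dtype=float)
    corr = np.empty_like(velocity)
    for axis in range(velocity.shape[1]):
        knots = velocity[anchors, axis]
        corr[:, axis] = np.interp(idx, anchors.astype(float), knots)
        # np.interp clamps beyond the ends; extrapolate the edge segments.
        slope0 = (knots[1] - knots[0]) / (anchors[1] - anchors[0])
        head = idx < anchors[0]
        corr[head, axis] = knots[0] + slope0 * (idx[head] - anchors[0])
        slope1 = (knots[-1] - knots[-2]) / (anchors[-1] - anchors[-2])
        tail = idx > anchors[-1]
        corr[tail, axis] = knots[-1] + slope1 * (idx[tail] - anchors[-1])
    corrected = velocity - corr
    corrected[anchors] = 0.0  # exact by construction; kill fp residue
    return corrected


def compute_strides(velocity: np.ndarray, events: FootfallEvents,
                    fs: float) -> StrideTable:
    """Spatiotemporal stride parameters from corrected velocity.

    Stride length is the planar (x-y) displacement between consecutive
    anchors, stride time the anchor time difference; foot speed is the total
    planar path length between the first and last anchor over the elapsed
    time. Fewer than two anchors yields an all-zero table.
    """
    anchors = np.asarray(events.anchors, dtype=int)
    if anchors.size < 2:
        log.warning("fewer than two footfalls; returning empty stride table")
        return StrideTable.empty()
    velocity = np.asarray(velocity, dtype=float)
    position = integrate.cumulative_trapezoid(velocity, dx=1.0 / fs, initial=0.0, axis=0)
    planar = position[:, :2]
    lengths = np.linalg.norm(np.diff(planar[anchors], axis=0), axis=1)
    times = np.diff(anchors) / fs
    steps = planar[anchors[0]:anchors[-1] + 1]
    path = float(np.linalg.norm(np.diff(steps, axis=0), axis=1).sum())
    elapsed = (anchors[-1] - anchors[0]) / fs
    var = (lambda x: float(np.var(x, ddof=1)) if x.size > 1 else 0.0)
    return StrideTable(
        lengths=lengths, times=times,
        stride_length_mean=float(lengths.mean()),
        stride_length_var=var(lengths),
        stride_time_mean=float(times.mean()),
        stride_time_var=var(times),
        stride_frequency_mean=float(np.mean(1.0 / times)),
        foot_speed_mean=path / elapsed,
    )


def foot_stride_table(accel_body: np.ndarray, gyro_body: np.ndarray, fs: float,
                      thresholds: StationaryThresholds | None = None,
                      ) -> tuple[StrideTable, FootfallEvents | None]:
    """Detection -> ZUPT -> strides for one foot, total over degenerate trials.

    Trials with no or a single footfall yield an all-zero table (with a
    logged warning) instead of aborting cohort assembly.
    """
    try:
        events = detect_stationary(accel_body, gyro_body, fs, thresholds)
    except NoFootfallsError:
        log.warning("no footfalls detected; zeroed stride features")
        return StrideTable.empty(), None
    if events.anchors.size < 2:
        log.warning("single footfall detected; zeroed stride features")
        return StrideTable.empty(), events
    velocity = zupt_correct(accel_body, events, fs)
    return compute_strides(velocity, events, fs), events
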