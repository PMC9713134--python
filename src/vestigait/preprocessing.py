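"""Sensor-to-body axis alignment, band-pass filtering, angular integration.

Each IMU is aligned to a body frame in which z points along gravity (up, as
measured during the static standing segment at the start of each trial), y is
the participant's frontal axis (the principal direction of angular velocity
in the plane orthogonal to z during walking), and x the sagittal axis fixed
by right-handedness. Aligned signals are band-pass filtered (zero-phase
Butterworth, 0.5-25 Hz) and angular rates are integrated to angular
displacements that capture sway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, signal

from .constants import G


class NoStaticGravityError(ValueError):
    """Static segment does not look static (mean acceleration norm << g)."""


class AmbiguousAxesError(ValueError):
    """In-plane angular velocity has no clear principal direction."""


class FilterLengthError(ValueError):
    """Series too short for the zero-phase filter's warm-up."""


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth band-pass specification (cutoffs in Hz)."""

    low: float = 0.5
    high: float = 25.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not (0 < self.low < self.high < fs / 2):
            raise ValueError(f"need 0 < low < high < fs/2, got {self} at fs={fs}")


@dataclass(frozen=True)
class BodyFrameAxes:
    """Orthonormal right-handed body axes expressed in the sensor frame."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.z):
            if abs(np.linalg.norm(v) - 1.0) > 1e-8:
                raise ValueError("axes must be unit vectors")
        for a, b in ((self.x, self.y), (self.y, self.z), (self.x, self.z)):
            if abs(float(a @ b)) > 1e-8:
                raise ValueError("axes must be pairwise orthogonal")
        if float(self.x @ np.cross(self.y, self.z)) <= 0:
            raise ValueError("axes must be right-handed")

    def as_matrix(self) -> np.ndarray:
        """Rotation matrix with rows (x, y, z): body = R @ sensor."""
        return np.vstack([self.x, self.y, self.z])

    @classmethod
    def identity(cls) -> "BodyFrameAxes":
        return cls(np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))


@dataclass
class AlignedSignals:
    """Body-frame signals for one placement.

    ``accel``/``gyro`` are the aligned raw series; ``accel_filt``/
    ``gyro_filt`` their band-passed versions; ``theta_x`` (roll) and
    ``theta_y`` (pitch) are angular displacements integrated from the
    filtered angular rate over the walking segment (starting at 0).
    ``walking_start`` is the first sample after the static lead-in.
    """

    accel: np.ndarray
    gyro: np.ndarray
    accel_filt: np.ndarray
    gyro_filt: np.ndarray
    theta_x: np.ndarray
    theta_y: np.ndarray
    fs: float
    walking_start: int
    axes: BodyFrameAxes


def estimate_gravity_axis(static_accel: np.ndarray, fs: float | None = None) -> np.ndarray:
    """Unit gravity ("up") direction in the sensor frame from a static segment.

    The mean acceleration over the segment is normalized; a resting
    accelerometer measures +g upward, so the returned vector points up. A
    mean norm below g/2 indicates the sensor was moving.
    """
    static_accel = np.asarray(static_accel, dtype=float)
    if static_accel.ndim != 2 or static_accel.shape[1] != 3:
        raise ValueError("expected an (n, 3) acceleration series")
    if fs is not None and static_accel.shape[0] < 0.5 * fs:
        raise ValueError("static segment must cover at least 0.5 s")
    mean = static_accel.mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm < 0.5 * G:
        raise NoStaticGravityError(
            f"mean static acceleration norm {norm:.2f} m/s^2 is below g/2; "
            "the sensor is likely moving")
    return mean / norm


def estimate_frontal_axis(walking_gyro: np.ndarray, z: np.ndarray) -> BodyFrameAxes:
    """Full body frame from the walking-segment gyroscope and the gravity axis.

    Angular velocity is projected onto the plane orthogonal to z; the first
    principal direction of the projected 2-D samples is the frontal (y) axis.
    The sign of y is fixed so the mean angular rate about y is >= 0, and x
    completes a right-handed frame (x = y x z).
    """
    walking_gyro = np.asarray(walking_gyro, dtype=float)
    z = np.asarray(z, dtype=float)
    z = z / np.linalg.norm(z)
    # Orthonormal basis (u1, u2) of the plane orthogonal to z.
    helper = np.array([1.0, 0.0, 0.0])
    if abs(float(helper @ z)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u1 = helper - (helper @ z) * z
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(z, u1)
    coords = walking_gyro @ np.column_stack([u1, u2])  # (n, 2) in-plane samples
    cov = np.cov(coords, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam1, lam2 = float(evals[1]), float(evals[0])
    if lam1 <= 0 or (lam2 > 0 and lam1 / lam2 < 1.05):
        raise AmbiguousAxesError(
            f"principal-component variance ratio {lam1 / lam2 if lam2 else np.inf:.3f} "
            "too close to 1; frontal axis is ambiguous")
    principal = evecs[:, 1]
    y = principal[0] * u1 + principal[1] * u2
    if float(walking_gyro.mean(axis=0) @ y) < 0:
        y = -y
    y = y - (y @ z) * z
    y /= np.linalg.norm(y)
    x = np.cross(y, z)
    x /= np.linalg.norm(x)
    return BodyFrameAxes(x=x, y=y, z=z)


def align_axes(accel: np.ndarray, gyro: np.ndarray,
               axes: BodyFrameAxes) -> tuple[np.ndarray, np.ndarray]:
    """Rotate sensor-frame series into the body frame (norm preserving)."""
    rot = axes.as_matrix()
    return np.asarray(accel) @ rot.T, np.asarray(gyro) @ rot.T


def _sos(spec: FilterSpec, fs: float) -> np.ndarray:
    spec.validate(fs)
    return signal.butter(spec.order, [spec.low, spec.high], btype="bandpass",
                         fs=fs, output="sos")


def bandpass(series: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Band-pass filter a series (1-D, or 2-D filtered along axis 0).

    Zero-phase realization applies the filter forward and backward
    (``sosfiltfilt``), doubling the effective order and cancelling phase
    delay so peak positions are preserved.
    """
    series = np.asarray(series, dtype=float)
    sos = _sos(spec, fs)
    n_zero = min(int((sos[:, 2] == 0).sum()), int((sos[:, 5] == 0).sum()))
    padlen = 3 * (2 * sos.shape[0] + 1 - n_zero)  # sosfiltfilt default warm-up
    if series.shape[0] <= 3 * padlen:
        raise FilterLengthError(
            f"series of length {series.shape[0]} too short for filter warm-up "
            f"({padlen} samples)")
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, series, axis=0)
    return signal.sosfilt(sos, series, axis=0)


def integrate_gyro(omega: np.ndarray, fs: float) -> np.ndarray:
    """Cumulative trapezoidal integral of angular rate, starting at 0 rad."""
    omega = np.asarray(omega, dtype=float)
    if not np.all(np.isfinite(omega)):
        raise ValueError("angular rate series contains non-finite values")
    return integrate.cumulative_trapezoid(omega, dx=1.0 / fs, initial=0.0, axis=0)


def preprocess_placement(accel: np.ndarray, gyro: np.ndarray, fs: float,
                         static_lead_in: float = 2.0,
                         filter_spec: FilterSpec | None = None) -> AlignedSignals:
    """Full preprocessing for one placement's raw sensor-frame signals.

    Estimates the body frame (gravity from the static lead-in, frontal axis
    by PCA over the walking-segment gyroscope), aligns the raw series,
    band-passes them, and integrates the filtered angular rate over the
    walking segment into roll/pitch displacement.
    """
    spec = filter_spec or FilterSpec()
    walking_start = int(round(static_lead_in * fs))
    z = estimate_gravity_axis(accel[:walking_start], fs)
    axes = estimate_frontal_axis(gyro[walking_start:], z)
    accel_b, gyro_b = align_axes(accel, gyro, axes)
    accel_f = bandpass(accel_b, spec, fs)
    gyro_f = bandpass(gyro_b, spec, fs)
    theta = integrate_gyro(gyro_f[walking_start:], fs)
    return AlignedSignals(
        accel=accel_b, gyro=gyro_b, accel_filt=accel_f, gyro_filt=gyro_f,
        theta_x=theta[:, 0], theta_y=theta[:, 1], fs=fs,
        walking_start=walking_start, axes=axes)
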