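"""Synthetic multi-IMU gait cohort generator.

Emulates a two-class gait study (vestibular deficit vs age-matched control)
recorded with 13 body-worn IMUs at 128 Hz: each trial starts with a static
standing segment, followed by periodic gait. Foot kinematics alternate true
zero-velocity stance phases with raised-cosine swing bumps whose integral is
the drawn stride length; arm angular rate about the frontal (pitch) axis is a
sinusoid at stride frequency whose integrated range equals the drawn
arm-swing amplitude. Gravity is projected through a per-placement random
mounting rotation, then white sensor noise and a linear gyroscope bias drift
are added. Every trial comes with ground truth (stride lengths/times,
footfall times, arm pitch ranges, mounting rotations) so downstream stages
can be validated without real recordings.

The between-class contrast defaults encode reduced arm swing in the
vestibular class (left arm pitch range 0.26 +/- 0.11 rad vs 0.49 +/- 0.21 rad
for controls, applied at full strength only in the eyes-closed task) together
with a shorter, slower stride.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import json
import logging
import pathlib

import numpy as np
import pandas as pd
from scipy.signal import square
from scipy.spatial.transform import Rotation

from .constants import G, PLACEMENTS, TASKS

log = logging.getLogger(__name__)


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


# Per-task kinematic profile: (speed multiplier, class-contrast strength,
# head-turn gyro axis or None). Only the eyes-closed task applies the class
# contrast at full strength; head-turn tasks add a square-wave head component
# but no extra contrast.
TASK_PROFILES = {
    "SSGS": (1.0, 0.4, None),
    "CGS": (1.0, 0.4, None),
    "GVHT": (1.0, 0.4, "pitch"),
    "GHHT": (1.0, 0.4, "yaw"),
    "GEC": (1.0, 1.0, None),
    "FGS": (1.25, 0.4, None),
    "SLGS": (0.75, 0.4, None),
}

# Segment-level oscillation amplitudes (pitch angular-displacement range in
# rad for non-arm placements; accelerations scaled per segment).
_SEGMENT_PITCH_RANGE = {
    "head": 0.06,
    "upper_back": 0.05,
    "lower_back": 0.04,
    "l_thigh": 0.55,
    "r_thigh": 0.55,
    "l_shank": 0.85,
    "r_shank": 0.85,
}
_SEGMENT_ACCEL_SCALE = {
    "head": 0.4,
    "upper_back": 0.5,
    "lower_back": 0.5,
    "l_arm": 0.8,
    "r_arm": 0.8,
    "l_wrist": 1.0,
    "r_wrist": 1.0,
    "l_thigh": 0.9,
    "r_thigh": 0.9,
    "l_shank": 1.2,
    "r_shank": 1.2,
}
_PHASES = {p: 0.0 if p.startswith("l_") else np.pi for p in PLACEMENTS}
_WRIST_SCALE = 1.15  # distal amplification of arm swing at the wrist
_STANCE_FRACTION = 0.4  # fraction of the stride spent foot-flat
_FOOT_SWING_GYRO_AMPLITUDE = 3.0  # rad/s, foot pitch rate during swing


@dataclass(frozen=True)
class SimConfig:
    """Cohort/protocol parameters for the synthetic gait study.

    Class-contrast parameters are (control, vestibular) pairs. Defaults
    reproduce the emulated protocol: 15 participants per class, 7 tasks of
    3 trials each, 128 Hz sampling, a 2 s static lead-in, and a left-arm
    pitch-range contrast of 0.49 vs 0.26 rad (SD 0.21 vs 0.11).
    """

    n_per_class: int = 15
    tasks: tuple[str, ...] = TASKS
    trials_per_task: int = 3
    fs: float = 128.0
    trial_duration: float = 10.0
    stride_length_mean: tuple[float, float] = (1.25, 1.05)  # m
    stride_time_mean: tuple[float, float] = (1.0, 1.1)  # s
    arm_pitch_range: tuple[float, float] = (0.49, 0.26)  # rad, left arm
    arm_pitch_range_sd: tuple[float, float] = (0.21, 0.11)
    arm_pitch_range_right: tuple[float, float] = (0.35, 0.26)  # rad
    arm_pitch_range_right_sd: tuple[float, float] = (0.14, 0.11)
    accel_noise_sd: float = 0.05  # m/s^2
    gyro_noise_sd: float = 0.01  # rad/s
    gyro_bias_drift: float = 0.002  # rad/s per s
    mounting_rotation_sd: float = 0.1  # rad
    static_lead_in: float = 2.0  # s
    stride_length_jitter_sd: float = 0.03  # m, within-trial stride-to-stride
    stride_time_jitter_sd: float = 0.02  # s
    placements: tuple[str, ...] = PLACEMENTS
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.fs <= 0 or self.trial_duration <= 0:
            raise InvalidConfigError("fs and trial_duration must be positive")
        if self.n_per_class < 1 or self.trials_per_task < 1:
            raise InvalidConfigError("counts must be positive")
        if self.static_lead_in <= 0 or self.static_lead_in >= self.trial_duration:
            raise InvalidConfigError("static_lead_in must lie inside the trial")
        for name in (
            "stride_length_mean",
            "stride_time_mean",
            "arm_pitch_range",
            "arm_pitch_range_sd",
            "arm_pitch_range_right",
            "arm_pitch_range_right_sd",
        ):
            pair = getattr(self, name)
            if len(pair) != 2:
                raise InvalidConfigError(f"{name} must have one value per class")
        if any(v <= 0 for v in self.stride_length_mean + self.stride_time_mean):
            raise InvalidConfigError("stride parameters must be positive")
        unknown = set(self.tasks) - set(TASKS)
        if unknown:
            raise InvalidConfigError(f"unknown tasks: {sorted(unknown)}")
        unknown = set(self.placements) - set(PLACEMENTS)
        if unknown:
            raise InvalidConfigError(f"unknown placements: {sorted(unknown)}")
        n = self.fs * self.trial_duration
        if abs(n - round(n)) > 1e-9:
            raise InvalidConfigError("fs * trial_duration must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.trial_duration))

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def noise_free(cls, **kw) -> "SimConfig":
        """A convenience configuration with every stochastic term disabled."""
        defaults = dict(
            accel_noise_sd=0.0,
            gyro_noise_sd=0.0,
            gyro_bias_drift=0.0,
            mounting_rotation_sd=0.0,
            stride_length_jitter_sd=0.0,
            stride_time_jitter_sd=0.0,
            arm_pitch_range_sd=(0.0, 0.0),
            arm_pitch_range_right_sd=(0.0, 0.0),
        )
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class GroundTruth:
    """Per-trial ground truth used by recovery tests."""

    stride_lengths: dict[str, list[float]]  # foot -> m per stride
    stride_times: dict[str, list[float]]  # foot -> s per stride
    footfall_times: dict[str, list[float]]  # foot -> stance-midpoint times (s)
    arm_pitch_range: dict[str, float]  # side ("l"/"r") -> rad
    mounting_rotation: dict[str, np.ndarray]  # placement -> body-from-sensor R
    label: int

    def validate(self) -> None:
        counts = [len(v) for v in self.footfall_times.values()]
        if counts and max(counts) - min(counts) > 1:
            raise AssertionError("stride counts per foot differ by more than 1")
        for name, r in self.mounting_rotation.items():
            if not np.allclose(r.T @ r, np.eye(3), atol=1e-10):
                raise AssertionError(f"mounting rotation for {name} not orthonormal")


@dataclass
class TrialRecording:
    """Synchronized accelerometer/gyroscope series for one trial.

    ``signals[placement]`` holds ``{"accel": (n, 3) m/s^2, "gyro": (n, 3)
    rad/s}`` in each sensor's own (mounted) frame.
    """

    participant_id: str
    task_id: str
    trial_index: int
    label: int
    fs: float
    signals: dict[str, dict[str, np.ndarray]]

    @property
    def n_samples(self) -> int:
        first = next(iter(self.signals.values()))
        return first["accel"].shape[0]

    @property
    def placements(self) -> tuple[str, ...]:
        return tuple(self.signals)


def participant_ids(config: SimConfig) -> list[tuple[str, int]]:
    """The cohort roster as (participant_id, label) pairs.

    Controls are ``H01..`` (label 0) and the vestibular class ``V01..``
    (label 1).
    """
    roster = [(f"H{i + 1:02d}", 0) for i in range(config.n_per_class)]
    roster += [(f"V{i + 1:02d}", 1) for i in range(config.n_per_class)]
    return roster


def _parse_participant(participant_id: str) -> tuple[int, int]:
    label = 1 if participant_id[0].upper() == "V" else 0
    return label, int(participant_id[1:])


def _participant_effects(config: SimConfig, participant_id: str) -> dict[str, float]:
    """Per-participant random effects, reproducible from the cohort seed.

    Stride offsets use half the between-class gap as their SD so trials of
    one participant are correlated; arm-swing offsets take half the class
    variance (the other half is trial-to-trial) so the trial-level population
    SD matches the configured per-class SD.
    """
    label, idx = _parse_participant(participant_id)
    ss = np.random.SeedSequence(config.seed, spawn_key=(0x5EED, label, idx))
    rng = np.random.default_rng(ss)
    u = rng.standard_normal(4)
    gap_len = abs(config.stride_length_mean[0] - config.stride_length_mean[1])
    gap_time = abs(config.stride_time_mean[0] - config.stride_time_mean[1])
    return {
        "stride_length": u[0] * gap_len / 2.0,
        "stride_time": u[1] * gap_time / 2.0,
        "arm_l": u[2] * config.arm_pitch_range_sd[label] / np.sqrt(2.0),
        "arm_r": u[3] * config.arm_pitch_range_right_sd[label] / np.sqrt(2.0),
    }


def _foot_schedule(rng, config: SimConfig, stride_time: float, stride_length: float,
                   phase: float):
    """Alternating stationary/swing intervals for one foot.

    Returns ``(stationary_runs, swings)`` where runs are ``(start, end)``
    times and swings are ``(start, end, length_m)``. The trial begins and
    ends with the foot stationary.
    """
    duration = config.trial_duration
    runs: list[tuple[float, float]] = []
    swings: list[tuple[float, float, float]] = []
    stance_start = config.static_lead_in + phase
    while True:
        ts = stride_time
        if config.stride_time_jitter_sd > 0:
            ts += rng.normal(0.0, config.stride_time_jitter_sd)
        ts = max(ts, 0.5 * stride_time)
        stance_end = stance_start + _STANCE_FRACTION * ts
        swing_end = stance_start + ts
        if swing_end > duration - 0.05:
            break
        length = stride_length
        if config.stride_length_jitter_sd > 0:
            length += rng.normal(0.0, config.stride_length_jitter_sd)
        length = max(length, 0.1)
        runs.append((stance_start, stance_end))
        swings.append((stance_end, swing_end, length))
        stance_start = swing_end
    runs.append((stance_start, duration))
    # The foot was already stationary through the static lead-in and any
    # phase delay; extend the first run back to the start of the walking
    # segment so ground-truth footfalls match maximal stationary intervals.
    runs[0] = (config.static_lead_in, runs[0][1])
    return runs, swings


def _foot_kinematics(t: np.ndarray, swings) -> tuple[np.ndarray, np.ndarray]:
    """World-frame kinematic acceleration and angular rate for one foot.

    Swing-phase forward velocity is a raised-cosine bump integrating to the
    stride length; vertical velocity a full sine (net zero lift). Both are
    returned as analytic accelerations; stance samples are exactly zero.
    """
    n = t.size
    accel = np.zeros((n, 3))
    gyro = np.zeros((n, 3))
    for start, end, length in swings:
        idx = (t >= start) & (t < end)
        t_sw = end - start
        tau = (t[idx] - start) / t_sw
        v_peak = 2.0 * length / t_sw
        accel[idx, 0] = v_peak * np.pi / t_sw * np.sin(2 * np.pi * tau)
        a_z = 0.25 * v_peak
        accel[idx, 2] = a_z * 2 * np.pi / t_sw * np.cos(2 * np.pi * tau)
        gyro[idx, 1] = _FOOT_SWING_GYRO_AMPLITUDE * np.sin(2 * np.pi * tau)
    return accel, gyro


_ONSET_RAMP = 2.5  # s, raised-cosine ease-in from standing / ease-out to stop


def _onset_envelope(t_walk: np.ndarray) -> np.ndarray:
    """Raised-cosine envelope: eases in over the first ramp and back out over
    the last, emulating gait initiation and termination on a short walkway.

    Slow ramps keep the modulation sidebands of stride-frequency components
    above the 0.5 Hz high-pass corner, so band-pass filtering does not
    distort the steady-gait amplitude. For short trials the ramp shrinks to
    a quarter of the walking span.
    """
    span = float(t_walk[-1] - t_walk[0])
    ramp_s = min(_ONSET_RAMP, span / 4.0)
    env = np.ones_like(t_walk)
    ramp = t_walk < ramp_s
    env[ramp] = 0.5 * (1.0 - np.cos(np.pi * t_walk[ramp] / ramp_s))
    remaining = t_walk[-1] - t_walk
    tail = remaining < ramp_s
    env[tail] *= 0.5 * (1.0 - np.cos(np.pi * remaining[tail] / ramp_s))
    return env


def _oscillation(t_walk: np.ndarray, f: float, pitch_range: float, phase: float,
                 accel_scale: float, accel_phases: np.ndarray):
    """Generic segment oscillation: pitch-dominant gyro plus gait-band accel.

    A raised-cosine onset envelope eases from standing into steady gait so
    the series has no step at the end of the static lead-in.
    """
    amp = pitch_range * np.pi * f  # so integrated pitch range == pitch_range
    w = 2 * np.pi * f * t_walk
    env = _onset_envelope(t_walk)
    # Roll leads pitch by a quarter cycle (as in normal gait), which keeps
    # the in-plane angular-velocity covariance diagonal: the principal
    # direction of sensor-frame gyro samples is the true frontal axis.
    gyro = env[:, None] * np.column_stack([
        0.25 * amp * np.sin(w + phase + np.pi / 2),
        amp * np.sin(w + phase),
        0.12 * amp * np.sin(w + phase + 2.0),
    ])
    accel = env[:, None] * np.column_stack([
        0.4 * accel_scale * np.sin(w + accel_phases[0]),
        0.2 * accel_scale * np.sin(w + accel_phases[1]),
        0.6 * accel_scale * np.sin(2 * w + accel_phases[2]),
    ])
    return accel, gyro


def _random_mounting(rng, sd: float) -> np.ndarray:
    """Small random body-from-sensor rotation with angle ~ N(0, sd)."""
    if sd == 0:
        return np.eye(3)
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.normal(0.0, sd)
    return Rotation.from_rotvec(axis * angle).as_matrix()


def simulate_trial(config: SimConfig, participant_id: str, task_id: str,
                   trial_index: int, rng=None) -> tuple[TrialRecording, GroundTruth]:
    """Generate one labeled trial plus its ground truth.

    Deterministic in ``(config.seed, participant_id, task_id, trial_index)``
    unless an explicit ``rng`` is supplied.
    """
    config.validate()
    if task_id not in config.tasks:
        raise InvalidConfigError(f"task {task_id!r} not in configured tasks")
    label, p_idx = _parse_participant(participant_id)
    if rng is None:
        task_idx = TASKS.index(task_id)
        ss = np.random.SeedSequence(
            config.seed, spawn_key=(0x7A1A, label, p_idx, task_idx, trial_index))
        rng = np.random.default_rng(ss)

    speed, contrast, head_turn = TASK_PROFILES[task_id]
    effects = _participant_effects(config, participant_id)

    def contrasted(pair):
        if label == 0:
            return pair[0]
        return pair[0] + contrast * (pair[1] - pair[0])

    stride_length = max(0.3, contrasted(config.stride_length_mean) + effects["stride_length"])
    stride_time = max(0.5, (contrasted(config.stride_time_mean) + effects["stride_time"]) / speed)
    f_stride = 1.0 / stride_time

    def draw_range(pair, sd_pair, offset):
        value = contrasted(pair) + offset
        if sd_pair[label] > 0:
            value += rng.normal(0.0, sd_pair[label] / np.sqrt(2.0))
        return max(value, 0.05)

    arm_range = {
        "l": draw_range(config.arm_pitch_range, config.arm_pitch_range_sd, effects["arm_l"]),
        "r": draw_range(config.arm_pitch_range_right, config.arm_pitch_range_right_sd,
                        effects["arm_r"]),
    }

    n = config.n_samples
    t = np.arange(n) / config.fs
    ws = int(round(config.static_lead_in * config.fs))
    t_walk = t[ws:] - config.static_lead_in

    foot_runs, foot_swings = {}, {}
    for foot, phase in (("l_foot", 0.0), ("r_foot", stride_time / 2.0)):
        foot_runs[foot], foot_swings[foot] = _foot_schedule(
            rng, config, stride_time, stride_length, phase)

    signals: dict[str, dict[str, np.ndarray]] = {}
    mounting: dict[str, np.ndarray] = {}
    gravity = np.array([0.0, 0.0, G])
    for placement in config.placements:
        accel_body = np.zeros((n, 3))
        gyro_body = np.zeros((n, 3))
        if placement in ("l_foot", "r_foot"):
            a, w = _foot_kinematics(t, foot_swings[placement])
            accel_body += a
            gyro_body += w
        else:
            if placement in ("l_arm", "r_arm", "l_wrist", "r_wrist"):
                side = placement[0]
                pitch_range = arm_range[side]
                if placement.endswith("wrist"):
                    pitch_range = pitch_range * _WRIST_SCALE
            else:
                pitch_range = _SEGMENT_PITCH_RANGE[placement]
            a, w = _oscillation(
                t_walk, f_stride, pitch_range, _PHASES[placement],
                _SEGMENT_ACCEL_SCALE.get(placement, 0.5), rng.uniform(0, 2 * np.pi, 3))
            accel_body[ws:] += a
            gyro_body[ws:] += w
            if placement == "head" and head_turn is not None:
                turn = 1.2 * square(2 * np.pi * t_walk / (1.5 * stride_time))
                axis = 1 if head_turn == "pitch" else 2
                gyro_body[ws:, axis] += _onset_envelope(t_walk) * turn
        accel_body += gravity  # specific force of a non-free-falling sensor

        r_mount = _random_mounting(rng, config.mounting_rotation_sd)
        mounting[placement] = r_mount
        accel_sensor = accel_body @ r_mount  # == (R^T a_body)^T per sample
        gyro_sensor = gyro_body @ r_mount
        if config.accel_noise_sd > 0:
            accel_sensor = accel_sensor + rng.normal(0, config.accel_noise_sd, (n, 3))
        if config.gyro_noise_sd > 0:
            gyro_sensor = gyro_sensor + rng.normal(0, config.gyro_noise_sd, (n, 3))
        if config.gyro_bias_drift > 0:
            bias_rate = rng.normal(0, config.gyro_bias_drift, 3)
            gyro_sensor = gyro_sensor + bias_rate[None, :] * t[:, None]
        signals[placement] = {"accel": accel_sensor, "gyro": gyro_sensor}

    truth = GroundTruth(
        stride_lengths={foot: [s[2] for s in foot_swings[foot]] for foot in foot_swings},
        stride_times={
            foot: np.diff([(a + b) / 2.0 for a, b in foot_runs[foot]]).tolist()
            for foot in foot_runs
        },
        footfall_times={
            foot: [(a + b) / 2.0 for a, b in foot_runs[foot]] for foot in foot_runs
        },
        arm_pitch_range=arm_range,
        mounting_rotation=mounting,
        label=label,
    )
    truth.validate()
    recording = TrialRecording(
        participant_id=participant_id,
        task_id=task_id,
        trial_index=trial_index,
        label=label,
        fs=config.fs,
        signals=signals,
    )
    return recording, truth


def simulate_cohort(config: SimConfig) -> tuple[list[TrialRecording], list[GroundTruth]]:
    """Generate the full cohort: every participant x task x trial."""
    trials, truths = [], []
    for participant_id, _label in participant_ids(config):
        for task_id in config.tasks:
            for trial_index in range(config.trials_per_task):
                rec, truth = simulate_trial(config, participant_id, task_id, trial_index)
                trials.append(rec)
                truths.append(truth)
    return trials, truths


# ---------------------------------------------------------------------------
# Cohort persistence: per-trial CSV + manifest CSV + ground-truth JSON.
# Values are written as float64 text at 17 significant digits so a
# write/read round-trip is bit-exact.
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"


def _trial_filename(rec: TrialRecording) -> str:
    return f"{rec.participant_id}_{rec.task_id}_{rec.trial_index}.csv"


def _trial_frame(rec: TrialRecording) -> pd.DataFrame:
    cols = {"time_s": np.arange(rec.n_samples) / rec.fs}
    for placement in rec.placements:
        for kind, key in (("acc", "accel"), ("gyr", "gyro")):
            arr = rec.signals[placement][key]
            for j, axis in enumerate("xyz"):
                cols[f"{placement}_{kind}_{axis}"] = arr[:, j]
    return pd.DataFrame(cols)


def write_cohort(trials: list[TrialRecording], truths: list[GroundTruth],
                 out_dir: str | pathlib.Path) -> pathlib.Path:
    """Write a cohort directory: trials/*.csv, manifest.csv, ground_truth.json."""
    out = pathlib.Path(out_dir)
    (out / "trials").mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    truth_obj = {}
    for rec, truth in zip(trials, truths):
        fname = _trial_filename(rec)
        _trial_frame(rec).to_csv(out / "trials" / fname, index=False,
                                 float_format=_FLOAT_FMT)
        manifest_rows.append({
            "participant_id": rec.participant_id,
            "task_id": rec.task_id,
            "trial_index": rec.trial_index,
            "label": rec.label,
            "fs": rec.fs,
            "file": f"trials/{fname}",
        })
        truth_obj[fname] = {
            "stride_lengths": truth.stride_lengths,
            "stride_times": truth.stride_times,
            "footfall_times": truth.footfall_times,
            "arm_pitch_range": truth.arm_pitch_range,
            "mounting_rotation": {k: v.tolist() for k, v in truth.mounting_rotation.items()},
            "label": truth.label,
        }
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    (out / "ground_truth.json").write_text(json.dumps(truth_obj, indent=1))
    return out


def read_cohort(cohort_dir: str | pathlib.Path) -> tuple[list[TrialRecording], list[GroundTruth]]:
    """Read a cohort directory written by :func:`write_cohort`."""
    root = pathlib.Path(cohort_dir)
    manifest = pd.read_csv(root / "manifest.csv", float_precision="round_trip")
    truth_obj = json.loads((root / "ground_truth.json").read_text())
    trials, truths = [], []
    for row in manifest.itertuples(index=False):
        frame = pd.read_csv(root / row.file, float_precision="round_trip")
        placements = sorted(
            {c.rsplit("_", 2)[0] for c in frame.columns if c != "time_s"},
            key=lambda p: PLACEMENTS.index(p))
        signals = {}
        for placement in placements:
            signals[placement] = {
                "accel": frame[[f"{placement}_acc_{a}" for a in "xyz"]].to_numpy(),
                "gyro": frame[[f"{placement}_gyr_{a}" for a in "xyz"]].to_numpy(),
            }
        trials.append(TrialRecording(
            participant_id=row.participant_id, task_id=row.task_id,
            trial_index=int(row.trial_index), label=int(row.label),
            fs=float(row.fs), signals=signals))
        tr = truth_obj[pathlib.Path(row.file).name]
        truths.append(GroundTruth(
            stride_lengths=tr["stride_lengths"],
            stride_times=tr["stride_times"],
            footfall_times=tr["footfall_times"],
            arm_pitch_range=tr["arm_pitch_range"],
            mounting_rotation={k: np.asarray(v) for k, v in tr["mounting_rotation"].items()},
            label=int(tr["label"])))
    return trials, truths
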