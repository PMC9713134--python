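"""Per-placement kinematic feature extraction and task dataset assembly.

Each placement contributes five statistical descriptors (maximum, minimum,
mean, RMS, range) of the three band-passed angular-rate axes, the three
band-passed acceleration axes, and the two total magnitudes, plus the mean
and range of pitch (theta_y) and roll (theta_x) angular displacement: 44
features. Head and trunk placements add the 95% confidence-ellipse areas of
sway velocity and sway displacement (46); feet add six spatiotemporal stride
summaries through the ZUPT path (50). Over the 13 placements this yields the
590-feature vector per trial; per-task datasets stack one row per trial with
the participant's diagnosis label.

Descriptor features are computed on band-passed signals and sway on the
integrated band-passed angular rate, while stride features run on the raw
(unfiltered) aligned foot signals, whose gravity content the stationary
detector and ZUPT correction rely on. The static lead-in is excluded from
all feature windows.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .constants import FOOT_PLACEMENTS, PLACEMENTS, TRUNK_PLACEMENTS
from .preprocessing import FilterSpec, preprocess_placement
from .zupt import StationaryThresholds, foot_stride_table
from .synthetic import TrialRecording

log = logging.getLogger(__name__)

DESCRIPTOR_NAMES = ("max", "min", "mean", "rms", "range")
SIGNAL_NAMES = ("gyr_x", "gyr_y", "gyr_z", "acc_x", "acc_y", "acc_z",
                "gyr_total", "acc_total")
THETA_NAMES = ("theta_y__mean", "theta_y__range", "theta_x__mean", "theta_x__range")
SWAY_NAMES = ("sway_velocity_ea", "sway_displacement_ea")
STRIDE_NAMES = ("stride_length__mean", "stride_length__var", "stride_time__mean",
                "stride_time__var", "stride_frequency__mean", "foot_speed__mean")

#: chi-square(2 dof) 95% quantile used by the confidence-ellipse area.
CHI2_95_2DF = float(stats.chi2.ppf(0.95, df=2))


class EmptyInputError(ValueError):
    pass


class ExtractionError(RuntimeError):
    """A feature came out non-finite; the message names it."""


class EmptyDatasetError(ValueError):
    pass


def placement_feature_names(placement: str) -> list[str]:
    """Canonical ordered feature names for one placement."""
    names = [f"{placement}__{sig}__{d}" for sig in SIGNAL_NAMES for d in DESCRIPTOR_NAMES]
    names += [f"{placement}__{t}" for t in THETA_NAMES]
    if placement in TRUNK_PLACEMENTS:
        names += [f"{placement}__{s}" for s in SWAY_NAMES]
    if placement in FOOT_PLACEMENTS:
        names += [f"{placement}__{s}" for s in STRIDE_NAMES]
    return names


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered feature-name catalogue over a set of placements.

    For the full 13-placement set the per-class counts are 44 (limbs), 46
    (head/trunk) and 50 (feet), 590 in total; this identity is asserted at
    construction.
    """

    placements: tuple[str, ...] = PLACEMENTS

    def __post_init__(self) -> None:
        unknown = set(self.placements) - set(PLACEMENTS)
        if unknown:
            raise ValueError(f"unknown placements: {sorted(unknown)}")
        for p in self.placements:
            expected = 50 if p in FOOT_PLACEMENTS else 46 if p in TRUNK_PLACEMENTS else 44
            assert len(placement_feature_names(p)) == expected, p
        if set(self.placements) == set(PLACEMENTS):
            assert len(self.names) == 590  # 8*44 + 3*46 + 2*50

    @property
    def names(self) -> list[str]:
        return [n for p in self.placements for n in placement_feature_names(p)]

    @property
    def n_features(self) -> int:
        return len(self.names)

    def subset(self, placements) -> "FeatureSpec":
        return FeatureSpec(tuple(placements))


@dataclass
class FeatureVector:
    """One trial's named feature values plus its diagnosis label."""

    participant_id: str
    task_id: str
    trial_index: int
    label: int
    names: list[str]
    values: np.ndarray

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


@dataclass
class TaskDataset:
    """Feature matrix for one gait task: rows = trials, columns = features."""

    task_id: str
    X: pd.DataFrame  # indexed by (participant_id, trial_index)
    y: np.ndarray
    groups: np.ndarray  # participant IDs, one per row

    @property
    def participants(self) -> np.ndarray:
        return np.unique(self.groups)

    def participant_labels(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g, label in zip(self.groups, self.y):
            out[g] = int(label)
        return out

    def select_placements(self, placements) -> "TaskDataset":
        cols = [n for p in placements for n in placement_feature_names(p)
                if n in self.X.columns]
        if not cols:
            raise KeyError(f"no columns for placements {placements}")
        return TaskDataset(self.task_id, self.X[cols], self.y, self.groups)


def descriptors(series: np.ndarray) -> dict[str, float]:
    """Maximum, minimum, mean, RMS and range of a series."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise EmptyInputError("cannot summarize an empty series")
    mx, mn = float(series.max()), float(series.min())
    return {
        "max": mx,
        "min": mn,
        "mean": float(series.mean()),
        "rms": float(np.sqrt(np.mean(series ** 2))),
        "range": mx - mn,
    }


def total_magnitude(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Elementwise Euclidean norm sqrt(x^2 + y^2 + z^2)."""
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ValueError("axis series must share one shape")
    return np.sqrt(x ** 2 + y ** 2 + z ** 2)


def ellipse_area_95(u: np.ndarray, v: np.ndarray) -> float:
    """Area of the 95% confidence ellipse of paired samples.

    area = pi * chi2_{2}(0.95) * sqrt(lambda1 * lambda2) with lambda_i the
    eigenvalues of the 2x2 sample covariance of (u, v). A degenerate
    covariance gives area 0.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("u and v must be equal-length 1-D series")
    if u.size < 10:
        raise ValueError("need at least 10 samples for the ellipse area")
    cov = np.cov(np.vstack([u, v]))
    evals = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
    return float(np.pi * CHI2_95_2DF * np.sqrt(evals[0] * evals[1]))


def extract_features(trial: TrialRecording, spec: FeatureSpec | None = None,
                     filter_spec: FilterSpec | None = None,
                     thresholds: StationaryThresholds | None = None,
                     static_lead_in: float = 2.0) -> FeatureVector:
    """Compute the full named feature vector for one trial."""
    spec = spec or FeatureSpec()
    filter_spec = filter_spec or FilterSpec()
    missing = set(spec.placements) - set(trial.placements)
    if missing:
        raise ValueError(f"trial lacks placements {sorted(missing)}")

    values: list[float] = []
    names: list[str] = []
    for placement in spec.placements:
        sig = trial.signals[placement]
        pre = preprocess_placement(sig["accel"], sig["gyro"], trial.fs,
                                   static_lead_in=static_lead_in,
                                   filter_spec=filter_spec)
        w = slice(pre.walking_start, None)
        gyr = pre.gyro_filt[w]
        acc = pre.accel_filt[w]
        channels = {
            "gyr_x": gyr[:, 0], "gyr_y": gyr[:, 1], "gyr_z": gyr[:, 2],
            "acc_x": acc[:, 0], "acc_y": acc[:, 1], "acc_z": acc[:, 2],
            "gyr_total": total_magnitude(gyr[:, 0], gyr[:, 1], gyr[:, 2]),
            "acc_total": total_magnitude(acc[:, 0], acc[:, 1], acc[:, 2]),
        }
        for sig_name in SIGNAL_NAMES:
            desc = descriptors(channels[sig_name])
            for d in DESCRIPTOR_NAMES:
                names.append(f"{placement}__{sig_name}__{d}")
                values.append(desc[d])
        for theta_name, series in (("theta_y", pre.theta_y), ("theta_x", pre.theta_x)):
            names.append(f"{placement}__{theta_name}__mean")
            values.append(float(series.mean()))
            names.append(f"{placement}__{theta_name}__range")
            values.append(float(series.max() - series.min()))
        if placement in TRUNK_PLACEMENTS:
            names.append(f"{placement}__sway_velocity_ea")
            values.append(ellipse_area_95(gyr[:, 1], gyr[:, 0]))  # (pitch, roll)
            names.append(f"{placement}__sway_displacement_ea")
            values.append(ellipse_area_95(pre.theta_y, pre.theta_x))
        if placement in FOOT_PLACEMENTS:
            table, _events = foot_stride_table(
                pre.accel[w], pre.gyro[w], trial.fs, thresholds)
            for key, value in table.summary().items():
                names.append(f"{placement}__{key.replace('_mean', '__mean').replace('_var', '__var')}")
                values.append(value)

    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = [n for n, v in zip(names, arr) if not np.isfinite(v)]
        raise ExtractionError(
            f"non-finite feature(s) {bad} for trial "
            f"({trial.participant_id}, {trial.task_id}, {trial.trial_index})")
    expected = spec.names
    assert names == expected, "feature order drifted from the catalogue"
    return FeatureVector(trial.participant_id, trial.task_id, trial.trial_index,
                         trial.label, names, arr)


def build_dataset(trials: list[TrialRecording], task_id: str,
                  spec: FeatureSpec | None = None,
                  filter_spec: FilterSpec | None = None,
                  thresholds: StationaryThresholds | None = None,
                  static_lead_in: float = 2.0) -> TaskDataset:
    """Assemble the per-task feature dataset, one row per trial.

    Rows are ordered by (participant_id, trial_index). Unequal trial counts
    across participants are reported as a warning, never silently dropped.
    """
    spec = spec or FeatureSpec()
    selected = [t for t in trials if t.task_id == task_id]
    if not selected:
        raise EmptyDatasetError(f"no trials for task {task_id!r}")
    selected.sort(key=lambda t: (t.participant_id, t.trial_index))
    counts = pd.Series([t.participant_id for t in selected]).value_counts()
    if counts.nunique() > 1:
        log.warning("unequal trial counts per participant for task %s: %s",
                    task_id, counts.to_dict())
    rows, labels, groups, index = [], [], [], []
    for t in selected:
        fv = extract_features(t, spec, filter_spec, thresholds, static_lead_in)
        rows.append(fv.values)
        labels.append(fv.label)
        groups.append(fv.participant_id)
        index.append((t.participant_id, t.trial_index))
    X = pd.DataFrame(np.vstack(rows), columns=spec.names,
                     index=pd.MultiIndex.from_tuples(index, names=["participant_id",
                                                                   "trial_index"]))
    return TaskDataset(task_id=task_id, X=X, y=np.asarray(labels, dtype=int),
                       groups=np.asarray(groups, dtype=object))
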