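"""Core trial data types and tabular file I/O.

A :class:`Trial` is the unit of all processing: a uniformly sampled 50 Hz
multi-channel time series (planar kinematics, 12 MVC-normalized EMG
envelopes, ground reaction force + centre of pressure, exoskeleton support
torque) plus condition metadata.

Sign and unit conventions (used package-wide):

* angles in radians; flexion positive; segment orientations measured from the
  global vertical, forward lean positive,
* moments about L5/S1 in newton-metres, **extension positive**,
* forces in newtons, positions in metres, x forward / y up.

Trial files are UTF-8 text: a ``#``-prefixed ``key: value`` metadata header
followed by one comma-delimited row per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FS_HZ = 50.0

#: Fixed 12-channel EMG order: rectus abdominis, internal oblique, external
#: oblique, iliocostalis lumborum, longissimus thoracis pars lumborum and
#: pars thoracis, left/right each.
EMG_CHANNELS = (
    "RA_L", "RA_R", "IO_L", "IO_R", "EO_L", "EO_R",
    "IL_L", "IL_R", "LTpl_L", "LTpl_R", "LTpt_L", "LTpt_R",
)

#: The 4 channels available to the reduced-sensor regression model.
REGMOD_EMG_CHANNELS = ("LTpl_L", "LTpl_R", "LTpt_L", "LTpt_R")

KINEMATIC_COLUMNS = (
    "trunk_inclination", "trunk_inclination_vel", "trunk_inclination_acc",
    "trunk_flexion", "hip_angle", "lumbar_flexion", "lumbar_flexion_vel",
    "phi_shank", "phi_thigh", "phi_pelvis", "phi_trunk", "phi_arm",
    "knee_x", "knee_y", "hip_x", "hip_y", "l5s1_x", "l5s1_y",
    "shoulder_x", "shoulder_y", "hand_x", "hand_y",
)

FORCE_COLUMNS = ("grf_fx", "grf_fy", "cop_x", "load_mass_kg", "hand_force_x")

TRIAL_COLUMNS = (
    ("time_s",)
    + KINEMATIC_COLUMNS
    + FORCE_COLUMNS
    + ("exo_torque_nm",)
    + tuple(f"emg_{ch}" for ch in EMG_CHANNELS)
)

TECHNIQUES = ("stoop", "squat", "free", "n/a")
VELOCITIES = ("very_slow", "slow", "normal", "fast", "n/a")
TASK_GROUPS = (
    "calibration_lift", "exo_lift", "stack_lift", "stack_carry",
    "shelf_lift", "push_pull",
)
EXO_STRATEGIES = ("none", "inclination", "dynamic", "velocity", "transparent")

#: Ordinal ranking of lifting-velocity classes.
VELOCITY_ORDER = {"very_slow": 0, "slow": 1, "normal": 2, "fast": 3}


class TrialValidationError(ValueError):
    """A trial violates a structural invariant."""


class TrialFormatError(ValueError):
    """A trial file does not match the documented dialect."""


@dataclass(frozen=True)
class TrialCondition:
    """Condition metadata of one trial."""

    mass_kg: float
    technique: str
    velocity: str
    task_group: str
    exo_strategy: str = "none"

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise TrialValidationError(f"unknown technique {self.technique!r}")
        if self.velocity not in VELOCITIES:
            raise TrialValidationError(f"unknown velocity {self.velocity!r}")
        if self.task_group not in TASK_GROUPS:
            raise TrialValidationError(f"unknown task group {self.task_group!r}")
        if self.exo_strategy not in EXO_STRATEGIES:
            raise TrialValidationError(f"unknown exo strategy {self.exo_strategy!r}")
        if self.task_group == "calibration_lift":
            if self.exo_strategy != "none":
                raise TrialValidationError(
                    "calibration lifts are performed without the exoskeleton"
                )
            if self.technique in ("stoop", "squat") and self.velocity not in (
                "slow", "normal",
            ):
                raise TrialValidationError(
                    f"{self.technique} calibration lifts exist only at slow/normal "
                    f"velocity, got {self.velocity!r}"
                )
            if self.technique == "free" and self.velocity not in (
                "very_slow", "normal", "fast",
            ):
                raise TrialValidationError(
                    "free calibration lifts exist only at very_slow/normal/fast "
                    f"velocity, got {self.velocity!r}"
                )

    @property
    def label(self) -> str:
        return f"{self.technique}-{self.mass_kg:g}-{self.velocity}"


@dataclass
class Trial:
    """One uniformly sampled 50 Hz trial."""

    trial_id: str
    subject_id: str
    condition: TrialCondition
    data: pd.DataFrame  # columns TRIAL_COLUMNS, one row per sample
    meta: dict = field(default_factory=dict)

    # -- convenience accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def time_s(self) -> np.ndarray:
        return self.data["time_s"].to_numpy()

    @property
    def emg(self) -> np.ndarray:
        """(n_samples, 12) MVC-normalized envelopes, EMG_CHANNELS order."""
        return self.data[[f"emg_{ch}" for ch in EMG_CHANNELS]].to_numpy()

    @property
    def exo_torque_nm(self) -> np.ndarray:
        return self.data["exo_torque_nm"].to_numpy()

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    # -- validation ------------------------------------------------------------
    def validate(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise TrialFormatError(f"missing channel column(s): {missing}")
        if self.n_samples < 2:
            raise TrialValidationError("trial must contain at least two samples")
        t = self.time_s
        dt = np.diff(t)
        if not np.allclose(dt, 1.0 / FS_HZ, atol=1e-9):
            raise TrialValidationError("time base is not uniform 50 Hz")
        if np.any(self.emg < 0):
            raise TrialValidationError("normalized EMG must be non-negative")
        if self.condition.exo_strategy == "none" and np.any(
            self.exo_torque_nm != 0.0
        ):
            raise TrialValidationError(
                "exoskeleton torque must be identically zero without an exoskeleton"
            )


@dataclass
class MomentSeries:
    """A moment about L5/S1 (N·m, extension positive) on a trial's time base."""

    time_s: np.ndarray
    values_nm: np.ndarray
    component: str  # net | human | active | passive

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.values_nm = np.asarray(self.values_nm, dtype=float)
        if self.component not in ("net", "human", "active", "passive"):
            raise ValueError(f"unknown moment component {self.component!r}")
        if self.time_s.shape != self.values_nm.shape:
            raise ValueError("time and values must have identical length")


# -- file I/O ------------------------------------------------------------------

_META_KEYS = ("trial_id", "subject_id", "mass_kg", "technique", "velocity",
              "task_group", "exo_strategy")


def write_trial(trial: Trial, path) -> None:
    """Write a trial to the documented text dialect.

    Numeric values are written with :func:`repr` round-trip precision, so
    ``read_trial(write_trial(t))`` reproduces the trial to better than 1e-10.
    """
    trial.validate()
    path = Path(path)
    lines = [
        f"# trial_id: {trial.trial_id}",
        f"# subject_id: {trial.subject_id}",
        f"# mass_kg: {trial.condition.mass_kg!r}",
        f"# technique: {trial.condition.technique}",
        f"# velocity: {trial.condition.velocity}",
        f"# task_group: {trial.condition.task_group}",
        f"# exo_strategy: {trial.condition.exo_strategy}",
        f"# fs_hz: {FS_HZ!r}",
    ]
    for key, value in sorted(trial.meta.items()):
        lines.append(f"# meta_{key}: {value}")
    lines.append(",".join(TRIAL_COLUMNS))
    cols = [trial.data[c].to_numpy() for c in TRIAL_COLUMNS]
    for i in range(trial.n_samples):
        lines.append(",".join(repr(float(col[i])) for col in cols))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trial(path) -> Trial:
    """Read and validate a trial file written by :func:`write_trial`."""
    path = Path(path)
    header: dict[str, str] = {}
    rows_start = 0
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            header[key.strip()] = value.strip()
        else:
            rows_start = i
            break
    else:
        raise TrialFormatError("file contains no sample rows")
    for key in _META_KEYS:
        if key not in header:
            raise TrialFormatError(f"missing header key {key!r}")
    columns = lines[rows_start].split(",")
    missing = [c for c in TRIAL_COLUMNS if c not in columns]
    if missing:
        raise TrialFormatError(f"missing channel column(s): {missing}")
    try:
        values = np.array(
            [[float(x) for x in line.split(",")] for line in lines[rows_start + 1:]
             if line],
            dtype=float,
        )
    except ValueError as exc:
        raise TrialFormatError(f"malformed sample row: {exc}") from exc
    data = pd.DataFrame(values, columns=columns)[list(TRIAL_COLUMNS)]
    condition = TrialCondition(
        mass_kg=float(header["mass_kg"]),
        technique=header["technique"],
        velocity=header["velocity"],
        task_group=header["task_group"],
        exo_strategy=header["exo_strategy"],
    )
    meta = {k[5:]: v for k, v in header.items() if k.startswith("meta_")}
    trial = Trial(
        trial_id=header["trial_id"],
        subject_id=header["subject_id"],
        condition=condition,
        data=data,
        meta=meta,
    )
    trial.validate()
    return trial
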