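"""Synthetic lifting-trial generator with known ground truth.

Generates the full study battery from a planar five-segment model driven by
minimum-jerk joint trajectories:

* battery A - 14 calibration lift conditions (2 masses x {stoop, squat} x
  {slow, normal} plus 2 masses x free x {very slow, normal, fast}), two
  repetitions each;
* battery B - exoskeleton-assisted free lifts (2 masses x {normal, fast} x
  4 control strategies);
* battery C - box stacking, lift and carry phases;
* battery D - shelf lifts (2 masses);
* battery E - isometric push and pull.

All kinematic derivatives are analytic, so the generated ground reaction
force and centre of pressure satisfy the whole-body Newton-Euler balance
exactly, and the top-down moment about L5/S1 is an independent oracle for
the bottom-up inverse-dynamics implementation.  EMG envelopes are produced
by inverting the ground-truth muscle model (equal drive to all agonist
elements, antagonists at a co-contraction baseline that is compensated
within the solve), then corrupted with multiplicative log-normal noise.
Box pick-up is modelled as a smooth hand-force ramp during a short dwell at
the deepest posture, as happens physically while grip force builds up.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .anthropometry import G_GRAVITY, SubjectModel, build_subject
from .emgmod import (MuscleGeometry, MuscleModelParams, default_geometry,
                     force_length, force_velocity, muscle_lengths,
                     passive_moment)
from .inverse_dynamics import numeric_derivatives
from .signals import FilterSpec, butterworth
from .trial_model import (EMG_CHANNELS, FS_HZ, MomentSeries, Trial,
                          TRIAL_COLUMNS, TrialCondition)

PAD_S = 0.6     # quiet posture held at both trial ends (filter warm-up)
DWELL_S = 0.5   # dwell at the deepest posture during which the box is gripped


class TaskParameterError(ValueError):
    pass


@dataclass(frozen=True)
class GroundTruth:
    """Ground-truth physiology and noise model of one synthetic subject."""

    params_true: MuscleModelParams = field(default_factory=MuscleModelParams)
    cocontraction_level: float = 0.03  # antagonist baseline, fraction of MVC
    emg_noise_sd: float = 0.05         # multiplicative log-normal SD
    kin_noise_sd: float = 0.005        # additive angle noise SD (rad)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.emg_noise_sd < 0 or self.kin_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.cocontraction_level <= 0.2:
            raise ValueError("co-contraction must be within [0, 0.2] of MVC")


@dataclass(frozen=True)
class LiftProfile:
    """Movement timing and per-technique posture targets.

    ``durations_s`` is the total down+up movement time per velocity class;
    peak angles are radians of shank lean, knee flexion, hip flexion and
    lumbar flexion at the deepest posture.
    """

    durations_s: dict = field(default_factory=lambda: {
        "very_slow": 6.0, "slow": 4.0, "normal": 2.5, "fast": 1.5,
    })
    peaks: dict = field(default_factory=lambda: {
        #            shank  knee   hip    lumbar
        "stoop": (0.09, 0.14, 0.87, 0.70),
        "squat": (0.44, 1.92, 1.75, 0.26),
        "free":  (0.26, 0.96, 1.13, 0.52),
    })
    box_mass_kg: float = 7.5

    def __post_init__(self) -> None:
        d = self.durations_s
        if not d["very_slow"] > d["slow"] > d["normal"] > d["fast"] > 0:
            raise ValueError("durations must strictly decrease with velocity")


#: Default exoskeleton controller gains.
EXO_GAINS = {"k1": 30.0, "k2": 1.0, "k3": 5.0}

PUSH_PULL_FORCE_N = 98.1  # horizontal hand force from a 10 kg tensioning mass
PUSH_PULL_ARM_ANGLE = 1.2  # rad from hanging, hands forward below shoulder
SHELF_ARM_ANGLE = (0.3, 1.4)  # hanging-forward -> raised to the 1.5 m shelf
CARRY_SWAY_AMPLITUDE = 0.10   # rad of trunk sway while carrying
CARRY_SWAY_HZ = 0.8


# -- elementary trajectories ---------------------------------------------------

def _minjerk_pva(theta0: float, theta1: float, duration_s: float, t: np.ndarray):
    """Quintic minimum-jerk position/velocity/acceleration on tau=t/T."""
    tau = np.clip(t / duration_s, 0.0, 1.0)
    d = theta1 - theta0
    pos = theta0 + d * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    vel = d * (30 * tau**2 - 60 * tau**3 + 30 * tau**4) / duration_s
    acc = d * (60 * tau - 180 * tau**2 + 120 * tau**3) / duration_s**2
    return pos, vel, acc


def minimum_jerk(theta0: float, theta1: float, duration_s: float,
                 fs: float = FS_HZ) -> np.ndarray:
    """Minimum-jerk angle trajectory from theta0 to theta1.

    Velocity and acceleration are zero at both ends; peak angular velocity is
    ``1.875 * (theta1 - theta0) / duration_s`` at the midpoint.
    """
    if duration_s <= 0:
        raise TaskParameterError("duration must be positive")
    t = np.arange(int(round(duration_s * fs)) + 1) / fs
    pos, _, _ = _minjerk_pva(theta0, theta1, duration_s, t)
    return pos


def _piecewise_minjerk(t: np.ndarray, knots):
    """Hold-and-move profile through (time, value) knots with minimum-jerk
    transitions between consecutive knots; returns (pos, vel, acc)."""
    pos = np.full_like(t, knots[0][1], dtype=float)
    vel = np.zeros_like(t)
    acc = np.zeros_like(t)
    for (t0, q0), (t1, q1) in zip(knots[:-1], knots[1:]):
        seg = (t >= t0) & (t <= t1)
        if t1 > t0:
            p, v, a = _minjerk_pva(q0, q1, t1 - t0, t[seg] - t0)
            pos[seg], vel[seg], acc[seg] = p, v, a
        after = t > t1
        pos[after] = q1
        vel[after] = 0.0
        acc[after] = 0.0
    return pos, vel, acc


def _enveloped_sine(t, t_on, t_off, ramp_s, amplitude, freq_hz):
    """amplitude * sin(2 pi f (t-t_on)) * env(t) with minimum-jerk on/off
    envelope; analytic first and second derivatives by the product rule."""
    env, denv, ddenv = _piecewise_minjerk(
        t, [(0.0, 0.0), (t_on, 0.0), (t_on + ramp_s, 1.0),
            (t_off - ramp_s, 1.0), (t_off, 0.0)])
    w = 2 * np.pi * freq_hz
    phase = w * (t - t_on)
    s, c = np.sin(phase), np.cos(phase)
    pos = amplitude * s * env
    vel = amplitude * (w * c * env + s * denv)
    acc = amplitude * (-w * w * s * env + 2 * w * c * denv + s * ddenv)
    return pos, vel, acc


# -- planar chain kinematics ---------------------------------------------------

@dataclass
class _Angle:
    pos: np.ndarray
    vel: np.ndarray
    acc: np.ndarray


@dataclass
class PlanarKinematics:
    """Full planar state of one trial with analytic derivatives."""

    time_s: np.ndarray
    angles: dict            # driven angles: shank, knee, hip, lumbar, arm
    phis: dict              # segment orientations (_Angle): shank..trunk, arm
    joints: dict            # joint name -> (n, 2) position
    joint_acc: dict         # joint name -> (n, 2) acceleration
    load_mass: np.ndarray   # effective supported box mass (kg) per sample
    hand_force_x: np.ndarray
    subject: SubjectModel

    @property
    def n_samples(self) -> int:
        return self.time_s.shape[0]

    def segment_states(self):
        """COM position/acceleration, orientation and angular acceleration
        per lumped segment, plus mass and inertia; the single source for all
        Newton-Euler bookkeeping in the generator."""
        sub = self.subject
        j, ja = self.joints, self.joint_acc
        zero = np.zeros((self.n_samples, 2))
        # (proximal, distal) joints per segment; feet are static on the ground
        spans = {
            "shanks": ("knee", "ankle"),
            "thighs": ("hip", "knee"),
            "pelvis": ("hip", "l5s1"),
            "trunk_head": ("l5s1", "shoulder"),
            "arms": ("shoulder", "hand"),
        }
        states = {}
        foot = sub.segments["feet"]
        foot_com = np.array([0.0, sub.ankle_height_m * 0.5])
        states["feet"] = {
            "com": np.broadcast_to(foot_com, (self.n_samples, 2)),
            "acc": zero, "phi_dd": np.zeros(self.n_samples),
            "mass": foot.mass_kg, "inertia": foot.inertia_kgm2,
        }
        phi_of = {"shanks": "shank", "thighs": "thigh", "pelvis": "pelvis",
                  "trunk_head": "trunk", "arms": "arm"}
        for name, (prox, dist) in spans.items():
            seg = sub.segments[name]
            f = seg.com_fraction
            states[name] = {
                "com": j[prox] + f * (j[dist] - j[prox]),
                "acc": ja[prox] + f * (ja[dist] - ja[prox]),
                "phi_dd": self.phis[phi_of[name]].acc,
                "mass": seg.mass_kg, "inertia": seg.inertia_kgm2,
            }
        return states


def _chain_up(base_p, base_a, length, phi: _Angle):
    """Endpoint of an up-pointing segment: base + L*(sin phi, cos phi)."""
    s, c = np.sin(phi.pos), np.cos(phi.pos)
    pos = base_p + length * np.stack([s, c], axis=1)
    acc = base_a + length * (
        np.stack([c, -s], axis=1) * phi.acc[:, None]
        - np.stack([s, c], axis=1) * phi.vel[:, None] ** 2)
    return pos, acc


def _chain_down(base_p, base_a, length, psi: _Angle):
    """Endpoint of a down-pointing segment: base + L*(sin psi, -cos psi)."""
    s, c = np.sin(psi.pos), np.cos(psi.pos)
    pos = base_p + length * np.stack([s, -c], axis=1)
    acc = base_a + length * (
        np.stack([c, s], axis=1) * psi.acc[:, None]
        + np.stack([-s, c], axis=1) * psi.vel[:, None] ** 2)
    return pos, acc


def _task_angles(condition: TrialCondition, profile: LiftProfile,
                 fs: float) -> tuple[np.ndarray, dict, np.ndarray, np.ndarray]:
    """Driven angle profiles, load-mass and hand-force series for one task."""
    tg = condition.task_group
    if tg in ("calibration_lift", "exo_lift", "stack_lift"):
        if condition.technique not in profile.peaks:
            raise TaskParameterError(
                f"unknown technique {condition.technique!r} for a lifting task"
            )
        half = profile.durations_s[condition.velocity]  # per movement phase
        duration = 2.0 * half
        t_end = 2 * PAD_S + duration + DWELL_S
        t = np.arange(int(round(t_end * fs)) + 1) / fs
        peaks = profile.peaks[condition.technique]
        angles = {}
        for name, peak in zip(("shank", "knee", "hip", "lumbar"), peaks):
            pos, vel, acc = _piecewise_minjerk(
                t, [(0.0, 0.0), (PAD_S, 0.0), (PAD_S + half, peak),
                    (PAD_S + half + DWELL_S, peak),
                    (PAD_S + duration + DWELL_S, 0.0)])
            angles[name] = _Angle(pos, vel, acc)
        angles["arm"] = _Angle(np.zeros_like(t), np.zeros_like(t),
                               np.zeros_like(t))
        # box gripped during the dwell: smooth support-force ramp
        ramp0 = PAD_S + half + 0.1 * DWELL_S
        ramp1 = PAD_S + half + 0.9 * DWELL_S
        load, _, _ = _piecewise_minjerk(
            t, [(0.0, 0.0), (ramp0, 0.0), (ramp1, condition.mass_kg)])
        return t, angles, load, np.zeros_like(t)

    if tg == "stack_carry":
        t_end = 2 * PAD_S + 4.0
        t = np.arange(int(round(t_end * fs)) + 1) / fs
        sway = _enveloped_sine(t, PAD_S, t_end - PAD_S, 0.6,
                               CARRY_SWAY_AMPLITUDE, CARRY_SWAY_HZ)
        zeros = _Angle(np.zeros_like(t), np.zeros_like(t), np.zeros_like(t))
        angles = {
            "shank": zeros,
            "knee": zeros,
            "hip": _Angle(*(0.5 * a for a in sway)),
            "lumbar": _Angle(*(0.5 * a for a in sway)),
            "arm": _Angle(np.zeros_like(t), np.zeros_like(t), np.zeros_like(t)),
        }
        load = np.full_like(t, condition.mass_kg)
        return t, angles, load, np.zeros_like(t)

    if tg == "shelf_lift":
        duration, half = 3.0, 1.5
        t_end = 2 * PAD_S + duration + DWELL_S
        t = np.arange(int(round(t_end * fs)) + 1) / fs
        psi0, psi1 = SHELF_ARM_ANGLE
        arm = _Angle(*_piecewise_minjerk(
            t, [(0.0, psi0), (PAD_S, psi0), (PAD_S + half, psi1),
                (PAD_S + half + DWELL_S, psi1),
                (PAD_S + duration + DWELL_S, psi0)]))
        angles = {"arm": arm}
        for name, peak in (("shank", 0.0), ("knee", 0.0), ("hip", 0.06),
                           ("lumbar", 0.06)):
            angles[name] = _Angle(*_piecewise_minjerk(
                t, [(0.0, 0.0), (PAD_S, 0.0), (PAD_S + half, peak),
                    (PAD_S + half + DWELL_S, peak),
                    (PAD_S + duration + DWELL_S, 0.0)]))
        load = np.full_like(t, condition.mass_kg)
        return t, angles, load, np.zeros_like(t)

    if tg == "push_pull":
        t_end = 2 * PAD_S + 3.0
        t = np.arange(int(round(t_end * fs)) + 1) / fs
        zeros = _Angle(np.zeros_like(t), np.zeros_like(t), np.zeros_like(t))
        angles = {name: zeros for name in ("shank", "knee", "hip", "lumbar")}
        angles["arm"] = _Angle(np.full_like(t, PUSH_PULL_ARM_ANGLE),
                               np.zeros_like(t), np.zeros_like(t))
        return t, angles, np.zeros_like(t), np.zeros_like(t)  # force set later

    raise TaskParameterError(f"unknown task group {tg!r}")


def generate_kinematics(condition: TrialCondition, subject: SubjectModel,
                        profile: LiftProfile | None = None,
                        fs: float = FS_HZ) -> PlanarKinematics:
    """Planar joint/segment time series for one trial condition."""
    profile = profile if profile is not None else LiftProfile()
    t, angles, load, hand_force_x = _task_angles(condition, profile, fs)
    # segment orientations from the driven joint angles
    shank = angles["shank"]
    thigh = _Angle(shank.pos - angles["knee"].pos,
                   shank.vel - angles["knee"].vel,
                   shank.acc - angles["knee"].acc)
    pelvis = _Angle(thigh.pos + angles["hip"].pos,
                    thigh.vel + angles["hip"].vel,
                    thigh.acc + angles["hip"].acc)
    trunk = _Angle(pelvis.pos + angles["lumbar"].pos,
                   pelvis.vel + angles["lumbar"].vel,
                   pelvis.acc + angles["lumbar"].acc)
    phis = {"shank": shank, "thigh": thigh, "pelvis": pelvis, "trunk": trunk,
            "arm": angles["arm"]}
    sub = subject
    n = t.shape[0]
    ankle = np.broadcast_to(np.array([0.0, sub.ankle_height_m]), (n, 2))
    zero = np.zeros((n, 2))
    joints = {"ankle": ankle}
    joint_acc = {"ankle": zero}
    joints["knee"], joint_acc["knee"] = _chain_up(
        ankle, zero, sub.segments["shanks"].length_m, shank)
    joints["hip"], joint_acc["hip"] = _chain_up(
        joints["knee"], joint_acc["knee"], sub.segments["thighs"].length_m, thigh)
    joints["l5s1"], joint_acc["l5s1"] = _chain_up(
        joints["hip"], joint_acc["hip"], sub.segments["pelvis"].length_m, pelvis)
    joints["shoulder"], joint_acc["shoulder"] = _chain_up(
        joints["l5s1"], joint_acc["l5s1"],
        sub.segments["trunk_head"].length_m, trunk)
    joints["hand"], joint_acc["hand"] = _chain_down(
        joints["shoulder"], joint_acc["shoulder"],
        sub.segments["arms"].length_m, angles["arm"])
    return PlanarKinematics(
        time_s=t, angles=angles, phis=phis, joints=joints, joint_acc=joint_acc,
        load_mass=load, hand_force_x=hand_force_x, subject=subject)


# -- forces and reference moments ----------------------------------------------

def whole_body_grf(kin: PlanarKinematics, subject: SubjectModel | None = None):
    """Ground reaction force and centre of pressure from whole-body
    Newton-Euler balance; returns (fx, fy, cop_x)."""
    sub = subject if subject is not None else kin.subject
    states = kin.segment_states()
    g = G_GRAVITY
    fx = np.zeros(kin.n_samples)
    fy = np.zeros(kin.n_samples)
    m_o = np.zeros(kin.n_samples)  # angular momentum balance about the origin
    for st in states.values():
        m, inertia = st["mass"], st["inertia"]
        x, y = st["com"][:, 0], st["com"][:, 1]
        ax, ay = st["acc"][:, 0], st["acc"][:, 1]
        fx += m * ax
        fy += m * (ay + g)
        m_o += m * (x * ay - y * ax) + inertia * st["phi_dd"] + m * g * x
    hx, hy = kin.joints["hand"][:, 0], kin.joints["hand"][:, 1]
    hax, hay = kin.joint_acc["hand"][:, 0], kin.joint_acc["hand"][:, 1]
    ml = kin.load_mass
    fx += ml * hax - kin.hand_force_x
    fy += ml * (hay + g)
    m_o += ml * (hx * hay - hy * hax) + ml * g * hx + hy * kin.hand_force_x
    cop_x = m_o / fy
    return fx, fy, cop_x


def reference_human_moment(kin: PlanarKinematics,
                           subject: SubjectModel | None = None) -> MomentSeries:
    """Top-down net L5/S1 moment (extension positive): the generator's
    independent oracle for the bottom-up inverse-dynamics implementation."""
    sub = subject if subject is not None else kin.subject
    states = kin.segment_states()
    g = G_GRAVITY
    p = kin.joints["l5s1"]
    m_net = np.zeros(kin.n_samples)
    for name in ("trunk_head", "arms"):
        st = states[name]
        dx = st["com"][:, 0] - p[:, 0]
        dy = st["com"][:, 1] - p[:, 1]
        ax, ay = st["acc"][:, 0], st["acc"][:, 1]
        m_net += st["mass"] * (dx * (ay + g) - dy * ax) \
            + st["inertia"] * st["phi_dd"]
    hx = kin.joints["hand"][:, 0] - p[:, 0]
    hy = kin.joints["hand"][:, 1] - p[:, 1]
    hax, hay = kin.joint_acc["hand"][:, 0], kin.joint_acc["hand"][:, 1]
    m_net += kin.load_mass * (hx * (hay + g) - hy * hax)
    m_net += hy * kin.hand_force_x
    return MomentSeries(kin.time_s, m_net, "net")


def exo_torque(kin: PlanarKinematics, strategy: str,
               gains: dict | None = None) -> np.ndarray:
    """Exoskeleton support torque (N·m, extension positive).

    inclination: tau = k1*alpha; dynamic: k1*alpha + k2*alpha_dd;
    velocity: k1*alpha + k3*alpha_d; transparent: 0.
    """
    gains = {**EXO_GAINS, **(gains or {})}
    alpha = kin.phis["trunk"]
    if strategy == "inclination":
        return gains["k1"] * alpha.pos
    if strategy == "dynamic":
        return gains["k1"] * alpha.pos + gains["k2"] * alpha.acc
    if strategy == "velocity":
        return gains["k1"] * alpha.pos + gains["k3"] * alpha.vel
    if strategy == "transparent":
        return np.zeros(kin.n_samples)
    raise TaskParameterError(f"unknown exoskeleton strategy {strategy!r}")


# -- EMG synthesis -------------------------------------------------------------

ACTIVATION_CAP = 1.5


def emg_from_moment(m_human: MomentSeries, theta: np.ndarray,
                    theta_dot: np.ndarray, truth: GroundTruth,
                    geometry: MuscleGeometry | None = None,
                    rng: np.random.Generator | None = None):
    """12-channel normalized EMG reproducing ``m_human`` under the
    ground-truth parameters.

    Returns ``(emg, feasible)``; ``feasible`` is False when the required
    activation exceeded the cap before noise.  With zero noise the forward
    model evaluated at the true parameters reproduces ``m_human`` exactly.
    """
    geometry = geometry if geometry is not None else default_geometry()
    p = truth.params_true
    m_pass = passive_moment(theta, p, geometry)
    m_req = m_human.values_nm - m_pass
    lam, lam_dot = muscle_lengths(theta, theta_dot, p, geometry)
    fl = force_length(lam, p.fl_width)
    fv = force_velocity(lam_dot, p.ecc_scale, p.con_scale)
    weight = p.gain * geometry.arms * geometry.pcsas * fl * fv  # (n, 12)
    ext = geometry.extensor_mask
    d_ext = weight[:, ext].sum(axis=1)
    d_flex = weight[:, ~ext].sum(axis=1)
    c0 = truth.cocontraction_level
    a_ext = np.where(m_req >= 0, (m_req + c0 * d_flex) / d_ext, c0)
    a_flex = np.where(m_req >= 0, c0, (-m_req + c0 * d_ext) / d_flex)
    feasible = bool(np.all(a_ext <= ACTIVATION_CAP)
                    and np.all(a_flex <= ACTIVATION_CAP))
    act = np.zeros((theta.shape[0], 12))
    cols_ext = geometry.channels[ext]
    cols_flex = geometry.channels[~ext]
    act[:, cols_ext] = np.clip(a_ext, 0.0, ACTIVATION_CAP)[:, None]
    act[:, cols_flex] = np.clip(a_flex, 0.0, ACTIVATION_CAP)[:, None]
    if truth.emg_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(truth.seed)
        sd = truth.emg_noise_sd
        noise = np.exp(rng.normal(-0.5 * sd * sd, sd, size=act.shape))
        act = np.clip(act * noise, 0.0, ACTIVATION_CAP)
    return act, feasible


# -- trial assembly ------------------------------------------------------------

def _noisy_angle_channels(kin: PlanarKinematics, truth: GroundTruth,
                          rng: np.random.Generator, fs: float):
    """Measured angle channels: analytic when noise-free, otherwise white
    angle noise followed by 5 Hz low-pass differentiation for the rates."""
    trunk = kin.phis["trunk"]
    channels = {
        "trunk_inclination": trunk.pos,
        "trunk_inclination_vel": trunk.vel,
        "trunk_inclination_acc": trunk.acc,
        "trunk_flexion": kin.angles["hip"].pos + kin.angles["lumbar"].pos,
        "hip_angle": kin.angles["hip"].pos,
        "lumbar_flexion": kin.angles["lumbar"].pos,
        "lumbar_flexion_vel": kin.angles["lumbar"].vel,
    }
    if truth.kin_noise_sd <= 0:
        return channels
    sd = truth.kin_noise_sd
    spec = FilterSpec("lowpass", 2, 5.0)
    n = kin.n_samples

    def measure(pos):
        noisy = pos + rng.normal(0.0, sd, size=n)
        smooth = butterworth(noisy, fs, spec)
        vel, acc = numeric_derivatives(smooth, fs)
        return smooth, vel, acc

    incl, incl_v, incl_a = measure(trunk.pos)
    lumbar, lumbar_v, _ = measure(kin.angles["lumbar"].pos)
    channels.update({
        "trunk_inclination": incl,
        "trunk_inclination_vel": incl_v,
        "trunk_inclination_acc": incl_a,
        "trunk_flexion": butterworth(
            channels["trunk_flexion"] + rng.normal(0.0, sd, size=n), fs, spec),
        "hip_angle": butterworth(
            channels["hip_angle"] + rng.normal(0.0, sd, size=n), fs, spec),
        "lumbar_flexion": lumbar,
        "lumbar_flexion_vel": lumbar_v,
    })
    return channels


def generate_trial(trial_id: str, condition: TrialCondition,
                   subject: SubjectModel, truth: GroundTruth,
                   profile: LiftProfile | None = None,
                   geometry: MuscleGeometry | None = None,
                   rng: np.random.Generator | None = None,
                   hand_force_sign: float = 1.0,
                   return_reference: bool = False):
    """Generate one complete trial (kinematics, GRF, exo torque, EMG).

    With ``return_reference`` the analytic top-down net moment is returned
    alongside the trial, as ``(trial, m_net)``.
    """
    geometry = geometry if geometry is not None else default_geometry()
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    kin = generate_kinematics(condition, subject, profile)
    if condition.task_group == "push_pull":
        kin.hand_force_x = np.full(kin.n_samples,
                                   hand_force_sign * PUSH_PULL_FORCE_N)
    fx, fy, cop_x = whole_body_grf(kin)
    m_net = reference_human_moment(kin)
    tau = (exo_torque(kin, condition.exo_strategy)
           if condition.exo_strategy != "none" else np.zeros(kin.n_samples))
    m_human = MomentSeries(kin.time_s, m_net.values_nm - tau, "human")
    channels = _noisy_angle_channels(kin, truth, rng, FS_HZ)
    emg, feasible = emg_from_moment(
        m_human, channels["lumbar_flexion"], channels["lumbar_flexion_vel"],
        truth, geometry, rng)
    data = {"time_s": kin.time_s}
    data.update(channels)
    for name, phi in kin.phis.items():
        data[f"phi_{name}"] = phi.pos
    for joint in ("knee", "hip", "l5s1", "shoulder", "hand"):
        data[f"{joint}_x"] = kin.joints[joint][:, 0]
        data[f"{joint}_y"] = kin.joints[joint][:, 1]
    data.update({
        "grf_fx": fx, "grf_fy": fy, "cop_x": cop_x,
        "load_mass_kg": kin.load_mass, "hand_force_x": kin.hand_force_x,
        "exo_torque_nm": tau,
    })
    for i, ch in enumerate(EMG_CHANNELS):
        data[f"emg_{ch}"] = emg[:, i]
    frame = pd.DataFrame(data)[list(TRIAL_COLUMNS)]
    meta = {}
    if not feasible:
        meta["infeasible_activation"] = "true"
    trial = Trial(trial_id=trial_id, subject_id=subject.subject_id,
                  condition=condition, data=frame, meta=meta)
    trial.validate()
    if return_reference:
        return trial, m_net
    return trial


# -- study battery -------------------------------------------------------------

def calibration_conditions(masses=(7.5, 15.0)) -> list[TrialCondition]:
    """The 14 (2 x 2 x 2 + 2 x 1 x 3) calibration lift conditions."""
    conditions = []
    for mass in masses:
        for technique in ("stoop", "squat"):
            for velocity in ("slow", "normal"):
                conditions.append(TrialCondition(
                    mass, technique, velocity, "calibration_lift"))
    for mass in masses:
        for velocity in ("very_slow", "normal", "fast"):
            conditions.append(TrialCondition(
                mass, "free", velocity, "calibration_lift"))
    return conditions


def evaluation_conditions(masses=(7.5, 15.0)) -> list[tuple[TrialCondition, float]]:
    """The test battery (B-E); returns (condition, hand-force sign) pairs."""
    out = []
    for mass in masses:
        for velocity in ("normal", "fast"):
            for strategy in ("inclination", "dynamic", "velocity",
                             "transparent"):
                out.append((TrialCondition(mass, "free", velocity, "exo_lift",
                                           strategy), 0.0))
    out.append((TrialCondition(7.5, "free", "normal", "stack_lift",
                               "inclination"), 0.0))
    out.append((TrialCondition(7.5, "n/a", "n/a", "stack_carry",
                               "inclination"), 0.0))
    for mass in masses:
        out.append((TrialCondition(mass, "n/a", "n/a", "shelf_lift"), 0.0))
    out.append((TrialCondition(0.0, "n/a", "n/a", "push_pull"), -1.0))  # push
    out.append((TrialCondition(0.0, "n/a", "n/a", "push_pull"), 1.0))   # pull
    return out


def _condition_slug(condition: TrialCondition, extra: str = "") -> str:
    parts = [condition.task_group, condition.technique,
             f"{condition.mass_kg:g}kg", condition.velocity]
    if condition.exo_strategy != "none":
        parts.append(condition.exo_strategy)
    if extra:
        parts.append(extra)
    return "_".join(p.replace("/", "") for p in parts)


def _trial_rng(seed: int, subject_index: int, trial_id: str
               ) -> np.random.Generator:
    crc = zlib.crc32(trial_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, subject_index, crc]))


def sample_truth(rng: np.random.Generator, seed: int,
                 emg_noise_sd: float = 0.05, kin_noise_sd: float = 0.005,
                 cocontraction_level: float = 0.03) -> GroundTruth:
    """Draw subject physiology well inside the calibration bounds."""
    params = MuscleModelParams(
        gain=rng.uniform(30.0, 55.0),
        passive_offset=rng.uniform(0.98, 1.06),
        passive_scale=rng.uniform(8.0, 25.0),
        ecc_scale=rng.uniform(0.2, 0.5),
        con_scale=rng.uniform(0.3, 0.7),
        optimum_angle=rng.uniform(0.40, 0.70),
        fl_width=rng.uniform(0.40, 0.70),
    )
    return GroundTruth(params_true=params, emg_noise_sd=emg_noise_sd,
                       kin_noise_sd=kin_noise_sd,
                       cocontraction_level=cocontraction_level, seed=seed)


@dataclass
class SubjectData:
    """All generated trials of one synthetic subject."""

    subject: SubjectModel
    truth: GroundTruth
    calibration_trials: list   # 14 conditions x 2 repetitions, battery A
    test_trials: list          # batteries B-E
    top_down_reference: dict = field(default_factory=dict)
    # trial_id -> analytic net-moment MomentSeries (the dynamics oracle)


def generate_subject(subject_index: int, seed: int,
                     emg_noise_sd: float = 0.05, kin_noise_sd: float = 0.005,
                     profile: LiftProfile | None = None,
                     geometry: MuscleGeometry | None = None) -> SubjectData:
    """Generate the full battery for one subject, deterministically seeded
    from ``(seed, subject_index, trial_id)``."""
    rng0 = np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, subject_index]))
    subject = build_subject(
        subject_id=f"S{subject_index:02d}",
        body_mass_kg=float(rng0.normal(73.8, 7.6)),
        stature_m=float(rng0.normal(1.82, 0.09)),
    )
    truth = sample_truth(rng0, seed, emg_noise_sd=emg_noise_sd,
                         kin_noise_sd=kin_noise_sd)
    calibration, test, refs = [], [], {}
    for condition in calibration_conditions():
        for rep in (1, 2):
            trial_id = f"{subject.subject_id}_{_condition_slug(condition)}_r{rep}"
            rng = _trial_rng(seed, subject_index, trial_id)
            trial, m_net = generate_trial(
                trial_id, condition, subject, truth, profile, geometry, rng,
                return_reference=True)
            calibration.append(trial)
            refs[trial_id] = m_net
    for condition, sign in evaluation_conditions():
        extra = ("push" if sign < 0 else "pull") \
            if condition.task_group == "push_pull" else ""
        trial_id = f"{subject.subject_id}_{_condition_slug(condition, extra)}"
        rng = _trial_rng(seed, subject_index, trial_id)
        trial, m_net = generate_trial(
            trial_id, condition, subject, truth, profile, geometry, rng,
            hand_force_sign=sign, return_reference=True)
        test.append(trial)
        refs[trial_id] = m_net
    return SubjectData(subject=subject, truth=truth,
                       calibration_trials=calibration, test_trials=test,
                       top_down_reference=refs)


def generate_study(n_subjects: int, seed: int = 0,
                   emg_noise_sd: float = 0.05, kin_noise_sd: float = 0.005,
                   profile: LiftProfile | None = None,
                   geometry: MuscleGeometry | None = None) -> list[SubjectData]:
    """Generate the full synthetic cohort."""
    return [generate_subject(i + 1, seed, emg_noise_sd, kin_noise_sd,
                             profile, geometry)
            for i in range(n_subjects)]


def manifest(subjects: list[SubjectData]) -> pd.DataFrame:
    """Long table of every generated trial and its condition metadata."""
    rows = []
    for sd in subjects:
        for role, trials in (("calibration", sd.calibration_trials),
                             ("test", sd.test_trials)):
            for tr in trials:
                c = tr.condition
                rows.append({
                    "subject": sd.subject.subject_id, "trial_id": tr.trial_id,
                    "role": role, "task_group": c.task_group,
                    "mass_kg": c.mass_kg, "technique": c.technique,
                    "velocity": c.velocity, "exo_strategy": c.exo_strategy,
                    "n_samples": tr.n_samples,
                })
    return pd.DataFrame(rows)
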