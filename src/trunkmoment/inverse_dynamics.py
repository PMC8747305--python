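"""Bottom-up inverse dynamics: net and human L5/S1 moments.

The net moment transmitted to the upper body at L5/S1 is computed from the
ground reaction force, centre of pressure and lower-body kinematics by a
sagittal Newton-Euler balance of the foot-shank-thigh-pelvis subsystem
about the (moving) L5/S1 joint:

    M_net = (x_cop - x_p) Fy + y_p Fx
            - sum_low [ m_i ((x_i - x_p)(a_yi + g) - (y_i - y_p) a_xi)
                        + I_i phidd_i ]

with p the L5/S1 position, extension positive.  Segment accelerations are
obtained by double central differentiation of 5 Hz low-pass filtered
positions (forces and centre of pressure are filtered identically) to avoid
noise amplification.  In exoskeleton trials the human share is
``M_human = M_net - M_exo``.
"""

from __future__ import annotations

import numpy as np

from .anthropometry import G_GRAVITY, SubjectModel
from .signals import FilterSpec, butterworth
from .trial_model import MomentSeries, Trial


class InputError(ValueError):
    pass


def numeric_derivatives(series, fs: float):
    """First and second time derivatives by central differences.

    Interior samples use central differences; endpoints use one-sided
    differences.  Returns ``(velocity, acceleration)``.
    """
    x = np.asarray(series, dtype=float)
    if x.shape[0] < 3:
        raise InputError("need at least 3 samples to differentiate")
    vel = np.gradient(x, 1.0 / fs, axis=0)
    acc = np.gradient(vel, 1.0 / fs, axis=0)
    return vel, acc


_LOWPASS_5HZ = FilterSpec("lowpass", 2, 5.0)

#: (segment, proximal joint, distal joint) spans of the lower body; the COM
#: lies at ``prox + com_fraction * (dist - prox)``.
_LOWER_SPANS = (
    ("shanks", "knee", "ankle"),
    ("thighs", "hip", "knee"),
    ("pelvis", "hip", "l5s1"),
)

_LOWER_PHI = {"shanks": "phi_shank", "thighs": "phi_thigh",
              "pelvis": "phi_pelvis"}


def bottom_up_moment(trial: Trial, subject: SubjectModel, fs: float = 50.0,
                     prefiltered: bool = False) -> MomentSeries:
    """Net L5/S1 moment (extension positive) by bottom-up recursion.

    Positions, forces and centre of pressure are 5 Hz low-pass filtered
    before differentiation unless ``prefiltered`` is set.
    """
    for col in ("grf_fx", "grf_fy", "cop_x"):
        if col not in trial.data.columns:
            raise InputError(f"missing ground-reaction channel {col!r}")

    def channel(name):
        x = trial.column(name)
        return x if prefiltered else butterworth(x, fs, _LOWPASS_5HZ)

    fx = channel("grf_fx")
    fy = channel("grf_fy")
    cop_x = channel("cop_x")
    n = trial.n_samples
    joints = {"ankle": np.column_stack([np.zeros(n),
                                        np.full(n, subject.ankle_height_m)])}
    for j in ("knee", "hip", "l5s1"):
        joints[j] = np.column_stack([channel(f"{j}_x"), channel(f"{j}_y")])
    p = joints["l5s1"]
    g = G_GRAVITY
    m_sum = np.zeros(n)
    # static feet: gravity lever only
    feet = subject.segments["feet"]
    foot_com_x = 0.0
    foot_com_y = subject.ankle_height_m * 0.5
    m_sum += feet.mass_kg * ((foot_com_x - p[:, 0]) * g)
    for name, prox, dist in _LOWER_SPANS:
        seg = subject.segments[name]
        com = joints[prox] + seg.com_fraction * (joints[dist] - joints[prox])
        _, acc = numeric_derivatives(com, fs)
        phi = channel(_LOWER_PHI[name])
        _, phi_dd = numeric_derivatives(phi, fs)
        dx = com[:, 0] - p[:, 0]
        dy = com[:, 1] - p[:, 1]
        m_sum += seg.mass_kg * (dx * (acc[:, 1] + g) - dy * acc[:, 0]) \
            + seg.inertia_kgm2 * phi_dd
    m_net = (cop_x - p[:, 0]) * fy + p[:, 1] * fx - m_sum
    return MomentSeries(trial.time_s, m_net, "net")


def human_moment(m_net: MomentSeries, exo_torque) -> MomentSeries:
    """Human share of the net moment: ``M_human = M_net - M_exo``."""
    tau = np.asarray(exo_torque, dtype=float)
    if tau.shape != m_net.values_nm.shape:
        raise InputError("exoskeleton torque length does not match the moment")
    return MomentSeries(m_net.time_s, m_net.values_nm - tau, "human")


def human_moment_from_trial(trial: Trial, subject: SubjectModel,
                            **kwargs) -> MomentSeries:
    """Convenience: bottom-up net moment minus the trial's exoskeleton torque."""
    return human_moment(bottom_up_moment(trial, subject, **kwargs),
                        trial.exo_torque_nm)
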