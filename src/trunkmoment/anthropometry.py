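"""Planar segment-parameter tables and subject scaling.

The sagittal linked-segment chain used throughout the package lumps the two
legs into single ``feet``/``shanks``/``thighs`` segments and the two upper
limbs into one ``arms`` segment.  Segment masses, lengths, centre-of-mass
locations and radii of gyration are taken as fixed fractions of body mass and
stature, in the style of the classical cadaver-based tables used in
linked-segment modelling.  All values are documented constants and can be
overridden per subject.

Conventions
-----------
* x forward, y up, angles in radians measured from the global vertical
  (forward lean positive).
* The ankle joint of the lumped legs sits at ``(0, ankle_height)``.
* The pelvis segment runs from the hip-joint midpoint to L5/S1; placing
  L5/S1 at a fixed fraction of stature above the hips is the package's
  documented convention (the anatomical location is not observable here).
"""

from __future__ import annotations

from dataclasses import dataclass


G_GRAVITY = 9.81  # m/s^2

SEGMENT_NAMES = ("feet", "shanks", "thighs", "pelvis", "trunk_head", "arms")

#: Segment mass as a fraction of total body mass (pairs lumped).  The
#: fractions sum to exactly 1 so that segment masses reconstruct body mass.
MASS_FRACTIONS = {
    "feet": 0.029,
    "shanks": 0.093,
    "thighs": 0.200,
    "pelvis": 0.142,
    "trunk_head": 0.426,
    "arms": 0.110,
}

#: Segment length as a fraction of stature (proximal->distal joint).
LENGTH_FRACTIONS = {
    "feet": 0.152,       # heel->toe, used only for foot geometry
    "shanks": 0.246,     # ankle->knee
    "thighs": 0.245,     # knee->hip
    "pelvis": 0.090,     # hip->L5/S1
    "trunk_head": 0.300, # L5/S1->shoulder (head mass folded into the segment)
    "arms": 0.440,       # shoulder->hand (upper arm + forearm + hand)
}

#: Centre-of-mass position as a fraction of segment length from the proximal
#: end.  trunk_head > 0.5 accounts for the head mass above the shoulders.
COM_FRACTIONS = {
    "feet": 0.500,
    "shanks": 0.433,
    "thighs": 0.433,
    "pelvis": 0.500,
    "trunk_head": 0.550,
    "arms": 0.450,
}

#: Radius of gyration about the segment COM as a fraction of segment length.
GYRATION_FRACTIONS = {
    "feet": 0.475,
    "shanks": 0.302,
    "thighs": 0.323,
    "pelvis": 0.310,
    "trunk_head": 0.400,
    "arms": 0.368,
}

ANKLE_HEIGHT_FRACTION = 0.039  # ankle joint height above ground / stature

#: Default 12-channel MVC linear-envelope peaks (arbitrary amplifier units).
DEFAULT_MVC_PEAK = 1.0


@dataclass(frozen=True)
class SegmentParams:
    """Inertial parameters of one lumped planar segment."""

    mass_kg: float
    length_m: float
    com_fraction: float
    inertia_kgm2: float  # about the segment COM


@dataclass(frozen=True)
class SubjectModel:
    """Planar anthropometry plus per-channel MVC peaks for one subject."""

    subject_id: str
    body_mass_kg: float
    stature_m: float
    segments: dict[str, SegmentParams]
    mvc_peaks: tuple[float, ...]  # 12 channels, order of trial_model.EMG_CHANNELS
    ankle_height_m: float = 0.07

    def __post_init__(self) -> None:
        total = sum(s.mass_kg for s in self.segments.values())
        if abs(total - self.body_mass_kg) > 1e-9 * max(1.0, self.body_mass_kg):
            raise ValueError(
                f"segment masses sum to {total!r}, expected body mass "
                f"{self.body_mass_kg!r}"
            )
        for name, seg in self.segments.items():
            if seg.length_m <= 0:
                raise ValueError(f"segment {name!r} has non-positive length")
        if len(self.mvc_peaks) != 12:
            raise ValueError("mvc_peaks must have 12 entries")
        if any(p <= 0 for p in self.mvc_peaks):
            raise ValueError("MVC peaks must be positive")

    @property
    def weight_n(self) -> float:
        return self.body_mass_kg * G_GRAVITY


def build_subject(
    subject_id: str,
    body_mass_kg: float = 73.8,
    stature_m: float = 1.82,
    mvc_peaks: tuple[float, ...] | None = None,
) -> SubjectModel:
    """Scale the fraction tables to one subject.

    Defaults reproduce the mean body mass and stature of a young male cohort
    typically recruited for exoskeleton studies (73.8 kg, 1.82 m).
    """
    segments = {}
    for name in SEGMENT_NAMES:
        m = MASS_FRACTIONS[name] * body_mass_kg
        length = LENGTH_FRACTIONS[name] * stature_m
        k = GYRATION_FRACTIONS[name] * length
        segments[name] = SegmentParams(
            mass_kg=m,
            length_m=length,
            com_fraction=COM_FRACTIONS[name],
            inertia_kgm2=m * k * k,
        )
    if mvc_peaks is None:
        mvc_peaks = tuple([DEFAULT_MVC_PEAK] * 12)
    return SubjectModel(
        subject_id=subject_id,
        body_mass_kg=body_mass_kg,
        stature_m=stature_m,
        segments=segments,
        mvc_peaks=tuple(mvc_peaks),
        ankle_height_m=ANKLE_HEIGHT_FRACTION * stature_m,
    )


def write_subject(subject: SubjectModel, path) -> None:
    """Write a subject as a flat key:value text file."""
    lines = [
        f"subject_id: {subject.subject_id}",
        f"body_mass_kg: {subject.body_mass_kg!r}",
        f"stature_m: {subject.stature_m!r}",
        f"ankle_height_m: {subject.ankle_height_m!r}",
    ]
    for name, seg in subject.segments.items():
        lines.append(
            f"segment_{name}: {seg.mass_kg!r},{seg.length_m!r},"
            f"{seg.com_fraction!r},{seg.inertia_kgm2!r}"
        )
    lines.append("mvc_peaks: " + ",".join(repr(p) for p in subject.mvc_peaks))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_subject(path) -> SubjectModel:
    """Read a subject file written by :func:`write_subject`."""
    kv: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            key, _, value = line.partition(":")
            kv[key.strip()] = value.strip()
    segments = {}
    for name in SEGMENT_NAMES:
        parts = [float(x) for x in kv[f"segment_{name}"].split(",")]
        segments[name] = SegmentParams(*parts)
    return SubjectModel(
        subject_id=kv["subject_id"],
        body_mass_kg=float(kv["body_mass_kg"]),
        stature_m=float(kv["stature_m"]),
        segments=segments,
        mvc_peaks=tuple(float(x) for x in kv["mvc_peaks"].split(",")),
        ankle_height_m=float(kv["ankle_height_m"]),
    )
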