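"""15-segment anthropometric body model and whole-body center of mass.

The whole body is treated as a link system of 15 rigid segments (head, chest,
lower torso, and left/right upper arms, forearms, hands, thighs, shanks and
feet).  Each segment carries a length fraction (segment length / body height),
a mass fraction (segment mass / body mass) and an internal-division ratio
``gamma`` that places the segment center of mass on the line from the
proximal to the distal joint:

    p_com = p_proximal + gamma * (p_distal - p_proximal)

The fractions are calibrated from a reference lean subject (1.65 m, 57.00 kg)
whose per-segment values derive from a Japanese body statistical model; they
rescale linearly with height and mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SegmentSpec",
    "SubjectModel",
    "REFERENCE_SEGMENTS",
    "build_subject_model",
    "segment_com",
    "whole_body_com",
]

# Reference subject: height 1.65 m, mass 57.00 kg.  Columns: segment name,
# absolute length (m), absolute mass (kg), COM internal-division ratio gamma,
# (proximal joint, distal joint).
_REFERENCE_HEIGHT = 1.65
_REFERENCE_MASS = 57.00
_REFERENCE_TABLE = [
    ("head", 0.22, 3.93, 0.821, ("neck", "head_top")),
    ("chest", 0.45, 17.21, 0.428, ("neck", "chest_bottom")),
    ("body", 0.45, 10.66, 0.609, ("chest_bottom", "pelvis")),
    ("r_upper_arm", 0.25, 1.54, 0.529, ("r_shoulder", "r_elbow")),
    ("r_fore_arm", 0.25, 0.91, 0.415, ("r_elbow", "r_wrist")),
    ("r_hand", 0.17, 0.34, 0.891, ("r_wrist", "r_hand_tip")),
    ("l_upper_arm", 0.25, 1.54, 0.529, ("l_shoulder", "l_elbow")),
    ("l_fore_arm", 0.25, 0.91, 0.415, ("l_elbow", "l_wrist")),
    ("l_hand", 0.17, 0.34, 0.891, ("l_wrist", "l_hand_tip")),
    ("r_upper_leg", 0.33, 6.27, 0.475, ("r_hip", "r_knee")),
    ("r_lower_leg", 0.33, 2.91, 0.406, ("r_knee", "r_ankle")),
    ("r_foot", 0.10, 0.63, 0.595, ("r_ankle", "r_toe")),
    ("l_upper_leg", 0.33, 6.27, 0.475, ("l_hip", "l_knee")),
    ("l_lower_leg", 0.33, 2.91, 0.406, ("l_knee", "l_ankle")),
    ("l_foot", 0.10, 0.63, 0.595, ("l_ankle", "l_toe")),
]


@dataclass(frozen=True)
class SegmentSpec:
    """Dimensionless description of one body segment.

    Attributes
    ----------
    name : str
        Segment identifier (one of the 15 canonical segments).
    length_fraction : float
        Segment length divided by body height.
    mass_fraction : float
        Segment mass divided by body mass.
    gc_ratio : float
        Proximal-to-distal internal-division ratio gamma in [0, 1] locating
        the segment center of mass.
    joints : tuple[str, str]
        (proximal joint, distal joint) names.
    """

    name: str
    length_fraction: float
    mass_fraction: float
    gc_ratio: float
    joints: tuple[str, str]

    def __post_init__(self) -> None:
        if self.length_fraction <= 0 or self.mass_fraction <= 0:
            raise ValueError(f"segment {self.name}: fractions must be positive")
        if not 0.0 <= self.gc_ratio <= 1.0:
            raise ValueError(f"segment {self.name}: gc_ratio outside [0, 1]")


REFERENCE_SEGMENTS: tuple[SegmentSpec, ...] = tuple(
    SegmentSpec(
        name=name,
        length_fraction=length / _REFERENCE_HEIGHT,
        mass_fraction=mass / _REFERENCE_MASS,
        gc_ratio=gamma,
        joints=joints,
    )
    for name, length, mass, gamma, joints in _REFERENCE_TABLE
)


@dataclass(frozen=True)
class RealizedSegment:
    """A SegmentSpec scaled to a concrete subject (length in m, mass in kg)."""

    spec: SegmentSpec
    length: float
    mass: float

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def joints(self) -> tuple[str, str]:
        return self.spec.joints

    @property
    def gc_ratio(self) -> float:
        return self.spec.gc_ratio


@dataclass(frozen=True)
class SubjectModel:
    """Anthropometric subject: height, mass and the 15 realized segments."""

    height: float
    mass: float
    segments: tuple[RealizedSegment, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.segments) != 15:
            raise ValueError("a SubjectModel must have exactly 15 segments")
        total = sum(s.mass for s in self.segments)
        if abs(total - self.mass) > 1e-6 * max(1.0, self.mass):
            raise ValueError("segment masses do not conserve body mass")

    def segment(self, name: str) -> RealizedSegment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def weight(self) -> float:
        """Body weight in newtons (g = 9.81 m/s^2)."""
        return self.mass * 9.81


def build_subject_model(height: float, mass: float, overrides: dict | None = None) -> SubjectModel:
    """Scale the reference segment table to a subject's height and mass.

    Parameters
    ----------
    height : float
        Body height in metres (> 0).
    mass : float
        Body mass in kilograms (> 0).
    overrides : dict, optional
        Per-segment overrides, e.g. ``{"head": {"mass_fraction": 0.07}}``;
        recognized keys are ``mass_fraction``, ``length_fraction`` and
        ``gc_ratio``.  Overridden mass fractions must still sum to 1 over
        the 15 segments (mass conservation is not silently re-normalized).

    Returns
    -------
    SubjectModel
        Absolute segment lengths ``height * length_fraction`` and masses
        ``mass * mass_fraction``; segment masses sum to ``mass`` to 1e-9.
    """
    if height <= 0 or mass <= 0:
        raise ValueError("height and mass must be positive")
    specs = list(REFERENCE_SEGMENTS)
    if overrides:
        unknown = set(overrides) - {s.name for s in specs}
        if unknown:
            raise KeyError(f"unknown segment(s) in overrides: {sorted(unknown)}")
        specs = [
            SegmentSpec(
                name=s.name,
                length_fraction=overrides.get(s.name, {}).get("length_fraction", s.length_fraction),
                mass_fraction=overrides.get(s.name, {}).get("mass_fraction", s.mass_fraction),
                gc_ratio=overrides.get(s.name, {}).get("gc_ratio", s.gc_ratio),
                joints=s.joints,
            )
            for s in specs
        ]
        total = sum(s.mass_fraction for s in specs)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"overridden mass fractions sum to {total:.6f}, not 1: "
                "adjust the other segments to conserve body mass"
            )
    segments = tuple(
        RealizedSegment(spec=s, length=height * s.length_fraction, mass=mass * s.mass_fraction)
        for s in specs
    )
    return SubjectModel(height=height, mass=mass, segments=segments)


def segment_com(p_proximal, p_distal, gc_ratio: float) -> np.ndarray:
    """Segment center of mass as an internal division of the joint vector.

    Returns ``p_proximal + gamma * (p_distal - p_proximal)``.
    """
    if not 0.0 <= gc_ratio <= 1.0:
        raise ValueError("gc_ratio outside [0, 1]")
    p0 = np.asarray(p_proximal, dtype=float)
    p1 = np.asarray(p_distal, dtype=float)
    return p0 + gc_ratio * (p1 - p0)


def whole_body_com(model: SubjectModel, joint_poses: dict) -> np.ndarray:
    """Mass-weighted mean of the 15 segment centers of mass.

    Parameters
    ----------
    model : SubjectModel
    joint_poses : dict
        Mapping joint name -> 3-vector position (m).  Every proximal and
        distal joint referenced by the model must be present.

    Raises
    ------
    KeyError
        Naming the first missing joint.
    """
    total = np.zeros(3)
    for seg in model.segments:
        prox, dist = seg.joints
        if prox not in joint_poses:
            raise KeyError(prox)
        if dist not in joint_poses:
            raise KeyError(dist)
        com = segment_com(joint_poses[prox], joint_poses[dist], seg.gc_ratio)
        total += seg.mass * com
    return total / model.mass
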