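"""Sensor-side ZMP from foot-mounted force plates, and the foot-shape model.

Each shoe carries two thin 6-axis force plates (toe and heel).  Given plate
positions x_i, forces f_i and torques n_i in the world frame, the moment
balance about the ZMP gives, along the travel axis,

    x_zmp = sum_i(-n_iy - (z_i - z_zmp) f_ix + x_i f_iz) / sum_i f_iz

and symmetrically for the lateral axis.  The foot-shape (insole outline)
model provides the per-sample lowest/highest point of the foot used by the
kinematic gait-phase rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "CONTACT_FORCE_FRACTION",
    "PlateWrench",
    "FootShapeModel",
    "default_insole_outline",
    "measured_zmp",
    "measured_zmp_xy",
    "transform_foot_points",
    "foot_clearance",
]

# Vertical force below this fraction of body weight counts as no contact.
CONTACT_FORCE_FRACTION = 0.03


@dataclass(frozen=True)
class PlateWrench:
    """One force plate sample: world position (m), force (N), torque (N m)."""

    position: np.ndarray
    force: np.ndarray
    torque: np.ndarray
    plate_id: str = ""

    def __post_init__(self) -> None:
        for name in ("position", "force", "torque"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 3-vector")
            object.__setattr__(self, name, v)


def default_insole_outline(n_per_plate: int = 8) -> np.ndarray:
    """Insole outline as two rectangles (toe 0.090 x 0.080 m ahead of a heel
    plate 0.080 x 0.080 m), discretized along their perimeters.

    Coordinates are in the foot frame: x forward from the heel's back edge,
    y lateral, at the sole plane.  Returns an (2*n_per_plate, 2) array.
    """

    def rect(x0, x1, y0, y1, n):
        corners = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
        pts = []
        for i in range(4):
            a, b = corners[i], corners[(i + 1) % 4]
            for f in np.linspace(0.0, 1.0, max(n // 4, 1), endpoint=False):
                pts.append(a + f * (b - a))
        return np.array(pts[:n])

    heel = rect(0.0, 0.080, -0.040, 0.040, n_per_plate)
    toe = rect(0.090, 0.180, -0.040, 0.040, n_per_plate)
    return np.vstack([heel, toe])


@dataclass
class FootShapeModel:
    """Insole outline points plus the foot's rigid pose.

    Attributes
    ----------
    outline : (N, 2) array
        Sole outline in the foot frame (m), N >= 3.
    position : 3-vector
        Foot-frame origin in the world (m).
    quaternion : 4-vector, scalar-first (w, x, y, z)
        Foot orientation; normalized (a warning is issued if the input norm
        deviates from 1 by more than 1e-9).
    """

    outline: np.ndarray = field(default_factory=default_insole_outline)
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    quaternion: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        self.outline = np.asarray(self.outline, dtype=float)
        if self.outline.ndim != 2 or self.outline.shape[0] < 3 or self.outline.shape[1] != 2:
            raise ValueError("outline must be an (N>=3, 2) array")
        self.position = np.asarray(self.position, dtype=float)
        q = np.asarray(self.quaternion, dtype=float)
        norm = np.linalg.norm(q)
        if norm == 0:
            raise ValueError("zero quaternion")
        if abs(norm - 1.0) > 1e-9:
            warnings.warn("non-unit quaternion normalized", stacklevel=2)
        self.quaternion = q / norm

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quaternion, scalar_first=True)


def transform_foot_points(model: FootShapeModel) -> np.ndarray:
    """Outline points rigidly transformed to the world frame, shape (N, 3)."""
    local = np.column_stack([model.outline, np.zeros(len(model.outline))])
    return model.rotation.apply(local) + model.position


def foot_clearance(model: FootShapeModel) -> tuple[float, float]:
    """(min, max) height of the transformed outline points (m)."""
    z = transform_foot_points(model)[:, 2]
    return float(z.min()), float(z.max())


def measured_zmp(
    plates,
    z_zmp: float = 0.0,
    axis: str = "x",
    force_threshold: float = 0.0,
    variant: str = "standard",
):
    """Moment-balance ZMP of 1-4 plate wrenches along one horizontal axis.

    Parameters
    ----------
    plates : sequence of PlateWrench
    z_zmp : float
        Height of the ZMP plane (ground = 0).
    axis : "x" or "y"
    force_threshold : float
        Minimum total vertical force (N); below it the foot is considered
        airborne and ``None`` is returned instead of a ZMP.
    variant : "standard" or "as_printed"
        "standard" uses the moment-balance numerator
        -n_y - (z_i - z_zmp) f_x + x_i f_z.  "as_printed" replaces the last
        term with x_i f_x (a form that appears in print but is dimensionally
        a truncation); it is provided for comparison only.

    Returns
    -------
    float or None
        ZMP coordinate (m), or None during flight.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    if variant not in ("standard", "as_printed"):
        raise ValueError("variant must be 'standard' or 'as_printed'")
    plates = list(plates)
    if not 1 <= len(plates) <= 4:
        raise ValueError("expected 1-4 plate wrenches")
    fz_total = sum(p.force[2] for p in plates)
    if fz_total <= force_threshold:
        return None
    num = 0.0
    for p in plates:
        x, y, z = p.position
        fx, fy, fz = p.force
        nx, ny, _ = p.torque
        if axis == "x":
            lever = x * fz if variant == "standard" else x * fx
            num += -ny - (z - z_zmp) * fx + lever
        else:
            num += nx - (z - z_zmp) * fy + y * fz
    return float(num / fz_total)


def measured_zmp_xy(plates, z_zmp: float = 0.0, force_threshold: float = 0.0):
    """Convenience: (x_zmp, y_zmp) tuple, or None during flight."""
    x = measured_zmp(plates, z_zmp, "x", force_threshold)
    if x is None:
        return None
    y = measured_zmp(plates, z_zmp, "y", force_threshold)
    return (x, y)


def measured_zmp_series(
    recording,
    z_zmp: float = 0.0,
    axis: str = "x",
    force_threshold: float = 0.0,
    variant: str = "standard",
) -> np.ndarray:
    """Vectorized :func:`measured_zmp` over a full recording.

    Returns the per-sample ZMP (m) along ``axis`` from the four plate
    channels; samples whose total vertical force is at or below
    ``force_threshold`` (flight) are NaN.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    n = len(recording)
    num = np.zeros(n)
    den = np.zeros(n)
    for name in ("l_heel", "l_toe", "r_heel", "r_toe"):
        p = recording.plate(name)
        x, y, z = p["pos"].T
        fx, fy, fz = p["f"].T
        nx, ny, _ = p["n"].T
        if axis == "x":
            lever = x * fz if variant == "standard" else x * fx
            num += -ny - (z - z_zmp) * fx + lever
        else:
            num += nx - (z - z_zmp) * fy + y * fz
        den += fz
    out = np.full(n, np.nan)
    ok = den > force_threshold
    out[ok] = num[ok] / den[ok]
    return out
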