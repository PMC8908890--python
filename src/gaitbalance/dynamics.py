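"""COM-ZMP inverted-pendulum dynamics for the horizontal balance axis.

The horizontal center-of-mass (COM) coordinate x relative to the zero moment
point (ZMP) behaves, to first order, like an inverted pendulum.  With a
symmetric eigenstructure the modes are (+zeta, -zeta) with
zeta = sqrt(g / z_com).  Human recovery and collapse motions are not mirror
images, so the model admits distinct magnitudes for the divergent and
convergent modes, eigenvalues (zeta1, -zeta2), giving the equation of motion

    xdd = zeta1 * zeta2 * (x - x_zmp) + (zeta1 - zeta2) * xd

which reduces to the symmetric pendulum when zeta1 == zeta2.  This module
holds that model: state/parameter containers, the companion (system) matrix,
the two-exponential closed-form solution under constant ZMP, the capture
point, linear COM feedback on the ZMP, ZMP saturation to the support area,
and the angular-momentum-corrected ZMP computed from whole-body kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GRAVITY",
    "PendulumParams",
    "PlanarState",
    "SupportBounds",
    "FeedbackGains",
    "natural_frequency",
    "com_acceleration",
    "system_matrix",
    "closed_form_solution",
    "capture_point",
    "feedback_gains",
    "target_zmp_feedback",
    "saturate_zmp",
    "zmp_from_kinematics",
    "angular_momentum_about_com",
]

GRAVITY = 9.81  # m/s^2, default; configurable wherever it enters


@dataclass(frozen=True)
class PendulumParams:
    """Eigenvalue magnitudes of the COM-ZMP pendulum.

    zeta1 is the divergent (unstable) mode, zeta2 the convergent (stable)
    mode, both in 1/s and positive.  The model is symmetric iff
    zeta1 == zeta2.
    """

    zeta1: float
    zeta2: float
    g: float = GRAVITY
    z_com: float = 1.0

    def __post_init__(self) -> None:
        if self.zeta1 <= 0 or self.zeta2 <= 0:
            raise ValueError("eigenvalue magnitudes must be positive")
        if self.g <= 0 or self.z_com <= 0:
            raise ValueError("g and z_com must be positive")

    @classmethod
    def symmetric(cls, z_com: float, g: float = GRAVITY) -> "PendulumParams":
        zeta = natural_frequency(z_com, g)
        return cls(zeta1=zeta, zeta2=zeta, g=g, z_com=z_com)

    @property
    def is_symmetric(self) -> bool:
        return self.zeta1 == self.zeta2


@dataclass(frozen=True)
class PlanarState:
    """COM position (m) and velocity (m/s) along one horizontal axis."""

    x: float
    xdot: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.xdot)):
            raise ValueError("state must be finite")


@dataclass(frozen=True)
class SupportBounds:
    """Admissible ZMP interval [x_zmp_min, x_zmp_max] set by the feet."""

    x_zmp_min: float
    x_zmp_max: float

    def __post_init__(self) -> None:
        if self.x_zmp_min > self.x_zmp_max:
            raise ValueError("x_zmp_min must not exceed x_zmp_max")


@dataclass(frozen=True)
class FeedbackGains:
    """Virtual spring-damper ZMP feedback: k1 (spring, -), k2 (damper, s)."""

    k1: float
    k2: float
    xd: float = 0.0


def natural_frequency(z_com: float, g: float = GRAVITY) -> float:
    """Pendulum eigenfrequency sqrt(g / z_com) in 1/s."""
    if z_com <= 0:
        raise ValueError("z_com must be positive")
    return float(np.sqrt(g / z_com))


def com_acceleration(state: PlanarState, x_zmp: float, params: PendulumParams) -> float:
    """Horizontal COM acceleration under the (possibly asymmetric) pendulum.

    Returns ``zeta1*zeta2*(x - x_zmp) + (zeta1 - zeta2)*xdot``; for
    zeta1 == zeta2 == zeta this is the symmetric ``zeta**2 * (x - x_zmp)``.
    """
    z1, z2 = params.zeta1, params.zeta2
    return z1 * z2 * (state.x - x_zmp) + (z1 - z2) * state.xdot


def system_matrix(params: PendulumParams) -> np.ndarray:
    """Companion matrix [[0, 1], [zeta1*zeta2, zeta1 - zeta2]].

    Its eigenvalues are (zeta1, -zeta2) with eigenvectors proportional to
    [1, zeta1] and [1, -zeta2].
    """
    z1, z2 = params.zeta1, params.zeta2
    return np.array([[0.0, 1.0], [z1 * z2, z1 - z2]])


def closed_form_solution(
    state0: PlanarState, x_zmp: float, params: PendulumParams, t: float
) -> PlanarState:
    """Exact solution under constant ZMP as a sum of two exponentials.

    With chi0 = x0 - x_zmp,

        x(t) = A e^{zeta1 t} + B e^{-zeta2 t} + x_zmp
        A = (chi0 + xd0/zeta2) / (1 + zeta1/zeta2)
        B = (chi0 - xd0/zeta1) / (1 + zeta2/zeta1)

    and xd(t) = A zeta1 e^{zeta1 t} - B zeta2 e^{-zeta2 t}.  At t = 0 this
    reproduces the initial state; for any t it matches numerical integration
    of :func:`com_acceleration`.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    z1, z2 = params.zeta1, params.zeta2
    chi0 = state0.x - x_zmp
    a = (chi0 + state0.xdot / z2) / (1.0 + z1 / z2)
    b = (chi0 - state0.xdot / z1) / (1.0 + z2 / z1)
    e_up = np.exp(z1 * t)
    e_dn = np.exp(-z2 * t)
    x = a * e_up + b * e_dn + x_zmp
    xd = a * z1 * e_up - b * z2 * e_dn
    return PlanarState(x=float(x), xdot=float(xd))


def capture_point(state: PlanarState, zeta2: float) -> float:
    """Point where placing the ZMP brings the COM asymptotically to rest.

    x_c = x + xdot / zeta2.  Holding the ZMP there zeroes the divergent-mode
    coefficient, so the COM converges to x_c along the stable mode.
    """
    if zeta2 <= 0:
        raise ValueError("zeta2 must be positive")
    return state.x + state.xdot / zeta2


def feedback_gains(q1: float, q2: float, zeta: float) -> FeedbackGains:
    """Gains k1 = q1*q2 + 1, k2 = (q1 + q2)/zeta placing the closed-loop
    eigenvalues at (-zeta*q1, -zeta*q2)."""
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    return FeedbackGains(k1=q1 * q2 + 1.0, k2=(q1 + q2) / zeta)


def target_zmp_feedback(state: PlanarState, gains: FeedbackGains) -> float:
    """Linear COM-state feedback ZMP: k1*(x - xd) + k2*xdot + xd."""
    return gains.k1 * (state.x - gains.xd) + gains.k2 * state.xdot + gains.xd


def saturate_zmp(x_zmp_desired: float, bounds: SupportBounds) -> float:
    """Clamp a desired ZMP to the support interval."""
    return float(np.clip(x_zmp_desired, bounds.x_zmp_min, bounds.x_zmp_max))


def zmp_from_kinematics(
    com_pos,
    com_acc,
    Ldot_y: float,
    M: float,
    g: float = GRAVITY,
) -> float:
    """ZMP along x from COM kinematics with angular-momentum correction.

    x_zmp = (x*(g + zdd) - xdd*z) / (g + zdd) - Ldot_y / (M*(g + zdd))

    The second term is the rate of whole-body angular momentum about the COM
    (pitch component); its coefficient is negative, shifting the ZMP
    backwards when angular momentum builds up after landing.  With
    Ldot_y = 0 and zdd = 0 the expression reduces to x - xdd*z/g.

    Raises
    ------
    ValueError
        If M <= 0 or g + zdd <= 0 (flight; the ZMP is undefined).
    """
    if M <= 0:
        raise ValueError("M must be positive")
    x, _, z = np.asarray(com_pos, dtype=float)
    xdd, _, zdd = np.asarray(com_acc, dtype=float)
    gz = g + zdd
    if gz <= 0:
        raise ValueError("g + zdd <= 0: flight phase, ZMP undefined")
    return float((x * gz - xdd * z) / gz - Ldot_y / (M * gz))


def angular_momentum_about_com(segment_coms, segment_velocities, segment_masses) -> np.ndarray:
    """Whole-body angular momentum L = sum_i r_i x (m_i v_i), r_i relative
    to the whole-body COM."""
    r = np.atleast_2d(np.asarray(segment_coms, dtype=float))
    v = np.atleast_2d(np.asarray(segment_velocities, dtype=float))
    m = np.atleast_1d(np.asarray(segment_masses, dtype=float))
    if not (len(r) == len(v) == len(m)):
        raise ValueError("segment arrays must have equal length")
    return np.einsum("i,ij->j", m, np.cross(r, v))
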