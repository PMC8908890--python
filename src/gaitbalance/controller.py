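"""Capture-point model-predictive ZMP law and its bilateral extension.

During one stepping window the controller drives the COM by placing the ZMP
near the support foot (axle) xP while guaranteeing that the capture point
reaches the target stepping position xSd at the landing time T.  Minimizing
the integral of (x_zmp - xP)^2 subject to that terminal condition yields the
state-feedback law (foot-relative quantities xCP = x + xd/zeta2 - xP and
xSP = xSd - xP):

    u = 2 * (xCP - exp(-zeta1*(T - t)) * xSP) / (1 - exp(-2*zeta1*(T - t)))
    x_zmp = xP + u

Continuous walking alternates left/right windows: each window runs from one
foot's toe-off to the opposite foot's toe-off (option "B" switching), with
the horizon T at the swinging foot's heel contact.  The window is split at
heel contact into two sections, each with its own axle: before heel contact
the law above drives the step; after it (double support) the landed foot is
already the new axle, and the *next* step's finite-horizon task takes over
so the COM rolls forward instead of braking — continuous walking never
brings the COM velocity to zero between steps.  Only the final window,
which has no successor, ends in the infinite-horizon braking limit
u = 2 * xCP that pins the capture point on the last landing position and
brings the COM to rest (the stepping-and-braking motion is exactly this
one-window case).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

from .dynamics import PendulumParams, PlanarState, SupportBounds, saturate_zmp

__all__ = [
    "HORIZON_FLOOR",
    "HEEL_BOUND_OFFSET",
    "TOE_BOUND_OFFSET",
    "SteppingTask",
    "SwitchSchedule",
    "mpc_zmp",
    "braking_zmp",
    "bilateral_mpc_zmp",
    "task_support_bounds",
    "zmp_objective",
]

HORIZON_FLOOR = 0.0005  # s; below this the law evaluates at the floor
# Support-area extent of one foot relative to its ankle point, from the
# insole geometry (heel plate back edge / toe plate front edge).
HEEL_BOUND_OFFSET = 0.05  # m behind the ankle
TOE_BOUND_OFFSET = 0.13  # m ahead of the ankle


@dataclass(frozen=True)
class SteppingTask:
    """One stepping window: support foot x_p, target x_sd, landing time T."""

    x_p: float
    x_sd: float
    T: float
    leg: str = "right"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_p) and np.isfinite(self.x_sd) and np.isfinite(self.T)):
            raise ValueError("task fields must be finite")
        if self.leg not in ("left", "right"):
            raise ValueError("leg must be 'left' or 'right'")


@dataclass(frozen=True)
class SwitchSchedule:
    """Controller-switching windows, one per step.

    ``starts[i]`` is the toe-off time opening window i (the swing leg of
    ``legs[i]`` is in the air until its heel contact at the task horizon);
    the window closes at ``starts[i+1]`` (the opposite foot's toe-off) or,
    for the last window, at ``end``.
    """

    starts: tuple[float, ...]
    legs: tuple[str, ...]
    end: float

    def __post_init__(self) -> None:
        if len(self.starts) != len(self.legs) or not self.starts:
            raise ValueError("starts and legs must be equal-length and non-empty")
        if any(b <= a for a, b in zip(self.starts, self.starts[1:])):
            raise ValueError("window start times must be strictly increasing")
        if any(a == b for a, b in zip(self.legs, self.legs[1:])):
            raise ValueError("legs must alternate between consecutive windows")
        if self.end <= self.starts[-1]:
            raise ValueError("end must exceed the last window start")

    def active_window(self, t: float) -> int:
        """Index of the window covering time t (option-B tiling)."""
        if t < self.starts[0] or t > self.end:
            raise ValueError(
                f"t={t:.4f} s outside the schedule "
                f"[{self.starts[0]:.4f}, {self.end:.4f}]"
            )
        return bisect_right(self.starts, t) - 1


def mpc_zmp(state: PlanarState, task: SteppingTask, t: float, params: PendulumParams) -> float:
    """Model-predictive ZMP command for one stepping window.

    The horizon tau = T - t is clamped at :data:`HORIZON_FLOOR` so the
    command stays finite through and beyond the landing instant (after
    landing the clamped law holds the capture point at the target).
    """
    tau = max(task.T - t, HORIZON_FLOOR)
    z1 = params.zeta1
    x_cp = state.x + state.xdot / params.zeta2 - task.x_p
    x_sp = task.x_sd - task.x_p
    e1 = np.exp(-z1 * tau)
    u = 2.0 * (x_cp - e1 * x_sp) / (1.0 - e1 * e1)
    return task.x_p + float(u)


def braking_zmp(state: PlanarState, anchor: float, zeta2: float) -> float:
    """Infinite-horizon limit of the window law, anchored at ``anchor``.

    u = 2 * (x + xd/zeta2 - anchor); holding the ZMP there drives the
    capture point to the anchor, bringing the COM asymptotically to rest
    over it.  Used after heel contact (anchor = the landing position) and
    for walk-stop braking.
    """
    return anchor + 2.0 * (state.x + state.xdot / zeta2 - anchor)


def task_support_bounds(task: SteppingTask, t: float) -> SupportBounds:
    """Support-area ZMP bounds for a window at time t.

    Before the landing time T only the support foot is on the ground; after
    T the landed foot extends the support area to the target side.
    """
    lo = task.x_p - HEEL_BOUND_OFFSET
    hi = task.x_p + TOE_BOUND_OFFSET
    if t >= task.T:
        lo = min(task.x_p, task.x_sd) - HEEL_BOUND_OFFSET
        hi = max(task.x_p, task.x_sd) + TOE_BOUND_OFFSET
    return SupportBounds(lo, hi)


def bilateral_mpc_zmp(
    state: PlanarState,
    schedule: SwitchSchedule,
    tasks,
    t: float,
    params: PendulumParams,
    saturate: bool = True,
) -> tuple[float, str]:
    """ZMP command of the active window's law, plus the active leg tag.

    Parameters
    ----------
    tasks : sequence of SteppingTask
        One task per schedule window (``tasks[i]`` belongs to window i).
    saturate : bool
        Clamp the command to the window's support bounds (default).

    Returns
    -------
    (x_zmp, leg)
        ``leg`` is the swinging leg of the active window.
    """
    i = schedule.active_window(t)
    task = tasks[i]
    if t >= task.T:
        if i + 1 < len(tasks):
            task = tasks[i + 1]  # double support: next step's task drives
        else:
            zmp = braking_zmp(state, task.x_sd, params.zeta2)
            if saturate:
                zmp = saturate_zmp(zmp, task_support_bounds(task, t))
            return zmp, schedule.legs[i]
    zmp = mpc_zmp(state, task, t, params)
    if saturate:
        zmp = saturate_zmp(zmp, task_support_bounds(task, t))
    return zmp, schedule.legs[i]


def zmp_objective(zmp_trace, times, x_p: float) -> float:
    """Trapezoidal integral of (x_zmp - x_p)^2 over the trace (m^2 s)."""
    z = np.asarray(zmp_trace, dtype=float)
    t = np.asarray(times, dtype=float)
    if z.size == 0 or z.shape != t.shape:
        raise ValueError("trace must be non-empty and match the time grid")
    return float(np.trapezoid((z - x_p) ** 2, t))
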