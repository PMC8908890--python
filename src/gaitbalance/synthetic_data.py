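"""Closed-loop synthetic gait generator.

Produces complete :class:`~gaitbalance.recording.GaitRecording` files —
COM trajectory, per-foot poses, lower-limb joints and four plate wrenches at
60 Hz — together with ground-truth phase timelines and the true controller
parameters, so the detector and the identification pipeline can be exercised
without motion-capture hardware.

The COM is integrated in closed loop under the bilateral capture-point MPC
law with option-B (toe-off to opposite toe-off) switching and support-area
saturation; each step's task realizes the scenario's stride and timing.
Foot kinematics and ground reaction forces are then synthesized backwards
from the ground-truth phase timeline so that every detection rule (force and
kinematic) crosses its threshold at the true event time:

* per-foot vertical GRF follows a two-peak profile reaching 120 % body
  weight at the end of Loading Response and decaying to zero at toe-off,
  with the heel plate leading at contact and the toe plate after Mid-Stance;
* plate torques are solved per sample so that the moment-balance ZMP of the
  synthesized plates reproduces the simulator's true ZMP exactly;
* foot pitch performs a heel pivot through Loading Response, lies flat in
  Mid-Stance, and rises about the toe from the Mid-/Terminal-Stance
  boundary; swing clears the ground, the swing ankle passes the support
  ankle at the Initial-/Mid-Swing boundary, and the shank reaches
  verticality at the Mid-/Terminal-Swing boundary.

The default phase template (percent of cycle) is LR 10, MSt 20, TSt 20,
PSw 12, ISw 13, MSw 13, TSw 12, i.e. a 62/38 stance/swing split.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.spatial.transform import Rotation

from .anthropometry import SubjectModel, build_subject_model
from .controller import (
    SteppingTask,
    SwitchSchedule,
    bilateral_mpc_zmp,
)
from .dynamics import GRAVITY, PendulumParams, PlanarState, closed_form_solution
from .gait_phase import PhaseTimeline
from .recording import GaitRecording

__all__ = [
    "DEFAULT_PHASE_TEMPLATE",
    "DEFAULT_NOISE_SIGMA",
    "WalkScenario",
    "SimResult",
    "simulate_walk",
    "synthesize_foot_kinematics",
    "synthesize_force_plates",
]

DEFAULT_PHASE_TEMPLATE = {
    "LoadingResponse": 10.0,
    "MidStance": 20.0,
    "TerminalStance": 20.0,
    "PreSwing": 12.0,
    "InitialSwing": 13.0,
    "MidSwing": 13.0,
    "TerminalSwing": 12.0,
}

# Additive Gaussian sensor noise (1-sigma) at noise_level = 1.
DEFAULT_NOISE_SIGMA = {
    "position": 2e-3,  # m, all position channels
    "velocity": 1e-2,  # m/s
    "force": 2.0,  # N
    "torque": 0.1,  # N m
}

# Foot geometry shared with the insole outline (0.18 m long sole).
_FOOT_LEN = 0.18
_ANKLE_BACK = 0.05  # ankle is 0.05 m ahead of the heel's back edge
_ANKLE_H = 0.08  # ankle height in stance, m
_THETA_IC = np.radians(15.0)  # toe-up pitch at heel strike
_PHI_MAX = np.radians(35.0)  # heel-rise pitch at toe-off
_FOOT_Y = {"left": 0.10, "right": -0.10}
_PLATE_LOCAL = {"heel": np.array([0.040, 0.0, 0.003]), "toe": np.array([0.135, 0.0, 0.003])}
_SHANK_TO_ANGLE = np.radians(30.0)  # shank tilt at toe-off
_STANCE_SHANK = np.radians(5.0)


@dataclass(frozen=True)
class WalkScenario:
    """Study conditions for one synthetic trial.

    kind is one of ``stepping`` (single step from quiet standing, then
    braking to rest), ``straight_walk`` and ``turn_walk`` (straight, a
    90-degree turn near the midpoint, straight).  ``stride`` is the per-step
    advance of the landing foot (m).  ``noise_level`` scales
    :data:`DEFAULT_NOISE_SIGMA` (0 = noiseless).
    """

    kind: str = "straight_walk"
    n_steps: int = 6
    stride: float = 0.30
    step_duration: float = 0.55
    turn_angle: float = 90.0
    turn_step: int | None = None
    subject: SubjectModel | None = None
    params: PendulumParams | None = None
    phase_template: dict | None = None
    noise_level: float = 1.0
    seed: int = 0
    lead_in: float = 0.8
    tail: float = 1.5
    fs: float = 60.0

    def __post_init__(self) -> None:
        if self.kind not in ("stepping", "straight_walk", "turn_walk"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not 0.1 <= self.stride <= 0.6:
            raise ValueError("stride must lie in [0.1, 0.6] m")
        if self.kind == "stepping" and self.n_steps != 1:
            raise ValueError("stepping scenarios take a single step")

    def realized(self) -> "WalkScenario":
        """Fill derived defaults (subject, controller parameters)."""
        subj = self.subject or build_subject_model(1.65, 57.0)
        params = self.params or PendulumParams(
            zeta1=4.0, zeta2=8.67 / 4.0, g=GRAVITY, z_com=0.57 * subj.height
        )
        return replace(self, subject=subj, params=params)

    def template_for(self, leg: str) -> dict:
        tpl = self.phase_template or DEFAULT_PHASE_TEMPLATE
        tpl = tpl.get(leg, tpl) if any(k in tpl for k in ("left", "right")) else tpl
        if abs(sum(tpl.values()) - 100.0) > 1e-9:
            raise ValueError("phase template must sum to 100 %")
        return tpl


@dataclass
class SimResult:
    """Simulator output: recording, ground truth and true parameters."""

    scenario: WalkScenario
    subject: SubjectModel
    params: PendulumParams
    schedule: SwitchSchedule
    tasks: tuple
    events: dict
    timelines: dict
    time: np.ndarray
    com_x: np.ndarray
    com_xdot: np.ndarray
    true_zmp: np.ndarray
    recording: GaitRecording | None = None


# ---------------------------------------------------------------------------
# event schedule and closed-loop COM
# ---------------------------------------------------------------------------


def _build_events(sc: WalkScenario) -> dict:
    tc = 2.0 * sc.step_duration
    legs = tuple("right" if i % 2 == 0 else "left" for i in range(sc.n_steps))
    to = np.array([sc.lead_in + i * sc.step_duration for i in range(sc.n_steps)])
    swing_frac = np.array(
        [
            sum(sc.template_for(leg)[p] for p in ("InitialSwing", "MidSwing", "TerminalSwing"))
            / 100.0
            for leg in legs
        ]
    )
    hc = to + swing_frac * tc
    landing = np.array([(i + 1) * sc.stride for i in range(sc.n_steps)])
    support = np.array([i * sc.stride for i in range(sc.n_steps)])
    t_pass, t_align = [], []
    for i, leg in enumerate(legs):
        tpl = sc.template_for(leg)
        sw = swing_frac[i] * 100.0
        dur = hc[i] - to[i]
        t_pass.append(to[i] if i == 0 else to[i] + tpl["InitialSwing"] / sw * dur)
        t_align.append(to[i] + (tpl["InitialSwing"] + tpl["MidSwing"]) / sw * dur)
    tpl0 = sc.template_for(legs[0])
    t_dest = to[0] - (tpl0["TerminalStance"] + tpl0["PreSwing"]) / 100.0 * tc
    if t_dest < 0.1:
        raise ValueError("lead_in too short for the walk-start destabilization")
    end = hc[-1] + sc.tail
    end = np.ceil(end * sc.fs) / sc.fs
    return {
        "tc": tc,
        "legs": legs,
        "to": to,
        "hc": hc,
        "landing_x": landing,
        "support_x": support,
        "t_pass": np.array(t_pass),
        "t_align": np.array(t_align),
        "t_dest": float(t_dest),
        "end": float(end),
    }


def _tasks_and_schedule(ev: dict) -> tuple[tuple, SwitchSchedule]:
    tasks = tuple(
        SteppingTask(x_p=float(ev["support_x"][i]), x_sd=float(ev["landing_x"][i]), T=float(ev["hc"][i]), leg=ev["legs"][i])
        for i in range(len(ev["legs"]))
    )
    schedule = SwitchSchedule(starts=tuple(float(t) for t in ev["to"]), legs=ev["legs"], end=ev["end"])
    return tasks, schedule


def _integrate_com(sc: WalkScenario, ev: dict, tasks, schedule, oversample: int = 10):
    """Closed-loop COM under the bilateral MPC law (exact propagation on
    piecewise-constant ZMP at ``oversample`` x the output rate).

    Control starts at the walk-start destabilization onset: the first
    window's task already shifts the ZMP backwards before toe-off
    (anticipatory postural adjustment), which makes the first step
    reachable from rest within the support bounds.
    """
    from .controller import mpc_zmp, saturate_zmp, task_support_bounds

    dt = 1.0 / (sc.fs * oversample)
    n = int(round(ev["end"] * sc.fs)) * oversample
    t_int = np.arange(n + 1) * dt
    x = np.zeros(n + 1)
    xd = np.zeros(n + 1)
    zmp = np.zeros(n + 1)
    state = PlanarState(0.0, 0.0)
    t0 = schedule.starts[0]
    t_ctl = ev["t_dest"]
    for k in range(n + 1):
        t = min(t_int[k], schedule.end)
        if t < t_ctl - 1e-12:
            cmd = 0.0
        elif t < t0 - 1e-12:
            cmd = saturate_zmp(
                mpc_zmp(state, tasks[0], t, sc.params), task_support_bounds(tasks[0], t)
            )
        else:
            cmd, _ = bilateral_mpc_zmp(state, schedule, tasks, t, sc.params)
        x[k], xd[k], zmp[k] = state.x, state.xdot, cmd
        if k < n and t_int[k + 1] >= t_ctl - 1e-12:
            state = closed_form_solution(state, cmd, sc.params, dt)
    s = slice(0, n + 1, oversample)
    return t_int[s], x[s], xd[s], zmp[s]


# ---------------------------------------------------------------------------
# ground-truth timelines
# ---------------------------------------------------------------------------


def _ground_truth_timelines(sc: WalkScenario, ev: dict) -> dict:
    tc = ev["tc"]
    timelines = {}
    for leg in ("left", "right"):
        tpl = sc.template_for(leg)
        lr, mst = tpl["LoadingResponse"] / 100.0, tpl["MidStance"] / 100.0
        tst = tpl["TerminalStance"] / 100.0
        steps = [i for i, l in enumerate(ev["legs"]) if l == leg]
        entries = [(0.0, "MidStance")]
        for k, i in enumerate(steps):
            if k == 0:
                if i == 0:
                    entries += [(ev["t_dest"], "TerminalStance"), (float(ev["to"][0]), "PreSwing")]
                else:
                    tst_start = float(ev["hc"][i - 1] - tst * tc)
                    entries += [(tst_start, "TerminalStance"), (float(ev["hc"][i - 1]), "PreSwing")]
            else:
                prev_ic = float(ev["hc"][steps[k - 1]])
                entries += [
                    (prev_ic + (lr + mst) * tc, "TerminalStance"),
                    (float(ev["hc"][i - 1]), "PreSwing"),
                ]
            entries += [
                (float(ev["to"][i]), "InitialSwing"),
                (float(ev["t_pass"][i]), "MidSwing"),
                (float(ev["t_align"][i]), "TerminalSwing"),
                (float(ev["hc"][i]), "LoadingResponse"),
                (float(ev["hc"][i] + lr * tc), "MidStance"),
            ]
        timelines[leg] = PhaseTimeline(leg=leg, entries=entries, end_time=ev["end"])
    return timelines


# ---------------------------------------------------------------------------
# foot kinematics
# ---------------------------------------------------------------------------


def _leg_steps(ev: dict, leg: str) -> list[int]:
    return [i for i, l in enumerate(ev["legs"]) if l == leg]


def synthesize_foot_kinematics(result: SimResult, subject: SubjectModel) -> dict:
    """Foot pose, ankle and knee channels honoring every kinematic rule.

    The joints are idealized trajectories anchored at the ground-truth event
    times (ankle passing at the ISw/MSw boundary, shank verticality at the
    MSw/TSw boundary) rather than a strict rigid linkage with the foot body.
    """
    sc, ev = result.scenario, result.events
    t = result.time
    tc = ev["tc"]
    theta_flat = np.arcsin(0.025 / _FOOT_LEN)  # matches the default foot-flat threshold
    shank = subject.segment("r_lower_leg").length
    align_angle = np.arcsin(0.020 / shank)  # matches the default alignment tolerance
    cols: dict[str, np.ndarray] = {}

    for leg in ("left", "right"):
        y_f = _FOOT_Y[leg]
        steps = _leg_steps(ev, leg)
        pitch = np.zeros(len(t))  # toe-up positive
        ox = np.full(len(t), -_ANKLE_BACK)
        oz = np.zeros(len(t))
        ankle_x = np.zeros(len(t))
        ankle_z = np.full(len(t), _ANKLE_H)
        shank_ang = np.full(len(t), _STANCE_SHANK)

        def stance_flat(mask, heel_x):
            ox[mask] = heel_x
            oz[mask] = 0.0
            pitch[mask] = 0.0

        def heel_pivot(mask, heel_x, th):
            # rotation about the heel point (origin stays on the ground)
            ox[mask] = heel_x
            oz[mask] = 0.0
            pitch[mask] = th

        def toe_pivot(mask, heel_x, phi):
            # rotation about the toe tip; heel rises
            toe_x = heel_x + _FOOT_LEN
            ox[mask] = toe_x - _FOOT_LEN * np.cos(phi)
            oz[mask] = _FOOT_LEN * np.sin(phi)
            pitch[mask] = -phi

        def interp(tt, knots_t, knots_v):
            return np.interp(tt, knots_t, knots_v)

        # per-step segments; between them the foot stands at its current spot
        cur_ankle = 0.0
        prev_ic = None  # time of this leg's last IC
        seg_end_prev = 0.0
        for k, i in enumerate(steps):
            to_i, hc_i = float(ev["to"][i]), float(ev["hc"][i])
            land = float(ev["landing_x"][i])
            heel_here = cur_ankle - _ANKLE_BACK
            # --- stance before toe-off ---------------------------------
            if k == 0:
                tst_start = ev["t_dest"] if i == 0 else float(ev["hc"][i - 1]) - sc.template_for(leg)["TerminalStance"] / 100.0 * tc
            else:
                lrmst = (sc.template_for(leg)["LoadingResponse"] + sc.template_for(leg)["MidStance"]) / 100.0
                tst_start = float(ev["hc"][steps[k - 1]]) + lrmst * tc
            ramp0 = tst_start - 0.04 * tc  # pre-ramp so the heel crosses the
            # flat threshold exactly at the Mid-/Terminal-Stance boundary
            m = (t >= seg_end_prev) & (t < ramp0)
            if prev_ic is None:
                stance_flat(m, heel_here)
            else:
                # flat after the Loading-Response flattening
                lr_end = prev_ic + sc.template_for(leg)["LoadingResponse"] / 100.0 * tc
                m_lr = m & (t < lr_end)
                heel_pivot(m_lr, heel_here, interp(t[m_lr], [prev_ic, lr_end], [_THETA_IC, theta_flat]))
                flat_t = lr_end + 0.3 * sc.template_for(leg)["MidStance"] / 100.0 * tc
                m_fl = m & (t >= lr_end)
                heel_pivot(
                    m_fl,
                    heel_here,
                    np.clip(interp(t[m_fl], [lr_end, flat_t], [theta_flat, 0.0]), 0.0, None),
                )
            m = (t >= ramp0) & (t < to_i)
            phi = interp(t[m], [ramp0, tst_start, to_i], [0.0, theta_flat, _PHI_MAX])
            toe_pivot(m, heel_here, phi)
            ankle_x[(t >= seg_end_prev) & (t < to_i)] = cur_ankle
            # --- swing -------------------------------------------------
            m = (t >= to_i) & (t < hc_i)
            sw = hc_i - to_i
            x0 = heel_here + _FOOT_LEN * (1.0 - np.cos(_PHI_MAX))
            h_new = land - _ANKLE_BACK
            ck_t = [to_i, to_i + 0.6 * sw, hc_i]
            ck_x = [x0, x0 + 0.75 * (h_new - x0), h_new]
            ox[m] = PchipInterpolator(ck_t, ck_x)(t[m])
            pitch[m] = interp(t[m], [to_i, hc_i], [-_PHI_MAX, _THETA_IC])
            clr = PchipInterpolator(
                [to_i, to_i + 0.25 * sw, to_i + 0.5 * sw, to_i + 0.85 * sw, hc_i],
                [0.0, 0.035, 0.05, 0.03, 0.0],
            )(t[m])
            lowest = np.minimum(0.0, _FOOT_LEN * np.sin(pitch[m]))
            oz[m] = clr - lowest
            # ankle: passes the support ankle exactly at the ISw/MSw boundary
            t_pass = float(ev["t_pass"][i])
            supp_ankle = float(ev["support_x"][i])
            if t_pass <= to_i + 1e-9:
                ka_t, ka_x = [to_i, to_i + 0.5 * sw, hc_i], [cur_ankle, cur_ankle + 0.6 * (land - cur_ankle), land]
            else:
                ka_t, ka_x = [to_i, t_pass, hc_i], [cur_ankle, supp_ankle, land]
            ankle_x[m] = PchipInterpolator(ka_t, ka_x)(t[m])
            ankle_z[m] = _ANKLE_H + 0.06 * np.sin(np.pi * (t[m] - to_i) / sw)
            shank_ang[m] = interp(
                t[m], [to_i, float(ev["t_align"][i]), hc_i], [_SHANK_TO_ANGLE, align_angle, 0.0]
            )
            cur_ankle = land
            prev_ic = hc_i
            seg_end_prev = hc_i
        # --- final stance to the end of the recording ------------------
        m = t >= seg_end_prev
        heel_here = cur_ankle - _ANKLE_BACK
        if prev_ic is None:
            stance_flat(m, heel_here)
        else:
            lr_end = prev_ic + sc.template_for(leg)["LoadingResponse"] / 100.0 * tc
            m_lr = m & (t < lr_end)
            heel_pivot(m_lr, heel_here, interp(t[m_lr], [prev_ic, lr_end], [_THETA_IC, theta_flat]))
            flat_t = lr_end + 0.1 * tc
            m_fl = m & (t >= lr_end)
            heel_pivot(
                m_fl,
                heel_here,
                np.clip(interp(t[m_fl], [lr_end, flat_t], [theta_flat, 0.0]), 0.0, None),
            )
        ankle_x[m] = cur_ankle

        quats = Rotation.from_euler("y", (-pitch)[:, None]).as_quat(scalar_first=True)
        f = leg[0]
        cols[f"foot_{f}_pos_x"] = ox
        cols[f"foot_{f}_pos_y"] = np.full(len(t), y_f)
        cols[f"foot_{f}_pos_z"] = oz
        for j, c in enumerate("wxyz"):
            cols[f"foot_{f}_quat_{c}"] = quats[:, j]
        cols[f"joint_{f}_ankle_x"] = ankle_x
        cols[f"joint_{f}_ankle_y"] = np.full(len(t), y_f)
        cols[f"joint_{f}_ankle_z"] = ankle_z
        cols[f"joint_{f}_knee_x"] = ankle_x + shank * np.sin(shank_ang)
        cols[f"joint_{f}_knee_y"] = np.full(len(t), y_f)
        cols[f"joint_{f}_knee_z"] = ankle_z + shank * np.cos(shank_ang)
    return cols


# ---------------------------------------------------------------------------
# ground reaction forces
# ---------------------------------------------------------------------------


def _interp_knots(ts, knots):
    kt = np.array([k[0] for k in knots])
    kv = np.array([k[1] for k in knots])
    order = np.argsort(kt, kind="stable")
    return np.interp(ts, kt[order], kv[order])


def _full_stance_knots(ic, lr_end, mst_end, psw_start, to, tc, toe_delta=0.0):
    """Heel/toe knots (fractions of BW) for a steady walking stance."""
    lr_d, mst_d = lr_end - ic, mst_end - lr_end
    tst_d, psw_d = psw_start - mst_end, to - psw_start
    heel = [
        (ic, 0.0),
        (ic + 0.3 * lr_d, 0.95),
        (lr_end, 0.90),
        (lr_end + 0.5 * mst_d, 0.47),
        (mst_end, 0.03),
        (mst_end + 0.2 * tst_d, 0.0),
        (to, 0.0),
    ]
    d = toe_delta
    toe = [
        (ic, 0.0),
        (lr_end - 1e-9, 0.0),
        (lr_end, 0.30),
        (lr_end + 0.5 * mst_d, 0.73 + d),
        (mst_end, 0.92 + d),
        (mst_end + 0.5 * tst_d, 1.05 + d),
        (psw_start, 0.85 + d),
        (psw_start + 0.5 * psw_d, 0.45 + d),
        (to - 0.03 * tc, 0.08),
        (to, 0.0),
    ]
    return heel, toe


def _steady_toe_delta(tc, tpl) -> float:
    """Additive correction to the interior toe knots so one stance
    integrates to 0.5 * Tc * BW (total force averages body weight)."""
    lr = tpl["LoadingResponse"] / 100.0 * tc
    mst = tpl["MidStance"] / 100.0 * tc
    tst = tpl["TerminalStance"] / 100.0 * tc
    psw = tpl["PreSwing"] / 100.0 * tc
    ic = 0.0
    grid = np.linspace(0.0, lr + mst + tst + psw, 4001)

    def integral(d):
        heel, toe = _full_stance_knots(ic, lr, lr + mst, lr + mst + tst, lr + mst + tst + psw, tc, d)
        return np.trapezoid(_interp_knots(grid, heel) + _interp_knots(grid, toe), grid)

    i0, i1 = integral(0.0), integral(0.1)
    target = 0.5 * tc
    return 0.1 * (target - i0) / (i1 - i0)


def synthesize_force_plates(
    result: SimResult, subject: SubjectModel, kinematics: dict | None = None
) -> dict:
    """Plate position/force/torque channels realizing the true ZMP.

    Vertical forces follow the two-peak stance profile (120 % BW at the end
    of Loading Response); horizontal force equals the foot's share of
    M * xdd; plate pitch torques are solved per sample so that the
    moment-balance ZMP of the four plates equals the simulator's ZMP.
    """
    sc, ev = result.scenario, result.events
    t = result.time
    tc = ev["tc"]
    bw = subject.mass * GRAVITY
    if kinematics is None:
        kinematics = synthesize_foot_kinematics(result, subject)

    n = len(t)
    frac = {}  # (leg, plate) -> BW fraction arrays
    # first pass: the first stepper's own profile (needed for complement)
    first_leg = ev["legs"][0]
    other_leg = "left" if first_leg == "right" else "right"

    def leg_profiles(leg, opp_total=None):
        tpl = sc.template_for(leg)
        lr_tc = tpl["LoadingResponse"] / 100.0 * tc
        tst_tc = tpl["TerminalStance"] / 100.0 * tc
        steps = _leg_steps(ev, leg)
        heel_kn: list = []
        toe_kn: list = []
        delta = _steady_toe_delta(tc, tpl)

        def add_standing(t0, t1, total0=0.5, total1=0.5):
            heel_kn.extend([(t0, 0.6 * total0), (t1, 0.6 * total1)])
            toe_kn.extend([(t0, 0.4 * total0), (t1, 0.4 * total1)])

        if not steps:
            # stance leg of a stepping trial: complement of the stepper
            t_to0, t_hc0 = float(ev["to"][0]), float(ev["hc"][0])
            for tt, v in opp_total:
                if tt <= t_to0 + 1e-12:
                    heel_kn.append((tt, 0.6 * (1.0 - v)))
                    toe_kn.append((tt, 0.4 * (1.0 - v)))
            heel_kn += [(t_hc0, 0.6), (t_hc0 + 0.15 * tc, 0.30), (ev["end"], 0.30)]
            toe_kn += [(t_hc0, 0.4), (t_hc0 + 0.15 * tc, 0.20), (ev["end"], 0.20)]
            return heel_kn, toe_kn

        for k, i in enumerate(steps):
            to_i, hc_i = float(ev["to"][i]), float(ev["hc"][i])
            if k == 0 and i == 0:
                # quiet standing, then walk-start destabilization
                td = ev["t_dest"]
                heel_kn += [(0.0, 0.30), (td - 0.10 * tc, 0.30), (td, 0.03), (td + 0.04 * tc, 0.0), (to_i, 0.0)]
                toe_kn += [
                    (0.0, 0.20),
                    (td - 0.10 * tc, 0.20 + 0.27),  # weight moves to the forefoot
                    (td, 0.47),
                    (to_i - 0.03 * tc, 0.08),
                    (to_i, 0.0),
                ]
            elif k == 0:
                # window-0 support leg: complement until the first toe-off,
                # then its own unloading toward its first swing
                t_to0 = float(ev["to"][0])
                for tt, v in opp_total:
                    if tt <= t_to0 + 1e-12:
                        heel_kn.append((tt, 0.6 * (1.0 - v)))
                        toe_kn.append((tt, 0.4 * (1.0 - v)))
                tst_start = float(ev["hc"][i - 1]) - tst_tc
                psw_start = float(ev["hc"][i - 1])
                psw_d = to_i - psw_start
                heel_kn += [
                    (tst_start - 0.10 * tc, 0.60),
                    (tst_start, 0.03),
                    (tst_start + 0.04 * tc, 0.0),
                    (to_i, 0.0),
                ]
                toe_kn += [
                    (t_to0, 0.40),
                    (tst_start - 0.10 * tc, 0.45),
                    (tst_start, 1.02),
                    (tst_start + 0.5 * tst_tc, 1.05),
                    (psw_start, 0.85),
                    (psw_start + 0.5 * psw_d, 0.45),
                    (to_i - 0.03 * tc, 0.08),
                    (to_i, 0.0),
                ]
            else:
                # steady pre-toe-off handled by the previous landing's
                # full-stance knots
                pass
            # --- landing side ------------------------------------------
            lr_end = hc_i + lr_tc
            last_own = k == len(steps) - 1
            if not last_own:
                i2 = steps[k + 1]
                mst_end = hc_i + (tpl["LoadingResponse"] + tpl["MidStance"]) / 100.0 * tc
                h, tkn = _full_stance_knots(
                    hc_i, lr_end, mst_end, float(ev["hc"][i2 - 1]), float(ev["to"][i2]), tc, delta
                )
                heel_kn += h
                toe_kn += tkn
            else:
                later_opp = [j for j in range(len(ev["legs"])) if j > i]
                if later_opp:
                    # trailing foot: opposite foot still lands after us;
                    # decay to quiet standing without a heel rise
                    hc_next = float(ev["hc"][later_opp[0]])
                    heel_kn += [
                        (hc_i, 0.0),
                        (hc_i + 0.3 * lr_tc, 0.95),
                        (lr_end, 0.90),
                        (hc_next, 0.45),
                        (hc_next + 0.15 * tc, 0.30),
                        (ev["end"], 0.30),
                    ]
                    toe_kn += [
                        (lr_end - 1e-9, 0.0),
                        (lr_end, 0.30),
                        (hc_next, 0.55),
                        (hc_next + 0.15 * tc, 0.20),
                        (ev["end"], 0.20),
                    ]
                else:
                    # final landing: braking onto this foot
                    heel_kn += [
                        (hc_i, 0.0),
                        (hc_i + 0.4 * lr_tc, 0.75),
                        (lr_end, 0.55),
                        (lr_end + 0.15 * tc, 0.30),
                        (ev["end"], 0.30),
                    ]
                    toe_kn += [
                        (lr_end - 1e-9, 0.0),
                        (lr_end, 0.15),
                        (lr_end + 0.15 * tc, 0.20),
                        (ev["end"], 0.20),
                    ]
        return heel_kn, toe_kn

    heel1, toe1 = leg_profiles(first_leg)
    total1 = sorted({tt for tt, _ in heel1 + toe1})
    total1 = [(tt, float(_interp_knots([tt], heel1)[0] + _interp_knots([tt], toe1)[0])) for tt in total1]
    heel2, toe2 = leg_profiles(other_leg, opp_total=total1)
    frac[(first_leg, "heel")] = _interp_knots(t, heel1)
    frac[(first_leg, "toe")] = _interp_knots(t, toe1)
    frac[(other_leg, "heel")] = _interp_knots(t, heel2)
    frac[(other_leg, "toe")] = _interp_knots(t, toe2)

    # COM acceleration (exact from the model) for horizontal shear forces
    z1, z2 = result.params.zeta1, result.params.zeta2
    xdd = z1 * z2 * (result.com_x - result.true_zmp) + (z1 - z2) * result.com_xdot

    cols: dict[str, np.ndarray] = {}
    plate_keys = []
    fz_total = np.zeros(n)
    for leg in ("left", "right"):
        f = leg[0]
        pos_f = np.column_stack([kinematics[f"foot_{f}_pos_{c}"] for c in "xyz"])
        quat_f = np.column_stack([kinematics[f"foot_{f}_quat_{c}"] for c in "wxyz"])
        rot = Rotation.from_quat(quat_f, scalar_first=True)
        for plate in ("heel", "toe"):
            key = f"{f}_{plate}"
            p = rot.apply(np.tile(_PLATE_LOCAL[plate], (n, 1))) + pos_f
            fz = np.clip(frac[(leg, plate)], 0.0, None) * bw
            plate_keys.append((key, p, fz))
            fz_total += fz
            for j, c in enumerate("xyz"):
                cols[f"plate_{key}_pos_{c}"] = p[:, j]
    fz_total = np.maximum(fz_total, 1e-9)
    # horizontal force shared by vertical-load fraction; pitch torques close
    # the moment balance so the plate ZMP equals the true ZMP exactly
    sum_xfz = np.zeros(n)
    sum_zfx = np.zeros(n)
    for key, p, fz in plate_keys:
        share = fz / fz_total
        fx = share * subject.mass * xdd
        cols[f"plate_{key}_f_x"] = fx
        cols[f"plate_{key}_f_y"] = np.zeros(n)
        cols[f"plate_{key}_f_z"] = fz
        sum_xfz += p[:, 0] * fz
        sum_zfx += p[:, 2] * fx
    ny_total = sum_xfz - sum_zfx - result.true_zmp * fz_total
    for key, p, fz in plate_keys:
        share = fz / fz_total
        cols[f"plate_{key}_n_x"] = np.zeros(n)
        cols[f"plate_{key}_n_y"] = share * ny_total
        cols[f"plate_{key}_n_z"] = np.zeros(n)
    return cols


# ---------------------------------------------------------------------------
# lateral sway, turning, noise, assembly
# ---------------------------------------------------------------------------


def _lateral_sway(sc: WalkScenario, ev: dict, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(ev["legs"]) < 2:
        return np.zeros(len(t)), np.zeros(len(t))
    t0 = float(ev["to"][0])
    amp = 0.03
    # support alternates each window; first window's support is the
    # opposite of the first stepper
    sign = 1.0 if ev["legs"][0] == "right" else -1.0
    raw = sign * amp * np.sin(np.pi * (t - t0) / sc.step_duration)
    ramp = np.clip((t - ev["t_dest"]) / (t0 - ev["t_dest"]), 0.0, 1.0)
    fade = np.clip(1.0 - (t - float(ev["hc"][-1])) / (0.5 * ev["tc"]), 0.0, 1.0)
    y = raw * ramp * fade
    dy = np.gradient(y, t)
    return y, dy


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _apply_turn(sc: WalkScenario, ev: dict, df: pd.DataFrame) -> pd.DataFrame:
    """Map the forward-frame trial onto a curved path with a heading change.

    The trial is generated in the trunk-heading local frame and mapped to
    the global frame as the exact inverse of the rectified local-frame
    transform: the trunk heading follows a smoothstep from 0 to the turn
    angle (spread over ~3.5 step lengths, a natural curved-walking radius),
    the waist's global path integrates its local increments rotated by the
    instantaneous heading, and every other channel is carried rigidly per
    sample (positions relative to the waist, vectors and orientations
    rotated by the heading).  The trunk-relative geometry of the straight
    walk is therefore preserved exactly; the price is that ground-fixed
    points are only approximately stationary in the global frame (a planted
    foot drifts by a few centimetres while the heading changes).
    """
    angle = np.radians(sc.turn_angle)
    step = sc.turn_step if sc.turn_step is not None else sc.n_steps // 2
    length = 3.5 * sc.stride  # heading change spread over ~3.5 steps
    s_com = df["com_x"].to_numpy()
    s0 = float(ev["landing_x"][min(step, sc.n_steps - 1)]) - 0.5 * length
    psi = angle * _smoothstep((s_com - s0) / length)  # per-sample trunk heading
    c, s = np.cos(psi), np.sin(psi)

    # waist (trunk) global path: integrate the local waist increments
    # rotated by the instantaneous heading
    wx_l = df["joint_waist_x"].to_numpy()
    wy_l = df["joint_waist_y"].to_numpy()
    dxl, dyl = np.diff(wx_l), np.diff(wy_l)
    cm, sm = np.cos(0.5 * (psi[1:] + psi[:-1])), np.sin(0.5 * (psi[1:] + psi[:-1]))
    wx_g = wx_l[0] + np.concatenate([[0.0], np.cumsum(cm * dxl - sm * dyl)])
    wy_g = wy_l[0] + np.concatenate([[0.0], np.cumsum(sm * dxl + cm * dyl)])

    out = df.copy()
    pos_prefixes = ["com", "foot_l_pos", "foot_r_pos", "joint_l_ankle", "joint_r_ankle",
                    "joint_l_knee", "joint_r_knee", "joint_waist"]
    pos_prefixes += [f"plate_{p}_pos" for p in ("l_heel", "l_toe", "r_heel", "r_toe")]
    vec_prefixes = ["dcom"]
    vec_prefixes += [f"plate_{p}_{cc}" for p in ("l_heel", "l_toe", "r_heel", "r_toe") for cc in ("f", "n")]

    for pref in pos_prefixes:
        rx = df[f"{pref}_x"].to_numpy() - wx_l
        ry = df[f"{pref}_y"].to_numpy() - wy_l
        out[f"{pref}_x"] = wx_g + c * rx - s * ry
        out[f"{pref}_y"] = wy_g + s * rx + c * ry
    for pref in vec_prefixes:
        vx = df[f"{pref}_x"].to_numpy()
        vy = df[f"{pref}_y"].to_numpy()
        out[f"{pref}_x"] = c * vx - s * vy
        out[f"{pref}_y"] = s * vx + c * vy
    # orientations follow the trunk heading
    rot = Rotation.from_euler("z", psi[:, None])
    for pref in ("foot_l_quat", "foot_r_quat", "chest_quat"):
        q = np.column_stack([df[f"{pref}_{cc}"].to_numpy() for cc in "wxyz"])
        qn = (rot * Rotation.from_quat(q, scalar_first=True)).as_quat(scalar_first=True)
        for j, cc in enumerate("wxyz"):
            out[f"{pref}_{cc}"] = qn[:, j]
    return out


def _add_noise(df: pd.DataFrame, level: float, rng: np.random.Generator) -> pd.DataFrame:
    if level <= 0:
        return df
    out = df.copy()
    for c in df.columns:
        if c == "time_s" or "_quat_" in c or c.startswith("phase_"):
            continue
        if c.startswith("dcom"):
            sigma = DEFAULT_NOISE_SIGMA["velocity"]
        elif "_f_" in c:
            sigma = DEFAULT_NOISE_SIGMA["force"]
        elif "_n_" in c:
            sigma = DEFAULT_NOISE_SIGMA["torque"]
        else:
            sigma = DEFAULT_NOISE_SIGMA["position"]
        out[c] = df[c].to_numpy() + level * sigma * rng.standard_normal(len(df))
    return out


def simulate_walk(scenario: WalkScenario) -> SimResult:
    """Run the closed-loop simulator and synthesize a full recording.

    Deterministic given ``scenario.seed``; two runs with the same scenario
    are bit-identical.
    """
    sc = scenario.realized()
    ev = _build_events(sc)
    tasks, schedule = _tasks_and_schedule(ev)
    t, x, xd, zmp = _integrate_com(sc, ev, tasks, schedule)
    capture = x + xd / sc.params.zeta2
    for i, task in enumerate(tasks):
        miss = abs(float(np.interp(task.T, t, capture)) - task.x_sd)
        if miss > 5e-3:
            raise ValueError(
                f"step {i} ({task.leg}) infeasible: capture point misses the "
                f"target by {miss * 1e3:.1f} mm within the support bounds"
            )
    timelines = _ground_truth_timelines(sc, ev)
    result = SimResult(
        scenario=sc,
        subject=sc.subject,
        params=sc.params,
        schedule=schedule,
        tasks=tasks,
        events=ev,
        timelines=timelines,
        time=t,
        com_x=x,
        com_xdot=xd,
        true_zmp=zmp,
    )
    kin = synthesize_foot_kinematics(result, sc.subject)
    plates = synthesize_force_plates(result, sc.subject, kinematics=kin)
    y, dy = _lateral_sway(sc, ev, t)
    cols = {"time_s": t}
    cols["com_x"] = x
    cols["com_y"] = y
    cols["com_z"] = np.full(len(t), sc.params.z_com)
    cols["dcom_x"] = xd
    cols["dcom_y"] = dy
    cols["dcom_z"] = np.zeros(len(t))
    cols.update(kin)
    cols.update(plates)
    cols["joint_waist_x"] = x
    cols["joint_waist_y"] = y
    cols["joint_waist_z"] = np.zeros(len(t))
    for j, c in enumerate("wxyz"):
        cols[f"chest_quat_{c}"] = np.full(len(t), 1.0 if c == "w" else 0.0)
    df = pd.DataFrame(cols)
    if sc.kind == "turn_walk":
        df = _apply_turn(sc, ev, df)
    rng = np.random.default_rng(sc.seed)
    df = _add_noise(df, sc.noise_level, rng)
    result.recording = GaitRecording(df)
    return result
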