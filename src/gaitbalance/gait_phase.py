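"""Rule-based detection of the seven Perry gait phases per leg.

One gait cycle runs from heel contact (Initial Contact, an instantaneous
event) to the next ipsilateral heel contact and is divided into Loading
Response, Mid-Stance, Terminal Stance, Pre-Swing (stance, ~62 % of the cycle)
and Initial Swing, Mid-Swing, Terminal Swing (swing, ~38 %).  Each boundary
has a force rule (toe/heel plate vertical force rising or falling through a
small fraction of body weight) and a kinematic rule (foot-shape
lowest/highest point, ankle passing, shank verticality).  The force rule is
primary whenever plate channels are present; the kinematic rule is the
fallback and a cross-check (disagreement beyond 5 samples is logged).

Zero-duration phases are permitted: at the start of walking there is no
boundary between Terminal Stance and Pre-Swing (the opposite foot never
lands) and Initial Swing can vanish when the feet start side by side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator

from .anthropometry import SubjectModel
from .dynamics import GRAVITY
from .recording import GaitRecording
from .zmp_estimation import default_insole_outline

logger = logging.getLogger(__name__)

__all__ = [
    "PHASES",
    "STANCE_PHASES",
    "SWING_PHASES",
    "DetectorThresholds",
    "PhaseTimeline",
    "GaitPhaseDetector",
    "detect_phases",
    "cycle_statistics",
    "bout_cycle_statistics",
    "phase_label_columns",
]

PHASES = (
    "LoadingResponse",
    "MidStance",
    "TerminalStance",
    "PreSwing",
    "InitialSwing",
    "MidSwing",
    "TerminalSwing",
)
STANCE_PHASES = PHASES[:4]
SWING_PHASES = PHASES[4:]
_NEXT = {p: PHASES[(i + 1) % 7] for i, p in enumerate(PHASES)}


@dataclass(frozen=True)
class DetectorThresholds:
    """Detection thresholds (all positive; defaults are design choices).

    floor_contact_dist / foot_flat_dist / clearance_dist are heights (m) of
    the foot-outline lowest/highest point; force_on is the contact force
    threshold as a fraction of body weight; knee_ankle_align_tol (m) tests
    shank verticality; debounce is in samples.
    """

    floor_contact_dist: float = 0.010
    foot_flat_dist: float = 0.025
    clearance_dist: float = 0.020
    force_on: float = 0.03
    knee_ankle_align_tol: float = 0.020
    debounce: int = 3

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PhaseTimeline:
    """Per-leg sequence of (start time, phase) pairs up to ``end_time``."""

    leg: str
    entries: list = field(default_factory=list)  # [(t_start, phase), ...]
    end_time: float = 0.0

    def __post_init__(self) -> None:
        times = [t for t, _ in self.entries]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("entry times must be non-decreasing")

    def intervals(self) -> list:
        """[(t0, t1, phase)] with t1 = next entry's start (or end_time)."""
        out = []
        for i, (t0, phase) in enumerate(self.entries):
            t1 = self.entries[i + 1][0] if i + 1 < len(self.entries) else self.end_time
            out.append((t0, t1, phase))
        return out

    def ic_times(self) -> np.ndarray:
        return np.array([t for t, p in self.entries if p == "LoadingResponse"])

    def toe_off_times(self) -> np.ndarray:
        return np.array([t for t, p in self.entries if p == "InitialSwing"])

    def event_time(self, phase: str, occurrence: int = 0) -> float:
        times = [t for t, p in self.entries if p == phase]
        return times[occurrence]

    def cycles(self) -> list:
        """Complete heel-contact-bounded cycles.

        Returns [(t_ic, t_ic_next, {phase: duration})]; every one of the 7
        phases appears (zero duration when skipped).
        """
        ics = self.ic_times()
        out = []
        for t0, t1 in zip(ics, ics[1:]):
            durs = dict.fromkeys(PHASES, 0.0)
            for a, b, phase in self.intervals():
                lo, hi = max(a, t0), min(b, t1)
                if hi > lo:
                    durs[phase] += hi - lo
            out.append((t0, t1, durs))
        return out


def _debounce(raw: np.ndarray, k: int) -> np.ndarray:
    """Hysteresis filter: the state flips only after k consecutive samples
    of the opposite value, retroactively from the first sample of the run
    (so a clean transition keeps its exact onset sample)."""
    if k <= 1:
        return raw.astype(bool).copy()
    out = np.empty(len(raw), dtype=bool)
    state = bool(raw[0])
    out[0] = state
    run_start = None
    for i in range(1, len(raw)):
        if bool(raw[i]) != state:
            run_start = i if run_start is None else run_start
            if i - run_start + 1 >= k:
                state = bool(raw[i])
                out[run_start : i + 1] = state
                run_start = None
            else:
                out[i] = state
        else:
            run_start = None
            out[i] = state
    return out


def _rising(b: np.ndarray) -> np.ndarray:
    e = np.zeros(len(b), dtype=bool)
    e[1:] = b[1:] & ~b[:-1]
    e[0] = b[0] and False
    return e


def _outline_extremes(positions, quats, outline) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (lowest, highest) z of the transformed foot outline."""
    rot = Rotation.from_quat(quats, scalar_first=True)
    n = len(positions)
    zmin = np.full(n, np.inf)
    zmax = np.full(n, -np.inf)
    for px, py in outline:
        p = np.tile([px, py, 0.0], (n, 1))
        z = rot.apply(p)[:, 2] + positions[:, 2]
        zmin = np.minimum(zmin, z)
        zmax = np.maximum(zmax, z)
    return zmin, zmax


class GaitPhaseDetector(BaseEstimator):
    """Per-leg gait-phase state machine over a :class:`GaitRecording`.

    Parameters mirror :class:`DetectorThresholds`; ``use_force`` selects the
    primary rule family (force when plates are available, else kinematic).
    The detector is stateless across recordings; ``detect`` returns one
    :class:`PhaseTimeline` per leg.
    """

    def __init__(
        self,
        floor_contact_dist: float = 0.010,
        foot_flat_dist: float = 0.025,
        clearance_dist: float = 0.020,
        force_on: float = 0.03,
        knee_ankle_align_tol: float = 0.020,
        debounce: int = 3,
        use_force: bool = True,
        outline=None,
    ):
        self.floor_contact_dist = floor_contact_dist
        self.foot_flat_dist = foot_flat_dist
        self.clearance_dist = clearance_dist
        self.force_on = force_on
        self.knee_ankle_align_tol = knee_ankle_align_tol
        self.debounce = debounce
        self.use_force = use_force
        self.outline = outline

    @property
    def thresholds(self) -> DetectorThresholds:
        return DetectorThresholds(
            floor_contact_dist=self.floor_contact_dist,
            foot_flat_dist=self.foot_flat_dist,
            clearance_dist=self.clearance_dist,
            force_on=self.force_on,
            knee_ankle_align_tol=self.knee_ankle_align_tol,
            debounce=self.debounce,
        )

    # -- signal preparation ---------------------------------------------
    def _signals(self, rec: GaitRecording, subject: SubjectModel) -> dict:
        outline = self.outline if self.outline is not None else default_insole_outline()
        f_thr = self.force_on * subject.mass * GRAVITY
        k = int(self.debounce)
        sig = {}
        for leg, f in (("left", "l"), ("right", "r")):
            pos, quats = rec.foot_pose(leg)
            zmin, zmax = _outline_extremes(pos, quats, outline)
            heel_fz = rec.col(f"plate_{f}_heel_f_z")
            toe_fz = rec.col(f"plate_{f}_toe_f_z")
            ankle = rec.joint(f"{f}_ankle")
            knee = rec.joint(f"{f}_knee")
            sig[leg] = {
                "zmin": zmin,
                "zmax": zmax,
                "heel_on": _debounce(heel_fz > f_thr, k),
                "toe_on": _debounce(toe_fz > f_thr, k),
                "foot_on": _debounce(heel_fz + toe_fz > f_thr, k),
                "low_contact": _debounce(zmin < self.floor_contact_dist, k),
                "flat": _debounce(zmax < self.foot_flat_dist, k),
                "clear": _debounce(zmin > self.clearance_dist, k),
                "ankle_x": ankle[:, 0],
                "knee_offset": np.hypot(knee[:, 0] - ankle[:, 0], knee[:, 1] - ankle[:, 1]),
            }
        for leg, opp in (("left", "right"), ("right", "left")):
            s, o = sig[leg], sig[opp]
            if self.use_force:
                sig[leg]["opp_ic"] = _rising(o["heel_on"])
                sig[leg]["ic"] = s["heel_on"]
                sig[leg]["lr_end"] = s["toe_on"]
                sig[leg]["mst_end"] = ~s["heel_on"]
                sig[leg]["psw_end"] = ~s["toe_on"]
            else:
                sig[leg]["opp_ic"] = _rising(o["low_contact"])
                sig[leg]["ic"] = s["low_contact"]
                sig[leg]["lr_end"] = s["flat"]
                sig[leg]["mst_end"] = ~s["flat"]
                sig[leg]["psw_end"] = s["clear"]
            sig[leg]["isw_end"] = s["ankle_x"] >= o["ankle_x"] - 1e-9
            sig[leg]["msw_end"] = s["knee_offset"] < self.knee_ankle_align_tol
        return sig

    # -- state machine ---------------------------------------------------
    def detect(self, recording: GaitRecording, subject: SubjectModel) -> dict:
        """Run detection; returns {"left": PhaseTimeline, "right": ...}."""
        t = recording.time
        sig = self._signals(recording, subject)
        timelines = {}
        for leg in ("left", "right"):
            s = sig[leg]
            state = "MidStance" if s["foot_on"][0] else "MidSwing"
            entries = [(t[0], state)]
            tst_entry_opp_ic = False
            for i in range(len(t)):
                for _ in range(7):  # allow zero-duration cascades
                    nxt = _NEXT[state]
                    if state == "TerminalStance" and s["opp_ic"][i]:
                        tst_entry_opp_ic = True
                    fire = {
                        "LoadingResponse": lambda: s["lr_end"][i],
                        "MidStance": lambda: s["mst_end"][i],
                        "TerminalStance": lambda: tst_entry_opp_ic,
                        "PreSwing": lambda: s["psw_end"][i],
                        "InitialSwing": lambda: s["isw_end"][i],
                        "MidSwing": lambda: s["msw_end"][i],
                        "TerminalSwing": lambda: s["ic"][i],
                    }[state]()
                    # start-of-walk special case: the opposite foot never
                    # lands, so Terminal Stance runs straight into toe-off
                    # (zero-duration Pre-Swing).
                    if state == "TerminalStance" and not fire and s["psw_end"][i] and not s["toe_on"][i] and not s["heel_on"][i]:
                        fire = True
                    if not fire:
                        break
                    state = nxt
                    entries.append((t[i], state))
                    if state == "TerminalStance":
                        tst_entry_opp_ic = False
            timelines[leg] = PhaseTimeline(leg=leg, entries=entries, end_time=t[-1])
        self._cross_check(timelines, sig, recording)
        return timelines

    # sklearn-style aliases: detection is a stateless transform
    def fit(self, recording: GaitRecording, subject: SubjectModel = None):
        return self

    def transform(self, recording: GaitRecording, subject: SubjectModel = None) -> dict:
        if subject is None:
            raise ValueError("transform requires the subject model")
        return self.detect(recording, subject)

    def _cross_check(self, timelines: dict, sig: dict, rec: GaitRecording) -> None:
        """Log IC events where force and kinematic rules disagree > 5 samples."""
        if not self.use_force:
            return
        dt = rec.dt
        t = rec.time
        for leg, tl in timelines.items():
            kin_ics = t[_rising(sig[leg]["low_contact"])]
            for t_ic in tl.ic_times():
                if len(kin_ics) == 0:
                    continue
                gap = np.min(np.abs(kin_ics - t_ic))
                if gap > 5 * dt:
                    logger.warning(
                        "%s IC at %.3f s: kinematic rule disagrees by %.0f samples",
                        leg,
                        t_ic,
                        gap / dt,
                    )


def detect_phases(
    recording: GaitRecording,
    model: SubjectModel,
    thresholds: DetectorThresholds | None = None,
    use_force: bool = True,
) -> dict:
    """Functional wrapper over :class:`GaitPhaseDetector`."""
    thr = thresholds or DetectorThresholds()
    det = GaitPhaseDetector(use_force=use_force, **asdict(thr))
    return det.detect(recording, model)


def cycle_statistics(timeline: PhaseTimeline, exclude: set | None = None) -> dict:
    """Per-phase percentages of the gait cycle and the stance/swing split.

    Parameters
    ----------
    timeline : PhaseTimeline
    exclude : set of int, optional
        Cycle indices to drop (e.g. transients flagged at bout level).

    Returns
    -------
    dict with ``n_cycles``, ``cycle_spans``, ``phase_pct`` (mean % per
    phase), ``stance_pct``, ``swing_pct``.  Percentages sum to 100.
    """
    cycles = timeline.cycles()
    keep = [c for i, c in enumerate(cycles) if not exclude or i not in exclude]
    if not keep:
        raise ValueError("no complete gait cycle available")
    pct = {p: [] for p in PHASES}
    spans = []
    for t0, t1, durs in keep:
        total = t1 - t0
        spans.append((t0, t1))
        for p in PHASES:
            pct[p].append(100.0 * durs[p] / total)
    phase_pct = {p: float(np.mean(v)) for p, v in pct.items()}
    stance = sum(phase_pct[p] for p in STANCE_PHASES)
    return {
        "leg": timeline.leg,
        "n_cycles": len(keep),
        "cycle_spans": spans,
        "phase_pct": phase_pct,
        "stance_pct": stance,
        "swing_pct": 100.0 - stance,
    }


def bout_cycle_statistics(timelines: dict, exclude_transient: bool = True) -> dict:
    """Statistics over a walking bout (both legs).

    The earliest-starting and latest-ending heel-contact-bounded cycles of
    the bout cover the start and braking transients; they are flagged as
    transient and excluded by default (the phase pattern is only steady in
    continuous walking).
    """
    all_cycles = []
    for leg, tl in timelines.items():
        for i, (t0, t1, _) in enumerate(tl.cycles()):
            all_cycles.append((leg, i, t0, t1))
    if not all_cycles:
        raise ValueError("no complete gait cycle in either leg")
    exclude = {"left": set(), "right": set()}
    if exclude_transient and len(all_cycles) > 1:
        first = min(all_cycles, key=lambda c: c[2])
        last = max(all_cycles, key=lambda c: c[3])
        exclude[first[0]].add(first[1])
        exclude[last[0]].add(last[1])
    per_leg = {}
    for leg, tl in timelines.items():
        try:
            per_leg[leg] = cycle_statistics(tl, exclude=exclude[leg])
        except ValueError:
            per_leg[leg] = None
    kept = [s for s in per_leg.values() if s]
    if not kept:
        raise ValueError("no steady gait cycle after transient exclusion")
    return {
        "per_leg": per_leg,
        "stance_pct": float(np.mean([s["stance_pct"] for s in kept])),
        "swing_pct": float(np.mean([s["swing_pct"] for s in kept])),
    }


def phase_label_columns(timelines: dict, time: np.ndarray) -> dict:
    """Per-sample phase label arrays, e.g. for appending to a recording."""
    out = {}
    for leg, tl in timelines.items():
        labels = np.empty(len(time), dtype=object)
        labels[:] = ""
        for t0, t1, phase in tl.intervals():
            labels[(time >= t0) & (time < t1)] = phase
        if tl.entries:
            labels[time >= tl.entries[-1][0]] = tl.entries[-1][1]
        out[f"phase_{leg[0]}"] = labels
    return out
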