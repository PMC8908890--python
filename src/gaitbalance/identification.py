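"""Identification of the walking balance-control parameters.

The forward model is the bilateral capture-point MPC law evaluated along the
*measured* COM trajectory: within each controller window (toe-off to
opposite toe-off, split at the intervening heel contact) the model ZMP is

    x_zmp(t) = sat( xP + 2*(xCP - e^{-zeta1 (T-t)} xSP) / (1 - e^{-2 zeta1 (T-t)}) )

with xCP = x + xd/zeta2 - xP, xSP = xSd - xP, the horizon clamped at a
small floor, and saturation to the support area around the axle.  Windows
are split at heel contact and each section gets its own axle xP: before
heel contact the window's own task applies; after it the landed foot is the
axle and the next window's task (or, for the last window, the
infinite-horizon braking limit) applies.  The fit minimizes the mean
squared error between this model and the sensor ZMP (four-plate moment
balance) over all sections, over zeta1 and one axle per section, with
zeta2 = C/zeta1 under an optional product constraint C (the
stepping/braking studies use C = 8.67 1/s^2) or free otherwise.  Landing
targets xSd and the toe-off / heel-contact times are taken from the
detected (or ground-truth) phase timeline, not co-estimated.

For walking that is not straight, recordings are first expressed in a
trunk-heading local frame (arc-length-rectified forward coordinate, chest
heading as X) and the same forward-axis model is fitted there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.optimize import minimize, minimize_scalar
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator

from .controller import HEEL_BOUND_OFFSET, HORIZON_FLOOR, TOE_BOUND_OFFSET
from .recording import GaitRecording
from .zmp_estimation import measured_zmp_series

__all__ = [
    "FitSegment",
    "FitResult",
    "segment_trials",
    "ControllerIdentifier",
    "fit_controller",
    "model_zmp_trace",
    "to_local_frame",
    "from_local_frame",
]


@dataclass(frozen=True)
class FitSegment:
    """One fitted sub-segment of a controller window.

    ``leg`` is the swinging leg of the window; ``context`` is ``pre_hc``
    (single support up to the landing) or ``post_hc`` (double support after
    it); ``hc_time`` is the window's horizon T.
    """

    leg: str
    window: int
    t_start: float
    t_end: float
    context: str
    hc_time: float


def segment_trials(timelines: dict, end_time: float | None = None) -> list[FitSegment]:
    """Windows from each toe-off to the opposite toe-off, split at the
    swinging leg's heel contact.

    Parameters
    ----------
    timelines : {"left": PhaseTimeline, "right": PhaseTimeline}
        From the detector or the simulator ground truth.
    end_time : float, optional
        Close of the last window (defaults to the timelines' end).
    """
    events = []
    for leg, tl in timelines.items():
        for t in tl.toe_off_times():
            events.append((float(t), leg))
    events.sort()
    if not events:
        return []
    if end_time is None:
        end_time = max(tl.end_time for tl in timelines.values())
    for (t0, a), (t1, b) in zip(events, events[1:]):
        if a == b:
            raise ValueError(f"consecutive toe-offs of the same leg at {t0:.3f} and {t1:.3f} s")
    segments = []
    for w, (t0, leg) in enumerate(events):
        t1 = events[w + 1][0] if w + 1 < len(events) else end_time
        ics = timelines[leg].ic_times()
        ics = ics[(ics > t0 + 1e-9) & (ics <= t1 + 1e-9)]
        if len(ics):
            hc = float(ics[0])
            segments.append(FitSegment(leg, w, t0, hc, "pre_hc", hc))
            if t1 > hc:
                segments.append(FitSegment(leg, w, hc, t1, "post_hc", hc))
        else:
            segments.append(FitSegment(leg, w, t0, t1, "pre_hc", t1))
    return segments


@dataclass
class FitResult:
    """Fitted controller parameters and fit quality."""

    zeta1: float
    zeta2: float
    x_p: list
    x_sd: dict
    rmse: float
    constraint_product: float | None
    converged: bool
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        if self.constraint_product is not None:
            prod = self.zeta1 * self.zeta2
            if abs(prod - self.constraint_product) > 1e-9 * self.constraint_product:
                raise ValueError("constraint product violated")


def _segment_model_zmp(t, x, xd, zeta1, zeta2, x_p, x_sd, T, clip=False):
    """Vectorized window law along measured states.

    Pre-heel-contact sections use the window's own finite-horizon task.
    Post-heel-contact sections anchor at the landed foot with the *next*
    window's task (``T``/``x_sd`` of the following step); a final section
    with no successor uses the infinite-horizon braking limit (``T = None``).

    ``clip`` adds the support-area saturation around the axle.  It is on
    for double-support (post-heel-contact) sections, where the commanded
    ZMP genuinely rides the heel-side bound of the just-landed foot and
    the measured plateau pins the axle; it is off for single-support
    sections, where the command stays interior on walking trajectories and
    a saturated branch would let least squares park noisy samples on the
    noise-free clip bound, biasing the axle estimate.  Unclipped, the law
    is linear in x_p with response-side noise only, so the axle fit is
    unbiased.
    """
    xcp = x + xd / zeta2 - x_p
    if T is None:
        zmp = x_p + 2.0 * xcp
    else:
        tau = np.maximum(T - t, HORIZON_FLOOR)
        e1 = np.exp(-zeta1 * tau)
        zmp = x_p + 2.0 * (xcp - e1 * (x_sd - x_p)) / (1.0 - e1 * e1)
    if clip:
        zmp = np.clip(zmp, x_p - HEEL_BOUND_OFFSET, x_p + TOE_BOUND_OFFSET)
    return zmp


class ControllerIdentifier(BaseEstimator):
    """Scikit-learn-style estimator for the balance-controller parameters.

    Parameters
    ----------
    constraint_product : float or None
        If set, enforce zeta1 * zeta2 = constraint_product (1/s^2).
    zeta_bounds : (float, float)
        Search interval for zeta1 (and zeta2 when unconstrained), 1/s.
    n_starts : int
        Multi-start budget for the derivative-free outer optimization.
    seed : int
        Seeds the start points; the fit is deterministic given the seed.

    Attributes (after ``fit``)
    --------------------------
    zeta1_, zeta2_ : float
        Divergent / convergent eigenvalue magnitudes (1/s).
    x_p_ : list of float
        Fitted axle position per segment (m).
    rmse_ : float
        Root-mean-square model-vs-measured ZMP error (m).
    result_ : FitResult
    """

    def __init__(
        self,
        constraint_product: float | None = None,
        zeta_bounds: tuple = (1.0, 10.0),
        n_starts: int = 8,
        seed: int = 0,
        tau_floor: float = 0.03,
        x_p_radius: float = 0.10,
    ):
        self.constraint_product = constraint_product
        self.zeta_bounds = zeta_bounds
        self.n_starts = n_starts
        self.seed = seed
        # samples closer than tau_floor to the landing are excluded from the
        # objective: there the law's gain diverges like 1/(zeta1*(T-t)) and a
        # single sample would dominate the fit with a near-singular
        # sensitivity (the model itself still covers them)
        self.tau_floor = tau_floor
        # the axle is searched within this radius of the support ankle; the
        # foot cannot be further from its own ankle channel than this
        self.x_p_radius = x_p_radius

    # -- data extraction -------------------------------------------------
    def _prepare(self, recording: GaitRecording, segments: list):
        t = recording.time
        x = recording.col("com_x")
        xd = recording.col("dcom_x")
        z_meas = measured_zmp_series(recording)
        # landing target and horizon per window, from the timeline/recording
        x_sd = {}
        hc_of = {}
        for seg in segments:
            hc_of.setdefault(seg.window, seg.hc_time)
            if seg.window not in x_sd:
                swing = seg.leg[0]
                hc_mask = (t >= seg.hc_time - 1e-9) & (t <= seg.hc_time + 0.15)
                if np.any(hc_mask):
                    x_sd[seg.window] = float(
                        np.median(recording.col(f"joint_{swing}_ankle_x")[hc_mask])
                    )
        data = []
        for seg in segments:
            mask = (t >= seg.t_start - 1e-9) & (t < seg.t_end - 1e-9)
            mask &= np.isfinite(z_meas)
            if seg.context == "pre_hc":
                mask &= t < seg.hc_time - self.tau_floor
            if not np.any(mask):
                continue
            if seg.context == "pre_hc":
                T, sd = seg.hc_time, x_sd.get(seg.window)
                anchor_leg = "l" if seg.leg == "right" else "r"  # support foot
            else:
                # double support: the landed foot is the axle and the next
                # window's task drives (braking when there is no successor)
                T, sd = hc_of.get(seg.window + 1), x_sd.get(seg.window + 1)
                anchor_leg = seg.leg[0]
            guess = float(np.median(recording.col(f"joint_{anchor_leg}_ankle_x")[mask]))
            data.append(
                {
                    "segment": seg,
                    "t": t[mask],
                    "x": x[mask],
                    "xd": xd[mask],
                    "z": z_meas[mask],
                    "T": T,
                    "x_sd": sd,
                    "guess": guess,
                    "radius": self.x_p_radius,
                    "clip": seg.context == "post_hc" and T is not None,
                }
            )
        return data, x_sd

    @staticmethod
    def _segment_sse(d, zeta1, zeta2):
        """Best-x_p squared error for one segment; returns (sse, x_p)."""

        def model(xp, t, x, xd):
            return _segment_model_zmp(
                t, x, xd, zeta1, zeta2, xp, d["x_sd"], d["T"], clip=d["clip"]
            )

        def err(xp, sel=slice(None)):
            m = model(xp, d["t"][sel], d["x"][sel], d["xd"][sel])
            return float(np.sum((m - d["z"][sel]) ** 2))

        def solve(fun, lo, hi):
            # saturation makes the objective multimodal: bracket the global
            # basin on a coarse grid first, then refine
            grid = np.linspace(lo, hi, 41)
            i = int(np.argmin([fun(g) for g in grid]))
            res = minimize_scalar(
                fun,
                bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
                method="bounded",
                options={"xatol": 1e-9},
            )
            return float(res.x)

        lo, hi = d["guess"] - d["radius"], d["guess"] + d["radius"]
        xp = solve(err, lo, hi)
        return err(xp), xp

    def _objective(self, data, zeta1, zeta2):
        sse = 0.0
        xps = []
        for d in data:
            s, xp = self._segment_sse(d, zeta1, zeta2)
            sse += s
            xps.append(xp)
        return sse, xps

    # -- fitting ---------------------------------------------------------
    def fit(self, recording: GaitRecording, segments: list):
        if not segments:
            raise ValueError("no fit segments provided")
        data, x_sd = self._prepare(recording, segments)
        if not data:
            raise ValueError("segments contain no usable samples")
        lo, hi = self.zeta_bounds
        rng = np.random.default_rng(self.seed)
        converged = False
        best = (np.inf, None)

        if self.constraint_product is not None:
            C = self.constraint_product

            def f(z1):
                z1 = float(np.clip(z1, lo, hi))
                return self._objective(data, z1, C / z1)[0]

            starts = np.sort(rng.uniform(lo, hi, self.n_starts))
            for s in starts:
                res = minimize(
                    lambda v: f(v[0]),
                    x0=[s],
                    method="Nelder-Mead",
                    bounds=[(lo, hi)],
                    options={"xatol": 1e-6, "fatol": 1e-14, "maxiter": 200},
                )
                if res.fun < best[0]:
                    best = (res.fun, [float(res.x[0])])
                    converged = converged or bool(res.success)
            z1 = best[1][0]
            z2 = C / z1
        else:

            def f2(v):
                z1 = float(np.clip(v[0], lo, hi))
                z2 = float(np.clip(v[1], lo, hi))
                return self._objective(data, z1, z2)[0]

            starts = rng.uniform(lo, hi, size=(self.n_starts, 2))
            for s in starts:
                res = minimize(
                    f2,
                    x0=s,
                    method="Nelder-Mead",
                    bounds=[(lo, hi), (lo, hi)],
                    options={"xatol": 1e-6, "fatol": 1e-14, "maxiter": 400},
                )
                if res.fun < best[0]:
                    best = (res.fun, [float(res.x[0]), float(res.x[1])])
                    converged = converged or bool(res.success)
            z1 = float(np.clip(best[1][0], lo, hi))
            z2 = float(np.clip(best[1][1], lo, hi))

        sse, xps = self._objective(data, z1, z2)
        n = sum(len(d["t"]) for d in data)
        self.zeta1_, self.zeta2_ = float(z1), float(z2)
        self.x_p_ = xps
        self.x_sd_ = x_sd
        self.rmse_ = float(np.sqrt(sse / n))
        self._data = data
        self.result_ = FitResult(
            zeta1=self.zeta1_,
            zeta2=self.zeta2_,
            x_p=xps,
            x_sd=x_sd,
            rmse=self.rmse_,
            constraint_product=self.constraint_product,
            converged=converged,
            n_samples=n,
            seed=self.seed,
        )
        return self

    def predict(self, recording: GaitRecording, segments: list | None = None) -> np.ndarray:
        """Model ZMP along the recording (NaN outside fitted windows)."""
        if not hasattr(self, "result_"):
            raise RuntimeError("fit the estimator first")
        if segments is None:
            data = self._data
        else:
            data, _ = self._prepare(recording, segments)
        t = recording.time
        x = recording.col("com_x")
        xd = recording.col("dcom_x")
        out = np.full(len(t), np.nan)
        for d, xp in zip(data, self.x_p_):
            seg = d["segment"]
            mask = (t >= seg.t_start - 1e-9) & (t < seg.t_end - 1e-9)
            out[mask] = _segment_model_zmp(
                t[mask], x[mask], xd[mask], self.zeta1_, self.zeta2_, xp, d["x_sd"], d["T"],
                clip=d["clip"],
            )
        return out


def fit_controller(
    recording: GaitRecording,
    segments: list,
    constraint_product: float | None = None,
    n_starts: int = 8,
    seed: int = 0,
    zeta_bounds: tuple = (1.0, 10.0),
) -> FitResult:
    """Functional wrapper over :class:`ControllerIdentifier`."""
    est = ControllerIdentifier(
        constraint_product=constraint_product,
        zeta_bounds=zeta_bounds,
        n_starts=n_starts,
        seed=seed,
    )
    est.fit(recording, segments)
    return est.result_


def model_zmp_trace(
    result: FitResult,
    recording: GaitRecording,
    segments: list,
    continuous: bool = False,
) -> dict:
    """Model ZMP evaluated along the measured COM trajectory.

    Returns ``{"time", "model_zmp", "measured_zmp", "rmse"}``.  The RMSE is
    always computed on the raw trace.  With ``continuous=True`` the
    returned trace follows the convention of displaying the model ZMP as
    continuous behavior across support switches: the rendering horizon is
    clamped at the fit's tau floor (suppressing the near-landing gain
    spike) and each remaining jump at a section boundary is absorbed by a
    linear taper over the following section.
    """
    est = ControllerIdentifier(constraint_product=result.constraint_product, seed=result.seed)
    est.zeta1_, est.zeta2_ = result.zeta1, result.zeta2
    est.x_p_ = result.x_p
    data, _ = est._prepare(recording, segments)
    est._data = data
    est.result_ = result
    raw = est.predict(recording)
    t = recording.time
    meas = measured_zmp_series(recording)
    # rmse on the same samples the fit uses (near-landing samples, where
    # the law's gain diverges, are excluded there as well)
    sse, n = 0.0, 0
    for d, xp in zip(data, est.x_p_):
        mdl = _segment_model_zmp(
            d["t"], d["x"], d["xd"], result.zeta1, result.zeta2, xp, d["x_sd"], d["T"],
            clip=d["clip"],
        )
        sse += float(np.sum((mdl - d["z"]) ** 2))
        n += len(d["t"])
    rmse = float(np.sqrt(sse / max(n, 1)))
    trace = raw
    if continuous:
        x = recording.col("com_x")
        xd = recording.col("dcom_x")
        trace = np.full(len(t), np.nan)
        pieces = []
        for d, xp in zip(data, est.x_p_):
            seg = d["segment"]
            m = (t >= seg.t_start - 1e-9) & (t < seg.t_end - 1e-9)
            if not np.any(m):
                continue
            T = d["T"]
            if T is not None:
                # clamp the rendering time at T - tau_floor: the command is
                # held where the law's gain diverges
                vals = _segment_model_zmp(
                    np.minimum(t[m], T - est.tau_floor), x[m], xd[m],
                    result.zeta1, result.zeta2, xp, d["x_sd"], T, clip=d["clip"],
                )
            else:
                vals = _segment_model_zmp(
                    t[m], x[m], xd[m], result.zeta1, result.zeta2, xp, None, None,
                    clip=d["clip"],
                )
            pieces.append((np.where(m)[0], vals))
        pieces.sort(key=lambda p: p[0][0])
        prev_last = None
        for idx, vals in pieces:
            vals = vals.copy()
            if prev_last is not None:
                jump = vals[0] - prev_last
                ramp = np.linspace(1.0, 0.0, len(vals))
                vals -= jump * ramp
            trace[idx] = vals
            prev_last = vals[-1]
    return {"time": t, "model_zmp": trace, "measured_zmp": meas, "rmse": rmse}


# ---------------------------------------------------------------------------
# trunk-fixed local frame
# ---------------------------------------------------------------------------

_POS_PREFIXES = (
    "com",
    "foot_l_pos",
    "foot_r_pos",
    "joint_l_ankle",
    "joint_r_ankle",
    "joint_l_knee",
    "joint_r_knee",
    "joint_waist",
    "plate_l_heel_pos",
    "plate_l_toe_pos",
    "plate_r_heel_pos",
    "plate_r_toe_pos",
)
_VEC_PREFIXES = (
    "dcom",
    "plate_l_heel_f",
    "plate_l_toe_f",
    "plate_r_heel_f",
    "plate_r_toe_f",
    "plate_l_heel_n",
    "plate_l_toe_n",
    "plate_r_heel_n",
    "plate_r_toe_n",
)
_QUAT_PREFIXES = ("foot_l_quat", "foot_r_quat", "chest_quat")


def _chest_heading(recording: GaitRecording, filter_hz: float | None) -> np.ndarray:
    q = recording.quat("chest_quat")
    fwd = Rotation.from_quat(q, scalar_first=True).apply(np.tile([1.0, 0.0, 0.0], (len(q), 1)))
    yaw = np.unwrap(np.arctan2(fwd[:, 1], fwd[:, 0]))
    if filter_hz:
        fs = recording.fs
        if len(yaw) > 15:
            b, a = signal.butter(2, filter_hz / (fs / 2.0), btype="low")
            yaw = signal.filtfilt(b, a, yaw)
    return yaw


def to_local_frame(recording: GaitRecording, filter_hz: float | None = 1.0) -> GaitRecording:
    """Re-express the recording in the trunk-heading local frame.

    Per sample the frame is anchored at the waist's ground projection with
    X along the chest's forward heading (yaw only; Z stays vertical).  So
    that positions that are stationary on the ground (the support foot, the
    ZMP) remain stationary in the local frame while the trunk walks a
    curved path, the forward coordinate is rectified to arc length: with
    s(t) the waist's cumulative forward progress along its own heading,

        x_loc = s + R(yaw)^T (p - waist) . e_x
        y_loc =     R(yaw)^T (p - waist) . e_y

    Velocity, force and torque *vectors* are rotated into the local axes
    (forward COM velocity = physical speed along the heading).  On a
    straight walk this reduces to the global frame up to a constant offset.
    The yaw, waist origin and arc length are stored in ``frame_yaw_rad``,
    ``frame_origin_{x,y}`` and ``frame_arc_s`` columns so the transform can
    be inverted exactly.

    ``filter_hz`` low-pass filters the heading (2nd-order Butterworth) to
    keep step-cycle oscillation out of the frame; pass None for the raw
    heading.
    """
    if not recording.has("joint_waist") or "chest_quat_w" not in recording.data.columns:
        raise ValueError("local frame requires joint_waist and chest_quat channels")
    t = recording.time
    yaw = _chest_heading(recording, filter_hz)
    waist = recording.vec3("joint_waist")
    ox, oy = waist[:, 0], waist[:, 1]
    c, s = np.cos(yaw), np.sin(yaw)
    # waist forward progress along the heading (arc length of the path)
    vx = np.gradient(ox, t)
    vy = np.gradient(oy, t)
    fwd = vx * c + vy * s
    arc = np.concatenate([[0.0], np.cumsum(0.5 * (fwd[1:] + fwd[:-1]) * np.diff(t))])
    df = recording.data.copy()

    def rot_into(xc, yc, positional):
        x = df[xc].to_numpy(dtype=float)
        y = df[yc].to_numpy(dtype=float)
        if positional:
            x = x - ox
            y = y - oy
        lx = c * x + s * y
        ly = -s * x + c * y
        if positional:
            lx = lx + arc
        return lx, ly

    for pref in _POS_PREFIXES:
        if f"{pref}_x" in df.columns:
            df[f"{pref}_x"], df[f"{pref}_y"] = rot_into(f"{pref}_x", f"{pref}_y", True)
    for pref in _VEC_PREFIXES:
        if f"{pref}_x" in df.columns:
            df[f"{pref}_x"], df[f"{pref}_y"] = rot_into(f"{pref}_x", f"{pref}_y", False)
    r_inv = Rotation.from_euler("z", (-yaw)[:, None])
    for pref in _QUAT_PREFIXES:
        if f"{pref}_w" in df.columns:
            q = np.column_stack([df[f"{pref}_{cc}"].to_numpy() for cc in "wxyz"])
            qn = (r_inv * Rotation.from_quat(q, scalar_first=True)).as_quat(scalar_first=True)
            for j, cc in enumerate("wxyz"):
                df[f"{pref}_{cc}"] = qn[:, j]
    df["frame_yaw_rad"] = yaw
    df["frame_origin_x"] = ox
    df["frame_origin_y"] = oy
    df["frame_arc_s"] = arc
    return GaitRecording(df)


def from_local_frame(recording: GaitRecording) -> GaitRecording:
    """Invert :func:`to_local_frame` using the stored frame columns."""
    for col in ("frame_yaw_rad", "frame_origin_x", "frame_origin_y", "frame_arc_s"):
        if col not in recording.data.columns:
            raise ValueError(f"missing frame column {col}")
    yaw = recording.col("frame_yaw_rad")
    ox, oy = recording.col("frame_origin_x"), recording.col("frame_origin_y")
    arc = recording.col("frame_arc_s")
    c, s = np.cos(yaw), np.sin(yaw)
    df = recording.data.copy()

    def rot_out(xc, yc, positional):
        x = df[xc].to_numpy(dtype=float)
        y = df[yc].to_numpy(dtype=float)
        if positional:
            x = x - arc
        gx = c * x - s * y
        gy = s * x + c * y
        if positional:
            gx = gx + ox
            gy = gy + oy
        return gx, gy

    for pref in _POS_PREFIXES:
        if f"{pref}_x" in df.columns:
            df[f"{pref}_x"], df[f"{pref}_y"] = rot_out(f"{pref}_x", f"{pref}_y", True)
    for pref in _VEC_PREFIXES:
        if f"{pref}_x" in df.columns:
            df[f"{pref}_x"], df[f"{pref}_y"] = rot_out(f"{pref}_x", f"{pref}_y", False)
    r_fwd = Rotation.from_euler("z", yaw[:, None])
    for pref in _QUAT_PREFIXES:
        if f"{pref}_w" in df.columns:
            q = np.column_stack([df[f"{pref}_{cc}"].to_numpy() for cc in "wxyz"])
            qn = (r_fwd * Rotation.from_quat(q, scalar_first=True)).as_quat(scalar_first=True)
            for j, cc in enumerate("wxyz"):
                df[f"{pref}_{cc}"] = qn[:, j]
    df = df.drop(columns=["frame_yaw_rad", "frame_origin_x", "frame_origin_y", "frame_arc_s"])
    return GaitRecording(df)
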