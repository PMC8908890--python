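"""Tabular gait-recording container.

A :class:`GaitRecording` wraps one synchronized 60 Hz time series: COM
position/velocity, per-foot pose (position + scalar-first quaternion), four
foot-plate wrenches (position, force, torque), lower-limb joint positions and
the trunk (waist/chest) channels used by the local-frame transform.  Units
are SI throughout; the world frame has X along the travel direction and Z up.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["GaitRecording", "PLATE_NAMES", "MANDATORY_COLUMNS", "resample"]

PLATE_NAMES = ("l_heel", "l_toe", "r_heel", "r_toe")
_XYZ = ("x", "y", "z")
_WXYZ = ("w", "x", "y", "z")


def _vec_cols(prefix: str) -> list[str]:
    return [f"{prefix}_{c}" for c in _XYZ]


def _quat_cols(prefix: str) -> list[str]:
    return [f"{prefix}_{c}" for c in _WXYZ]


MANDATORY_COLUMNS: tuple[str, ...] = tuple(
    ["time_s"]
    + _vec_cols("com")
    + _vec_cols("dcom")
    + sum((_vec_cols(f"foot_{f}_pos") + _quat_cols(f"foot_{f}_quat") for f in ("l", "r")), [])
    + sum(
        (
            _vec_cols(f"plate_{p}_pos") + _vec_cols(f"plate_{p}_f") + _vec_cols(f"plate_{p}_n")
            for p in PLATE_NAMES
        ),
        [],
    )
)


class GaitRecording:
    """Validated wrapper around the recording DataFrame.

    Parameters
    ----------
    data : pandas.DataFrame
        Must contain :data:`MANDATORY_COLUMNS`; unknown columns are kept and
        survive round trips.  ``time_s`` must be strictly increasing.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in MANDATORY_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"recording is missing mandatory column(s): {missing}")
        t = data["time_s"].to_numpy(dtype=float)
        if len(t) == 0:
            raise ValueError("empty recording")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time_s must be strictly increasing")
        self.data = data.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def time(self) -> np.ndarray:
        return self.data["time_s"].to_numpy(dtype=float)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    def col(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise KeyError(name)
        return self.data[name].to_numpy(dtype=float)

    def vec3(self, prefix: str) -> np.ndarray:
        """(n, 3) array for columns ``{prefix}_{x,y,z}``."""
        return np.column_stack([self.col(c) for c in _vec_cols(prefix)])

    def quat(self, prefix: str) -> np.ndarray:
        """(n, 4) scalar-first quaternion array for ``{prefix}_{w,x,y,z}``."""
        return np.column_stack([self.col(c) for c in _quat_cols(prefix)])

    def has(self, prefix_or_col: str) -> bool:
        if prefix_or_col in self.data.columns:
            return True
        return all(c in self.data.columns for c in _vec_cols(prefix_or_col))

    def copy(self) -> "GaitRecording":
        return GaitRecording(self.data.copy())

    # -- convenience channel groups -------------------------------------
    def foot_pose(self, leg: str) -> tuple[np.ndarray, np.ndarray]:
        """(positions (n,3), quaternions (n,4) scalar-first) for 'l'/'r'."""
        f = leg[0]
        return self.vec3(f"foot_{f}_pos"), self.quat(f"foot_{f}_quat")

    def plate(self, name: str) -> dict[str, np.ndarray]:
        if name not in PLATE_NAMES:
            raise KeyError(name)
        return {
            "pos": self.vec3(f"plate_{name}_pos"),
            "f": self.vec3(f"plate_{name}_f"),
            "n": self.vec3(f"plate_{name}_n"),
        }

    def joint(self, name: str) -> np.ndarray:
        return self.vec3(f"joint_{name}")


def resample(recording: GaitRecording, fs: float) -> GaitRecording:
    """Linear-interpolate every channel onto a uniform grid at ``fs`` Hz.

    Quaternion columns are renormalized after interpolation.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    t = recording.time
    new_t = np.arange(t[0], t[-1] + 0.5 / fs, 1.0 / fs)
    new_t = new_t[new_t <= t[-1] + 1e-12]
    out = {}
    for c in recording.data.columns:
        if c == "time_s":
            out[c] = new_t
        else:
            out[c] = np.interp(new_t, t, recording.data[c].to_numpy(dtype=float))
    df = pd.DataFrame(out)
    quat_prefixes = {c[: -len("_w")] for c in df.columns if c.endswith("_quat_w")}
    for p in quat_prefixes:
        cols = _quat_cols(p)
        q = df[cols].to_numpy()
        df[cols] = q / np.linalg.norm(q, axis=1, keepdims=True)
    return GaitRecording(df)
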