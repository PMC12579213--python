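"""Trajectory-level migration statistics.

Given centroid tracks C_t = (x_t, y_t) on a uniform time grid, this module
computes:

* path statistics — total path length, net displacement, directionality
  (displacement / total path length) and speed (total path length / elapsed
  time);
* turning angles between two movement vectors,
  theta = arccos(a.b / (|a||b|)) in degrees;
* 6-frame windowed speed and direction centred on frame t,
  Speed(t) = (sum_{k=-2..3} |C_{t+k} - C_{t+k-1}|) / 6 and
  Direction(t) = (sum_{k=-2..3} (C_{t+k} - C_{t+k-1})) / 6, which telescopes
  to (C_{t+3} - C_{t-3}) / 6;
* the directional autocorrelation: per lag, the mean cosine of the angle
  between displacement vectors separated by that lag, pooled over cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectories import Trajectory


class UndefinedValueError(ValueError):
    pass


@dataclass
class PathStats:
    total_path_len: float  # um
    displacement: float  # um
    directionality: float  # [0, 1]
    speed: float  # um/min


@dataclass
class TurnEvent:
    a_vec: np.ndarray
    b_vec: np.ndarray
    theta_deg: float


@dataclass
class AutocorrCurve:
    lags: np.ndarray  # minutes
    values: np.ndarray  # mean cosine per lag
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_min": self.lags, "mean_cos": self.values,
                             "n_pairs": self.n_pairs})


def path_stats(traj: Trajectory) -> PathStats:
    """Total path length, displacement, directionality and mean speed."""
    steps = traj.steps
    seg = np.linalg.norm(steps, axis=1)
    total = float(seg.sum())
    disp = float(np.linalg.norm(traj.positions[-1] - traj.positions[0]))
    if total == 0:
        raise UndefinedValueError("zero path length; directionality undefined")
    elapsed = float(traj.t_min[-1] - traj.t_min[0])
    return PathStats(total_path_len=total, displacement=disp,
                     directionality=disp / total, speed=total / elapsed)


def turning_angle(a_vec, b_vec) -> TurnEvent:
    """Angle in degrees (0-180) between two movement vectors."""
    a = np.asarray(a_vec, dtype=float)
    b = np.asarray(b_vec, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedValueError("turning angle undefined for a zero vector")
    cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return TurnEvent(a_vec=a, b_vec=b, theta_deg=float(np.degrees(np.arccos(cosang))))


def _check_window(traj: Trajectory, t: int) -> None:
    # the 6-term sum uses C_{t-3} .. C_{t+3}
    if not 3 <= t <= traj.n_frames - 4:
        raise IndexError(
            f"windowed statistic undefined at t={t} "
            f"(valid 3..{traj.n_frames - 4} for {traj.n_frames} frames)")


def windowed_speed(traj: Trajectory, t: int) -> float:
    """6-frame windowed speed (um/frame) at frame t:
    (sum_{k=-2..3} |C_{t+k} - C_{t+k-1}|) / 6."""
    _check_window(traj, t)
    pos = traj.positions
    total = 0.0
    for k in range(-2, 4):
        total += float(np.linalg.norm(pos[t + k] - pos[t + k - 1]))
    return total / 6.0


def windowed_direction(traj: Trajectory, t: int) -> np.ndarray:
    """6-frame windowed direction vector at frame t:
    (sum_{k=-2..3} (C_{t+k} - C_{t+k-1})) / 6 = (C_{t+3} - C_{t-3}) / 6."""
    _check_window(traj, t)
    pos = traj.positions
    return (pos[t + 3] - pos[t - 3]) / 6.0


def direction_autocorrelation(trajs, max_lag_min: float = 120.0,
                              dt_min: float = 10.0) -> AutocorrCurve:
    """Mean cosine between displacement vectors separated by each lag.

    Trajectories are resampled to the analysis time step ``dt_min`` by
    nearest frame when acquired faster. For lag L (a multiple of dt_min) the
    estimator averages, over all cells and valid start times t,
    cos(angle between (C_{t+dt} - C_t) and (C_{t+L+dt} - C_{t+L})); zero
    displacement steps are excluded from pairs. Lag 0 equals 1 by
    construction.
    """
    if not isinstance(trajs, (list, tuple)):
        trajs = [trajs]
    lags = np.arange(0.0, max_lag_min + 1e-9, dt_min)
    sums = np.zeros(len(lags))
    counts = np.zeros(len(lags), dtype=int)
    any_motion = False
    for traj in trajs:
        ratio = dt_min / traj.dt_min
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1 - 1e-9:
            raise UndefinedValueError(
                f"analysis step {dt_min} min is not a multiple of the "
                f"sampling interval {traj.dt_min} min")
        stride = max(int(round(ratio)), 1)
        pos = traj.positions[::stride]
        steps = np.diff(pos, axis=0)
        norms = np.linalg.norm(steps, axis=1)
        ok = norms > 0
        if not ok.any():
            continue
        any_motion = True
        unit = np.zeros_like(steps)
        unit[ok] = steps[ok] / norms[ok, None]
        n = len(steps)
        for li, lag in enumerate(lags):
            d = int(round(lag / dt_min))
            if d >= n:
                continue
            valid = ok[: n - d] & ok[d:]
            cos = np.einsum("ij,ij->i", unit[: n - d][valid], unit[d:][valid])
            sums[li] += cos.sum()
            counts[li] += int(valid.sum())
    if not any_motion:
        raise UndefinedValueError("all trajectories have zero displacement")
    values = np.full(len(lags), np.nan)
    nz = counts > 0
    values[nz] = sums[nz] / counts[nz]
    return AutocorrCurve(lags=lags, values=values, n_pairs=counts)
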