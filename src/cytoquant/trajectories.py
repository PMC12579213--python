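"""Cell-centroid trajectory container.

Positions are micrometre coordinates of a tracked centroid (typically the
nucleus) sampled on a uniform time grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Trajectory:
    """Time-ordered centroid positions C_t = (x_t, y_t).

    Parameters
    ----------
    t_min : ndarray
        Strictly increasing time points (minutes) with constant spacing.
    x_um, y_um : ndarray
        Centroid coordinates in micrometres.
    cell_id : str
        Track label.
    """

    t_min: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        n = len(self.t_min)
        if n < 2 or len(self.x_um) != n or len(self.y_um) != n:
            raise ValueError("trajectory needs >= 2 points with matching lengths")
        dt = np.diff(self.t_min)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(dt, dt[0]):
            raise ValueError("time spacing must be uniform")

    @property
    def n_frames(self) -> int:
        return len(self.t_min)

    @property
    def dt_min(self) -> float:
        return float(self.t_min[1] - self.t_min[0])

    @property
    def positions(self) -> np.ndarray:
        """(T, 2) array of (x, y)."""
        return np.column_stack([self.x_um, self.y_um])

    @property
    def steps(self) -> np.ndarray:
        """(T-1, 2) displacement vectors between consecutive frames."""
        return np.diff(self.positions, axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "frame": np.arange(self.n_frames),
                "t_min": self.t_min,
                "x_um": self.x_um,
                "y_um": self.y_um,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cell_id: str | None = None) -> "Trajectory":
        if cell_id is not None:
            df = df[df["cell_id"] == cell_id]
        df = df.sort_values("t_min")
        cid = str(df["cell_id"].iloc[0]) if "cell_id" in df else "cell"
        return cls(df["t_min"].to_numpy(), df["x_um"].to_numpy(),
                   df["y_um"].to_numpy(), cell_id=cid)


def read_trajectories(path) -> list[Trajectory]:
    """Read a trajectory CSV (cell_id, frame, t_min, x_um, y_um) into tracks."""
    df = pd.read_csv(path)
    return [Trajectory.from_frame(g) for _, g in df.groupby("cell_id", sort=True)]


def write_trajectories(trajs: list[Trajectory], path) -> None:
    pd.concat([tr.to_frame() for tr in trajs], ignore_index=True).to_csv(path, index=False)
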