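"""Workspace geometry and trajectory-error metrics for center-out reaching.

The task is a planar center-out reach: from a central start point to one of
six targets on a circle of radius 0.1 m.  Target angles are measured in
degrees *clockwise from anterior*, where anterior is the +y axis.  Three
targets form the training set (90, 210, -30 degrees) and three the test set
(0, +120, -120 degrees).

Error metrics follow the standard kinematic definitions for this paradigm:

* ``error_profile`` decomposes a hand path into an along-line coordinate
  ``r`` (distance travelled along the ideal straight start-to-target line)
  and a signed perpendicular deviation ``eps(r)``.  Positive deviation is
  counter-clockwise of the ideal line, so errors induced by a
  counter-clockwise cursor rotation are positive.
* ``trajectory_error`` is the signed perpendicular deviation of largest
  magnitude over the whole path (the conventional "maximum perpendicular
  distance" reach error).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "TRAINING_ANGLES_DEG",
    "TEST_ANGLES_DEG",
    "TargetSpec",
    "Trajectory",
    "ErrorProfile",
    "rotate_about",
    "error_profile",
    "trajectory_error",
    "average_error_profile",
    "default_targets",
]

#: Training / test target sets, degrees clockwise from anterior (+y).
TRAINING_ANGLES_DEG: tuple[float, ...] = (90.0, 210.0, -30.0)
TEST_ANGLES_DEG: tuple[float, ...] = (0.0, 120.0, -120.0)

#: Default workspace radius in meters.
DEFAULT_RADIUS_M = 0.1


class InvalidGeometryError(ValueError):
    """Raised when a trajectory's geometry is degenerate (start == target)."""


@dataclass(frozen=True)
class TargetSpec:
    """A reach target on the workspace circle.

    Parameters
    ----------
    angle_deg
        Target direction in degrees clockwise from anterior (+y axis).
    radius_m
        Distance from the central start point, meters.
    role
        ``"training"`` or ``"test"``.
    """

    angle_deg: float
    radius_m: float = DEFAULT_RADIUS_M
    role: Literal["training", "test"] = "training"

    def __post_init__(self) -> None:
        if not np.isfinite(self.angle_deg):
            raise ValueError("angle_deg must be finite")
        if not (self.radius_m > 0):
            raise ValueError("radius_m must be positive")

    def position(self, center: Sequence[float] = (0.0, 0.0)) -> np.ndarray:
        """Cartesian target position; clockwise-from-+y convention."""
        a = np.deg2rad(self.angle_deg)
        return np.asarray(center, dtype=float) + self.radius_m * np.array(
            [np.sin(a), np.cos(a)]
        )


def default_targets(radius_m: float = DEFAULT_RADIUS_M) -> list[TargetSpec]:
    """The six standard targets: three training, three test."""
    train = [TargetSpec(a, radius_m, "training") for a in TRAINING_ANGLES_DEG]
    test = [TargetSpec(a, radius_m, "test") for a in TEST_ANGLES_DEG]
    return train + test


@dataclass
class Trajectory:
    """A sampled 2-D hand path for one outward reach.

    ``t`` must be strictly increasing (nominal 100 Hz sampling) and the
    first sample must lie within 1 mm of ``start``.
    """

    t: np.ndarray  # seconds
    x: np.ndarray  # meters
    y: np.ndarray  # meters
    start: np.ndarray
    target: TargetSpec

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.start = np.asarray(self.start, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have equal length")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("sample times must be strictly increasing")
        if self.t.size:
            d0 = np.hypot(self.x[0] - self.start[0], self.y[0] - self.start[1])
            if d0 > 1e-3:
                raise ValueError(
                    f"first sample is {d0 * 1e3:.2f} mm from start (limit 1 mm)"
                )

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    def points(self) -> np.ndarray:
        """Samples as an (n, 2) array."""
        return np.column_stack([self.x, self.y])


@dataclass
class ErrorProfile:
    """Signed perpendicular error as a function of along-line distance.

    ``r_grid`` is a fixed ascending grid on [0, R]; ``eps`` holds the
    perpendicular deviation at each grid point (positive counter-clockwise
    of the ideal line).
    """

    r_grid: np.ndarray
    eps: np.ndarray
    target: TargetSpec

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.eps = np.asarray(self.eps, dtype=float)
        if self.r_grid.shape != self.eps.shape:
            raise ValueError("r_grid and eps must have equal length")
        if self.r_grid.size >= 2 and not np.all(np.diff(self.r_grid) > 0):
            raise ValueError("r_grid must be strictly increasing")

    def interp(self, r: float | np.ndarray) -> float | np.ndarray:
        """Linear interpolation of eps at r; constant beyond the grid ends."""
        return np.interp(r, self.r_grid, self.eps)

    def peak(self) -> float:
        """Signed eps value of largest magnitude on the grid."""
        i = int(np.argmax(np.abs(self.eps)))
        return float(self.eps[i])


def rotate_about(
    p: Sequence[float], center: Sequence[float], angle_ccw_deg: float
) -> np.ndarray:
    """Rotate point ``p`` counter-clockwise by ``angle_ccw_deg`` about ``center``."""
    p = np.asarray(p, dtype=float)
    c = np.asarray(center, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(c)) and np.isfinite(angle_ccw_deg)):
        raise ValueError("rotate_about requires finite inputs")
    a = np.deg2rad(angle_ccw_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return c + rot @ (p - c)


def _line_frame(start: np.ndarray, target: TargetSpec) -> tuple[np.ndarray, np.ndarray, float]:
    """Unit along-line and CCW-normal vectors of the ideal line, plus its length."""
    start = np.asarray(start, dtype=float)
    tpos = target.position(start)
    d = tpos - start
    length = float(np.hypot(*d))
    if length < 1e-12:
        raise InvalidGeometryError("start and target coincide")
    u = d / length
    v = np.array([-u[1], u[0]])  # +90 deg CCW of u
    return u, v, length


def _decompose(traj: Trajectory) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-sample (r, eps) coordinates relative to the ideal line.

    r is the projection onto the start->target line, clipped to [0, R];
    eps is the signed perpendicular coordinate (CCW positive).
    """
    if traj.n_samples < 2:
        raise ValueError("trajectory needs at least 2 samples")
    u, v, R = _line_frame(traj.start, traj.target)
    rel = traj.points() - traj.start
    r = np.clip(rel @ u, 0.0, R)
    eps = rel @ v
    return r, eps, R


def error_profile(traj: Trajectory, grid_size: int = 50) -> ErrorProfile:
    """Resample a trajectory's perpendicular error onto a fixed r grid.

    Because hand paths can briefly backtrack, eps is interpolated against
    the running maximum (monotone envelope) of r, which makes eps a
    single-valued function of r.  Grid points beyond the furthest r reached
    take the last observed value.
    """
    r, eps, R = _decompose(traj)
    r_env = np.maximum.accumulate(r)
    # keep the most recent sample at each envelope value so interpolation
    # reflects where the hand actually was, not a stale backtracked sample
    keep = np.ones(r_env.size, dtype=bool)
    keep[:-1] = r_env[:-1] < r_env[1:]
    grid = np.linspace(0.0, R, grid_size)
    eps_grid = np.interp(grid, r_env[keep], eps[keep])
    return ErrorProfile(grid, eps_grid, traj.target)


def trajectory_error(traj: Trajectory) -> float:
    """Signed maximum perpendicular deviation of the hand path, meters.

    Returns the perpendicular deviation of largest absolute value over all
    samples, carrying its sign (positive = counter-clockwise of the ideal
    straight start-to-target line).
    """
    _, eps, _ = _decompose(traj)
    i = int(np.argmax(np.abs(eps)))
    return float(eps[i])


def average_error_profile(profiles: Iterable[ErrorProfile]) -> ErrorProfile:
    """Pointwise mean of error profiles sharing a grid and target."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("average_error_profile requires at least one profile")
    first = profiles[0]
    for p in profiles[1:]:
        if p.r_grid.shape != first.r_grid.shape or not np.allclose(
            p.r_grid, first.r_grid, rtol=0, atol=1e-12
        ):
            raise ValueError("all profiles must share the same r grid")
        if p.target.angle_deg != first.target.angle_deg:
            raise ValueError("all profiles must share the same target")
    eps = np.mean([p.eps for p in profiles], axis=0)
    return ErrorProfile(first.r_grid.copy(), eps, first.target)
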