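import numpy as np
import pytest

from erraug.geometry import TargetSpec, Trajectory
from erraug.simulate import LearnerState, make_schedule


@pytest.fixture(scope="session")
def schedule():
    """Default three-phase schedule (165/390/165, 1-in-8 catches)."""
    return make_schedule(rng_seed=1)


@pytest.fixture(scope="session")
def noise_free_state():
    return LearnerState(motor_noise_sd_deg=0.0)


@pytest.fixture
def target_90():
    return TargetSpec(90.0, 0.1, "training")


def straight_trajectory(target: TargetSpec, angle_off_deg: float = 0.0, n: int = 41):
    """A straight-line reach toward the ideal line rotated CCW by angle_off_deg."""
    start = np.zeros(2)
    tpos = target.position(start)
    u = (tpos - start) / target.radius_m
    a = np.deg2rad(angle_off_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    d = rot @ u
    r = np.linspace(0.0, target.radius_m, n)
    pts = start + np.outer(r, d)
    return Trajectory(
        t=np.arange(n) * 0.01, x=pts[:, 0], y=pts[:, 1], start=start, target=target
    )


def bell_trajectory(target: TargetSpec, peak_m: float, n: int = 41):
    """Reach along the ideal line with lateral bell deviation peak_m*sin(pi r/R)."""
    start = np.zeros(2)
    R = target.radius_m
    tpos = target.position(start)
    u = (tpos - start) / R
    v = np.array([-u[1], u[0]])
    r = np.linspace(0.0, R, n)
    eps = peak_m * np.sin(np.pi * r / R)
    pts = start + np.outer(r, u) + np.outer(eps, v)
    return Trajectory(
        t=np.arange(n) * 0.01, x=pts[:, 0], y=pts[:, 1], start=start, target=target
    )
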