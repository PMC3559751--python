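"""Trial-by-trial simulation of visuomotor-rotation learning.

Synthetic-data generator for the three-phase center-out reaching
experiment: a baseline phase (165 movements, with rotated probe trials in
the latter 120), a training phase (390 movements under a constant 30
degree counter-clockwise cursor rotation, with catch trials once per
8-trial block), and a washout phase (165 movements, rotation off).

Subjects are modelled as state-space learners: an internal compensation
estimate ``theta_hat`` (degrees, counter-clockwise) is updated after every
movement by a fixed fraction ``lambda_frac`` of the angular error
*perceived on the displayed cursor path*:

    theta_hat <- theta_hat + lambda_frac * perceived_error_deg

With error feedback scaled by a gain g this gives the classic per-trial
error dynamics delta_{k+1} = (1 - lambda*g) * delta_k (small errors), so
learning is stable and monotone for lambda*g < 1, underdamped
(sign-alternating) for 1 < lambda*g < 2, and unstable for lambda*g > 2.
The default correction fraction is 0.32, the empirical single-trial
compensation fraction for trajectory errors in planar reaching, which
puts the stability limit at a feedback gain of 1/0.32 ~= 3.1.

Each simulated movement is synthesized as a minimum-jerk reach whose
lateral deviation is a half-sine bell d*sin(pi*r/R) with peak
d = c*R*sin(delta), where delta is the trial's effective angular error
and c in (0, 1] attenuates the deviation to reflect within-movement
online correction.  With the defaults (c = 0.6, 30 degree rotation) the
first rotated movements err by about 0.03 m, the magnitude typical of
human initial exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .augmentation import (
    AugmentationSpec,
    ConfigurationError,
    OffsetTemplateSet,
    build_offset_template,
)
from .geometry import (
    DEFAULT_RADIUS_M,
    TargetSpec,
    Trajectory,
    TRAINING_ANGLES_DEG,
    TEST_ANGLES_DEG,
    trajectory_error,
)

__all__ = [
    "ROTATION_DEG",
    "GROUPS",
    "GROUP_GAINS",
    "LearnerState",
    "TrialSpec",
    "ExperimentSchedule",
    "TrialRecord",
    "make_schedule",
    "execute_trial",
    "update_learner",
    "simulate_subject",
    "simulate_experiment",
    "records_to_frame",
    "simulate_error_sequence",
    "theoretical_gain_limit",
]

#: Imposed cursor rotation, degrees counter-clockwise about the start point.
ROTATION_DEG = 30.0

#: The four treatment groups and the feedback gain each experiences.
GROUPS = ("control", "x2", "offset", "x3p1")
GROUP_GAINS = {"x2": 2.0, "x3p1": 3.1}

#: Movement-speed feedback window: peak speed 0.45 +/- 0.05 m/s.
PEAK_SPEED_MPS = 0.45
PEAK_SPEED_SD_MPS = 0.03

#: Default execution-noise SD on the effective angular error, degrees.
#: Calibrated so that catch-trial residuals about the fitted exponential
#: have ~0.94 mm RMS, the trial-to-trial variability typical of this task.
DEFAULT_MOTOR_NOISE_SD_DEG = 1.5

#: Internal resolution for displayed-error profiles (odd so the bell peak
#: at r = R/2 falls exactly on a grid node).
_FINE_GRID = 201

Phase = Literal["baseline", "training", "washout"]


def theoretical_gain_limit(lambda_frac: float) -> float:
    """Feedback gain at which one trial cancels the whole error (1/lambda).

    Beyond this gain the per-trial update overshoots: trial-to-trial
    learning leaves the monotone regime (and diverges past 2/lambda).
    """
    if not (0 < lambda_frac < 1):
        raise ValueError("lambda_frac must lie in (0, 1)")
    return 1.0 / lambda_frac


@dataclass(frozen=True)
class LearnerState:
    """Internal state of the trial-by-trial learner.

    Parameters
    ----------
    theta_hat_deg
        Current rotation-compensation estimate, degrees counter-clockwise.
    lambda_frac
        Fraction of the perceived error corrected on the next trial.
    motor_noise_sd_deg
        SD of zero-mean Gaussian execution noise on the effective angular
        error, degrees.
    online_correction_c
        Within-movement correction attenuation in (0, 1]: the peak lateral
        deviation is c*R*sin(delta) rather than the full open-loop R*sin(delta).
    generalization
        Fraction of theta_hat expressed at unpracticed test targets.
    learn_on_catch
        Whether the learner also updates from the (un-augmented) error
        displayed on catch/probe trials.
    cautious, cautious_threshold_deg, cautious_factor
        Optional "cautious learner": when the perceived error magnitude
        exceeds the threshold, lambda is scaled down by ``cautious_factor``.
        Off by default; used to illustrate how discounting implausibly
        large errors slows learning at high feedback gains.
    """

    theta_hat_deg: float = 0.0
    lambda_frac: float = 0.32
    motor_noise_sd_deg: float = DEFAULT_MOTOR_NOISE_SD_DEG
    online_correction_c: float = 0.6
    generalization: float = 1.0
    learn_on_catch: bool = True
    cautious: bool = False
    cautious_threshold_deg: float = 45.0
    cautious_factor: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.lambda_frac < 1):
            raise ValueError("lambda_frac must lie in (0, 1)")
        if self.motor_noise_sd_deg < 0:
            raise ValueError("motor_noise_sd_deg must be >= 0")
        if not (0 < self.online_correction_c <= 1):
            raise ValueError("online_correction_c must lie in (0, 1]")


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled movement."""

    index: int  # global movement number, 0-based
    phase: Phase
    phase_index: int  # movement number within phase, 1-based
    target: TargetSpec
    rotation_on: bool
    augmentation_on: bool
    is_catch: bool  # probe trial in baseline, catch trial in training


@dataclass(frozen=True)
class ExperimentSchedule:
    """The full ordered trial list shared by all subjects."""

    trials: tuple[TrialSpec, ...]

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def phase(self, phase: Phase) -> list[TrialSpec]:
        return [t for t in self.trials if t.phase == phase]


@dataclass(frozen=True)
class TrialRecord:
    """Simulated outcome of one movement."""

    subject_id: str
    group: str
    index: int
    phase: Phase
    phase_index: int
    target_deg: float
    rotation_on: bool
    augment_mode: str
    is_catch: bool
    trajectory_error_m: float
    peak_speed_mps: float


def _balanced_sequence(angles: Sequence[float], n: int, rng: np.random.Generator) -> list[float]:
    """n target angles with all angles equally frequent (shuffled blocks)."""
    out: list[float] = []
    while len(out) < n:
        block = list(angles)
        rng.shuffle(block)
        out.extend(block)
    return out[:n]


def make_schedule(
    rng_seed: int,
    baseline_trials: int = 165,
    training_trials: int = 390,
    washout_trials: int = 165,
    probe_block: int = 8,
    baseline_probe_trials: int = 120,
    radius_m: float = DEFAULT_RADIUS_M,
) -> ExperimentSchedule:
    """Build the three-phase trial schedule.

    Catch/probe trials occur exactly once per complete ``probe_block``
    movements (trailing remainders carry none), pseudo-randomly placed and
    never on two consecutive movements, including across block and phase
    boundaries.  Baseline probes occupy only the latter
    ``baseline_probe_trials`` movements of the baseline phase and cycle the
    three training targets; training trials use only training targets, all
    equally often.
    """
    if probe_block < 2:
        raise ConfigurationError("probe_block must be at least 2")
    if baseline_probe_trials > baseline_trials:
        raise ConfigurationError("baseline_probe_trials exceeds baseline_trials")
    rng = np.random.default_rng(rng_seed)
    train_targets = {a: TargetSpec(a, radius_m, "training") for a in TRAINING_ANGLES_DEG}
    all_targets = dict(train_targets)
    all_targets.update({a: TargetSpec(a, radius_m, "test") for a in TEST_ANGLES_DEG})

    def catch_positions(start: int, n: int, last_catch: list[int]) -> set[int]:
        """One catch per complete block in [start, start+n), no adjacency."""
        chosen: set[int] = set()
        for b in range(n // probe_block):
            lo = start + b * probe_block
            slots = [i for i in range(lo, lo + probe_block) if i > last_catch[0] + 1]
            pos = int(rng.choice(slots))
            chosen.add(pos)
            last_catch[0] = pos
        return chosen

    last_catch = [-2]  # boxed so catch_positions can update it across phases
    trials: list[TrialSpec] = []

    # --- baseline ---------------------------------------------------------
    n_plain = baseline_trials - baseline_probe_trials
    probe_start = n_plain
    probes = catch_positions(probe_start, baseline_probe_trials, last_catch)
    n_probes = len(probes)
    plain_angles = _balanced_sequence(sorted(all_targets), baseline_trials - n_probes, rng)
    probe_angles = _balanced_sequence(TRAINING_ANGLES_DEG, n_probes, rng)
    it_plain, it_probe = iter(plain_angles), iter(probe_angles)
    for i in range(baseline_trials):
        is_probe = i in probes
        angle = next(it_probe) if is_probe else next(it_plain)
        trials.append(
            TrialSpec(
                index=i,
                phase="baseline",
                phase_index=i + 1,
                target=all_targets[angle],
                rotation_on=is_probe,
                augmentation_on=False,
                is_catch=is_probe,
            )
        )

    # --- training ---------------------------------------------------------
    t0 = baseline_trials
    catches = catch_positions(t0, training_trials, last_catch)
    train_angles = _balanced_sequence(TRAINING_ANGLES_DEG, training_trials, rng)
    for j in range(training_trials):
        i = t0 + j
        is_catch = i in catches
        trials.append(
            TrialSpec(
                index=i,
                phase="training",
                phase_index=j + 1,
                target=train_targets[train_angles[j]],
                rotation_on=True,
                augmentation_on=not is_catch,
                is_catch=is_catch,
            )
        )

    # --- washout ----------------------------------------------------------
    w0 = t0 + training_trials
    wash_angles = _balanced_sequence(TRAINING_ANGLES_DEG, washout_trials, rng)
    for j in range(washout_trials):
        trials.append(
            TrialSpec(
                index=w0 + j,
                phase="washout",
                phase_index=j + 1,
                target=train_targets[wash_angles[j]],
                rotation_on=False,
                augmentation_on=False,
                is_catch=False,
            )
        )
    return ExperimentSchedule(tuple(trials))


def _minimum_jerk_r(R: float, peak_speed: float, dt: float = 0.01) -> np.ndarray:
    """Along-line distance samples of a minimum-jerk reach at 100 Hz."""
    duration = 1.875 * R / peak_speed  # peak speed of min-jerk = 1.875 R/T
    t = np.arange(0.0, duration + dt / 2, dt)
    tau = np.clip(t / duration, 0.0, 1.0)
    r = R * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    return r


def _effective_theta(state: LearnerState, target: TargetSpec) -> float:
    if target.role == "test":
        return state.generalization * state.theta_hat_deg
    return state.theta_hat_deg


def execute_trial(
    state: LearnerState,
    spec: TrialSpec,
    aug: AugmentationSpec,
    rng: np.random.Generator,
    start: Sequence[float] = (0.0, 0.0),
) -> tuple[Trajectory, float, float]:
    """Simulate one movement.

    The subject aims compensated by ``theta_hat``; with the cursor rotation
    this leaves an effective angular error delta = rotation - theta_hat
    (plus execution noise).  The hand path deviates laterally by the bell
    profile d*sin(pi*r/R) with signed peak d = c*R*sin(delta) (positive =
    counter-clockwise).  The error the learner perceives is the signed
    peak deviation of the *displayed* cursor path, i.e. after augmentation,
    converted back to an equivalent angle via arcsin(d'/(c*R)) (saturating
    at +/-90 degrees when augmented feedback exceeds the representable
    range).

    Returns ``(trajectory, perceived_error_deg, peak_speed_mps)``.
    """
    R = spec.target.radius_m
    c = state.online_correction_c
    rotation = ROTATION_DEG if spec.rotation_on else 0.0
    noise = rng.normal(0.0, state.motor_noise_sd_deg) if state.motor_noise_sd_deg else 0.0
    delta_deg = rotation - _effective_theta(state, spec.target) + noise
    d = c * R * np.sin(np.deg2rad(delta_deg))

    # displayed perpendicular error on a fine grid (peak node included)
    r_fine = np.linspace(0.0, R, _FINE_GRID)
    eps_hand = d * np.sin(np.pi * r_fine / R)
    eps_disp = np.asarray(aug.displayed_eps(eps_hand, r_fine), dtype=float)
    d_disp = float(eps_disp[np.argmax(np.abs(eps_disp))])
    perceived_deg = float(
        np.rad2deg(np.arcsin(np.clip(d_disp / (c * R), -1.0, 1.0)))
    )

    peak_speed = rng.normal(PEAK_SPEED_MPS, PEAK_SPEED_SD_MPS)
    peak_speed = float(np.clip(peak_speed, 0.2, 0.8))
    r = _minimum_jerk_r(R, peak_speed)
    eps = d * np.sin(np.pi * r / R)
    start = np.asarray(start, dtype=float)
    tpos = spec.target.position(start)
    u = (tpos - start) / R
    v = np.array([-u[1], u[0]])
    pts = start + np.outer(r, u) + np.outer(eps, v)
    traj = Trajectory(
        t=np.arange(r.size) * 0.01,
        x=pts[:, 0],
        y=pts[:, 1],
        start=start,
        target=spec.target,
    )
    return traj, perceived_deg, peak_speed


def update_learner(
    state: LearnerState, perceived_error_deg: float, update_enabled: bool = True
) -> LearnerState:
    """Advance the learner by one trial: theta += lambda * perceived error."""
    if not update_enabled:
        return state
    lam = state.lambda_frac
    if state.cautious and abs(perceived_error_deg) > state.cautious_threshold_deg:
        lam *= state.cautious_factor
    return replace(state, theta_hat_deg=state.theta_hat_deg + lam * perceived_error_deg)


def _group_augmentation(
    group: str, templates: OffsetTemplateSet | None, target: TargetSpec
) -> AugmentationSpec:
    if group == "control":
        return AugmentationSpec(mode="none")
    if group in GROUP_GAINS:
        return AugmentationSpec(mode="gain", gain_g=GROUP_GAINS[group])
    if group == "offset":
        if templates is None:
            raise ConfigurationError("offset group reached training without templates")
        return templates.spec_for(target)
    raise ConfigurationError(f"unknown group {group!r}")


def simulate_subject(
    group: str,
    schedule: ExperimentSchedule,
    seed: int,
    subject_id: str = "s01",
    state: LearnerState | None = None,
    grid_size: int = 50,
    keep_trajectories: bool = False,
) -> list[TrialRecord] | tuple[list[TrialRecord], list[Trajectory]]:
    """Run one subject through the full schedule.

    The offset group's templates are built from that subject's own baseline
    probe trials, frozen at the end of baseline, and applied throughout
    training.  Deterministic given ``seed``.
    """
    if group not in GROUPS:
        raise ConfigurationError(f"group must be one of {GROUPS}, got {group!r}")
    rng = np.random.default_rng(seed)
    st = state if state is not None else LearnerState()
    templates: OffsetTemplateSet | None = None
    probe_trajs: list[Trajectory] = []
    records: list[TrialRecord] = []
    trajs: list[Trajectory] = []

    none_aug = AugmentationSpec(mode="none")
    for spec in schedule:
        if spec.phase != "baseline" and templates is None and group == "offset":
            templates = build_offset_template(probe_trajs, grid_size=grid_size)
        if spec.phase == "training" and spec.augmentation_on:
            aug = _group_augmentation(group, templates, spec.target)
        else:
            aug = none_aug
        traj, perceived, peak_speed = execute_trial(st, spec, aug, rng)
        err = trajectory_error(traj)
        update = st.learn_on_catch or not spec.is_catch
        st = update_learner(st, perceived, update_enabled=update)
        if spec.phase == "baseline" and spec.is_catch:
            probe_trajs.append(traj)
        records.append(
            TrialRecord(
                subject_id=subject_id,
                group=group,
                index=spec.index,
                phase=spec.phase,
                phase_index=spec.phase_index,
                target_deg=spec.target.angle_deg,
                rotation_on=spec.rotation_on,
                augment_mode=aug.mode,
                is_catch=spec.is_catch,
                trajectory_error_m=err,
                peak_speed_mps=peak_speed,
            )
        )
        if keep_trajectories:
            trajs.append(traj)
    if keep_trajectories:
        return records, trajs
    return records


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Trial records as a tidy DataFrame (one row per movement)."""
    return pd.DataFrame([r.__dict__ for r in records])


def simulate_experiment(
    seed: int,
    group_size: int = 4,
    groups: Sequence[str] = GROUPS,
    state: LearnerState | None = None,
    schedule: ExperimentSchedule | None = None,
    **schedule_kwargs,
) -> pd.DataFrame:
    """Simulate the full multi-group experiment into one trial-log frame.

    All subjects share one schedule (catch trials fall on the same movement
    numbers for every subject); each subject gets an independent noise
    stream spawned from ``seed``.
    """
    if group_size < 1:
        raise ConfigurationError("group_size must be >= 1")
    if schedule is None:
        schedule = make_schedule(seed, **schedule_kwargs)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(groups) * group_size)
    frames = []
    k = 0
    for group in groups:
        for j in range(group_size):
            sid = f"{group}_{j + 1:02d}"
            sub_seed = int(children[k].generate_state(1)[0] % (2**31))
            recs = simulate_subject(group, schedule, sub_seed, subject_id=sid, state=state)
            frames.append(records_to_frame(recs))
            k += 1
    return pd.concat(frames, ignore_index=True)


def simulate_error_sequence(
    lambda_frac: float,
    gain: float,
    rotation_deg: float = ROTATION_DEG,
    n_trials: int = 40,
    noise_sd_deg: float = 0.0,
    c: float = 0.6,
    seed: int | None = None,
) -> np.ndarray:
    """Signed angular error on successive training trials under a feedback gain.

    A bare training loop (every trial augmented, no catches) useful for
    studying the stability regimes of trial-to-trial learning: monotone
    decay for lambda*gain < 1, sign-alternating decay for
    1 < lambda*gain < 2, divergence beyond 2.
    """
    rng = np.random.default_rng(seed)
    st = LearnerState(
        lambda_frac=lambda_frac,
        motor_noise_sd_deg=noise_sd_deg,
        online_correction_c=c,
    )
    target = TargetSpec(90.0, DEFAULT_RADIUS_M, "training")
    aug = AugmentationSpec(mode="gain", gain_g=gain) if gain != 1.0 else AugmentationSpec()
    errors = np.empty(n_trials)
    for k in range(n_trials):
        noise = rng.normal(0.0, noise_sd_deg) if noise_sd_deg else 0.0
        delta = rotation_deg - st.theta_hat_deg + noise
        errors[k] = delta
        d_disp = (aug.gain_g or 1.0) * c * target.radius_m * np.sin(np.deg2rad(delta))
        perceived = float(
            np.rad2deg(np.arcsin(np.clip(d_disp / (c * target.radius_m), -1.0, 1.0)))
        )
        st = update_learner(st, perceived)
    return errors
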