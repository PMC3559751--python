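"""Error-augmentation feedback transforms.

Two ways of enlarging the movement error a subject sees, both acting only
on the perpendicular component of the cursor position (motion along the
straight line toward the target is displayed unaltered):

* **gain** — the displayed perpendicular error is ``g * eps``; the
  experimental gains are 2 and 3.1.
* **offset** — a fixed per-subject, per-target template ``eps_o(r)`` is
  added to the instantaneous error: displayed error is ``eps + eps_o(r)``.
  The template is the trial-average error profile recorded during a
  subject's initial exposure to the rotation, so at the start of training
  gain-2 and offset feedback look alike, but offset feedback keeps errors
  visibly large even once the subject has improved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .geometry import (
    ErrorProfile,
    TargetSpec,
    Trajectory,
    TRAINING_ANGLES_DEG,
    _line_frame,
    average_error_profile,
    error_profile,
)

__all__ = [
    "AugmentationSpec",
    "OffsetTemplateSet",
    "cursor_position",
    "augment_profile",
    "build_offset_template",
]

Mode = Literal["none", "gain", "offset"]


class ConfigurationError(ValueError):
    """Raised when an augmentation spec is inconsistent with the trial."""


class InsufficientDataError(ValueError):
    """Raised when too few trials exist to build a template."""


@dataclass(frozen=True)
class AugmentationSpec:
    """How displayed error relates to actual error on one trial."""

    mode: Mode = "none"
    gain_g: float | None = None
    template: ErrorProfile | None = None

    def __post_init__(self) -> None:
        if self.mode == "gain":
            if self.gain_g is None or not (self.gain_g > 0):
                raise ConfigurationError("gain mode requires gain_g > 0")
        elif self.mode == "offset":
            if self.template is None:
                raise ConfigurationError("offset mode requires a template")
        elif self.mode != "none":
            raise ConfigurationError(f"unknown augmentation mode {self.mode!r}")

    def displayed_eps(self, eps: np.ndarray | float, r: np.ndarray | float):
        """Perpendicular error shown to the subject at along-line distance r."""
        if self.mode == "none":
            return eps
        if self.mode == "gain":
            return self.gain_g * eps
        return eps + self.template.interp(r)


class OffsetTemplateSet(Mapping[float, ErrorProfile]):
    """One offset template per training target for a single subject."""

    def __init__(self, templates: Mapping[float, ErrorProfile]):
        missing = set(TRAINING_ANGLES_DEG) - set(templates)
        if missing:
            raise InsufficientDataError(
                f"missing templates for training targets {sorted(missing)}"
            )
        grids = [templates[a].r_grid for a in TRAINING_ANGLES_DEG]
        for g in grids[1:]:
            if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
                raise ConfigurationError("template grids must be identical")
        self._templates = dict(templates)

    def __getitem__(self, angle_deg: float) -> ErrorProfile:
        try:
            return self._templates[angle_deg]
        except KeyError:
            raise ConfigurationError(
                f"no offset template for target {angle_deg} deg"
            ) from None

    def __iter__(self):
        return iter(self._templates)

    def __len__(self) -> int:
        return len(self._templates)

    def spec_for(self, target: TargetSpec) -> AugmentationSpec:
        return AugmentationSpec(mode="offset", template=self[target.angle_deg])


def cursor_position(
    hand: Sequence[float],
    start: Sequence[float],
    target: TargetSpec,
    spec: AugmentationSpec,
) -> np.ndarray:
    """Displayed cursor position for a hand position under augmentation.

    The hand point is decomposed into its along-line coordinate r and
    signed perpendicular coordinate eps relative to the ideal straight
    line; r is displayed unchanged and eps is transformed by ``spec``.
    """
    hand = np.asarray(hand, dtype=float)
    start = np.asarray(start, dtype=float)
    if not (np.all(np.isfinite(hand)) and np.all(np.isfinite(start))):
        raise ValueError("cursor_position requires finite inputs")
    u, v, _ = _line_frame(start, target)
    rel = hand - start
    r = float(rel @ u)
    eps = float(rel @ v)
    eps_disp = spec.displayed_eps(eps, r)
    return start + r * u + eps_disp * v


def augment_profile(profile: ErrorProfile, spec: AugmentationSpec) -> ErrorProfile:
    """Apply an augmentation transform to a whole error profile."""
    eps_disp = np.asarray(spec.displayed_eps(profile.eps, profile.r_grid), dtype=float)
    return ErrorProfile(profile.r_grid.copy(), eps_disp, profile.target)


def build_offset_template(
    initial_exposure_trials: Iterable[Trajectory], grid_size: int = 50
) -> OffsetTemplateSet:
    """Average initial-exposure error profiles into per-target templates.

    ``initial_exposure_trials`` are the rotated probe trials collected
    during the baseline phase (under the default schedule, five per
    training target per subject).  Profiles are grouped by target angle
    and averaged; every training target must contribute at least one trial.
    """
    by_target: dict[float, list[ErrorProfile]] = {}
    for traj in initial_exposure_trials:
        by_target.setdefault(traj.target.angle_deg, []).append(
            error_profile(traj, grid_size=grid_size)
        )
    empty = [a for a in TRAINING_ANGLES_DEG if not by_target.get(a)]
    if empty:
        raise InsufficientDataError(
            f"no initial-exposure trials for training targets {empty}"
        )
    return OffsetTemplateSet(
        {a: average_error_profile(by_target[a]) for a in TRAINING_ANGLES_DEG}
    )
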