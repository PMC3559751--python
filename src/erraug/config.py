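"""Run configuration: explicit, file-round-trippable experiment settings."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulated experiment.

    All seeds are explicit (no wall-clock seeding); ``config_hash`` of the
    serialized form is stamped into every output manifest.
    """

    seed: int = 1
    group_size: int = 4
    baseline_trials: int = 165
    training_trials: int = 390
    washout_trials: int = 165
    probe_block: int = 8
    baseline_probe_trials: int = 120
    radius_m: float = 0.1
    lambda_frac: float = 0.32
    motor_noise_sd_deg: float = 1.5
    online_correction_c: float = 0.6
    gain_x2: float = 2.0
    gain_x3p1: float = 3.1
    grid_size: int = 50
    learn_on_catch: bool = True
    recovery_replicates: int = 200
    noise_sd_m: float = 0.94e-3

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(d)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
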