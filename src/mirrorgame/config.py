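"""Declarative run configuration tying the pipeline stages together.

A :class:`RunConfig` holds every stage's tunables plus one master seed; all
per-stage seeds are derived from it with the stateless splitmix hash, so a
whole end-to-end run is reproducible from the config file alone.  The config
round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .controller import ControllerConfig
from .follow_net import FollowNetConfig
from .lead_net import LeadNetConfig
from .synthetic import SynthesisConfig, splitmix64

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Primitive-valued, file-serializable configuration of a full run."""

    master_seed: int = 0
    rate: float = 90.0
    n_trials: int = 6
    trial_duration_s: float = 30.0
    lag_frames: int = 20
    follower_noise: float = 0.02
    # follow-net
    follow_history: int = 120
    follow_stride: int = 4
    follow_hidden: int = 128
    follow_dense: tuple[int, ...] = (128, 64)
    follow_epochs: int = 15
    follow_lr: float = 1e-3
    # lead-net
    lead_chunk_s: float = 10.0
    lead_hidden: int = 128
    lead_epochs: int = 15
    lead_recursions: int = 15
    lead_used_s: float = 120.0
    lead_noise_sd: float = 0.01
    # analysis
    wtlcc_window: int = 300
    wtlcc_step: int = 50
    wtlcc_max_lag: int = 90

    def seed_for(self, stage: str) -> int:
        """Stable per-stage seed derived from the master seed."""
        return splitmix64(self.master_seed, sum(ord(c) * (i + 1) for i, c in enumerate(stage)))

    def synthesis(self) -> SynthesisConfig:
        return SynthesisConfig(
            seed=self.seed_for("synthesis"),
            rate=self.rate,
            lag=self.lag_frames,
            follower_noise=self.follower_noise,
        )

    def follow(self) -> FollowNetConfig:
        return FollowNetConfig(
            history=self.follow_history,
            stride=self.follow_stride,
            hidden=self.follow_hidden,
            dense_widths=tuple(self.follow_dense),
            epochs=self.follow_epochs,
            learning_rate=self.follow_lr,
        )

    def lead(self) -> LeadNetConfig:
        return LeadNetConfig(
            rate=self.rate,
            stride=self.follow_stride,
            chunk_seconds=self.lead_chunk_s,
            hidden=self.lead_hidden,
            epochs=self.lead_epochs,
            noise_sd=self.lead_noise_sd,
            recursions=self.lead_recursions,
            used_seconds=self.lead_used_s,
        )

    def controller(self) -> ControllerConfig:
        return ControllerConfig()

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["follow_dense"] = list(d["follow_dense"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "follow_dense" in d:
            d["follow_dense"] = tuple(d["follow_dense"])
        return cls(**d)
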