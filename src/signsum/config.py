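"""Structured run configuration (YAML) shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Round-trippable settings for a ranking / simulation run."""

    statistic: str = "sign_sum"
    a: int = 1
    b: int = 10
    mode: str | None = None
    n_draws: int = 10_000
    seed: int = 0
    orientation: str = "signed"
    situation: str | None = None
    n: int | None = None
    n_reps: int = 100
    k_top: int = 100
    out: str | None = None
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls(**raw)
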