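"""Pipeline configuration: a single YAML/JSON-loadable dataclass.

Unknown keys are rejected so a typo in a config file fails loudly before
any stage runs; the resolved configuration is written next to the run's
outputs for reproducibility.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .simulate import SimulationConfig


@dataclass
class PipelineConfig:
    """All tunable parameters of the end-to-end pipeline."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # built-in caller, run under two parameterizations as the two "callers"
    window: int = 100
    step: int = 50
    alpha: float = 1e-6
    caller_b_window: int = 150
    caller_b_step: int = 75
    min_support: int = 2
    require_tss_cover: bool = True
    pseudocount: float = 0.0
    fc_threshold: float = 1.5
    min_pairs: int = 4
    metagene_bins: tuple[int, int, int] = (20, 50, 30)
    codon_window: int = 100
    n_shuffles: int = 200
    flank: int = 200
    bin_width: int = 10
    write_reads: bool = False  # per-sample read BEDs are large; opt in

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = _build(SimulationConfig, self.simulation)
        self.metagene_bins = tuple(self.metagene_bins)
        self.validate()

    def validate(self) -> None:
        if not (self.window >= self.step > 0):
            raise ValueError("need window >= step > 0")
        if not (self.caller_b_window >= self.caller_b_step > 0):
            raise ValueError("need caller_b_window >= caller_b_step > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        if not 1 <= self.min_pairs <= self.simulation.n_pairs:
            raise ValueError("min_pairs must be between 1 and n_pairs")
        if any(b <= 0 for b in self.metagene_bins) or len(self.metagene_bins) != 3:
            raise ValueError("metagene_bins must be three positive counts")
        if self.flank <= 0 or (2 * self.flank) % self.bin_width != 0:
            raise ValueError("bin_width must divide 2*flank")

    # ------------------------------------------------------------- loading
    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build(cls, data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        from .io import atomic_write

        with atomic_write(path) as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)
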