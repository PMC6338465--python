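"""Run configuration: one JSON-serializable object that reproduces a run.

Defaults follow the measured protocol wherever one exists: 2,500 Hz
sampling, 250 Hz smoothing, 100 ms velocity windows, tenth-length median
filter, 0-60 pN range with 3 pN (opposing) / 2 pN (hairpin) bins, eWLC
with Lp = 40 nm and S = 1000 pN.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

from .kinetics import RateSet
from .polymer import ForkParams, PolymerParams


@dataclass
class PipelineConfig:
    f_c: float = 250.0  # Hz
    window_s: float = 0.1
    median_fraction: float = 0.1
    bin_width_opposing: float = 3.0  # pN
    bin_width_hairpin: float = 2.0  # pN
    f_range: tuple[float, float] = (0.0, 60.0)
    min_count: int = 5
    average: str = "ensemble"

    @property
    def bin_width(self) -> dict:
        return {"opposing_force": self.bin_width_opposing,
                "hairpin_assisting": self.bin_width_hairpin}


@dataclass
class FittingConfig:
    mode: str = "shared_chemistry"
    n_starts: int = 50
    weights: str = "none"
    force_column: str = "f_mean"
    n_boot: int = 200


@dataclass
class RunConfig:
    """Full provenance for a simulate/process/fit run."""

    scheme_id: str = "br-binding"
    seed: int = 0
    fs: float = 2500.0  # Hz
    sigma_nm: float = 2.0
    rates: dict = field(default_factory=dict)  # context -> RateSet dict
    fork: dict = field(default_factory=lambda: asdict(ForkParams()))
    polymer: dict = field(default_factory=lambda: asdict(PolymerParams()))
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    fitting: FittingConfig = field(default_factory=FittingConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> tuple["RunConfig", list[str]]:
        """Build a config, applying defaults; returns (config, defaulted keys)."""
        defaulted = []
        kw = {}
        for f in fields(cls):
            if f.name in d:
                v = d[f.name]
                if f.name == "pipeline" and isinstance(v, dict):
                    v = PipelineConfig(**v)
                if f.name == "fitting" and isinstance(v, dict):
                    v = FittingConfig(**v)
                kw[f.name] = v
            else:
                defaulted.append(f.name)
        cfg = cls(**kw)
        if isinstance(cfg.pipeline, dict):
            cfg.pipeline = PipelineConfig(**cfg.pipeline)
        if isinstance(cfg.fitting, dict):
            cfg.fitting = FittingConfig(**cfg.fitting)
        return cfg, defaulted

    def rate_set(self, context: str) -> RateSet:
        return RateSet.from_dict(self.rates[context])

    def fork_params(self) -> ForkParams:
        return ForkParams(**self.fork)

    def polymer_params(self) -> PolymerParams:
        return PolymerParams(**self.polymer)
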