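"""Run configuration: a single serializable record of everything a run uses.

A :class:`RunConfig` captures the construct (preset name or inline ITAM
list), scheme, rates, totals, sweep grid, solver tolerances and the fit
jitter seed.  It loads from / saves to YAML, and a run's manifest
reproduces it exactly, making any command-line run reproducible from
its manifest alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import yaml

from .constructs import (
    ChainSpec,
    ConcentrationTotals,
    RateSet,
    ValidationError,
    chain_spec_from_dict,
    chain_spec_to_dict,
    preset_construct,
)

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    construct: Optional[str] = None  # preset name; or use inline_spec
    inline_spec: Optional[dict] = None  # chain_spec_to_dict form
    scheme: Optional[str] = None  # overrides the preset's scheme
    zap_enabled: Optional[bool] = None
    observable: str = "bound_zap"
    rates: RateSet = field(default_factory=RateSet)
    totals: ConcentrationTotals = field(default_factory=ConcentrationTotals)
    x_min: float = -2.0
    x_max: float = 2.0
    x_points: int = 61
    tol: float = 1e-8
    t_max: float = 1e6
    seed: int = 0  # fit multi-start jitter only

    def chain_spec(self) -> ChainSpec:
        from dataclasses import replace

        if self.inline_spec is not None:
            spec = chain_spec_from_dict(self.inline_spec)
        elif self.construct is not None:
            spec = preset_construct(self.construct)
        else:
            raise ValidationError("config must set 'construct' or 'inline_spec'")
        if self.scheme is not None:
            spec = replace(spec, scheme=self.scheme)
        if self.zap_enabled is not None:
            spec = replace(spec, zap_enabled=self.zap_enabled)
        return spec

    def x_grid(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.x_points)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rates"] = asdict(self.rates)
        d["totals"] = asdict(self.totals)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "rates" in d and not isinstance(d["rates"], RateSet):
            d["rates"] = RateSet(**d["rates"])
        if "totals" in d and not isinstance(d["totals"], ConcentrationTotals):
            d["totals"] = ConcentrationTotals(**d["totals"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
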