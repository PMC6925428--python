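"""Run configuration: one YAML file (one seed) describes a whole analysis."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .rates import AGE_ALL, AGE_GROUPS, NATIONALITIES, PERIOD_YEARS

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration (reported before any compute)."""


@dataclass
class RunConfig:
    seed: int
    out_dir: str
    # either pre-existing inputs ...
    counts: str | None = None
    indicators: str | None = None
    adjacency: str | None = None
    polygons: str | None = None
    # ... or a synthetic city simulated in-run
    simulate: dict[str, Any] | None = None
    periods: dict[str, tuple[int, int]] = field(default_factory=lambda: dict(PERIOD_YEARS))
    mcmc: dict[str, int] = field(
        default_factory=lambda: {"n_chains": 2, "n_iter": 5000, "burn_in": 2000, "thin": 2}
    )
    tau_u_prior: tuple[float, float] = (0.5, 0.0005)
    tau_v_prior: tuple[float, float] = (0.5, 0.0005)
    percentiles: tuple[float, float] = (5.0, 95.0)
    septiles: int = 7
    smooth_age_groups: tuple[str, ...] = (AGE_ALL,)
    smooth_nationalities: tuple[str, ...] = NATIONALITIES
    regress_age_groups: tuple[str, ...] = AGE_GROUPS + (AGE_ALL,)
    regress_nationalities: tuple[str, ...] = NATIONALITIES
    shared_fields: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        if "seed" not in raw:
            raise ConfigError("config must set an integer seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "periods" in kwargs:
            kwargs["periods"] = {k: tuple(v) for k, v in kwargs["periods"].items()}
        for key in ("tau_u_prior", "tau_v_prior", "percentiles"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        for key in (
            "smooth_age_groups",
            "smooth_nationalities",
            "regress_age_groups",
            "regress_nationalities",
        ):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        if self.simulate is None and not (self.counts and self.indicators and self.adjacency):
            raise ConfigError(
                "either a 'simulate' block or counts+indicators+adjacency paths are required"
            )
        spans = sorted(self.periods.values())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if a1 > a0 and b0 <= a1 and a0 <= b1:
                raise ConfigError(f"periods overlap: {(a0, a1)} and {(b0, b1)}")
        lo, hi = self.percentiles
        if not 0 <= lo < hi <= 100:
            raise ConfigError("percentiles must satisfy 0 <= lo < hi <= 100")
        if self.septiles < 2:
            raise ConfigError("need at least 2 quantile groups")
        for k in ("n_chains", "n_iter", "burn_in", "thin"):
            if k not in self.mcmc:
                raise ConfigError(f"mcmc block missing {k!r}")
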