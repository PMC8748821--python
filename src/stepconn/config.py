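"""Pipeline configuration: defaults are the published analysis parameters.

The defaults encode the analysis as reported: ridge 0.5, FDR level 0.05,
1000 bootstraps of 90% of subjects, 95% edge-retention threshold, steps 1-5,
hub multiplier 1.5, 5000 permutations. Configs round-trip losslessly through
YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass(frozen=True)
class PathsConfig:
    timeseries_dir: str = "timeseries"
    phenotype_file: str = "phenotypes.tsv"
    parcellation_file: str = "parcellation.tsv"
    output_dir: str = "outputs"


@dataclass(frozen=True)
class ConnectivityConfig:
    rho: float = 0.5
    degree_mode: str = "absolute"          # or "positive_only"
    ridge_dialect: str = "identity"        # or "scaled"


@dataclass(frozen=True)
class SeedsConfig:
    alpha: float = 0.05
    phenotype: str = "whr"
    n_boot: int = 1000
    boot_frac: float = 0.9


@dataclass(frozen=True)
class SFCConfig:
    percentile: float = 95.0
    max_step: int = 5
    hub_multiplier: float = 1.5
    edge_rank: str = "signed"              # or "absolute"


@dataclass(frozen=True)
class StatsConfig:
    t_variant: str = "welch"               # or "pooled"
    criteria: str = "bmi_whr"              # or "who_whr"
    n_boot_balanced: int = 1000


@dataclass(frozen=True)
class BehaviorConfig:
    n_perm: int = 5000
    step: int | None = None                # None -> max_step
    convention: str = "add_one"            # or "plug_in"


@dataclass(frozen=True)
class PipelineConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    seeds: SeedsConfig = field(default_factory=SeedsConfig)
    sfc: SFCConfig = field(default_factory=SFCConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    rng_seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        sections = {
            "paths": PathsConfig, "connectivity": ConnectivityConfig, "seeds": SeedsConfig,
            "sfc": SFCConfig, "stats": StatsConfig, "behavior": BehaviorConfig,
        }
        kwargs: dict = {}
        for key, value in payload.items():
            if key in sections:
                known = {f.name for f in fields(sections[key])}
                bad = set(value) - known
                if bad:
                    raise ConfigurationError(f"unknown keys in '{key}' section: {sorted(bad)}")
                kwargs[key] = sections[key](**value)
            elif key == "rng_seed":
                kwargs[key] = int(value)
            else:
                raise ConfigurationError(f"unknown config section {key!r}")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    def with_seed(self, rng_seed: int) -> "PipelineConfig":
        return replace(self, rng_seed=int(rng_seed))
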