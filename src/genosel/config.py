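"""Run configuration: prior hyperparameters, EM and MCMC settings.

Two named presets carry the hyperparameter pairs used throughout the
benchmark scenarios: ``bsr`` (nu=4.012, S=0.002) for BayesA-type shrinkage
over all SNPs, and ``ssvs`` (nu=4.234, S=0.0429) for the variable-selection
methods (SSVS/BayesB and weighted BSR with p < 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["ConfigError", "PriorSettings", "EmSettings", "McmcSettings",
           "RunConfig", "PRESETS", "load_config"]


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class PriorSettings:
    nu: float = 4.012
    s: float = 0.002
    p: float = 1.0


@dataclass
class EmSettings:
    tolerance: float = 1e-6
    max_iterations: int = 2000


@dataclass
class McmcSettings:
    total_cycles: int = 11000
    burn_in: int = 1000
    thinning: int = 10
    mh_proposals_per_locus: int = 10


@dataclass
class RunConfig:
    prior: PriorSettings = field(default_factory=PriorSettings)
    em: EmSettings = field(default_factory=EmSettings)
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    maf_threshold: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.prior.nu < 0:
            problems.append(f"prior.nu must be >= 0, got {self.prior.nu}")
        if self.prior.s < 0:
            problems.append(f"prior.s must be >= 0, got {self.prior.s}")
        if not (0 < self.prior.p <= 1):
            problems.append(f"prior.p must be in (0, 1], got {self.prior.p}")
        if self.em.tolerance <= 0:
            problems.append(f"em.tolerance must be > 0, got {self.em.tolerance}")
        if self.em.max_iterations < 1:
            problems.append("em.max_iterations must be >= 1")
        if self.mcmc.burn_in >= self.mcmc.total_cycles:
            problems.append(
                f"mcmc.burn_in ({self.mcmc.burn_in}) must be smaller than "
                f"total_cycles ({self.mcmc.total_cycles})"
            )
        if self.mcmc.thinning < 1:
            problems.append("mcmc.thinning must be >= 1")
        if self.mcmc.mh_proposals_per_locus < 1:
            problems.append("mcmc.mh_proposals_per_locus must be >= 1")
        if not (0 <= self.maf_threshold < 0.5):
            problems.append(
                f"maf_threshold must be in [0, 0.5), got {self.maf_threshold}"
            )
        if problems:
            raise ConfigError("; ".join(problems))

    def to_dict(self) -> dict:
        return asdict(self)


#: (nu, S, default p) per preset.
PRESETS = {
    "bsr": {"nu": 4.012, "s": 0.002, "p": 1.0},
    "ssvs": {"nu": 4.234, "s": 0.0429, "p": 0.5},
    "wbsr": {"nu": 4.234, "s": 0.0429, "p": 0.5},
}


def load_config(path=None, preset: str | None = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file, a preset, and overrides.

    Precedence (lowest to highest): built-in defaults, ``preset``, the YAML
    file, keyword overrides.  Overrides use dotted keys for nested fields,
    e.g. ``load_config(preset='ssvs', **{'prior.p': 0.1})``.
    """
    cfg = RunConfig()
    if preset is not None:
        if preset not in PRESETS:
            raise ConfigError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        for key, val in PRESETS[preset].items():
            setattr(cfg.prior, key, val)
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        _apply_mapping(cfg, raw, source=str(path))
    for dotted, val in overrides.items():
        _apply_dotted(cfg, dotted, val)
    cfg.validate()
    return cfg


def _apply_mapping(cfg: RunConfig, raw: dict, source: str) -> None:
    for section, value in raw.items():
        if section in ("prior", "em", "mcmc"):
            block = getattr(cfg, section)
            if not isinstance(value, dict):
                raise ConfigError(f"{source}: section {section!r} must be a mapping")
            for key, v in value.items():
                if not hasattr(block, key):
                    raise ConfigError(f"{source}: unknown key {section}.{key}")
                setattr(block, key, type(getattr(block, key))(v))
        elif section in ("maf_threshold", "seed"):
            setattr(cfg, section, type(getattr(cfg, section))(value))
        elif section == "preset":
            if value not in PRESETS:
                raise ConfigError(f"{source}: unknown preset {value!r}")
            for key, v in PRESETS[value].items():
                setattr(cfg.prior, key, v)
        else:
            raise ConfigError(f"{source}: unknown section {section!r}")


def _apply_dotted(cfg: RunConfig, dotted: str, val) -> None:
    parts = dotted.split(".")
    obj = cfg
    for part in parts[:-1]:
        obj = getattr(obj, part)
    if not hasattr(obj, parts[-1]):
        raise ConfigError(f"unknown configuration key {dotted!r}")
    setattr(obj, parts[-1], type(getattr(obj, parts[-1]))(val))
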