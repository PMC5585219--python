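"""Run configuration: documented keys, validation, YAML round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .adapter import AdapterSpec


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range parameter values."""


@dataclass
class RunConfig:
    """Stage parameters for the calling pipeline.

    All thresholds are surfaced here and on the command line; unknown
    config keys are rejected rather than silently ignored.
    """

    adapter: AdapterSpec = field(default_factory=AdapterSpec.v2_default)
    min_overlap: int = 30
    max_mismatch_frac: float = 0.1
    trim_n: int = 2
    max_edit_frac: float = 0.05
    family_mismatch_frac: float = 0.01
    min_reads: int = 3
    max_key_mismatches: int = 2
    spurious_threshold: int = 5
    per_block_key: bool = False
    min_duplex_molecules: int = 1
    keep_unknown_orientation: bool = True
    seed: int = 1
    log_level: str = "INFO"

    _RANGES = {
        "min_overlap": (1, 10_000),
        "max_mismatch_frac": (0.0, 1.0),
        "trim_n": (0, 50),
        "max_edit_frac": (0.0, 1.0),
        "family_mismatch_frac": (0.0, 1.0),
        "min_reads": (1, 10_000),
        "max_key_mismatches": (0, 24),
        "spurious_threshold": (0, 24),
        "min_duplex_molecules": (1, 10_000),
    }

    def __post_init__(self):
        for name, (lo, hi) in self._RANGES.items():
            value = getattr(self, name)
            if not lo <= value <= hi:
                raise ConfigError(f"{name}={value} outside [{lo}, {hi}]")

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["adapter"] = self.adapter.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "adapter" in kwargs and isinstance(kwargs["adapter"], dict):
            kwargs["adapter"] = AdapterSpec.from_dict(kwargs["adapter"])
        return cls(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} is not a mapping")
    return RunConfig.from_dict(data)


def dump_run_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def dump_sim_config(sim_config, path: str | Path) -> None:
    """Echo the resolved simulation parameters (reference stored as lengths only)."""
    d = {
        "n_molecules": sim_config.n_molecules,
        "fragment_length_mean": sim_config.fragment_length_mean,
        "fragment_length_sd": sim_config.fragment_length_sd,
        "family_size_model": sim_config.family_size_model,
        "family_size_params": dict(sim_config.family_size_params),
        "polymerase_error_rate": sim_config.polymerase_error_rate,
        "damage_rate_c_to_a": sim_config.damage_rate_c_to_a,
        "seq_error_rate": sim_config.seq_error_rate,
        "read_length": sim_config.read_length,
        "quality": sim_config.quality,
        "seed": sim_config.seed,
        "mispair_profile": [float(p) for p in sim_config.mispair_profile],
        "adapter": sim_config.adapter.to_dict(),
        "reference_loci": {k: len(v) for k, v in sorted(sim_config.reference.items())},
        "target_sites": [
            {"locus": t.locus, "position": t.position, "ref": t.ref,
             "alt": t.alt, "vaf": t.vaf}
            for t in sim_config.target_sites
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)
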