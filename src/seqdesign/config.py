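"""Run configuration: YAML parsing with schema validation and round-trip.

A run config is a nested mapping with a global ``seed``, an output
directory, and one optional parameter block per pipeline.  Unknown keys are
rejected with the offending field path so typos fail loudly; omitted keys
take the documented defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig", "parse_config", "write_config"]

_BLOCK_KEYS = {
    "population": {
        "demography", "n_hap", "region_length_bp", "Ne",
        "mutation_rate", "recombination_rate",
    },
    "effects": {"pi0", "q0", "rr_cap", "q_cap", "tau_coef"},
    "cohort": {"n_case", "n_control", "prevalence"},
    "twophase": {
        "scheme", "n_subsample", "rare_threshold", "maf_common", "alpha",
        "r2_threshold",
    },
    "design": {"n_total"},
    "yield": {
        "n_subsample", "c_values", "c_prime_values", "n_reference",
        "n_cases", "n_controls", "alpha",
    },
    "pedigree": {"min_cases", "n_families", "design_code", "prevalence"},
    "power": {
        "design_type", "total_units", "stage1_prop", "c_min", "threshold",
        "seq_per_family", "cost_enroll", "cost_seq", "cost_genotype",
        "genome_total", "genome_causal", "grid",
    },
}
_TOP_KEYS = {"seed", "outdir", "verbose"} | set(_BLOCK_KEYS)


@dataclass
class RunConfig:
    """Validated run configuration with per-module parameter blocks."""

    seed: int = 0
    outdir: str = "seqdesign_out"
    verbose: bool = False
    blocks: dict = field(default_factory=dict)

    def block(self, name: str) -> dict:
        return dict(self.blocks.get(name, {}))

    def to_dict(self) -> dict:
        d = {"seed": self.seed, "outdir": self.outdir, "verbose": self.verbose}
        d.update({k: dict(v) for k, v in self.blocks.items()})
        return d


def _validate(d: dict) -> RunConfig:
    if not isinstance(d, dict):
        raise ValueError("config root must be a mapping")
    blocks = {}
    for key, val in d.items():
        if key not in _TOP_KEYS:
            raise ValueError(f"unknown config key: {key!r}")
        if key in _BLOCK_KEYS:
            if not isinstance(val, dict):
                raise ValueError(f"config block {key!r} must be a mapping")
            for sub in val:
                if sub not in _BLOCK_KEYS[key]:
                    raise ValueError(f"unknown config key: {key}.{sub}")
            blocks[key] = dict(val)
    return RunConfig(
        seed=int(d.get("seed", 0)),
        outdir=str(d.get("outdir", "seqdesign_out")),
        verbose=bool(d.get("verbose", False)),
        blocks=blocks,
    )


def parse_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    if hasattr(path, "read"):
        d = yaml.safe_load(path)
    else:
        with open(path) as fh:
            d = yaml.safe_load(fh)
    return _validate(d or {})


def write_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
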