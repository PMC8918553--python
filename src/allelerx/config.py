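"""Run configuration: per-stage parameter maps loaded from YAML.

A :class:`RunConfig` names a pipeline stage and carries its parameters.
Unknown keys are rejected so that typos in a params file fail loudly, and
every simulator stage must carry an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

STAGE_KEYS: Mapping[str, frozenset[str]] = {
    "design": frozenset({"fasta", "mut_pos", "ref_base", "alt_base", "length", "allele", "out"}),
    "screen": frozenset({"wells", "mode", "out"}),
    "quant": frozenset({"r1", "r2", "signatures", "max_mismatch", "theoretical", "out"}),
    "offtarget": frozenset({"query", "db", "max_mm", "top", "strands", "exclude", "out"}),
    "offtarget-expr": frozenset({"expr", "groups", "genes", "group_a", "group_b", "out"}),
    "qpcr": frozenset({"ct", "out"}),
    "simulate-reads": frozenset(
        {"seed", "n_fragments", "mut_fraction", "error_rate", "read_len", "anti_fraction"}
    ),
    "simulate-transcriptome": frozenset(
        {"seed", "query", "n_background", "background_len", "planted"}
    ),
    "simulate-screen": frozenset(
        {"seed", "true_ratios", "nt_intensity", "cv", "n_replicates"}
    ),
    "simulate-ct": frozenset(
        {"seed", "true_rel_expr", "conditions", "base_ct", "noise_sd"}
    ),
}


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    stage: str
    params: dict[str, Any] = field(default_factory=dict)
    out_dir: Path = Path(".")
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.stage not in STAGE_KEYS:
            raise ConfigError(
                f"unknown stage {self.stage!r}; known: {sorted(STAGE_KEYS)}"
            )
        unknown = set(self.params) - STAGE_KEYS[self.stage]
        if unknown:
            raise ConfigError(
                f"unknown parameter(s) for stage {self.stage!r}: {sorted(unknown)}"
            )
        if self.stage.startswith("simulate"):
            seed = self.params.get("seed")
            if not isinstance(seed, int) or isinstance(seed, bool):
                raise ConfigError(
                    f"stage {self.stage!r} requires an explicit integer seed"
                )
        self.out_dir = Path(self.out_dir)


def load_config(path: str | Path, stage: str, **overrides: Any) -> RunConfig:
    """Load a stage parameter map from a YAML file, applying overrides."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    out_dir = raw.pop("out_dir", ".")
    log_level = raw.pop("log_level", "INFO")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(stage=stage, params=raw, out_dir=out_dir, log_level=log_level)
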