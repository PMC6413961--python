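"""Run configuration: structured-text (YAML) config files with strict keys.

A config collects a stimulus block, the periphery choice, SACF/regularization
constants, cortical parameters (every Table-style symbol, defaulted), an
optional experiment block, the output directory and a global seed.  Unknown
keys are rejected by name; a loaded config round-trips losslessly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .cortex import CorticalParams
from .periodicity import SACFParams
from .stimuli import StimulusSpec


@dataclass(frozen=True)
class ExperimentBlock:
    """Batch-experiment request."""

    kind: str = "none"  # none | irn-sweep | irn-iterations | dyads
    n_runs: int = 10
    delays_ms: list[float] = field(default_factory=lambda: [4.0, 8.0, 12.0, 16.0])
    iteration_counts: list[int] = field(default_factory=lambda: [4, 8, 16, 32])
    intervals: list[str] = field(default_factory=list)
    tuning: str = "just"
    delay_t0_ms: float = 6.25
    iterations: int = 8


@dataclass(frozen=True)
class RunConfig:
    """Complete, validated run configuration."""

    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    periphery: str = "simple"
    sacf: SACFParams = field(default_factory=SACFParams)
    cortex: CorticalParams = field(default_factory=CorticalParams)
    experiment: ExperimentBlock = field(default_factory=ExperimentBlock)
    out_dir: str = "runs"
    seed: int = 0
    log_level: str = "INFO"

    def as_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "stimulus": StimulusSpec,
    "sacf": SACFParams,
    "cortex": CorticalParams,
    "experiment": ExperimentBlock,
}
_SCALARS = {"periphery": str, "out_dir": str, "seed": int, "log_level": str}


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise KeyError(
            f"unknown key(s) in [{section}]: {sorted(unknown)}; "
            f"valid keys: {sorted(valid)}"
        )
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid value in [{section}]: {exc}") from exc


def config_from_dict(data: dict) -> RunConfig:
    """Validate a nested dict into a RunConfig (all defaults filled)."""
    data = dict(data or {})
    kwargs = {}
    for section, cls in _SECTIONS.items():
        if section in data:
            kwargs[section] = _build_section(cls, data.pop(section) or {}, section)
    for key, typ in _SCALARS.items():
        if key in data:
            kwargs[key] = typ(data.pop(key))
    if data:
        raise KeyError(
            f"unknown top-level key(s): {sorted(data)}; valid: "
            f"{sorted(list(_SECTIONS) + list(_SCALARS))}"
        )
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config file; omitted keys get defaults."""
    path = Path(path)
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.as_dict(), sort_keys=False))


def with_overrides(config: RunConfig, **cortex_overrides) -> RunConfig:
    """Convenience: replace cortical parameters by keyword."""
    return replace(config, cortex=config.cortex.with_updates(**cortex_overrides))
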