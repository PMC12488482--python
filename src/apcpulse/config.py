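"""Run configuration: YAML schema, validation and defaults.

A run configuration is a nested mapping with sections ``model``,
``protocols``, ``reporter``, ``population``, ``analysis`` plus top-level
``output_dir`` and ``seed``.  Every field is optional: an empty file (or
empty mapping) yields the standard model constants and this package's
documented analysis defaults.  Unknown keys anywhere are rejected by name
so typos cannot silently revert a parameter to its default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .analytics import DEFAULT_PRE_WINDOW
from .model import KineticParameters, StimulusProtocol
from .synth import Cdk2GeneratorParams, PopulationConfig, ReporterParameters

__all__ = ["AnalysisSettings", "RunConfig", "load_config", "default_protocols"]


@dataclass(frozen=True)
class AnalysisSettings:
    """Windows and thresholds used by the analytics stage."""

    pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW
    post_window: tuple[float, float] | None = None  # derived from mg132_time
    min_prominence: float | None = None  # None -> robust noise-based default
    terminal_fraction: float = 0.5
    smooth_window: int = 5
    epsilon_fraction: float = 0.05  # of the control median dynamic range
    sustain_points: int = 3
    cdk2_threshold: float = 1.0
    cdk2_sustain_points: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.epsilon_fraction < 1:
            raise ValueError("epsilon_fraction must be in (0, 1)")
        if self.sustain_points < 1 or self.cdk2_sustain_points < 1:
            raise ValueError("sustain settings must be >= 1")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if not 0 <= self.terminal_fraction <= 1:
            raise ValueError("terminal_fraction must be in [0, 1]")


def default_protocols() -> dict[str, StimulusProtocol]:
    """The standard scenario suite: control plus the three perturbations."""
    return {
        "control": StimulusProtocol(),
        "rapamycin_0h": StimulusProtocol(rapamycin_time=0.0),
        "phosphatase_inhibitor": StimulusProtocol(phosphatase_inhibitor_time=0.0),
        "t129a": StimulusProtocol(cdh1_phospho_blocked=True),
    }


@dataclass
class RunConfig:
    """Fully validated configuration of one scenario-suite run."""

    model: KineticParameters = field(default_factory=KineticParameters)
    protocols: dict[str, StimulusProtocol] = field(default_factory=default_protocols)
    reporter: ReporterParameters = field(default_factory=ReporterParameters)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    cdk2: Cdk2GeneratorParams = field(default_factory=Cdk2GeneratorParams)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    output_dir: Path = Path("apcpulse_run")
    seed: int = 0
    control_scenario: str = "control"

    def __post_init__(self) -> None:
        if not self.protocols:
            raise ValueError("at least one protocol/scenario is required")


def _build(cls, section: str, mapping: dict[str, Any]):
    """Construct a dataclass from a config mapping, rejecting unknown keys."""
    if mapping is None:
        mapping = {}
    if not isinstance(mapping, dict):
        raise ValueError(f"config section {section!r} must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(mapping) - known)
    if unknown:
        raise ValueError(
            f"unknown key(s) in config section {section!r}: {', '.join(unknown)}"
        )
    coerced = {}
    for key, value in mapping.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"config section {section!r}: {exc}") from exc


_TOP_KEYS = {
    "model", "protocols", "reporter", "population", "cdk2",
    "analysis", "output_dir", "seed", "control_scenario",
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``path=None`` (or an empty file) returns the full default
    configuration.  ``overrides`` is an optional mapping merged on top of
    the file's top-level keys (used by the CLI for --seed/--out).
    """
    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config root must be a mapping")
        raw = loaded
    if overrides:
        raw = {**raw, **overrides}

    unknown = sorted(set(raw) - _TOP_KEYS)
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {', '.join(unknown)}")

    protocols_raw = raw.get("protocols")
    if protocols_raw is None:
        protocols = default_protocols()
    else:
        if not isinstance(protocols_raw, dict) or not protocols_raw:
            raise ValueError("'protocols' must be a non-empty mapping of scenarios")
        protocols = {
            name: _build(StimulusProtocol, f"protocols.{name}", spec)
            for name, spec in protocols_raw.items()
        }

    cfg = RunConfig(
        model=_build(KineticParameters, "model", raw.get("model")),
        protocols=protocols,
        reporter=_build(ReporterParameters, "reporter", raw.get("reporter")),
        population=_build(PopulationConfig, "population", raw.get("population")),
        cdk2=_build(Cdk2GeneratorParams, "cdk2", raw.get("cdk2")),
        analysis=_build(AnalysisSettings, "analysis", raw.get("analysis")),
        output_dir=Path(raw.get("output_dir", "apcpulse_run")),
        seed=int(raw.get("seed", 0)),
        control_scenario=str(raw.get("control_scenario", "control")),
    )
    if cfg.control_scenario not in cfg.protocols:
        raise ValueError(
            f"control_scenario {cfg.control_scenario!r} not among protocols "
            f"{sorted(cfg.protocols)}"
        )
    return cfg


def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    """Effective (post-default) configuration as a plain mapping, for the
    manifest and logs."""
    out = {
        "model": dataclasses.asdict(cfg.model),
        "protocols": {k: dataclasses.asdict(v) for k, v in cfg.protocols.items()},
        "reporter": dataclasses.asdict(cfg.reporter),
        "population": dataclasses.asdict(cfg.population),
        "cdk2": dataclasses.asdict(cfg.cdk2),
        "analysis": dataclasses.asdict(cfg.analysis),
        "output_dir": str(cfg.output_dir),
        "seed": cfg.seed,
        "control_scenario": cfg.control_scenario,
    }
    return out
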