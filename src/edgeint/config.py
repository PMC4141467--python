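"""Run configuration: validated YAML in, fully-defaulted RunConfig out.

Units everywhere: angles in degrees, luminances in cd/m², logarithms
natural.  Unknown keys fail loudly; every numeric range is validated
before any computation runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .integration import ModelConfig
from .selection import SpotlightSpec
from .stimuli import StimulusSpec

__all__ = ["RunConfig", "load_config", "save_config"]

_MODEL_KEYS = {
    "w_inc",
    "w_dec",
    "kernel",
    "tau",
    "range_cutoff",
    "loglin_b",
    "loglin_d0",
    "ideal_observer",
}
_SPOTLIGHT_KEYS = {"mode", "default_interpretation", "g_illum", "g_gradient"}
_STIMULUS_KEYS = {"kind", "params"}
_TOP_KEYS = {"model", "stimulus", "spotlight", "out_dir", "verbose"}


@dataclass
class RunConfig:
    """Everything one CLI run needs."""

    model: ModelConfig = field(default_factory=ModelConfig)
    stimulus: Optional[StimulusSpec] = None
    spotlight: SpotlightSpec = field(default_factory=SpotlightSpec)
    out_dir: Optional[str] = None
    verbose: bool = False

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"model": asdict(self.model)}
        if self.stimulus is not None:
            d["stimulus"] = {"kind": self.stimulus.kind, "params": dict(self.stimulus.params)}
        d["spotlight"] = {
            "mode": self.spotlight.mode,
            "default_interpretation": self.spotlight.default_interpretation,
            "g_illum": self.spotlight.g_illum,
            "g_gradient": self.spotlight.g_gradient,
        }
        if self.out_dir is not None:
            d["out_dir"] = self.out_dir
        d["verbose"] = self.verbose
        return d


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def from_dict(data: Optional[dict]) -> RunConfig:
    """Build a validated RunConfig; missing sections use the documented
    defaults (w_inc = 1/3, w_dec = 1, exponential kernel with
    τ = 10/ln 20 ≈ 3.34°, 10° cutoff, wide spotlight)."""
    data = data or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    _check_keys(data, _TOP_KEYS, "top level")
    model_d = data.get("model", {}) or {}
    _check_keys(model_d, _MODEL_KEYS, "model")
    model = ModelConfig(**model_d)
    spot_d = data.get("spotlight", {}) or {}
    _check_keys(spot_d, _SPOTLIGHT_KEYS, "spotlight")
    spotlight = SpotlightSpec(**spot_d)
    stimulus = None
    if "stimulus" in data and data["stimulus"]:
        stim_d = data["stimulus"]
        _check_keys(stim_d, _STIMULUS_KEYS, "stimulus")
        params = stim_d.get("params", {}) or {}
        # YAML gives lists; generators expect tuples for shapes
        params = {
            k: tuple(v) if k in ("shape", "center", "widths") and isinstance(v, list) else v
            for k, v in params.items()
        }
        stimulus = StimulusSpec(kind=stim_d["kind"], params=params)
    return RunConfig(
        model=model,
        stimulus=stimulus,
        spotlight=spotlight,
        out_dir=data.get("out_dir"),
        verbose=bool(data.get("verbose", False)),
    )


def load_config(path: "str | Path") -> RunConfig:
    """Load and validate a YAML config file; an empty file yields all
    defaults."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        return from_dict(data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config {path}: {exc}") from exc


def save_config(config: RunConfig, path: "str | Path") -> None:
    """Serialise a RunConfig so that load(save(x)) == x."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
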