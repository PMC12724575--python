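"""Pipeline configuration: one YAML document drives every stage.

Defaults ship with the package (``defaults.yaml``); a user file overrides
any subset of keys.  The config round-trips losslessly through YAML and its
hash is logged with every run so derived thresholds are auditable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .simulate import LocomotionModel
from .traversal import BinGrid
from .zones import ZoneScheme

__all__ = ["PipelineConfig", "load_config", "default_config"]


def _deep_update(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


@dataclass(frozen=True)
class PipelineConfig:
    """Validated view over the raw configuration mapping."""

    raw: dict = field(repr=False)

    def __post_init__(self) -> None:
        g = self.raw["grid"]
        if not (g["v_min"] < g["v_max"] and g["width"] > 0):
            raise ValueError("invalid grid")
        if self.raw["beta"] <= 0:
            raise ValueError("beta must be positive")
        km = self.raw["k_mode"]
        if km != "auto" and not (isinstance(km, int) and 2 <= km <= 20):
            raise ValueError("k_mode must be 'auto' or an integer in [2, 20]")
        lo, hi = self.raw["k_range"]
        if not (2 <= lo and hi >= lo + 2):
            raise ValueError("k_range must satisfy 2 <= lo and hi >= lo + 2")
        c = self.raw["cleaning"]
        if not (0 < c["max_removed_fraction"] < 1 and c["spike_cutoff"] > 0):
            raise ValueError("invalid cleaning parameters")
        if not (0 < self.raw["alpha_norm"] < 1):
            raise ValueError("alpha_norm must be in (0, 1)")

    # -- typed accessors ------------------------------------------------
    @property
    def grid(self) -> BinGrid:
        g = self.raw["grid"]
        return BinGrid(g["v_min"], g["v_max"], g["width"])

    @property
    def beta(self) -> float:
        return float(self.raw["beta"])

    @property
    def k_mode(self) -> int | str:
        return self.raw["k_mode"]

    @property
    def k_range(self) -> tuple[int, int]:
        return tuple(self.raw["k_range"])

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def spike_cutoff(self) -> float:
        return float(self.raw["cleaning"]["spike_cutoff"])

    @property
    def max_removed_fraction(self) -> float:
        return float(self.raw["cleaning"]["max_removed_fraction"])

    @property
    def alpha_norm(self) -> float:
        return float(self.raw["alpha_norm"])

    @property
    def holm(self) -> bool:
        return bool(self.raw.get("holm", False))

    @property
    def generic_scheme(self) -> ZoneScheme:
        s = self.raw["generic_scheme"]
        return ZoneScheme("generic-rugby", tuple(s["boundaries"]), tuple(s["zone_names"]))

    def locomotion_model(self, cohort: str, spike_rate: float | None = None) -> LocomotionModel:
        m = dict(self.raw["locomotion_models"][cohort])
        if spike_rate is not None:
            m["spike_rate"] = spike_rate
        return LocomotionModel(
            state_means=np.asarray(m["state_means"], float),
            state_sds=np.asarray(m["state_sds"], float),
            dwell_mean_s=np.asarray(m["dwell_mean_s"], float),
            transition_weights=np.asarray(m["transition_weights"], float),
            a_max=float(m["a_max"]),
            v_cap=float(m["v_cap"]),
            spike_rate=float(m.get("spike_rate", 0.0)),
            sample_hz=float(m["sample_hz"]),
        )

    @property
    def simulation_duration_s(self) -> float:
        return float(self.raw["simulation"]["duration_s"])

    @property
    def simulation_spike_rate(self) -> float:
        return float(self.raw["simulation"]["spike_rate"])

    # -- serialisation ---------------------------------------------------
    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.raw, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def default_config() -> PipelineConfig:
    text = resources.files("velozones").joinpath("defaults.yaml").read_text()
    return PipelineConfig(yaml.safe_load(text))


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Defaults, optionally overridden by a YAML file, then by kwargs."""
    raw = default_config().raw
    if path is not None:
        raw = _deep_update(raw, yaml.safe_load(Path(path).read_text()) or {})
    if overrides:
        raw = _deep_update(raw, overrides)
    return PipelineConfig(raw)
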