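"""Pipeline configuration: flat dotted keys, dataset presets, file parsing.

A configuration is a flat mapping of dotted keys to values; unknown keys are
rejected. Config files are plain ``key = value`` text (one pair per line,
``#`` comments). Every value is overridable programmatically or from the
CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

from .errors import ConfigError

_DEFAULTS: dict[str, Any] = {
    "clahe.tiles": 8,
    "clahe.clip_limit": 0.01,
    "clahe.n_bins": 256,
    "fov.method": "otsu",
    "fov.fixed_threshold": 15.0,
    "fov.erode_px": 0,
    "filter.symmetric.sigma": 2.4,
    "filter.symmetric.rho_max": 8.0,
    "filter.symmetric.rho_step": 2.0,
    "filter.asymmetric.enabled": True,
    "filter.asymmetric.sigma": 1.8,
    "filter.asymmetric.rho_max": 22.0,
    "filter.asymmetric.rho_step": 2.0,
    "filter.sigma0_prime": 3.0,
    "filter.alpha": 0.7,
    "filter.n_orientations": 12,
    "filter.t": 0.0,
    "filter.weight_sigma": "auto",
    "filter.prototype_width": 3,
    "filter.config_threshold": 0.2,
    "dog.sign": "center_on",
    "segment.se_size": 11,
    "segment.threshold": 0.37,
    "postprocess.min_area": 20,
    "postprocess.max_recovery_iters": 10,
    "metrics.fov_only": True,
}

# Per-dataset manual thresholds. The public-database values were chosen on
# the synthetic fixtures as sensible starting points, not measured on the
# databases themselves; users segmenting DRIVE/STARE/CHASEDB1 should sweep
# segment.threshold per dataset.
PRESETS: dict[str, dict[str, Any]] = {
    "drive": {"segment.threshold": 0.37},
    "stare": {"segment.threshold": 0.37},
    "chasedb1": {"segment.threshold": 0.38},
    "synthetic": {"segment.threshold": 0.22, "segment.se_size": 7},
}

_BOOL_STRINGS = {"true": True, "false": False, "yes": True, "no": False, "1": True, "0": False}


def _coerce(key: str, raw: Any) -> Any:
    """Coerce a raw (possibly string) value to the type of the default."""
    default = _DEFAULTS[key]
    if isinstance(raw, str):
        raw = raw.strip()
        if key == "filter.weight_sigma":
            return "auto" if raw == "auto" else float(raw)
        if isinstance(default, bool):
            try:
                return _BOOL_STRINGS[raw.lower()]
            except KeyError:
                raise ConfigError(f"invalid boolean for {key}: {raw!r}") from None
        if isinstance(default, int):
            return int(raw)
        if isinstance(default, float):
            return float(raw)
        return raw
    if isinstance(default, bool):
        return bool(raw)
    if isinstance(default, float) and isinstance(raw, (int, float)):
        return float(raw)
    return raw


@dataclass(frozen=True)
class PipelineConfig:
    """Concrete values for every stage of the segmentation pipeline."""

    values: dict[str, Any] = field(default_factory=lambda: dict(_DEFAULTS))
    preset: str | None = None

    @classmethod
    def from_preset(cls, name: str, overrides: Mapping[str, Any] | None = None) -> "PipelineConfig":
        if name not in PRESETS:
            raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        cfg = cls(preset=name).with_overrides(PRESETS[name])
        return cfg.with_overrides(overrides) if overrides else cfg

    @classmethod
    def from_file(cls, path: str | Path, preset: str | None = None) -> "PipelineConfig":
        cfg = cls.from_preset(preset) if preset else cls()
        overrides: dict[str, Any] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            overrides[key] = value
        return cfg.with_overrides(overrides)

    def with_overrides(self, overrides: Mapping[str, Any]) -> "PipelineConfig":
        new = dict(self.values)
        for key, raw in overrides.items():
            if key not in _DEFAULTS:
                raise ConfigError(f"unknown config key {key!r}")
            new[key] = _coerce(key, raw)
        return PipelineConfig(values=new, preset=self.preset)

    def __getitem__(self, key: str) -> Any:
        try:
            return self.values[key]
        except KeyError:
            raise ConfigError(f"unknown config key {key!r}") from None

    def weight_sigma(self) -> float | None:
        v = self["filter.weight_sigma"]
        return None if v == "auto" else float(v)
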