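"""Flat key=value run configuration shared by the CLI subcommands."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

from .confidence import ClassifierThresholds
from .geometry import ContactCriteria

__all__ = ["RunConfig", "load_config"]

_DEFAULTS: dict[str, float] = {
    "stable_pae_max": 10.0,
    "unstable_pae_min": 20.0,
    "plddt_min": 70.0,
    "interface_distance": 8.0,
    "hbond_cutoff": 3.5,
    "salt_bridge_cutoff": 4.0,
    "hydrophobic_cutoff": 4.5,
    "probe_radius": 1.4,
    "sasa_points": 960,
    "min_minor_area": 25.0,
}


@dataclass
class RunConfig:
    values: dict[str, float] = field(default_factory=lambda: dict(_DEFAULTS))
    seed: int = 0

    @property
    def thresholds(self) -> ClassifierThresholds:
        v = self.values
        return ClassifierThresholds(
            stable_pae_max=v["stable_pae_max"],
            unstable_pae_min=v["unstable_pae_min"],
            plddt_min=v["plddt_min"],
            interface_distance=v["interface_distance"],
        )

    @property
    def criteria(self) -> ContactCriteria:
        v = self.values
        return ContactCriteria(
            hbond_cutoff=v["hbond_cutoff"],
            salt_bridge_cutoff=v["salt_bridge_cutoff"],
            hydrophobic_cutoff=v["hydrophobic_cutoff"],
        )

    def digest(self) -> str:
        blob = ";".join(f"{k}={self.values[k]}" for k in sorted(self.values))
        blob += f";seed={self.seed}"
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: "str | Path | None", seed: int = 0) -> RunConfig:
    """Parse ``key = value`` lines ('#' comments allowed); unknown keys raise."""
    cfg = RunConfig(seed=seed)
    if path is None:
        return cfg
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}, line {lineno}: expected key=value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in _DEFAULTS:
                raise KeyError(
                    f"{path}, line {lineno}: unknown key {key!r} "
                    f"(known: {sorted(_DEFAULTS)})"
                )
            cfg.values[key] = float(value)
    return cfg
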