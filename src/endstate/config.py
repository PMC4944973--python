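"""Run configuration: a flat key-value file (YAML) with field validation.

The defaults reproduce the headline analysis settings: solute dielectric 1
(with 2 and 4 available), solvent dielectric 80, γ/β = 0.0072/0 (GB) and
0.00542/0.92 (PB) kcal/mol/Å², snapshot plans of 500 @ 20 ps and 125 @
80 ps over a 10 ns span, 2.00 kcal/mol hot-spot threshold, 8 Å interface
shell, and the OH-π strong-interaction windows 65–90° / 2.0–3.5 Å.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    temperature: float = 300.0  # K
    solute_dielectrics: tuple[int, ...] = (1, 2, 4)
    headline_dielectric: int = 1
    solvent_models: tuple[str, ...] = ("GB", "PB")
    gb_gamma: float = 0.0072  # kcal/mol/Å²
    gb_beta: float = 0.0  # kcal/mol
    pb_gamma: float = 0.00542
    pb_beta: float = 0.92
    span_ps: float = 10000.0
    energy_interval_ps: float = 20.0  # → 500 snapshots over 10 ns
    entropy_interval_ps: float = 80.0  # → 125 snapshots over 10 ns
    hotspot_threshold: float = 2.00  # kcal/mol
    interface_cutoff: float = 8.0  # Å
    ohpi_angle_window: tuple[float, float] = (65.0, 90.0)  # degrees
    ohpi_distance_window: tuple[float, float] = (2.0, 3.5)  # Å
    pb_spacing: float = 0.5  # Å
    pb_margin: float = 8.0  # Å
    pb_tolerance: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {"temperature": self.temperature,
                    "hotspot_threshold": self.hotspot_threshold,
                    "interface_cutoff": self.interface_cutoff,
                    "span_ps": self.span_ps,
                    "energy_interval_ps": self.energy_interval_ps,
                    "entropy_interval_ps": self.entropy_interval_ps,
                    "pb_spacing": self.pb_spacing,
                    "pb_tolerance": self.pb_tolerance}
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.headline_dielectric not in self.solute_dielectrics:
            raise ValueError("headline dielectric must be among solute_dielectrics")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(_plain(asdict(self)), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        tupled = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
        return cls(**tupled)

    @property
    def digest(self) -> str:
        canon = yaml.safe_dump(_plain(asdict(self)), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _plain(obj):
    if isinstance(obj, tuple):
        return [_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    return obj
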