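"""Seeded configuration for the synthetic gonad generator.

All linear positions along the gonad are expressed as fractions of gonad
length: x = 0 at the distal tip, x = 1 at the proximal turn.  Volumes are
femtolitres (1 fl = 1 um^3), radii micrometres, velocities um/s unless a
field says otherwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["SyntheticConfig", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic gonad generator.

    Defaults are chosen so that the generated data exhibit the structure the
    downstream analysis assumes: distal volumes unimodal around 100-150 fl,
    a bimodal proximal mixture widening towards 65 and 1200 fl, a material
    uptake profile changing sign exactly once at ``transition_position``,
    and apoptosis confined to the 70-90% zone.
    """

    seed: int = 0
    n_gonads: int = 18
    cells_per_gonad: int = 300
    axis_grid: int = 101
    transition_position: float = 0.65

    # volume model (fl)
    distal_mean_start: float = 100.0
    distal_mean_end: float = 150.0
    proximal_small: float = 65.0
    proximal_large: float = 1200.0
    volume_cv: float = 0.10
    # weight of the small mode at the proximal turn (decreases linearly
    # from 0.5 at x* -- small cells are progressively removed)
    small_mode_weight_end: float = 0.35
    # proximal regime: mixture mean at the turn and the (steeper) slope of
    # the SD-vs-mean law beyond the transition
    proximal_mean_end: float = 800.0
    proximal_sd_slope: float = 0.8

    # geometry (um)
    gonad_length: float = 250.0
    gonad_radius: float = 12.0
    rachis_radius: float = 5.0  # uniform a(x) by default

    # flux bookkeeping
    uptake_amplitude: float = 40.0  # peak S, fl per unit fractional length per min
    uptake_export_fraction: float = 0.6  # proximal lobe amplitude relative to distal
    rachis_flux_peak: float = 10.0  # peak Qr, fl/min

    # imaging / velocity noise
    noise_sd_velocity: float = 0.0  # um/s
    frame_interval: float = 10.0  # s
    pixel_size: float = 0.106  # um

    # event rates, per hour
    apoptosis_rate: float = 0.05
    apoptosis_zone: tuple[float, float] = (0.70, 0.90)
    mitosis_rate: float = 0.04
    mitosis_zone: tuple[float, float] = (0.0, 0.15)

    # speckle texture
    speckle_sigma_px: float = 1.0

    def __post_init__(self) -> None:
        # x* = 1 is permitted as the degenerate "no transition" edge case
        if not 0.0 < self.transition_position <= 1.0:
            raise ConfigurationError("transition_position must lie in (0, 1]")
        if self.n_gonads <= 0 or self.cells_per_gonad <= 0:
            raise ConfigurationError("n_gonads and cells_per_gonad must be positive")
        if self.axis_grid < 4:
            raise ConfigurationError("axis_grid must be >= 4")
        for name in ("distal_mean_start", "distal_mean_end", "proximal_small", "proximal_large"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be a positive volume")
        if self.volume_cv < 0:
            raise ConfigurationError("volume_cv must be >= 0")
        if not 0 < self.rachis_radius < self.gonad_radius:
            raise ConfigurationError("rachis radius must satisfy 0 < a < gonad_radius")
        if not 0 <= self.apoptosis_rate <= 1 or not 0 <= self.mitosis_rate <= 1:
            raise ConfigurationError("event rates must be probabilities per hour in [0, 1]")

    # -- derived grids -------------------------------------------------

    @property
    def x_grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.axis_grid)

    def rachis_radius_profile(self) -> np.ndarray:
        """Lumen radius a(x) on the axial grid (uniform by default)."""
        return np.full(self.axis_grid, float(self.rachis_radius))

    def apoptosis_rate_profile(self, x: np.ndarray) -> np.ndarray:
        """Apoptosis probability per cell-hour at positions x."""
        lo, hi = self.apoptosis_zone
        return np.where((x >= lo) & (x <= hi), self.apoptosis_rate, 0.0)

    def mitosis_rate_profile(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.mitosis_zone
        return np.where((x >= lo) & (x <= hi), self.mitosis_rate, 0.0)

    # -- (de)serialisation ---------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["apoptosis_zone"] = list(d["apoptosis_zone"])
        d["mitosis_zone"] = list(d["mitosis_zone"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("apoptosis_zone", "mitosis_zone"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        """Stable short hash of the configuration, for provenance stamps."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
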