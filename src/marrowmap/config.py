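"""Simulation configuration for synthetic bone-marrow sections.

A :class:`SimulationConfig` fixes every free parameter of the generator:
section geometry and its PM/CM/DM partition, the vessel network, the
N-cad+ stromal hotspots, the CXCL12 field (source amplitude, decay
length, baseline, DPP4 degradation, GPC3 protection) and the chemotaxis
strength used to place cells.  All lengths are in micrometres and field
amplitudes in arbitrary units.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic longitudinal femur section.

    Parameters
    ----------
    section_length_um, section_width_um
        Size of the rectangular section; x runs proximal (0) to distal.
    region_bounds
        Two fractions ``0 < b1 < b2 < 1`` splitting the long axis into
        proximal metaphysis [0, b1), central marrow [b1, b2) and distal
        metaphysis [b2, 1].
    grid_resolution_um
        Pixel size of the raster grid carrying the marrow mask and the
        chemokine field.
    n_vessels, vessel_radius_um, vessel_length_um
        Number of vessel segments, their lumen radius, and segment length.
    n_stromal, stromal_pm_dm_enrichment
        Number of N-cad+ stromal hotspots and the odds multiplier for
        placing them in the metaphyses (PM/DM) relative to central marrow;
        1 means spatially uniform.
    source_amplitude, decay_length_um, baseline_c0
        CXCL12 point-source amplitude A, exponential decay length lambda,
        and spatially uniform baseline c0 (all arbitrary units).
    dpp4_activity
        Fractional CXCL12 degradation k in [0, 1] where GPC3 protection
        is absent; 0 disables the protease entirely.
    gpc3_radius_um, gpc3_strength
        Radius of the GPC3 protective halo around each stromal hotspot
        and the per-hotspot protection level in [0, 1].
    attraction_beta
        Chemotaxis exponent: cells are placed with probability
        proportional to field**beta; 0 gives uniform placement.
    n_cells
        Number of cells to place.
    seed
        Master seed; every random sub-stream is derived from it.
    exclude_vessel_lumen
        When true, vessel interiors are removed from the marrow mask
        before cells are placed.
    """

    section_length_um: float = 1600.0
    section_width_um: float = 400.0
    region_bounds: tuple[float, float] = (0.3, 0.7)
    grid_resolution_um: float = 2.0
    n_vessels: int = 25
    vessel_radius_um: float = 5.0
    vessel_length_um: float = 80.0
    n_stromal: int = 40
    stromal_pm_dm_enrichment: float = 5.0
    source_amplitude: float = 1.0
    decay_length_um: float = 60.0
    baseline_c0: float = 0.05
    dpp4_activity: float = 0.7
    gpc3_radius_um: float = 40.0
    gpc3_strength: float = 1.0
    attraction_beta: float = 2.0
    n_cells: int = 500
    seed: int = 0
    exclude_vessel_lumen: bool = False

    def __post_init__(self):
        for name in ("section_length_um", "section_width_um",
                     "grid_resolution_um", "vessel_radius_um",
                     "vessel_length_um", "source_amplitude",
                     "decay_length_um", "gpc3_radius_um"):
            if not getattr(self, name) > 0:
                raise ValidationError(name, "must be strictly positive")
        b1, b2 = self.region_bounds
        if not (0.0 < b1 < b2 < 1.0):
            raise ValidationError(
                "region_bounds",
                f"must satisfy 0 < b1 < b2 < 1, got ({b1}, {b2})")
        for name in ("n_vessels", "n_stromal"):
            if getattr(self, name) < 0:
                raise ValidationError(name, "must be non-negative")
        if self.n_cells < 1:
            raise ValidationError("n_cells", "must be a positive integer")
        for name in ("dpp4_activity", "gpc3_strength"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(name, f"must lie in [0, 1], got {v}")
        if self.stromal_pm_dm_enrichment < 0:
            raise ValidationError("stromal_pm_dm_enrichment",
                                  "must be >= 0")
        if self.attraction_beta < 0:
            raise ValidationError("attraction_beta", "must be >= 0")
        if self.baseline_c0 < 0:
            raise ValidationError("baseline_c0", "must be >= 0")

    def replace(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["region_bounds"] = list(self.region_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(sorted(unknown)[0],
                                  "unknown configuration field")
        d = dict(d)
        if "region_bounds" in d:
            d["region_bounds"] = tuple(d["region_bounds"])
        return cls(**d)


def load_config(path: str | Path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError("config", f"{path} does not hold a mapping")
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(config.to_dict()))
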