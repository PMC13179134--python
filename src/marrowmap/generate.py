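"""Synthetic bone-marrow section generator.

Emulates longitudinal femur sections with a PM/CM/DM partition, a vessel
network, N-cad+ stromal hotspots carrying GPC3, a CXCL12 field shaped by
DPP4 protease activity locally antagonized by GPC3, and cell patterns
placed uniformly or by chemotaxis-weighted sampling.  Every output is a
pure function of (config, seed); each generator stage draws from its own
deterministic substream so adding one stage never perturbs another.

The CXCL12 model is deliberately the simplest form reproducing the
qualitative biology: each stromal hotspot contributes an exponential
kernel A*exp(-d/lambda) on top of a uniform baseline c0, and DPP4
degrades the summed field by a factor 1 - k*(1 - prot(x)), where the
protection prot(x) is a bounded sum of conical GPC3 halos around the
hotspots.  With metaphysis-enriched hotspots this yields higher CXCL12
in PM/DM than CM; switching the protease off (k = 0) flattens the
gradient by raising CM.  It is a generative stand-in, not a mechanistic
reaction-diffusion solution.
"""

from __future__ import annotations

import numpy as np

from .config import SimulationConfig
from .containers import (CellPattern, ChemokineField, LDADataset,
                         Primitive, SectionGeometry, StructureSet)
from .distances import primitive_distances
from .errors import DegenerateWeightsError, ValidationError

# fixed substream keys so stages are independent of each other
_STREAMS = {"vessels": 0, "stromal": 1, "cells": 2, "lda": 3, "null": 4}


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-stage random generator derived from one seed."""
    key = _STREAMS[name]
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def _sample_pixels(geometry: SectionGeometry, n: int,
                   rng: np.random.Generator,
                   weights: np.ndarray | None = None) -> np.ndarray:
    """Sample n points: weighted marrow-pixel choice + in-pixel jitter."""
    rows, cols = np.nonzero(geometry.marrow_mask)
    if weights is None:
        picks = rng.integers(0, len(rows), size=n)
    else:
        p = weights / weights.sum()
        picks = rng.choice(len(rows), size=n, p=p)
    res = geometry.resolution_um
    jitter = rng.uniform(0.0, 1.0, size=(n, 2))
    x = (cols[picks] + jitter[:, 0]) * res
    y = (rows[picks] + jitter[:, 1]) * res
    return np.column_stack([x, y])


def generate_section(config: SimulationConfig
                     ) -> tuple[SectionGeometry, StructureSet, StructureSet]:
    """Build geometry plus vessel and stromal structure sets.

    Vessels are uniform-density segments over the marrow; stromal
    hotspots are points whose placement odds in PM/DM are multiplied by
    ``stromal_pm_dm_enrichment`` relative to CM.
    """
    res = config.grid_resolution_um
    nx = max(1, int(round(config.section_length_um / res)))
    ny = max(1, int(round(config.section_width_um / res)))
    b1, b2 = (config.region_bounds[0] * config.section_length_um,
              config.region_bounds[1] * config.section_length_um)
    geometry = SectionGeometry(
        length_um=config.section_length_um,
        width_um=config.section_width_um,
        region_bounds_um=(b1, b2),
        resolution_um=res,
        marrow_mask=np.ones((ny, nx), dtype=bool),
    )

    # --- vessels: uniform centers, isotropic orientation ---------------
    rng_v = substream(config.seed, "vessels")
    vessel_prims: list[Primitive] = []
    if config.n_vessels > 0:
        centers = _sample_pixels(geometry, config.n_vessels, rng_v)
        angles = rng_v.uniform(0.0, np.pi, size=config.n_vessels)
        half = config.vessel_length_um / 2.0
        for c, a in zip(centers, angles):
            d = np.array([np.cos(a), np.sin(a)])
            p0 = np.clip(c - half * d, [0, 0],
                         [geometry.length_um, geometry.width_um])
            p1 = np.clip(c + half * d, [0, 0],
                         [geometry.length_um, geometry.width_um])
            vessel_prims.append(Primitive(
                kind="segment", coordinates=np.array([p0, p1]),
                radius_um=config.vessel_radius_um))
    vessels = StructureSet(primitives=vessel_prims, label="vessel")

    if config.exclude_vessel_lumen and len(vessels):
        lumen = vessels.rasterize(geometry)
        mask = geometry.marrow_mask & ~lumen
        if mask.any():
            geometry.marrow_mask = mask

    # --- stromal hotspots: metaphysis-enriched placement ---------------
    rng_s = substream(config.seed, "stromal")
    stromal_prims: list[Primitive] = []
    if config.n_stromal > 0:
        pts = geometry.marrow_pixel_centers()
        labels = geometry.region_of(pts[:, 0])
        w = np.where(labels == "CM", 1.0, config.stromal_pm_dm_enrichment)
        if w.sum() == 0:
            raise ValidationError("stromal_pm_dm_enrichment",
                                  "all placement weights are zero")
        coords = _sample_pixels(geometry, config.n_stromal, rng_s,
                                weights=w)
        stromal_prims = [Primitive(kind="point", coordinates=c,
                                   radius_um=0.0) for c in coords]
    stromal = StructureSet(
        primitives=stromal_prims, label="stromal",
        marks={
            "ncad_pos": np.ones(len(stromal_prims), dtype=bool),
            "gpc3_level": np.full(len(stromal_prims),
                                  config.gpc3_strength, dtype=float),
        })
    return geometry, vessels, stromal


def compute_cxcl12_field(geometry: SectionGeometry, stromal: StructureSet,
                         config: SimulationConfig) -> ChemokineField:
    """CXCL12 concentration under the DPP4/GPC3 mechanism.

    field(x) = [c0 + sum_i A*exp(-d(x, s_i)/lambda)]
               * [1 - k_dpp4 * (1 - prot(x))]
    prot(x)  = min(1, sum_j gpc3_level_j * max(0, 1 - d(x, g_j)/R_gpc3))
    """
    gpc3 = stromal.require_mark("gpc3_level")
    xg, yg = geometry.pixel_centers()
    pts = np.column_stack([xg.ravel(), yg.ravel()])
    source = np.full(len(pts), config.baseline_c0, dtype=float)
    prot = np.zeros(len(pts))
    if len(stromal):
        d = primitive_distances(pts, stromal)
        source += config.source_amplitude * \
            np.exp(-d / config.decay_length_um).sum(axis=1)
        halo = np.maximum(0.0, 1.0 - d / config.gpc3_radius_um)
        prot = np.minimum(1.0, halo @ np.asarray(gpc3, dtype=float))
    values = source * (1.0 - config.dpp4_activity * (1.0 - prot))
    values = np.maximum(values, 0.0).reshape(geometry.shape)
    return ChemokineField(values=values,
                          resolution_um=geometry.resolution_um)


def place_cells(geometry: SectionGeometry, field: ChemokineField,
                n: int, beta: float, seed: int | np.random.Generator,
                marks: dict | None = None) -> CellPattern:
    """Sample n cells over marrow pixels with probability ~ field**beta.

    beta = 0 gives uniform placement over the marrow; larger beta
    concentrates cells on chemokine hotspots.  Cell coordinates are
    jittered uniformly within the sampled pixel, so all cells lie inside
    the marrow mask.
    """
    if n < 1:
        raise ValidationError("n", "must place at least one cell")
    if beta < 0:
        raise ValidationError("beta", "must be >= 0")
    if field.shape != geometry.shape:
        raise ValidationError("field", "field grid does not match geometry")
    rng = seed if isinstance(seed, np.random.Generator) \
        else substream(int(seed), "cells")
    weights = None
    if beta > 0:
        w = field.values[geometry.marrow_mask] ** beta
        if not np.any(w > 0):
            raise DegenerateWeightsError(
                "field is zero over the whole marrow; cannot weight "
                "placement with beta > 0")
        weights = w
    coords = _sample_pixels(geometry, n, rng, weights=weights)
    base_marks = {
        "gfp": np.ones(n, dtype=bool),
        "kit": np.zeros(n, dtype=bool),
        "genotype": np.full(n, "Dpp4+/+", dtype=object),
    }
    if marks:
        for k, v in marks.items():
            base_marks[k] = np.broadcast_to(np.asarray(v), (n,)).copy() \
                if np.ndim(v) == 0 else np.asarray(v)
    return CellPattern(coords[:, 0], coords[:, 1], base_marks)


def simulate_lda(true_frequency: float, doses, n_per_dose,
                 seed: int, group_id: str = "group") -> LDADataset:
    """Simulate a single-hit limiting-dilution experiment.

    Each transplanted animal responds independently with probability
    1 - (1 - f)^dose, i.e. it develops leukaemia when at least one of
    the transplanted cells is tumour-initiating.
    """
    import pandas as pd
    f = float(true_frequency)
    if not (0.0 < f <= 1.0):
        raise ValidationError("true_frequency", "must lie in (0, 1]")
    doses = np.asarray(doses, dtype=int)
    n_per_dose = np.broadcast_to(np.asarray(n_per_dose, dtype=int),
                                 doses.shape)
    if np.any(doses <= 0):
        raise ValidationError("doses", "must be strictly positive")
    if np.any(n_per_dose <= 0):
        raise ValidationError("n_per_dose", "must be strictly positive")
    rng = substream(int(seed), "lda")
    p_respond = 1.0 - (1.0 - f) ** doses
    responding = rng.binomial(n_per_dose, p_respond)
    table = pd.DataFrame({
        "group": group_id,
        "dose": doses,
        "n_tested": n_per_dose,
        "n_responding": responding,
    })
    return LDADataset(table)
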