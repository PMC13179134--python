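"""Core data containers: section geometry, structures, cells, fields.

Coordinate convention: (0, 0) is the proximal-top corner of the section,
x increases distally along the bone's long axis, y across the marrow.
All coordinates are micrometres.  Raster grids are indexed [row, col] =
[y, x] with pixel (i, j) covering [j*res, (j+1)*res) x [i*res, (i+1)*res).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError

REGIONS = ("PM", "CM", "DM")


# ---------------------------------------------------------------------------
# SectionGeometry
# ---------------------------------------------------------------------------

@dataclass
class SectionGeometry:
    """The 2D longitudinal marrow frame: extent, PM/CM/DM split, marrow mask.

    ``region_bounds_um`` are the two x positions (b1, b2) delimiting
    PM = [0, b1), CM = [b1, b2), DM = [b2, length]; the half-open
    convention maps every x to exactly one region.
    """

    length_um: float
    width_um: float
    region_bounds_um: tuple[float, float]
    resolution_um: float
    marrow_mask: np.ndarray  # bool, shape (ny, nx)

    def __post_init__(self):
        self.marrow_mask = np.asarray(self.marrow_mask, dtype=bool)
        b1, b2 = self.region_bounds_um
        if not (0.0 < b1 < b2 < self.length_um):
            raise ValidationError(
                "region_bounds_um",
                f"must satisfy 0 < b1 < b2 < length, got ({b1}, {b2})")
        if not self.marrow_mask.any():
            raise ValidationError("marrow_mask",
                                  "must contain at least one marrow pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.marrow_mask.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of all pixel centers, shape (ny, nx)."""
        ny, nx = self.shape
        xs = (np.arange(nx) + 0.5) * self.resolution_um
        ys = (np.arange(ny) + 0.5) * self.resolution_um
        return np.meshgrid(xs, ys)

    def marrow_pixel_centers(self) -> np.ndarray:
        """Coordinates of marrow pixel centers, shape (n_marrow, 2)."""
        xg, yg = self.pixel_centers()
        m = self.marrow_mask
        return np.column_stack([xg[m], yg[m]])

    def region_of(self, x_um) -> np.ndarray:
        """Vectorized PM/CM/DM label for x coordinates (half-open bins)."""
        x = np.asarray(x_um, dtype=float)
        b1, b2 = self.region_bounds_um
        out = np.where(x < b1, "PM", np.where(x < b2, "CM", "DM"))
        return out

    def region_area_fractions(self) -> dict[str, float]:
        """Fraction of marrow pixels in each region."""
        pts = self.marrow_pixel_centers()
        labels = self.region_of(pts[:, 0])
        n = len(labels)
        return {r: float(np.sum(labels == r)) / n for r in REGIONS}

    def to_dict(self) -> dict:
        return {
            "length_um": self.length_um,
            "width_um": self.width_um,
            "region_bounds_um": list(self.region_bounds_um),
            "resolution_um": self.resolution_um,
            "marrow_mask_shape": list(self.shape),
            # compact run-length encoding keeps the JSON small and text-only
            "marrow_mask_rle": _rle_encode(self.marrow_mask),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SectionGeometry":
        shape = tuple(d["marrow_mask_shape"])
        mask = _rle_decode(d["marrow_mask_rle"], shape)
        return cls(length_um=d["length_um"], width_um=d["width_um"],
                   region_bounds_um=tuple(d["region_bounds_um"]),
                   resolution_um=d["resolution_um"], marrow_mask=mask)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def read_json(cls, path: str | Path) -> "SectionGeometry":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _rle_encode(mask: np.ndarray) -> list[int]:
    """Run lengths of the flattened mask, starting with a False run."""
    flat = mask.ravel()
    if flat.size == 0:
        return []
    change = np.flatnonzero(np.diff(flat.view(np.int8))) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    runs = np.diff(bounds).tolist()
    if flat[0]:  # prepend empty False run so parity encodes the value
        runs = [0] + runs
    return [int(r) for r in runs]


def _rle_decode(runs: list[int], shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, value = 0, False
    for r in runs:
        if value:
            out[pos:pos + r] = True
        pos += r
        value = not value
    return out.reshape(shape)


# ---------------------------------------------------------------------------
# StructureSet
# ---------------------------------------------------------------------------

VALID_KINDS = ("segment", "disk", "point")


@dataclass
class Primitive:
    kind: str                      # segment | disk | point
    coordinates: np.ndarray        # (2,2) for segment, (2,) otherwise
    radius_um: float = 0.0

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ValidationError("kind", f"unknown primitive kind "
                                          f"{self.kind!r}")
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.radius_um < 0:
            raise ValidationError("radius_um", "must be >= 0")


@dataclass
class StructureSet:
    """Vessel or stromal primitives against which distances are measured.

    ``marks`` holds optional per-primitive annotations, e.g. ``ncad_pos``
    (boolean) and ``gpc3_level`` (non-negative real) for stromal cells.
    """

    primitives: list[Primitive]
    label: str = "structure"
    marks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.marks = {k: np.asarray(v) for k, v in self.marks.items()}
        for k, v in self.marks.items():
            if len(v) != len(self.primitives):
                raise ValidationError(
                    "marks", f"mark {k!r} has length {len(v)}, expected "
                             f"{len(self.primitives)}")

    def __len__(self) -> int:
        return len(self.primitives)

    def require_mark(self, name: str) -> np.ndarray:
        if name not in self.marks:
            raise ContractError(
                f"StructureSet {self.label!r} lacks required mark {name!r}")
        return self.marks[name]

    def centers(self) -> np.ndarray:
        """Representative point per primitive (segment midpoint)."""
        out = np.empty((len(self), 2))
        for i, p in enumerate(self.primitives):
            out[i] = p.coordinates.mean(axis=0) if p.kind == "segment" \
                else p.coordinates
        return out

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "primitives": [
                {"kind": p.kind,
                 "coordinates": p.coordinates.tolist(),
                 "radius_um": p.radius_um}
                for p in self.primitives],
            "marks": {k: np.asarray(v).tolist()
                      for k, v in self.marks.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StructureSet":
        prims = [Primitive(kind=p["kind"],
                           coordinates=np.asarray(p["coordinates"]),
                           radius_um=float(p.get("radius_um", 0.0)))
                 for p in d["primitives"]]
        marks = {k: np.asarray(v) for k, v in d.get("marks", {}).items()}
        return cls(primitives=prims, label=d.get("label", "structure"),
                   marks=marks)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def read_json(cls, path: str | Path) -> "StructureSet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def rasterize(self, geometry: SectionGeometry) -> np.ndarray:
        """Boolean occupancy mask of all primitives on the geometry grid."""
        from .distances import min_distances  # local import avoids a cycle
        xg, yg = geometry.pixel_centers()
        pts = np.column_stack([xg.ravel(), yg.ravel()])
        d, _ = min_distances(pts, self)
        # a pixel is covered when its center lies on/inside a surface,
        # padded by half a pixel so thin structures are not lost
        return (d <= geometry.resolution_um / 2).reshape(geometry.shape)


# ---------------------------------------------------------------------------
# CellPattern
# ---------------------------------------------------------------------------

@dataclass
class CellPattern:
    """Labelled cell coordinates with categorical marks.

    Marks mirror the imaging channels used to classify cells: ``gfp``
    (leukaemic), ``kit`` (stem-enriched) and ``genotype``.
    """

    x_um: np.ndarray
    y_um: np.ndarray
    marks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if self.x_um.shape != self.y_um.shape:
            raise ValidationError("y_um", "x and y must have equal length")
        self.marks = {k: np.asarray(v) for k, v in self.marks.items()}
        for k, v in self.marks.items():
            if len(v) != len(self.x_um):
                raise ValidationError(
                    "marks", f"mark {k!r} has length {len(v)}, expected "
                             f"{len(self.x_um)}")

    def __len__(self) -> int:
        return len(self.x_um)

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x_um, self.y_um])

    def subset(self, mask: np.ndarray) -> "CellPattern":
        mask = np.asarray(mask)
        return CellPattern(self.x_um[mask], self.y_um[mask],
                           {k: v[mask] for k, v in self.marks.items()})

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"x_um": self.x_um, "y_um": self.y_um})
        for k in ("gfp", "kit", "genotype"):
            if k in self.marks:
                df[k] = self.marks[k]
        for k, v in self.marks.items():
            if k not in df.columns:
                df[k] = v
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CellPattern":
        if "x_um" not in df.columns or "y_um" not in df.columns:
            raise ValidationError("x_um", "cell table needs x_um and y_um "
                                          "columns")
        marks = {c: df[c].to_numpy()
                 for c in df.columns if c not in ("x_um", "y_um")}
        return cls(df["x_um"].to_numpy(float), df["y_um"].to_numpy(float),
                   marks)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "CellPattern":
        return cls.from_dataframe(pd.read_csv(path))


# ---------------------------------------------------------------------------
# ChemokineField
# ---------------------------------------------------------------------------

@dataclass
class ChemokineField:
    """Gridded CXCL12 concentration (arbitrary units) on the section grid."""

    values: np.ndarray          # float, shape (ny, nx), >= 0
    resolution_um: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values", "field must be finite")
        if np.any(self.values < 0):
            raise ValidationError("values", "field must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def write_tiff(self, path: str | Path) -> None:
        """32-bit float TIFF with a JSON sidecar recording the resolution."""
        import tifffile
        path = Path(path)
        tifffile.imwrite(path, self.values.astype(np.float32))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"resolution_um": self.resolution_um}))

    @classmethod
    def read_tiff(cls, path: str | Path) -> "ChemokineField":
        import tifffile
        path = Path(path)
        values = tifffile.imread(path).astype(float)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text())
        return cls(values=values, resolution_um=float(meta["resolution_um"]))


# ---------------------------------------------------------------------------
# LDADataset
# ---------------------------------------------------------------------------

LDA_COLUMNS = ("group", "dose", "n_tested", "n_responding")


@dataclass
class LDADataset:
    """Dose/response counts of a limiting-dilution transplantation assay."""

    table: pd.DataFrame   # columns: group, dose, n_tested, n_responding

    def __post_init__(self):
        df = self.table
        missing = [c for c in LDA_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(missing[0], "missing LDA column")
        if (df["dose"] <= 0).any():
            raise ValidationError("dose", "doses must be strictly positive")
        if (df["n_tested"] <= 0).any():
            raise ValidationError("n_tested", "must be strictly positive")
        if (df["n_responding"] < 0).any() or \
                (df["n_responding"] > df["n_tested"]).any():
            raise ValidationError(
                "n_responding", "must satisfy 0 <= n_responding <= n_tested")

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def group(self, group_id: str) -> pd.DataFrame:
        sub = self.table[self.table["group"] == group_id]
        if sub.empty:
            raise ValidationError("group", f"no rows for group "
                                           f"{group_id!r}")
        return sub

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "LDADataset":
        return cls(pd.read_csv(path))
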