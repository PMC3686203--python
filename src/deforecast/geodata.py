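"""Raster and vector plumbing shared by every other module.

Rasters are plain rectangular grids on an equal-area metric grid (the
30 x 30 m Landsat convention: a pixel covers 0.09 ha).  The on-disk
dialect is the ESRI ASCII grid (text, one header + one row per line)
plus a small JSON sidecar carrying the semantics tag, so that fixtures
and outputs stay human-readable.

Vector administrative units (firaisana / fokontany) are read from
GeoJSON feature collections and rasterized by pixel-center containment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import shape as _shapely_shape

__all__ = [
    "Raster",
    "AdminLayer",
    "AlignmentError",
    "read_raster",
    "write_raster",
    "read_admin_geojson",
    "rasterize_units",
    "require_aligned",
]

#: semantics tags a raster may carry
SEMANTICS = (
    "landcover",
    "distance_m",
    "density_peop_km2",
    "acd_Mg_ha",
    "probability",
    "class_code",
    "unit_id",
    "year",
)


class AlignmentError(ValueError):
    """Two rasters with different shape or geotransform were combined."""


@dataclass
class Raster:
    """A single-band raster on a north-up equal-area grid.

    Parameters
    ----------
    values : ndarray (nrows, ncols)
        Cell values; ``nodata`` marks missing cells.
    transform : (origin_x, origin_y, pixel_size)
        ``origin`` is the outer corner of pixel (0, 0) (upper-left);
        ``pixel_size`` is the square cell edge in meters.
    nodata : float
        Sentinel for missing cells.
    semantics : str
        One of :data:`SEMANTICS`; declares the value meaning and units.
    """

    values: np.ndarray
    transform: tuple[float, float, float]
    nodata: float = -9999.0
    semantics: str = "class_code"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D grid")
        if self.transform[2] <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.semantics not in SEMANTICS:
            raise ValueError(f"unknown semantics tag {self.semantics!r}")

    # -- geometry ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_size(self) -> float:
        return self.transform[2]

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size**2 / 10_000.0

    def mask(self) -> np.ndarray:
        """Boolean grid, True where the cell holds a valid value."""
        vals = self.values
        if np.issubdtype(vals.dtype, np.floating):
            return ~np.isclose(vals, self.nodata) & ~np.isnan(vals)
        return vals != self.nodata

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, each (nrows, ncols)."""
        ox, oy, px = self.transform
        nr, nc = self.shape
        xs = ox + (np.arange(nc) + 0.5) * px
        ys = oy - (np.arange(nr) + 0.5) * px
        return np.meshgrid(xs, ys)

    def aligned_with(self, other: "Raster") -> bool:
        return self.shape == other.shape and np.allclose(
            self.transform, other.transform
        )

    def like(self, values: np.ndarray, semantics: str, nodata: float | None = None) -> "Raster":
        """New raster on this grid with different values/semantics."""
        return Raster(
            values=values,
            transform=self.transform,
            nodata=self.nodata if nodata is None else nodata,
            semantics=semantics,
        )


def require_aligned(*rasters: Raster) -> None:
    """Raise :class:`AlignmentError` unless all rasters share one grid."""
    ref = rasters[0]
    for r in rasters[1:]:
        if not ref.aligned_with(r):
            raise AlignmentError(
                f"rasters differ in shape/transform: {ref.shape}/{ref.transform}"
                f" vs {r.shape}/{r.transform}"
            )


# ---------------------------------------------------------------------------
# ASCII-grid I/O
# ---------------------------------------------------------------------------

def write_raster(raster: Raster, path: str | Path) -> None:
    """Write an ESRI ASCII grid plus a ``<path>.meta.json`` sidecar.

    The sidecar records the semantics tag, which the ASCII-grid header
    cannot carry.  Values are written with 17 significant digits so a
    write -> read round trip is exact.
    """
    path = Path(path)
    ox, oy, px = raster.transform
    nr, nc = raster.shape
    header = (
        f"ncols {nc}\n"
        f"nrows {nr}\n"
        f"xllcorner {ox!r}\n"
        f"yllcorner {(oy - nr * px)!r}\n"
        f"cellsize {px!r}\n"
        f"NODATA_value {raster.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values, fmt="%.17g")
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump({"semantics": raster.semantics}, fh)


def read_raster(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_raster`.

    Rejects files whose semantics sidecar is missing: a raster without
    a declared meaning cannot be safely combined with others.
    """
    path = Path(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if not meta_path.exists():
        raise ValueError(f"semantics sidecar missing for {path}")
    with open(meta_path) as fh:
        semantics = json.load(fh)["semantics"]
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    nr, nc = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nr, nc):
        raise ValueError(f"grid shape {values.shape} does not match header")
    px = header["cellsize"]
    transform = (header["xllcorner"], header["yllcorner"] + nr * px, px)
    return Raster(values, transform, header["nodata_value"], semantics)


# ---------------------------------------------------------------------------
# Administrative units
# ---------------------------------------------------------------------------

@dataclass
class AdminLayer:
    """Administrative-unit polygons with census bookkeeping attributes.

    ``level`` distinguishes firaisana (towns) from fokontany
    (sub-towns); fokontany carry the id of their parent firaisana.
    """

    ids: list = field(default_factory=list)
    geometries: list = field(default_factory=list)
    levels: list = field(default_factory=list)
    areas_km2: list = field(default_factory=list)
    parents: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for level in set(self.levels):
            ids = [i for i, l in zip(self.ids, self.levels) if l == level]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate unit ids within level {level!r}")
        if any(a <= 0 for a in self.areas_km2):
            raise ValueError("unit areas must be > 0")

    def __len__(self) -> int:
        return len(self.ids)

    def select(self, level: str) -> "AdminLayer":
        keep = [i for i, l in enumerate(self.levels) if l == level]
        return AdminLayer(
            ids=[self.ids[i] for i in keep],
            geometries=[self.geometries[i] for i in keep],
            levels=[self.levels[i] for i in keep],
            areas_km2=[self.areas_km2[i] for i in keep],
            parents=[self.parents[i] for i in keep],
        )


def read_admin_geojson(path: str | Path) -> AdminLayer:
    """Read units from a GeoJSON feature collection.

    Expected feature properties: ``id``, ``level``, ``area_km2`` and
    optionally ``parent_id``; any other attribute is ignored.
    """
    with open(path) as fh:
        doc = json.load(fh)
    layer = AdminLayer()
    for feat in doc["features"]:
        props = feat["properties"]
        layer.ids.append(props["id"])
        layer.levels.append(props["level"])
        layer.areas_km2.append(float(props["area_km2"]))
        layer.parents.append(props.get("parent_id"))
        layer.geometries.append(_shapely_shape(feat["geometry"]))
    layer.__post_init__()
    return layer


def rasterize_units(admin: AdminLayer, template: Raster) -> Raster:
    """Burn unit ids into the template grid by pixel-center containment.

    Every pixel whose center falls inside a unit polygon carries that
    unit's id; pixels outside all units are nodata.  Ids are burned in
    layer order, first containing unit wins, so overlapping polygons do
    not double-assign.
    """
    if len(admin) == 0:
        raise ValueError("empty admin layer")
    xs, ys = template.cell_centers()
    out = np.full(template.shape, template.nodata, dtype=float)
    unassigned = np.ones(template.shape, dtype=bool)
    for uid, geom in zip(admin.ids, admin.geometries):
        if not unassigned.any():
            break
        hit = shapely.contains_xy(geom, xs[unassigned], ys[unassigned])
        idx = np.flatnonzero(unassigned.ravel())[hit]
        out.ravel()[idx] = uid
        unassigned.ravel()[idx] = False
    if not (~unassigned).any():
        warnings.warn("no pixel center falls inside any unit", stacklevel=2)
    return template.like(out, "unit_id")
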