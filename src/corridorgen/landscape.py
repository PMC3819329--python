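"""Resistance layers and study-area mask from rasters and road polylines.

All layers live on a shared :class:`RasterGrid` (row 0 at the top, origin at
the lower-left corner, cells in km).  Each landscape element becomes a
resistance surface rescaled to [1, 100]:

* habitat — Euclidean distance to forest patches larger than 10 km²
  (habitat itself = 1, far = 100);
* tree cover — inverted percent cover (low cover = high resistance);
* settlements — inverted distance to illuminated cells (near = 100); cells
  brighter than the urban threshold are removed from the landscape entirely;
* roads — road density in km of road per km² cell, by exact segment
  clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class RasterGrid:
    """Rectangular grid of cell values with georeferencing.

    ``data`` is (nrows, ncols) with row 0 at the top; ``origin`` is the
    (x, y) of the lower-left corner in km; nodata cells carry ``nodata``.
    """

    data: np.ndarray
    cell_size_km: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_size_km <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def valid_mask(self) -> np.ndarray:
        return self.data != self.nodata

    def like(self, data: np.ndarray, nodata: float | None = None) -> "RasterGrid":
        return RasterGrid(data=np.asarray(data, dtype=float),
                          cell_size_km=self.cell_size_km, origin=self.origin,
                          nodata=self.nodata if nodata is None else nodata)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing point (x, y) in km."""
        col = int((x - self.origin[0]) // self.cell_size_km)
        nrows = self.data.shape[0]
        row = nrows - 1 - int((y - self.origin[1]) // self.cell_size_km)
        return row, col


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for ln in fh:
            parts = ln.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                    "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(x) for x in parts])
    data = np.asarray(rows, dtype=float)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: grid shape does not match header")
    return RasterGrid(data=data, cell_size_km=header["cellsize"],
                      origin=(header.get("xllcorner", 0.0),
                              header.get("yllcorner", 0.0)),
                      nodata=header.get("nodata_value", -9999.0))


def write_ascii_grid(raster: RasterGrid, path) -> None:
    nr, nc = raster.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nc}\n")
        fh.write(f"nrows {nr}\n")
        fh.write(f"xllcorner {raster.origin[0]:g}\n")
        fh.write(f"yllcorner {raster.origin[1]:g}\n")
        fh.write(f"cellsize {raster.cell_size_km:g}\n")
        fh.write(f"NODATA_value {raster.nodata:g}\n")
        for row in raster.data:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


@dataclass
class ResistanceLayer:
    """A RasterGrid whose valid cells lie in [1, 100]."""

    raster: RasterGrid
    provenance: str = "combined"

    def __post_init__(self) -> None:
        v = self.raster.data[self.raster.valid_mask()]
        if v.size and (v.min() < 1 - 1e-9 or v.max() > 100 + 1e-9):
            raise ValueError("resistance values must lie in [1, 100]")

    @property
    def data(self) -> np.ndarray:
        return self.raster.data


@dataclass
class PatchSet:
    """Labelled habitat patches with areas in km²."""

    labels: np.ndarray                  # 0 = background, 1..n = patch id
    areas_km2: dict[int, float] = field(default_factory=dict)

    @property
    def n_patches(self) -> int:
        return len(self.areas_km2)

    def mask(self, patch_id: int | None = None) -> np.ndarray:
        if patch_id is None:
            return self.labels > 0
        return self.labels == patch_id


# ---------------------------------------------------------------------------
# Layer construction


def rescale_1_100(raster: RasterGrid, invert: bool = False,
                  provenance: str = "combined") -> ResistanceLayer:
    """Linearly rescale valid cells to [1, 100]; constant rasters become 1.

    With ``invert`` the mapping runs from the maximum (→1) down to the
    minimum (→100), e.g. dense tree cover = low resistance.
    """
    valid = raster.valid_mask()
    if not valid.any():
        raise ValueError("all-nodata raster")
    v = raster.data[valid]
    lo, hi = float(v.min()), float(v.max())
    out = np.full(raster.shape, raster.nodata)
    if hi == lo:
        out[valid] = 1.0
    else:
        x = (raster.data[valid] - lo) / (hi - lo)
        if invert:
            x = 1.0 - x
        out[valid] = 1.0 + 99.0 * x
    return ResistanceLayer(raster=raster.like(out), provenance=provenance)


def label_patches(habitat_mask: np.ndarray, cell_size_km: float,
                  min_patch_km2: float = 10.0) -> PatchSet:
    """8-connected components of habitat, keeping areas > ``min_patch_km2``."""
    lab, n = ndimage.label(habitat_mask, structure=EIGHT)
    cell_area = cell_size_km ** 2
    out = np.zeros_like(lab)
    areas: dict[int, float] = {}
    next_id = 1
    for i in range(1, n + 1):
        area = float((lab == i).sum() * cell_area)
        if area > min_patch_km2:
            out[lab == i] = next_id
            areas[next_id] = area
            next_id += 1
    return PatchSet(labels=out, areas_km2=areas)


def habitat_resistance(landcover: RasterGrid, habitat_classes=(1,),
                       min_patch_km2: float = 10.0
                       ) -> tuple[ResistanceLayer, PatchSet]:
    """Habitat-proximity resistance: distance to the nearest large patch.

    Habitat patches larger than ``min_patch_km2`` keep the minimum
    resistance of 1; elsewhere the Euclidean distance (km) to the nearest
    retained patch is rescaled to [1, 100].
    """
    mask = np.isin(landcover.data, habitat_classes) & landcover.valid_mask()
    patches = label_patches(mask, landcover.cell_size_km, min_patch_km2)
    if patches.n_patches == 0:
        raise ValueError("no habitat patch survives the area filter")
    dist = ndimage.distance_transform_edt(~patches.mask(),
                                          sampling=landcover.cell_size_km)
    dist[~landcover.valid_mask()] = landcover.nodata
    layer = rescale_1_100(landcover.like(dist), provenance="habitat")
    layer.raster.data[patches.mask()] = 1.0
    return layer, patches


def treecover_resistance(treecover: RasterGrid) -> ResistanceLayer:
    """Percent tree cover, inverted: bare cells resist, dense cover is open."""
    return rescale_1_100(treecover, invert=True, provenance="treecover")


def settlement_resistance(lights: RasterGrid, urban_threshold: float = 20.0
                          ) -> tuple[ResistanceLayer, np.ndarray]:
    """Settlement-proximity resistance and the urban mask.

    Illuminated cells (radiance > 0) are settlement sources; resistance is
    the inverted rescaled distance to them (adjacent = 100, farthest = 1).
    Cells brighter than ``urban_threshold`` form the urban mask, which the
    study-area step removes from the landscape altogether.
    """
    valid = lights.valid_mask()
    lit = (lights.data > 0) & valid
    urban = (lights.data > urban_threshold) & valid
    if not lit.any():
        out = np.where(valid, 1.0, lights.nodata)
        return (ResistanceLayer(raster=lights.like(out),
                                provenance="settlements"), urban)
    dist = ndimage.distance_transform_edt(~lit, sampling=lights.cell_size_km)
    dist[~valid] = lights.nodata
    layer = rescale_1_100(lights.like(dist), invert=True,
                          provenance="settlements")
    return layer, urban


def road_resistance(polylines, grid: RasterGrid) -> ResistanceLayer:
    """Road-density resistance: km of road per km² cell, rescaled to 1–100.

    Polylines are lists of (x, y) vertices in km; segment length inside each
    cell is computed exactly by splitting segments at grid lines.  Cells
    without roads keep the minimum resistance of 1.
    """
    density = road_density(polylines, grid)
    if float(np.nanmax(np.where(grid.valid_mask(), density, 0.0))) == 0.0:
        out = np.where(grid.valid_mask(), 1.0, grid.nodata)
        return ResistanceLayer(raster=grid.like(out), provenance="roads")
    d = np.where(grid.valid_mask(), density, grid.nodata)
    return rescale_1_100(grid.like(d), provenance="roads")


def road_density(polylines, grid: RasterGrid) -> np.ndarray:
    """Total polyline length per cell divided by the cell area (km/km²)."""
    nr, nc = grid.shape
    cs = grid.cell_size_km
    x0, y0 = grid.origin
    dens = np.zeros((nr, nc))
    for line in polylines:
        for (xa, ya), (xb, yb) in zip(line[:-1], line[1:]):
            for row, col, seg in _clip_segment(xa - x0, ya - y0, xb - x0,
                                               yb - y0, nr, nc, cs):
                dens[row, col] += seg
    return dens / (cs * cs)


def _clip_segment(xa, ya, xb, yb, nr, nc, cs):
    """Yield (row, col, length) of a segment's pieces inside grid cells."""
    length = float(np.hypot(xb - xa, yb - ya))
    if length == 0:
        return
    # parameter values where the segment crosses grid lines
    ts = {0.0, 1.0}
    for grids, a, b in (((np.arange(nc + 1) * cs), xa, xb),
                        ((np.arange(nr + 1) * cs), ya, yb)):
        if b != a:
            t = (grids - a) / (b - a)
            ts.update(t[(t > 0) & (t < 1)].tolist())
    ts = sorted(ts)
    for t0, t1 in zip(ts[:-1], ts[1:]):
        tm = (t0 + t1) / 2
        xm = xa + tm * (xb - xa)
        ym = ya + tm * (yb - ya)
        col = int(xm // cs)
        row = nr - 1 - int(ym // cs)
        if 0 <= row < nr and 0 <= col < nc:
            yield row, col, (t1 - t0) * length


def study_area(patches: PatchSet, grid: RasterGrid, buffer_km: float = 30.0,
               urban_mask: np.ndarray | None = None) -> np.ndarray:
    """Valid-cell mask: within ``buffer_km`` of a retained patch, not urban."""
    dist = ndimage.distance_transform_edt(~patches.mask(),
                                          sampling=grid.cell_size_km)
    valid = dist <= buffer_km
    if urban_mask is not None:
        valid &= ~urban_mask
    if not valid.any():
        raise ValueError("study-area mask is empty")
    return valid


def apply_mask(layer: ResistanceLayer, valid: np.ndarray) -> ResistanceLayer:
    data = np.where(valid, layer.raster.data, layer.raster.nodata)
    return ResistanceLayer(raster=layer.raster.like(data),
                           provenance=layer.provenance)


def combine_layers(layers: list[ResistanceLayer],
                   weights=None) -> ResistanceLayer:
    """Cell-wise weighted mean of rescaled layers, rescaled again to 1–100.

    Nodata in any input propagates to the output.
    """
    if not layers:
        raise ValueError("no layers to combine")
    shape = layers[0].raster.shape
    for ly in layers:
        if ly.raster.shape != shape:
            raise ValueError("layers are not co-registered")
    w = np.ones(len(layers)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    valid = np.ones(shape, dtype=bool)
    acc = np.zeros(shape)
    for wi, ly in zip(w, layers):
        valid &= ly.raster.valid_mask()
        acc += wi * np.where(ly.raster.valid_mask(), ly.raster.data, 0.0)
    base = layers[0].raster
    data = np.where(valid, acc, base.nodata)
    name = "+".join(ly.provenance for ly in layers)
    return rescale_1_100(base.like(data), provenance=name)
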