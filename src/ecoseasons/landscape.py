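"""Synthetic raster landscapes for testing the space-use pipeline.

A :class:`LandscapeStack` bundles co-registered layers on a shared projected
grid (meters): a categorical land-cover layer, terrain (slope in degrees,
northness as the cosine of aspect), and Euclidean distance surfaces to a
synthetic shoreline and a synthetic road polyline.  Land cover is generated by
thresholding a smoothed Gaussian random field at class-quantile breakpoints,
which matches requested class proportions by construction while producing
spatially coherent patches, and terrain is derived from a second smoothed
field acting as an elevation surface.

Layers are stored row-major with row 0 at the *top* (largest y), the usual
raster convention.  Cell (r, c) has center
``(origin_x + (c + 0.5) * cell_size, origin_y - (r + 0.5) * cell_size)``
where ``origin_x, origin_y`` is the top-left corner of the grid.

On disk a landscape is a directory of ESRI ASCII grids (one ``.asc`` per
layer) plus a ``legend.json`` sidecar holding the grid metadata and the
integer codes of the land-cover classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import DegenerateLandscapeError, InvalidConfigError

#: Canonical land-cover classes (agriculture and grassland are folded into
#: shrubland upstream of this package).
LAND_COVER_CLASSES = (
    "open_water",
    "coniferous_forest",
    "deciduous_forest",
    "mixed_forest",
    "shrubland",
    "wetland",
)

#: Mainland-style class proportions used as the default study landscape
#: (44% mixed forest, 17% deciduous, 11% coniferous, 9% shrubland,
#: 7% wetland, 5% open water; the 7% remainder is assigned to the largest
#: class, mixed forest).
MAINLAND_PROPORTIONS = {
    "mixed_forest": 0.44,
    "deciduous_forest": 0.17,
    "coniferous_forest": 0.11,
    "shrubland": 0.09,
    "wetland": 0.07,
    "open_water": 0.05,
}

CONTINUOUS_LAYERS = ("slope", "northness", "dist_lake", "dist_road")


@dataclass
class GridSpec:
    """Geometry of a raster grid in a projected CRS (meters)."""

    n_rows: int
    n_cols: int
    cell_size: float = 30.0
    origin_x: float = 0.0
    origin_y: float | None = None  # top-left y; defaults to n_rows * cell

    def __post_init__(self):
        if self.origin_y is None:
            self.origin_y = self.n_rows * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the grid footprint."""
        xmin = self.origin_x
        xmax = self.origin_x + self.n_cols * self.cell_size
        ymax = self.origin_y
        ymin = self.origin_y - self.n_rows * self.cell_size
        return xmin, xmax, ymin, ymax

    def cell_centers(self):
        """Return (x_centers[n_cols], y_centers[n_rows]) of cell centers."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def rowcol(self, x, y):
        """Map point coordinates to (row, col) by the half-open cell
        convention: x in [left, right), y in (bottom, top]."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size)
        row = np.ceil((self.origin_y - np.asarray(y)) / self.cell_size) - 1
        return row.astype(int), col.astype(int)


@dataclass
class LandscapeStack:
    """Co-registered raster layers sharing one grid."""

    grid: GridSpec
    land_cover: np.ndarray  # int codes indexing LAND_COVER_CLASSES
    slope: np.ndarray  # degrees >= 0
    northness: np.ndarray  # cos(aspect), in [-1, 1]
    dist_lake: np.ndarray  # meters >= 0
    dist_road: np.ndarray  # meters >= 0
    classes: tuple[str, ...] = LAND_COVER_CLASSES
    shoreline_mask: np.ndarray | None = field(default=None, repr=False)
    road_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        shape = (self.grid.n_rows, self.grid.n_cols)
        for name in ("land_cover", "slope", "northness", "dist_lake", "dist_road"):
            layer = getattr(self, name)
            if layer.shape != shape:
                raise InvalidConfigError(
                    f"layer {name!r} shape {layer.shape} != grid shape {shape}"
                )

    @property
    def layer_names(self) -> tuple[str, ...]:
        return ("land_cover",) + CONTINUOUS_LAYERS

    def class_fractions(self) -> dict[str, float]:
        """Realized areal fraction of each land-cover class."""
        n = self.land_cover.size
        return {
            cls: float(np.count_nonzero(self.land_cover == i)) / n
            for i, cls in enumerate(self.classes)
        }

    def covariates_at(self, x, y):
        """Nearest-cell covariate lookup; returns dict of arrays.

        Raises IndexError implicitly for out-of-range cells; callers that
        need a diagnostic use :func:`ecoseasons.trackprep.extract_covariates`.
        """
        row, col = self.grid.rowcol(x, y)
        return {
            "land_cover": self.land_cover[row, col],
            "slope": self.slope[row, col],
            "northness": self.northness[row, col],
            "dist_lake": self.dist_lake[row, col],
            "dist_road": self.dist_road[row, col],
        }


def _smooth_field(shape, sigma, rng):
    field = rng.standard_normal(shape)
    field = ndimage.gaussian_filter(field, sigma=sigma, mode="reflect")
    field -= field.mean()
    sd = field.std()
    return field / sd if sd > 0 else field


def _terrain(shape, cell_size, rng, relief_m=400.0, sigma=8.0):
    """Slope (deg) and northness from a synthetic elevation surface."""
    elev = _smooth_field(shape, sigma, rng) * (relief_m / 4.0)
    # np.gradient rows run top->bottom, i.e. decreasing y
    dz_drow, dz_dcol = np.gradient(elev, cell_size)
    dz_dy = -dz_drow
    dz_dx = dz_dcol
    slope = np.degrees(np.arctan(np.hypot(dz_dx, dz_dy)))
    # aspect = downslope direction; northness = cos(aspect from north)
    aspect = np.arctan2(-dz_dx, -dz_dy)  # 0 = north, clockwise positive
    northness = np.cos(aspect)
    flat = (dz_dx == 0) & (dz_dy == 0)
    northness[flat] = 0.0
    return slope, northness


def _shoreline_mask(shape, rng):
    """A wavy one-cell-wide shoreline near the southern (bottom) edge."""
    n_rows, n_cols = shape
    base = n_rows - max(2, n_rows // 10)
    wiggle = ndimage.gaussian_filter(rng.standard_normal(n_cols), sigma=max(2, n_cols // 20))
    wsd = wiggle.std()
    amp = max(1, n_rows // 15)
    offs = np.zeros(n_cols, dtype=int) if wsd == 0 else np.round(wiggle / wsd * amp).astype(int)
    rows = np.clip(base + offs, 0, n_rows - 1)
    mask = np.zeros(shape, dtype=bool)
    mask[rows, np.arange(n_cols)] = True
    return mask


def _road_mask(shape, rng):
    """A wavy road polyline running inland, crossing the full grid height
    (roughly perpendicular to the shoreline, as access roads tend to be)."""
    n_rows, n_cols = shape
    base = n_cols // 3
    wiggle = ndimage.gaussian_filter(rng.standard_normal(n_rows), sigma=max(2, n_rows // 15))
    wsd = wiggle.std()
    amp = max(1, n_cols // 10)
    offs = np.zeros(n_rows, dtype=int) if wsd == 0 else np.round(wiggle / wsd * amp).astype(int)
    cols = np.clip(base + offs, 0, n_cols - 1)
    mask = np.zeros(shape, dtype=bool)
    prev = cols[0]
    for r in range(n_rows):
        c = cols[r]
        lo, hi = (prev, c) if prev <= c else (c, prev)
        mask[r, lo : hi + 1] = True  # keep the polyline 8-connected
        prev = c
    return mask


def _distance_layer(mask, cell_size):
    """Euclidean distance (m) from each cell center to the nearest True cell."""
    return ndimage.distance_transform_edt(~mask, sampling=cell_size)


def make_landscape(
    class_proportions: dict[str, float] | None = None,
    grid_spec: GridSpec | None = None,
    seed: int = 0,
    patch_sigma: float = 4.0,
) -> LandscapeStack:
    """Generate a synthetic landscape with target class proportions.

    Parameters
    ----------
    class_proportions
        Map class name -> target areal fraction.  Must sum to <= 1; any
        remainder is assigned to the largest requested class.  Defaults to
        the mainland study-area mixture (:data:`MAINLAND_PROPORTIONS`).
    grid_spec
        Grid geometry; defaults to 200 x 200 cells of 30 m.
    seed
        Seed for the landscape random field, shoreline and road shapes.
    patch_sigma
        Gaussian smoothing length (cells) of the land-cover field;
        larger values give larger habitat patches.
    """
    if class_proportions is None:
        class_proportions = dict(MAINLAND_PROPORTIONS)
    if grid_spec is None:
        grid_spec = GridSpec(200, 200)
    for cls, p in class_proportions.items():
        if cls not in LAND_COVER_CLASSES:
            raise InvalidConfigError(f"unknown land-cover class {cls!r}")
        if p < 0:
            raise InvalidConfigError(f"negative proportion for {cls!r}: {p}")
    total = sum(class_proportions.values())
    if total > 1 + 1e-9:
        raise InvalidConfigError(f"proportions sum to {total:.3f} > 1")
    if grid_spec.n_rows < 50 or grid_spec.n_cols < 50:
        raise DegenerateLandscapeError(
            f"grid {grid_spec.n_rows}x{grid_spec.n_cols} below the 50x50 minimum"
        )

    props = dict(class_proportions)
    remainder = 1.0 - total
    if remainder > 1e-9:
        largest = max(props, key=props.get)
        props[largest] += remainder

    n_cells = grid_spec.n_rows * grid_spec.n_cols
    active = [(c, p) for c, p in props.items() if p > 0]
    for cls, p in active:
        if p * n_cells < 1:
            raise DegenerateLandscapeError(
                f"grid too small to realize class {cls!r} at fraction {p:.3g}"
            )

    rng = np.random.default_rng(seed)
    shape = (grid_spec.n_rows, grid_spec.n_cols)
    field = _smooth_field(shape, patch_sigma, rng)

    # threshold the field at quantile breakpoints so realized fractions
    # match requested fractions up to the cell-count granularity
    order = sorted(active, key=lambda cp: -cp[1])  # largest class first
    flat = field.ravel()
    ranks = np.argsort(flat, kind="stable")
    land = np.empty(n_cells, dtype=np.int8)
    start = 0
    for i, (cls, p) in enumerate(order):
        count = int(round(p * n_cells)) if i < len(order) - 1 else n_cells - start
        count = min(count, n_cells - start)
        land[ranks[start : start + count]] = LAND_COVER_CLASSES.index(cls)
        start += count
    land_cover = land.reshape(shape)

    slope, northness = _terrain(shape, grid_spec.cell_size, rng)
    shoreline = _shoreline_mask(shape, rng)
    road = _road_mask(shape, rng)
    dist_lake = _distance_layer(shoreline, grid_spec.cell_size)
    dist_road = _distance_layer(road, grid_spec.cell_size)

    return LandscapeStack(
        grid=grid_spec,
        land_cover=land_cover,
        slope=slope,
        northness=northness,
        dist_lake=dist_lake,
        dist_road=dist_road,
        shoreline_mask=shoreline,
        road_mask=road,
    )


# ---------------------------------------------------------------------------
# ASCII-grid serialization


def _write_asc(path: Path, grid: GridSpec, layer: np.ndarray, fmt: str):
    xmin, _, ymin, _ = grid.extent
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {xmin}\n"
        f"yllcorner {ymin}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, layer, fmt=fmt)


def _read_asc(path: Path):
    meta = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        data = np.loadtxt(fh)
    return meta, data


def write_landscape(stack: LandscapeStack, out_dir: str | Path) -> Path:
    """Write the stack as per-layer ESRI ASCII grids plus legend.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_asc(out / "land_cover.asc", stack.grid, stack.land_cover, "%d")
    for name in CONTINUOUS_LAYERS:
        _write_asc(out / f"{name}.asc", stack.grid, getattr(stack, name), "%.4f")
    legend = {
        "classes": {str(i): cls for i, cls in enumerate(stack.classes)},
        "grid": {
            "n_rows": stack.grid.n_rows,
            "n_cols": stack.grid.n_cols,
            "cell_size": stack.grid.cell_size,
            "origin_x": stack.grid.origin_x,
            "origin_y": stack.grid.origin_y,
        },
        "layers": list(("land_cover",) + CONTINUOUS_LAYERS),
    }
    (out / "legend.json").write_text(json.dumps(legend, indent=2))
    return out


def read_landscape(in_dir: str | Path) -> LandscapeStack:
    """Read a landscape directory written by :func:`write_landscape`."""
    src = Path(in_dir)
    legend = json.loads((src / "legend.json").read_text())
    g = legend["grid"]
    grid = GridSpec(
        n_rows=int(g["n_rows"]),
        n_cols=int(g["n_cols"]),
        cell_size=float(g["cell_size"]),
        origin_x=float(g["origin_x"]),
        origin_y=float(g["origin_y"]),
    )
    _, land = _read_asc(src / "land_cover.asc")
    layers = {}
    for name in CONTINUOUS_LAYERS:
        _, layers[name] = _read_asc(src / f"{name}.asc")
    classes = tuple(
        legend["classes"][str(i)] for i in range(len(legend["classes"]))
    )
    return LandscapeStack(
        grid=grid,
        land_cover=land.astype(np.int8).reshape(grid.n_rows, grid.n_cols),
        slope=layers["slope"],
        northness=layers["northness"],
        dist_lake=layers["dist_lake"],
        dist_road=layers["dist_road"],
        classes=classes,
    )
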