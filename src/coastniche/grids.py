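"""Gridded environmental data containers and plain-text raster I/O.

A study region is a regular grid of square cells. Sea (or otherwise invalid)
cells are carried as a boolean nodata mask rather than a sentinel value, so
inundation under sea-level rise is expressed by growing the mask.

Rasters are read and written as ESRI ASCII grids (``.asc``) — a plain-text
format every GIS understands — with a YAML manifest recording layer order,
kinds and units for a whole stack.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

#: Canonical layer names for the 15-variable coastal stack: seven bioclimatic
#: variables, six soil variables (two categorical) and elevation.
CLIMATE_LAYERS = ("Bio02", "Bio03", "Bio05", "Bio08", "Bio14", "Bio15", "Bio19")
SOIL_CONTINUOUS_LAYERS = ("Tece", "Tgravel", "Toc", "Tph", "Tsand")
SOIL_CATEGORICAL_LAYERS = ("Drainage", "Tclass")
ELEVATION_LAYER = "Elevation"
DEFAULT_LAYER_ORDER = (
    CLIMATE_LAYERS
    + SOIL_CONTINUOUS_LAYERS
    + SOIL_CATEGORICAL_LAYERS
    + (ELEVATION_LAYER,)
)

ASC_NODATA = -9999.0


@dataclass
class GridSpec:
    """Geometry of a regular raster grid.

    ``origin`` is the (x, y) map coordinate of the outer corner of cell
    (row 0, col 0); x grows with column index and y with row index. Cells are
    half-open: a point with ``origin[0] <= x < origin[0] + cell_size`` falls
    in column 0. ``cell_size`` is the cell edge in km.
    """

    nrows: int
    ncols: int
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError(f"grid dimensions must be >= 1, got {self.nrows}x{self.ncols}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros((self.nrows, self.ncols), dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != (self.nrows, self.ncols):
                raise ValueError(
                    f"nodata_mask shape {self.nodata_mask.shape} does not match "
                    f"grid {(self.nrows, self.ncols)}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_unmasked(self) -> int:
        return int((~self.nodata_mask).sum())

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col) indices.

        Returns (row, col, inside) where ``inside`` flags points whose cell
        lies within the grid bounds. Cells are half-open intervals
        ``[edge, edge + cell_size)``.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        inside = (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)
        return row, col, inside

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin[1] + (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def same_geometry(self, other: "GridSpec") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin == other.origin
        )

    def copy(self) -> "GridSpec":
        return GridSpec(
            self.nrows, self.ncols, self.cell_size, self.origin, self.nodata_mask.copy()
        )


@dataclass
class Layer:
    """A single named environmental raster layer."""

    name: str
    values: np.ndarray
    kind: str = "continuous"  # "continuous" | "categorical"
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)

    def copy(self) -> "Layer":
        return Layer(self.name, self.values.copy(), self.kind, self.units)


class EnvironmentalStack:
    """An ordered set of co-registered layers over one grid."""

    def __init__(self, grid: GridSpec, layers: Iterable[Layer]):
        self.grid = grid
        self.layers: dict[str, Layer] = {}
        for layer in layers:
            if layer.name in self.layers:
                raise ValueError(f"duplicate layer name {layer.name!r}")
            if layer.values.shape != grid.shape:
                raise ValueError(
                    f"layer {layer.name!r} shape {layer.values.shape} does not "
                    f"match grid {grid.shape}"
                )
            self.layers[layer.name] = layer

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> Layer:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def copy(self) -> "EnvironmentalStack":
        return EnvironmentalStack(self.grid.copy(), [l.copy() for l in self.layers.values()])

    def values_at(self, rows: np.ndarray, cols: np.ndarray) -> dict[str, np.ndarray]:
        return {name: layer.values[rows, cols] for name, layer in self.layers.items()}

    def table(self) -> "np.ndarray":
        """Unmasked cell values as an (n_unmasked, n_layers) array (layer order)."""
        keep = ~self.grid.nodata_mask
        return np.column_stack([l.values[keep] for l in self.layers.values()])


@dataclass
class ScenarioSet:
    """Environmental stacks for the current state and three futures.

    CUR: current conditions. CLC: climate layers offset, rest unchanged.
    SLR: elevation lowered by the sea-level rise, newly negative cells
    inundated (masked). CCS: both changes combined.
    """

    CUR: EnvironmentalStack
    CLC: EnvironmentalStack
    SLR: EnvironmentalStack
    CCS: EnvironmentalStack

    def __post_init__(self) -> None:
        g = self.CUR.grid
        for name in ("CLC", "SLR", "CCS"):
            if not getattr(self, name).grid.same_geometry(g):
                raise ValueError(f"scenario {name} grid differs from CUR")

    def items(self):
        return (("CUR", self.CUR), ("CLC", self.CLC), ("SLR", self.SLR), ("CCS", self.CCS))


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_ascii_grid(path: str | Path, values: np.ndarray, grid: GridSpec,
                     nodata: float = ASC_NODATA, fmt: str = "%.6g") -> None:
    """Write one layer as an ESRI ASCII grid (row 0 written last: the format
    stores rows north-to-south, our row index grows with y)."""
    values = np.asarray(values, dtype=float)
    out = values.copy()
    out[grid.nodata_mask] = nodata
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.origin[0]}\n"
        f"yllcorner {grid.origin[1]}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    body = np.flipud(out)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; returns (values, GridSpec with nodata mask)."""
    header: dict[str, float] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            ):
                header[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
    values = np.loadtxt(path, skiprows=n_header)
    values = np.atleast_2d(values)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise ValueError(f"{path}: data shape {values.shape} != header {(nrows, ncols)}")
    values = np.flipud(values).copy()
    nodata = header.get("nodata_value", ASC_NODATA)
    mask = values == nodata
    grid = GridSpec(
        nrows, ncols, header["cellsize"],
        (header["xllcorner"], header["yllcorner"]), mask,
    )
    values[mask] = np.nan
    return values, grid


def write_stack(directory: str | Path, stack: EnvironmentalStack,
                manifest_name: str = "stack.yaml") -> Path:
    """Write a stack as one .asc file per layer plus a YAML manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, layer in stack.layers.items():
        fname = f"{name}.asc"
        write_ascii_grid(directory / fname, layer.values, stack.grid)
        entries.append({"name": name, "file": fname, "kind": layer.kind, "units": layer.units})
    manifest = {
        "grid": {
            "nrows": stack.grid.nrows,
            "ncols": stack.grid.ncols,
            "cell_size": stack.grid.cell_size,
            "origin": list(stack.grid.origin),
        },
        "layers": entries,
    }
    mpath = directory / manifest_name
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath


def read_stack(manifest_path: str | Path) -> EnvironmentalStack:
    """Assemble a stack from a manifest written by :func:`write_stack`.

    Layers must agree exactly on grid geometry; the stack mask is the union
    of per-layer nodata masks.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    directory = manifest_path.parent
    layers: list[Layer] = []
    grid: GridSpec | None = None
    mask: np.ndarray | None = None
    for entry in manifest["layers"]:
        values, g = read_ascii_grid(directory / entry["file"])
        if grid is None:
            grid, mask = g, g.nodata_mask.copy()
        else:
            if not grid.same_geometry(g):
                raise ValueError(
                    f"layer {entry['name']!r} geometry {g.shape} does not match stack"
                )
            mask |= g.nodata_mask
        values = np.where(np.isnan(values), 0.0, values)
        layers.append(Layer(entry["name"], values, entry.get("kind", "continuous"),
                            entry.get("units", "")))
    assert grid is not None
    grid.nodata_mask = mask
    return EnvironmentalStack(grid, layers)
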