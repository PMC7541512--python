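"""Grid data model and raster plumbing shared by every pipeline stage.

A :class:`Layer` is a single georeferenced raster; an :class:`EnvStack` is a
named, grid-aligned collection of them (the environmental state at one time
point).  All cross-layer operations require exact alignment of the five
:class:`GridSpec` fields.  The interchange format is the ESRI ASCII grid
(``.asc``): header keys ``ncols, nrows, xllcorner, yllcorner, cellsize,
NODATA_value`` followed by rows top-to-bottom.

Coordinate convention
---------------------
Cell ``(row 0, col 0)`` is the *top-left* cell; map coordinates use the
lower-left origin of the ESRI header.  Cell membership is half-open,
``[x0, x0 + cs) x (y0, y0 + cs]`` per cell, so every point maps to exactly
one cell: a point on a shared vertical edge belongs to the cell on its
right, a point on a shared horizontal edge to the cell above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class RasterFormatError(ValueError):
    """Malformed ESRI ASCII grid input."""


class AlignmentError(ValueError):
    """Operation across layers whose GridSpecs differ."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry shared by all layers of one analysis grid.

    ``x_origin``/``y_origin`` locate the lower-left corner in map units;
    cells are square with side ``cellsize``.
    """

    nrows: int
    ncols: int
    x_origin: float = 0.0
    y_origin: float = 0.0
    cellsize: float = 1.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("nrows and ncols must be >= 1")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid in map units."""
        return (
            self.x_origin,
            self.y_origin,
            self.x_origin + self.ncols * self.cellsize,
            self.y_origin + self.nrows * self.cellsize,
        )

    def aligned(self, other: "GridSpec") -> bool:
        return (
            self.nrows == other.nrows
            and self.ncols == other.ncols
            and self.x_origin == other.x_origin
            and self.y_origin == other.y_origin
            and self.cellsize == other.cellsize
        )

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Map a point to its (row, col); raises if outside the extent.

        Half-open membership: [x0, x0+cs) horizontally, (y0, y0+cs]
        vertically, so edge points go right/above.
        """
        xmin, ymin, xmax, ymax = self.extent
        if not (xmin <= x < xmax) or not (ymin < y <= ymax):
            raise ValueError(f"point ({x}, {y}) outside grid extent {self.extent}")
        col = int(np.floor((x - xmin) / self.cellsize))
        # rows count from the top; the top edge (y == ymax) belongs to row 0
        row_from_bottom = int(np.ceil((y - ymin) / self.cellsize)) - 1
        row = self.nrows - 1 - row_from_bottom
        return row, col

    def cell_centre(self, row: int, col: int) -> tuple[float, float]:
        x = self.x_origin + (col + 0.5) * self.cellsize
        y = self.y_origin + (self.nrows - row - 0.5) * self.cellsize
        return x, y

    def centre_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centre x and y as full (nrows, ncols) arrays."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.x_origin + (cols + 0.5) * self.cellsize
        y = self.y_origin + (self.nrows - rows - 0.5) * self.cellsize
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(
            y[:, None], self.shape
        ).copy()


@dataclass
class Layer:
    """One named raster on a :class:`GridSpec`.

    ``values`` is an (nrows, ncols) float array stored top-to-bottom;
    cells equal to ``spec.nodata`` or non-finite are invalid.
    """

    spec: GridSpec
    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != spec shape {self.spec.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean validity mask: True where the cell carries a real value."""
        return np.isfinite(self.values) & (self.values != self.spec.nodata)

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def with_values(self, values: np.ndarray, name: str | None = None) -> "Layer":
        return Layer(self.spec, name if name is not None else self.name, values)

    def copy(self) -> "Layer":
        return Layer(self.spec, self.name, self.values.copy())


@dataclass
class EnvStack:
    """Ordered name -> Layer mapping, all aligned to one GridSpec."""

    spec: GridSpec
    layers: dict[str, Layer] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, layer in self.layers.items():
            self._check(name, layer)

    def _check(self, name: str, layer: Layer) -> None:
        if not layer.spec.aligned(self.spec):
            raise AlignmentError(f"layer {name!r} is not aligned to the stack grid")

    def add(self, layer: Layer) -> None:
        if layer.name in self.layers:
            raise ValueError(f"duplicate layer name {layer.name!r}")
        self._check(layer.name, layer)
        self.layers[layer.name] = layer

    def __getitem__(self, name: str) -> Layer:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def subset(self, names: list[str]) -> "EnvStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return EnvStack(self.spec, {n: self.layers[n] for n in names})

    def joint_mask(self, names: list[str] | None = None) -> np.ndarray:
        """Cells valid in every requested layer."""
        names = names if names is not None else self.names
        mask = np.ones(self.spec.shape, dtype=bool)
        for n in names:
            mask &= self.layers[n].mask
        return mask


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path, name: str | None = None) -> Layer:
    """Read an ESRI ASCII grid file into a :class:`Layer`.

    The six-line header (``NODATA_value`` optional, default -9999) is parsed
    case-insensitively; data rows run top-to-bottom.
    """
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    header: dict[str, float] = {}
    idx = 0
    for ln in lines:
        parts = ln.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            header[parts[0].lower()] = float(parts[1])
            idx += 1
        else:
            break
    for key in _HEADER_KEYS:
        if key not in header:
            raise RasterFormatError(f"missing header key {key!r} in {path}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", -9999.0)
    rows = lines[idx:]
    if len(rows) != nrows:
        raise RasterFormatError(f"expected {nrows} data rows, found {len(rows)} in {path}")
    values = np.empty((nrows, ncols), dtype=float)
    for i, ln in enumerate(rows):
        fields = ln.split()
        if len(fields) != ncols:
            raise RasterFormatError(
                f"row {i}: expected {ncols} values, found {len(fields)} in {path}"
            )
        values[i] = [float(v) for v in fields]
    spec = GridSpec(
        nrows=nrows,
        ncols=ncols,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=nodata,
    )
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return Layer(spec, name, values)


def write_ascii_grid(layer: Layer, path, precision: int = 6) -> None:
    """Write a Layer as an ESRI ASCII grid; round-trips with read_ascii_grid."""
    s = layer.spec
    with open(path, "w") as fh:
        fh.write(f"ncols {s.ncols}\n")
        fh.write(f"nrows {s.nrows}\n")
        fh.write(f"xllcorner {s.x_origin:.10g}\n")
        fh.write(f"yllcorner {s.y_origin:.10g}\n")
        fh.write(f"cellsize {s.cellsize:.10g}\n")
        fh.write(f"NODATA_value {s.nodata:.10g}\n")
        for row in layer.values:
            fh.write(" ".join(f"{v:.{precision}g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Resampling and predictor selection


def upscale(layer: Layer, factor: int, method: str = "mean") -> Layer:
    """Aggregate factor x factor blocks into one coarser cell.

    ``method='mean'`` for continuous layers, ``'majority'`` for categorical.
    Nodata cells are ignored inside a block; an all-nodata block stays nodata.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    s = layer.spec
    if s.nrows % factor or s.ncols % factor:
        raise ValueError(
            f"grid {s.nrows}x{s.ncols} not divisible by factor {factor}"
        )
    if method not in ("mean", "majority"):
        raise ValueError(f"unknown method {method!r}")
    nr, nc = s.nrows // factor, s.ncols // factor
    blocks = layer.values.reshape(nr, factor, nc, factor).transpose(0, 2, 1, 3)
    blocks = blocks.reshape(nr, nc, factor * factor)
    valid = np.isfinite(blocks) & (blocks != s.nodata)
    out = np.full((nr, nc), s.nodata)
    if method == "mean":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sums = np.where(valid, blocks, 0.0).sum(axis=2)
            counts = valid.sum(axis=2)
            np.divide(sums, counts, out=out, where=counts > 0)
    else:
        for i in range(nr):
            for j in range(nc):
                vals = blocks[i, j][valid[i, j]]
                if vals.size:
                    uniq, cnt = np.unique(vals, return_counts=True)
                    out[i, j] = uniq[np.argmax(cnt)]
    new_spec = replace(s, nrows=nr, ncols=nc, cellsize=s.cellsize * factor)
    return Layer(new_spec, layer.name, out)


def select_uncorrelated(
    stack: EnvStack,
    threshold: float = 0.7,
    priority: list[str] | None = None,
) -> EnvStack:
    """Greedy predictor selection by pairwise Pearson correlation.

    Scanning in ``priority`` order (default: stack order), a layer is kept
    iff its |r| with every already-kept layer, over jointly valid cells, is
    below ``threshold``.  Zero-variance layers are skipped with a warning.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    priority = priority if priority is not None else stack.names
    if len(priority) < 2:
        raise ValueError("need at least 2 layers to select among")
    kept: list[str] = []
    for name in priority:
        layer = stack[name]
        admissible = True
        for prev in kept:
            other = stack[prev]
            joint = layer.mask & other.mask
            if joint.sum() < 3:
                raise ValueError(
                    f"layers {name!r} and {prev!r} share fewer than 3 valid cells"
                )
            a, b = layer.values[joint], other.values[joint]
            if a.std() == 0 or b.std() == 0:
                warnings.warn(
                    f"zero-variance layer among ({name!r}, {prev!r}); skipping {name!r}"
                )
                admissible = False
                break
            r = np.corrcoef(a, b)[0, 1]
            if abs(r) >= threshold:
                admissible = False
                break
        if admissible:
            kept.append(name)
    return stack.subset(kept)


def extract_values(
    stack: EnvStack, points: list[tuple[float, float]], ids=None
) -> pd.DataFrame:
    """Look up every layer's value at each point's containing cell.

    Returns a tidy frame with columns ``id, x, y, <layer...>, valid_flag``.
    Out-of-extent points get ``valid_flag='out_of_extent'`` and NaN values;
    points whose cell is nodata in any layer get ``'nodata_cell'``.
    """
    ids = ids if ids is not None else list(range(len(points)))
    rows = []
    for pid, (x, y) in zip(ids, points):
        rec: dict = {"id": pid, "x": x, "y": y}
        try:
            r, c = stack.spec.cell_of(x, y)
        except ValueError:
            for n in stack.names:
                rec[n] = np.nan
            rec["valid_flag"] = "out_of_extent"
            rows.append(rec)
            continue
        ok = True
        for n in stack.names:
            layer = stack[n]
            rec[n] = layer.values[r, c]
            ok = ok and bool(layer.mask[r, c])
        rec["valid_flag"] = "ok" if ok else "nodata_cell"
        rows.append(rec)
    return pd.DataFrame(rows)
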