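"""Range size, range change, centre-of-gravity shift and Schoener's D.

These are the summary statistics used to compare suitable and reachable
ranges across species, model tiers, emission scenarios and time periods:
how many cells of habitat, how much it grew or shrank relative to today,
where the range centroid moved (distance and compass bearing), and how much
two species' suitability surfaces overlap (Schoener's D, from 0 for no
overlap to 1 for full overlap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grids import AlignmentError, Layer


class EmptyRangeError(ValueError):
    """Statistic requested on a range with no cells."""


@dataclass
class RangeSummary:
    cell_count: int
    area: float  # cells x cellsize^2, map units squared
    cog: tuple[float, float] | None = None
    percent_change: float | None = None


@dataclass
class OverlapResult:
    schoener_d: float
    p: np.ndarray  # normalized surfaces over shared valid cells
    q: np.ndarray


def _check_binary(layer: Layer) -> np.ndarray:
    vals = layer.values[layer.mask]
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError(f"layer {layer.name!r} is not binary (0/1/nodata)")
    return layer.mask & (layer.values == 1.0)


def range_size(binary: Layer) -> RangeSummary:
    """Count suitable cells and convert to area."""
    ones = _check_binary(binary)
    count = int(ones.sum())
    return RangeSummary(cell_count=count, area=count * binary.spec.cellsize**2)


def range_change(reference: Layer, future: Layer) -> float:
    """Percent change in cell count relative to the reference map."""
    if not reference.spec.aligned(future.spec):
        raise AlignmentError("range_change requires aligned layers")
    n_ref = range_size(reference).cell_count
    n_fut = range_size(future).cell_count
    if n_ref == 0:
        raise EmptyRangeError("reference range is empty; change undefined")
    return 100.0 * (n_fut - n_ref) / n_ref


def centre_of_gravity(layer: Layer, weighted: bool = False) -> tuple[float, float]:
    """Centroid of the range in map units.

    Unweighted (default): mean cell-centre coordinate over 1-cells of a
    binary map.  Weighted: suitability-weighted mean over all valid cells
    with positive value.
    """
    xs, ys = layer.spec.centre_coords()
    if weighted:
        w = np.where(layer.mask, np.clip(layer.values, 0, None), 0.0)
    else:
        w = _check_binary(layer).astype(float)
    total = w.sum()
    if total == 0:
        raise EmptyRangeError("no positive cells; centre of gravity undefined")
    return float((xs * w).sum() / total), float((ys * w).sum() / total)


def cog_shift(a: tuple[float, float], b: tuple[float, float]) -> tuple[float, float]:
    """Shift from a to b: (Euclidean distance, bearing clockwise from North)."""
    dx, dy = b[0] - a[0], b[1] - a[1]
    if not all(map(math.isfinite, (*a, *b))):
        raise ValueError("coordinates must be finite")
    dist = math.hypot(dx, dy)
    bearing = math.degrees(math.atan2(dx, dy)) % 360.0
    return dist, bearing


def schoener_d(sa: Layer, sb: Layer) -> OverlapResult:
    """Schoener's D between two suitability surfaces.

    Both surfaces are normalized to sum 1 over their shared valid cells and
    D = 1 - 0.5 * sum |p_i - q_i|.  Works for continuous suitabilities
    (default use) or binary maps treated as uniform masses.
    """
    if not sa.spec.aligned(sb.spec):
        raise AlignmentError("schoener_d requires aligned layers")
    shared = sa.mask & sb.mask
    a = np.clip(sa.values[shared], 0, None)
    b = np.clip(sb.values[shared], 0, None)
    if a.sum() <= 0 or b.sum() <= 0:
        raise EmptyRangeError("a surface has zero total over shared valid cells")
    p = a / a.sum()
    q = b / b.sum()
    if not np.minimum(p, q).any():  # disjoint supports: exactly zero overlap
        d = 0.0
    else:
        d = min(1.0, max(0.0, 1.0 - 0.5 * float(np.abs(p - q).sum())))
    return OverlapResult(schoener_d=d, p=p, q=q)
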