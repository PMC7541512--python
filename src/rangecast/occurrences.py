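"""Occurrence cleaning and per-species calibration areas.

Presence-only records (citizen-science style) arrive with null coordinates,
exact duplicates, and many records per raster cell.  Cleaning drops the
unusable ones, thins to one record per cell, and reports counts per drop
reason.  The calibration area restricts model fitting and background
sampling to an altitude band: lowland specialists are calibrated below
1000 m, the more tolerant species below 1500 m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridSpec, Layer

#: default altitude cutoffs (map units of the elevation layer) per niche role
DEFAULT_ELEVATION_CUTOFF = {"specialist": 1000.0, "generalist": 1500.0}


class NoUsableRecordsError(ValueError):
    """Cleaning removed every record."""


class EmptyCalibrationAreaError(ValueError):
    """The altitude mask excludes every cell."""


@dataclass
class OccurrenceSet:
    """Cleaned presence (or pseudo-absence) points on the analysis grid.

    ``records`` holds ``(id, x, y, is_presence)`` tuples with finite
    coordinates inside the grid extent.
    """

    species: str
    records: list[tuple[int, float, float, bool]]
    spec: GridSpec

    def __len__(self) -> int:
        return len(self.records)

    @property
    def xy(self) -> np.ndarray:
        return np.array([(x, y) for _, x, y, _ in self.records], dtype=float).reshape(
            -1, 2
        )

    def cells(self) -> list[tuple[int, int]]:
        return [self.spec.cell_of(x, y) for _, x, y, _ in self.records]

    def cell_set(self) -> set[tuple[int, int]]:
        return set(self.cells())

    def presence_mask_layer(self) -> Layer:
        """Binary layer with 1 in every occupied cell."""
        vals = np.zeros(self.spec.shape)
        for r, c in self.cells():
            vals[r, c] = 1.0
        return Layer(self.spec, f"presence_{self.species}", vals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records, columns=["id", "x", "y", "is_presence"]
        ).assign(species=self.species)


@dataclass
class CleaningReport:
    """Counts of records dropped per reason during cleaning."""

    n_input: int = 0
    null_coordinate: int = 0
    duplicate_coordinate: int = 0
    out_of_extent: int = 0
    same_cell_thinned: int = 0
    n_kept: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass
class CalibrationArea:
    """Binary mask of cells usable for fitting and background sampling."""

    mask_layer: Layer

    @property
    def mask(self) -> np.ndarray:
        return self.mask_layer.values == 1.0

    @property
    def n_usable(self) -> int:
        return int(self.mask.sum())


def clean_occurrences(
    raw: list[tuple],
    spec: GridSpec,
    species: str = "species",
) -> tuple[OccurrenceSet, CleaningReport]:
    """Clean raw ``(id, x, y)`` records down to one presence per cell.

    Drop order: null/non-finite coordinates, exact duplicate coordinates
    (first occurrence kept), out-of-extent points, then per-cell thinning
    keeping the record with the smallest id (ties broken by input order).
    """
    report = CleaningReport(n_input=len(raw))
    usable: list[tuple[int, float, float]] = []
    seen_xy: set[tuple[float, float]] = set()
    for rec in raw:
        rid, x, y = rec[0], rec[1], rec[2]
        if x is None or y is None or not (math.isfinite(x) and math.isfinite(y)):
            report.null_coordinate += 1
            continue
        if (x, y) in seen_xy:
            report.duplicate_coordinate += 1
            continue
        seen_xy.add((x, y))
        try:
            spec.cell_of(x, y)
        except ValueError:
            report.out_of_extent += 1
            continue
        usable.append((rid, float(x), float(y)))

    best: dict[tuple[int, int], tuple[int, int]] = {}  # cell -> (id, input order)
    for order, (rid, x, y) in enumerate(usable):
        cell = spec.cell_of(x, y)
        if cell not in best or (rid, order) < best[cell]:
            best[cell] = (rid, order)
    keep_keys = set(best.values())
    records = []
    for order, (rid, x, y) in enumerate(usable):
        if (rid, order) in keep_keys:
            records.append((rid, x, y, True))
        else:
            report.same_cell_thinned += 1
    report.n_kept = len(records)
    if not records:
        raise NoUsableRecordsError(f"no usable records for {species!r}")
    return OccurrenceSet(species=species, records=records, spec=spec), report


def clean_occurrences_frame(
    df: pd.DataFrame, spec: GridSpec, species: str | None = None
) -> tuple[OccurrenceSet, CleaningReport]:
    """Frame-based wrapper: expects columns id, x, y (and optionally species)."""
    if species is None:
        species = str(df["species"].iloc[0]) if "species" in df else "species"
    raw = [
        (int(r.id), None if pd.isna(r.x) else float(r.x), None if pd.isna(r.y) else float(r.y))
        for r in df.itertuples()
    ]
    return clean_occurrences(raw, spec, species=species)


def build_calibration_area(
    elevation: Layer, max_elevation: float
) -> CalibrationArea:
    """Mask of cells strictly below ``max_elevation`` (and valid)."""
    usable = elevation.mask & (elevation.values < max_elevation)
    if not usable.any():
        raise EmptyCalibrationAreaError(
            f"no cells below {max_elevation} map units"
        )
    return CalibrationArea(
        Layer(elevation.spec, "calibration_area", usable.astype(float))
    )
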