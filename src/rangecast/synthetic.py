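"""Synthetic landscapes, future scenarios and virtual species.

Real applications of this pipeline run on downloaded climate and land-use
rasters plus museum/citizen-science occurrence records.  This module
replaces those inputs with fully controlled stand-ins that keep their
statistical structure: spatially autocorrelated climate fields, percent
land-cover layers, an elevation ramp with relief, a binary imperviousness
mask, additive/multiplicative "future" shifts, and presence-only samples
drawn from a known suitability surface — so parameter recovery can be
checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import EnvStack, GridSpec, Layer

#: layers produced by :func:`make_landscape`; percent layers are clipped to
#: [0, 100], imperviousness is binary, elevation nonnegative.
LANDSCAPE_LAYERS = (
    "temperature",
    "max_temperature",
    "diurnal_range",
    "temp_wettest_q",
    "precipitation",
    "forest",
    "wetness",
    "grassland",
    "elevation",
    "imperviousness",
)

PERCENT_LAYERS = ("forest", "wetness", "grassland")

#: climate-only predictor tier vs climate + land-use tier
BIOC_PREDICTORS = (
    "temperature",
    "max_temperature",
    "diurnal_range",
    "temp_wettest_q",
    "precipitation",
)
BLU_PREDICTORS = BIOC_PREDICTORS + PERCENT_LAYERS


@dataclass
class LandscapeConfig:
    """Knobs of the synthetic landscape generator.

    ``ranges`` holds per-layer autocorrelation ranges in cells (default 10);
    ``means``/``sds`` the per-layer location and scale in layer units.
    Defaults emulate a cool, wet boreal region at 1 km cell size.
    """

    spec: GridSpec = field(default_factory=lambda: GridSpec(100, 100, cellsize=1000.0))
    ranges: dict[str, float] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    elevation_relief: float = 800.0
    impervious_fraction: float = 0.05
    seed: int = 0

    #: fallback statistics per layer (mean, sd, range in cells)
    DEFAULTS = {
        "temperature": (8.0, 3.0, 12.0),
        "max_temperature": (20.0, 3.0, 12.0),
        "diurnal_range": (9.0, 1.5, 8.0),
        "temp_wettest_q": (12.0, 2.5, 12.0),
        "precipitation": (700.0, 200.0, 15.0),
        "forest": (45.0, 25.0, 8.0),
        "wetness": (30.0, 20.0, 6.0),
        "grassland": (15.0, 12.0, 8.0),
        "elevation": (400.0, None, 20.0),
    }

    def stat(self, name: str) -> tuple[float, float, float]:
        mean0, sd0, rng0 = self.DEFAULTS[name]
        return (
            self.means.get(name, mean0),
            self.sds.get(name, sd0),
            self.ranges.get(name, rng0),
        )

    def __post_init__(self) -> None:
        if not 0 <= self.impervious_fraction <= 1:
            raise ValueError("impervious_fraction must be in [0, 1]")
        for name, rng in self.ranges.items():
            if rng < 1:
                raise ValueError(f"autocorrelation range for {name!r} must be >= 1 cell")


@dataclass
class VirtualSpecies:
    """A species defined by Gaussian responses to named predictors.

    Each term ``(layer, optimum, breadth, weight)`` contributes
    ``exp(-0.5 ((x - optimum)/breadth)^2) ** weight`` to the product
    suitability, so suitability is 1 exactly where every predictor sits at
    its optimum and decays with niche breadth away from it.
    """

    name: str
    responses: list[tuple[str, float, float, float]]
    prevalence: float = 0.3
    n_samples: int = 200

    def __post_init__(self) -> None:
        if not self.responses:
            raise ValueError("at least one response term required")
        for layer, _opt, breadth, weight in self.responses:
            if breadth <= 0:
                raise ValueError(f"breadth for {layer!r} must be > 0")
            if weight < 0:
                raise ValueError(f"weight for {layer!r} must be >= 0")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")


@dataclass
class ScenarioDelta:
    """Additive/multiplicative layer shifts emulating a future climate period."""

    period: str
    shifts: dict[str, float] = field(default_factory=dict)
    factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.period == "current" and (
            any(v != 0 for v in self.shifts.values())
            or any(v != 1 for v in self.factors.values())
        ):
            raise ValueError("the 'current' period must have zero shift and unit factor")


def gaussian_random_field(spec: GridSpec, range_cells: float, seed: int) -> Layer:
    """Stationary, isotropic Gaussian random field with unit variance.

    White noise is smoothed with a Gaussian kernel of scale
    ``range_cells / 2`` cells (wrap-around boundary, so the field is
    stationary), then standardized to exactly zero mean and unit sample
    variance.  Identical (spec, range, seed) give identical output.
    """
    if range_cells < 1:
        raise ValueError("range_cells must be >= 1")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(spec.shape)
    smooth = ndimage.gaussian_filter(white, sigma=range_cells / 2.0, mode="wrap")
    smooth -= smooth.mean()
    sd = smooth.std()
    if sd > 0:
        smooth /= sd
    return Layer(spec, f"grf_r{range_cells:g}", smooth)


def make_landscape(config: LandscapeConfig) -> EnvStack:
    """Generate the full 10-layer synthetic environment.

    Climate layers are unbounded; forest/wetness/grassland are percent
    covers clipped to [0, 100]; elevation is a nonnegative relief field;
    imperviousness is the binary mask of the configured fraction of cells
    with the *highest* value of an independent autocorrelated field (so
    sealed soil is spatially clumped, as in real built-up areas).
    """
    stack = EnvStack(config.spec)
    for i, name in enumerate(LANDSCAPE_LAYERS[:-1]):
        mean, sd, rng_cells = config.stat(name)
        f = gaussian_random_field(config.spec, rng_cells, config.seed * 1009 + i)
        if name == "elevation":
            relief = config.elevation_relief
            vals = mean + relief * f.values / 2.0
            vals = np.clip(vals, 0.0, None)
        else:
            vals = mean + sd * f.values
            if name in PERCENT_LAYERS:
                vals = np.clip(vals, 0.0, 100.0)
        stack.add(Layer(config.spec, name, vals))
    frac = config.impervious_fraction
    f = gaussian_random_field(
        config.spec, 4.0, config.seed * 1009 + len(LANDSCAPE_LAYERS)
    )
    if frac <= 0:
        imp = np.zeros(config.spec.shape)
    elif frac >= 1:
        imp = np.ones(config.spec.shape)
    else:
        cut = np.quantile(f.values, 1.0 - frac)
        imp = (f.values > cut).astype(float)
    stack.add(Layer(config.spec, "imperviousness", imp))
    return stack


def apply_scenario(stack: EnvStack, delta: ScenarioDelta) -> EnvStack:
    """Project a stack to a future period: value' = value * factor + shift.

    Nodata is preserved; percent layers are re-clipped to [0, 100];
    imperviousness and elevation are left untouched unless explicitly named.
    """
    for name in list(delta.shifts) + list(delta.factors):
        if name not in stack:
            raise KeyError(f"scenario refers to unknown layer {name!r}")
    out = EnvStack(stack.spec)
    for name, layer in stack.layers.items():
        factor = delta.factors.get(name, 1.0)
        shift = delta.shifts.get(name, 0.0)
        vals = layer.values.copy()
        m = layer.mask
        vals[m] = vals[m] * factor + shift
        if name in PERCENT_LAYERS:
            vals[m] = np.clip(vals[m], 0.0, 100.0)
        out.add(Layer(stack.spec, name, vals))
    return out


def virtual_suitability(stack: EnvStack, species: VirtualSpecies) -> Layer:
    """The species' true suitability surface in [0, 1] on this landscape."""
    names = [t[0] for t in species.responses]
    for n in names:
        if n not in stack:
            raise KeyError(f"response layer {n!r} not in stack")
    suit = np.ones(stack.spec.shape)
    for layer_name, optimum, breadth, weight in species.responses:
        x = stack[layer_name].values
        term = np.exp(-0.5 * ((x - optimum) / breadth) ** 2) ** weight
        suit = suit * term
    mask = stack.joint_mask(names)
    suit[~mask] = stack.spec.nodata
    return Layer(stack.spec, f"suitability_{species.name}", suit)


def sample_occurrences(
    suitability: Layer, n: int, seed: int, species: str = "virtual"
):
    """Draw ``n`` presence cells without replacement, P(cell) ∝ suitability.

    Points are placed at cell centres.  Raises if fewer than ``n`` cells
    have positive suitability.  Returns an
    :class:`~rangecast.occurrences.OccurrenceSet`.
    """
    from .occurrences import OccurrenceSet

    if n < 1:
        raise ValueError("n must be >= 1")
    mask = suitability.mask
    vals = np.where(mask, suitability.values, 0.0)
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("suitability must lie in [0, 1]")
    flat = vals.ravel()
    positive = np.flatnonzero(flat > 0)
    if positive.size < n:
        raise ValueError(
            f"only {positive.size} cells with positive suitability; need {n}"
        )
    rng = np.random.default_rng(seed)
    p = flat[positive] / flat[positive].sum()
    chosen = rng.choice(positive, size=n, replace=False, p=p)
    spec = suitability.spec
    records = []
    for i, cell in enumerate(np.sort(chosen)):
        r, c = divmod(int(cell), spec.ncols)
        x, y = spec.cell_centre(r, c)
        records.append((i, x, y, True))
    return OccurrenceSet(species=species, records=records, spec=spec)


def default_species() -> tuple[VirtualSpecies, VirtualSpecies]:
    """The two shipped virtual species: a wide-niche generalist and a
    narrow-niche specialist whose suitable set is nested inside the
    generalist's (same optima on the shared predictors, smaller breadths,
    plus an extra forest requirement)."""
    generalist = VirtualSpecies(
        name="generalist",
        responses=[
            ("temperature", 9.0, 4.0, 1.0),
            ("wetness", 40.0, 35.0, 1.0),
        ],
    )
    specialist = VirtualSpecies(
        name="specialist",
        responses=[
            ("temperature", 9.0, 2.0, 1.0),
            ("wetness", 40.0, 18.0, 1.0),
            ("forest", 55.0, 30.0, 1.0),
        ],
    )
    return generalist, specialist
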