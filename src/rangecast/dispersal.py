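"""Dispersal-constrained range forecasting: a stochastic cellular automaton.

Suitable habitat is only reachable if propagules can get there.  The
automaton runs annual steps over a timeline of binary suitability maps
(current and future periods).  Each step, every *mature* occupied cell
(age >= maturity delay; newly colonized populations need two years by
default before producing propagules) seeds two dispersal modes:

* short-distance (rappelling): each empty suitable cell within kernel
  range is colonized with probability ``kernel[d]``, where ``d`` is the
  Chebyshev distance to the nearest mature source — one Bernoulli draw per
  target cell per step;
* long-distance (ballooning): each mature source triggers, with a small
  per-step probability, a single jump of uniform random direction and
  distance; the landing cell is colonized iff suitable, empty and not a
  settlement barrier (jumps pass over barriers but cannot settle on them).

Impervious (sealed-soil) cells are settlement barriers for both modes;
cells outside connectivity corridors can additionally be flagged as
barriers to short-distance dispersal only.  When the suitability map of a
new period is swapped in, occupied cells that turned unsuitable are
decolonized.  The whole simulation is replicated (default 30 times) and
cell-wise colonization frequencies are averaged across replicates; cells
occupied in at least a threshold fraction of replicates (default 0.5)
constitute the *reachable* range.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import Layer

logger = logging.getLogger(__name__)

#: stand-in aerial-dispersal decline with distance (probability at 1..5 km);
#: the species-specific kernels weight these by the rappelling proportion
DEFAULT_BASE_DISTANCES_KM = (1.0, 2.0, 3.0, 4.0, 5.0)
DEFAULT_BASE_PROBS = (0.5, 0.3875, 0.275, 0.1625, 0.05)

#: observed short-distance (rappelling) proportions per species role
RAPPEL_WEIGHTS = {"generalist": 0.766, "specialist": 0.59}
#: observed long-distance (ballooning) proportions per species role
LDD_PROBABILITIES = {"generalist": 0.14, "specialist": 0.029}


def build_kernel(
    base_distances_km=DEFAULT_BASE_DISTANCES_KM,
    base_probs=DEFAULT_BASE_PROBS,
    rappel_weight: float = 1.0,
    cellsize_km: float = 1.0,
) -> np.ndarray:
    """Colonization probability per cell distance 1..K.

    The literature-style base curve (probability vs km) is linearly
    interpolated at each cell-ring distance and multiplied by the
    proportion of individuals that disperse by rappelling; the kernel is
    truncated at the largest base distance (aerial dispersal beyond ~5 km
    is treated as long-distance dispersal instead).
    """
    base_distances_km = np.asarray(base_distances_km, dtype=float)
    base_probs = np.asarray(base_probs, dtype=float)
    if base_distances_km.size == 0 or base_probs.size == 0:
        raise ValueError("base distance/probability vectors must be non-empty")
    if base_distances_km.size != base_probs.size:
        raise ValueError("base distances and probabilities must have equal length")
    if np.any(np.diff(base_distances_km) <= 0):
        raise ValueError("base distances must be strictly ascending")
    if np.any((base_probs < 0) | (base_probs > 1)) or not 0 <= rappel_weight <= 1:
        raise ValueError("probabilities and rappel_weight must be in [0, 1]")
    if cellsize_km <= 0:
        raise ValueError("cellsize_km must be > 0")
    k_max = int(math.floor(base_distances_km[-1] / cellsize_km))
    if k_max < 1:
        raise ValueError("cell size exceeds the kernel extent; no ring reachable")
    dists = np.arange(1, k_max + 1) * cellsize_km
    return np.interp(dists, base_distances_km, base_probs) * rappel_weight


@dataclass
class DispersalParams:
    """All tunables of one CA run."""

    kernel: np.ndarray = field(
        default_factory=lambda: build_kernel(rappel_weight=RAPPEL_WEIGHTS["generalist"])
    )
    ldd_probability: float = LDD_PROBABILITIES["generalist"]
    ldd_distance: tuple[float, float] = (6.0, 15.0)  # cells
    maturity_age: int = 2
    replicates: int = 30
    steps_per_period: dict[str, int] = field(
        default_factory=lambda: {"current": 0, "2050": 30, "2070": 20}
    )
    reachable_frequency_threshold: float = 0.5
    per_pair_draws: bool = False

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if np.any((self.kernel < 0) | (self.kernel > 1)):
            raise ValueError("kernel entries must be in [0, 1]")
        if not 0 <= self.ldd_probability <= 1:
            raise ValueError("ldd_probability must be in [0, 1]")
        if self.ldd_distance[0] > self.ldd_distance[1]:
            raise ValueError("ldd_distance min must be <= max")
        if self.maturity_age < 0:
            raise ValueError("maturity_age must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 < self.reachable_frequency_threshold <= 1:
            raise ValueError("reachable_frequency_threshold must be in (0, 1]")


@dataclass
class CAResult:
    """Replicate-averaged outcome of one dispersal simulation."""

    colonization_frequency: Layer
    reachable: Layer
    occupied_counts: np.ndarray  # (replicates, total steps + 1)
    params: DispersalParams
    master_seed: int
    period_reachable: dict[str, Layer] = field(default_factory=dict)

    @property
    def reachable_mask(self) -> np.ndarray:
        return self.reachable.values == 1.0


def _binary(layer: Layer) -> np.ndarray:
    return layer.mask & (layer.values == 1.0)


def run_dispersal(
    initial_occupied: Layer,
    suitability_timeline: dict[str, Layer],
    params: DispersalParams,
    settlement_barrier: np.ndarray | None = None,
    sdd_barrier: np.ndarray | None = None,
    master_seed: int = 0,
) -> CAResult:
    """Simulate colonization over the period timeline, replicated.

    ``suitability_timeline`` maps period labels (in chronological order) to
    binary suitability layers; ``params.steps_per_period`` gives the number
    of annual steps run *within* each period (the first period is typically
    0: it only sets the starting suitability).  ``settlement_barrier``
    blocks all settlement; ``sdd_barrier`` blocks short-distance settlement
    only.  Replicate ``r`` uses seed ``master_seed + r``; all random draws
    are full-grid arrays in fixed order, so runs differing only in barriers
    share common random numbers (adding barriers can then never enlarge the
    reachable set when the kernel is non-increasing).
    """
    spec = initial_occupied.spec
    shape = spec.shape
    periods = list(suitability_timeline)
    for label in periods:
        if not suitability_timeline[label].spec.aligned(spec):
            raise ValueError(f"suitability layer {label!r} not aligned to the grid")
        if label not in params.steps_per_period:
            raise ValueError(f"no step count configured for period {label!r}")
    settlement_barrier = (
        np.zeros(shape, bool) if settlement_barrier is None else settlement_barrier.astype(bool)
    )
    sdd_barrier = np.zeros(shape, bool) if sdd_barrier is None else sdd_barrier.astype(bool)

    init = _binary(initial_occupied) & ~settlement_barrier
    first_suit = _binary(suitability_timeline[periods[0]])
    dropped = init & ~first_suit
    if dropped.any():
        logger.warning(
            "%d initial cells are unsuitable at the first period and were dropped",
            int(dropped.sum()),
        )
    init &= first_suit
    kernel = params.kernel
    k_max = len(kernel)
    ldd_min, ldd_max = params.ldd_distance
    total_steps = sum(params.steps_per_period[p] for p in periods)

    freq = np.zeros(shape)
    period_freq = {label: np.zeros(shape) for label in periods}
    counts = np.zeros((params.replicates, total_steps + 1), dtype=int)
    for rep in range(params.replicates):
        rng = np.random.default_rng(master_seed + rep)
        occupied = init.copy()
        age = np.where(occupied, params.maturity_age, 0)
        step_idx = 0
        counts[rep, 0] = occupied.sum()
        for pi, label in enumerate(periods):
            suitable = _binary(suitability_timeline[label])
            if pi > 0:
                # period switch: habitat lost -> decolonized
                occupied &= suitable
            for _ in range(params.steps_per_period[label]):
                mature = occupied & (age >= params.maturity_age)
                # fixed draw order for common random numbers across configs
                u_sdd = rng.random(shape)
                u_event = rng.random(shape)
                u_dir = rng.random(shape)
                u_dist = rng.random(shape)
                new = np.zeros(shape, bool)
                if mature.any():
                    targets = suitable & ~occupied & ~settlement_barrier & ~sdd_barrier
                    if kernel.size and targets.any():
                        if params.per_pair_draws:
                            p_miss = _per_pair_miss(mature, kernel, shape)
                            p_col = 1.0 - p_miss
                        else:
                            dist = ndimage.distance_transform_cdt(
                                ~mature, metric="chessboard"
                            )
                            in_range = (dist >= 1) & (dist <= k_max)
                            p_col = np.zeros(shape)
                            p_col[in_range] = kernel[dist[in_range] - 1]
                        new |= targets & (u_sdd < p_col)
                    if params.ldd_probability > 0:
                        new |= _ldd_colonize(
                            mature & (u_event < params.ldd_probability),
                            u_dir,
                            u_dist,
                            ldd_min,
                            ldd_max,
                            suitable & ~occupied & ~settlement_barrier,
                        )
                occupied |= new
                age[new] = 0
                age[occupied] += 1
                step_idx += 1
                counts[rep, step_idx] = occupied.sum()
            period_freq[label] += occupied
        freq += occupied
    freq /= params.replicates
    valid = suitability_timeline[periods[0]].mask
    freq_vals = np.where(valid, freq, spec.nodata)
    reach_vals = np.where(
        valid, (freq >= params.reachable_frequency_threshold).astype(float), spec.nodata
    )
    period_reachable = {}
    for label in periods:
        pf = period_freq[label] / params.replicates
        period_reachable[label] = Layer(
            spec,
            f"reachable_{label}",
            np.where(
                valid,
                (pf >= params.reachable_frequency_threshold).astype(float),
                spec.nodata,
            ),
        )
    return CAResult(
        colonization_frequency=Layer(spec, "colonization_frequency", freq_vals),
        reachable=Layer(spec, "reachable", reach_vals),
        occupied_counts=counts,
        params=params,
        master_seed=master_seed,
        period_reachable=period_reachable,
    )


def _ldd_colonize(sources, u_dir, u_dist, ldd_min, ldd_max, can_settle):
    """One long-distance jump per triggered source, row-major order."""
    shape = sources.shape
    new = np.zeros(shape, bool)
    for r, c in zip(*np.nonzero(sources)):
        theta = 2.0 * math.pi * u_dir[r, c]
        d = ldd_min + (ldd_max - ldd_min) * u_dist[r, c]
        rr = r + int(round(-d * math.cos(theta)))  # theta=0 points North
        cc = c + int(round(d * math.sin(theta)))
        if 0 <= rr < shape[0] and 0 <= cc < shape[1] and can_settle[rr, cc]:
            new[rr, cc] = True
    return new


def _per_pair_miss(mature, kernel, shape):
    """P(not colonized) per target under one-draw-per-source-target semantics:
    product over sources within range of (1 - kernel[d])."""
    log_miss = np.zeros(shape)
    k_max = len(kernel)
    for r, c in zip(*np.nonzero(mature)):
        r0, r1 = max(0, r - k_max), min(shape[0], r + k_max + 1)
        c0, c1 = max(0, c - k_max), min(shape[1], c + k_max + 1)
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        d = np.maximum(np.abs(rr - r), np.abs(cc - c))
        in_range = (d >= 1) & (d <= k_max)
        p = np.zeros(d.shape)
        p[in_range] = kernel[d[in_range] - 1]
        with np.errstate(divide="ignore"):
            log_miss[r0:r1, c0:c1] += np.where(p < 1, np.log1p(-np.minimum(p, 1 - 1e-15)), -np.inf)
    return np.exp(log_miss)
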