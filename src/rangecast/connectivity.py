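"""Circuit-theory landscape connectivity.

Habitat suitability is turned into a per-cell movement resistance with the
negative-exponential rescaling

    R(h) = 100 - 99 * (1 - exp(-c h)) / (1 - exp(-c)),      c > 0 (default 8)

so perfect habitat (h = 1) has resistance 1 and hostile habitat (h = 0)
resistance 100.  The raster becomes an electrical network: valid cells are
nodes, 4-neighbours are joined by conductance 2 / (R_a + R_b) (two half-cell
resistances in series).  A unit total current is injected, split equally,
across one map edge and extracted at the opposite edge (the wall-to-wall
scheme), and the Kirchhoff system is solved for node voltages; per-node
current intensity is half the sum of absolute incident edge currents.

The South->North and West->East current maps are multiplied into a
consensus map; cells whose consensus exceeds mean + one standard deviation
(over valid, non-electrode cells) are corridors, and everything outside the
corridors feeds the dispersal stage as a barrier to short-distance
dispersal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .grids import Layer


class CircuitError(ValueError):
    """No conducting path between the electrodes."""


_OPPOSITE = {"N": "S", "S": "N", "E": "W", "W": "E"}


@dataclass
class ResistanceMap:
    """Per-cell movement resistance in [1, 100]; nodata = excluded node."""

    resistance: Layer
    c: float = 8.0


def suitability_to_resistance(h: Layer, c: float = 8.0) -> ResistanceMap:
    """Negative-exponential suitability-to-resistance transform."""
    if c <= 0:
        raise ValueError("transform constant c must be > 0")
    vals = h.values
    mask = h.mask
    if np.any((vals[mask] < 0) | (vals[mask] > 1)):
        raise ValueError("suitability must lie in [0, 1]")
    out = np.full(h.spec.shape, h.spec.nodata)
    out[mask] = 100.0 - 99.0 * (1.0 - np.exp(-c * vals[mask])) / (1.0 - np.exp(-c))
    return ResistanceMap(Layer(h.spec, "resistance", out), c=c)


@dataclass
class CircuitSystem:
    """Solved Kirchhoff system for one electrode pair."""

    voltages: Layer
    current: Layer  # per-node current intensity
    source_edge: str
    ground_edge: str
    injected: float
    extracted: float
    node_balance_max: float
    n_components: int
    n_dead_components: int

    def report(self) -> dict:
        return {
            "source_edge": self.source_edge,
            "ground_edge": self.ground_edge,
            "injected": self.injected,
            "extracted": self.extracted,
            "conservation_error": abs(self.injected - self.extracted)
            / max(self.injected, 1e-300),
            "node_balance_max": self.node_balance_max,
            "n_components": self.n_components,
            "n_dead_components": self.n_dead_components,
        }


def _edge_cells(shape, edge: str) -> np.ndarray:
    mask = np.zeros(shape, bool)
    if edge == "N":
        mask[0, :] = True
    elif edge == "S":
        mask[-1, :] = True
    elif edge == "W":
        mask[:, 0] = True
    elif edge == "E":
        mask[:, -1] = True
    else:
        raise ValueError(f"unknown edge {edge!r}")
    return mask


def solve_current(res: ResistanceMap, source_edge: str, ground_edge: str | None = None) -> CircuitSystem:
    """Solve the lattice circuit between two opposite map edges.

    Unit total current is injected in equal per-node shares over the valid
    source-edge cells of components that also touch the ground edge;
    components not touching both electrodes carry zero current and are
    reported.  Ground nodes are clamped to 0 V.
    """
    if ground_edge is None:
        ground_edge = _OPPOSITE[source_edge]
    if _OPPOSITE[source_edge] != ground_edge:
        raise ValueError("source and ground must be opposite edges")
    layer = res.resistance
    spec = layer.spec
    shape = spec.shape
    valid = layer.mask
    n = int(valid.sum())
    if n == 0:
        raise CircuitError("no valid cells")
    index = -np.ones(shape, dtype=int)
    index[valid] = np.arange(n)
    R = layer.values

    rows_i, cols_j, conds = [], [], []
    # horizontal and vertical 4-neighbour links
    for dr, dc in ((0, 1), (1, 0)):
        a = valid[: shape[0] - dr, : shape[1] - dc] & valid[dr:, dc:]
        ra = R[: shape[0] - dr, : shape[1] - dc][a]
        rb = R[dr:, dc:][a]
        ia = index[: shape[0] - dr, : shape[1] - dc][a]
        ib = index[dr:, dc:][a]
        g = 2.0 / (ra + rb)
        rows_i.append(ia)
        cols_j.append(ib)
        conds.append(g)
    if rows_i and sum(len(r) for r in rows_i):
        ii = np.concatenate(rows_i)
        jj = np.concatenate(cols_j)
        gg = np.concatenate(conds)
    else:
        ii = jj = np.array([], dtype=int)
        gg = np.array([])
    W = sparse.coo_matrix(
        (np.concatenate([gg, gg]), (np.concatenate([ii, jj]), np.concatenate([jj, ii]))),
        shape=(n, n),
    ).tocsr()
    lap = sparse.diags(np.asarray(W.sum(axis=1)).ravel()) - W

    src_nodes = index[_edge_cells(shape, source_edge) & valid]
    gnd_nodes = index[_edge_cells(shape, ground_edge) & valid]
    if src_nodes.size == 0 or gnd_nodes.size == 0:
        raise CircuitError("an electrode edge has no valid cell")

    n_comp, comp = connected_components(W, directed=False)
    live = np.zeros(n_comp, bool)
    src_comp = set(comp[src_nodes])
    gnd_comp = set(comp[gnd_nodes])
    for c_id in src_comp & gnd_comp:
        live[c_id] = True
    if not live.any():
        raise CircuitError("no valid path between the electrode edges")
    n_dead = int(n_comp - live.sum())

    inject_nodes = src_nodes[live[comp[src_nodes]]]
    I = np.zeros(n)
    I[inject_nodes] = 1.0 / inject_nodes.size

    is_ground = np.zeros(n, bool)
    is_ground[gnd_nodes] = True
    solve_mask = live[comp] & ~is_ground
    free = np.flatnonzero(solve_mask)
    V = np.zeros(n)
    if free.size:
        A = lap[free][:, free].tocsc()
        V[free] = spsolve(A, I[free])

    # edge currents and per-node intensity
    intensity = np.zeros(n)
    dV = V[ii] - V[jj]
    edge_cur = gg * dV
    np.add.at(intensity, ii, np.abs(edge_cur))
    np.add.at(intensity, jj, np.abs(edge_cur))
    intensity *= 0.5

    # conservation: net current at each node should equal injection/extraction
    net = lap @ V
    extracted = float(-net[is_ground].sum() + I[is_ground].sum())
    interior = solve_mask & (I == 0)
    balance_max = float(np.abs(net[interior]).max()) if interior.any() else 0.0

    v_map = np.full(shape, spec.nodata)
    v_map[valid] = V
    i_map = np.full(shape, spec.nodata)
    i_map[valid] = intensity
    return CircuitSystem(
        voltages=Layer(spec, f"voltage_{source_edge}{ground_edge}", v_map),
        current=Layer(spec, f"current_{source_edge}{ground_edge}", i_map),
        source_edge=source_edge,
        ground_edge=ground_edge,
        injected=1.0,
        extracted=extracted,
        node_balance_max=balance_max,
        n_components=n_comp,
        n_dead_components=n_dead,
    )


@dataclass
class CorridorMask:
    """Consensus current map, corridor raster and the derived SDD barrier."""

    consensus: Layer
    corridors: Layer
    threshold: float
    systems: dict = field(default_factory=dict)

    @property
    def barrier_sdd(self) -> np.ndarray:
        """Valid cells outside corridors: barriers to short-distance dispersal."""
        return self.corridors.mask & (self.corridors.values == 0.0)


def wall_to_wall(res: ResistanceMap) -> CorridorMask:
    """South->North and West->East solves, multiplied into a consensus map.

    Electrode strips (the outer ring) are excluded from the consensus and
    from the mean + SD corridor statistic.  Corridors are cells whose
    consensus strictly exceeds mean + SD (with a tiny relative tolerance so
    a numerically flat field yields no spurious corridors).
    """
    sn = solve_current(res, "S", "N")
    we = solve_current(res, "W", "E")
    spec = res.resistance.spec
    shape = spec.shape
    electrode = (
        _edge_cells(shape, "N")
        | _edge_cells(shape, "S")
        | _edge_cells(shape, "E")
        | _edge_cells(shape, "W")
    )
    valid = res.resistance.mask & ~electrode
    cons = np.full(shape, spec.nodata)
    cons[valid] = sn.current.values[valid] * we.current.values[valid]
    if not valid.any():
        raise CircuitError("grid too small: no non-electrode cells")
    vals = cons[valid]
    thr = float(vals.mean() + vals.std())
    tol = 1e-9 * (abs(vals.mean()) + 1e-300)
    corr = np.full(shape, spec.nodata)
    corr[valid] = (cons[valid] > thr + tol).astype(float)
    return CorridorMask(
        consensus=Layer(spec, "consensus_current", cons),
        corridors=Layer(spec, "corridors", corr),
        threshold=thr,
        systems={"SN": sn.report(), "WE": we.report()},
    )
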