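"""Pseudo-absence generation with environmental profiling.

Presence-background SDMs need absence stand-ins.  Rather than sampling
anywhere, profiling restricts pseudo-absences to cells environmentally
*dissimilar* from the presences: a per-predictor quantile envelope
(default q = 0.025, i.e. the central 95% of presence values) defines the
presence-like region, and background cells are drawn uniformly from the
calibration area OUTSIDE that envelope.  If too few such cells exist the
sampler tops up from inside-envelope cells and logs a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import EnvStack
from .occurrences import CalibrationArea, OccurrenceSet

logger = logging.getLogger(__name__)


class PseudoAbsenceError(ValueError):
    """Not enough eligible cells to draw the requested sample."""


@dataclass
class EnvelopeProfile:
    """Per-predictor (low, high) presence envelope from quantiles q, 1-q."""

    intervals: dict[str, tuple[float, float]]
    q: float

    def inside(self, values: dict[str, np.ndarray]) -> np.ndarray:
        """Vectorized: True where EVERY profiled predictor is inside its
        interval (i.e. the cell is environmentally presence-like)."""
        inside = None
        for name, (low, high) in self.intervals.items():
            v = values[name]
            ok = (v >= low) & (v <= high)
            inside = ok if inside is None else (inside & ok)
        if inside is None:
            raise ValueError("empty profile")
        return inside


def fit_profile(presence_env: pd.DataFrame, q: float = 0.025) -> EnvelopeProfile:
    """Fit the quantile envelope from a presences-by-predictors table.

    Columns that are entirely missing are excluded with a warning; at least
    5 presence rows with valid values are required.
    """
    if not 0 <= q < 0.5:
        raise ValueError("q must be in [0, 0.5)")
    if len(presence_env) < 5:
        raise ValueError("need at least 5 presence records to fit a profile")
    intervals: dict[str, tuple[float, float]] = {}
    for col in presence_env.columns:
        vals = presence_env[col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(f"predictor {col!r} has no valid presence values; excluded")
            continue
        low = float(np.quantile(vals, q))
        high = float(np.quantile(vals, 1.0 - q))
        intervals[col] = (low, high)
    if not intervals:
        raise ValueError("no predictor with valid presence values")
    return EnvelopeProfile(intervals=intervals, q=q)


def sample_pseudo_absences(
    stack: EnvStack,
    area: CalibrationArea,
    profile: EnvelopeProfile,
    n: int,
    exclude_cells: set[tuple[int, int]],
    seed: int,
    species: str = "species",
) -> tuple[OccurrenceSet, dict]:
    """Draw ``n`` pseudo-absence cells uniformly without replacement.

    Eligible cells are inside the calibration area, valid in every profiled
    predictor, not presence cells, and outside the envelope.  A shortfall is
    made up from inside-envelope non-presence cells (warning logged); if
    even that cannot reach ``n``, a :class:`PseudoAbsenceError` is raised.

    Returns the sampled set and a manifest dict with eligibility counts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = stack.spec
    names = list(profile.intervals)
    valid = stack.joint_mask(names) & area.mask
    presence = np.zeros(spec.shape, dtype=bool)
    for r, c in exclude_cells:
        presence[r, c] = True
    candidate = valid & ~presence
    values = {nme: stack[nme].values for nme in names}
    inside = profile.inside(values)
    eligible = candidate & ~inside
    fallback = candidate & inside

    rng = np.random.default_rng(seed)
    elig_idx = np.flatnonzero(eligible.ravel())
    fall_idx = np.flatnonzero(fallback.ravel())
    manifest = {
        "n_requested": n,
        "n_eligible": int(elig_idx.size),
        "n_fallback_pool": int(fall_idx.size),
        "n_from_fallback": 0,
        "seed": seed,
    }
    if elig_idx.size >= n:
        chosen = rng.choice(elig_idx, size=n, replace=False)
    else:
        shortfall = n - elig_idx.size
        if fall_idx.size < shortfall:
            raise PseudoAbsenceError(
                f"need {n} pseudo-absences but only "
                f"{elig_idx.size} outside-profile + {fall_idx.size} fallback cells"
            )
        logger.warning(
            "only %d outside-profile cells for %d pseudo-absences; "
            "sampling %d from inside the envelope",
            elig_idx.size,
            n,
            shortfall,
        )
        manifest["n_from_fallback"] = shortfall
        extra = rng.choice(fall_idx, size=shortfall, replace=False)
        chosen = np.concatenate([elig_idx, extra])
    records = []
    for i, cell in enumerate(np.sort(chosen)):
        r, c = divmod(int(cell), spec.ncols)
        x, y = spec.cell_centre(r, c)
        records.append((i, x, y, False))
    return OccurrenceSet(species=species, records=records, spec=spec), manifest


def replicate_seeds(master_seed: int, n_replicates: int = 10) -> list[int]:
    """Derive independent per-replicate seeds from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n_replicates)]
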