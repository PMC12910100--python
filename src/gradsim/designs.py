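"""Sampling procedures and location-placement strategies.

A *sampling procedure* splits a total sample budget ``N`` into ``L``
distinct gradient positions times ``r`` replicates per position
(``N = L * r``).  A *sampling strategy* decides where along the driver
gradient those ``L`` positions go:

``systematic``
    equidistant positions;
``log_systematic``
    equidistant in ``log(x)`` (natural for drivers with multiplicative
    scaling such as light or water availability);
``random``
    uniform draws from a dense candidate grid;
``pref_slope`` / ``pref_extreme`` / ``pref_combined``
    preferential draws weighted by *criticality* — the local slope
    ``|f'(x)|``, the extremeness of the response relative to the midpoint
    of its range, or their equal-weight combination.  These emulate a
    researcher who concentrates effort on critical response points, which
    presumes a priori knowledge of the response curve.

The *predictor extremes* scenario controls whether the two gradient
endpoints are always sampled (a gradient-length effect): with extremes
forced, systematic placements include both ends and random/preferential
draws have their most extreme points replaced by the endpoints; without,
systematic placements sit at bin centres and the endpoints are excluded
from the candidate grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .shapes import DEFAULT_GRID_SIZE, ResponseShape

__all__ = [
    "STRATEGY_IDS",
    "PREFERENTIAL_MODES",
    "SamplingProcedure",
    "PlacementResult",
    "enumerate_procedures",
    "criticality_weights",
    "place_locations",
]

STRATEGY_IDS = (
    "systematic",
    "log_systematic",
    "random",
    "pref_slope",
    "pref_extreme",
    "pref_combined",
)

#: criticality mode used by each preferential strategy
PREFERENTIAL_MODES = {
    "pref_slope": "slope",
    "pref_extreme": "extreme",
    "pref_combined": "combined",
}

#: default admissible ranges of the locations-vs-replicates trade-off
MIN_LOCATIONS = 3
MAX_REPLICATES = 32
DEFAULT_TOTALS = (6, 12, 24, 48, 96)

#: weight floor applied after min–max standardization, as a fraction of the
#: maximum (which is 1 after standardization); keeps every candidate
#: reachable, e.g. the apex of a hump under slope-preferential sampling
DEFAULT_WEIGHT_FLOOR = 1e-3


@dataclass(frozen=True, order=True)
class SamplingProcedure:
    """One factorization of the total budget: ``n_total = n_locations * n_replicates``."""

    n_locations: int
    n_replicates: int

    def __post_init__(self) -> None:
        if self.n_locations < 1 or self.n_replicates < 1:
            raise ValueError("n_locations and n_replicates must be positive")

    @property
    def n_total(self) -> int:
        return self.n_locations * self.n_replicates


@dataclass(frozen=True)
class PlacementResult:
    """Sorted, duplicate-free gradient positions chosen for one run."""

    locations: np.ndarray
    strategy_id: str
    extremes_included: bool


def enumerate_procedures(
    totals: Sequence[int] = DEFAULT_TOTALS,
    min_locations: int = MIN_LOCATIONS,
    max_replicates: int = MAX_REPLICATES,
) -> List[SamplingProcedure]:
    """All admissible ``L x r`` factorizations of each budget.

    Returns every ``n_total = L * r`` with ``L >= min_locations`` and
    ``r <= max_replicates``, each exactly once, sorted by
    ``(n_total, n_replicates)``.  A budget with no admissible factorization
    simply contributes nothing.
    """
    procs = []
    for n in dict.fromkeys(int(t) for t in totals):  # dedupe, keep order
        for r in range(1, min(max_replicates, n // max(min_locations, 1)) + 1):
            if n % r == 0:
                loc = n // r
                if loc >= min_locations:
                    procs.append(SamplingProcedure(n_locations=loc, n_replicates=r))
    return sorted(procs, key=lambda p: (p.n_total, p.n_replicates))


def criticality_weights(
    shape: ResponseShape,
    candidate_grid: Optional[np.ndarray] = None,
    mode: str = "slope",
    weight_floor: float = DEFAULT_WEIGHT_FLOOR,
) -> np.ndarray:
    """Sampling probabilities over the candidate grid from local criticality.

    ``slope``: weight ∝ |f'(x)|.  ``extreme``: weight ∝ distance of f(x)
    from the arithmetic mean of the dense-grid min and max of f.
    ``combined``: mean of the two min–max standardized criticalities.
    The result is min–max standardized, floored at ``weight_floor`` of its
    maximum, and normalized to sum to one.  A flat criticality (e.g. the
    slope of a linear shape) yields uniform probabilities.
    """
    if candidate_grid is None:
        candidate_grid, f = shape.dense_values()
    else:
        candidate_grid = np.asarray(candidate_grid, dtype=float)
        f = shape.evaluate(candidate_grid)

    def _standardize(c: np.ndarray) -> Optional[np.ndarray]:
        lo, hi = c.min(), c.max()
        if hi - lo <= 1e-12 * max(abs(hi), 1.0):
            return None  # flat criticality
        return (c - lo) / (hi - lo)

    if mode == "slope":
        std = _standardize(np.abs(shape.derivative(candidate_grid)))
    elif mode == "extreme":
        mid = 0.5 * (shape.f_min + shape.f_max)
        std = _standardize(np.abs(f - mid))
    elif mode == "combined":
        parts = []
        for sub in ("slope", "extreme"):
            if sub == "slope":
                c = np.abs(shape.derivative(candidate_grid))
            else:
                c = np.abs(f - 0.5 * (shape.f_min + shape.f_max))
            s = _standardize(c)
            parts.append(s if s is not None else np.full(candidate_grid.size, 0.5))
        std = _standardize(0.5 * (parts[0] + parts[1]))
    else:
        raise ValueError(f"unknown criticality mode {mode!r}")

    if std is None:
        return np.full(candidate_grid.size, 1.0 / candidate_grid.size)
    w = np.maximum(std, weight_floor)
    return w / w.sum()


def _bin_centers(lo: float, hi: float, n: int) -> np.ndarray:
    edges = np.linspace(lo, hi, n + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def place_locations(
    strategy_id: str,
    procedure: SamplingProcedure,
    shape: Optional[ResponseShape] = None,
    extremes_included: bool = True,
    rng: Optional[np.random.Generator] = None,
    candidate_grid_size: int = DEFAULT_GRID_SIZE,
    weight_floor: float = DEFAULT_WEIGHT_FLOOR,
) -> PlacementResult:
    """Choose ``n_locations`` distinct gradient positions under a strategy.

    Random and preferential strategies draw without replacement from a
    dense equidistant candidate grid (default 1000 points, mirroring the
    evaluation grid) and require a seeded ``rng``; preferential strategies
    additionally require ``shape`` for the criticality weights.  Replication
    is represented downstream — placements never contain duplicates.
    """
    if strategy_id not in STRATEGY_IDS:
        raise ValueError(f"unknown strategy {strategy_id!r}; valid: {STRATEGY_IDS}")
    if shape is None:
        raise ValueError("place_locations requires a shape (for its domain)")
    L = procedure.n_locations
    dom = shape.domain
    min_needed = 2 if extremes_included else 3
    if L < min_needed:
        raise ValueError(f"n_locations={L} too small for placement")

    if strategy_id == "systematic":
        if extremes_included:
            locs = np.linspace(dom.x_min, dom.x_max, L)
        else:
            locs = _bin_centers(dom.x_min, dom.x_max, L)
    elif strategy_id == "log_systematic":
        if extremes_included:
            locs = np.exp(np.linspace(np.log(dom.x_min), np.log(dom.x_max), L))
        else:
            locs = np.exp(_bin_centers(np.log(dom.x_min), np.log(dom.x_max), L))
        locs = np.clip(locs, dom.x_min, dom.x_max)
    else:
        if rng is None:
            raise ValueError(f"strategy {strategy_id!r} requires a seeded rng")
        grid = dom.grid(candidate_grid_size)
        if extremes_included:
            cand, p_cand = grid, None
        else:
            cand, p_cand = grid[1:-1], None
        if strategy_id in PREFERENTIAL_MODES:
            w = criticality_weights(
                shape, grid, mode=PREFERENTIAL_MODES[strategy_id], weight_floor=weight_floor
            )
            if not extremes_included:
                w = w[1:-1]
                w = w / w.sum()
            p_cand = w
        if L > cand.size:
            raise ValueError(f"n_locations={L} exceeds candidate grid size {cand.size}")
        locs = rng.choice(cand, size=L, replace=False, p=p_cand, shuffle=False)
        if extremes_included:
            # force the gradient endpoints in, keeping n_locations constant
            locs = np.sort(locs)
            locs[0] = dom.x_min
            locs[-1] = dom.x_max

    locs = np.sort(np.asarray(locs, dtype=float))
    if np.unique(locs).size != L:
        raise RuntimeError("placement produced duplicate locations")
    return PlacementResult(locations=locs, strategy_id=strategy_id, extremes_included=extremes_included)
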