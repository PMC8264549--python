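"""Colony-level phenotypes: swarm coherence and foraging performance.

Two summary measures characterise a run: the cumulative number of nest ->
food -> nest round trips (foraging performance), and the distance
coefficient, a pairwise-distance swarm-coherence metric.  A per-arm
pheromone-mass decomposition operationalises trail "locking" onto one arm
of the T-maze.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist

from .arena import BASELINE_LEVEL, Arena
from .errors import ConfigurationError


def distance_coefficient(positions: np.ndarray, mode: str = "sum_over_n") -> float:
    """Swarm distance coefficient of ``N`` ant positions.

    DC = (1/N) * sum_i sum_j dis(ant_i, ant_j) over all ordered pairs, with
    ``dis`` the Euclidean distance between cell centres (``mode
    "sum_over_n"``, the default; equal to ``(N - 1)`` times the mean
    pairwise distance).  ``mode "mean_pairwise"`` instead averages over
    unordered pairs.  A tight swarm on one arm gives small values; a colony
    spread over both arms gives large ones.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    n = pos.shape[0]
    if n == 0:
        raise ConfigurationError("distance coefficient undefined for zero ants")
    if n == 1:
        return 0.0
    d = pdist(pos)  # unordered pairs
    if mode == "sum_over_n":
        return float(2.0 * d.sum() / n)
    if mode == "mean_pairwise":
        return float(d.mean())
    raise ConfigurationError(f"unknown distance coefficient mode {mode!r}")


def round_trips_timeseries(result) -> np.ndarray:
    """Cumulative colony round trips at each step of a finished run.

    Sums the per-agent cumulative counts recorded in
    ``result.round_trips`` (shape ``(n_steps, n_ants)``).
    """
    rt = np.asarray(result.round_trips)
    if rt.size == 0:
        return np.zeros(0, dtype=np.int64)
    return rt.sum(axis=1).astype(np.int64)


def arm_pheromone_mass(arena: Arena) -> tuple[int, int]:
    """Deposited pheromone mass on the left and right halves of the maze.

    Sums ``level - 1`` (mass above the no-pheromone baseline) over walkable
    cells strictly left / strictly right of the stem centreline; cells on
    the centreline itself (possible when the stem is an odd number of
    columns wide) count toward neither arm.
    """
    centre = (arena.stem_cols[0] + arena.stem_cols[1]) / 2.0
    cols = np.arange(arena.width)
    excess = np.where(arena.walkable, arena.pheromone - BASELINE_LEVEL, 0)
    left = int(excess[:, cols < centre].sum())
    right = int(excess[:, cols > centre].sum())
    return left, right
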