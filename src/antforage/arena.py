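"""T-maze arena: geometry, pheromone field, food schedule, deposition and decay.

The arena doubles as the generative process of the simulation: every grid cell
emits a pheromone-level outcome (an integer from 1 to 10, where 1 means "no
deposited pheromone"), and the per-cell outcome distributions form the
reallocation matrix from which each forager's local likelihood is re-cut at
every step.  Coordinates are 0-based ``(row, col)`` with row increasing
downward, so the nest sits at the maximal row of the stem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, LogicError

#: Number of discrete pheromone levels an ant can observe.
N_LEVELS = 10

#: Baseline level meaning "no deposited pheromone".
BASELINE_LEVEL = 1

#: Number of one-step relocation policies = cells of the 3x3 neighbourhood.
N_POLICIES = 9

#: Canonical 9-neighbourhood order [stay, N, NE, E, SE, S, SW, W, NW] as
#: (drow, dcol) offsets.  Index i of a local window is the destination of
#: policy i; the same order indexes hidden states and transition matrices.
NEIGHBOR_OFFSETS = np.array(
    [(0, 0), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)],
    dtype=np.int64,
)

#: Default per-cell per-step probability that one pheromone level evaporates.
DEFAULT_P_DECAY = 1e-4


@dataclass
class FoodSchedule:
    """Alternation schedule for the food patch between the two T-maze arms.

    The food sits on ``initial_arm`` for the first ``switch_period`` steps,
    then alternates: the arm at step ``t`` is ``initial_arm`` when
    ``floor(t / switch_period)`` is even, the opposite arm when it is odd.
    """

    switch_period: int = 500
    initial_arm: str = "left"
    horizon: int = 2000

    def __post_init__(self) -> None:
        if self.initial_arm not in ("left", "right"):
            raise ConfigurationError(
                f"initial_arm must be 'left' or 'right', got {self.initial_arm!r}"
            )
        if self.switch_period <= 0:
            raise ConfigurationError("switch_period must be positive")

    def arm_at(self, t: int) -> str:
        """Arm ('left' or 'right') holding food at step ``t``."""
        if t < 0:
            raise ConfigurationError("step index must be non-negative")
        even = (t // self.switch_period) % 2 == 0
        if even:
            return self.initial_arm
        return "right" if self.initial_arm == "left" else "left"


@dataclass
class Arena:
    """T-maze grid world with an integer pheromone field.

    Attributes
    ----------
    walkable
        Boolean mask of corridor cells (the gray foraging area).
    pheromone
        Integer level per cell in ``[1, 10]``; non-walkable cells stay at 1.
    nest, food_left, food_right
        ``(row, col)`` coordinates, all on walkable cells.
    stem_cols
        ``(first, last)`` columns of the vertical stem; the arm centreline
        used by the per-arm pheromone-mass metric is their midpoint.
    """

    height: int
    width: int
    walkable: np.ndarray
    pheromone: np.ndarray
    nest: tuple[int, int]
    food_left: tuple[int, int]
    food_right: tuple[int, int]
    food_schedule: FoodSchedule = field(default_factory=FoodSchedule)
    stem_cols: tuple[int, int] = (0, 0)
    time: int = 0

    # Cached neighbourhood tables, built lazily (see _neighbor_tables).
    _nbr_flat: np.ndarray | None = field(default=None, repr=False, compare=False)
    _feasible: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.walkable = np.asarray(self.walkable, dtype=bool)
        self.pheromone = np.asarray(self.pheromone, dtype=np.int64)
        if self.walkable.shape != (self.height, self.width):
            raise ConfigurationError("walkable mask shape does not match grid size")
        if self.pheromone.shape != (self.height, self.width):
            raise ConfigurationError("pheromone field shape does not match grid size")
        for name, pos in (("nest", self.nest), ("food_left", self.food_left),
                          ("food_right", self.food_right)):
            if not self.walkable[pos]:
                raise ConfigurationError(f"{name} position {pos} is not walkable")

    # -- neighbourhood tables -------------------------------------------------

    def _neighbor_tables(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat destination index and feasibility per (cell, policy).

        Returns ``(nbr_flat, feasible)`` of shape ``(height*width, 9)``.
        ``nbr_flat[c, i]`` is the flat index of the destination of policy i
        from cell c (the cell itself when the move leaves the grid);
        ``feasible[c, i]`` is True iff that destination is on-grid and
        walkable.  Built once and cached: the mask never changes.
        """
        if self._nbr_flat is None:
            rows, cols = np.indices((self.height, self.width))
            r = rows.ravel()[:, None] + NEIGHBOR_OFFSETS[:, 0][None, :]
            c = cols.ravel()[:, None] + NEIGHBOR_OFFSETS[:, 1][None, :]
            on_grid = (r >= 0) & (r < self.height) & (c >= 0) & (c < self.width)
            rc = np.where(on_grid, r, rows.ravel()[:, None])
            cc = np.where(on_grid, c, cols.ravel()[:, None])
            flat = rc * self.width + cc
            feas = on_grid & self.walkable.ravel()[flat]
            self._nbr_flat = flat.astype(np.int64)
            self._feasible = feas
        return self._nbr_flat, self._feasible

    def flat_index(self, position: tuple[int, int]) -> int:
        return int(position[0]) * self.width + int(position[1])


def build_tmaze(
    height: int = 40,
    width: int = 40,
    corridor_width: int = 6,
    stem_length: int | None = None,
    food_schedule: FoodSchedule | None = None,
) -> Arena:
    """Construct the T-maze arena on a ``height`` x ``width`` grid.

    The horizontal bar occupies the top ``corridor_width`` rows across the
    full grid width; the vertical stem (also ``corridor_width`` wide,
    centred) runs from the bar down ``stem_length`` rows (default: to the
    bottom row).  The nest is at the bottom-centre of the stem; the two food
    positions are at the distal (outermost-column) ends of the bar, on its
    middle row.  All pheromone levels start at the baseline 1.
    """
    if corridor_width < 1:
        raise ConfigurationError("corridor_width must be at least 1")
    if stem_length is None:
        stem_length = height - corridor_width
    if stem_length < 1:
        raise ConfigurationError("stem_length must be at least 1")
    if corridor_width + stem_length > height:
        raise ConfigurationError(
            f"maze does not fit: corridor_width {corridor_width} + stem_length "
            f"{stem_length} exceeds grid height {height}"
        )
    if corridor_width > width:
        raise ConfigurationError("corridor_width exceeds grid width")

    walkable = np.zeros((height, width), dtype=bool)
    walkable[:corridor_width, :] = True  # the bar
    stem_first = (width - corridor_width) // 2
    stem_last = stem_first + corridor_width - 1
    stem_bottom = corridor_width + stem_length - 1
    walkable[corridor_width : stem_bottom + 1, stem_first : stem_last + 1] = True

    nest = (stem_bottom, (stem_first + stem_last) // 2)
    bar_mid = corridor_width // 2
    food_left = (bar_mid, 0)
    food_right = (bar_mid, width - 1)

    return Arena(
        height=height,
        width=width,
        walkable=walkable,
        pheromone=np.full((height, width), BASELINE_LEVEL, dtype=np.int64),
        nest=nest,
        food_left=food_left,
        food_right=food_right,
        food_schedule=food_schedule or FoodSchedule(),
        stem_cols=(stem_first, stem_last),
    )


def make_reallocation_matrix(arena: Arena) -> np.ndarray:
    """Per-cell outcome distribution over the 10 pheromone levels.

    With unbiased sensing each location's distribution is one-hot at the
    cell's current pheromone level, so the matrix (shape
    ``(height*width, 10)``) is the environment-side likelihood
    P(pheromone | location) from which agent likelihoods are re-cut.
    Non-walkable cells map to the baseline level 1.
    """
    levels = np.where(arena.walkable, arena.pheromone, BASELINE_LEVEL).ravel()
    out = np.zeros((arena.height * arena.width, N_LEVELS))
    out[np.arange(out.shape[0]), levels - 1] = 1.0
    return out


def local_window(
    arena: Arena, position: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Pheromone levels and feasibility of the 9-cell neighbourhood.

    Returns ``(levels, feasible)``, both length 9 in the canonical order
    [stay, N, NE, E, SE, S, SW, W, NW]; index i is the destination of policy
    i.  Off-grid or wall destinations are infeasible and report the baseline
    level 1.
    """
    if not arena.walkable[position]:
        raise LogicError(f"query position {position} is not walkable")
    nbr, feas = arena._neighbor_tables()
    c = arena.flat_index(position)
    levels = arena.pheromone.ravel()[nbr[c]]
    feasible = feas[c]
    levels = np.where(feasible, levels, BASELINE_LEVEL)
    return levels, feasible


def deposit_pheromone(arena: Arena, position: tuple[int, int]) -> Arena:
    """Raise the pheromone level at ``position`` by one, saturating at 10."""
    if not arena.walkable[position]:
        raise LogicError(f"cannot deposit on non-walkable cell {position}")
    level = arena.pheromone[position]
    if level < N_LEVELS:
        arena.pheromone[position] = level + 1
    return arena


def decay_step(
    arena: Arena,
    rng: np.random.Generator,
    p_decay: float = DEFAULT_P_DECAY,
    mode: str = "decrement",
) -> Arena:
    """Stochastic pheromone evaporation, applied once per simulation step.

    Independently for each cell above baseline, with probability ``p_decay``
    the level drops by one (``mode='decrement'``, gradual evaporation) or is
    reset to baseline (``mode='reset'``).
    """
    if not 0.0 <= p_decay <= 1.0:
        raise ConfigurationError(f"p_decay must be in [0, 1], got {p_decay}")
    if mode not in ("decrement", "reset"):
        raise ConfigurationError(f"unknown decay mode {mode!r}")
    above = arena.pheromone > BASELINE_LEVEL
    if not above.any():
        if p_decay > 0.0:
            # Keep the stream advancing identically whether or not any cell
            # currently holds pheromone, so trajectories do not depend on
            # whether decay draws were skipped early on.
            rng.random(arena.pheromone.size)
        return arena
    draws = rng.random(arena.pheromone.shape)
    hit = above & (draws < p_decay)
    if mode == "decrement":
        arena.pheromone[hit] -= 1
    else:
        arena.pheromone[hit] = BASELINE_LEVEL
    return arena


def current_food_position(arena: Arena, t: int) -> tuple[int, int]:
    """Food cell at step ``t`` according to the alternation schedule."""
    arm = arena.food_schedule.arm_at(t)
    return arena.food_left if arm == "left" else arena.food_right


def sense_triggers(
    arena: Arena,
    position: tuple[int, int],
    t: int,
    scent_radius: int = 0,
) -> tuple[bool, bool]:
    """Whether a forager at ``position`` smells food and/or home at step ``t``.

    Both scents use Chebyshev distance with the same ``scent_radius``
    (default 0: detection requires standing on the cell).
    """
    if not arena.walkable[position]:
        raise LogicError(f"query position {position} is not walkable")
    food = current_food_position(arena, t)
    food_scent = _chebyshev(position, food) <= scent_radius
    home_scent = _chebyshev(position, arena.nest) <= scent_radius
    return food_scent, home_scent


def _chebyshev(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))
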