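"""Behavioural controller for a single forager.

Ties the inference core to the foraging ecology: the outbound/inbound state
machine (unladen ants search, laden ants home and deposit pheromone), the
nest-ward homing bias, and round-trip accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import agent as _agent
from .arena import (
    NEIGHBOR_OFFSETS,
    Arena,
    deposit_pheromone,
    local_window,
    sense_triggers,
)
from .agent import BeliefState, GenerativeModel


@dataclass
class Forager:
    """One ant's mutable state.

    ``laden`` flips to True on contact with the food scent and back to False
    (incrementing ``round_trips``) on contact with the home scent.  Each
    forager owns an independent random stream so that colonies of any size
    are reproducible agent-by-agent.
    """

    id: int
    position: tuple[int, int]
    laden: bool = False
    round_trips: int = 0
    rng: np.random.Generator | None = None


def homing_bonus(
    position: tuple[int, int],
    nest: tuple[int, int],
    feasible: np.ndarray,
    kappa: float = 2.0,
) -> np.ndarray:
    """Additive log-space bonus steering laden foragers toward the nest.

    Policy pi earns ``kappa`` iff its destination strictly decreases the
    Euclidean distance to the nest (and is feasible); all other policies get
    0.  Composes additively with the pheromone-driven expected-free-energy
    score inside the policy softmax.  Unladen (outbound) foragers receive no
    bonus: outbound movement is a pheromone-biased random walk only.
    """
    r, c = position
    dests = np.array([r, c]) + NEIGHBOR_OFFSETS
    d_now = float(np.hypot(r - nest[0], c - nest[1]))
    d_dest = np.hypot(dests[:, 0] - nest[0], dests[:, 1] - nest[1])
    closer = (d_dest < d_now) & np.asarray(feasible, bool)
    return np.where(closer, float(kappa), 0.0)


def step_forager(
    forager: Forager,
    arena: Arena,
    model: GenerativeModel,
    scent_radius: int = 0,
    action_mode: str = "sample",
    deposit_at: str = "destination",
    sense_arena: Arena | None = None,
) -> BeliefState:
    """One full perception-action cycle for ``forager`` at ``arena.time``.

    In order: sense the local window; re-cut the likelihood; infer local
    states from the centre-cell level; score the 9 policies by expected free
    energy; form the policy posterior (with the homing bonus when laden);
    sample an action; move; deposit pheromone if laden; and finally update
    the laden flag and round-trip count from the food/home scent triggers.

    ``sense_arena`` lets the synchronous scheduler present a frozen copy of
    the pheromone field for sensing while deposits land in the live arena.
    The forager is mutated in place; the arena receives at most one deposit.
    """
    sense = sense_arena if sense_arena is not None else arena

    levels, feasible = local_window(sense, forager.position)
    A = _agent.remap_likelihood(levels)
    qs = _agent.infer_states(A, model.D, int(levels[0]))
    G = _agent.expected_free_energy(A, model.B, model.C, qs)
    bonus = (
        homing_bonus(forager.position, arena.nest, feasible, model.kappa)
        if forager.laden
        else None
    )
    qpi = _agent.policy_posterior(G, feasible, model.gamma, bonus)
    action = _agent.select_action(qpi, forager.rng, action_mode)

    origin = forager.position
    dr, dc = NEIGHBOR_OFFSETS[action]
    forager.position = (origin[0] + int(dr), origin[1] + int(dc))

    if forager.laden:
        deposit_pheromone(
            arena, forager.position if deposit_at == "destination" else origin
        )

    food_scent, home_scent = sense_triggers(
        arena, forager.position, arena.time, scent_radius
    )
    if not forager.laden and food_scent:
        forager.laden = True
    elif forager.laden and home_scent:
        forager.laden = False
        forager.round_trips += 1

    return BeliefState(qs=qs, G=G, qpi=qpi)
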