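"""Run orchestration: scheduling, seeding, food switching, decay, recording.

A run is fully specified by a :class:`SimulationConfig`; identical configs
(including the master seed) give bit-identical results.  Each step: the food
position is updated from the alternation schedule, every forager performs
one perception-action cycle (sequentially in id order by default, so that a
deposit is visible to later-indexed nestmates within the same step), the
pheromone field decays stochastically, and the colony metrics are recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .arena import Arena, FoodSchedule, build_tmaze, current_food_position, decay_step
from .agent import GenerativeModel, build_preferences
from .errors import ConfigurationError
from .forager import Forager, step_forager
from .metrics import arm_pheromone_mass, distance_coefficient

logger = logging.getLogger("antforage")

#: Reserved stream id for environment (decay) randomness; agent ids must be
#: smaller than this.
ENV_STREAM_ID = 2**20


@dataclass
class SimulationConfig:
    """Full specification of one simulation run.

    The defaults reproduce the reference setup: a 40x40 T-maze, colony
    sizes drawn from {10, 30, 50, 70}, 2,000 steps with the food arm
    alternating every 500 steps (switches at steps 500, 1,000 and 1,500),
    per-cell decay probability 1e-4 per step, strict (monotone) pheromone
    preferences, and softmax action sampling.
    """

    n_ants: int = 30
    n_steps: int = 2000
    switch_period: int = 500
    initial_arm: str = "left"
    p_decay: float = 1e-4
    decay_mode: str = "decrement"    # or "reset"
    preference: str = "strict"       # or "flat"
    alpha: float = 0.5               # strict-preference slope (per level)
    gamma: float = 1.0               # policy precision
    kappa: float = 2.0               # homing-bias weight for laden foragers
    scent_radius: int = 0            # Chebyshev detection range of both scents
    height: int = 40
    width: int = 40
    corridor_width: int = 6
    stem_length: int | None = None
    master_seed: int = 0
    snapshot_every: int = 50
    action_selection: str = "sample"  # or "argmax"
    update_order: str = "sequential"  # or "synchronous"
    deposit_at: str = "destination"   # or "origin"

    def validate(self) -> "SimulationConfig":
        if self.n_ants <= 0:
            raise ConfigurationError("n_ants must be positive")
        if self.n_ants >= ENV_STREAM_ID:
            raise ConfigurationError(f"n_ants must be below {ENV_STREAM_ID}")
        if self.n_steps < 0:
            raise ConfigurationError("n_steps must be non-negative")
        if self.switch_period <= 0:
            raise ConfigurationError("switch_period must be positive")
        if not 0.0 <= self.p_decay <= 1.0:
            raise ConfigurationError("p_decay must be in [0, 1]")
        if self.scent_radius < 0:
            raise ConfigurationError("scent_radius must be non-negative")
        if self.snapshot_every <= 0:
            raise ConfigurationError("snapshot_every must be positive")
        if self.gamma <= 0:
            raise ConfigurationError("gamma must be positive")
        if self.kappa < 0:
            raise ConfigurationError("kappa must be non-negative")
        if self.preference not in ("flat", "strict"):
            raise ConfigurationError(f"unknown preference kind {self.preference!r}")
        if self.decay_mode not in ("decrement", "reset"):
            raise ConfigurationError(f"unknown decay_mode {self.decay_mode!r}")
        if self.action_selection not in ("sample", "argmax"):
            raise ConfigurationError(
                f"unknown action_selection {self.action_selection!r}"
            )
        if self.update_order not in ("sequential", "synchronous"):
            raise ConfigurationError(f"unknown update_order {self.update_order!r}")
        if self.deposit_at not in ("destination", "origin"):
            raise ConfigurationError(f"unknown deposit_at {self.deposit_at!r}")
        if self.master_seed < 0:
            raise ConfigurationError("master_seed must be non-negative")
        return self

    def build_arena(self) -> Arena:
        return build_tmaze(
            height=self.height,
            width=self.width,
            corridor_width=self.corridor_width,
            stem_length=self.stem_length,
            food_schedule=FoodSchedule(
                switch_period=self.switch_period,
                initial_arm=self.initial_arm,
                horizon=self.n_steps,
            ),
        )

    def build_model(self) -> GenerativeModel:
        return GenerativeModel(
            C=build_preferences(self.preference, self.alpha),
            gamma=self.gamma,
            kappa=self.kappa,
        )


@dataclass
class SimulationResult:
    """Recorded outcome of one run; fully determined by its config.

    Arrays are indexed by step (axis 0) and agent id (axis 1 where
    applicable).  ``snapshots`` maps step index to a copy of the pheromone
    field taken at the end of that step; the final field is always included.
    """

    config: SimulationConfig
    positions: np.ndarray          # (n_steps, n_ants, 2) int16
    laden: np.ndarray              # (n_steps, n_ants) bool
    round_trips: np.ndarray        # (n_steps, n_ants) cumulative per agent
    distance_coefficients: np.ndarray  # (n_steps,)
    left_arm_mass: np.ndarray      # (n_steps,)
    right_arm_mass: np.ndarray     # (n_steps,)
    food_positions: np.ndarray     # (n_steps, 2)
    snapshots: dict[int, np.ndarray]
    final_arena: Arena

    def metrics_frame(self) -> pd.DataFrame:
        """Tidy per-step metrics table."""
        return pd.DataFrame(
            {
                "step": np.arange(self.config.n_steps, dtype=np.int64),
                "distance_coefficient": self.distance_coefficients,
                "cumulative_round_trips": self.round_trips.sum(axis=1).astype(
                    np.int64
                )
                if self.round_trips.size
                else np.zeros(0, dtype=np.int64),
                "left_arm_mass": self.left_arm_mass.astype(np.int64),
                "right_arm_mass": self.right_arm_mass.astype(np.int64),
            }
        )

    def trajectories_frame(self) -> pd.DataFrame:
        """Tidy per-agent trajectory table (step, id, row, col, laden, round_trips)."""
        n_steps, n_ants = self.laden.shape
        steps = np.repeat(np.arange(n_steps), n_ants)
        ids = np.tile(np.arange(n_ants), n_steps)
        return pd.DataFrame(
            {
                "step": steps,
                "id": ids,
                "row": self.positions[:, :, 0].ravel(),
                "col": self.positions[:, :, 1].ravel(),
                "laden": self.laden.ravel(),
                "round_trips": self.round_trips.ravel(),
            }
        )


def derive_agent_stream(master_seed: int, agent_id: int) -> np.random.Generator:
    """Independent, reproducible random stream for one agent.

    Streams are spawned from ``SeedSequence(master_seed)`` keyed by
    ``agent_id``, so any (seed, id) pair always yields the same stream and
    different ids yield statistically independent ones.  The environment's
    decay stream uses the reserved id ``ENV_STREAM_ID``.
    """
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(agent_id,))
    return np.random.default_rng(ss)


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Execute a full run and record trajectories, metrics and snapshots."""
    config.validate()
    arena = config.build_arena()
    model = config.build_model()

    foragers = [
        Forager(id=i, position=arena.nest, rng=derive_agent_stream(config.master_seed, i))
        for i in range(config.n_ants)
    ]
    env_rng = derive_agent_stream(config.master_seed, ENV_STREAM_ID)

    n, m = config.n_steps, config.n_ants
    positions = np.zeros((n, m, 2), dtype=np.int16)
    laden = np.zeros((n, m), dtype=bool)
    round_trips = np.zeros((n, m), dtype=np.int32)
    dcs = np.zeros(n)
    left_mass = np.zeros(n, dtype=np.int64)
    right_mass = np.zeros(n, dtype=np.int64)
    food_positions = np.zeros((n, 2), dtype=np.int16)
    snapshots: dict[int, np.ndarray] = {}

    for t in range(n):
        arena.time = t
        food = current_food_position(arena, t)

        if config.update_order == "synchronous":
            sense = replace(arena, pheromone=arena.pheromone.copy())
        else:
            sense = None
        for f in foragers:
            step_forager(
                f,
                arena,
                model,
                scent_radius=config.scent_radius,
                action_mode=config.action_selection,
                deposit_at=config.deposit_at,
                sense_arena=sense,
            )

        decay_step(arena, env_rng, config.p_decay, config.decay_mode)

        pos = np.array([f.position for f in foragers], dtype=np.int16)
        positions[t] = pos
        laden[t] = [f.laden for f in foragers]
        round_trips[t] = [f.round_trips for f in foragers]
        dcs[t] = distance_coefficient(pos)
        left_mass[t], right_mass[t] = arm_pheromone_mass(arena)
        food_positions[t] = food

        if (t + 1) % config.snapshot_every == 0 or t == n - 1:
            snapshots[t] = arena.pheromone.copy()
        if (t + 1) % 500 == 0:
            logger.info(
                "step %d/%d: trips=%d DC=%.1f arm mass L=%d R=%d",
                t + 1, n, int(round_trips[t].sum()), dcs[t],
                left_mass[t], right_mass[t],
            )

    return SimulationResult(
        config=config,
        positions=positions,
        laden=laden,
        round_trips=round_trips,
        distance_coefficients=dcs,
        left_arm_mass=left_mass,
        right_arm_mass=right_mass,
        food_positions=food_positions,
        snapshots=snapshots,
        final_arena=arena,
    )


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
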