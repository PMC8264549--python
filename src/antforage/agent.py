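"""Per-step active-inference core of a single forager.

Each forager runs a single-factor, one-step-horizon Markov decision process
over its 3x3 neighbourhood.  The 9 hidden states are the neighbourhood cells
in the canonical order [stay, N, NE, E, SE, S, SW, W, NW]; the 10 outcomes
are pheromone levels; the 9 policies are one-step relocations to each
neighbourhood cell.  Because sensing is unbiased the likelihood ``A`` is
re-cut each step from the environment's reallocation matrix (one-hot
columns at the local pheromone levels), which is what confines the agent's
knowledge to its immediate surroundings.

State inference minimises variational free energy; for this model the
minimiser is the exact categorical posterior, so it is computed in closed
form.  Policies are scored by expected free energy (risk relative to the
pheromone preference distribution ``C`` plus ambiguity of the likelihood)
and an action is sampled from a softmax over the negative scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arena import N_LEVELS, N_POLICIES
from .errors import ConfigurationError, LogicError

#: Probability floor applied before every logarithm.
P_FLOOR = 1e-16


def _log(p: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(p, P_FLOOR))


def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - np.max(x))
    return z / z.sum()


def make_transition_set() -> np.ndarray:
    """The 9 one-step relocation transition matrices, stacked (9, 9, 9).

    ``B[i]`` is deterministic: it maps every current state to state i, i.e.
    row i is all ones.  Each matrix is column-stochastic.
    """
    B = np.zeros((N_POLICIES, N_POLICIES, N_POLICIES))
    B[np.arange(N_POLICIES), np.arange(N_POLICIES), :] = 1.0
    return B


def build_preferences(kind: str = "strict", alpha: float = 0.5) -> np.ndarray:
    """Preference distribution ``C`` over the 10 pheromone levels.

    ``flat``
        Uniform: the forager has no preference among observations, which
        reduces movement to Brownian diffusion on the grid.
    ``strict``
        Monotonically increasing, ``C(o) ∝ exp(alpha * o)``: denser
        pheromone is preferred, which produces trail following.  ``alpha``
        sets the slope (per-level log-odds), default 0.5.
    """
    if kind == "flat":
        return np.full(N_LEVELS, 1.0 / N_LEVELS)
    if kind == "strict":
        if alpha <= 0:
            raise ConfigurationError("alpha must be positive for strict preferences")
        w = np.exp(alpha * np.arange(1, N_LEVELS + 1, dtype=float))
        return w / w.sum()
    raise ConfigurationError(f"unknown preference kind {kind!r}")


@dataclass
class GenerativeModel:
    """A forager's generative model and precision parameters.

    ``A`` (10 outcomes x 9 states) is re-cut from the environment each step
    by :func:`remap_likelihood`; ``B`` (9 policies x 9 x 9) and ``C`` are
    fixed for the whole run; ``D`` is the prior over the 9 local states,
    one-hot at "stay" by default (the ant knows which cell it occupies).
    ``gamma`` is the policy precision of the action softmax and ``kappa``
    the homing-bias weight applied to laden foragers.
    """

    A: np.ndarray = field(
        default_factory=lambda: np.full((N_LEVELS, N_POLICIES), 1.0 / N_LEVELS)
    )
    B: np.ndarray = field(default_factory=make_transition_set)
    C: np.ndarray = field(default_factory=build_preferences)
    D: np.ndarray = field(default_factory=lambda: np.eye(N_POLICIES)[0])
    gamma: float = 1.0
    kappa: float = 2.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ConfigurationError("gamma must be positive")
        if self.kappa < 0:
            raise ConfigurationError("kappa must be non-negative")


@dataclass
class BeliefState:
    """Posterior beliefs produced by one perception-action cycle."""

    qs: np.ndarray
    G: np.ndarray
    qpi: np.ndarray


def remap_likelihood(window_levels: np.ndarray) -> np.ndarray:
    """Re-cut the likelihood ``A`` from the local pheromone levels.

    Column j of the returned (10, 9) matrix is one-hot at
    ``window_levels[j]`` — unbiased sensing of the 3x3 window, i.e. the 9
    rows of the environment's reallocation matrix transposed into columns.
    Valid for the current step only; it must be rebuilt after every move.
    """
    levels = np.asarray(window_levels, dtype=np.int64)
    if levels.shape != (N_POLICIES,):
        raise LogicError(f"expected 9 window levels, got shape {levels.shape}")
    if ((levels < 1) | (levels > N_LEVELS)).any():
        raise LogicError(f"pheromone level out of range 1..{N_LEVELS}: {levels}")
    A = np.zeros((N_LEVELS, N_POLICIES))
    A[levels - 1, np.arange(N_POLICIES)] = 1.0
    return A


def infer_states(A: np.ndarray, D: np.ndarray, observation: int) -> np.ndarray:
    """Exact posterior over the 9 local states given one observation.

    ``qs = softmax(ln D + ln A[observation, :])`` — the minimiser of
    variational free energy for a single-factor, single-timestep model.
    ``observation`` is a pheromone level in 1..10.
    """
    if not 1 <= observation <= N_LEVELS:
        raise LogicError(f"observation {observation} outside 1..{N_LEVELS}")
    return _softmax(_log(np.asarray(D, float)) + _log(A[observation - 1, :]))


def expected_free_energy(
    A: np.ndarray, B: np.ndarray, C: np.ndarray, qs: np.ndarray
) -> np.ndarray:
    """Expected free energy ``G`` of each one-step policy (lower is better).

    For policy pi with predicted states ``qs_pi = B[pi] @ qs`` and predicted
    outcomes ``qo_pi = A @ qs_pi``::

        G(pi) = sum_o qo_pi(o) * (ln qo_pi(o) - ln C(o))   # risk
              + sum_s qs_pi(s) * H[A(:, s)]                # ambiguity

    with ``H`` the Shannon entropy (nats) of a likelihood column.
    """
    qs_pred = B @ qs                       # (9 policies, 9 states)
    qo_pred = qs_pred @ A.T                # (9 policies, 10 outcomes)
    risk = np.sum(qo_pred * (_log(qo_pred) - _log(C)[None, :]), axis=1)
    col_entropy = -np.sum(A * _log(A), axis=0)  # H of each A column
    ambiguity = qs_pred @ col_entropy
    return risk + ambiguity


def policy_posterior(
    G: np.ndarray,
    feasible: np.ndarray,
    gamma: float = 1.0,
    homing_bonus: np.ndarray | None = None,
) -> np.ndarray:
    """Softmax posterior over the 9 policies.

    ``qpi(pi) ∝ exp(-gamma * G(pi) + homing_bonus(pi))`` over feasible
    policies; wall and off-grid moves are masked out before normalisation so
    wall-adjacent agents renormalise over their feasible moves.
    """
    feasible = np.asarray(feasible, dtype=bool)
    if not feasible.any():
        raise LogicError("no feasible policy (disconnected walkable mask?)")
    score = -gamma * np.asarray(G, float)
    if homing_bonus is not None:
        score = score + np.asarray(homing_bonus, float)
    score = np.where(feasible, score, -np.inf)
    z = np.exp(score - score[feasible].max())
    return z / z.sum()


def sample_action(qpi: np.ndarray, rng: np.random.Generator) -> int:
    """Draw a policy index from ``qpi`` using the agent's own stream."""
    u = rng.random()
    return int(np.searchsorted(np.cumsum(qpi), u, side="right").clip(0, len(qpi) - 1))


def select_action(
    qpi: np.ndarray, rng: np.random.Generator, mode: str = "sample"
) -> int:
    """Action selection: stochastic sampling (default) or greedy argmax.

    Sampling is the model's source of behavioural stochasticity; the greedy
    mode makes each agent deterministic given its observations.
    """
    if mode == "sample":
        return sample_action(qpi, rng)
    if mode == "argmax":
        return int(np.argmax(qpi))
    raise ConfigurationError(f"unknown action selection mode {mode!r}")
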