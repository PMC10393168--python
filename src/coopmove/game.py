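"""Public-goods payoffs and exploration-phase fitness.

At every movement step each individual plays an excludable public goods
game — the charitable prisoner's dilemma — with the group at the place it
arrived at.  A cooperator pays a cost ``c`` to contribute ``v``, which is
split equally among the *other* group members (cooperators never benefit
from their own contribution).  Everyone also receives a background reward
of 1.  The per-step reward of an individual in a group of size ``g``
containing ``gc`` cooperators is

    cooperator:  1 - c + (gc - 1) / (g - 1) * v   (1 - c when alone)
    defector:    1 + gc / (g - 1) * v             (1 when alone)

A movement cost ``lam`` is deducted at every step where the individual
changed place, and the fitness of an exploration phase is the sum of the
T per-step contributions (fitness resets to zero at the start of each
phase).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _engine
from .movement import COOPERATE, Trajectory, _types_array

__all__ = ["GameParams", "FitnessRecord", "payoff", "step_contribution",
           "fitness_from_trajectory"]


@dataclass(frozen=True)
class GameParams:
    """Public goods game parameters: reward v, cost c, movement cost lam,
    and the background reward added to every per-step payoff."""

    v: float = 0.4
    c: float = 0.04
    lam: float = 0.0
    background: float = 1.0

    def __post_init__(self) -> None:
        # v = c = 0 (a fully neutral game) is allowed as a degenerate case
        if self.v < 0:
            raise ValueError("reward v must be >= 0")
        if self.c < 0:
            raise ValueError("cost c must be >= 0")
        if self.lam < 0:
            raise ValueError("movement cost lam must be >= 0")


@dataclass(frozen=True)
class FitnessRecord:
    """Per-step rewards and contributions, and phase totals.

    rewards, contributions : (T, N) arrays (row t-1 holds step t).
    total : (N,) array; total[n] = sum_t contributions[t-1, n].
    """

    rewards: np.ndarray
    contributions: np.ndarray
    total: np.ndarray


def payoff(
    group_size: int,
    n_cooperators_in_group: int,
    focal_is_cooperator: bool,
    params: GameParams,
) -> float:
    """Per-step reward of a focal individual in the given group.

    Counts include the focal individual itself.
    """
    g, gc = group_size, n_cooperators_in_group
    if g < 1 or gc < 0 or gc > g:
        raise ValueError(f"inconsistent group counts (size {g}, cooperators {gc})")
    if focal_is_cooperator and gc < 1:
        raise ValueError("focal cooperator not counted among the group's cooperators")
    if not focal_is_cooperator and gc > g - 1:
        raise ValueError("focal defector leaves no room for the cooperator count")
    if focal_is_cooperator:
        if g > 1:
            return params.background - params.c + (gc - 1) / (g - 1) * params.v
        return params.background - params.c
    if g > 1:
        return params.background + gc / (g - 1) * params.v
    return params.background


def step_contribution(R: float, moved: bool, lam: float) -> float:
    """Fitness contribution of one step: the reward minus the movement
    cost if the individual changed place (may be negative)."""
    return R - lam if moved else R


def fitness_from_trajectory(
    traj: Trajectory, types: Sequence[str], params: GameParams
) -> FitnessRecord:
    """Accumulate payoffs and movement costs over an exploration phase.

    Payoffs at step t use the groups at the arrived positions (row t of
    the trajectory); no payoff accrues at t = 0, where every individual is
    alone at home.
    """
    T, N = traj.T, traj.N
    if len(types) != N:
        raise ValueError("one interactive type per individual required")
    is_coop = np.array([t == COOPERATE for t in types])
    rewards = np.empty((T, N))
    for t in range(1, T + 1):
        pos = traj.positions[t]
        size = np.bincount(pos, minlength=N)
        ncoop = np.bincount(pos, weights=is_coop, minlength=N)
        g = size[pos]
        gc = ncoop[pos]
        shared = np.where(g > 1, (gc - is_coop) / np.maximum(g - 1, 1), 0.0)
        rewards[t - 1] = (
            params.background - params.c * is_coop + params.v * shared
        )
    contributions = rewards - params.lam * traj.moved
    return FitnessRecord(rewards, contributions, contributions.sum(axis=0))


def total_fitness(
    traj: Trajectory, types: Sequence[str], params: GameParams
) -> np.ndarray:
    """Phase-total fitness via the compiled kernel (same result as
    ``fitness_from_trajectory(...).total``; used in hot loops)."""
    N = traj.N
    F = np.empty(N)
    gs = np.empty(N, dtype=np.int64)
    gc = np.empty(N, dtype=np.int64)
    _engine.accumulate_fitness(
        traj.positions,
        traj.moved.astype(np.uint8),
        _types_array(types, N),
        params.v,
        params.c,
        params.lam,
        params.background,
        F,
        gs,
        gc,
    )
    return F
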