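"""Markov movement: group-dependent staying probabilities and exploration.

Individuals start each exploration phase at their home place (individual
``n`` homed at place ``n``) and take ``T`` synchronous steps.  At each
step an individual either stays at its current place — with a probability
that depends on its own staying propensity ``alpha`` and on the net
attractiveness of its current group — or moves to a uniformly random
neighbouring place.  The staying probability is

    h = alpha / (alpha + (1 - alpha) * S**beta)

where ``beta`` is the summed attractiveness of the *other* group members
(+1 per cooperator, -1 per defector by default) and ``S`` is the
sensitivity: with small ``S`` (default 0.03) a cooperator-rich group makes
staying almost certain and a defector-rich group makes leaving almost
certain, while ``S = 1`` removes the group dependence entirely.  An
individual alone at a place has ``beta = 0`` and stays with probability
exactly ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _engine
from .networks import PlaceNetwork

__all__ = [
    "MovementParams",
    "PositionState",
    "Trajectory",
    "group_of",
    "group_attractiveness",
    "staying_probability",
    "step_distribution",
    "simulate_exploration",
    "home_state",
]

COOPERATE = "C"
DEFECT = "D"


@dataclass(frozen=True)
class MovementParams:
    """Movement model parameters.

    S : sensitivity (> 0); 0.03 by default.
    beta_C, beta_D : attractiveness of a cooperator / defector (+1 / -1).
    T : exploration time, number of synchronous movement steps (>= 1).
    """

    S: float = 0.03
    beta_C: float = 1.0
    beta_D: float = -1.0
    T: int = 10

    def __post_init__(self) -> None:
        if not self.S > 0:
            raise ValueError("sensitivity S must be > 0")
        if self.T < 1:
            raise ValueError("exploration time T must be >= 1")


@dataclass(frozen=True)
class PositionState:
    """Positions of all individuals at one time step."""

    t: int
    positions: np.ndarray  # (N,) int array, positions[n] = place of individual n

    @property
    def N(self) -> int:
        return len(self.positions)


def home_state(N: int) -> PositionState:
    """The t=0 configuration: individual n at its home place n."""
    return PositionState(0, np.arange(N, dtype=np.int64))


@dataclass(frozen=True)
class Trajectory:
    """Positions over a full exploration phase.

    positions : (T+1, N) int array; row 0 is the home configuration.
    moved : (T, N) bool array; moved[t-1, n] is True iff individual n
        changed place at step t.
    """

    positions: np.ndarray
    moved: np.ndarray

    @property
    def T(self) -> int:
        return self.positions.shape[0] - 1

    @property
    def N(self) -> int:
        return self.positions.shape[1]

    def state(self, t: int) -> PositionState:
        return PositionState(t, self.positions[t])

    def to_csv(self, path: str | Path) -> None:
        """Long-format dump: columns t, individual, place, moved."""
        with open(path, "w") as fh:
            fh.write("t,individual,place,moved\n")
            for t in range(self.T + 1):
                for n in range(self.N):
                    mv = 0 if t == 0 else int(self.moved[t - 1, n])
                    fh.write(f"{t},{n},{self.positions[t, n]},{mv}\n")


def group_of(state: PositionState, n: int) -> np.ndarray:
    """Indices of all individuals co-located with ``n`` (including ``n``)."""
    if not (0 <= n < state.N):
        raise ValueError(f"invalid individual index {n}")
    return np.flatnonzero(state.positions == state.positions[n])


def group_attractiveness(
    members_excluding_self: Iterable[str], params: MovementParams = MovementParams()
) -> float:
    """Summed attractiveness of the given group members (the focal
    individual must already have been excluded by the caller)."""
    total = 0.0
    for t in members_excluding_self:
        if t == COOPERATE:
            total += params.beta_C
        elif t == DEFECT:
            total += params.beta_D
        else:
            raise ValueError(f"unknown interactive type {t!r}")
    return total


def staying_probability(alpha: float, beta_sum: float, S: float) -> float:
    """Probability of staying put given the current group's attractiveness.

    Monotone increasing in ``alpha``; for S < 1 increasing in ``beta_sum``
    (attractive groups retain); alpha = 0 or 1 are absorbing regardless of
    the group.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if not S > 0:
        raise ValueError("S must be > 0")
    return float(_engine.staying_prob(alpha, beta_sum, S))


def _types_array(types: Sequence[str] | Mapping[int, str], N: int) -> np.ndarray:
    out = np.empty(N, dtype=np.int8)
    for n in range(N):
        t = types[n]
        if t == COOPERATE:
            out[n] = 1
        elif t == DEFECT:
            out[n] = 0
        else:
            raise ValueError(f"unknown interactive type {t!r}")
    return out


def step_distribution(
    n: int,
    prev: PositionState,
    types: Sequence[str],
    alphas: Sequence[float],
    net: PlaceNetwork,
    params: MovementParams,
) -> np.ndarray:
    """One-step position distribution of individual ``n`` given the full
    previous configuration.

    Returns a length-M probability vector: mass ``h`` on the current
    place and ``(1-h)/d`` on each neighbour, where ``h`` conditions on the
    group at the previous step excluding ``n`` itself.
    """
    if not (0 <= n < prev.N):
        raise ValueError(f"invalid individual index {n}")
    members = group_of(prev, n)
    beta = group_attractiveness((types[i] for i in members if i != n), params)
    h = staying_probability(float(alphas[n]), beta, params.S)
    m = int(prev.positions[n])
    dist = np.zeros(net.M)
    dist[m] = h
    nbrs = net.neighbors(m)
    dist[nbrs] += (1.0 - h) / len(nbrs)
    return dist


def simulate_exploration(
    types: Sequence[str],
    alphas: Sequence[float],
    net: PlaceNetwork,
    params: MovementParams,
    seed: int,
) -> Trajectory:
    """Simulate a full exploration phase from home; reproducible per seed.

    All individuals update synchronously: every step-t draw conditions on
    the complete step t-1 configuration.
    """
    N = net.M
    if len(alphas) != N or len(types) != N:
        raise ValueError("types and alphas must have one entry per place (M = N)")
    tarr = _types_array(types, N)
    aarr = np.asarray(alphas, dtype=np.float64)
    if np.any((aarr < 0) | (aarr > 1)):
        raise ValueError("staying propensities must lie in [0, 1]")
    positions = np.empty((params.T + 1, N), dtype=np.int64)
    moved = np.empty((params.T, N), dtype=np.uint8)
    _engine.seed_rng(int(seed) & 0xFFFFFFFF)
    _engine.explore(
        tarr,
        aarr,
        net.adj_indptr,
        net.adj_indices,
        net.degrees,
        params.S,
        params.beta_C,
        params.beta_D,
        params.T,
        positions,
        moved,
    )
    return Trajectory(positions, moved.astype(bool))
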