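"""Exact brute-force solutions for tiny systems.

For populations small enough that every joint movement outcome can be
enumerated (N <= 3, T <= 2 on the built-in topologies), the full model —
exploration, payoffs, one-step replacement weights and the update rules —
can be marginalised exactly, and fixation probabilities obtained by
solving the absorbing Markov chain over strategy-label states.  These
solutions are the ground truth the stochastic simulator is validated
against; nothing here is used on realistically sized systems.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dynamics import DEFAULT_FITNESS_FLOOR, replacement_kernel
from .game import GameParams, payoff
from .movement import COOPERATE, DEFECT, MovementParams, staying_probability
from .networks import PlaceNetwork
from .replacement import time_spent
from .evolution import Strategy

__all__ = [
    "SmallSystemSpec",
    "enumerate_one_step_weights",
    "exact_update_distribution",
    "exact_fixation",
]

_MAX_OUTCOMES = 500_000


@dataclass(frozen=True)
class SmallSystemSpec:
    """A fully enumerable system: network, dynamics and parameters."""

    net: PlaceNetwork
    kind: str
    move_params: MovementParams = MovementParams()
    game_params: GameParams = GameParams()
    fitness_floor: float = DEFAULT_FITNESS_FLOOR


def enumerate_one_step_weights(
    alphas: Sequence[float], net: PlaceNetwork
) -> np.ndarray:
    """Replacement weights by exhaustive enumeration of all joint one-step
    outcomes (independent moves from home).  Oracle for
    :func:`coopmove.replacement.weights_exact`."""
    N = net.M
    opts = []
    for n in range(N):
        d = net.degree(n)
        o = [(n, float(alphas[n]))]
        o += [(int(j), (1.0 - float(alphas[n])) / d) for j in net.neighbors(n)]
        opts.append(o)
    if int(np.prod([len(o) for o in opts])) > _MAX_OUTCOMES:
        raise ValueError("one-step outcome space too large to enumerate")
    W = np.zeros((N, N))
    for combo in itertools.product(*opts):
        p = 1.0
        for _, q in combo:
            p *= q
        if p == 0.0:
            continue
        pos = np.array([m for m, _ in combo])
        W += p * time_spent(pos)
    return W


def _step_options(prev: np.ndarray, types, alphas, net, mp):
    """Per-individual (place, prob) options given the previous joint
    configuration, conditioning each h on the previous group."""
    N = len(prev)
    beta = {COOPERATE: mp.beta_C, DEFECT: mp.beta_D}
    place_beta = np.zeros(net.M)
    for n in range(N):
        place_beta[prev[n]] += beta[types[n]]
    opts = []
    for n in range(N):
        m = int(prev[n])
        h = staying_probability(alphas[n], place_beta[m] - beta[types[n]], mp.S)
        o = [(m, h)]
        nbrs = net.neighbors(m)
        o += [(int(j), (1.0 - h) / len(nbrs)) for j in nbrs]
        opts.append(o)
    return opts


def _fitness_of_path(path: list[np.ndarray], types, gp: GameParams) -> np.ndarray:
    N = len(path[0])
    F = np.zeros(N)
    for t in range(1, len(path)):
        pos = path[t]
        for n in range(N):
            members = np.flatnonzero(pos == pos[n])
            gc = sum(1 for i in members if types[i] == COOPERATE)
            R = payoff(len(members), gc, types[n] == COOPERATE, gp)
            if pos[n] != path[t - 1][n]:
                R -= gp.lam
            F[n] += R
    return F


def exact_update_distribution(
    spec: SmallSystemSpec, types: Sequence[str], alphas: Sequence[float]
) -> np.ndarray:
    """Expected replacement kernel E[tau] for one evolutionary update.

    Enumerates every joint exploration trajectory with its exact
    probability, computes fitness for each, and averages the update
    rule's kernel over trajectories (the one-step weights are
    deterministic given the alphas).
    """
    net, mp, gp = spec.net, spec.move_params, spec.game_params
    N = net.M
    W = enumerate_one_step_weights(alphas, net)
    n_outcomes = 1
    for n in range(N):
        n_outcomes *= net.degree(n) + 1
    if n_outcomes**mp.T > _MAX_OUTCOMES:
        raise ValueError("trajectory space too large to enumerate")
    Etau = np.zeros((N, N))
    home = np.arange(N)

    def recurse(path: list[np.ndarray], prob: float, t: int) -> None:
        if prob == 0.0:
            return
        if t == mp.T:
            F = _fitness_of_path(path, types, gp)
            Etau[:, :] += prob * replacement_kernel(
                spec.kind, F, W, spec.fitness_floor
            )
            return
        opts = _step_options(path[-1], types, alphas, net, mp)
        for combo in itertools.product(*opts):
            p = prob
            for _, q in combo:
                p *= q
            recurse(path + [np.array([m for m, _ in combo])], p, t + 1)

    recurse([home], 1.0, 0)
    return Etau


def exact_fixation(
    spec: SmallSystemSpec,
    resident: Strategy,
    mutant: Strategy,
    start_labels: Sequence[int] | None = None,
    n_mutants: int | None = None,
) -> float:
    """Exact mutant fixation probability by absorbing-chain solution.

    The chain's states are the 2^N assignments of resident/mutant labels
    to home slots (tracked per slot, so asymmetric topologies such as the
    star are handled without symmetry assumptions).  Either an explicit
    ``start_labels`` vector or ``n_mutants`` (uniformly placed) selects
    the initial distribution.
    """
    N = spec.net.M
    if N > 16:
        raise ValueError("label state space too large")
    n_states = 2**N
    full = n_states - 1
    # expected kernels per transient state
    trans = {}
    for s in range(1, full):
        labels = [(s >> n) & 1 for n in range(N)]
        types = [mutant.interactive if b else resident.interactive for b in labels]
        alphas = [mutant.alpha if b else resident.alpha for b in labels]
        trans[s] = (labels, exact_update_distribution(spec, types, alphas))
    transient = sorted(trans)
    index = {s: k for k, s in enumerate(transient)}
    nt = len(transient)
    A = np.zeros((nt, nt))
    b = np.zeros(nt)
    for s in transient:
        labels, Etau = trans[s]
        for i in range(N):
            for j in range(N):
                p = Etau[i, j]
                if p == 0.0 or labels[i] == labels[j]:
                    s2 = s
                else:
                    s2 = (s | (1 << j)) if labels[i] else (s & ~(1 << j))
                if s2 == full:
                    b[index[s]] += p
                elif s2 != 0:
                    A[index[s], index[s2]] += p
    x = np.linalg.solve(np.eye(nt) - A, b)
    if start_labels is not None:
        s0 = sum((1 << n) for n, v in enumerate(start_labels) if v)
        if s0 == 0:
            return 0.0
        if s0 == full:
            return 1.0
        return float(x[index[s0]])
    if n_mutants is None:
        raise ValueError("provide start_labels or n_mutants")
    if not 1 <= n_mutants <= N - 1:
        raise ValueError("n_mutants must lie in 1..N-1")
    vals = [
        x[index[sum(1 << n for n in combo)]]
        for combo in itertools.combinations(range(N), n_mutants)
    ]
    return float(np.mean(vals))
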