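"""Emergent evolutionary-graph replacement weights.

Replacement events are weighted by the time individuals spend together
one movement step after leaving home.  For a single position
configuration the time-spent matrix ``u`` gives each individual's unit of
time split equally among the other members of its group (all of it on
itself only when alone).  The replacement weight ``w[i, j]`` is the
expectation of ``u[i, j]`` over the one-step joint position distribution.

Because every individual is alone at home, the first step's moves are
independent: individual ``n`` stays with probability ``alphas[n]`` and
otherwise lands on a uniformly chosen neighbour (the group term of the
staying probability vanishes for singleton groups, so attractiveness and
interactive types play no role here).  This independence makes the
expectation computable exactly; the resulting weight matrix is symmetric
and doubly stochastic for every population and topology, i.e. the
emergent evolutionary graph is isothermal.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import _engine
from .movement import PositionState
from .networks import PlaceNetwork

__all__ = ["time_spent", "one_step_occupancy", "weights_exact", "weights_mc"]


def time_spent(positions: PositionState | np.ndarray) -> np.ndarray:
    """Time-spent matrix u for one position configuration.

    ``u[i, j] = 1/(|G_i| - 1)`` for co-located ``i != j``, ``u[i, i] = 1``
    iff ``i`` is alone; each row sums to 1 and the matrix is symmetric.
    """
    pos = positions.positions if isinstance(positions, PositionState) else positions
    pos = np.asarray(pos)
    N = len(pos)
    same = pos[:, None] == pos[None, :]
    gsize = same.sum(axis=1)
    u = np.zeros((N, N))
    alone = gsize == 1
    u[alone, alone] = 1.0
    grouped = ~alone
    if grouped.any():
        u[np.ix_(grouped, grouped)] = (
            same[np.ix_(grouped, grouped)] / (gsize[grouped] - 1)[:, None]
        )
        u[grouped, grouped] = 0.0
    return u


def one_step_occupancy(alphas: Sequence[float], net: PlaceNetwork) -> np.ndarray:
    """(N, M) matrix of one-step-from-home occupancy probabilities:
    row n has ``alphas[n]`` on the home place n and ``(1-alphas[n])/d(n)``
    on each of its neighbours."""
    N = net.M
    a = np.asarray(alphas, dtype=float)
    if len(a) != N:
        raise ValueError("one alpha per individual (M = N) required")
    P = np.zeros((N, N))
    P[np.arange(N), np.arange(N)] = a
    for n in range(N):
        P[n, net.neighbors(n)] = (1.0 - a[n]) / net.degree(n)
    return P


def weights_exact(alphas: Sequence[float], net: PlaceNetwork) -> np.ndarray:
    """Exact replacement weights one movement step from home.

    Exploits the independence of first-step moves: for each place the
    count of other arrivals is Poisson-binomial, and the expected shared
    time ``E[1/(1+K)]`` is integrated exactly by Gauss-Legendre
    quadrature.  The result is symmetric and doubly stochastic to machine
    precision.
    """
    N = net.M
    a = np.asarray(alphas, dtype=np.float64)
    if len(a) != N:
        raise ValueError("one alpha per individual (M = N) required")
    if np.any((a < 0) | (a > 1)):
        raise ValueError("staying propensities must lie in [0, 1]")
    xq, wq = _engine.legendre_nodes(N)
    W = np.empty((N, N))
    _engine.one_step_weights(
        a, net.adj_indptr, net.adj_indices, net.degrees, xq, wq, W
    )
    return W


def weights_mc(
    alphas: Sequence[float],
    net: PlaceNetwork,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo estimate of the one-step replacement weights.

    Unbiased average of :func:`time_spent` over sampled one-step
    configurations; converges to :func:`weights_exact` as ``n_samples``
    grows.  Retained for validation and for variants whose weights have
    no closed form.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    N = net.M
    a = np.asarray(alphas, dtype=float)
    home = np.arange(N)
    # precompute per-individual neighbour tables
    nbrs = [net.neighbors(n) for n in range(N)]
    degs = net.degrees
    acc = np.zeros((N, N))
    stay = rng.random((n_samples, N)) < a
    pick = rng.integers(0, degs, size=(n_samples, N))
    for s in range(n_samples):
        pos = home.copy()
        for n in range(N):
            if not stay[s, n]:
                pos[n] = nbrs[n][pick[s, n]]
        acc += time_spent(pos)
    return acc / n_samples
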