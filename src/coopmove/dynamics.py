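"""The six stochastic update rules mapping fitness and replacement
weights to a replacement-event distribution.

Each update selects a birth individual ``i`` and a death individual ``j``
(``j``'s slot is overwritten by a copy of ``i``'s full strategy;
``i == j`` is a self-replacement that leaves the population unchanged).
The joint probability ``tau[i, j]`` depends on the rule:

======  ==========================================================
kind    tau[i, j]
======  ==========================================================
BDB     (F_i / sum_n F_n) * (w_ij / sum_n w_in)
DBD     (F_j^-1 / sum_n F_n^-1) * (w_ij / sum_n w_nj)
DBB     (1/N) * w_ij F_i / sum_n w_nj F_n
BDD     (1/N) * w_ij F_j^-1 / sum_n w_in F_n^-1
LB      w_ij F_i / sum_{n,k} w_nk F_n
LD      w_ij F_j^-1 / sum_{n,k} w_nk F_k^-1
======  ==========================================================

The first two letters give the event order (Birth-Death, Death-Birth, or
Link for simultaneous selection of the pair); the final letter names the
event selection acts on.  When the weight matrix is row-stochastic — as
the emergent one-step weights always are — BDB coincides with LB and DBD
with LD, which is why the isothermal replacement structure makes those
pairs of dynamics equivalent.

Fitness is floored at a small positive value before use (and before
inversion), since large movement costs can drive total fitness to zero or
below.
"""

from __future__ import annotations

import numpy as np

from . import _engine

__all__ = ["DYNAMICS_KINDS", "kind_index", "replacement_kernel", "sample_event",
           "DEFAULT_FITNESS_FLOOR"]

DYNAMICS_KINDS = ("bdb", "dbd", "dbb", "bdd", "lb", "ld")
DEFAULT_FITNESS_FLOOR = 1e-6


def kind_index(kind: str) -> int:
    """Integer code of a dynamics kind (case-insensitive name)."""
    try:
        return DYNAMICS_KINDS.index(kind.lower())
    except ValueError:
        raise ValueError(
            f"unknown dynamics kind {kind!r}; expected one of {DYNAMICS_KINDS}"
        ) from None


def replacement_kernel(
    kind: str,
    F: np.ndarray,
    W: np.ndarray,
    fitness_floor: float = DEFAULT_FITNESS_FLOOR,
) -> np.ndarray:
    """N x N replacement-event probabilities tau (sums to 1).

    Reference NumPy implementation of the table above; the compiled
    engine kernel is cross-checked against it in the test suite.
    """
    F = np.asarray(F, dtype=float)
    W = np.asarray(W, dtype=float)
    N = len(F)
    if W.shape != (N, N):
        raise ValueError("W must be N x N with N = len(F)")
    k = kind_index(kind)
    Ff = np.maximum(F, fitness_floor)
    Fi = 1.0 / Ff
    if k == _engine.KIND_BDB:
        b = Ff / Ff.sum()
        d = W / W.sum(axis=1, keepdims=True)
        tau = b[:, None] * d
    elif k == _engine.KIND_DBD:
        d = Fi / Fi.sum()
        b = W / W.sum(axis=0, keepdims=True)
        tau = b * d[None, :]
    elif k == _engine.KIND_DBB:
        tau = (W * Ff[:, None]) / (W * Ff[:, None]).sum(axis=0, keepdims=True) / N
    elif k == _engine.KIND_BDD:
        tau = (W * Fi[None, :]) / (W * Fi[None, :]).sum(axis=1, keepdims=True) / N
    elif k == _engine.KIND_LB:
        num = W * Ff[:, None]
        tau = num / num.sum()
    else:  # ld
        num = W * Fi[None, :]
        tau = num / num.sum()
    return tau


def sample_event(tau: np.ndarray, rng: np.random.Generator) -> tuple[int, int]:
    """Draw a replacement event (birth i, death j) from the kernel."""
    tau = np.asarray(tau, dtype=float)
    N = tau.shape[0]
    flat = tau.ravel()
    idx = rng.choice(flat.size, p=flat / flat.sum())
    return int(idx // N), int(idx % N)
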