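"""Numba-compiled inner loops shared by the simulation modules.

Everything here operates on flat numpy arrays: the place network is passed
in CSR form (``indptr``/``indices``/``degrees``), interactive types as an
int8 array (1 = cooperator, 0 = defector) and staying propensities as a
float64 array.  The public modules (:mod:`coopmove.movement`,
:mod:`coopmove.game`, :mod:`coopmove.replacement`,
:mod:`coopmove.dynamics`, :mod:`coopmove.evolution`) wrap these kernels
with validated, documented interfaces; the kernels themselves are the
single implementation used both for one-off calls and inside fixation
trials.

Randomness uses numba's internal ``np.random`` state, seeded per trial via
:func:`seed_rng`, which makes every trial reproducible from one 32-bit
integer.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Dynamics kinds are encoded as integers in kernel code.
KIND_BDB, KIND_DBD, KIND_DBB, KIND_BDD, KIND_LB, KIND_LD = range(6)


@njit(cache=True)
def seed_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def staying_prob(alpha, beta_sum, S):
    """h = alpha / (alpha + (1-alpha) * S**beta_sum), clamped at the ends."""
    if alpha >= 1.0:
        return 1.0
    if alpha <= 0.0:
        return 0.0
    return alpha / (alpha + (1.0 - alpha) * S**beta_sum)


@njit(cache=True)
def explore(
    types,
    alphas,
    indptr,
    indices,
    degrees,
    S,
    beta_C,
    beta_D,
    T,
    positions,
    moved,
):
    """Simulate one synchronous exploration phase of T steps from home.

    ``positions`` is a preallocated (T+1, N) int64 array (row 0 is set to
    the home bijection, individual n homed at place n); ``moved`` is a
    preallocated (T, N) uint8 array.  All individuals draw their step-t
    position from distributions conditioned on the full step t-1
    configuration.
    """
    N = alphas.shape[0]
    place_beta = np.zeros(N)
    for n in range(N):
        positions[0, n] = n
    for t in range(1, T + 1):
        for m in range(N):
            place_beta[m] = 0.0
        for n in range(N):
            b = beta_C if types[n] == 1 else beta_D
            place_beta[positions[t - 1, n]] += b
        for n in range(N):
            p = positions[t - 1, n]
            b = beta_C if types[n] == 1 else beta_D
            h = staying_prob(alphas[n], place_beta[p] - b, S)
            if np.random.random() < h:
                positions[t, n] = p
                moved[t - 1, n] = 0
            else:
                d = degrees[p]
                k = np.int64(np.random.random() * d)
                if k >= d:
                    k = d - 1
                positions[t, n] = indices[indptr[p] + k]
                moved[t - 1, n] = 1


@njit(cache=True)
def accumulate_fitness(
    positions, moved, types, v, c, lam, background, F, group_size, coop_count
):
    """Total exploration-phase fitness per individual (written into F).

    Payoffs use the groups at the arrived positions of each step t=1..T;
    the movement cost lam is charged at every step where the individual
    changed place.  ``group_size`` and ``coop_count`` are length-N work
    buffers (one slot per place).
    """
    T = moved.shape[0]
    N = types.shape[0]
    for n in range(N):
        F[n] = 0.0
    for t in range(1, T + 1):
        for m in range(N):
            group_size[m] = 0
            coop_count[m] = 0
        for n in range(N):
            m = positions[t, n]
            group_size[m] += 1
            if types[n] == 1:
                coop_count[m] += 1
        for n in range(N):
            m = positions[t, n]
            g = group_size[m]
            gc = coop_count[m]
            if types[n] == 1:
                if g > 1:
                    R = background - c + (gc - 1) / (g - 1) * v
                else:
                    R = background - c
            else:
                if g > 1:
                    R = background + gc / (g - 1) * v
                else:
                    R = background
            if moved[t - 1, n] == 1:
                R -= lam
            F[n] += R


@njit(cache=True)
def one_step_weights(alphas, indptr, indices, degrees, xq, wq, W):
    """Exact replacement weights one movement step from home (into W).

    One step from home every individual is alone, so moves are independent:
    n stays with probability alphas[n], else lands uniformly on a
    neighbour.  For co-located pairs the expected shared-time fraction
    E[1/(1+K)] over the Poisson-binomial count K of other arrivals is
    evaluated through the identity E[1/(1+K)] = int_0^1 prod_k
    (1 - p_k (1-x)) dx, computed exactly by Gauss-Legendre quadrature
    (xq, wq on [0,1]; the integrand is a polynomial of degree < 2*len(xq)).
    """
    N = alphas.shape[0]
    Q = xq.shape[0]
    for i in range(N):
        for j in range(N):
            W[i, j] = 0.0
    ks = np.empty(N, np.int64)
    ps = np.empty(N)
    G = np.empty((N, Q))
    prod = np.empty(Q)
    pref = np.empty(N + 1)
    suf = np.empty(N + 1)
    for m in range(N):
        # individuals that can occupy place m after one step: its home
        # occupant (stays) and the home occupants of neighbouring places
        nk = 0
        ks[nk] = m
        ps[nk] = alphas[m]
        nk += 1
        for e in range(indptr[m], indptr[m + 1]):
            k = indices[e]
            ks[nk] = k
            ps[nk] = (1.0 - alphas[k]) / degrees[k]
            nk += 1
        for a in range(nk):
            p = ps[a]
            for q in range(Q):
                G[a, q] = 1.0 - p * (1.0 - xq[q])
        for q in range(Q):
            pr = 1.0
            for a in range(nk):
                pr *= G[a, q]
            prod[q] = pr
        # leave-one-out products of (1 - p) for the alone-at-m probability
        pref[0] = 1.0
        for a in range(nk):
            pref[a + 1] = pref[a] * (1.0 - ps[a])
        suf[nk] = 1.0
        for a in range(nk - 1, -1, -1):
            suf[a] = suf[a + 1] * (1.0 - ps[a])
        for a in range(nk):
            W[ks[a], ks[a]] += ps[a] * pref[a] * suf[a + 1]
        for a in range(nk):
            pa = ps[a]
            if pa == 0.0:
                continue
            for b in range(a + 1, nk):
                pb = ps[b]
                if pb == 0.0:
                    continue
                acc = 0.0
                for q in range(Q):
                    acc += wq[q] * prod[q] / (G[a, q] * G[b, q])
                val = pa * pb * acc
                W[ks[a], ks[b]] += val
                W[ks[b], ks[a]] += val


@njit(cache=True)
def replacement_kernel(kind, F, W, floor, tau):
    """Replacement-event probabilities tau[i, j] (i gives birth, j dies).

    Fitness is floored at ``floor`` before use (and before inversion in
    the death-selection rules), so the kernel stays defined when movement
    costs push fitness to zero or below.
    """
    N = F.shape[0]
    Ff = np.empty(N)
    Fi = np.empty(N)
    for n in range(N):
        f = F[n]
        if f < floor:
            f = floor
        Ff[n] = f
        Fi[n] = 1.0 / f
    if kind == KIND_BDB:
        sF = 0.0
        for n in range(N):
            sF += Ff[n]
        for i in range(N):
            rw = 0.0
            for j in range(N):
                rw += W[i, j]
            bi = Ff[i] / sF
            for j in range(N):
                tau[i, j] = bi * W[i, j] / rw
    elif kind == KIND_DBD:
        sFi = 0.0
        for n in range(N):
            sFi += Fi[n]
        for j in range(N):
            cw = 0.0
            for n in range(N):
                cw += W[n, j]
            dj = Fi[j] / sFi
            for i in range(N):
                tau[i, j] = dj * W[i, j] / cw
    elif kind == KIND_DBB:
        for j in range(N):
            den = 0.0
            for n in range(N):
                den += W[n, j] * Ff[n]
            for i in range(N):
                tau[i, j] = W[i, j] * Ff[i] / den / N
    elif kind == KIND_BDD:
        for i in range(N):
            den = 0.0
            for n in range(N):
                den += W[i, n] * Fi[n]
            for j in range(N):
                tau[i, j] = W[i, j] * Fi[j] / den / N
    elif kind == KIND_LB:
        den = 0.0
        for n in range(N):
            for k in range(N):
                den += W[n, k] * Ff[n]
        for i in range(N):
            for j in range(N):
                tau[i, j] = W[i, j] * Ff[i] / den
    else:  # KIND_LD
        den = 0.0
        for n in range(N):
            for k in range(N):
                den += W[n, k] * Fi[k]
        for i in range(N):
            for j in range(N):
                tau[i, j] = W[i, j] * Fi[j] / den


@njit(cache=True)
def sample_pair(tau):
    """Draw (i, j) with probability tau[i, j] from the seeded stream."""
    N = tau.shape[0]
    r = np.random.random()
    acc = 0.0
    for i in range(N):
        for j in range(N):
            acc += tau[i, j]
            if r < acc:
                return i, j
    return N - 1, N - 1  # guard against rounding at r ~ 1


@njit(cache=True)
def fixation_trial(
    labels,
    type_res,
    alpha_res,
    type_mut,
    alpha_mut,
    indptr,
    indices,
    degrees,
    S,
    beta_C,
    beta_D,
    T,
    v,
    c,
    lam,
    background,
    kind,
    floor,
    max_updates,
    seed,
    xq,
    wq,
):
    """Run one fixation trial to absorption; returns (label, n_updates).

    ``labels`` (int8, modified in place) marks each home slot as resident
    (0) or mutant (1).  Each update runs a fresh exploration phase,
    recomputes fitness, reuses the cached replacement weights (they change
    only when the strategy composition changes), samples a replacement
    event and copies the birth individual's full strategy onto the death
    slot.  Self-replacements consume an update with no state change.

    Returns label 1 if the mutant strategy fixed, 0 if the resident did,
    -1 if ``max_updates`` was exceeded before absorption.
    """
    seed_rng(seed)
    N = labels.shape[0]
    types = np.empty(N, np.int8)
    alphas = np.empty(N)
    positions = np.empty((T + 1, N), np.int64)
    moved = np.empty((T, N), np.uint8)
    F = np.empty(N)
    gs = np.empty(N, np.int64)
    gc = np.empty(N, np.int64)
    W = np.empty((N, N))
    tau = np.empty((N, N))
    count_mut = 0
    for n in range(N):
        if labels[n] == 1:
            count_mut += 1
    updates = 0
    dirty = True
    while 0 < count_mut < N:
        if updates >= max_updates:
            return -1, updates
        updates += 1
        if dirty:
            for n in range(N):
                if labels[n] == 1:
                    types[n] = type_mut
                    alphas[n] = alpha_mut
                else:
                    types[n] = type_res
                    alphas[n] = alpha_res
            one_step_weights(alphas, indptr, indices, degrees, xq, wq, W)
            dirty = False
        explore(
            types, alphas, indptr, indices, degrees, S, beta_C, beta_D, T,
            positions, moved,
        )
        accumulate_fitness(positions, moved, types, v, c, lam, background, F, gs, gc)
        replacement_kernel(kind, F, W, floor, tau)
        i, j = sample_pair(tau)
        if labels[j] != labels[i]:
            if labels[i] == 1:
                count_mut += 1
            else:
                count_mut -= 1
            labels[j] = labels[i]
            dirty = True
    return (1 if count_mut == N else 0), updates


def legendre_nodes(N: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights on [0, 1], exact for the degree-(N-1)
    polynomials appearing in :func:`one_step_weights`."""
    Q = max(N // 2 + 1, 2)
    x, w = np.polynomial.legendre.leggauss(Q)
    return (x + 1.0) / 2.0, w / 2.0
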