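"""Fixation trials, fixation-probability estimation and the two
mutation-scenario pipelines.

A *complex strategy* couples an interactive type (cooperate/defect) with a
staying propensity ``alpha`` drawn from an 11-value grid, giving 22
strategies in total.  Mutations are assumed rare on the timescale of
replacement, so at most two strategies coexist and the quantity of
interest is the fixation probability ``rho`` of a mutant lineage, judged
against the neutral benchmarks 1/N (single mutant) and 1/2 (half-half
mixed population) with a two-standard-error band.

Two scenarios are supported.  Under *rare interactive mutations* each
interactive type first evolves to its optimal staying propensity
(defectors' optimum is the grid maximum whenever movement is costly);
the fittest mutant of the opposite type then determines the outcome
class.  Under *non-rare interactive mutations* both components mutate on
the same timescale and the relevant state is the half-cooperator,
half-defector population at the mutually-optimal pair of staying
propensities, found by iterated best response on the grid.
"""

from __future__ import annotations


from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _engine
from .dynamics import DEFAULT_FITNESS_FLOOR, kind_index
from .game import GameParams
from .movement import COOPERATE, DEFECT, MovementParams
from .networks import PlaceNetwork

__all__ = [
    "Strategy",
    "Population",
    "FixationEstimate",
    "OutcomeClass",
    "DEFAULT_ALPHA_GRID",
    "strategy_space",
    "fixation_trial",
    "estimate_fixation",
    "optimal_alpha_rare",
    "fittest_mutant_rare",
    "classify_rare",
    "mixed_fixation",
    "mutually_optimal_pair",
    "classify_nonrare",
]

#: Staying-propensity grid: 0.01 and 0.99 stand in for the unreachable
#: endpoints 0 and 1 of the inner 0.1 lattice.
DEFAULT_ALPHA_GRID: tuple[float, ...] = (
    0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.99,
)

DEFAULT_MAX_UPDATES = 1_000_000


@dataclass(frozen=True, order=True)
class Strategy:
    """A complex strategy: interactive type (C/D) plus staying propensity."""

    interactive: str
    alpha: float

    def __post_init__(self) -> None:
        if self.interactive not in (COOPERATE, DEFECT):
            raise ValueError("interactive type must be 'C' or 'D'")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass(frozen=True)
class Population:
    """Strategies assigned to home slots (individual n homed at place n)."""

    strategies: tuple[Strategy, ...]

    @property
    def N(self) -> int:
        return len(self.strategies)


def strategy_space(grid: Sequence[float] = DEFAULT_ALPHA_GRID) -> list[Strategy]:
    """All complex strategies: {C, D} x alpha grid (22 by default)."""
    return [Strategy(t, a) for t in (COOPERATE, DEFECT) for a in grid]


@dataclass(frozen=True)
class FixationEstimate:
    """Binomial estimate of a fixation probability.

    ``n_trials`` counts absorbed trials only; trials that hit the update
    cap are reported in ``n_nonabsorbed`` and excluded from the estimate.
    """

    n_success: int
    n_trials: int
    n_nonabsorbed: int = 0

    @property
    def rho_hat(self) -> float:
        return self.n_success / self.n_trials

    @property
    def sigma(self) -> float:
        p = self.rho_hat
        return float(np.sqrt(p * (1.0 - p) / self.n_trials))

    def above(self, neutral: float, n_sigma: float = 2.0) -> bool:
        return self.rho_hat > neutral + n_sigma * self.sigma

    def below(self, neutral: float, n_sigma: float = 2.0) -> bool:
        return self.rho_hat < neutral - n_sigma * self.sigma

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.rho_hat:.5f} ± {self.sigma:.5f} (n={self.n_trials})"


class OutcomeClass(str, Enum):
    FAVOURS_COOPERATION = "favours_cooperation"
    FAVOURS_DEFECTION = "favours_defection"
    FAVOURS_CHANGE = "favours_change"
    OPPOSES_CHANGE = "opposes_change"
    NEUTRAL = "neutral"


# ---------------------------------------------------------------------------
# trial execution


def _mutant_slots(
    N: int, n_mutants: int, placement: str, rng: np.random.Generator
) -> np.ndarray:
    if not 1 <= n_mutants <= N - 1:
        raise ValueError("n_mutants must lie in 1..N-1")
    if placement == "uniform":
        return rng.choice(N, size=n_mutants, replace=False)
    if placement == "hub":  # star convention: hub is place 0
        rest = rng.choice(N - 1, size=n_mutants - 1, replace=False) + 1
        return np.concatenate(([0], rest))
    if placement == "leaf":
        return rng.choice(N - 1, size=n_mutants, replace=False) + 1
    raise ValueError(f"unknown mutant placement {placement!r}")


def _run_trial(
    labels: np.ndarray,
    resident: Strategy,
    mutant: Strategy,
    kind: str,
    net: PlaceNetwork,
    move_params: MovementParams,
    game_params: GameParams,
    numba_seed: int,
    max_updates: int,
    fitness_floor: float,
) -> tuple[int, int]:
    return _engine.fixation_trial(
        labels,
        np.int8(resident.interactive == COOPERATE),
        resident.alpha,
        np.int8(mutant.interactive == COOPERATE),
        mutant.alpha,
        net.adj_indptr,
        net.adj_indices,
        net.degrees,
        move_params.S,
        move_params.beta_C,
        move_params.beta_D,
        move_params.T,
        game_params.v,
        game_params.c,
        game_params.lam,
        game_params.background,
        kind_index(kind),
        fitness_floor,
        max_updates,
        int(numba_seed) & 0xFFFFFFFF,
        *_engine.legendre_nodes(net.M),
    )


def fixation_trial(
    resident: Strategy,
    mutant: Strategy,
    n_mutants: int,
    kind: str,
    net: PlaceNetwork,
    move_params: MovementParams,
    game_params: GameParams,
    seed: int,
    max_updates: int = DEFAULT_MAX_UPDATES,
    mutant_placement: str = "uniform",
    fitness_floor: float = DEFAULT_FITNESS_FLOOR,
) -> str | None:
    """Run a single trial to absorption.

    Returns ``"mutant"`` or ``"resident"``, or ``None`` if the update cap
    was reached first.  Each update runs a full exploration phase, builds
    the replacement kernel from fitness and the exact one-step weights,
    samples a replacement event, and copies the birth individual's full
    strategy onto the death slot.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    labels = np.zeros(net.M, dtype=np.int8)
    labels[_mutant_slots(net.M, n_mutants, mutant_placement, rng)] = 1
    outcome, _ = _run_trial(
        labels, resident, mutant, kind, net, move_params, game_params,
        ss.generate_state(2)[1], max_updates, fitness_floor,
    )
    return {1: "mutant", 0: "resident", -1: None}[outcome]


def estimate_fixation(
    resident: Strategy,
    mutant: Strategy,
    n_mutants: int,
    n_trials: int,
    kind: str,
    net: PlaceNetwork,
    move_params: MovementParams,
    game_params: GameParams,
    seed: int,
    max_updates: int = DEFAULT_MAX_UPDATES,
    mutant_placement: str = "uniform",
    fitness_floor: float = DEFAULT_FITNESS_FLOOR,
) -> FixationEstimate:
    """Estimate the mutant fixation probability over independent trials.

    Trial seeds are derived from the master ``seed`` via a seed sequence,
    so estimates are reproducible and trials are independent.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_trials)
    n_success = n_absorbed = n_nonabsorbed = 0
    for child in children:
        rng = np.random.default_rng(child)
        labels = np.zeros(net.M, dtype=np.int8)
        labels[_mutant_slots(net.M, n_mutants, mutant_placement, rng)] = 1
        outcome, _ = _run_trial(
            labels, resident, mutant, kind, net, move_params, game_params,
            child.generate_state(2)[1], max_updates, fitness_floor,
        )
        if outcome < 0:
            n_nonabsorbed += 1
        else:
            n_absorbed += 1
            n_success += outcome
    if n_absorbed == 0:
        raise RuntimeError(
            f"no trial absorbed within {max_updates} updates; raise max_updates"
        )
    return FixationEstimate(n_success, n_absorbed, n_nonabsorbed)


# ---------------------------------------------------------------------------
# rare interactive mutations


@dataclass(frozen=True)
class OptimalAlphaResult:
    alpha: float
    non_invadable: bool
    #: (resident_alpha, mutant_alpha) -> FixationEstimate for every pair probed
    estimates: Mapping[tuple[float, float], FixationEstimate]


def optimal_alpha_rare(
    interactive: str,
    kind: str,
    net: PlaceNetwork,
    move_params: MovementParams,
    game_params: GameParams,
    grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    n_trials: int = 2000,
    seed: int = 0,
    max_updates: int = DEFAULT_MAX_UPDATES,
    mutant_placement: str = "uniform",
) -> OptimalAlphaResult:
    """Optimal staying propensity of a monomorphic population.

    A grid value is optimal when no same-interactive-type mutant with a
    different alpha invades it above the neutral rate 1/N by more than
    two standard errors.  Candidates are scanned in descending grid order
    (matching the highest-alpha tie-break) and the first non-invadable
    resident is returned; if every resident is invadable, the one whose
    worst invader exceeds neutrality the least is returned, flagged.
    """
    if not grid:
        raise ValueError("alpha grid must be nonempty")
    grid = sorted(set(grid))
    if len(grid) == 1:
        return OptimalAlphaResult(grid[0], True, {})
    N = net.M
    estimates: dict[tuple[float, float], FixationEstimate] = {}
    worst: dict[float, float] = {}
    for ri in reversed(range(len(grid))):
        resident = Strategy(interactive, grid[ri])
        invaded = False
        margin = -np.inf
        for mi, a_mut in enumerate(grid):
            if mi == ri:
                continue
            est = estimate_fixation(
                resident,
                Strategy(interactive, a_mut),
                1,
                n_trials,
                kind,
                net,
                move_params,
                game_params,
                seed=np.random.SeedSequence([seed, ri, mi]).generate_state(1)[0],
                max_updates=max_updates,
                mutant_placement=mutant_placement,
            )
            estimates[(grid[ri], a_mut)] = est
            margin = max(margin, est.rho_hat - (1.0 / N + 2.0 * est.sigma))
            if est.above(1.0 / N):
                invaded = True
        worst[grid[ri]] = margin
        if not invaded:
            return OptimalAlphaResult(grid[ri], True, estimates)
    best = min(worst, key=lambda a: (worst[a], -a))
    return OptimalAlphaResult(best, False, estimates)


@dataclass(frozen=True)
class FittestMutantResult:
    strategy: Strategy
    estimate: FixationEstimate
    estimates: Mapping[Strategy, FixationEstimate]


def fittest_mutant_rare(
    resident: Strategy,
    candidate_mutants: Sequence[Strategy],
    kind: str,
    net: PlaceNetwork,
    move_params: MovementParams,
    game_params: GameParams,
    n_trials: int = 2000,
    seed: int = 0,
    max_updates: int = DEFAULT_MAX_UPDATES,
    mutant_placement: str = "uniform",
) -> FittestMutantResult:
    """Single-mutant fixation estimate for each candidate; returns the
    argmax (ties broken toward higher alpha)."""
    if not candidate_mutants:
        raise ValueError("candidate list must be nonempty")
    estimates: dict[Strategy, FixationEstimate] = {}
    for ci, cand in enumerate(candidate_mutants):
        estimates[cand] = estimate_fixation(
            resident, cand, 1, n_trials, kind, net, move_params, game_params,
            seed=np.random.SeedSequence([seed, ci]).generate_state(1)[0],
            max_updates=max_updates, mutant_placement=mutant_placement,
        )
    best = max(estimates, key=lambda s: (estimates[s].rho_hat, s.alpha))
    return FittestMutantResult(best, estimates[best], estimates)


def classify_rare(
    rho_C: FixationEstimate,
    rho_D: FixationEstimate,
    N: int,
    one_sided: bool = False,
) -> OutcomeClass:
    """Classify the rare-mutation outcome from the fittest mutants'
    fixation estimates against the neutral rate 1/N.

    An estimate counts as above (below) neutral only beyond a two-sigma
    margin; with ``one_sided=True`` "below" relaxes to "not above", which
    makes the four classes exhaustive.
    """
    neutral = 1.0 / N
    c_above = rho_C.above(neutral)
    d_above = rho_D.above(neutral)
    c_below = (not c_above) if one_sided else rho_C.below(neutral)
    d_below = (not d_above) if one_sided else rho_D.below(neutral)
    if c_above and d_above:
        return OutcomeClass.FAVOURS_CHANGE
    if c_above and d_below:
        return OutcomeClass.FAVOURS_COOPERATION
    if c_below and d_above:
        return OutcomeClass.FAVOURS_DEFECTION
    return OutcomeClass.OPPOSES_CHANGE


# ---------------------------------------------------------------------------
# non-rare interactive mutations


def mixed_fixation(
    alpha_C: float,
    alpha_D: float,
    kind: str,
    net: PlaceNetwork,
    move_params: MovementParams,
    game_params: GameParams,
    n_trials: int = 2000,
    seed: int = 0,
    max_updates: int = DEFAULT_MAX_UPDATES,
) -> tuple[FixationEstimate, FixationEstimate]:
    """Fixation estimates (rho_C, rho_D) from the half-half mixed state.

    The two estimates come from complementary absorption events of the
    same trials, so their point estimates sum to one exactly.  Cooperator
    home slots are drawn uniformly at random per trial.
    """
    N = net.M
    if N % 2:
        raise ValueError("mixed populations require even N")
    est_C = estimate_fixation(
        Strategy(DEFECT, alpha_D),
        Strategy(COOPERATE, alpha_C),
        N // 2,
        n_trials,
        kind,
        net,
        move_params,
        game_params,
        seed,
        max_updates=max_updates,
    )
    est_D = FixationEstimate(
        est_C.n_trials - est_C.n_success, est_C.n_trials, est_C.n_nonabsorbed
    )
    return est_C, est_D


@dataclass(frozen=True)
class MutuallyOptimalResult:
    alpha_C: float
    alpha_D: float
    rho_C: FixationEstimate
    rho_D: FixationEstimate
    converged: bool
    diagnostics: dict


def mutually_optimal_pair(
    kind: str,
    net: PlaceNetwork,
    move_params: MovementParams,
    game_params: GameParams,
    grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    n_trials: int = 2000,
    seed: int = 0,
    start: tuple[float, float] | None = None,
    max_iters: int = 30,
    max_updates: int = DEFAULT_MAX_UPDATES,
) -> MutuallyOptimalResult:
    """Mutually-optimal staying propensities from the mixed population.

    Iterated best response on the alpha grid: cooperators pick the alpha
    maximising their fixation probability from the half-half state at the
    defectors' current alpha, then vice versa, until a fixed point.  If
    the iteration cycles, it is restarted with moves restricted to
    adjacent grid values; a persisting loop returns the median-index pair
    of the loop's visited values per type, recorded in the diagnostics.
    """
    grid = sorted(set(grid))
    if not grid:
        raise ValueError("alpha grid must be nonempty")
    cache: dict[tuple[float, float], tuple[FixationEstimate, FixationEstimate]] = {}

    def cell(a_C: float, a_D: float):
        key = (a_C, a_D)
        if key not in cache:
            iC, iD = grid.index(a_C), grid.index(a_D)
            cache[key] = mixed_fixation(
                a_C, a_D, kind, net, move_params, game_params, n_trials,
                seed=np.random.SeedSequence([seed, iC, iD]).generate_state(1)[0],
                max_updates=max_updates,
            )
        return cache[key]

    def best_response(
        which: str, a_current: float, a_fixed: float, candidates: Sequence[float]
    ) -> float:
        # A move away from the incumbent alpha requires a statistically
        # significant gain (two sigma on the difference of the binomial
        # estimates); otherwise estimation noise would make even a fully
        # neutral game wander over the grid.  Ties go to higher alpha.
        side = 0 if which == "C" else 1

        def est(a):
            return cell(a, a_fixed)[side] if which == "C" else cell(a_fixed, a)[side]

        best = max(candidates, key=lambda a: (est(a).rho_hat, a))
        if best == a_current:
            return a_current
        e_best, e_cur = est(best), est(a_current)
        gain = e_best.rho_hat - e_cur.rho_hat
        if gain > 2.0 * np.hypot(e_best.sigma, e_cur.sigma):
            return best
        return a_current

    def adjacent(a: float) -> list[float]:
        i = grid.index(a)
        return grid[max(i - 1, 0) : i + 2]

    if start is None:
        start = (grid[len(grid) // 2], grid[len(grid) // 2])
    history: list[tuple[float, float]] = [start]
    a_C, a_D = start
    converged = False
    restricted = False
    loop: list[tuple[float, float]] = []
    for _ in range(max_iters):
        cand_C = adjacent(a_C) if restricted else grid
        a_C_new = best_response("C", a_C, a_D, cand_C)
        cand_D = adjacent(a_D) if restricted else grid
        a_D_new = best_response("D", a_D, a_C_new, cand_D)
        pair = (a_C_new, a_D_new)
        if pair == (a_C, a_D):
            a_C, a_D = pair
            converged = True
            break
        if pair in history:
            if not restricted:
                restricted = True  # retry with nearest-value moves only
                history.append(pair)
                a_C, a_D = pair
                continue
            loop = history[history.index(pair) :] + [pair]
            cs = sorted(grid.index(p[0]) for p in loop)
            ds = sorted(grid.index(p[1]) for p in loop)
            a_C, a_D = grid[cs[len(cs) // 2]], grid[ds[len(ds) // 2]]
            break
        history.append(pair)
        a_C, a_D = pair
    est_C, est_D = cell(a_C, a_D)
    return MutuallyOptimalResult(
        a_C,
        a_D,
        est_C,
        est_D,
        converged,
        {"history": history, "loop": loop, "restricted": restricted},
    )


def classify_nonrare(
    rho_C_half: FixationEstimate, rho_D_half: FixationEstimate
) -> OutcomeClass:
    """Classify the non-rare-mutation outcome against the neutral 1/2."""
    c_above = rho_C_half.above(0.5)
    d_above = rho_D_half.above(0.5)
    if c_above and rho_D_half.below(0.5):
        return OutcomeClass.FAVOURS_COOPERATION
    if d_above and rho_C_half.below(0.5):
        return OutcomeClass.FAVOURS_DEFECTION
    return OutcomeClass.NEUTRAL
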