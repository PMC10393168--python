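# Methods

## Model overview

The population consists of `N` individuals homed one-per-node on a
connected simple graph of `M = N` places (complete, circle, star, or any
custom edge list; the star's hub is place 0 by convention).  Evolution
proceeds in generations, each consisting of an *exploration phase*
followed by one *replacement event*:

1. **Exploration.**  Everyone starts at home with zero fitness and takes
   `T` synchronous steps.  At step `t` individual `n` looks at the group
   it occupied at `t − 1` and stays with probability
   `h = α_n / (α_n + (1 − α_n) S^β)`, where `β` sums the attractiveness
   of the *other* group members (`+1` per cooperator, `−1` per defector);
   otherwise it moves to a uniformly chosen neighbour.  An individual
   alone has `β = 0`, so `h = α_n` exactly.  All step-`t` draws condition
   on the complete step-`t−1` configuration; there is no within-step
   ordering.
2. **Payoffs.**  At each step the group at the *arrived* place plays the
   excludable public goods game: cooperators pay `c` to contribute `v`,
   split equally among the other group members; everyone gets a
   background reward of 1 (payoffs: `1 − c + (g_C − 1)/(g − 1)·v` for a
   cooperator, `1 + g_C/(g − 1)·v` for a defector, `1 − c` / `1` when
   alone).  Moving costs `λ` per step.  No payoff accrues at `t = 0`,
   where everyone is alone at home; fitness is the sum of the `T`
   contributions and resets every generation.  In interacting groups the
   good is exactly conserved (`Σ(R − 1) = g_C (v − c)`); a lone
   cooperator pays `c` with nothing produced.
3. **Replacement.**  One event `(i births, j dies)` is drawn from one of
   six update rules (see below); `j`'s slot receives a copy of `i`'s
   full complex strategy.  `i = j` (self-replacement) is allowed and
   consumes an update without changing the state, so trials track wall
   updates, not only effective changes.

## Emergent replacement weights

Replacement is weighted by the expected co-location time `w_ij` one
movement step after leaving home.  For one configuration, an
individual's unit of time splits equally over the other members of its
group (`1/(g − 1)` each) and falls entirely on itself only when alone.
Because everyone is alone at home, first-step moves are independent:
individual `n` lands on place `m` with probability `α_n` (its own home)
or `(1 − α_n)/d` (a neighbouring home).  Writing `K` for the number of
*other* arrivals at `m` — a Poisson-binomial count — the off-diagonal
weight is `w_ij = Σ_m p_i(m) p_j(m) E[1/(1 + K)]` and the diagonal is
`w_ii = Σ_m p_i(m) P(K = 0)`.

`E[1/(1+K)]` is evaluated through the exact identity
`E[1/(1+K)] = ∫₀¹ Π_k (1 − p_k (1 − x)) dx`; the integrand is a
polynomial of degree ≤ N − 1, so Gauss–Legendre quadrature with
`⌊N/2⌋ + 1` nodes integrates it exactly (to machine precision), and the
leave-one-out products for `P(K = 0)` use prefix/suffix products so that
`α = 1` (probability-one factors) needs no division.  The result is
symmetric and doubly stochastic for every population and topology —
an isothermal evolutionary graph — which the test suite verifies to
1e−12 against exhaustive enumeration for small `N` and structurally for
`N ≤ 20`.  A Monte-Carlo estimator (`weights_mc`) is retained for
validation and for variants without a closed form.  Weights depend on
the population only through the `α` vector, so inside a fixation trial
they are cached and recomputed only when a replacement actually changes
the strategy composition.

## Update rules

With fitness vector `F` and weights `W`, the replacement kernel
`τ_ij` is (birth index first):

| kind | τ_ij |
|------|------|
| BDB | `(F_i/ΣF) · (w_ij/Σ_n w_in)` |
| DBD | `(F_j⁻¹/ΣF⁻¹) · (w_ij/Σ_n w_nj)` |
| DBB | `(1/N) · w_ij F_i / Σ_n w_nj F_n` |
| BDD | `(1/N) · w_ij F_j⁻¹ / Σ_n w_in F_n⁻¹` |
| LB  | `w_ij F_i / Σ_{n,k} w_nk F_n` |
| LD  | `w_ij F_j⁻¹ / Σ_{n,k} w_nk F_k⁻¹` |

With unit row sums BDB collapses to LB; with unit column sums as well
(always true for the emergent weights) DBD collapses to LD.  Note the
column-sum requirement: the pair identities as sometimes stated for
"row-stochastic" weights hold in full only on doubly stochastic ones.

**Fitness floor.**  With `λ` near 1, total fitness can reach zero or
below (a lone cooperator that moves every step earns
`T(1 − c) − Tλ < 0`), which breaks the inverse-fitness rules and makes
direct-fitness birth probabilities negative.  `F` is therefore clamped
at `ε = 1e−6` before use in *all six* rules.  This preserves the
ordering of positive fitnesses and touches nothing when all fitness is
positive; `ε` is configurable per call.

## Estimators and classification

A fixation trial repeats exploration → fitness → weights → kernel →
replacement until the population is monomorphic in *label* (resident vs
mutant), so two labels carrying identical strategies drift neutrally —
the neutral checks (`ρ = 1/N`, `ρ = 1/2`) exercise the full pipeline.
`ρ̂ = n_success/n_trials` with binomial standard error
`σ = √(ρ̂(1−ρ̂)/n_trials)`; each trial draws its RNG stream from a
per-trial seed spawned from the master seed, so estimates are exactly
reproducible.  Trials hitting the update cap (default 10⁶) are counted
and reported separately, never silently dropped.  Mutant home slots are
drawn uniformly per trial (configurable `hub`/`leaf` on the star, where
placement matters).

"Above neutral" means `ρ̂ > neutral + 2σ`.  We apply the same 2σ margin
on the *below* side (configurable to one-sided), which makes the
classification conservative: rare-scenario outcomes are
favours-cooperation / favours-defection / favours-change /
opposes-change, with band-straddling mixed cases falling to
opposes-change; non-rare outcomes are favours-cooperation /
favours-defection / neutral, judged against 1/2 from the half-half
state, whose two complementary estimates come from the same trials and
sum to one exactly.

**Optimal staying propensities (rare scenario).**  A resident grid value
is optimal when no same-type mutant with a different `α` invades it
above `1/N + 2σ`.  Residents are scanned in descending grid order
(matching the highest-α tie-break), returning the first non-invadable
value; if none exists, the least-invadable value is returned with a
flag.  For defectors with `λ > 0` the search terminates immediately at
0.99: moving buys a defector nothing when everyone defects.

**Mutually-optimal pair (non-rare scenario).**  Iterated best response
on the grid from the half-half state.  A move away from the incumbent
`α` requires the best candidate to beat the incumbent's estimate by 2σ
on the difference; without this gate, binomial noise makes even a fully
neutral game (`v = c = 0, λ = 0`) wander over the grid.  If the
iteration cycles, it restarts with moves restricted to adjacent grid
values; a persisting loop returns the median-index values of the loop
per type, with the loop recorded in the diagnostics.  The gate means
flat fixation landscapes can hold several admissible fixed points;
reruns from a common start are seed-stable.

## The exact oracle

For tiny systems (`N ≤ 3`, `T ≤ 2`) every joint trajectory is
enumerated with its exact probability, fitness is computed per
trajectory, the kernel is averaged, and fixation probabilities are read
off the absorbing Markov chain over the `2^N` label states (tracked per
home slot, so the star's asymmetry needs no special casing).  The
one-step weights used there come from exhaustive enumeration of joint
moves, independent of the quadrature path.  Simulation-vs-oracle
agreement within 3 standard errors across all six dynamics is part of
the acceptance suite.

## Problem sizes and defaults

Defaults mirror the study conditions: `S = 0.03`, `c = 0.04`, `v = 0.4`,
`T = 10`, attractiveness `±1`, the 11-value `α` grid, `λ ∈ {0, 0.1, …,
1.0}` for sweeps.  The package's own validation runs use desk-scale
trial counts — 2 000 per invasion pair for grid searches, 5 000–10 000
for drift and oracle comparisons, populations of `N = 10` (and `N ≤ 4`
for exact enumeration) — chosen so the full suite completes in minutes
on one core while keeping the 2σ bands narrow enough for the qualitative
claims being checked.  Larger populations and the published-scale
100 000-trial estimates are a matter of budget, not of code paths: all
operations scale polynomially in `N` and linearly in trials.

## What the simulations do and do not show

All inputs are self-generated: the "data" are the model's own
trajectories, so passing tests validate internal consistency (simulator
vs closed forms and exact enumeration), not any empirical claim about
biological populations.  Known limitations: movement is strictly
Markovian (no memory, no payoff-anticipating moves); the place network
is static and unweighted; only fixation (two-strategy) dynamics are
modelled, with mutation timescales assumed long; at a region boundary
the 2σ rule's verdict depends on trial counts, since the band shrinks
as `n^{-1/2}` while the underlying gap is fixed; and on flat fixation
landscapes the mutually-optimal pair is identified only up to the
significance gate described above.
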