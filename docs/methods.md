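# Methods

## Model

The sequential truel is a discrete stochastic game among players A, B, C with
single-shot hit probabilities (marksmanship) `0 ≤ a ≤ b ≤ c ≤ 1`. Turns cycle
A → B → C, skipping dead players; the shooter picks a target (a live
opponent, himself, or the air), the shot hits with the shooter's marksmanship
(air shots never hit), and a hit removes the victim. The game ends when one
player remains. Assumptions baked into the model:

- marksmanship is independent of the target: a suicide attempt succeeds with
  the same probability `a` as a shot at an opponent;
- B and C are not strategic: while all three are alive they always fire at
  their strongest live opponent (B at C, C at B, by the ordering `b ≤ c`);
  with one opponent left, everyone fires at that opponent;
- only player A, the weakest, chooses among seven strategies (strongest,
  abstain, suicide, target-B, uniform-random over opponents, uniform-random
  including self, and a per-turn random switch between suicide and
  abstention).

`c > 0` is required and enforced at validation: with `a = b = c = 0` no shot
can ever land and the game never terminates. For any valid triple and any
strategy the process is an absorbing Markov chain — every cycle of turns has
positive probability of a kill — so termination has probability 1.

## Exact solver

States are pairs (set of live players, player about to shoot): at most 9
transient states (3 shooters × the full set, 2 shooters × 3 pairs) plus 3
absorbing single-survivor states. The one-step law composes the shooter's
target distribution with the Bernoulli hit. Absorption probabilities solve
`(I − Q)x = R` (numpy dense solve; the system is at most 9×9). The solver is
the oracle for every other component: closed forms, simulator and sweeps are
all tested against it.

Numerical notes:

- components are clipped to [0, 1] after the solve (an exact 1.0 can come
  back as `1 + O(eps)`);
- the solve's conditioning scales like the reciprocal of the per-cycle kill
  probability. Conservation `p_a + p_b + p_c = 1` holds to 1e-12 for
  ordinary inputs, but degrades (to ~1e-10 at `c = 1e-6`) when all hit
  probabilities are pushed toward zero, and sub-denormal probabilities
  (~1e-80) make the duel blocks numerically singular. Exactly-zero
  marksmanship is safe: zero-probability transitions are pruned before the
  solve. The property suite therefore draws components from {0} ∪ [1e-3, 1];
- a sanity check rejects solutions whose absorption mass differs from 1 by
  more than 1e-9 (reachable only through inputs that bypass validation).

## Closed forms

**Suicidal strategy.** While all three live, each round is (A: self-shot,
B: shot at C, C: shot at B). Conditioning on which of the three "first
events" ends the phase gives scenario probabilities (complement notation
`x̄ = 1 − x`):

- `s_a1 = āb / (1 − āb̄c̄)` — A outlives his own shots, B removes C first;
- `s_a2 = a / (1 − āb̄)` — A then wins the A-first duel against B;
- `s_a3 = āb̄c / (1 − āb̄c̄)`, `s_a4 = a / (1 − āc̄)` — the C-branch analogues;
- `s_b3 = a·b·D(ā, b̄c̄)` and `s_c3 = a·b̄·c·D(ā, b̄c̄)` — A dies by his own
  hand while the B–C exchange resolves, where
  `D(x, y) = Σₙ yⁿ Σ_{k≤n} xᵏ = [1/(1−y) − x/(1−xy)]/(1−x)`

and `P_A = s_a1·s_a2 + s_a3·s_a4`, `P_B = s_a1(1−s_a2) + s_b3`,
`P_C = s_a3(1−s_a4) + s_c3`. We deliberately keep the scenario-product form
rather than a factored rearrangement of `P_A`: the factored form invites a
transcription slip (`āc` in place of `b̄c` in the second summand, which at
(0.3, 0.5, 1.0) gives 0.3085 instead of the correct 0.26654), and a dedicated
test documents that only the scenario-product form matches the Markov solver.
Ratios with zero numerators are defined as 0 (the scenario is unreachable)
even when the denominator also vanishes, so `a = b = 0` is handled; `D` is
evaluated only when `a > 0`, keeping its arguments inside the region of
convergence. A truncated-series evaluation of `D` (2,000 terms, tail < 1e-13
over the tested range) is kept in the test suite as an independent oracle.

**Abstention.** While A abstains, B and C fight a B-first duel that B wins
with `W = b / (1 − b̄c̄)`; A then enters the final duel as first shooter,
so `P_A = W·duel(a, b) + (1−W)·duel(a, c)` with
`duel(p₁, p₂) = p₁ / (1 − (1−p₁)(1−p₂))`, `P_B = W(1 − duel(a, b))`,
`P_C = (1−W)(1 − duel(a, c))`. The A–B duel term is only evaluated when
`W > 0`, which sidesteps the non-terminating `duel(0, 0)` corner.

**Target-B / suicide equivalence.** When `c = 1`, any round that leaves C
alive with A exposed is immediately fatal to A, so A's survival chances under
"shoot B" and "shoot yourself" coincide: both reduce to "survive the opening
round yourself and hope B removes C". The package computes the target-B
distribution with the exact solver and verifies the equivalence to 1e-10
across the grid; for `c < 1` the two strategies genuinely differ.

## Monte-Carlo simulator

Each game replays the rules literally: sample the target from the strategy's
per-state distribution, then a Bernoulli hit. Game `i` of a run uses its own
PCG64 generator seeded with `SeedSequence(seed, spawn_key=(i,))`, so results
are bit-reproducible and independent of execution order. Per-state sampling
structures are precompiled once per run, so a game costs at most two uniform
draws per turn. A per-game shot cap (default 10⁶, configurable) guards the
loop against non-terminating inputs that bypass validation; for valid inputs
it is unreachable in any practical sense (shots per game is bounded by a
geometric variable; the largest count observed in a run is reported as
`max_shots`). Estimates are win frequencies with binomial standard errors
`√(p̂(1−p̂)/n)`. The default `n = 10⁶` matches the resolution the region maps
were originally computed at; the test suite uses 10⁴–10⁵, which already pins
each probability to ±0.005 or better.

## Sweeps

A sweep evaluates one strategy on the lattice `{0, step, …, 1}²` restricted
to `a ≤ b` (and `b ≤ c` when `c < 1`; cells violating the ordering are
skipped with a warning), at fixed `c`. Per cell it records `(p_a, p_b, p_c)`
— from the solver, or from `n` simulated games with a per-cell spawned seed —
and the winner: the strict argmax, or `TIE` when the top two probabilities
are within `tie_tol` (default 1e-12 for exact sweeps, 0 for Monte-Carlo ones;
exact ties occur e.g. on the `a = b` diagonal for some strategies). The
default step 0.02 (1,326 cells at `c = 1`) resolves every qualitative
region claim — the suicidal and random-3 A-regions are empty, the random-2
A-region is a thin 7-cell band, abstention's 547-cell A-region dwarfs the
64 cells under strongest-targeting, and the suicide/abstain switch restores
281 cells — while keeping an exact sweep around 0.1 s; step 0.001 (~500k
cells) remains reachable through the same API. Grids round-trip through CSV
with 12-significant-digit floats; region summaries serialise to JSON.

## Design choices

- **Turn order after a death**: the A→B→C cycle continues from the shooter,
  skipping the dead. In particular A always enters the two-player endgame as
  first shooter when B or C fires the fatal three-player shot, which is what
  makes abstention powerful.
- **Strategy collapse**: suicide/abstention/random menus apply only while
  both opponents are alive; with one opponent left every strategy targets
  that opponent. Random menus never include the air; the air is reachable
  only through `abstain` and the `switch` mixture.
- **Switch strategy**: interpreted as an independent per-turn
  Bernoulli(`switch_prob`) choice between a suicide attempt and an air shot,
  with `switch_prob = 0.5` by default and exposed as a parameter. A per-game
  (rather than per-turn) coin is a plausible alternative reading; per-turn is
  the minimal one and is what the region results here refer to.
- **Ties**: winner labels use a strict-argmax margin (`tie_tol`) rather than
  an arbitrary winner, so diagonal symmetry shows up as `TIE` instead of a
  coin-flip label.

## What the tests do and do not show

All inputs here are the model's own parameters — there is no external data —
so the tests establish internal consistency (closed forms vs solver vs
simulation) and the qualitative geometry of the winner regions at step 0.02.
They do not probe strategic behaviour by B and C, simultaneous-fire variants,
n > 3 players, or marksmanship that differs between suicidal and adversarial
shots; all of these are out of scope of the model.
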