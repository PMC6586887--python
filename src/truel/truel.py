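"""Sequential three-player truel: exact solver, closed forms, simulation, sweeps.

The truel is a three-person generalisation of the duel. Players A, B and C,
with marksmanship (single-shot hit probabilities) ``a <= b <= c``, fire one
shot per turn in cyclic alphabetic order A -> B -> C, skipping dead players,
until a single survivor remains. While all three are alive, B and C always
target their strongest live opponent (B fires at C, C fires at B); only the
weakest player A chooses a strategy:

====================  =====================================================
``strongest``         fire at C, the strongest opponent
``abstain``           fire into the air (a guaranteed miss)
``suicide``           fire at himself, hitting with probability ``a``
``target_b``          fire at B, the intermediate opponent
``random2``           pick the target uniformly from {B, C}
``random3``           pick the target uniformly from {self, B, C}
``switch``            per turn, suicide with probability ``switch_prob``,
                      otherwise fire into the air
====================  =====================================================

Once only one opponent remains, every strategy collapses to firing at that
opponent, and the truel reduces to an alternating two-player duel in which
the first shooter wins with probability ``p1 / (1 - (1-p1)(1-p2))``.

The module is laid out in the order the method runs:

1.  game rules — players, states, turn order, per-turn target distributions;
2.  exact solver — absorption probabilities of the induced Markov chain,
    the oracle for everything else;
3.  closed forms — scenario decomposition of the suicidal strategy and the
    abstention duel decomposition, cross-validated against the solver;
4.  Monte-Carlo simulator — seeded, bit-reproducible replay of the game;
5.  parameter sweeps — winner-region maps over (a, b) at fixed c and
    region-area summaries.
"""

from __future__ import annotations

import enum
import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("truel")

__all__ = [
    "A", "B", "C", "PLAYERS", "SELF", "AIR", "TIE",
    "Strategy", "StrategyProfile", "Marksmanship", "GameState",
    "SurvivalDistribution", "ScenarioProbabilities",
    "ConstraintError", "NonTerminationError", "DivergenceError",
    "validate", "next_shooter", "target_distribution",
    "exact_survival", "duel_first_shooter_win",
    "double_geometric_sum", "scenario_probs_suicidal",
    "survival_suicidal", "survival_abstention", "survival_target_b",
    "SimulationResult", "play_one", "simulate",
    "SweepSpec", "RegionSummary", "winner_map", "region_summary",
    "compare_regions", "write_winner_grid", "read_winner_grid",
    "GRID_COLUMNS",
]

# --------------------------------------------------------------------------
# 1. Game rules
# --------------------------------------------------------------------------

A, B, C = "A", "B", "C"
PLAYERS: tuple[str, str, str] = (A, B, C)

#: special shot targets: one's own head, or the air (a guaranteed miss)
SELF = "SELF"
AIR = "AIR"

#: winner label for grid cells where no player is a strict argmax
TIE = "TIE"


class ConstraintError(ValueError):
    """A marksmanship ordering or range constraint is violated."""


class NonTerminationError(ValueError):
    """The game (or a sub-duel) can never reach a single survivor."""


class DivergenceError(ValueError):
    """A geometric series parameter lies outside its region of convergence."""


class Strategy(str, enum.Enum):
    """Player A's targeting rule while both opponents are alive."""

    STRONGEST = "strongest"
    ABSTAIN = "abstain"
    SUICIDE = "suicide"
    TARGET_B = "target_b"
    RANDOM2 = "random2"
    RANDOM3 = "random3"
    SWITCH_SUICIDE_AIR = "switch"

    @classmethod
    def coerce(cls, value: "Strategy | str") -> "Strategy":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            names = ", ".join(s.value for s in cls)
            raise ConstraintError(
                f"unknown strategy {value!r}; expected one of: {names}"
            ) from None


ALL_STRATEGIES: tuple[Strategy, ...] = tuple(Strategy)


@dataclass(frozen=True)
class StrategyProfile:
    """A's strategy; B and C always target the strongest opponent.

    ``switch_prob`` only matters for ``Strategy.SWITCH_SUICIDE_AIR``: each of
    A's turns with both opponents alive is an independent Bernoulli choice
    between a suicide attempt (probability ``switch_prob``) and firing into
    the air.
    """

    strategy: Strategy
    switch_prob: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "strategy", Strategy.coerce(self.strategy))
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ConstraintError(
                f"switch_prob must lie in [0, 1], got {self.switch_prob}"
            )


@dataclass(frozen=True)
class Marksmanship:
    """Hit probabilities (a, b, c) with the ordering 0 <= a <= b <= c <= 1.

    ``c > 0`` is required: with a = b = c = 0 no shot can ever land and the
    game never terminates.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        validate(self)

    def of(self, player: str) -> float:
        return {A: self.a, B: self.b, C: self.c}[player]

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)


def _as_marksmanship(m: "Marksmanship | Iterable[float]") -> Marksmanship:
    return m if isinstance(m, Marksmanship) else Marksmanship(*m)


def validate(m: Marksmanship) -> Marksmanship:
    """Check 0 <= a <= b <= c <= 1 and c > 0; return ``m`` unchanged."""
    a, b, c = m.a, m.b, m.c
    if not 0.0 <= a:
        raise ConstraintError(f"0 <= a violated: a = {a}")
    if not a <= b:
        raise ConstraintError(f"a <= b violated: a = {a}, b = {b}")
    if not b <= c:
        raise ConstraintError(f"b <= c violated: b = {b}, c = {c}")
    if not c <= 1.0:
        raise ConstraintError(f"c <= 1 violated: c = {c}")
    if c == 0.0:
        raise NonTerminationError(
            "a = b = c = 0: no shot can ever land, the truel never ends"
        )
    return m


@dataclass(frozen=True)
class GameState:
    """Set of live players plus whose turn it is to fire next."""

    alive: frozenset[str]
    turn: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "alive", frozenset(self.alive))
        if not self.alive <= set(PLAYERS):
            raise ConstraintError(f"unknown players in {set(self.alive)}")
        if not self.alive:
            raise ConstraintError("at least one player must be alive")
        if self.turn not in self.alive:
            raise ConstraintError(f"turn {self.turn!r} is not alive")

    @property
    def absorbing(self) -> bool:
        return len(self.alive) == 1


START = GameState(frozenset(PLAYERS), A)


def _next_alive(after: str, alive: frozenset[str]) -> str:
    i = PLAYERS.index(after)
    for k in (1, 2, 3):
        cand = PLAYERS[(i + k) % 3]
        if cand in alive:
            return cand
    raise NonTerminationError("no live player found")  # pragma: no cover


def next_shooter(state: GameState) -> str:
    """First live player strictly after ``state.turn`` in the cycle A->B->C->A."""
    if state.absorbing:
        raise NonTerminationError("absorbing state: no next shooter")
    return _next_alive(state.turn, state.alive)


def target_distribution(
    profile: StrategyProfile,
    shooter: str,
    state: GameState,
    m: Marksmanship,
) -> dict[str, float]:
    """Probability mass over this turn's target: a live opponent, SELF or AIR.

    With both opponents alive, B fires at C and C fires at B (strongest live
    opponent under a <= b <= c), while A follows ``profile.strategy``. With a
    single opponent left, every shooter puts all mass on that opponent.
    """
    if shooter not in state.alive:
        raise ConstraintError(f"shooter {shooter!r} is dead")
    opponents = [p for p in PLAYERS if p in state.alive and p != shooter]
    if not opponents:
        raise NonTerminationError("absorbing state: nothing to shoot at")
    if len(opponents) == 1:
        return {opponents[0]: 1.0}

    # all three alive
    if shooter == B:
        return {C: 1.0}
    if shooter == C:
        return {B: 1.0}
    s = profile.strategy
    if s is Strategy.STRONGEST:
        return {C: 1.0}
    if s is Strategy.ABSTAIN:
        return {AIR: 1.0}
    if s is Strategy.SUICIDE:
        return {SELF: 1.0}
    if s is Strategy.TARGET_B:
        return {B: 1.0}
    if s is Strategy.RANDOM2:
        return {B: 0.5, C: 0.5}
    if s is Strategy.RANDOM3:
        return {SELF: 1 / 3, B: 1 / 3, C: 1 / 3}
    if s is Strategy.SWITCH_SUICIDE_AIR:
        p = profile.switch_prob
        if p == 0.0:
            return {AIR: 1.0}
        if p == 1.0:
            return {SELF: 1.0}
        return {SELF: p, AIR: 1.0 - p}
    raise ConstraintError(f"unknown strategy {s!r}")  # pragma: no cover


# --------------------------------------------------------------------------
# 2. Exact solver (absorbing Markov chain)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalDistribution:
    """Probabilities that A, B, C respectively are the last one standing."""

    p_a: float
    p_b: float
    p_c: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_a, self.p_b, self.p_c)

    def of(self, player: str) -> float:
        return {A: self.p_a, B: self.p_b, C: self.p_c}[player]

    def winner(self, tie_tol: float = 1e-12) -> str:
        """Strict argmax label, or TIE if the top two are within ``tie_tol``."""
        probs = sorted(zip(self.as_tuple(), PLAYERS), reverse=True)
        if probs[0][0] - probs[1][0] > tie_tol:
            return probs[0][1]
        return TIE


def _one_step(
    profile: StrategyProfile, m: Marksmanship, state: GameState
) -> dict[GameState | str, float]:
    """One-turn transition law from ``state``; absorbing outcomes are player labels."""
    shooter = state.turn
    dist = target_distribution(profile, shooter, state, m)
    hit = m.of(shooter)
    edges: dict[GameState | str, float] = defaultdict(float)
    for target, mass in dist.items():
        if mass <= 0.0:
            continue
        victim = None if target == AIR else (shooter if target == SELF else target)
        p_hit = 0.0 if victim is None else hit
        if p_hit > 0.0:
            new_alive = state.alive - {victim}
            if len(new_alive) == 1:
                nxt: GameState | str = next(iter(new_alive))
            else:
                nxt = GameState(new_alive, _next_alive(shooter, new_alive))
            edges[nxt] += mass * p_hit
        if p_hit < 1.0:
            miss = GameState(state.alive, _next_alive(shooter, state.alive))
            edges[miss] += mass * (1.0 - p_hit)
    return dict(edges)


def exact_survival(
    profile: StrategyProfile,
    m: "Marksmanship | Iterable[float]",
    start: GameState = START,
) -> SurvivalDistribution:
    """Exact survival probabilities by solving the absorbing Markov chain.

    Enumerates the reachable (alive set, shooter) states — at most 9 transient
    states — and solves the linear system ``(I - Q) x = R`` for the absorption
    probability into each single-survivor state.
    """
    m = _as_marksmanship(m)
    # breadth-first enumeration of reachable transient states
    transitions: dict[GameState, dict[GameState | str, float]] = {}
    stack = [start]
    while stack:
        s = stack.pop()
        if s in transitions or s.absorbing:
            continue
        edges = _one_step(profile, m, s)
        transitions[s] = edges
        for nxt in edges:
            if isinstance(nxt, GameState):
                stack.append(nxt)

    if start.absorbing:
        out = {p: 0.0 for p in PLAYERS}
        out[next(iter(start.alive))] = 1.0
        return SurvivalDistribution(out[A], out[B], out[C])

    states = list(transitions)
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    q = np.zeros((n, n))
    r = np.zeros((n, 3))
    for s, edges in transitions.items():
        i = index[s]
        for nxt, p in edges.items():
            if isinstance(nxt, GameState):
                q[i, index[nxt]] += p
            else:
                r[i, PLAYERS.index(nxt)] += p
    try:
        absorb = np.linalg.solve(np.eye(n) - q, r)
    except np.linalg.LinAlgError:
        raise NonTerminationError(
            "the game contains a recurrent class with no exit"
        ) from None
    p_a, p_b, p_c = absorb[index[start]]
    total = p_a + p_b + p_c
    if abs(total - 1.0) > 1e-9:
        raise NonTerminationError(
            f"absorption probabilities sum to {total}, not 1: "
            "the game does not terminate with probability 1"
        )
    # clip float overshoot (an exact 1.0 can solve to 1 + O(eps))
    p_a, p_b, p_c = (min(max(float(p), 0.0), 1.0) for p in (p_a, p_b, p_c))
    return SurvivalDistribution(p_a, p_b, p_c)


def duel_first_shooter_win(p_first: float, p_second: float) -> float:
    """Win probability of the first shooter in an alternating two-player duel.

    The first shooter wins on his n-th shot after both miss n-1 times each,
    giving the geometric series p1 * sum ((1-p1)(1-p2))^n with closed form
    ``p1 / (1 - (1-p1)(1-p2))``.
    """
    if not (0.0 <= p_first <= 1.0 and 0.0 <= p_second <= 1.0):
        raise ConstraintError("duel hit probabilities must lie in [0, 1]")
    if p_first == 0.0 and p_second == 0.0:
        raise NonTerminationError("both duelists always miss: the duel never ends")
    return p_first / (1.0 - (1.0 - p_first) * (1.0 - p_second))


# --------------------------------------------------------------------------
# 3. Closed forms: suicidal scenario decomposition and abstention
# --------------------------------------------------------------------------

def double_geometric_sum(x: float, y: float) -> float:
    """The nested series sum_{n>=0} y^n sum_{k=0}^{n} x^k, for 0 <= x, y < 1.

    Closed form ``[1/(1-y) - x/(1-x y)] / (1-x)``; arises as the round-by-round
    bookkeeping of "A eventually dies by his own shot while the B-C exchange is
    still unresolved".
    """
    if not (0.0 <= x < 1.0 and 0.0 <= y < 1.0):
        raise DivergenceError(
            f"series requires 0 <= x < 1 and 0 <= y < 1, got x={x}, y={y}"
        )
    return (1.0 / (1.0 - y) - x / (1.0 - x * y)) / (1.0 - x)


@dataclass(frozen=True)
class ScenarioProbabilities:
    """Building blocks of the suicidal-strategy survival probabilities.

    With complements ab = 1-a etc., and all three players alive:

    * ``s_a1`` — A survives his own shots and B kills C first;
    * ``s_a2`` — A then wins the ensuing duel against B (A shoots first);
    * ``s_a3`` — A survives his own shots and C kills B first;
    * ``s_a4`` — A then wins the ensuing duel against C;
    * ``s_b3`` — A dies by his own hand and B kills C;
    * ``s_c3`` — A dies by his own hand and C kills B.
    """

    s_a1: float
    s_a2: float
    s_a3: float
    s_a4: float
    s_b3: float
    s_c3: float


def _ratio(num: float, den: float) -> float:
    # a zero numerator denotes an unreachable scenario, even if the ensuing
    # duel would itself be non-terminating (e.g. a = b = 0)
    if num == 0.0:
        return 0.0
    if den == 0.0:
        raise NonTerminationError("zero denominator in scenario recursion")
    return num / den


def scenario_probs_suicidal(
    m: "Marksmanship | Iterable[float]",
) -> ScenarioProbabilities:
    """Scenario probabilities for the suicidal strategy (see the class docs)."""
    m = _as_marksmanship(m)
    a, b, c = m.as_tuple()
    ab, bb, cb = 1.0 - a, 1.0 - b, 1.0 - c
    d3 = 1.0 - ab * bb * cb  # > 0 because c > 0
    s_a1 = _ratio(ab * b, d3)
    s_a2 = _ratio(a, 1.0 - ab * bb)
    s_a3 = _ratio(ab * bb * c, d3)
    s_a4 = _ratio(a, 1.0 - ab * cb)
    if a == 0.0:
        s_b3 = s_c3 = 0.0  # A can never kill himself
    else:
        d = double_geometric_sum(ab, bb * cb)
        s_b3 = a * b * d
        s_c3 = a * bb * c * d
    return ScenarioProbabilities(s_a1, s_a2, s_a3, s_a4, s_b3, s_c3)


def survival_suicidal(
    m: "Marksmanship | Iterable[float]",
) -> SurvivalDistribution:
    """Closed-form survival probabilities when A plays the suicidal strategy.

    P_A = s_a1 s_a2 + s_a3 s_a4; P_B = s_a1 (1 - s_a2) + s_b3;
    P_C = s_a3 (1 - s_a4) + s_c3. Agrees with the exact solver to rounding.
    """
    s = scenario_probs_suicidal(m)
    p_a = s.s_a1 * s.s_a2 + s.s_a3 * s.s_a4
    p_b = s.s_a1 * (1.0 - s.s_a2) + s.s_b3
    p_c = s.s_a3 * (1.0 - s.s_a4) + s.s_c3
    return SurvivalDistribution(p_a, p_b, p_c)


def survival_abstention(
    m: "Marksmanship | Iterable[float]",
) -> SurvivalDistribution:
    """Closed-form survival probabilities when A fires into the air.

    While A abstains, B and C fight a B-first duel; B wins it with probability
    W = b / (1 - (1-b)(1-c)). A then enters the final duel as first shooter:

        P_A = W * duel(a, b) + (1 - W) * duel(a, c).
    """
    m = _as_marksmanship(m)
    a, b, c = m.as_tuple()
    w = b / (1.0 - (1.0 - b) * (1.0 - c))  # denominator > 0 because c > 0
    dab = duel_first_shooter_win(a, b) if w > 0.0 else 0.0
    dac = duel_first_shooter_win(a, c)
    p_a = w * dab + (1.0 - w) * dac
    p_b = w * (1.0 - dab)
    p_c = (1.0 - w) * (1.0 - dac)
    return SurvivalDistribution(p_a, p_b, p_c)


def survival_target_b(
    m: "Marksmanship | Iterable[float]",
) -> SurvivalDistribution:
    """Survival probabilities when A fires at B while all three are alive.

    Computed with the exact solver. When c = 1, A's survival probability is
    identical to the suicidal strategy's: either way A's only route is to
    survive the first round himself while B removes C, since any shot that
    leaves C alive and A exposed is immediately fatal.
    """
    return exact_survival(StrategyProfile(Strategy.TARGET_B), m)


# --------------------------------------------------------------------------
# 4. Monte-Carlo simulator
# --------------------------------------------------------------------------

#: per-game shot cap guarding against non-termination (unreachable for valid inputs)
DEFAULT_SHOT_CAP = 10**6

_StateKey = tuple[frozenset[str], str]
_SimTable = dict[_StateKey, tuple[tuple[float, ...], tuple[str | None, ...],
                                  float, object, tuple[object, ...]]]


def _compile_sim_table(profile: StrategyProfile, m: Marksmanship) -> _SimTable:
    """Per-state sampling structure: target cut-points, victims, hit probability,
    miss successor, and kill successor per target (a player label if absorbing)."""
    table: _SimTable = {}
    masks = [frozenset(s) for s in
             ({A, B, C}, {A, B}, {A, C}, {B, C})]
    for alive in masks:
        for shooter in sorted(alive):
            state = GameState(alive, shooter)
            dist = target_distribution(profile, shooter, state, m)
            targets = list(dist)
            cum = tuple(float(x) for x in np.cumsum([dist[t] for t in targets]))
            victims = tuple(
                None if t == AIR else (shooter if t == SELF else t)
                for t in targets
            )
            miss_next: object = (alive, _next_alive(shooter, alive))
            kills = []
            for v in victims:
                if v is None:
                    kills.append(None)
                    continue
                new_alive = alive - {v}
                if len(new_alive) == 1:
                    kills.append(next(iter(new_alive)))
                else:
                    kills.append((new_alive, _next_alive(shooter, new_alive)))
            table[(alive, shooter)] = (cum, victims, m.of(shooter),
                                       miss_next, tuple(kills))
    return table


def _play(
    table: _SimTable,
    start: _StateKey,
    rng: np.random.Generator,
    shot_cap: int,
) -> tuple[str, int]:
    state: object = start
    shots = 0
    while True:
        cum, victims, hit, miss_next, kills = table[state]
        shots += 1
        if shots > shot_cap:
            raise NonTerminationError(
                f"game exceeded the shot cap of {shot_cap}"
            )
        u = rng.random()
        i = 0
        while cum[i] < u:
            i += 1
        nxt = miss_next
        if victims[i] is not None and rng.random() < hit:
            nxt = kills[i]
            if isinstance(nxt, str):
                return nxt, shots
        state = nxt


def play_one(
    profile: StrategyProfile,
    m: "Marksmanship | Iterable[float]",
    rng: np.random.Generator,
    shot_cap: int = DEFAULT_SHOT_CAP,
) -> str:
    """Simulate a single truel and return the surviving player's label.

    Each turn draws the target from :func:`target_distribution`, then a
    Bernoulli trial with the shooter's marksmanship (air shots never hit).
    """
    m = _as_marksmanship(m)
    table = _compile_sim_table(profile, m)
    survivor, _ = _play(table, (frozenset(PLAYERS), A), rng, shot_cap)
    return survivor


@dataclass(frozen=True)
class SimulationResult:
    """Outcome counts and survival estimates of ``n`` independent truels."""

    wins: Mapping[str, int]
    n: int
    estimates: SurvivalDistribution
    std_errors: tuple[float, float, float]
    seed: int
    max_shots: int

    def summary(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "wins": dict(self.wins),
            "estimates": dict(zip(("p_a", "p_b", "p_c"),
                                  self.estimates.as_tuple())),
            "std_errors": dict(zip(("p_a", "p_b", "p_c"), self.std_errors)),
            "max_shots": self.max_shots,
        }


def simulate(
    profile: StrategyProfile,
    m: "Marksmanship | Iterable[float]",
    n: int = 10**6,
    seed: int = 0,
    shot_cap: int = DEFAULT_SHOT_CAP,
) -> SimulationResult:
    """Estimate survival probabilities from ``n`` independent seeded games.

    Game ``i`` uses its own PCG64 stream spawned from
    ``SeedSequence(seed, spawn_key=(i,))``, so results are bit-reproducible
    and independent of execution order. The default ``n`` of one million
    matches the resolution the region maps were originally computed at;
    10^4–10^5 is plenty for desk-scale checks.
    """
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    m = _as_marksmanship(m)
    table = _compile_sim_table(profile, m)
    start = (frozenset(PLAYERS), A)
    wins = {A: 0, B: 0, C: 0}
    max_shots = 0
    for i in range(n):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(i,)))
        )
        survivor, shots = _play(table, start, rng, shot_cap)
        wins[survivor] += 1
        if shots > max_shots:
            max_shots = shots
    est = SurvivalDistribution(*(wins[p] / n for p in PLAYERS))
    se = tuple(math.sqrt(p * (1.0 - p) / n) for p in est.as_tuple())
    return SimulationResult(wins, n, est, se, seed, max_shots)


# --------------------------------------------------------------------------
# 5. Parameter sweeps and winner-region maps
# --------------------------------------------------------------------------

GRID_COLUMNS = ["a", "b", "c", "strategy", "method",
                "p_a", "p_b", "p_c", "winner"]


@dataclass(frozen=True)
class SweepSpec:
    """Grid sweep over (a, b) with 0 <= a <= b <= 1 at fixed c.

    ``step`` 0.02 (about 1,300 cells) is the desk-scale default; the original
    maps use 0.001. ``method`` is "exact" (Markov solver) or "monte_carlo"
    (``n`` games per cell). ``tie_tol`` defaults to 1e-12 for exact sweeps and
    0 for Monte-Carlo ones.
    """

    profile: StrategyProfile
    c: float = 1.0
    step: float = 0.02
    method: str = "exact"
    n: int = 10**5
    seed: int = 0
    tie_tol: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.step <= 1.0:
            raise ValueError(f"step must lie in (0, 1], got {self.step}")
        if not 0.0 < self.c <= 1.0:
            raise ValueError(f"c must lie in (0, 1], got {self.c}")
        if self.method not in ("exact", "monte_carlo"):
            raise ValueError(f"method must be 'exact' or 'monte_carlo', "
                             f"got {self.method!r}")

    @property
    def resolved_tie_tol(self) -> float:
        if self.tie_tol is not None:
            return self.tie_tol
        return 1e-12 if self.method == "exact" else 0.0

    def grid_values(self) -> np.ndarray:
        return np.round(np.arange(0.0, 1.0 + self.step / 2, self.step), 12)


def winner_map(spec: SweepSpec) -> pd.DataFrame:
    """Survival probabilities and strict-argmax winner for every grid cell.

    Cells whose (a, b, c) violate the ordering constraint (possible only when
    c < 1) are skipped with a warning. Monte-Carlo cells draw their seeds from
    ``SeedSequence(spec.seed, spawn_key=(cell index,))``.
    """
    vals = spec.grid_values()
    tol = spec.resolved_tie_tol
    records = []
    skipped = 0
    idx = 0
    for b in vals:
        for a in vals[vals <= b + 1e-12]:
            try:
                m = Marksmanship(float(a), float(b), spec.c)
            except ConstraintError:
                skipped += 1
                continue
            if spec.method == "exact":
                sd = exact_survival(spec.profile, m)
            else:
                cell_seed = int(
                    np.random.SeedSequence(
                        spec.seed, spawn_key=(idx,)
                    ).generate_state(1)[0]
                )
                sd = simulate(spec.profile, m, n=spec.n,
                              seed=cell_seed).estimates
            records.append((m.a, m.b, m.c, spec.profile.strategy.value,
                            spec.method, sd.p_a, sd.p_b, sd.p_c,
                            sd.winner(tol)))
            idx += 1
    if skipped:
        logger.warning("skipped %d grid cells with b > c = %g", skipped, spec.c)
    if not records:
        raise ValueError("sweep produced an empty grid")
    return pd.DataFrame.from_records(records, columns=GRID_COLUMNS)


@dataclass(frozen=True)
class RegionSummary:
    """Winner-region cell counts for one strategy's grid."""

    strategy: str
    cells_total: int
    cells_a: int
    cells_b: int
    cells_c: int
    cells_tie: int

    def fraction(self, label: str) -> float:
        count = {A: self.cells_a, B: self.cells_b,
                 C: self.cells_c, TIE: self.cells_tie}[label]
        return count / self.cells_total

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "cells_total": self.cells_total,
            "cells_a": self.cells_a,
            "cells_b": self.cells_b,
            "cells_c": self.cells_c,
            "cells_tie": self.cells_tie,
            "fraction_a": self.fraction(A),
            "fraction_b": self.fraction(B),
            "fraction_c": self.fraction(C),
            "fraction_tie": self.fraction(TIE),
        }


def region_summary(grid: pd.DataFrame) -> RegionSummary:
    """Tally winner labels of a grid produced by :func:`winner_map`."""
    if grid.empty:
        raise ValueError("cannot summarise an empty winner grid")
    counts = grid["winner"].value_counts()
    strategies = grid["strategy"].unique()
    strategy = strategies[0] if len(strategies) == 1 else "mixed"
    return RegionSummary(
        strategy=str(strategy),
        cells_total=int(len(grid)),
        cells_a=int(counts.get(A, 0)),
        cells_b=int(counts.get(B, 0)),
        cells_c=int(counts.get(C, 0)),
        cells_tie=int(counts.get(TIE, 0)),
    )


def compare_regions(
    spec1: SweepSpec, spec2: SweepSpec
) -> tuple[RegionSummary, RegionSummary]:
    """Region summaries for two strategies on the same grid geometry."""
    if spec1.c != spec2.c or spec1.step != spec2.step:
        raise ValueError(
            "region comparison requires identical grid geometry: "
            f"(c={spec1.c}, step={spec1.step}) vs (c={spec2.c}, step={spec2.step})"
        )
    return region_summary(winner_map(spec1)), region_summary(winner_map(spec2))


def write_winner_grid(grid: pd.DataFrame, path) -> None:
    """Write a winner grid as CSV with 12-significant-digit floats."""
    grid.to_csv(path, index=False, float_format="%.12g")


def read_winner_grid(path) -> pd.DataFrame:
    """Read back a winner grid written by :func:`write_winner_grid`."""
    grid = pd.read_csv(path, dtype={c: float for c in
                                    ("a", "b", "c", "p_a", "p_b", "p_c")})
    missing = set(GRID_COLUMNS) - set(grid.columns)
    if missing:
        raise ValueError(f"winner-grid CSV is missing columns: {sorted(missing)}")
    return grid[GRID_COLUMNS]
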