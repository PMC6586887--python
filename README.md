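# truel

Survival analysis for the **sequential truel** — the three-player
generalisation of the duel in which players A, B and C take turns firing one
shot each, in alphabetic order and skipping the dead, until a single player
is left standing.

Player X hits their chosen target with marksmanship probability
`0 ≤ a ≤ b ≤ c ≤ 1`, independently per shot. While all three are alive, B and
C always target their strongest live opponent (B fires at C, C fires at B).
Only the weakest player A chooses a strategy:

| strategy    | A's behaviour while both opponents are alive            |
|-------------|---------------------------------------------------------|
| `strongest` | fire at C                                               |
| `abstain`   | fire into the air (a guaranteed miss)                   |
| `suicide`   | fire at himself, hitting with probability `a`           |
| `target_b`  | fire at B                                               |
| `random2`   | target B or C uniformly at random                       |
| `random3`   | target himself, B or C uniformly at random              |
| `switch`    | each turn: suicide with probability `p`, else abstain   |

Once one opponent is dead every strategy collapses to firing at the sole
survivor, and the game reduces to an alternating duel whose first shooter
wins with probability `p₁ / (1 − (1−p₁)(1−p₂))`.

The package is for anyone studying "survival of the weakest" dynamics in
three-way conflicts (game theory, ecology of cyclic competition, opinion and
market models). It provides:

- **an exact solver** — the game is a finite absorbing Markov chain over
  (live set, shooter) states; absorption probabilities into each
  single-survivor state come from the linear system `(I − Q)x = R`;
- **closed forms** — a scenario decomposition of the suicidal strategy
  (`P_A = P(S_A1)P(S_A2) + P(S_A3)P(S_A4)`, with the cross terms involving
  the nested series `Σₙ yⁿ Σ_{k≤n} xᵏ = [1/(1−y) − x/(1−xy)]/(1−x)`), and the
  duel decomposition of abstention — both cross-validated against the solver;
- **a seeded Monte-Carlo simulator** with per-game PCG64 substreams
  (bit-reproducible, order-independent);
- **winner-region sweeps** over `(a, b)` at fixed `c`: per-cell survival
  probabilities, strict-argmax winner labels, and region-area summaries.

## Worked example

The weakest shot `(a, b, c) = (0.3, 0.5, 1.0)` playing the suicidal strategy:

```sh
$ truel exact --strategy suicide -a 0.3 -b 0.5 -c 1
p_a = 0.266538461538
p_b = 0.338461538462
p_c = 0.395
```

A survives 26.65% of games: he must first miss himself while B and C trade
shots (B removes C with probability 0.35, C removes B with 0.35, A dies by
his own hand with 0.30), then win the ensuing duel as first shooter (6/13
against B, 0.3 against C): `0.35·6/13 + 0.35·0.3 = 0.26654`. The simulator
agrees to within its binomial standard error:

```sh
$ truel simulate --strategy suicide -a 0.3 -b 0.5 -c 1 -n 100000 --seed 1
p_a = 0.266490 +/- 0.001398
p_b = 0.338090 +/- 0.001496
p_c = 0.395420 +/- 0.001546
n = 100000, seed = 1, max_shots = 29
```

Sweeping the `(a, b)` square at `c = 1` shows the strategy's catch — there is
*no* cell where the suicidal A is the outright favourite:

```sh
$ truel sweep --strategy suicide --step 0.02 --out grid.csv
{"strategy": "suicide", "cells_total": 1326, "cells_a": 0, "cells_b": 954,
 "cells_c": 371, "cells_tie": 1, ...}
```

whereas `--strategy abstain` gives A the largest region of all (547 of 1326
cells), and `--strategy switch` (a fair per-turn coin between suicide and
abstention) restores a 281-cell region. The same API is available in Python:

```python
from truel import StrategyProfile, SweepSpec, exact_survival, winner_map

exact_survival(StrategyProfile("abstain"), (0.3, 0.5, 1.0)).p_a  # 0.38077
grid = winner_map(SweepSpec(StrategyProfile("random2"), c=1.0, step=0.02))
```

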