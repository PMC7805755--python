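# rpdsim — evolution of automaton strategies in the repeated prisoner's dilemma

`rpdsim` is a research tool for studying how cooperation rises and falls
when strategies for the repeated prisoner's dilemma evolve in an
*unbounded* strategy space. It is aimed at evolutionary game theorists
and researchers in evolutionary computation who want simulations whose
output can be checked against game-theoretic predictions — in
particular, the prediction that no equilibrium is safe: every Nash
equilibrium can be toppled by an *indirect invasion*, a neutral mutant
drifting in and opening the door for a strategy with a strict advantage.

## The model

The stage game has payoffs T > R > P > S (here 3, 0, 4, 1 for R, S, T, P
by default) and continues after every round with probability δ, so a
match lasts i rounds with probability δ^(i−1)(1−δ). A pure strategy is a
finite state automaton (a Moore machine): each state carries an action
C or D and two transitions driven by the opponent's last action; state 0
moves first. Mutations can add and delete states, so the space is
unbounded and dense in the set of all deterministic repeated-game
strategies.

The package provides:

* **Exact payoffs.** Two machines with n and m states jointly occupy at
  most n·m states, so their play is a pre-period plus a cycle. The
  normalized discounted payoff Π(S,T) = (1−δ) Σ_t δ^(t−1) π_t is
  evaluated in closed form from that cycle decomposition (and exactly,
  in rational arithmetic, when equality comparisons matter). The δ = 1
  "limit of means" is the cycle average.
* **A Wright–Fisher simulator.** N individuals are randomly paired each
  generation, play one match (of sampled geometric length, or at its
  expected payoff in `exact` fitness mode), reproduce by roulette-wheel
  selection, and mutate with a small probability by one of four
  operations (add state / flip output / re-target transition / delete
  state, delete-biased to prevent bloat).
* **A Nash verifier ("best responder").** Playing against a fixed
  automaton is a Markov decision problem over its states; value
  iteration on V(i) = max_a {π(a, λ(i)) + δ V(μ(i,a))} yields the
  maximal payoff achievable against it and an automaton attaining it. A
  strategy is Nash iff its self-play payoff equals that maximum — both
  sides evaluated by the same payoff routine so rounding cancels.
* **Transition analysis.** Each logged generation is classified by the
  fewest strategies covering ≥90% of the population (pure / 2-mix /
  3-mix / other interior). Exits from pure Nash residents are followed
  through chains of neutral entrants (S_E) until a better (S_B) or worse
  (S_W) performer resolves them: one indirect invasion or one other
  path out of equilibrium.

## A worked example

```python
from rpdsim import (StageGame, make_named_strategy, discounted_payoff,
                    is_nash, compare_performers)

game = StageGame(R=3, S=0, T=4, P=1, delta=0.75)
tft, allc, alld = (make_named_strategy(n) for n in ("TFT", "ALLC", "ALLD"))

print(discounted_payoff(tft, tft, game))    # 3.0   mutual cooperation pays R
print(discounted_payoff(tft, alld, game))   # 0.75  one sucker round, then P
print(is_nash(tft, game).is_nash)           # True  (delta = 0.75 > 1/3)
print(is_nash(allc, game).is_nash)          # False (best response earns 4.0)
print(compare_performers(allc, tft, game))  # 'equal'  — a neutral mutant
print(compare_performers(alld, allc, game)) # 'better' — the door it opens
```

The three last lines are the indirect-invasion story in miniature: TFT
is an equilibrium, ALLC is its neutral mutant, and once ALLC is common
ALLD invades.

To watch it happen in a population, run the simulator and the analyzer
from the shell:

```sh
rpdsim simulate --pop-size 512 --delta 0.75 --payoffs 3,0,4,1 \
    --mut-rate 1e-4 --generations 200000 --seed 1 --fitness exact \
    --out log.csv
rpdsim analyze transitions log.csv --delta 0.75 --payoffs 3,0,4,1 \
    --threshold 0.9 --out report.json
```

The report tallies `indirect_invasions`, `other_paths`, and
`unclassified` exits, lists each exit's strategy chain, and gives
`nash_occupancy` — the (lower-bound) fraction of generations spent in a
pure Nash equilibrium.

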