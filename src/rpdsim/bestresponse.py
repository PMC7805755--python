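"""Best response against an automaton strategy, and Nash verification.

Playing against a fixed automaton S is a Markov decision problem whose
states are the states of S: the responder knows which state S is in,
chooses an action a, collects the stage payoff of a against S's action
in that state, and moves S to its successor state. Value iteration on

    V(i) = max_a { pi(a, output_S(i)) + delta * V(next_S(i, a)) }

converges for delta < 1 (a contraction); starting from V = 0 with
nonnegative stage payoffs the iterates increase monotonically to the
optimum. The discounted value (1-delta) * V*(0) is the maximal
normalized payoff achievable against S by *any* strategy, so S is a
Nash equilibrium iff its self-play payoff attains it.

To make that equality comparison robust, the verdict never compares the
iteration's value directly with a payoff: it extracts the best-response
automaton from the optimal policy and evaluates both the best response
against S and S against itself with the same closed-form payoff routine
(optionally in exact rational arithmetic), so both sides carry identical
rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fsa import Automaton, minimize
from .game import C, D, StageGame
from .payoffs import discounted_payoff


@dataclass(frozen=True)
class ValueIterationResult:
    """Optimal values and policy against a fixed automaton opponent.

    ``values[i]`` is the (unnormalized) optimal continuation value when the
    opponent is in state i; ``policy[i]`` the action attaining it.
    """

    values: tuple[float, ...]
    policy: tuple[str, ...]
    n_iterations: int
    sup_norm_gap: float


def value_iterate(s: Automaton, g: StageGame, tol: float = 1e-10) -> ValueIterationResult:
    """Solve the best-response problem against `s` by value iteration.

    Iterates from V = 0 until the sup-norm change falls below
    ``tol * (1-delta)/delta`` (the standard contraction bound certifying
    absolute accuracy <= tol) and the greedy policy is stable. Ties in
    the argmax are broken toward cooperation.
    """
    if g.delta >= 1:
        raise ValueError("value iteration requires delta < 1 (no contraction at 1)")
    if g.S < 0:
        raise ValueError(
            "stage payoffs must be nonnegative so that V = 0 starts below the optimum"
        )
    d = float(g.delta)
    pi_c = np.array([float(g.payoff(C, out)) for out in s.outputs])
    pi_d = np.array([float(g.payoff(D, out)) for out in s.outputs])
    nc = np.array(s.next_on_c)
    nd = np.array(s.next_on_d)
    values = np.zeros(s.n_states)
    threshold = np.inf if d == 0 else tol * (1.0 - d) / d
    policy = None
    n_iter = 0
    while True:
        n_iter += 1
        q_c = pi_c + d * values[nc]
        q_d = pi_d + d * values[nd]
        new_values = np.maximum(q_c, q_d)
        new_policy = np.where(q_c >= q_d, C, D)
        gap = float(np.max(np.abs(new_values - values)))
        stable = policy is not None and np.array_equal(new_policy, policy)
        values, policy = new_values, new_policy
        if gap < threshold and stable:
            break
    return ValueIterationResult(
        values=tuple(float(v) for v in values),
        policy=tuple(str(a) for a in policy),
        n_iterations=n_iter,
        sup_norm_gap=gap,
    )


def best_response_payoff(s: Automaton, g: StageGame, tol: float = 1e-10) -> float:
    """Maximal normalized payoff achievable against `s`: (1-delta) * V*(0)."""
    result = value_iterate(s, g, tol)
    return (1.0 - float(g.delta)) * result.values[0]


def best_response_automaton(s: Automaton, r: ValueIterationResult) -> Automaton:
    """An automaton implementing the optimal policy against `s`.

    One state per state of `s`: state i outputs the optimal action a*_i,
    and both transitions follow S's own move ``next_S(i, a*_i)`` — the
    responder tracks S's state deterministically and can ignore what it
    observes.
    """
    outputs = r.policy
    targets = tuple(
        s.next_on_c[i] if r.policy[i] == C else s.next_on_d[i]
        for i in range(s.n_states)
    )
    return Automaton(outputs, targets, targets)


@dataclass(frozen=True)
class NashVerdict:
    is_nash: bool
    self_payoff: float
    best_response_payoff: float
    best_response: Automaton
    exact: bool


def is_nash(
    s: Automaton, g: StageGame, exact: bool = False, tol: float = 1e-9
) -> NashVerdict:
    """Check whether the strategy implemented by `s` is a Nash equilibrium.

    Computes the best response BR by value iteration, then compares
    Pi(s, s) against Pi(BR, s) with the *same* closed-form payoff routine,
    so both numbers carry the same inaccuracies. With ``exact=True`` both
    payoffs are evaluated in rational arithmetic and compared exactly;
    otherwise a small absolute tolerance `tol` absorbs float rounding.
    The verdict depends only on the phenotype: `s` is minimized first.
    """
    phenotype = minimize(s)
    result = value_iterate(phenotype, g)
    br = minimize(best_response_automaton(phenotype, result))
    game = g.exact() if exact else g
    p_br = discounted_payoff(br, phenotype, game)
    p_self = discounted_payoff(phenotype, phenotype, game)
    margin = 0 if exact else tol
    return NashVerdict(
        is_nash=bool(p_self >= p_br - margin),
        self_payoff=float(p_self),
        best_response_payoff=float(p_br),
        best_response=br,
        exact=exact,
    )
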