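"""Exact payoffs for pairs of automaton strategies.

Two deterministic machines with n and m states can only be in n*m joint
states, so their joint play is eventually periodic: a finite pre-period
followed by a cycle that repeats forever. All payoff quantities are
computed in closed form from that decomposition:

* the expected normalized discounted payoff
  ``(1-delta) * sum_t delta^(t-1) * pi_t`` for ``delta < 1``;
* the limit-of-means payoff (average over the cycle) for ``delta = 1``;
* the realized payoff of a match truncated at a sampled geometric length.

All formulas work for exact `Fraction` arithmetic as well as floats: pass
``game.exact()`` to obtain payoffs free of rounding error (used for the
equality comparisons in Nash verification and neutrality tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fsa import Automaton
from .game import StageGame


@dataclass(frozen=True)
class CycleDecomposition:
    """Eventually-periodic joint play of two automata.

    ``preperiod`` holds the action pairs (own, opponent) of the rounds
    before the joint state first repeats; ``cycle`` holds the repeating
    block. Concatenating the pre-period with endless repetitions of the
    cycle reproduces the literal round-by-round play.
    """

    preperiod: tuple[tuple[str, str], ...]
    cycle: tuple[tuple[str, str], ...]

    def round_payoffs(self, g: StageGame):
        """Per-round stage payoff pairs ((to s, to t), ...) for pre-period and cycle."""
        pre = tuple(g.payoff_pair(a, b) for a, b in self.preperiod)
        cyc = tuple(g.payoff_pair(a, b) for a, b in self.cycle)
        return pre, cyc


def joint_play(s: Automaton, t: Automaton) -> CycleDecomposition:
    """Decompose the joint play of `s` against `t` into pre-period and cycle.

    Iterates the joint state (state of s, state of t) until the first
    repeat; deterministic, with cycle length at most
    ``s.n_states * t.n_states``.
    """
    seen: dict[tuple[int, int], int] = {}
    rounds: list[tuple[str, str]] = []
    i, j = 0, 0
    while (i, j) not in seen:
        seen[(i, j)] = len(rounds)
        a, b = s.outputs[i], t.outputs[j]
        rounds.append((a, b))
        i, j = s.step(i, b), t.step(j, a)
    start = seen[(i, j)]
    return CycleDecomposition(tuple(rounds[:start]), tuple(rounds[start:]))


def _discounted_from_decomposition(pre, cyc, delta):
    """(1-delta) * sum_t delta^(t-1) pi_t from per-round payoffs to one player."""
    one = delta**0  # 1 in the arithmetic of delta (int/float/Fraction)
    pre_sum = sum((delta**k) * pi for k, pi in enumerate(pre)) if pre else 0
    cyc_sum = sum((delta**k) * pi for k, pi in enumerate(cyc))
    p, c = len(pre), len(cyc)
    return (one - delta) * pre_sum + (delta**p) * (one - delta) / (
        one - delta**c
    ) * cyc_sum


def discounted_payoff(s: Automaton, t: Automaton, g: StageGame):
    """Expected normalized discounted payoff to `s` of playing `t`.

    This is ``(1-delta) * sum_{t>=1} delta^(t-1) pi_t``, evaluated exactly
    from the cycle decomposition; the value always lies in [S, T], and in
    [P, R] for self-play. Requires ``delta < 1``; for ``delta = 1`` use
    `limit_of_means_payoff`.
    """
    if g.delta == 1:
        raise ValueError(
            "discounted payoff undefined at delta = 1; use limit_of_means_payoff"
        )
    dec = joint_play(s, t)
    pre, cyc = dec.round_payoffs(g)
    return _discounted_from_decomposition(
        [p for p, _ in pre], [p for p, _ in cyc], g.delta
    )


def limit_of_means_payoff(s: Automaton, t: Automaton, g: StageGame):
    """Average stage payoff to `s` over the repeating cycle (pre-period ignored).

    This is the delta = 1 ("limit of means") payoff.
    """
    dec = joint_play(s, t)
    _, cyc = dec.round_payoffs(g)
    total = sum(p for p, _ in cyc)
    if isinstance(total, int):
        from fractions import Fraction

        return Fraction(total, len(cyc))
    return total / len(cyc)


def sample_rounds(delta: float, rng) -> int:
    """Sample a match length: P(i rounds) = delta^(i-1) * (1-delta), i >= 1."""
    if not 0 <= delta < 1:
        raise ValueError(f"delta must lie in [0, 1) to sample a finite length; got {delta}")
    return int(rng.geometric(1.0 - delta))


class PairPayoffs:
    """Cached payoff calculator for one ordered pair of strategies.

    Builds the cycle decomposition once and precomputes discounted prefix
    sums, so the expected payoff and the realized payoff of a match of any
    length are O(1) lookups. This is the performance lever of the
    simulator: populations contain few distinct phenotypes, so one
    instance per phenotype pair serves every match.
    """

    def __init__(self, s: Automaton, t: Automaton, g: StageGame):
        if g.delta >= 1:
            raise ValueError("PairPayoffs requires delta < 1")
        self.game = g
        dec = joint_play(s, t)
        self.decomposition = dec
        d = float(g.delta)
        pre, cyc = dec.round_payoffs(g)
        pre_s = [float(p) for p, _ in pre]
        pre_t = [float(q) for _, q in pre]
        cyc_s = [float(p) for p, _ in cyc]
        cyc_t = [float(q) for _, q in cyc]
        p, c = len(pre), len(cyc)
        self._p, self._c, self._d = p, c, d
        # Plain prefix sums of stage payoffs, for realized (truncated) matches:
        # _pre_prefix[k] = sum of the first k pre-period payoffs. Kept as
        # Python lists: realized() is called once per match in the inner
        # simulation loop and plain float arithmetic is fastest there.
        self._pre_prefix_s = np.concatenate([[0.0], np.cumsum(pre_s)]).tolist()
        self._pre_prefix_t = np.concatenate([[0.0], np.cumsum(pre_t)]).tolist()
        self._cyc_prefix_s = np.concatenate([[0.0], np.cumsum(cyc_s)]).tolist()
        self._cyc_prefix_t = np.concatenate([[0.0], np.cumsum(cyc_t)]).tolist()
        self.expected = (
            _discounted_from_decomposition(pre_s, cyc_s, d),
            _discounted_from_decomposition(pre_t, cyc_t, d),
        )

    def realized(self, n_rounds: int) -> tuple[float, float]:
        """Payoffs ``(1-delta) * sum_{t=1}^{n} pi_t`` of an n-round match.

        The sum is over realized (undiscounted) stage payoffs; the
        (1-delta) scaling makes its expectation over a geometric match
        length equal to the expected discounted payoff.
        """
        if n_rounds < 1:
            raise ValueError("a match has at least one round")
        n, p, c = n_rounds, self._p, self._c
        if n <= p:
            raw_s = self._pre_prefix_s[n]
            raw_t = self._pre_prefix_t[n]
        else:
            q, r = divmod(n - p, c)
            raw_s = self._pre_prefix_s[-1] + q * self._cyc_prefix_s[-1] + self._cyc_prefix_s[r]
            raw_t = self._pre_prefix_t[-1] + q * self._cyc_prefix_t[-1] + self._cyc_prefix_t[r]
        return (1.0 - self._d) * raw_s, (1.0 - self._d) * raw_t


def realized_match_payoffs(
    s: Automaton, t: Automaton, g: StageGame, n_rounds: int
) -> tuple[float, float]:
    """Realized normalized payoffs of one match of exactly `n_rounds` rounds.

    Scaled by (1-delta) so that the expectation over the geometric match
    length equals the expected discounted payoff of `discounted_payoff`.
    """
    return PairPayoffs(s, t, g).realized(n_rounds)
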