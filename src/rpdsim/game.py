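"""Stage-game parameterization of the repeated prisoner's dilemma.

The one-shot game is given by four payoffs ``R > P`` (reward, punishment)
and ``T > S`` (temptation, sucker) with the prisoner's-dilemma ordering
``T > R > P > S``, plus a continuation probability ``delta``: after every
round the match continues with probability delta, so match length is
geometric and expected payoffs are discounted sums.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from numbers import Real

C = "C"
D = "D"
ACTIONS = (C, D)


@dataclass(frozen=True)
class StageGame:
    """A prisoner's dilemma stage game plus continuation probability.

    Parameters
    ----------
    R, S, T, P
        Stage payoffs: mutual cooperation, sucker, temptation, mutual
        defection. Must satisfy ``T > R > P > S`` and all be >= 0 (fitness
        in the roulette-wheel selection step must be nonnegative).
    delta
        Per-round continuation probability in [0, 1]. ``delta == 1`` is
        only meaningful for limit-of-means payoffs.
    """

    R: Real
    S: Real
    T: Real
    P: Real
    delta: Real

    def __post_init__(self) -> None:
        if not (self.T > self.R > self.P > self.S):
            raise ValueError(
                "prisoner's dilemma ordering T > R > P > S violated: "
                f"T={self.T}, R={self.R}, P={self.P}, S={self.S}"
            )
        if self.S < 0:
            raise ValueError(
                "stage payoffs must be nonnegative (selection is "
                f"payoff-proportional); got S={self.S}"
            )
        if not (0 <= self.delta <= 1):
            raise ValueError(f"delta must lie in [0, 1]; got {self.delta}")

    def payoff(self, own: str, opponent: str) -> Real:
        """Stage payoff to a player choosing `own` against `opponent`."""
        if own == C:
            return self.R if opponent == C else self.S
        return self.T if opponent == C else self.P

    def payoff_pair(self, a: str, b: str) -> tuple[Real, Real]:
        """Stage payoffs to both players of the action pair (a, b)."""
        return self.payoff(a, b), self.payoff(b, a)

    def exact(self) -> "StageGame":
        """Return a copy with all numeric fields as exact `Fraction`s.

        Conversion from float is exact with respect to the binary float
        value (e.g. 0.75 becomes 3/4), so payoff comparisons done on the
        exact copy are free of rounding error.
        """
        return replace(
            self,
            R=Fraction(self.R),
            S=Fraction(self.S),
            T=Fraction(self.T),
            P=Fraction(self.P),
            delta=Fraction(self.delta),
        )
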