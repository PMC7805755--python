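"""Finite-state-automaton strategies for the repeated prisoner's dilemma.

A strategy is a Moore-style machine: every state carries an action
(C or D) that the player takes whenever the machine is in that state,
and two transitions saying which state to move to after observing the
opponent cooperate or defect. State 0 is always the initial state, so a
one-line machine ``D 0 0`` is the unconditional defector ALLD.

Because different machines can encode the same behaviour (the same
function from opponent histories to actions), the module also provides
Moore minimization and a canonical text key, so that populations can be
counted by *phenotype* (behaviour) rather than genotype (encoding).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

from .game import ACTIONS, C, D


@dataclass(frozen=True)
class Automaton:
    """A deterministic finite-state strategy machine.

    Fields are parallel tuples of length ``n_states``: ``outputs[i]`` is
    the action played in state ``i``; ``next_on_c[i]`` / ``next_on_d[i]``
    are the successor states after the opponent plays C / D. The initial
    state is index 0.
    """

    outputs: tuple[str, ...]
    next_on_c: tuple[int, ...]
    next_on_d: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "outputs", tuple(self.outputs))
        object.__setattr__(self, "next_on_c", tuple(int(i) for i in self.next_on_c))
        object.__setattr__(self, "next_on_d", tuple(int(i) for i in self.next_on_d))
        n = len(self.outputs)
        if n == 0:
            raise ValueError("automaton needs at least one state")
        if len(self.next_on_c) != n or len(self.next_on_d) != n:
            raise ValueError("outputs and transition tables must have equal length")
        for out in self.outputs:
            if out not in ACTIONS:
                raise ValueError(f"state output must be 'C' or 'D'; got {out!r}")
        for target in self.next_on_c + self.next_on_d:
            if not 0 <= target < n:
                raise ValueError(
                    f"transition target {target} out of range for {n} states"
                )

    @property
    def n_states(self) -> int:
        return len(self.outputs)

    def step(self, state: int, opponent_action: str) -> int:
        """Successor of `state` after the opponent plays `opponent_action`."""
        return self.next_on_c[state] if opponent_action == C else self.next_on_d[state]

    def respond(self, opponent_history: Iterable[str]) -> str:
        """Action taken after observing a (possibly empty) opponent history."""
        state = 0
        for action in opponent_history:
            state = self.step(state, action)
        return self.outputs[state]


def play_sequence(s: Automaton, t: Automaton, n_rounds: int) -> list[tuple[str, str]]:
    """Unfold n_rounds of literal joint play; round t is (action of s, action of t)."""
    i, j = 0, 0
    rounds = []
    for _ in range(n_rounds):
        a, b = s.outputs[i], t.outputs[j]
        rounds.append((a, b))
        i, j = s.step(i, b), t.step(j, a)
    return rounds


# ---------------------------------------------------------------------------
# Named strategies
# ---------------------------------------------------------------------------

def _named_table() -> dict[str, Automaton]:
    return {
        # Unconditional strategies.
        "ALLC": Automaton((C,), (0,), (0,)),
        "ALLD": Automaton((D,), (0,), (0,)),
        # Cooperates first, then repeats the opponent's previous move.
        "TFT": Automaton((C, D), (0, 0), (1, 1)),
        # Cooperates until the opponent defects once, then defects forever.
        "GRIM": Automaton((C, D), (0, 1), (1, 1)),
        # Suspicious tit-for-tat: defects first, mirrors afterwards.
        "STFT": Automaton((D, C), (1, 1), (0, 0)),
        # Cooperates twice unconditionally, mirrors afterwards (minimal form).
        "CTFT": Automaton((C, C, D), (1, 1, 1), (1, 2, 2)),
        # Win-stay lose-shift: repeats own move after R or T, switches after
        # P or S; deterministic memory-1 machine (1,1,0,0,1).
        "WSLS": Automaton((C, D), (0, 1), (1, 0)),
    }


NAMED_STRATEGIES = tuple(sorted(_named_table()))


def make_named_strategy(name: str) -> Automaton:
    """Return the minimal automaton for one of the classic named strategies.

    Recognized names: ALLC, ALLD, TFT, GRIM, STFT, CTFT, WSLS.
    """
    table = _named_table()
    key = name.strip().upper()
    if key not in table:
        raise ValueError(
            f"unknown strategy {name!r}; known strategies: {', '.join(sorted(table))}"
        )
    return table[key]


# ---------------------------------------------------------------------------
# Minimization and canonical keys
# ---------------------------------------------------------------------------

def _reachable_states(a: Automaton) -> list[int]:
    """States reachable from the initial state, in BFS order (C before D)."""
    seen = [0]
    seen_set = {0}
    queue = deque([0])
    while queue:
        i = queue.popleft()
        for target in (a.next_on_c[i], a.next_on_d[i]):
            if target not in seen_set:
                seen_set.add(target)
                seen.append(target)
                queue.append(target)
    return seen


def minimize(a: Automaton) -> Automaton:
    """The unique minimal automaton with the same behaviour as `a`.

    Unreachable states are dropped, behaviourally equivalent states are
    merged by Moore partition refinement (initial partition by output),
    and the result is renumbered canonically: breadth-first from the
    initial state, exploring the C-successor before the D-successor.
    Two automata implement the same strategy iff their minimized forms
    are structurally equal.
    """
    reach = _reachable_states(a)
    # Partition refinement over reachable states only.
    block = {i: a.outputs[i] for i in reach}
    while True:
        signature = {
            i: (block[i], block[a.next_on_c[i]], block[a.next_on_d[i]]) for i in reach
        }
        renamed = {sig: idx for idx, sig in enumerate(sorted(set(signature.values())))}
        new_block = {i: renamed[signature[i]] for i in reach}
        if len(set(new_block.values())) == len(set(block.values())):
            block = new_block
            break
        block = new_block

    # Canonical renumbering of the quotient machine: BFS from the block of
    # the initial state, C-transition before D-transition.
    rep = {}
    for i in reach:
        rep.setdefault(block[i], i)
    order: list[int] = []
    number: dict[int, int] = {}
    queue = deque([block[0]])
    number[block[0]] = 0
    order.append(block[0])
    while queue:
        b = queue.popleft()
        i = rep[b]
        for target_block in (block[a.next_on_c[i]], block[a.next_on_d[i]]):
            if target_block not in number:
                number[target_block] = len(order)
                order.append(target_block)
                queue.append(target_block)

    outputs = tuple(a.outputs[rep[b]] for b in order)
    next_c = tuple(number[block[a.next_on_c[rep[b]]]] for b in order)
    next_d = tuple(number[block[a.next_on_d[rep[b]]]] for b in order)
    return Automaton(outputs, next_c, next_d)


def _serialize(a: Automaton) -> str:
    return ";".join(
        f"{a.outputs[i]},{a.next_on_c[i]},{a.next_on_d[i]}" for i in range(a.n_states)
    )


@lru_cache(maxsize=65536)
def canonical_key(a: Automaton) -> str:
    """Canonical text key of the strategy `a` implements.

    The key is the serialization of the minimized, canonically numbered
    machine, one state per ``OUT,next_on_C,next_on_D`` triple joined by
    semicolons (ALLD is ``"D,0,0"``). Two automata get equal keys iff
    they implement the same strategy; `parse_key` inverts it.
    """
    return _serialize(minimize(a))


def parse_key(key: str) -> Automaton:
    """Rebuild the (minimal) automaton a canonical key serializes."""
    outputs, next_c, next_d = [], [], []
    for part in key.split(";"):
        fields = part.split(",")
        if len(fields) != 3:
            raise ValueError(f"malformed automaton key segment {part!r}")
        outputs.append(fields[0])
        next_c.append(int(fields[1]))
        next_d.append(int(fields[2]))
    return Automaton(tuple(outputs), tuple(next_c), tuple(next_d))


# ---------------------------------------------------------------------------
# Plain-text automaton files
# ---------------------------------------------------------------------------

def dumps_automaton(a: Automaton) -> str:
    """Automaton text format: one ``OUTPUT NEXT_ON_C NEXT_ON_D`` line per state."""
    return (
        "\n".join(
            f"{a.outputs[i]} {a.next_on_c[i]} {a.next_on_d[i]}"
            for i in range(a.n_states)
        )
        + "\n"
    )


def loads_automaton(text: str) -> Automaton:
    """Parse the automaton text format; line 0 is the initial state."""
    outputs, next_c, next_d = [], [], []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 3:
            raise ValueError(
                f"line {lineno}: expected 'OUTPUT NEXT_ON_C NEXT_ON_D', got {raw!r}"
            )
        out = fields[0].upper()
        if out not in ACTIONS:
            raise ValueError(f"line {lineno}: output must be C or D, got {fields[0]!r}")
        try:
            tc, td = int(fields[1]), int(fields[2])
        except ValueError as err:
            raise ValueError(f"line {lineno}: transitions must be integers") from err
        outputs.append(out)
        next_c.append(tc)
        next_d.append(td)
    if not outputs:
        raise ValueError("empty automaton file")
    try:
        return Automaton(tuple(outputs), tuple(next_c), tuple(next_d))
    except ValueError as err:
        raise ValueError(f"invalid automaton: {err}") from err


def read_automaton(path) -> Automaton:
    with open(path, "r", encoding="utf-8") as handle:
        return loads_automaton(handle.read())


def write_automaton(a: Automaton, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(dumps_automaton(a))


# ---------------------------------------------------------------------------
# Random machines (used by property tests and exploration)
# ---------------------------------------------------------------------------

def random_automaton(rng, max_states: int = 6) -> Automaton:
    """A uniformly random machine with 1..max_states states."""
    n = int(rng.integers(1, max_states + 1))
    outputs = tuple(C if rng.integers(2) == 0 else D for _ in range(n))
    next_c = tuple(int(x) for x in rng.integers(0, n, size=n))
    next_d = tuple(int(x) for x in rng.integers(0, n, size=n))
    return Automaton(outputs, next_c, next_d)


def enumerate_automata(max_states: int) -> list[Automaton]:
    """All machines with at most `max_states` states (initial state fixed at 0).

    The count grows as ``(2 n^2)^n`` per size n, so this is only meant for
    tiny sizes (used as an exhaustive best-response oracle for n <= 2).
    """
    machines = []
    for n in range(1, max_states + 1):
        for mask in range(2**n):
            outputs = tuple(C if (mask >> i) & 1 else D for i in range(n))
            for code in range(n ** (2 * n)):
                digits = []
                c = code
                for _ in range(2 * n):
                    digits.append(c % n)
                    c //= n
                next_c = tuple(digits[:n])
                next_d = tuple(digits[n:])
                machines.append(Automaton(outputs, next_c, next_d))
    return machines
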