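"""Classifying population states and counting paths out of equilibrium.

The simulator's raw output is a per-generation phenotype census. The
analysis proceeds in two steps.

*Step 1 — regions.* Each generation is classified by the minimum number
of strategies needed to cover a threshold share of the population
(default 90%): a *pure* state, a 2-mix, a 3-mix, or "other interior"
when even the top three fall short. The defining strategies are ordered
most- to least-popular. Merging consecutive identical labels turns a
noisy trajectory into a sequence of regions.

*Step 2 — exits.* For a resident pure strategy P that passes the Nash
check and was not itself reached by a neutral invasion, the chain of
subsequent entrants Q1, Q2, ... is followed. Entrants are compared with
the evolutionary performance sets: Q is a *neutral mutant* of P when
U(Q,P) = U(P,P) and U(Q,Q) = U(P,Q); *better* when U(Q,P) > U(P,P), or
the first comparison ties and U(Q,Q) > U(P,Q); *worse* symmetrically.
A maximal chain of neutral entrants ending in a better performer is one
*indirect invasion* — neutral mutants drift in and open the door to a
strategy with a strict advantage. A chain ending in a worse performer is
one *other path* out of equilibrium. Chains interrupted by unclassifiable
(other-interior) spans are tallied as *unclassified*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Sequence, Union

from .bestresponse import is_nash
from .fsa import Automaton, parse_key
from .game import StageGame
from .payoffs import discounted_payoff
from .evolution import SimulationLog

Mixture = Sequence[tuple[Automaton, float]]

WORSE, EQUAL, BETTER = "worse", "equal", "better"


@dataclass(frozen=True)
class RegionLabel:
    """Classification of one population state.

    ``kind`` is one of ``pure``, ``mix2``, ``mix3``, ``other_interior``;
    ``strategies`` holds the defining phenotype keys ordered most- to
    least-popular (empty for other_interior).
    """

    kind: str
    strategies: tuple[str, ...] = ()

    @property
    def n_strategies(self) -> int:
        return len(self.strategies)


@dataclass(frozen=True)
class RegionSpan:
    """A maximal run of consecutive generations sharing one label."""

    label: RegionLabel
    start: int  # first generation of the span
    stop: int  # one past the last generation

    @property
    def length(self) -> int:
        return self.stop - self.start


_KINDS = {1: "pure", 2: "mix2", 3: "mix3"}


def _validate_threshold(threshold: float, population_size: Optional[int] = None) -> None:
    if not 0.5 < threshold < 1:
        raise ValueError(
            f"threshold must lie strictly between 0.5 and 1; got {threshold}"
        )
    if population_size is not None and threshold >= (population_size - 1) / population_size:
        raise ValueError(
            f"threshold {threshold} leaves no corner pocket: it must be below "
            f"(N-1)/N = {(population_size - 1) / population_size} for N = {population_size}"
        )


def classify_state(
    freqs: Mapping[str, float], threshold: float = 0.9
) -> RegionLabel:
    """Label a population state by its most popular strategies.

    Strategies are ranked by frequency (ties broken by key order); the
    label is the smallest prefix of the ranking whose combined frequency
    reaches the threshold, capped at three strategies — beyond that the
    state is "other interior".
    """
    _validate_threshold(threshold)
    ranked = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
    cumulative = 0.0
    for rank, (key, freq) in enumerate(ranked, start=1):
        cumulative += freq
        if cumulative >= threshold - 1e-12:
            if rank <= 3:
                return RegionLabel(_KINDS[rank], tuple(k for k, _ in ranked[:rank]))
            break
    return RegionLabel("other_interior")


def compress_to_regions(
    log: SimulationLog, threshold: float = 0.9
) -> list[RegionSpan]:
    """Per-generation labels with consecutive duplicates merged.

    The returned spans tile the whole run.
    """
    n = log.config.get("population_size")
    _validate_threshold(threshold, n)
    bounds = log.generation_bounds()
    keys = log.phenotype_keys
    gen_col, pid_col, count_col = log.gen, log.pid, log.count
    pure_labels: dict[int, RegionLabel] = {}
    other_interior = RegionLabel("other_interior")
    spans: list[RegionSpan] = []
    prev_label: Optional[RegionLabel] = None
    start = 0
    for k in range(len(bounds) - 1):
        lo, hi = int(bounds[k]), int(bounds[k + 1])
        g = int(gen_col[lo])
        if hi - lo == 1:
            # Monomorphic generation: trivially a pure state.
            pid = int(pid_col[lo])
            label = pure_labels.get(pid)
            if label is None:
                label = RegionLabel("pure", (keys[pid],))
                pure_labels[pid] = label
        else:
            counts = count_col[lo:hi].tolist()
            ranked = sorted(
                zip(counts, (keys[p] for p in pid_col[lo:hi])),
                key=lambda cv: (-cv[0], cv[1]),
            )
            needed = threshold * sum(counts) - 1e-9
            cumulative = 0
            label = other_interior
            for rank, (cnt, key) in enumerate(ranked, start=1):
                cumulative += cnt
                if cumulative >= needed:
                    if rank <= 3:
                        label = RegionLabel(
                            _KINDS[rank], tuple(k for _, k in ranked[:rank])
                        )
                    break
        if label != prev_label:
            if prev_label is not None:
                spans.append(RegionSpan(prev_label, start, g))
            prev_label = label
            start = g
    if prev_label is not None:
        spans.append(RegionSpan(prev_label, start, log.n_generations))
    return spans


# ---------------------------------------------------------------------------
# Performance comparison (the S_W / S_E / S_B sets)
# ---------------------------------------------------------------------------


def _mixture_of(p: Union[Automaton, Mixture]):
    if isinstance(p, Automaton):
        return ((p, Fraction(1)),)
    return tuple((a, Fraction(w)) for a, w in p)


def compare_performers(
    q: Automaton,
    p: Union[Automaton, Mixture],
    g: StageGame,
    exact: bool = True,
    tol: float = 1e-9,
) -> str:
    """Place `q` in the worse/equal/better performer set against `p`.

    `p` may be a pure automaton or a mixture given as (automaton, weight)
    pairs; the payoff functional U extends linearly over the mixture. With
    ``exact=True`` (default) payoffs are evaluated in rational arithmetic
    and compared exactly; otherwise within absolute tolerance `tol`.
    """
    game = g.exact() if exact else g
    mix = _mixture_of(p)
    weights = [w for _, w in mix]
    if sum(weights) != 1 and abs(float(sum(weights)) - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")

    def U(a, b_mix):
        return sum(w * discounted_payoff(a, b, game) for b, w in b_mix)

    q_mix = ((q, Fraction(1)),)
    u_qp = U(q, mix)
    u_pp = sum(w * U(a, mix) for a, w in mix)
    u_qq = discounted_payoff(q, q, game)
    u_pq = sum(w * U(a, q_mix) for a, w in mix)

    def cmp(x, y):
        if exact:
            return (x > y) - (x < y)
        return 0 if abs(float(x) - float(y)) <= tol else (1 if x > y else -1)

    first = cmp(u_qp, u_pp)
    if first > 0:
        return BETTER
    if first < 0:
        return WORSE
    second = cmp(u_qq, u_pq)
    if second > 0:
        return BETTER
    if second < 0:
        return WORSE
    return EQUAL


# ---------------------------------------------------------------------------
# Exit-path counting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExitPathRecord:
    """One detected path out of a pure equilibrium.

    ``predecessor`` is the strategy O observed before the equilibrium P
    entered; ``chain`` is the observed entrant sequence Q1..Qn; the final
    entrant resolves the classification.
    """

    start_generation: int
    equilibrium: str
    predecessor: str
    chain: tuple[str, ...]
    classification: str  # indirect_invasion | other_path | unclassified


@dataclass
class ExitTally:
    indirect_invasions: int = 0
    other_paths: int = 0
    unclassified: int = 0
    records: list[ExitPathRecord] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.indirect_invasions + self.other_paths + self.unclassified


def count_exit_paths(
    spans: Sequence[RegionSpan],
    g: StageGame,
    exact: bool = True,
) -> ExitTally:
    """Count indirect invasions and other paths out of pure equilibria.

    The region sequence is walked once, event by event. A pure region
    whose resident P is Nash *establishes* an equilibrium, unless P was
    reached by a neutral invasion — then the running chain simply
    continues through it, so a whole stepping-stone sequence counts once.
    While an equilibrium is established, each entrant (the highest-ranked
    strategy of the new label absent from the old one) is compared with
    the last strategy of the chain: neutral entrants extend the chain, a
    better performer resolves it as one indirect invasion, a worse
    performer as one other path. A pure region of the resident itself
    discards an evaporated neutral excursion (the population never left
    the equilibrium); a pure region of a chain member truncates the chain
    to that member. Other-interior spans make an active exit unclassified.
    Chains still unresolved when the run ends are not counted as exits,
    and a mutant flickering around the threshold (the same resolution of
    the same equilibrium, repeatedly) is counted once per residency
    episode.
    """
    automata: dict[str, Automaton] = {}
    nash_cache: dict[str, bool] = {}
    compare_cache: dict[tuple[str, str], str] = {}

    def machine(key: str) -> Automaton:
        if key not in automata:
            automata[key] = parse_key(key)
        return automata[key]

    def is_equilibrium(key: str) -> bool:
        if key not in nash_cache:
            nash_cache[key] = is_nash(machine(key), g, exact=exact).is_nash
        return nash_cache[key]

    def compare(q_key: str, p_key: str) -> str:
        pair = (q_key, p_key)
        if pair not in compare_cache:
            compare_cache[pair] = compare_performers(
                machine(q_key), machine(p_key), g, exact=exact
            )
        return compare_cache[pair]

    tally = ExitTally()
    observed: list[str] = []  # every entrant / anchor strategy, in order
    p_key: Optional[str] = None  # established equilibrium, if any
    o_key = ""  # its observed predecessor
    p_generation = 0
    chain: list[str] = []  # neutral entrants since P
    episode_key: Optional[str] = None  # resident of the current episode
    counted: set[tuple[str, str]] = set()  # (P, final mutant) already counted

    def close(classification: Optional[str], final: Optional[str] = None) -> None:
        nonlocal p_key, chain
        if classification is not None and p_key is not None:
            # A mutant oscillating around the threshold flickers the label
            # between pure(P) and mix(P, mutant); that is one invasion
            # event, so an identical (P, final) resolution is counted only
            # once per residency episode.
            duplicate = final is not None and (p_key, final) in counted
            if not duplicate:
                if final is not None:
                    counted.add((p_key, final))
                full_chain = tuple(chain + ([final] if final else []))
                tally.records.append(
                    ExitPathRecord(
                        p_generation, p_key, o_key, full_chain, classification
                    )
                )
                if classification == "indirect_invasion":
                    tally.indirect_invasions += 1
                elif classification == "other_path":
                    tally.other_paths += 1
                else:
                    tally.unclassified += 1
        p_key = None
        chain = []

    def establish(key: str, generation: int) -> None:
        """Try to make `key` the established equilibrium at a pure region."""
        nonlocal p_key, o_key, p_generation, chain, episode_key
        if not is_equilibrium(key):
            p_key = None
            chain = []
            return
        predecessor = next((k for k in reversed(observed) if k != key), None)
        if predecessor is not None and compare(key, predecessor) == EQUAL:
            # Reached by a neutral invasion: not a new starting point.
            p_key = None
            chain = []
            return
        if key != episode_key:
            episode_key = key
            counted.clear()
        p_key = key
        o_key = predecessor or ""
        p_generation = generation
        chain = []

    for i, span in enumerate(spans):
        label = span.label
        if label.kind == "other_interior":
            if p_key is not None:
                close("unclassified")
            observed.clear()  # fresh anchor after an unclassifiable stretch
            episode_key = None
            counted.clear()
            continue

        if i == 0 or spans[i - 1].label.kind == "other_interior":
            anchor = label.strategies[0]
            observed.append(anchor)
            if label.kind == "pure":
                establish(anchor, span.start)
            continue

        prev_keys = set(spans[i - 1].label.strategies)
        entrant = next((k for k in label.strategies if k not in prev_keys), None)
        if entrant is not None:
            observed.append(entrant)
            if p_key is not None and entrant != p_key and entrant not in chain:
                # Re-entries of the resident or of an earlier chain member
                # (a strategy dipping below the threshold and back) are
                # drift within the already-observed set, not new mutants.
                verdict = compare(entrant, chain[-1] if chain else p_key)
                if verdict == EQUAL:
                    chain.append(entrant)
                elif verdict == BETTER:
                    close("indirect_invasion", final=entrant)
                else:
                    close("other_path", final=entrant)

        if label.kind == "pure":
            resident = label.strategies[0]
            if p_key is None:
                establish(resident, span.start)
            elif resident == p_key:
                chain = []  # neutral excursion evaporated; still at P
            elif chain and resident in chain:
                chain = chain[: chain.index(resident) + 1]
            # A pure region of the newest chain member keeps the chain as is.

    return tally


def nash_occupancy(
    spans: Sequence[RegionSpan], g: StageGame, exact: bool = True
) -> float:
    """Fraction of generations spent in pure regions whose resident is Nash.

    A lower bound on the time spent in equilibrium: mixed states cannot be
    certified (the best responder only works for pure strategies).
    """
    if g.delta >= 1:
        raise ValueError("Nash occupancy requires delta < 1")
    nash_cache: dict[str, bool] = {}
    total = 0
    in_nash = 0
    for span in spans:
        total += span.length
        if span.label.kind != "pure":
            continue
        key = span.label.strategies[0]
        if key not in nash_cache:
            nash_cache[key] = is_nash(parse_key(key), g, exact=exact).is_nash
        if nash_cache[key]:
            in_nash += span.length
    return in_nash / total if total else 0.0
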