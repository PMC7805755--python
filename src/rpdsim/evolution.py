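"""Wright-Fisher mutation-selection dynamics over automaton strategies.

A generation is a list of N machines (genotypes). Each generation:

1. all individuals are randomly matched in pairs;
2. each pair plays one repeated game — either a match of sampled
   geometric length (``fitness_mode="sampled"``) or its expectation, the
   exact discounted payoff (``fitness_mode="exact"``);
3. the next generation is drawn by roulette-wheel (Wright-Fisher)
   selection: N independent draws with replacement, probability
   proportional to payoff;
4. every individual mutates with a small probability, by exactly one of
   four operations: add a state, flip a state's output, re-target a
   transition, or delete a non-initial state.

The strategy space is unbounded — machines can grow without limit — but
the mutation kernel deletes states more often than it adds them, which
keeps genotype sizes stationary instead of bloating. Genotypes are never
minimized inside the population (added states are phenotypically neutral
raw material); minimization happens only when logging, where phenotypes
are counted by canonical key.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .fsa import Automaton, canonical_key, parse_key
from .game import C, D, StageGame
from .payoffs import PairPayoffs

# ---------------------------------------------------------------------------
# Mutation kernel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationKernel:
    """Per-individual mutation probability and the mix of the four operations.

    ``p_add < p_delete`` is required so that automaton sizes stabilize
    instead of growing indefinitely.
    """

    rate: float = 1e-4
    p_add: float = 0.20
    p_delete: float = 0.30
    p_change_output: float = 0.25
    p_change_transition: float = 0.25

    def __post_init__(self) -> None:
        probs = (self.p_add, self.p_delete, self.p_change_output, self.p_change_transition)
        if any(p < 0 for p in probs):
            raise ValueError("operation probabilities must be nonnegative")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError(f"operation probabilities must sum to 1; got {sum(probs)}")
        if not self.p_add < self.p_delete:
            raise ValueError(
                "p_add must be smaller than p_delete to keep automaton sizes bounded"
            )
        if not 0 <= self.rate <= 1:
            raise ValueError(f"mutation rate must lie in [0, 1]; got {self.rate}")


def add_state(a: Automaton, output: str, next_c: int, next_d: int) -> Automaton:
    """Append a state with the given output/transitions; existing wiring untouched.

    The new state is unreachable until a later transition mutation points
    at it, so this operation is phenotypically neutral.
    """
    n = a.n_states
    if not (0 <= next_c <= n and 0 <= next_d <= n):
        raise ValueError("new state's transitions must target an existing or the new state")
    return Automaton(
        a.outputs + (output,), a.next_on_c + (next_c,), a.next_on_d + (next_d,)
    )


def change_output(a: Automaton, state: int) -> Automaton:
    """Flip the action played in `state`."""
    outputs = list(a.outputs)
    outputs[state] = C if outputs[state] == D else D
    return Automaton(tuple(outputs), a.next_on_c, a.next_on_d)


def change_transition(a: Automaton, state: int, symbol: str, target: int) -> Automaton:
    """Re-target the transition of `state` on opponent action `symbol`."""
    if symbol == C:
        table = list(a.next_on_c)
        table[state] = target
        return Automaton(a.outputs, tuple(table), a.next_on_d)
    table = list(a.next_on_d)
    table[state] = target
    return Automaton(a.outputs, a.next_on_c, tuple(table))


def delete_state(a: Automaton, state: int, rng) -> Automaton:
    """Remove a non-initial `state`; dangling transitions are re-targeted
    uniformly at random among the surviving states."""
    if state == 0:
        raise ValueError("the initial state is never deleted")
    survivors = [i for i in range(a.n_states) if i != state]
    renumber = {old: new for new, old in enumerate(survivors)}

    def fix(target: int) -> int:
        if target == state:
            return int(rng.integers(0, len(survivors)))
        return renumber[target]

    outputs = tuple(a.outputs[i] for i in survivors)
    next_c = tuple(fix(a.next_on_c[i]) for i in survivors)
    next_d = tuple(fix(a.next_on_d[i]) for i in survivors)
    return Automaton(outputs, next_c, next_d)


def mutate(a: Automaton, kernel: MutationKernel, rng) -> Automaton:
    """Apply exactly one mutation operation, chosen by the kernel's mix.

    Deleting from a one-state machine is a no-op (the initial state is
    never deleted). Any machine can reach any other through a finite
    sequence of these operations, so the whole unbounded strategy space
    is explored with positive probability.
    """
    u = rng.random()
    if u < kernel.p_add:
        n = a.n_states
        output = C if rng.integers(2) == 0 else D
        return add_state(
            a, output, int(rng.integers(0, n + 1)), int(rng.integers(0, n + 1))
        )
    u -= kernel.p_add
    if u < kernel.p_delete:
        if a.n_states == 1:
            return a
        return delete_state(a, int(rng.integers(1, a.n_states)), rng)
    u -= kernel.p_delete
    if u < kernel.p_change_output:
        return change_output(a, int(rng.integers(0, a.n_states)))
    state = int(rng.integers(0, a.n_states))
    symbol = C if rng.integers(2) == 0 else D
    return change_transition(a, state, symbol, int(rng.integers(0, a.n_states)))


# ---------------------------------------------------------------------------
# Population, matching and selection
# ---------------------------------------------------------------------------


@dataclass
class Population:
    """An ordered list of N genotypes at some generation index."""

    members: list[Automaton]
    generation: int = 0

    def __post_init__(self) -> None:
        if len(self.members) % 2 != 0 or not self.members:
            raise ValueError(
                f"population size must be even and positive for pair matching; "
                f"got {len(self.members)}"
            )

    @property
    def size(self) -> int:
        return len(self.members)


def match_population(n: int, rng) -> np.ndarray:
    """A uniformly random perfect matching of n individuals.

    Returns an (n/2, 2) array of index pairs; every individual appears in
    exactly one pair.
    """
    if n % 2 != 0 or n <= 0:
        raise ValueError(f"pair matching requires an even, positive population; got {n}")
    return rng.permutation(n).reshape(-1, 2)


def wright_fisher_step(members: Sequence, fitnesses, rng) -> list:
    """Resample a whole generation with probability proportional to fitness.

    N independent draws with replacement (roulette-wheel selection). If
    every fitness is zero the draws are uniform. Fitnesses must be
    nonnegative.
    """
    fitnesses = np.asarray(fitnesses, dtype=float)
    if len(fitnesses) != len(members):
        raise ValueError("one fitness per member required")
    if np.any(fitnesses < 0):
        raise ValueError("fitnesses must be nonnegative for roulette-wheel selection")
    total = fitnesses.sum()
    if total == 0:
        idx = rng.integers(0, len(members), size=len(members))
    else:
        idx = rng.choice(len(members), size=len(members), p=fitnesses / total)
    return [members[i] for i in idx]


# ---------------------------------------------------------------------------
# Run configuration and log
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one simulation run (embedded in every log)."""

    population_size: int
    game: StageGame
    kernel: MutationKernel
    generations: int
    seed: int
    fitness_mode: str = "sampled"
    initial_strategy: str = "D,0,0"  # canonical key; the one-state defector

    def __post_init__(self) -> None:
        errors = []
        if self.population_size < 2 or self.population_size % 2 != 0:
            errors.append(
                f"population_size must be even and >= 2 (pair matching); "
                f"got {self.population_size}"
            )
        if self.generations < 0:
            errors.append(f"generations must be >= 0; got {self.generations}")
        if self.fitness_mode not in ("sampled", "exact"):
            errors.append(
                f"fitness_mode must be 'sampled' or 'exact'; got {self.fitness_mode!r}"
            )
        if self.game.delta >= 1:
            errors.append("delta must be < 1 for simulation (match lengths are finite)")
        try:
            parse_key(self.initial_strategy)
        except (ValueError, IndexError):
            errors.append(f"initial_strategy is not a valid automaton key: "
                          f"{self.initial_strategy!r}")
        if errors:
            raise ValueError("; ".join(errors))

    def to_dict(self) -> dict:
        return {
            "population_size": self.population_size,
            "R": float(self.game.R),
            "S": float(self.game.S),
            "T": float(self.game.T),
            "P": float(self.game.P),
            "delta": float(self.game.delta),
            "mutation_rate": self.kernel.rate,
            "p_add": self.kernel.p_add,
            "p_delete": self.kernel.p_delete,
            "p_change_output": self.kernel.p_change_output,
            "p_change_transition": self.kernel.p_change_transition,
            "generations": self.generations,
            "seed": self.seed,
            "fitness_mode": self.fitness_mode,
            "initial_strategy": self.initial_strategy,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(
            population_size=int(data["population_size"]),
            game=StageGame(
                R=data["R"], S=data["S"], T=data["T"], P=data["P"], delta=data["delta"]
            ),
            kernel=MutationKernel(
                rate=data["mutation_rate"],
                p_add=data.get("p_add", 0.20),
                p_delete=data.get("p_delete", 0.30),
                p_change_output=data.get("p_change_output", 0.25),
                p_change_transition=data.get("p_change_transition", 0.25),
            ),
            generations=int(data["generations"]),
            seed=int(data["seed"]),
            fitness_mode=data.get("fitness_mode", "sampled"),
            initial_strategy=data.get("initial_strategy", "D,0,0"),
        )


@dataclass
class SimulationLog:
    """Per-generation phenotype counts and mean payoffs, in columnar form.

    One row per (generation, phenotype): ``gen[k]``, ``pid[k]``,
    ``count[k]``, ``mean_payoff[k]``. ``phenotype_keys[pid]`` maps the
    integer phenotype id to its canonical key. Rows are ordered by
    generation, then by pid.
    """

    config: dict
    phenotype_keys: list[str]
    gen: np.ndarray
    pid: np.ndarray
    count: np.ndarray
    mean_payoff: np.ndarray
    # Mean number of genotype states per generation (one entry per
    # generation, NaN for synthetic logs). Genotypes can carry unreachable
    # or redundant states, so this differs from the phenotype sizes.
    genotype_size: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.genotype_size is None:
            self.genotype_size = np.full(self.n_generations, np.nan)

    @property
    def n_generations(self) -> int:
        return int(self.gen[-1]) + 1 if len(self.gen) else 0

    def keys_present(self) -> list[str]:
        return [self.phenotype_keys[p] for p in sorted(set(self.pid.tolist()))]

    def generation_bounds(self) -> np.ndarray:
        """Row index where each generation's block starts (plus end sentinel)."""
        starts = np.flatnonzero(np.diff(self.gen, prepend=self.gen[0] - 1))
        return np.append(starts, len(self.gen))

    def frequencies(self, generation: int) -> dict[str, float]:
        """Phenotype-key -> frequency map for one generation."""
        mask = self.gen == generation
        total = self.count[mask].sum()
        return {
            self.phenotype_keys[p]: c / total
            for p, c in zip(self.pid[mask], self.count[mask])
        }

    def mean_payoff_trace(self) -> np.ndarray:
        """Population mean payoff per generation."""
        n_gens = self.n_generations
        totals = np.zeros(n_gens)
        sizes = np.zeros(n_gens)
        np.add.at(totals, self.gen, self.count * self.mean_payoff)
        np.add.at(sizes, self.gen, self.count)
        return totals / sizes

    def mean_phenotype_size_trace(self) -> np.ndarray:
        """Mean number of states of the (minimized) phenotypes per generation."""
        sizes = np.array([k.count(";") + 1 for k in self.phenotype_keys])
        n_gens = self.n_generations
        totals = np.zeros(n_gens)
        ns = np.zeros(n_gens)
        np.add.at(totals, self.gen, self.count * sizes[self.pid])
        np.add.at(ns, self.gen, self.count)
        return totals / ns

    def equals(self, other: "SimulationLog") -> bool:
        """Content equality (phenotype ids may differ between instances)."""
        if self.config != other.config or len(self.gen) != len(other.gen):
            return False
        mine = [self.phenotype_keys[p] for p in self.pid]
        theirs = [other.phenotype_keys[p] for p in other.pid]
        return (
            mine == theirs
            and np.array_equal(self.gen, other.gen)
            and np.array_equal(self.count, other.count)
            and np.allclose(self.mean_payoff, other.mean_payoff, equal_nan=True)
            and np.allclose(self.genotype_size, other.genotype_size, equal_nan=True)
        )


# ---------------------------------------------------------------------------
# The simulator
# ---------------------------------------------------------------------------


class _Columns:
    """Append-only columnar buffer with amortized doubling."""

    def __init__(self) -> None:
        self._cap = 1024
        self._len = 0
        self.gen = np.empty(self._cap, dtype=np.int64)
        self.pid = np.empty(self._cap, dtype=np.int64)
        self.count = np.empty(self._cap, dtype=np.int64)
        self.payoff = np.empty(self._cap)

    def append(self, generation: int, pids, counts, payoffs) -> None:
        k = len(pids)
        while self._len + k > self._cap:
            self._cap *= 2
            for name in ("gen", "pid", "count", "payoff"):
                old = getattr(self, name)
                grown = np.empty(self._cap, dtype=old.dtype)
                grown[: self._len] = old[: self._len]
                setattr(self, name, grown)
        lo, hi = self._len, self._len + k
        self.gen[lo:hi] = generation
        self.pid[lo:hi] = pids
        self.count[lo:hi] = counts
        self.payoff[lo:hi] = payoffs
        self._len = hi

    def snapshot(self):
        n = self._len
        return (
            self.gen[:n].copy(),
            self.pid[:n].copy(),
            self.count[:n].copy(),
            self.payoff[:n].copy(),
        )


class Simulation:
    """A running Wright-Fisher simulation; supports incremental `run` calls.

    All randomness flows from a single generator seeded by the config, so
    a run is reproducible and chunked execution (``run(k)`` twice) gives
    byte-identical logs to a single ``run(2k)``.
    """

    def __init__(
        self, config: RunConfig, initial_population: Optional[Sequence[Automaton]] = None
    ):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.game = config.game
        n = config.population_size
        self.members = np.empty(n, dtype=object)
        self._keys: dict[str, int] = {}
        self._phenotypes: list[Automaton] = []
        if initial_population is None:
            initial = parse_key(config.initial_strategy)
            self.members[:] = initial
            self.pids = np.full(n, self._pid_of(initial), dtype=np.int64)
        else:
            if len(initial_population) != n:
                raise ValueError(
                    f"initial population has {len(initial_population)} members; "
                    f"config expects {n}"
                )
            self.members[:] = list(initial_population)
            self.pids = np.array(
                [self._pid_of(a) for a in initial_population], dtype=np.int64
            )
        self.sizes = np.array([a.n_states for a in self.members], dtype=np.int64)
        self._size_log: list[float] = []
        self._pair_cache: dict[tuple[int, int], PairPayoffs] = {}
        self._matrix_cache: dict[bytes, np.ndarray] = {}
        self.generation = 0
        self._log = _Columns()

    def _pid_of(self, genotype: Automaton) -> int:
        key = canonical_key(genotype)
        pid = self._keys.get(key)
        if pid is None:
            pid = len(self._phenotypes)
            self._keys[key] = pid
            self._phenotypes.append(parse_key(key))
        return pid

    def _pair_payoffs(self, p: int, q: int) -> PairPayoffs:
        pair = self._pair_cache.get((p, q))
        if pair is None:
            pair = PairPayoffs(self._phenotypes[p], self._phenotypes[q], self.game)
            self._pair_cache[(p, q)] = pair
            if p != q:
                # Mirror entry shares the decomposition work conceptually but
                # is cheap enough to build directly and keeps lookups O(1).
                self._pair_cache[(q, p)] = PairPayoffs(
                    self._phenotypes[q], self._phenotypes[p], self.game
                )
        return pair

    def _expected_matrix(self, present: np.ndarray) -> np.ndarray:
        """Matrix of expected payoffs between the phenotypes currently present."""
        key = present.tobytes()
        matrix = self._matrix_cache.get(key)
        if matrix is None:
            k = len(present)
            matrix = np.empty((k, k))
            for x in range(k):
                for y in range(k):
                    matrix[x, y] = self._pair_payoffs(
                        int(present[x]), int(present[y])
                    ).expected[0]
            self._matrix_cache[key] = matrix
        return matrix

    def step(self) -> None:
        """Advance one full generation: match, play, log, select, mutate."""
        n = self.config.population_size
        exact = self.config.fitness_mode == "exact"
        pid0 = int(self.pids[0])
        if exact and bool((self.pids == pid0).all()):
            # Monomorphic-phenotype fast path: every match is the same pairing
            # of identical phenotypes, so fitness is constant and selection
            # reduces to uniform resampling of the genotypes.
            payoff = self._pair_payoffs(pid0, pid0).expected[0]
            self._log.append(self.generation, (pid0,), (n,), (payoff,))
            self._size_log.append(self.sizes.mean())
            idx = self.rng.integers(0, n, size=n)
            self.members = self.members[idx]
            self.sizes = self.sizes[idx]
        else:
            order = match_population(n, self.rng).ravel()
            first, second = order[0::2], order[1::2]
            present, local = np.unique(self.pids, return_inverse=True)
            fitness = np.empty(n)
            if exact:
                matrix = self._expected_matrix(present)
                fitness[first] = matrix[local[first], local[second]]
                fitness[second] = matrix[local[second], local[first]]
            else:
                lengths = self.rng.geometric(
                    1.0 - float(self.game.delta), size=len(first)
                )
                pids = self.pids
                for k in range(len(first)):
                    i, j = first[k], second[k]
                    pair = self._pair_payoffs(int(pids[i]), int(pids[j]))
                    fitness[i], fitness[j] = pair.realized(int(lengths[k]))

            # Log the composition and per-phenotype mean payoffs.
            counts = np.bincount(local)
            sums = np.zeros(len(present))
            np.add.at(sums, local, fitness)
            self._log.append(self.generation, present, counts, sums / counts)
            self._size_log.append(self.sizes.mean())

            # Selection (roulette wheel / Wright-Fisher): N independent draws
            # with probability proportional to fitness, via the inverse CDF.
            cdf = np.cumsum(fitness)
            total = cdf[-1]
            if total == 0:
                idx = self.rng.integers(0, n, size=n)
            else:
                idx = np.searchsorted(cdf, self.rng.random(n) * total, side="right")
            self.members = self.members[idx]
            self.pids = self.pids[idx]
            self.sizes = self.sizes[idx]

        # Mutation: each individual mutates independently with the kernel rate.
        n_mut = self.rng.binomial(n, self.config.kernel.rate)
        if n_mut:
            hits = self.rng.choice(n, size=n_mut, replace=False)
            for i in hits:
                mutant = mutate(self.members[i], self.config.kernel, self.rng)
                self.members[i] = mutant
                self.pids[i] = self._pid_of(mutant)
                self.sizes[i] = mutant.n_states

        self.generation += 1

    def run(self, n_generations: Optional[int] = None) -> None:
        if n_generations is None:
            n_generations = self.config.generations
        for _ in range(n_generations):
            self.step()

    def log(self) -> SimulationLog:
        """Snapshot of everything logged so far."""
        gen, pid, count, payoff = self._log.snapshot()
        return SimulationLog(
            config=self.config.to_dict(),
            phenotype_keys=list(self._keys),
            gen=gen,
            pid=pid,
            count=count,
            mean_payoff=payoff,
            genotype_size=np.array(self._size_log),
        )


def run_simulation(config: RunConfig) -> SimulationLog:
    """Run `config.generations` generations and return the log.

    The log covers generations 0 .. generations-1 (composition and payoffs
    are recorded before each selection step).
    """
    sim = Simulation(config)
    sim.run()
    return sim.log()
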