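"""The headline experiment: how do populations leave equilibria?

Runs the Wright-Fisher simulation at the reference study conditions
(N = 512, delta = 0.75, payoffs R,S,T,P = 3,0,4,1, per-individual
mutation probability 1e-4, all-defector start) and classifies every
qualifying exit from a pure Nash equilibrium as an indirect invasion or
another kind of path out.

Equilibrium exits are rare events — a handful per million generations at
these conditions — so the driver runs in chunks and stops once enough
exits have accumulated for a meaningful proportion (or at a generation
cap). Exact-fitness mode is used: it evaluates every match at its
expected payoff, removing match-length noise while keeping matching
noise and drift, and makes long runs affordable through payoff caching.
"""

from __future__ import annotations

from dataclasses import dataclass

from .evolution import MutationKernel, RunConfig, Simulation, SimulationLog
from .game import StageGame
from .transitions import ExitTally, compress_to_regions, count_exit_paths

REFERENCE_GAME = dict(R=3.0, S=0.0, T=4.0, P=1.0, delta=0.75)
REFERENCE_POPULATION = 512
REFERENCE_MUTATION_RATE = 1e-4


@dataclass
class StudyResult:
    """Outcome of one invasion-counting run."""

    log: SimulationLog
    tally: ExitTally
    generations: int
    indirect_fraction: float  # of all detected qualifying exits
    payoff_low: float  # minimum of the mean-payoff trace
    payoff_high: float  # maximum of the mean-payoff trace


def reference_config(
    seed: int,
    generations: int,
    population_size: int = REFERENCE_POPULATION,
    mutation_rate: float = REFERENCE_MUTATION_RATE,
    fitness_mode: str = "exact",
) -> RunConfig:
    """The reference study conditions as a run configuration."""
    return RunConfig(
        population_size=population_size,
        game=StageGame(**REFERENCE_GAME),
        kernel=MutationKernel(rate=mutation_rate),
        generations=generations,
        seed=seed,
        fitness_mode=fitness_mode,
    )


def run_invasion_study(
    seed: int,
    min_exits: int = 10,
    max_generations: int = 12_000_000,
    chunk: int = 500_000,
    threshold: float = 0.9,
) -> StudyResult:
    """Run until at least `min_exits` qualifying equilibrium exits are seen.

    The simulation advances in chunks; after each chunk the full log is
    compressed to regions and exits are re-counted. The run stops when
    `min_exits` exits have been detected and the mean-payoff trace has
    visited both the defection band (< 1.5) and the cooperation band
    (> 2.5), or when `max_generations` is reached. Chunked execution is
    deterministic: the trajectory is identical to a single long run with
    the same seed.
    """
    config = reference_config(seed, generations=max_generations)
    sim = Simulation(config)
    game = config.game
    while True:
        remaining = max_generations - sim.generation
        sim.run(min(chunk, remaining))
        log = sim.log()
        spans = compress_to_regions(log, threshold)
        tally = count_exit_paths(spans, game)
        trace = log.mean_payoff_trace()
        low, high = float(trace.min()), float(trace.max())
        done = tally.total >= min_exits and low < 1.5 and high > 2.5
        if done or sim.generation >= max_generations:
            fraction = (
                tally.indirect_invasions / tally.total if tally.total else float("nan")
            )
            return StudyResult(
                log=log,
                tally=tally,
                generations=sim.generation,
                indirect_fraction=fraction,
                payoff_low=low,
                payoff_high=high,
            )
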