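"""Log serialization, run configuration files, and scripted fixture logs.

Simulation logs are CSV files with one row per (generation, phenotype)
and a JSON config header in ``#`` comment lines — streamable, diff-able,
and loadable back into a `SimulationLog` without loss.
"""

from __future__ import annotations

import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .evolution import MutationKernel, RunConfig, SimulationLog
from .game import StageGame

_HEADER_PREFIX = "# config: "


def write_log(log: SimulationLog, path) -> None:
    """Write a simulation log as CSV with a JSON config header line."""
    frame = pd.DataFrame(
        {
            "generation": log.gen,
            "phenotype_key": [log.phenotype_keys[p] for p in log.pid],
            "count": log.count,
            "mean_payoff": log.mean_payoff,
            "mean_genotype_size": log.genotype_size[log.gen],
        }
    )
    with open(path, "w", encoding="utf-8", newline="") as handle:
        handle.write(_HEADER_PREFIX + json.dumps(log.config, sort_keys=True) + "\n")
        frame.to_csv(handle, index=False)


def read_log(path) -> SimulationLog:
    """Read a log written by `write_log` (or any CSV with the same schema)."""
    config: dict = {}
    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            if not line.startswith("#"):
                break
            if line.startswith(_HEADER_PREFIX):
                config = json.loads(line[len(_HEADER_PREFIX):])
    frame = pd.read_csv(path, comment="#")
    keys: list[str] = []
    index: dict[str, int] = {}
    pids = np.empty(len(frame), dtype=np.int64)
    for row, key in enumerate(frame["phenotype_key"]):
        pid = index.get(key)
        if pid is None:
            pid = len(keys)
            index[key] = pid
            keys.append(key)
        pids[row] = pid
    gen = frame["generation"].to_numpy(dtype=np.int64)
    if "mean_genotype_size" in frame.columns and len(gen):
        per_row = frame["mean_genotype_size"].to_numpy(dtype=float)
        genotype_size = np.full(int(gen[-1]) + 1, np.nan)
        genotype_size[gen] = per_row  # last write per generation; identical by schema
    else:
        genotype_size = None
    return SimulationLog(
        config=config,
        phenotype_keys=keys,
        gen=gen,
        pid=pids,
        count=frame["count"].to_numpy(dtype=np.int64),
        mean_payoff=frame["mean_payoff"].to_numpy(dtype=float),
        genotype_size=genotype_size,
    )


# ---------------------------------------------------------------------------
# Configuration files
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = {
    "population_size",
    "R",
    "S",
    "T",
    "P",
    "delta",
    "mutation_rate",
    "p_add",
    "p_delete",
    "p_change_output",
    "p_change_transition",
    "generations",
    "seed",
    "fitness_mode",
    "initial_strategy",
}

_REQUIRED = {
    "population_size",
    "R",
    "S",
    "T",
    "P",
    "delta",
    "mutation_rate",
    "generations",
    "seed",
}


def load_config(path=None, overrides: Mapping | None = None) -> RunConfig:
    """Build a validated `RunConfig` from a YAML/JSON file and/or overrides.

    Flag-style overrides take precedence over the file. All missing or
    invalid fields are reported together in a single error.
    """
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as handle:
            loaded = yaml.safe_load(handle) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})

    errors = [f"unknown config field: {k}" for k in sorted(set(data) - _CONFIG_FIELDS)]
    errors += [f"missing config field: {k}" for k in sorted(_REQUIRED - set(data))]
    if errors:
        raise ValueError("; ".join(errors))

    try:
        game = StageGame(
            R=data["R"], S=data["S"], T=data["T"], P=data["P"], delta=data["delta"]
        )
    except ValueError as err:
        raise ValueError(str(err)) from err
    kernel = MutationKernel(
        rate=data["mutation_rate"],
        p_add=data.get("p_add", 0.20),
        p_delete=data.get("p_delete", 0.30),
        p_change_output=data.get("p_change_output", 0.25),
        p_change_transition=data.get("p_change_transition", 0.25),
    )
    return RunConfig(
        population_size=int(data["population_size"]),
        game=game,
        kernel=kernel,
        generations=int(data["generations"]),
        seed=int(data["seed"]),
        fitness_mode=data.get("fitness_mode", "sampled"),
        initial_strategy=data.get("initial_strategy", "D,0,0"),
    )


# ---------------------------------------------------------------------------
# Scripted fixture logs
# ---------------------------------------------------------------------------


def make_fixture_log(
    script: Sequence[tuple[Mapping[str, float], int]],
    population_size: int = 100,
    config: Mapping | None = None,
) -> SimulationLog:
    """Build a synthetic log realizing a scripted trajectory exactly.

    `script` is a list of (phenotype-key -> frequency map, span length)
    entries; each map must sum to 1 and produce integer counts at the
    given population size. Useful for testing the transition analysis on
    hand-written trajectories.
    """
    gens, pids, counts = [], [], []
    keys: list[str] = []
    index: dict[str, int] = {}
    generation = 0
    for freqs, span in script:
        if span < 1:
            raise ValueError("span lengths must be positive")
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies must sum to 1; got {total}")
        block = []
        for key, freq in freqs.items():
            count = freq * population_size
            if abs(count - round(count)) > 1e-6:
                raise ValueError(
                    f"frequency {freq} of {key!r} is not an integer count "
                    f"at population size {population_size}"
                )
            if round(count) == 0:
                continue
            pid = index.get(key)
            if pid is None:
                pid = len(keys)
                index[key] = pid
                keys.append(key)
            block.append((pid, int(round(count))))
        block.sort()
        for g in range(generation, generation + span):
            for pid, count in block:
                gens.append(g)
                pids.append(pid)
                counts.append(count)
        generation += span
    full_config = {"population_size": population_size, "fixture": True}
    if config:
        full_config.update(config)
    return SimulationLog(
        config=full_config,
        phenotype_keys=keys,
        gen=np.array(gens, dtype=np.int64),
        pid=np.array(pids, dtype=np.int64),
        count=np.array(counts, dtype=np.int64),
        mean_payoff=np.full(len(gens), np.nan),
    )
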