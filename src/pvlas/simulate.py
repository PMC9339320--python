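"""Multi-generation breeding-program engine.

Each simulated program iterates initialization → selection →
reproduction for ``T`` generations: a mating plan of ``S`` crosses is
chosen by the configured strategy (CGS, LAS or PV-LAS), each cross
produces ``N / S`` progeny, and four criteria are recorded on every
fresh progeny generation: mean GEBV, lower and upper genetic potential,
and best GEBV (all net of the overall mean ``mu``, as the criteria are
functions of allele content only).  At the end of a run the realized
per-generation best GEBVs are discounted into a single present value.

LAS uses a shrinking horizon (``T - t`` generations remain until the
fixed deadline), whereas PV-LAS always looks ``W`` generations ahead —
that asymmetry is the central design difference between the methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .core import (
    GainLedger,
    GeneticMap,
    GenotypeTensor,
    TraitModel,
    aggregate_blocks,
    gebv,
    lower_potential,
    present_value_of_gains,
    upper_potential,
)
from .errors import ConstraintError
from .meiosis import LookAheadSpec, make_progeny
from .optimize import MatingPlan, check_feasibility, select_with_method

__all__ = [
    "ProgramConfig",
    "run_generation",
    "run_program",
    "run_replicates",
    "run_sweep",
    "founder_sampler_from_pool",
]

logger = logging.getLogger("pvlas")

METRIC_COLUMNS = [
    "replicate", "generation", "method",
    "mean_gebv", "lower_potential", "upper_potential", "best_gebv", "pv",
]


@dataclass
class ProgramConfig:
    """Configuration of one breeding program.

    ``N`` individuals per generation, ``S`` crosses per cycle (``S``
    must divide ``N``), ``T`` generations, selection ``method`` in
    {cgs, las, pvlas} with look-ahead parameters ``spec``.  ``n_blocks``
    optionally aggregates SNPs into recombination blocks before
    objective evaluation.  ``eval_discount`` is the rate used when
    scoring realized gains (defaults to the objective's own rate).
    """

    N: int = 200
    S: int = 10
    T: int = 10
    method: str = "pvlas"
    spec: LookAheadSpec = field(default_factory=LookAheadSpec)
    n_replicates: int = 1
    seed: int = 0
    n_blocks: int | None = None
    eval_discount: float | None = None
    max_stall_passes: int = 3

    def __post_init__(self):
        if self.N % self.S != 0:
            raise ConstraintError(f"S={self.S} must divide N={self.N}")
        if self.T < 1 or self.n_replicates < 1:
            raise ValueError("T and n_replicates must be >= 1")
        if self.method not in ("cgs", "las", "pvlas"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def progeny_per_cross(self) -> int:
        return self.N // self.S

    @property
    def evaluation_discount(self) -> float:
        return self.spec.discount if self.eval_discount is None else self.eval_discount


def _metrics_row(population: GenotypeTensor, trait: TraitModel) -> dict:
    """The four evaluation criteria on one population (net of mu)."""
    v = gebv(population, trait) - trait.mu
    return {
        "mean_gebv": float(v.mean()),
        "lower_potential": lower_potential(population, trait),
        "upper_potential": upper_potential(population, trait),
        "best_gebv": float(v.max()),
    }


def run_generation(
    population: GenotypeTensor,
    trait: TraitModel,
    gmap: GeneticMap,
    config: ProgramConfig,
    horizon: int,
    rng: np.random.Generator,
) -> tuple[GenotypeTensor, MatingPlan, dict]:
    """One selection + reproduction cycle.

    Selects a plan (LAS at the remaining ``horizon``; PV-LAS over its
    window), makes each cross produce exactly ``N / S`` progeny, and
    returns the new population with its metrics row.
    """
    blocked = None
    if config.n_blocks is not None and config.method in ("las", "pvlas"):
        blocked = aggregate_blocks(population, trait, gmap, config.n_blocks)
    plan = select_with_method(
        population, trait, gmap, config.method, config.S, config.spec, rng,
        horizon=horizon, blocked=blocked, max_stall_passes=config.max_stall_passes,
    )
    violations = check_feasibility(plan, population.n_individuals, config.S)
    if violations:
        raise ConstraintError(f"selector emitted an infeasible plan: {violations}")
    offspring = []
    for idx, pair in enumerate(plan.pairs):
        offspring.append(
            make_progeny(
                population, pair, config.progeny_per_cross, gmap, rng,
                id_prefix=f"G{population.generation + 1}.c{idx}",
            )
        )
    alleles = np.concatenate([o.alleles for o in offspring], axis=2)
    ids = [name for o in offspring for name in o.individual_ids]
    next_population = GenotypeTensor(alleles, ids, generation=population.generation + 1)
    row = _metrics_row(next_population, trait)
    return next_population, plan, row


def run_program(
    config: ProgramConfig,
    founders: GenotypeTensor,
    trait: TraitModel,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Run ``T`` generations from a founder population.

    Returns one metrics row per generation; the ``pv`` column holds the
    run's present value of realized per-generation best GEBVs
    (constant within the run).
    """
    population = founders
    rows = []
    for step in range(config.T):
        horizon = config.T - step  # generations remaining until the deadline
        population, plan, row = run_generation(
            population, trait, gmap, config, horizon, rng
        )
        row["generation"] = step + 1
        rows.append(row)
        logger.info(
            "generation %d/%d method=%s best=%.4f mean=%.4f",
            step + 1, config.T, config.method, row["best_gebv"], row["mean_gebv"],
        )
    table = pd.DataFrame(rows)
    ledger = GainLedger(
        per_generation_best=table["best_gebv"].to_numpy(),
        discount=config.evaluation_discount,
    )
    table["pv"] = present_value_of_gains(ledger)
    table["method"] = config.method
    return table


def founder_sampler_from_pool(
    pool: GenotypeTensor, N: int
) -> Callable[[np.random.Generator], GenotypeTensor]:
    """Founder sampler drawing ``N`` individuals from a fixed panel —
    without replacement when the panel is large enough, with
    replacement otherwise."""

    def sampler(rng: np.random.Generator) -> GenotypeTensor:
        replace_draw = pool.n_individuals < N
        idx = rng.choice(pool.n_individuals, size=N, replace=replace_draw)
        alleles = pool.alleles[:, :, idx]
        ids = [f"R{k}_{pool.individual_ids[i]}" for k, i in enumerate(idx)]
        return GenotypeTensor(alleles, ids, generation=0)

    return sampler


def _replicate_seeds(master_seed: int, n: int) -> list[tuple[int, int]]:
    """Per-replicate (founder, program) seeds.  Founder seeds depend only
    on the master seed and replicate index, so different methods run on
    common founders when given the same master seed."""
    ss = np.random.SeedSequence(master_seed)
    out = []
    for r, child in enumerate(ss.spawn(n)):
        founder_seed, program_seed = child.generate_state(2, dtype=np.uint32)
        out.append((int(founder_seed), int(program_seed)))
    return out


def run_replicates(
    config: ProgramConfig,
    founder_sampler: Callable[[np.random.Generator], GenotypeTensor],
    trait: TraitModel,
    gmap: GeneticMap,
    stream: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Independent replicates of one program configuration.

    Founders are redrawn per replicate by ``founder_sampler``; replicate
    seeds derive deterministically from ``config.seed``.  ``stream``
    offsets the within-program random stream without touching founder
    draws: arms of a paired experiment can share founders yet evolve
    under independent program noise (stream 0 for every arm instead
    yields fully common random numbers).  Returns the stacked metrics
    table and a summary with the per-generation mean trajectory and the
    empirical CDF of the replicate present values.
    """
    tables = []
    for r, (founder_seed, program_seed) in enumerate(
        _replicate_seeds(config.seed, config.n_replicates)
    ):
        founders = founder_sampler(np.random.default_rng(founder_seed))
        program_key = program_seed if stream == 0 else (program_seed, stream)
        table = run_program(
            config, founders, trait, gmap, np.random.default_rng(program_key)
        )
        table["replicate"] = r
        tables.append(table)
        logger.info("replicate %d/%d (%s) done", r + 1, config.n_replicates, config.method)
    metrics = pd.concat(tables, ignore_index=True)[METRIC_COLUMNS]
    pv = metrics.groupby("replicate")["pv"].first().to_numpy()
    pv_sorted = np.sort(pv)
    summary = {
        "method": config.method,
        "n_replicates": config.n_replicates,
        "mean_trajectory": metrics.groupby("generation")[
            ["mean_gebv", "lower_potential", "upper_potential", "best_gebv"]
        ].mean().reset_index().to_dict(orient="list"),
        "mean_pv": float(pv.mean()),
        "pv_ecdf": {
            "value": pv_sorted.tolist(),
            "prob": ((np.arange(pv.size) + 1) / pv.size).tolist(),
        },
    }
    return metrics, summary


def run_sweep(
    config: ProgramConfig,
    parameter: str,
    values: list,
    founder_sampler: Callable[[np.random.Generator], GenotypeTensor],
    trait: TraitModel,
    gmap: GeneticMap,
) -> pd.DataFrame:
    """Sensitivity sweep over the window length ``W`` (benchmark
    ``W = 1``) or the discount rate (benchmark 0, window as
    configured).  All arms share founder seeds (same master seed), and
    the table reports per-generation mean-GEBV differences from the
    benchmark arm."""
    if parameter not in ("W", "lambda"):
        raise ValueError("parameter must be 'W' or 'lambda'")
    benchmark = 1 if parameter == "W" else 0.0
    arm_values = list(values)
    if benchmark not in arm_values:
        arm_values = [benchmark] + arm_values

    arms = {}
    for value in arm_values:
        if parameter == "W":
            spec = replace(config.spec, W=int(value))
        else:
            spec = replace(config.spec, discount=float(value))
        arm_config = replace(config, spec=spec)
        metrics, _ = run_replicates(arm_config, founder_sampler, trait, gmap)
        arms[value] = metrics.groupby("generation")["mean_gebv"].mean()

    rows = []
    for value in values:
        diff = arms[value] - arms[benchmark]
        for generation, d in diff.items():
            rows.append(
                {"parameter": parameter, "value": value,
                 "generation": int(generation), "mean_gebv_diff": float(d)}
            )
    return pd.DataFrame(rows)
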