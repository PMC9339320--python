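"""Scaled-down comparison study of CGS, LAS, and PV-LAS.

The full-size experiments behind the method run 500 replicates of a
200-individual program on a maize panel with over a million SNPs
aggregated into 10,000 blocks — far beyond what a test suite should
pay for.  This module defines a single scaled-down study used by both
the test suite and the acceptance script: a synthetic inbred founder
panel of 75 lines with 800 SNPs on 4 chromosomes aggregated into 200
blocks, programs of N = 50 individuals, S = 5 crosses, T = 8
generations, window W = 3, discount 0.1, gamma = 0.8, and K = 200
Monte-Carlo progeny per offset.  All methods share founder seeds so
replicates are paired.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .meiosis import LookAheadSpec
from .simulate import ProgramConfig, founder_sampler_from_pool, run_replicates
from .synthetic import generate_effects, generate_founders, generate_map

__all__ = ["scaled_study_inputs", "scaled_config", "scaled_comparison"]

POOL_SIZE = 75
N = 50
L = 800
N_BLOCKS = 200
CHROM_COUNT = 4
S = 5
T = 8
W = 3
DISCOUNT = 0.1
GAMMA = 0.8
K = 200
# 200 SNPs per ~150 cM chromosome: adjacent markers are ~0.75 cM apart,
# i.e. r ~ 0.0075 under Haldane — a dense panel, as the methods assume.
MEAN_R = 0.0075


def scaled_study_inputs(seed: int):
    """Synthetic panel, trait and map for the scaled study (fixed sizes,
    data seeded by ``seed``)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xDA7A)))
    pool = generate_founders(POOL_SIZE, L, chrom_count=CHROM_COUNT, rng=rng, inbred=True)
    trait = generate_effects(L, sparsity=0.2, scale=1.0, mu=0.0, rng=rng)
    gmap = generate_map(L, chrom_count=CHROM_COUNT, mean_r=MEAN_R, rng=rng)
    return pool, trait, gmap


def scaled_config(method: str, seed: int, n_replicates: int, **overrides) -> ProgramConfig:
    spec = LookAheadSpec(W=W, discount=DISCOUNT, gamma=GAMMA, K=K)
    config = ProgramConfig(
        N=N, S=S, T=T, method=method, spec=spec,
        n_replicates=n_replicates, seed=seed, n_blocks=N_BLOCKS,
    )
    return replace(config, **overrides) if overrides else config


def scaled_comparison(
    seed: int,
    n_replicates: int = 50,
    methods: tuple[str, ...] = ("cgs", "las", "pvlas"),
    stream: int = 0,
    **overrides,
) -> tuple[pd.DataFrame, dict]:
    """Run the scaled study for several methods on common founders.

    ``stream`` offsets the within-program random stream (founder draws
    stay paired across arms regardless).  Returns the stacked metrics
    table and a per-method summary dict (as produced by
    :func:`pvlas.simulate.run_replicates`).
    """
    pool, trait, gmap = scaled_study_inputs(seed)
    sampler = founder_sampler_from_pool(pool, N)
    tables, summaries = [], {}
    for method in methods:
        config = scaled_config(method, seed, n_replicates, **overrides)
        metrics, summary = run_replicates(config, sampler, trait, gmap, stream=stream)
        tables.append(metrics)
        summaries[method] = summary
    return pd.concat(tables, ignore_index=True), summaries
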