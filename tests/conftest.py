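"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pvlas import (
    CrossSet,
    GeneticMap,
    GenotypeTensor,
    TraitModel,
    generate_effects,
    generate_founders,
    generate_map,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20220602)


@pytest.fixture
def small_population(rng):
    """Random outbred population: N=6 individuals, L=12 loci, 2 chromosomes."""
    founders = generate_founders(6, 12, chrom_count=2, rng=rng, inbred=False)
    trait = generate_effects(12, sparsity=0.8, scale=1.0, mu=0.0, rng=rng)
    gmap = generate_map(12, chrom_count=2, mean_r=0.1, rng=rng)
    return founders, trait, gmap


def random_three_locus_instance(seed: int):
    """One parent (two random 3-locus haplotypes) and a random map."""
    rng = np.random.default_rng(seed)
    hap1 = rng.integers(0, 2, 3)
    hap2 = rng.integers(0, 2, 3)
    gmap = GeneticMap(recomb=rng.uniform(0.0, 0.5, 2), chrom=[0, 0, 0])
    return hap1, hap2, gmap


def empirical_tv_distance(draws: np.ndarray, exact: dict) -> float:
    """Total-variation distance between sampled gametes and an exact
    gamete distribution (dict of allele-tuple -> probability)."""
    values, counts = np.unique(draws, axis=0, return_counts=True)
    empirical = {tuple(int(a) for a in v): c / draws.shape[0]
                 for v, c in zip(values, counts)}
    keys = set(empirical) | set(exact)
    return 0.5 * sum(abs(empirical.get(k, 0.0) - exact.get(k, 0.0)) for k in keys)


# ---------------------------------------------------------------------------
# exact oracle for the descendant-gamete chain (independent of the kernels)
# ---------------------------------------------------------------------------

def enumerate_descendant_gamete_scores(
    pool: np.ndarray, recomb: np.ndarray, tau: int
) -> dict[float, float]:
    """Exact score distribution of one descendant gamete at offset
    ``tau >= 2`` by brute-force enumeration of all state paths.

    States are (cross, slot) over the ``(S, 4, L)`` weighted pool.  At
    each interval the chain migrates to a uniformly chosen slot of a
    different uniformly chosen cross with probability
    ``min((S-1)(1-(1-r)^tau)/S, 0.5)`` (zero for ``tau = 2``), else
    switches to one of the other 3 slots of its cross with probability
    ``min(1-(1-r)^tau, 0.5)``.
    """
    S, _, L = pool.shape
    states = list(itertools.product(range(S), range(4)))
    q = np.minimum(1.0 - (1.0 - recomb) ** tau, 0.5)
    if tau >= 3:
        m = np.minimum((S - 1) * (1.0 - (1.0 - recomb) ** tau) / S, 0.5)
    else:
        m = np.zeros(L - 1)

    def step_prob(l: int, a, b) -> float:
        ca, ha = a
        cb, hb = b
        if ca == cb:
            within = (1.0 - m[l]) * q[l] / 3.0
            return (1.0 - m[l]) * (1.0 - q[l]) if ha == hb else within
        return m[l] / ((S - 1) * 4.0)

    dist: dict[float, float] = {}
    for path in itertools.product(states, repeat=L):
        p = 1.0 / (4.0 * S)
        for l in range(1, L):
            p *= step_prob(l - 1, path[l - 1], path[l])
        score = sum(pool[c, h, l] for l, (c, h) in enumerate(path))
        key = round(float(score), 12)
        dist[key] = dist.get(key, 0.0) + p
    return dist


def enumerated_progeny_mean(pool: np.ndarray, recomb: np.ndarray, tau: int) -> float:
    """Exact mean progeny score at offset ``tau >= 2`` (two independent
    descendant gametes)."""
    dist = enumerate_descendant_gamete_scores(pool, recomb, tau)
    gamete_mean = sum(score * p for score, p in dist.items())
    return 2.0 * gamete_mean


def ohv_plan_objective(genotypes: GenotypeTensor, trait: TraitModel):
    """Deterministic plan objective for optimizer tests: twice the sum
    over loci of the best weighted allele among the selected parents'
    haplotypes (the value of the best achievable fully homozygous
    descendant, ignoring linkage)."""
    weighted = trait.beta[:, None, None] * genotypes.alleles  # (L, 2, N)

    def objective(plan, seed=None) -> float:
        parents = sorted({p for pair in plan.pairs for p in pair})
        w = weighted[:, :, parents].reshape(genotypes.n_loci, -1)
        return float(2.0 * w.max(axis=1).sum())

    return objective
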