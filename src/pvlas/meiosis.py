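"""Gamete and progeny simulation under a first-order Markov recombination model.

A gamete is a mosaic of its parent's two haplotypes: the source at the
first locus is uniform, and at each inter-locus interval ``l`` the
source switches with probability ``r_l``, independently (Haldane-style
no-interference model).  The look-ahead machinery extends this to a
descendant gamete ``tau`` generations downstream of a mating plan of
``S`` crosses, where the mosaic runs over the 4 haplotypes of a cross
and migrates between crosses with the generation-inflated frequency

    R~_l(tau) = 0                               for tau in {1, 2}
    R~_l(tau) = (S - 1) [1 - (1 - r_l)^tau] / S for tau >= 3.

All randomness is pre-drawn from a :class:`numpy.random.Generator`
before entering the compiled kernels, so results are reproducible and
candidate mating plans can be compared under common random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import GeneticMap, GenotypeTensor, TraitModel
from .errors import DimensionError, SizeError

__all__ = [
    "CrossSet",
    "LookAheadSpec",
    "sample_gamete",
    "sample_gametes",
    "make_progeny",
    "lookahead_recomb",
    "simulate_descendant_progeny",
    "descendant_score_samples",
    "draw_progeny_uniforms",
    "enumerate_gamete_distribution",
    "haplotype_pool",
]


@dataclass
class CrossSet:
    """An unordered list of ``S`` parent pairs; selfing ``(i, i)`` is allowed."""

    pairs: list[tuple[int, int]]

    def __post_init__(self):
        if len(self.pairs) < 1:
            raise ValueError("a cross set needs at least one pair")
        self.pairs = [tuple(sorted((int(i), int(j)))) for i, j in self.pairs]

    @property
    def n_crosses(self) -> int:
        return len(self.pairs)

    def validate_against(self, n_individuals: int) -> None:
        for i, j in self.pairs:
            if not (0 <= i < n_individuals and 0 <= j < n_individuals):
                raise DimensionError(f"pair ({i}, {j}) outside population of size {n_individuals}")


@dataclass
class LookAheadSpec:
    """Parameters of the stochastic look-ahead objective.

    W : window length in generations (LAS substitutes the remaining
        horizon ``T - t`` for it); discount : per-generation discount
    rate lambda >= 0; gamma : quantile/risk parameter in (0, 1);
    K : Monte-Carlo progeny per look-ahead offset.
    """

    W: int = 3
    discount: float = 0.1
    gamma: float = 0.8
    K: int = 500

    def __post_init__(self):
        if self.W < 1:
            raise ValueError("W must be a positive integer")
        if self.discount < 0:
            raise ValueError("discount rate must be non-negative")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie strictly between 0 and 1")
        if self.K < 1:
            raise ValueError("K must be a positive integer")


# ---------------------------------------------------------------------------
# single-meiosis simulation
# ---------------------------------------------------------------------------

def sample_gametes(
    hap1: np.ndarray,
    hap2: np.ndarray,
    gmap: GeneticMap,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` independent gametes from one parent, shape ``(n, L)``."""
    hap1 = np.asarray(hap1)
    hap2 = np.asarray(hap2)
    L = hap1.size
    if hap2.size != L or gmap.recomb.size != L - 1:
        raise DimensionError("haplotype and map lengths are inconsistent")
    start = rng.integers(0, 2, size=(n, 1))
    if L > 1:
        switches = rng.random((n, L - 1)) < gmap.recomb
        source = np.cumsum(np.concatenate([start, switches], axis=1), axis=1) % 2
    else:
        source = start
    haps = np.stack([hap1, hap2])  # (2, L)
    return haps[source, np.arange(L)]


def sample_gamete(
    hap1: np.ndarray,
    hap2: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a single gamete (Markov mosaic of the two parental haplotypes)."""
    return sample_gametes(hap1, hap2, gmap, 1, rng)[0]


def make_progeny(
    genotypes: GenotypeTensor,
    pair: tuple[int, int],
    n_progeny: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
    id_prefix: str | None = None,
) -> GenotypeTensor:
    """Produce progeny of one cross; each progeny unites one independent
    gamete from each parent (two independent gametes from the same
    parent under selfing)."""
    i, j = pair
    g_i = sample_gametes(
        genotypes.haplotype(i, 0), genotypes.haplotype(i, 1), gmap, n_progeny, rng
    )
    g_j = sample_gametes(
        genotypes.haplotype(j, 0), genotypes.haplotype(j, 1), gmap, n_progeny, rng
    )
    alleles = np.stack([g_i.T, g_j.T], axis=1)  # (L, 2, n)
    gen = genotypes.generation + 1
    prefix = id_prefix if id_prefix is not None else f"G{gen}.{i}x{j}"
    ids = [f"{prefix}.{k}" for k in range(n_progeny)]
    return GenotypeTensor(alleles, ids, generation=gen)


# ---------------------------------------------------------------------------
# look-ahead recombination and descendant simulation
# ---------------------------------------------------------------------------

def lookahead_recomb(gmap: GeneticMap, tau: int, S: int) -> np.ndarray:
    """Effective recombination frequency seen by a descendant ``tau``
    generations ahead under a plan of ``S`` crosses (between-cross
    mixing term).  Zero for ``tau`` in {1, 2}; otherwise
    ``(S - 1) [1 - (1 - r_l)^tau] / S`` elementwise."""
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if S < 1:
        raise ValueError("S must be >= 1")
    if tau <= 2:
        return np.zeros_like(gmap.recomb)
    return (S - 1) * (1.0 - (1.0 - gmap.recomb) ** tau) / S


@njit(cache=True)
def _progeny_scores_tau1(pool, recomb, u_cross, u_init, u_ev):  # pragma: no cover
    K = u_cross.shape[0]
    S, _, L = pool.shape
    out = np.zeros(K)
    for g in range(2 * K):
        k = g % K
        c = int(u_cross[k] * S)          # both gametes share the chosen cross
        base = 0 if g < K else 2
        h = base + (1 if u_init[g] >= 0.5 else 0)
        total = pool[c, h, 0]
        for l in range(1, L):
            if u_ev[g, l - 1] < recomb[l - 1]:
                h = 2 * base + 1 - h
            total += pool[c, h, l]
        out[k] += total
    return out


@njit(cache=True)
def _gamete_scores_lookahead(pool, p_within, p_migrate, u_init, u_ev, u_tgt):  # pragma: no cover
    G = u_init.shape[0]
    S, _, L = pool.shape
    out = np.empty(G)
    for g in range(G):
        c = int(u_init[g, 0] * S)
        h = int(u_init[g, 1] * 4)
        total = pool[c, h, 0]
        for l in range(1, L):
            u = u_ev[g, l - 1]
            m = p_migrate[l - 1]
            if u < m:
                idx = int(u_tgt[g, l - 1] * ((S - 1) * 4))
                co = idx // 4
                c = co if co < c else co + 1
                h = idx % 4
            elif u < m + (1.0 - m) * p_within[l - 1]:
                t = int(u_tgt[g, l - 1] * 3)
                h = t if t < h else t + 1
            total += pool[c, h, l]
        out[g] = total
    return out


def haplotype_pool(hap_scores: np.ndarray, crosses: CrossSet) -> np.ndarray:
    """Weighted-haplotype pool of a mating plan, shape ``(S, 4, L)``.

    ``hap_scores`` has shape ``(L, 2, N)`` and holds per-locus weighted
    allele content (``beta_l * G[l, m, i]``, or block scores).  Slots
    0-1 of a cross are the first parent's haplotypes, slots 2-3 the
    second parent's; a selfing cross therefore duplicates its parent's
    haplotypes and never imports foreign alleles.
    """
    S = crosses.n_crosses
    L = hap_scores.shape[0]
    pool = np.empty((S, 4, L))
    for s, (i, j) in enumerate(crosses.pairs):
        pool[s, 0] = hap_scores[:, 0, i]
        pool[s, 1] = hap_scores[:, 1, i]
        pool[s, 2] = hap_scores[:, 0, j]
        pool[s, 3] = hap_scores[:, 1, j]
    return pool


def draw_progeny_uniforms(
    tau: int, K: int, L: int, rng: np.random.Generator
) -> tuple[np.ndarray, ...]:
    """Pre-draw the uniform variates one call to
    :func:`descendant_score_samples` consumes.  The shapes depend only
    on ``(tau, K, L)``, never on the mating plan, so one draw can be
    shared across competing plans (common random numbers)."""
    n_int = max(L - 1, 1)
    if tau == 1:
        return (rng.random(K), rng.random(2 * K), rng.random((2 * K, n_int)))
    return (
        rng.random((2 * K, 2)),
        rng.random((2 * K, n_int)),
        rng.random((2 * K, n_int)),
    )


def descendant_score_samples(
    hap_scores: np.ndarray,
    recomb: np.ndarray,
    crosses: CrossSet,
    tau: int,
    K: int,
    rng: np.random.Generator | None = None,
    pool: np.ndarray | None = None,
    uniforms: tuple[np.ndarray, ...] | None = None,
) -> np.ndarray:
    """``K`` simulated progeny scores (GEBV net of the mean) ``tau``
    generations ahead of the current population under ``crosses``.

    At ``tau = 1`` a progeny unites one gamete from each parent of a
    uniformly chosen cross.  At ``tau >= 2`` it unites two independent
    descendant gametes, each a mosaic over the 4-haplotype pools of the
    crosses: within-cross switches occur with probability
    ``min(1 - (1 - r_l)^tau, 0.5)`` and between-cross migration with
    probability ``min(R~_l(tau), 0.5)``.

    The number and order of random draws depends only on ``(K, L, tau)``
    — never on the plan — so evaluations of competing plans from
    generators with the same state share common random numbers.
    """
    recomb = np.asarray(recomb, dtype=float)
    L = hap_scores.shape[0]
    if pool is None:
        pool = haplotype_pool(hap_scores, crosses)
    S = pool.shape[0]
    if uniforms is None:
        if rng is None:
            raise ValueError("provide either rng or pre-drawn uniforms")
        uniforms = draw_progeny_uniforms(tau, K, L, rng)
    if tau == 1:
        u_cross, u_init, u_ev = uniforms
        return _progeny_scores_tau1(pool, recomb, u_cross, u_init, u_ev)
    p_within = np.minimum(1.0 - (1.0 - recomb) ** tau, 0.5)
    if tau >= 3:
        p_migrate = np.minimum((S - 1) * (1.0 - (1.0 - recomb) ** tau) / S, 0.5)
    else:
        p_migrate = np.zeros(max(L - 1, 1))
    u_init, u_ev, u_tgt = uniforms
    scores = _gamete_scores_lookahead(pool, p_within, p_migrate, u_init, u_ev, u_tgt)
    return scores[:K] + scores[K:]


def simulate_descendant_progeny(
    genotypes: GenotypeTensor,
    crosses: CrossSet,
    tau: int,
    trait: TraitModel,
    gmap: GeneticMap,
    K: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """``K`` independent simulated GEBVs of a random progeny ``tau``
    generations ahead under the mating plan ``crosses``."""
    if tau < 1:
        raise ValueError("tau must be >= 1")
    crosses.validate_against(genotypes.n_individuals)
    if trait.n_loci != genotypes.n_loci:
        raise DimensionError("beta length does not match the number of loci")
    hap_scores = trait.beta[:, None, None] * genotypes.alleles
    return trait.mu + descendant_score_samples(
        hap_scores, gmap.recomb, crosses, tau, K, rng
    )


# ---------------------------------------------------------------------------
# exact enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_gamete_distribution(
    hap1: np.ndarray,
    hap2: np.ndarray,
    gmap: GeneticMap,
) -> dict[tuple[int, ...], float]:
    """Exact gamete distribution of :func:`sample_gamete` by exhaustive
    enumeration of the ``2^L`` source paths (guarded at ``L <= 16``).

    Returns a mapping from gamete allele tuples to probabilities,
    merged over source paths that yield the same gamete; probabilities
    sum to 1.
    """
    hap1 = np.asarray(hap1)
    hap2 = np.asarray(hap2)
    L = hap1.size
    if L > 16:
        raise SizeError(f"enumeration over 2^{L} source paths refused (L > 16)")
    if hap2.size != L or gmap.recomb.size != L - 1:
        raise DimensionError("haplotype and map lengths are inconsistent")
    haps = np.stack([hap1, hap2])
    r = gmap.recomb
    dist: dict[tuple[int, ...], float] = {}
    for path in range(2 ** L):
        sources = [(path >> l) & 1 for l in range(L)]
        p = 0.5
        for l in range(1, L):
            p *= r[l - 1] if sources[l] != sources[l - 1] else 1.0 - r[l - 1]
        gamete = tuple(int(haps[sources[l], l]) for l in range(L))
        dist[gamete] = dist.get(gamete, 0.0) + p
    return dist
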