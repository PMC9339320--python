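"""Synthetic founder panels, additive effect vectors, and genetic maps.

These generators emulate the statistical structure the selection
algorithms assume — a panel of genotyped (by default fully homozygous,
i.e. inbred) founders, a sparse mixed-sign additive architecture, and a
multi-chromosome recombination map — standing in for a real crop panel
such as a set of maize inbred lines with estimated marker effects.
Loci are generated independently (no linkage disequilibrium), which is
sufficient to exercise the algorithms but does not mimic real LD
structure.
"""

from __future__ import annotations

import numpy as np

from .core import GeneticMap, GenotypeTensor, TraitModel

__all__ = [
    "generate_founders",
    "generate_effects",
    "generate_map",
    "toy_example",
]


def generate_founders(
    N: int,
    L: int,
    chrom_count: int = 1,
    allele_freq: float | np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    inbred: bool = True,
) -> GenotypeTensor:
    """Draw a founder panel of ``N`` diploid individuals with ``L`` loci.

    Alleles are independent Bernoulli draws with locus-specific
    major-allele frequency ``p_l`` (a scalar, a length-``L`` vector, or
    ``None`` for ``p_l ~ Uniform(0.1, 0.9)``).  In ``inbred`` mode
    (default, as for inbred crop lines) haplotype 1 is copied to
    haplotype 2 so every founder is fully homozygous.
    """
    rng = np.random.default_rng() if rng is None else rng
    if N < 1 or L < 1 or chrom_count < 1:
        raise ValueError("N, L and chrom_count must be positive")
    if allele_freq is None:
        p = rng.uniform(0.1, 0.9, size=L)
    else:
        p = np.broadcast_to(np.asarray(allele_freq, dtype=float), (L,)).copy()
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")
    if inbred:
        hap = (rng.random((L, 1, N)) < p[:, None, None]).astype(np.uint8)
        alleles = np.concatenate([hap, hap], axis=1)
    else:
        alleles = (rng.random((L, 2, N)) < p[:, None, None]).astype(np.uint8)
    ids = [f"F{i:04d}" for i in range(N)]
    return GenotypeTensor(alleles, ids, generation=0)


def generate_effects(
    L: int,
    sparsity: float = 0.1,
    scale: float = 1.0,
    mu: float = 0.0,
    rng: np.random.Generator | None = None,
    max_redraws: int = 1000,
) -> TraitModel:
    """Sparse mixed-sign additive architecture.

    Each effect is non-zero with probability ``sparsity`` and then drawn
    from a zero-mean normal with standard deviation ``scale``.  When
    ``L >= 20`` and ``sparsity > 0`` the draw is repeated until both
    positive and negative effects are present, so complementation
    between parents is always possible.
    """
    rng = np.random.default_rng() if rng is None else rng
    if L < 1:
        raise ValueError("L must be positive")
    if not 0.0 <= sparsity <= 1.0:
        raise ValueError("sparsity must lie in [0, 1]")
    for _ in range(max_redraws):
        nonzero = rng.random(L) < sparsity
        beta = np.where(nonzero, rng.normal(0.0, scale, size=L), 0.0)
        if sparsity == 0.0 or L < 20:
            break
        if (beta > 0).any() and (beta < 0).any():
            break
    return TraitModel(beta=beta, mu=mu)


def generate_map(
    L: int,
    chrom_count: int = 1,
    mean_r: float = 0.1,
    rng: np.random.Generator | None = None,
) -> GeneticMap:
    """Loci split evenly across chromosomes (remainder to the earliest);
    within-chromosome recombination frequencies i.i.d. uniform on
    ``(0, 2 * mean_r]`` capped at 0.5; chromosome boundaries at 0.5."""
    rng = np.random.default_rng() if rng is None else rng
    if not 0.0 < mean_r <= 0.5:
        raise ValueError("mean_r must lie in (0, 0.5]")
    if chrom_count > L:
        raise ValueError("cannot have more chromosomes than loci")
    base, rem = divmod(L, chrom_count)
    sizes = [base + (1 if c < rem else 0) for c in range(chrom_count)]
    chrom = np.repeat(np.arange(chrom_count), sizes)
    recomb = np.minimum((1.0 - rng.random(max(L - 1, 0))) * 2.0 * mean_r, 0.5)
    recomb[np.diff(chrom) != 0] = 0.5
    return GeneticMap(recomb=recomb, chrom=chrom)


def toy_example() -> tuple[GenotypeTensor, TraitModel, GeneticMap, dict]:
    """Fixed small instance for walking through the algorithms end to end.

    Dimensions follow the worked illustration of the method: S = 3
    crosses from N = 8 diploid individuals genotyped at L = 10 SNPs,
    deadline / window T = W = 3, K = 500 simulated progeny per offset,
    gamma = 0.8 (and discount rate 0.1 for the present-value variant).
    Genotype, effect and map values are fixed arbitrary stand-ins drawn
    from this package's own generators under a frozen seed.
    """
    rng = np.random.default_rng(1)
    founders = generate_founders(
        N=8, L=10, chrom_count=2, allele_freq=0.5, rng=rng, inbred=False
    )
    trait = generate_effects(L=10, sparsity=0.6, scale=1.0, mu=0.0, rng=rng)
    gmap = generate_map(L=10, chrom_count=2, mean_r=0.15, rng=rng)
    config = {"N": 8, "L": 10, "S": 3, "T": 3, "W": 3, "K": 500,
              "gamma": 0.8, "discount": 0.1}
    return founders, trait, gmap, config
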