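"""Population genotypes, trait model, genetic map, and genetic-gain accounting.

The central state of a breeding program is a phased, biallelic genotype
tensor ``G`` of shape ``(L, 2, N)``: ``G[l, m, i]`` is 1 if haplotype
``m`` of diploid individual ``i`` carries the major allele at locus
``l`` and 0 otherwise.  A trait is additive: the genomic estimated
breeding value (GEBV) of individual ``i`` is

    v_i = mu + sum_l beta_l * (G[l, 0, i] + G[l, 1, i]).

This module also provides the population-level diversity metrics (lower
and upper genetic potential), present-value accounting of realized
gains, and aggregation of SNPs into recombination blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConstraintError, DimensionError


@dataclass
class GenotypeTensor:
    """Phased biallelic genotypes of a population.

    Parameters
    ----------
    alleles
        Binary array of shape ``(L, 2, N)``; axis order is
        (locus, haplotype, individual).
    individual_ids
        ``N`` unique individual labels.
    generation
        Non-negative index of the generation this population belongs to
        (founders are generation 0).
    """

    alleles: np.ndarray
    individual_ids: list[str] = None
    generation: int = 0

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles)
        if self.alleles.ndim != 3 or self.alleles.shape[1] != 2:
            raise DimensionError(
                f"alleles must have shape (L, 2, N), got {self.alleles.shape}"
            )
        if self.alleles.shape[0] < 1 or self.alleles.shape[2] < 1:
            raise DimensionError("need at least one locus and one individual")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be 0 (minor) or 1 (major)")
        self.alleles = self.alleles.astype(np.uint8)
        if self.individual_ids is None:
            self.individual_ids = [f"I{i}" for i in range(self.n_individuals)]
        self.individual_ids = list(self.individual_ids)
        if len(self.individual_ids) != self.n_individuals:
            raise DimensionError(
                f"{len(self.individual_ids)} ids for {self.n_individuals} individuals"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual_ids must be unique")
        if self.generation < 0:
            raise ValueError("generation must be non-negative")

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[2]

    def haplotype(self, individual: int, m: int) -> np.ndarray:
        """Return haplotype ``m`` (0 or 1) of one individual, shape ``(L,)``."""
        return self.alleles[:, m, individual]


@dataclass
class TraitModel:
    """Additive trait: per-locus allele effects ``beta`` and overall mean ``mu``."""

    beta: np.ndarray
    mu: float = 0.0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if self.beta.size < 1:
            raise DimensionError("beta must have at least one entry")
        if not np.isfinite(self.beta).all() or not np.isfinite(self.mu):
            raise ValueError("beta and mu must be finite")
        self.mu = float(self.mu)

    @property
    def n_loci(self) -> int:
        return self.beta.size


@dataclass
class GeneticMap:
    """Per-interval recombination frequencies with a chromosome partition.

    ``recomb[l]`` is the recombination frequency between loci ``l`` and
    ``l + 1`` (length ``L - 1``); ``chrom`` assigns each locus to a
    chromosome and must be non-decreasing.  Intervals that straddle a
    chromosome boundary must carry ``r = 0.5`` (independent assortment).
    """

    recomb: np.ndarray
    chrom: np.ndarray = None

    def __post_init__(self):
        self.recomb = np.asarray(self.recomb, dtype=float).ravel()
        if self.chrom is None:
            self.chrom = np.zeros(self.recomb.size + 1, dtype=int)
        self.chrom = np.asarray(self.chrom, dtype=int).ravel()
        if self.chrom.size != self.recomb.size + 1:
            raise DimensionError(
                f"chrom has {self.chrom.size} entries for {self.recomb.size} intervals"
            )
        if np.any(np.diff(self.chrom) < 0):
            raise ValueError("chrom must be non-decreasing")
        if np.any(self.recomb < 0) or np.any(self.recomb > 0.5):
            raise ValueError("recombination frequencies must lie in [0, 0.5]")
        boundary = self.boundaries
        if not np.allclose(self.recomb[boundary], 0.5):
            raise ValueError("chromosome boundaries must carry r = 0.5")

    @property
    def n_loci(self) -> int:
        return self.chrom.size

    @property
    def boundaries(self) -> np.ndarray:
        """Boolean mask over intervals that cross a chromosome boundary."""
        return np.diff(self.chrom) != 0

    @property
    def n_chromosomes(self) -> int:
        return len(np.unique(self.chrom))


@dataclass
class BlockedPopulation:
    """SNPs aggregated into contiguous blocks inherited as atomic units.

    ``block_scores[b, m, i]`` is the summed weighted allele content
    ``sum_{l in block b} beta_l * G[l, m, i]``, so block scores play the
    role of weighted haplotype values and sum to ``v_i - mu`` exactly.
    """

    block_scores: np.ndarray        # (B, 2, N)
    block_map: list[tuple[int, int]]  # half-open locus ranges, contiguous
    block_recomb: np.ndarray        # (B - 1,)
    block_chrom: np.ndarray = None  # (B,)

    def __post_init__(self):
        self.block_scores = np.asarray(self.block_scores, dtype=float)
        self.block_recomb = np.asarray(self.block_recomb, dtype=float).ravel()
        if self.block_chrom is None:
            self.block_chrom = np.zeros(len(self.block_map), dtype=int)
        if np.any(self.block_recomb < 0) or np.any(self.block_recomb > 0.5):
            raise ValueError("block recombination frequencies must lie in [0, 0.5]")

    @property
    def n_blocks(self) -> int:
        return self.block_scores.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.block_scores.shape[2]


@dataclass
class GainLedger:
    """Best GEBV realized in each completed generation, plus a discount rate."""

    per_generation_best: np.ndarray
    discount: float = 0.1

    def __post_init__(self):
        self.per_generation_best = np.asarray(
            self.per_generation_best, dtype=float
        ).ravel()
        if self.per_generation_best.size < 1:
            raise DimensionError("ledger must cover at least one generation")
        if self.discount < 0:
            raise ValueError("discount rate must be non-negative")


def _check_dims(genotypes: GenotypeTensor, trait: TraitModel) -> None:
    if trait.n_loci != genotypes.n_loci:
        raise DimensionError(
            f"beta has {trait.n_loci} effects for {genotypes.n_loci} loci"
        )


def gebv(genotypes: GenotypeTensor, trait: TraitModel) -> np.ndarray:
    """Genomic estimated breeding values, shape ``(N,)``.

    ``v_i = mu + sum_l beta_l (G[l,0,i] + G[l,1,i])``.
    """
    _check_dims(genotypes, trait)
    dosage = genotypes.alleles.sum(axis=1)  # (L, N)
    return trait.mu + trait.beta @ dosage


def lower_potential(genotypes: GenotypeTensor, trait: TraitModel) -> float:
    """Theoretical lower bound of GEBV given the alleles still segregating.

    ``2 * sum_l min_{m,i} (G[l,m,i] * beta_l)`` — the GEBV (net of the
    mean) of a hypothetical individual homozygous for the worst
    remaining allele at every locus.
    """
    _check_dims(genotypes, trait)
    w = trait.beta[:, None, None] * genotypes.alleles
    return float(2.0 * w.min(axis=(1, 2)).sum())


def upper_potential(genotypes: GenotypeTensor, trait: TraitModel) -> float:
    """Theoretical upper bound of GEBV given the alleles still segregating."""
    _check_dims(genotypes, trait)
    w = trait.beta[:, None, None] * genotypes.alleles
    return float(2.0 * w.max(axis=(1, 2)).sum())


def present_value_of_gains(ledger: GainLedger) -> float:
    """Discounted sum of per-generation best GEBVs.

    ``sum_{tau=1..T} best[tau] / (1 + lambda)^tau``; a gain realized in
    generation ``tau`` is worth ``1/(1+lambda)^tau`` of the same gain
    realized today.
    """
    tau = np.arange(1, ledger.per_generation_best.size + 1)
    return float(np.sum(ledger.per_generation_best / (1.0 + ledger.discount) ** tau))


def _allocate_blocks(counts: np.ndarray, n_blocks: int) -> np.ndarray:
    """Distribute ``n_blocks`` among chromosomes with ``counts`` loci.

    Greedy divisor rule: start with one block per chromosome, then
    repeatedly add a block to the chromosome with the largest
    loci-per-block ratio (ties to the earliest chromosome).
    Deterministic; never exceeds the locus count of a chromosome.
    """
    n_chrom = counts.size
    alloc = np.ones(n_chrom, dtype=int)
    for _ in range(n_blocks - n_chrom):
        ratio = np.where(alloc < counts, counts / alloc, -np.inf)
        alloc[int(np.argmax(ratio))] += 1
    return alloc


def aggregate_blocks(
    genotypes: GenotypeTensor,
    trait: TraitModel,
    gmap: GeneticMap,
    n_blocks: int,
) -> BlockedPopulation:
    """Aggregate SNPs into contiguous blocks to speed up look-ahead simulation.

    Blocks are contiguous, equal-count-as-possible within each
    chromosome (remainder loci go to the earliest blocks), and never
    span a chromosome boundary.  The recombination frequency between
    consecutive blocks ``b`` and ``b+1`` on the same chromosome
    combines all map intervals between their first loci,
    ``1 - prod(1 - r_l)``, capped at 0.5; across chromosomes it is 0.5.
    Block scores preserve GEBVs exactly:
    ``sum_{b,m} block_scores[b,m,i] = v_i - mu``.
    """
    _check_dims(genotypes, trait)
    if gmap.n_loci != genotypes.n_loci:
        raise DimensionError("map and genotypes disagree on the number of loci")
    L = genotypes.n_loci
    chroms, counts = np.unique(gmap.chrom, return_counts=True)
    n_chrom = chroms.size
    if n_blocks < n_chrom:
        raise ConstraintError(
            f"cannot partition {n_chrom} chromosomes into {n_blocks} blocks"
        )
    if n_blocks > L:
        raise ConstraintError(f"n_blocks={n_blocks} exceeds L={L}")

    alloc = _allocate_blocks(counts, n_blocks)
    block_map: list[tuple[int, int]] = []
    block_chrom: list[int] = []
    offset = 0
    for c in range(n_chrom):
        n_c, a_c = int(counts[c]), int(alloc[c])
        base, rem = divmod(n_c, a_c)
        start = offset
        for b in range(a_c):
            size = base + (1 if b < rem else 0)
            block_map.append((start, start + size))
            block_chrom.append(int(chroms[c]))
            start += size
        offset += n_c

    weighted = trait.beta[:, None, None] * genotypes.alleles  # (L, 2, N)
    starts = np.array([s for s, _ in block_map])
    block_scores = np.add.reduceat(weighted, starts, axis=0)

    block_recomb = np.empty(n_blocks - 1)
    for b in range(n_blocks - 1):
        if block_chrom[b] != block_chrom[b + 1]:
            block_recomb[b] = 0.5
        else:
            lo, hi = block_map[b][0], block_map[b + 1][0]
            r = 1.0 - np.prod(1.0 - gmap.recomb[lo:hi])
            block_recomb[b] = min(r, 0.5)

    return BlockedPopulation(
        block_scores=block_scores,
        block_map=block_map,
        block_recomb=block_recomb,
        block_chrom=np.array(block_chrom),
    )
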