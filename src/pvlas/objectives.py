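"""Stochastic breeding objectives.

Three objectives are implemented:

* CGS score — total GEBV of the selected parents (deterministic).
* LAS objective ``phi`` — the gamma-quantile of a random progeny's GEBV
  at the terminal generation, ``horizon = T - t`` ahead.
* PV-LAS objective ``zeta`` — the discounted sum of per-offset
  gamma-quantiles over a sliding window of ``W`` generations,
  ``zeta = sum_{tau=1..W} psi_tau / (1 + lambda)^tau``.

``psi_tau`` (and ``phi``) are quantiles of a *random* progeny's GEBV:
the largest value attained with probability at least ``1 - gamma``.
Empirically this is the ascending order statistic at rank
``ceil(gamma * K)`` with no interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BlockedPopulation, GeneticMap, GenotypeTensor, TraitModel
from .errors import ConstraintError
from .meiosis import CrossSet, LookAheadSpec, descendant_score_samples

__all__ = [
    "ObjectiveValue",
    "gamma_quantile",
    "cgs_score",
    "las_objective",
    "pvlas_objective",
    "evaluate_psi",
]


@dataclass
class ObjectiveValue:
    """Value of a look-ahead objective together with its per-offset quantiles.

    ``value`` is ``zeta`` for PV-LAS (discounted trait units) or ``phi``
    for LAS (trait units); ``psi[k]`` is the gamma-quantile at offset
    ``offsets[k]``; ``discount`` is the rate used (None for LAS).
    """

    value: float
    psi: np.ndarray
    offsets: tuple[int, ...]
    discount: float | None = None

    @property
    def phi(self) -> float:
        return self.value

    @property
    def zeta(self) -> float:
        return self.value


def gamma_quantile(samples: np.ndarray, gamma: float) -> float:
    """Largest value ``q`` with empirical ``Pr[g >= q] >= 1 - gamma``:
    the ascending order statistic at rank ``ceil(gamma * K)``."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("cannot take a quantile of an empty sample vector")
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie strictly between 0 and 1")
    k = int(np.ceil(gamma * samples.size))
    k = min(max(k, 1), samples.size)
    return float(np.partition(samples, k - 1)[k - 1])


def cgs_score(v: np.ndarray, x: np.ndarray, S: int | None = None) -> float:
    """Total GEBV of the selected parents, ``sum_i x_i v_i``.

    If ``S`` is given, enforces the selection-count constraint
    ``sum_i x_i = 2 S``.
    """
    v = np.asarray(v, dtype=float).ravel()
    x = np.asarray(x).ravel()
    if x.size != v.size:
        raise ConstraintError("selection vector and GEBV vector differ in length")
    if not np.isin(x, (0, 1)).all():
        raise ConstraintError("selection indicators must be binary")
    if S is not None and int(x.sum()) != 2 * S:
        raise ConstraintError(f"expected {2 * S} selected parents, got {int(x.sum())}")
    return float(x @ v)


def _hap_scores_and_recomb(
    genotypes: GenotypeTensor,
    trait: TraitModel,
    gmap: GeneticMap,
    blocked: BlockedPopulation | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted haplotype representation for look-ahead simulation:
    block scores when a blocked population is supplied, raw
    ``beta_l * G`` otherwise (identical code path downstream)."""
    if blocked is not None:
        return blocked.block_scores, blocked.block_recomb
    return trait.beta[:, None, None] * genotypes.alleles, gmap.recomb


def evaluate_psi(
    hap_scores: np.ndarray,
    recomb: np.ndarray,
    crosses: CrossSet,
    offsets: tuple[int, ...],
    K: int,
    gamma: float,
    mu: float = 0.0,
    rng: np.random.Generator | None = None,
    uniforms: list | None = None,
) -> np.ndarray:
    """Per-offset gamma-quantiles of the simulated progeny GEBV.

    ``uniforms`` (one pre-drawn tuple per offset, see
    :func:`pvlas.meiosis.draw_progeny_uniforms`) lets competing plans be
    scored under common random numbers; otherwise fresh variates are
    drawn from ``rng`` in offset order.
    """
    from .meiosis import haplotype_pool

    pool = haplotype_pool(hap_scores, crosses)
    psi = np.empty(len(offsets))
    for k, tau in enumerate(offsets):
        u = uniforms[k] if uniforms is not None else None
        samples = mu + descendant_score_samples(
            hap_scores, recomb, crosses, tau, K, rng, pool=pool, uniforms=u
        )
        psi[k] = gamma_quantile(samples, gamma)
    return psi


def las_objective(
    genotypes: GenotypeTensor,
    crosses: CrossSet,
    trait: TraitModel,
    gmap: GeneticMap,
    horizon: int,
    spec: LookAheadSpec,
    rng: np.random.Generator | None = None,
    blocked: BlockedPopulation | None = None,
    uniforms: list | None = None,
) -> ObjectiveValue:
    """LAS objective: ``phi`` = gamma-quantile of a random progeny's
    GEBV at the terminal generation, ``horizon`` generations ahead."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    hap_scores, recomb = _hap_scores_and_recomb(genotypes, trait, gmap, blocked)
    psi = evaluate_psi(
        hap_scores, recomb, crosses, (horizon,), spec.K, spec.gamma,
        mu=trait.mu, rng=rng, uniforms=uniforms,
    )
    return ObjectiveValue(value=float(psi[0]), psi=psi, offsets=(horizon,))


def pvlas_objective(
    genotypes: GenotypeTensor,
    crosses: CrossSet,
    trait: TraitModel,
    gmap: GeneticMap,
    spec: LookAheadSpec,
    rng: np.random.Generator | None = None,
    blocked: BlockedPopulation | None = None,
    uniforms: list | None = None,
) -> ObjectiveValue:
    """PV-LAS objective ``zeta = sum_{tau=1..W} psi_tau / (1+lambda)^tau``
    where ``psi_tau`` is the gamma-quantile over ``K`` simulated progeny
    at look-ahead offset ``tau``."""
    hap_scores, recomb = _hap_scores_and_recomb(genotypes, trait, gmap, blocked)
    offsets = tuple(range(1, spec.W + 1))
    psi = evaluate_psi(
        hap_scores, recomb, crosses, offsets, spec.K, spec.gamma,
        mu=trait.mu, rng=rng, uniforms=uniforms,
    )
    tau_grid = np.asarray(offsets)
    zeta = float(np.sum(psi / (1.0 + spec.discount) ** tau_grid))
    return ObjectiveValue(
        value=zeta, psi=psi, offsets=offsets, discount=spec.discount
    )
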