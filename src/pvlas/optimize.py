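"""Selection algorithms: CGS truncation selection, feasibility checking,
the Step-1/Step-2 local-search heuristic for the look-ahead objectives,
and an exhaustive oracle for small instances.

A mating plan is normalized as a list of ``S`` unordered parent pairs;
the equivalent matrix form (selection indicators ``x`` and symmetric
mating matrix ``Y``) is derived from it.  The feasibility constraints
are numbered as in the optimization model:

(6) only selected individuals are mated:
    ``(1/N) sum_j y_ij <= x_i <= sum_j y_ij``;
(7) exactly ``S`` crosses are made;
(8) ``Y`` is symmetric;
(9) all indicators are binary.
"""

from __future__ import annotations

import itertools
import math
from typing import Callable

import numpy as np

from .core import GeneticMap, GenotypeTensor, TraitModel, gebv
from .errors import ConstraintError, SizeError
from .meiosis import CrossSet, LookAheadSpec, draw_progeny_uniforms
from .objectives import evaluate_psi

__all__ = [
    "MatingPlan",
    "check_feasibility",
    "select_cgs",
    "initial_feasible_plan",
    "local_search",
    "exhaustive_search",
    "select_with_method",
]

#: objective(plan, seed) -> float; all evaluations within one search pass
#: receive the same seed, so stochastic objectives can (and should) reuse
#: one random substream across competing plans — common random numbers.
#: Deterministic objectives simply ignore the seed.
PlanObjective = Callable[["MatingPlan", int], float]


class MatingPlan:
    """Selection vector ``x``, mating matrix ``Y``, and the pair list.

    Constructed from pairs, ``x`` and ``Y`` are derived consistently
    (and lazily, since the optimizer builds many short-lived neighbor
    plans); explicit, possibly inconsistent ``x``/``Y`` may be supplied
    to exercise :func:`check_feasibility`.
    """

    def __init__(self, pairs, N: int, x=None, Y=None):
        self.pairs = [tuple(sorted((int(i), int(j)))) for i, j in pairs]
        self.N = int(N)
        self._x = None if x is None else np.asarray(x)
        self._y = None if Y is None else np.asarray(Y)

    def __repr__(self):
        return f"MatingPlan(pairs={self.pairs}, N={self.N})"

    def __eq__(self, other):
        return (
            isinstance(other, MatingPlan)
            and sorted(self.pairs) == sorted(other.pairs)
            and self.N == other.N
        )

    @property
    def Y(self) -> np.ndarray:
        if self._y is None:
            y = np.zeros((self.N, self.N), dtype=np.uint8)
            for i, j in self.pairs:
                y[i, j] = 1
                y[j, i] = 1
            self._y = y
        return self._y

    @property
    def x(self) -> np.ndarray:
        if self._x is None:
            self._x = (self.Y.sum(axis=1) > 0).astype(np.uint8)
        return self._x

    @property
    def crosses(self) -> CrossSet:
        return CrossSet(self.pairs)

    @property
    def n_crosses(self) -> int:
        return len(self.pairs)

    def replace_parent(self, pair_index: int, old: int, new: int) -> "MatingPlan":
        """Neighbor plan in which parent ``old`` of cross ``pair_index``
        is replaced by individual ``new``."""
        i, j = self.pairs[pair_index]
        if old == i:
            new_pair = (new, j)
        elif old == j:
            new_pair = (i, new)
        else:
            raise ValueError(f"{old} is not a parent of cross {pair_index}")
        pairs = list(self.pairs)
        pairs[pair_index] = new_pair
        return MatingPlan(pairs, self.N)


def check_feasibility(plan: MatingPlan, N: int, S: int) -> list[str]:
    """Return the list of violated constraints (empty iff feasible).

    Violations are reported as data, not raised; each entry names the
    constraint number it violates.
    """
    violations: list[str] = []
    x, Y = plan.x, plan.Y
    if x.shape != (N,) or Y.shape != (N, N):
        violations.append(f"(9): x/Y dimensions {x.shape}/{Y.shape} do not match N={N}")
        return violations
    if not np.isin(x, (0, 1)).all() or not np.isin(Y, (0, 1)).all():
        violations.append("(9): x and Y must be binary")
        return violations
    if not np.array_equal(Y, Y.T):
        bad = np.argwhere(Y != Y.T)[0]
        violations.append(f"(8): Y is asymmetric at ({bad[0]}, {bad[1]})")
    row = Y.sum(axis=1)
    for i in range(N):
        if not (row[i] / N <= x[i] <= row[i]):
            violations.append(
                f"(6): individual {i} has x={x[i]} but {row[i]} mating entries"
            )
    if plan.n_crosses != S:
        violations.append(f"(7): plan has {plan.n_crosses} crosses, expected {S}")
    for i, j in plan.pairs:
        if not (0 <= i < N and 0 <= j < N):
            violations.append(f"(9): pair ({i}, {j}) outside population of size {N}")
        elif not (Y[i, j] == 1 and Y[j, i] == 1):
            violations.append(f"(8): pair ({i}, {j}) not reflected in Y")
    return violations


def _top_2s(v: np.ndarray, S: int) -> np.ndarray:
    """Indices of the 2S highest GEBVs, ties broken by ascending index."""
    order = np.argsort(-np.asarray(v, dtype=float), kind="stable")
    return order[: 2 * S]


def select_cgs(v: np.ndarray, S: int, rng: np.random.Generator) -> MatingPlan:
    """Conventional genomic selection: truncation-select the ``2S``
    individuals with highest GEBV and pair them by a uniformly random
    perfect matching (no selfing)."""
    v = np.asarray(v, dtype=float).ravel()
    N = v.size
    if N < 2 * S:
        raise ConstraintError(f"need at least {2 * S} individuals, have {N}")
    top = _top_2s(v, S)
    perm = rng.permutation(2 * S)
    shuffled = top[perm]
    pairs = [(int(shuffled[2 * k]), int(shuffled[2 * k + 1])) for k in range(S)]
    return MatingPlan(pairs, N)


def initial_feasible_plan(
    genotypes: GenotypeTensor, trait: TraitModel, S: int
) -> MatingPlan:
    """Deterministic warm start for the local search: the top-``2S``
    GEBV individuals paired rank-1-with-rank-2, rank-3-with-rank-4, ...;
    feasible by construction."""
    v = gebv(genotypes, trait)
    N = v.size
    if N < 2 * S:
        raise ConstraintError(f"need at least {2 * S} individuals, have {N}")
    top = _top_2s(v, S)
    pairs = [(int(top[2 * k]), int(top[2 * k + 1])) for k in range(S)]
    return MatingPlan(pairs, N)


def local_search(
    objective: PlanObjective,
    start: MatingPlan,
    N: int,
    S: int,
    rng: np.random.Generator,
    max_stall_passes: int = 3,
    return_trace: bool = False,
):
    """Step-2 iterative improvement over the pair-replacement neighborhood.

    Each pass visits the incumbent's crosses in random order; for the
    visited cross one parent (chosen at random) is tentatively replaced
    by every candidate ``k`` in the population, and the incumbent moves
    to the best strictly improving feasible neighbor.  Within a pass,
    all evaluations — including the incumbent's — reuse one random
    substream (common random numbers), so comparisons of stochastic
    objectives are not dominated by sampling noise.  Terminates at the
    first improvement-free pass or after ``max_stall_passes`` passes.
    The returned plan is feasible and, under the final pass's common
    stream, scores at least as well as the start.
    """
    if max_stall_passes < 1:
        raise ValueError("max_stall_passes must be >= 1")
    violations = check_feasibility(start, N, S)
    if violations:
        raise ConstraintError(f"infeasible start plan: {violations}")
    incumbent = start
    trace: list[float] = []
    pass_seed = 0
    for _ in range(max_stall_passes):
        pass_seed = int(rng.integers(0, 2**31))
        incumbent_value = objective(incumbent, pass_seed)
        if not trace:
            trace.append(incumbent_value)
        improved = False
        for pair_index in rng.permutation(incumbent.n_crosses):
            i, j = incumbent.pairs[pair_index]
            replaced = int(i if rng.random() < 0.5 else j)
            best_value = incumbent_value
            best_plan = None
            for k in range(N):
                if k == replaced:
                    continue
                # replacement neighbors keep S pairs over valid indices,
                # so they are feasible by construction
                neighbor = incumbent.replace_parent(int(pair_index), replaced, k)
                value = objective(neighbor, pass_seed)
                if value > best_value:
                    best_value = value
                    best_plan = neighbor
            if best_plan is not None:
                incumbent = best_plan
                incumbent_value = best_value
                trace.append(best_value)
                improved = True
        if not improved:
            break
    # monotone-acceptance guarantee under the final common stream
    start_value = objective(start, pass_seed)
    final_value = objective(incumbent, pass_seed)
    if start_value > final_value:
        incumbent = start
    if return_trace:
        return incumbent, trace
    return incumbent


def _all_pairs(N: int, selfing: bool = True) -> list[tuple[int, int]]:
    pairs = [(i, j) for i in range(N) for j in range(i, N) if selfing or i != j]
    return pairs


def exhaustive_search(
    objective: Callable[[MatingPlan], float],
    N: int,
    S: int,
    selfing: bool = True,
    max_plans: int = 10**6,
) -> MatingPlan:
    """Enumerate every feasible plan of ``S`` unordered (self-allowed)
    pairs and return the arg-max of a deterministic objective; ties are
    broken lexicographically (first in pair-list order wins).  Guarded
    against instances with more than ``max_plans`` candidate plans."""
    pairs = _all_pairs(N, selfing)
    n_plans = math.comb(len(pairs) + S - 1, S)
    if n_plans > max_plans:
        raise SizeError(f"{n_plans} candidate plans exceed the {max_plans} guard")
    best_plan = None
    best_value = -np.inf
    for combo in itertools.combinations_with_replacement(pairs, S):
        plan = MatingPlan(list(combo), N)
        value = objective(plan)
        if value > best_value:
            best_value = value
            best_plan = plan
    return best_plan


def select_with_method(
    genotypes: GenotypeTensor,
    trait: TraitModel,
    gmap: GeneticMap,
    method: str,
    S: int,
    spec: LookAheadSpec,
    rng: np.random.Generator,
    horizon: int | None = None,
    blocked=None,
    max_stall_passes: int = 3,
) -> MatingPlan:
    """Dispatch to one of the selection strategies.

    ``cgs`` truncation-selects on GEBV with random mating; ``las`` and
    ``pvlas`` run the warm-started local search on their respective
    look-ahead objectives (LAS at the remaining ``horizon``, PV-LAS over
    the sliding window ``spec.W``).
    """
    N = genotypes.n_individuals
    if method == "cgs":
        return select_cgs(gebv(genotypes, trait), S, rng)
    if method == "las":
        if horizon is None or horizon < 1:
            raise ValueError("las requires a remaining horizon >= 1")
        offsets = (horizon,)
        weights = np.ones(1)
    elif method == "pvlas":
        offsets = tuple(range(1, spec.W + 1))
        weights = 1.0 / (1.0 + spec.discount) ** np.asarray(offsets, dtype=float)
    else:
        raise ValueError(f"unknown method {method!r}; expected cgs, las or pvlas")

    if blocked is not None:
        hap_scores, recomb = blocked.block_scores, blocked.block_recomb
    else:
        hap_scores = trait.beta[:, None, None] * genotypes.alleles
        recomb = gmap.recomb
    L_eff = hap_scores.shape[0]
    cache: dict = {"seed": None, "uniforms": None}

    def objective(plan: MatingPlan, seed: int) -> float:
        # one uniform draw per pass seed, shared by every candidate plan
        if cache["seed"] != seed:
            u_rng = np.random.default_rng(seed)
            cache["uniforms"] = [
                draw_progeny_uniforms(tau, spec.K, L_eff, u_rng) for tau in offsets
            ]
            cache["seed"] = seed
        psi = evaluate_psi(
            hap_scores, recomb, plan.crosses, offsets, spec.K, spec.gamma,
            mu=trait.mu, uniforms=cache["uniforms"],
        )
        return float(weights @ psi)

    start = initial_feasible_plan(genotypes, trait, S)
    return local_search(
        objective, start, N, S, rng, max_stall_passes=max_stall_passes
    )
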