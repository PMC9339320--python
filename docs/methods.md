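# Methods

## Model

A population is a phased, biallelic genotype tensor `G ∈ {0,1}^(L×2×N)`
with `G[l,m,i] = 1` when haplotype `m` of diploid individual `i`
carries the major allele at locus `l`. Traits are strictly additive:
the genomic estimated breeding value is
`v_i = μ + Σ_l β_l (G[l,1,i] + G[l,2,i])`, with marker effects `β` and
recombination frequencies `r` treated as known, fixed inputs (no
re-estimation, no dominance/epistasis, no genotype-by-environment
terms). Meiosis follows a first-order Markov (Haldane,
no-interference) model: a gamete copies one parental haplotype at the
first locus (uniformly) and switches source at interval `l` with
probability `r_l`, independently across intervals and gametes.
Intervals crossing a chromosome boundary carry `r = 0.5`.

## Objectives

All three selection strategies pick `S` unordered parent pairs
(selfing allowed) under the mating-plan constraints: the selection
vector `x` and symmetric mating matrix `Y` are binary, exactly `S`
crosses are made, and individuals are selected iff mated.

* **CGS** maximizes `Σ x_i v_i` by truncation; the selected `2S` are
  paired by a uniformly random perfect matching (no selfing in CGS).
* **LAS** maximizes `φ`, the empirical `γ`-quantile of a simulated
  random progeny's GEBV at the deadline, `T − t` generations ahead.
* **PV-LAS** maximizes `ζ = Σ_{τ=1..W} ψ_τ/(1+λ)^τ`, where `ψ_τ` is
  the `γ`-quantile at offset `τ`. The window always spans `W`
  generations (a moving horizon), whereas the LAS horizon shrinks as
  the deadline approaches — that asymmetry is deliberate and is
  hard-coded per method.

`ψ_τ`/`φ` are quantiles of a *random* progeny's GEBV (the largest value
attained with probability ≥ 1 − γ), not of a best-of-batch progeny; the
empirical quantile is the ascending order statistic at rank `⌈γK⌉`
without interpolation, so results are exactly reproducible.

## Look-ahead progeny simulation

The probabilistic construction of a descendant `τ` generations ahead of
a plan of `S` crosses is as follows. Each simulated progeny unites two
independent descendant gametes.

* `τ = 1`: a cross is drawn uniformly; one gamete is sampled from each
  of its parents by ordinary meiosis.
* `τ ≥ 2`: each descendant gamete is a Markov mosaic over the
  4-haplotype pools of the crosses (a selfing cross contributes its
  parent's two haplotypes twice, so selfing-only plans never import
  foreign alleles). The initial state is a uniform cross and slot. At
  interval `l` the chain migrates to a uniformly chosen slot of a
  different uniformly chosen cross with probability
  `R̃_l(τ) = (S−1)[1−(1−r_l)^τ]/S` (zero for `τ ∈ {1,2}`); otherwise it
  switches to one of the other three slots of its current cross
  (uniformly) with probability `1 − (1 − r_l)^τ`.

This reproduces single-meiosis behaviour at `τ = 1`, accumulates
within-cross recombination as `1 − (1−r)^τ`, and introduces
between-cross mixing exactly when `R̃` is non-zero (`τ ≥ 3`, once
grand-progeny of different crosses can mate). All effective switch
probabilities are capped at 0.5, since a recombination fraction cannot
exceed independent assortment; `R̃` itself is reported uncapped by
`lookahead_recomb` (it is bounded by `(S−1)/S` by construction).
Whether the within-cross switch at `τ ≥ 2` should target the three
alternative slots uniformly or favour the homologous parent is an open
modelling choice; uniform was chosen. Likewise, a "progeny" sample is a
full diploid (two gametes), not a single gamete.

Exactness is verified against two independent oracles: exhaustive
enumeration of all `2^L` source paths of a single meiosis (total
variation distance of 100,000 draws < 0.01 on random 3-locus
instances), and brute-force path enumeration of the `4S`-state
descendant chain (empirical means within 3 standard errors at several
offsets).

## Optimization

LAS and PV-LAS plans are found by iterative improvement. The warm
start pairs the top-`2S` GEBV individuals rank-1-with-rank-2,
rank-3-with-rank-4, and so on. Each pass visits the incumbent's
crosses in random order; for a visited cross, one parent (chosen at
random) is tentatively replaced by every individual in the population,
and the incumbent moves to the best strictly improving neighbour. The
search stops at the first improvement-free pass, with a cap of
`max_stall_passes` (default 3) total passes to bound the cost of
noise-driven improvements in stochastic objectives.

Because the objectives are Monte-Carlo estimates, all evaluations
within a pass — including the incumbent's — reuse a single random
substream (common random numbers): the uniform variates are drawn once
per pass and shared across candidate plans, whose draw pattern depends
only on `(K, L, τ)`, never on the plan. On return the incumbent is
compared with the start under the final pass's stream, so the search
never returns a plan that scores worse than its start. An exhaustive
enumerator over all self-allowed pair multisets serves as the test
oracle on small instances.

## Block aggregation

For large marker panels, SNPs are aggregated into `B` contiguous
blocks: block haplotype scores `Σ_{l∈b} β_l G[l,m,i]` sum exactly to
`v_i − μ`, and the look-ahead simulation runs on blocks as atomic units
(within-block recombination is ignored after aggregation — the standard
approximation this aggregation exists to enable). Blocks never span a
chromosome boundary. The partition is equal-count-as-possible within
each chromosome, with blocks allocated to chromosomes by a greedy
divisor rule and remainder loci going to the earliest blocks —
deterministic given `(L, chrom, B)`; an equal-count rule was chosen
over equal-cM or LD-based blocking for simplicity and reproducibility.
The recombination frequency between consecutive blocks on one
chromosome combines every map interval between their first loci,
`1 − Π(1 − r_l)`, capped at 0.5.

## Breeding-program engine and evaluation criteria

Each simulated program iterates selection → reproduction for `T`
generations; every cross produces `N/S` progeny so the population size
is constant. Four criteria are recorded on each fresh progeny
generation, all net of the overall mean `μ` (they are functions of
allele content only):

* mean GEBV `(1/N) Σ_i Σ_l Σ_m G[l,m,i] β_l`;
* lower potential `2 Σ_l min_{m,i} G[l,m,i] β_l` and upper potential
  `2 Σ_l max_{m,i} G[l,m,i] β_l` — bounds on achievable GEBV assuming
  the extreme allele could be fixed homozygous at every locus, i.e.
  measures of remaining useful diversity;
* the present value of per-generation best GEBVs,
  `Σ_τ max_i v_i^(τ) / (1+λ_eval)^τ`.

The evaluation discount `λ_eval` defaults to the PV-LAS objective's own
rate but can be set independently. Without mutation the per-locus
allele multiset can only shrink, so the upper potential is
non-increasing and the lower potential non-decreasing across
generations — asserted in every simulated run.

Replicates draw founders independently from a fixed panel (without
replacement when the panel is large enough). Founder seeds derive from
the master seed and replicate index only, so different methods run on
paired founder populations and can be compared replicate by replicate.
Identical configuration and master seed reproduce output tables byte
for byte.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `W` | 3 | look-ahead window, generations |
| `λ` | 0.1 | discount per generation (dimensionless) |
| `γ` | 0.8 | quantile/risk level of the progeny GEBV distribution |
| `K` | 500 | Monte-Carlo progeny per look-ahead offset |
| `N`, `S`, `T` | 200, 10, 10 | population size, crosses, generations |
| `max_stall_passes` | 3 | local-search pass cap |

## Synthetic data

The generators emulate an inbred crop panel: founders are fully
homozygous by default (an outbred mode exists), with locus-wise
major-allele frequencies uniform on [0.1, 0.9]; effects are sparse
(10% non-zero by default) zero-mean normal draws with both signs
guaranteed for `L ≥ 20`; maps split loci evenly across chromosomes with
within-chromosome `r` uniform on `(0, 2·mean_r]`. Loci are generated
independently, so the panels carry no linkage disequilibrium, no allele
frequency spectrum shaped by demography, and no clustering of effects —
passing tests therefore demonstrate correctness of the algorithms and
the direction of method differences, not effect sizes expected on real
crop data.

The scaled-down comparison study used by the test suite and the
acceptance script runs a 75-line inbred panel with 800 SNPs on 4
chromosomes aggregated into 200 blocks; programs use `N = 50`,
`S = 5`, `T = 8`, `W = 3`, `λ = 0.1`, `γ = 0.8`, `K = 200`, with 50
replicates per method in the test suite and 30 in the acceptance
script. Marker density matters here: with 200 markers on a ~150 cM
chromosome, adjacent markers are ~0.75 cM apart (`r ≈ 0.0075` under
Haldane), the dense-panel regime the look-ahead methods assume — a
sparse map with nearly unlinked blocks would erase the linkage-aware
planning signal the methods exist to exploit. The study sizes keep a
full three-method comparison tractable on one CPU while leaving the
method ordering (PV-LAS > LAS > CGS in mean present value, and PV-LAS ≥
LAS in early-generation mean gain) resolvable by paired sign tests at
α = 0.05.

## Numerical and degenerate-input choices

* Quantile ties and plan-objective ties break deterministically
  (ascending order statistic; first-in-lexicographic-order plan).
* GEBV ties in truncation selection break by ascending individual
  index.
* `L = 1` populations, monomorphic populations, and selfing-only plans
  are all valid and exercised in tests; a selfed fully homozygous
  parent yields exactly degenerate progeny distributions.
* Chromosome boundaries are represented as intervals with `r = 0.5`,
  and the map is interval-based (`L − 1` values), sidestepping physical
  coordinates; centimorgan input is converted with Haldane's function
  `r = 0.5(1 − e^{−2d/100})`, consistent with the no-interference
  meiosis model (Kosambi would presume interference the simulator does
  not model).
* Monte-Carlo kernels are JIT-compiled; all random variates are drawn
  from seeded numpy generators outside the kernels, so determinism
  never depends on the compiler's RNG.

### What the scaled study does and does not show

At this scale the study reproduces the qualitative mechanics of the
methods: both look-ahead strategies dominate CGS decisively in present
value; PV-LAS achieves higher mean and best GEBV than LAS in the early
generations and spends genetic diversity faster (a visibly lower upper
potential from generation 3 on), while LAS finishes with the higher
terminal gain. The *aggregate* present-value separation between PV-LAS
and LAS, however, is within sampling noise at 50 replicates — the
paired PV difference is of the order of 1% with a comparable standard
error — and the first-generation advantage of a heavily discounted
objective over an undiscounted one, while positive in a majority of
paired replicates, is not significant at 30 replicates. Resolving
those two contrasts appears to need the full-scale setting (hundreds
of individuals, ten crosses, dense real maps, hundreds of replicates)
rather than a desk-scale one. One structural reason: at long look-ahead
horizons the descendant-gamete chain is close to fully mixed, so the
LAS objective measures aggregate favorable-allele content across the
whole plan and LAS is not early-generation-weak here, unlike in the
full-scale setting it was originally compared in.

## Known limitations

* No LD or demographic structure in synthetic founders; no mutation,
  crossover interference, sex, or ploidy beyond diploid.
* Marker effects and recombination rates are assumed exact; the
  look-ahead methods consume more of this information than CGS and are
  correspondingly more sensitive to its accuracy.
* The local search is a heuristic: it guarantees feasibility and
  monotone improvement, not global optimality (the exhaustive oracle is
  limited to small instances).
* Resource allocation is fixed at equal progeny per cross; the
  exact integer program behind the look-ahead formulation is not
  solved.
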