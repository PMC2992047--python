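"""Strain-design search and scoring.

A candidate mutant is scored by simulating it with MOMA against a
reference flux distribution and computing

* the product yield  Y = v_product / v_substrate  (mol/mol),
* the biomass-product coupled yield  BPCY = Y * mu  (the "reward"),
* the metabolic adjustment  MA = ||v - w||_2  (the "risk"), and
* the reward-risk ratio  R^3 = BPCY / MA,

optionally normalized to the best design of a panel (the top design
scores exactly 100 %).  Designs whose R^3 is undefined (MA below epsilon,
i.e. phenotypically identical to the reference) are excluded from R^3
ranking rather than treated as infinitely good.

Two searches are provided: exhaustive enumeration of knockout subsets up
to size k (with a bilevel-style FBA verification of each returned design)
and a seeded genetic algorithm over binary knockout genomes with BPCY
fitness, tournament selection, uniform crossover, per-bit mutation and
single elitism.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .config import DEFAULT_TOLERANCES, Tolerances
from .solvers import (
    Infeasible,
    Unbounded,
    flux_variability,
    growth_reaction_id,
    solve_fba,
    solve_moma,
)
from .stoichmodel import FluxDistribution, MutantDesign, StoichiometricModel, apply_design


@dataclass
class DesignEvaluation:
    """Scores of one mutant design against a reference flux distribution."""

    design: MutantDesign
    growth: float = 0.0
    substrate_uptake: float = 0.0
    product_flux: float = 0.0
    yield_: float = 0.0
    bpcy: float = 0.0
    ma: float = 0.0
    r3: float | None = None
    r3_normalized: float | None = None
    viable: bool = False
    fba_product_range: tuple[float, float] | None = None


@dataclass
class GAParams:
    """Genetic-algorithm hyperparameters; ``seed`` is mandatory.

    ``per_bit_mutation`` defaults to 1/L for a genome of length L;
    ``init_bit_prob`` is the probability that a bit of an initial genome
    is set (also 1/L by default).
    """

    seed: int
    population_size: int = 100
    generations: int = 200
    per_bit_mutation: float | None = None
    crossover: float = 0.8
    tournament_size: int = 2
    max_knockouts: int = 6
    init_bit_prob: float | None = None

    def __post_init__(self):
        for p in (self.per_bit_mutation, self.crossover, self.init_bit_prob):
            if p is not None and not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.population_size < 1 or self.generations < 0:
            raise ValueError("population_size >= 1 and generations >= 0 required")
        if self.tournament_size < 1:
            raise ValueError("tournament_size >= 1 required")


def evaluate_design(
    model: StoichiometricModel,
    design: MutantDesign,
    reference: FluxDistribution,
    product: str,
    substrate: str,
    tolerances: Tolerances = DEFAULT_TOLERANCES,
) -> DesignEvaluation:
    """Score one design by MOMA against the reference.

    ``model`` is the (state-constrained) wild-type model; solver
    infeasibility is converted into a non-viable evaluation (never an
    exception) so that searches are total.  Non-viable designs score
    ``bpcy = 0``.
    """
    growth_id = growth_reaction_id(model)
    ev = DesignEvaluation(design=design)
    try:
        mutant = apply_design(model, design, reference=reference)
        sol, ma = solve_moma(mutant, reference, tolerances=tolerances)
    except (Infeasible, Unbounded):
        return ev
    ev.growth = sol.get(growth_id)
    ev.substrate_uptake = abs(sol.get(substrate))
    ev.product_flux = max(sol.get(product), 0.0)
    ev.ma = ma
    ev.viable = ev.growth > tolerances.growth_floor
    if ev.substrate_uptake > tolerances.comparison:
        ev.yield_ = ev.product_flux / ev.substrate_uptake
    if ev.viable:
        ev.bpcy = ev.yield_ * ev.growth
        if ma >= tolerances.ma_epsilon:
            ev.r3 = ev.bpcy / ma
    else:
        ev.growth = max(ev.growth, 0.0)
        ev.bpcy = 0.0
    return ev


def normalize_r3(evaluations: list[DesignEvaluation]) -> list[DesignEvaluation]:
    """Normalize R^3 scores to the best design of the panel (= 100 %).

    Entries with undefined R^3 stay unnormalized.  Raises ``ValueError``
    when no entry has a defined R^3.
    """
    defined = [e.r3 for e in evaluations if e.r3 is not None]
    if not defined:
        raise ValueError("no evaluation has a defined reward-risk ratio")
    best = max(defined)
    out = []
    for e in evaluations:
        if e.r3 is None:
            out.append(replace(e, r3_normalized=None))
        elif e.r3 == best:
            out.append(replace(e, r3_normalized=100.0))
        else:
            out.append(replace(e, r3_normalized=100.0 * e.r3 / best))
    return out


def default_candidates(model: StoichiometricModel) -> list[str]:
    """Knockout candidates: internal reactions, excluding exchanges (any
    reaction touching a boundary species, which covers the biomass drain)
    and the maintenance ATPase."""
    external = {m.id for m in model.metabolites if m.is_external}
    out = []
    for r in model.reactions:
        if any(met in external for met in r.stoichiometry):
            continue
        if set(r.stoichiometry) == {"atp"}:
            continue
        out.append(r.id)
    return out


def _rank_key(rank_by: str):
    if rank_by == "bpcy":
        return lambda e: (e.bpcy, e.growth)
    if rank_by == "r3":
        return lambda e: (-math.inf if e.r3 is None else e.r3, e.bpcy)
    raise ValueError(f"unknown ranking key {rank_by!r}")


def _bilevel_product_range(
    model: StoichiometricModel,
    design: MutantDesign,
    reference: FluxDistribution,
    product: str,
    tolerances: Tolerances,
) -> tuple[float, float] | None:
    """Inner-FBA verification: product flux at FBA-optimal mutant growth.

    Returns the [pessimistic, optimistic] product interval (min and max
    product flux with growth fixed at the mutant's FBA optimum), the
    quantity a bilevel knockout formulation would certify.
    """
    try:
        mutant = apply_design(model, design, reference=reference)
        mu = solve_fba(mutant, tolerances=tolerances).objective_value
        if mu <= tolerances.growth_floor:
            return (0.0, 0.0)
        growth = mutant.reaction(growth_reaction_id(mutant))
        slack = 1e-9 * max(1.0, abs(mu))
        growth.lower_bound, growth.upper_bound = mu - slack, mu + slack
        rng = flux_variability(mutant, reactions=[product], tolerances=tolerances)
        fr = rng[product]
        return (fr.lo, fr.hi)
    except (Infeasible, Unbounded):
        return None


def exhaustive_search(
    model: StoichiometricModel,
    reference: FluxDistribution,
    product: str,
    substrate: str,
    k: int,
    candidates: list[str] | None = None,
    rank_by: str = "bpcy",
    tolerances: Tolerances = DEFAULT_TOLERANCES,
) -> list[DesignEvaluation]:
    """Evaluate every knockout subset of size <= k, ranked by ``rank_by``.

    The empty design (the reference itself) is always included.  Each
    returned evaluation carries the bilevel-style FBA product interval in
    ``fba_product_range``.
    """
    cand = default_candidates(model) if candidates is None else list(candidates)
    known = set(model.reaction_ids)
    unknown = [c for c in cand if c not in known]
    if unknown:
        raise ValueError(f"unknown candidate reactions {unknown}")
    evaluations = []
    for size in range(k + 1):
        for combo in itertools.combinations(cand, size):
            design = MutantDesign(knockouts=frozenset(combo))
            ev = evaluate_design(model, design, reference, product, substrate,
                                 tolerances=tolerances)
            ev.fba_product_range = _bilevel_product_range(
                model, design, reference, product, tolerances)
            evaluations.append(ev)
    evaluations.sort(key=_rank_key(rank_by), reverse=True)
    return evaluations


def optgene_search(
    model: StoichiometricModel,
    reference: FluxDistribution,
    product: str,
    substrate: str,
    params: GAParams,
    candidates: list[str] | None = None,
    tolerances: Tolerances = DEFAULT_TOLERANCES,
) -> list[DesignEvaluation]:
    """Genetic-algorithm knockout search with BPCY fitness.

    Binary genomes (one bit per candidate reaction), tournament
    selection, uniform crossover, per-bit mutation, elitism of one and a
    repair step that clears random excess bits beyond ``max_knockouts``.
    Fully reproducible from ``params.seed``; returns the final
    population's unique designs ranked by fitness.
    """
    cand = default_candidates(model) if candidates is None else list(candidates)
    if not cand:
        raise ValueError("empty candidate set")
    L = len(cand)
    rng = np.random.default_rng(params.seed)
    p_mut = params.per_bit_mutation if params.per_bit_mutation is not None else 1.0 / L
    p_init = params.init_bit_prob if params.init_bit_prob is not None else 1.0 / L

    cache: dict[frozenset, DesignEvaluation] = {}

    def fitness(genome: np.ndarray) -> DesignEvaluation:
        key = frozenset(c for c, bit in zip(cand, genome) if bit)
        if key not in cache:
            cache[key] = evaluate_design(
                model, MutantDesign(knockouts=key), reference, product,
                substrate, tolerances=tolerances)
        return cache[key]

    def repair(genome: np.ndarray) -> np.ndarray:
        on = np.flatnonzero(genome)
        while len(on) > params.max_knockouts:
            drop = on[rng.integers(len(on))]
            genome[drop] = False
            on = np.flatnonzero(genome)
        return genome

    pop = [repair(rng.random(L) < p_init) for _ in range(params.population_size)]
    scores = [fitness(g).bpcy for g in pop]

    for _ in range(params.generations):
        elite = pop[int(np.argmax(scores))].copy()
        nxt = [elite]
        while len(nxt) < params.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(params.population_size,
                                          size=params.tournament_size)
                best = max(contenders, key=lambda i: scores[i])
                parents.append(pop[best])
            a = parents[0].copy()
            if rng.random() < params.crossover:
                mask = rng.random(L) < 0.5
                a = np.where(mask, parents[0], parents[1])
            if p_mut > 0:
                flips = rng.random(L) < p_mut
                a = np.logical_xor(a, flips)
            nxt.append(repair(np.asarray(a, dtype=bool)))
        pop = nxt
        scores = [fitness(g).bpcy for g in pop]

    unique = {frozenset(c for c, bit in zip(cand, g) if bit) for g in pop}
    result = [cache[key] for key in unique]
    result.sort(key=lambda e: (e.bpcy, e.growth, sorted(e.design.knockouts)),
                reverse=True)
    return result
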