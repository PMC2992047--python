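"""Optimization layer: FBA, parsimonious reference FBA, MOMA, FVA and
minimum metabolite turnover.

All linear programs run through scipy's HiGHS interface; the quadratic
MOMA projection is solved by a primal active-set method on the strictly
convex program ``min ||v - w||^2 s.t. S v = 0, bounds`` (exact KKT solves
on the working set), with a gradient-based interior-point fallback.  Every
routine is deterministic given fixed inputs and tolerances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np
from scipy.optimize import linprog

from .config import DEFAULT_TOLERANCES, Tolerances
from .stoichmodel import (
    FluxDistribution,
    ModelValidationError,
    StoichiometricModel,
    validate_model,
)

if TYPE_CHECKING:  # pragma: no cover
    from .toynet import PhysiologicalState


class Infeasible(Exception):
    """The constraint polytope is empty.

    ``details`` lists the non-default bound intervals that were in force,
    so the caller can see which constraints to suspect.
    """

    def __init__(self, message: str, details: list[str] | None = None):
        super().__init__(message)
        self.details = details or []


class Unbounded(Exception):
    """The LP objective is unbounded; the message names witness reactions."""


@dataclass
class FluxRange:
    """Attainable flux interval of one reaction under fixed constraints."""

    reaction: str
    lo: float
    hi: float


@dataclass
class FluxSumResult:
    """Minimum turnover of a metabolite and a flux vector attaining it."""

    metabolite: str
    phi_min: float
    support: FluxDistribution


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _require_valid(model: StoichiometricModel) -> None:
    """Solvers rely on structural validity; reject broken models up front."""
    errors = [d for d in validate_model(model, check_carbon=False)
              if d.severity == "error"]
    if errors:
        raise ModelValidationError(
            "model fails validation: " + "; ".join(d.message or d.code for d in errors)
        )


def growth_reaction_id(model: StoichiometricModel) -> str:
    """The growth reaction: the single positively weighted objective key."""
    keys = [k for k, c in model.objective.items() if c]
    if len(keys) != 1:
        raise ValueError(
            f"expected a single objective (growth) reaction, found {keys}"
        )
    return keys[0]


def apply_state(
    model: StoichiometricModel, state: "PhysiologicalState"
) -> StoichiometricModel:
    """Return a copy of the model constrained to a physiological state."""
    out = model.copy()
    for rxn_id, (lo, hi) in state.fixed_rates.items():
        rxn = out.reaction(rxn_id)
        rxn.lower_bound, rxn.upper_bound = lo, hi
    if state.glucose_uptake is not None and "glucose_uptake" not in state.fixed_rates:
        rxn = out.reaction("glucose_uptake")
        rxn.lower_bound, rxn.upper_bound = state.glucose_uptake
    if state.oxygen_uptake is not None:
        rxn = out.reaction("oxygen_uptake")
        rxn.lower_bound, rxn.upper_bound = state.oxygen_uptake
    if state.growth_rate is not None:
        rxn = out.reaction(growth_reaction_id(out))
        rxn.lower_bound = rxn.upper_bound = state.growth_rate
    return out


def _bound_report(model: StoichiometricModel) -> list[str]:
    from .stoichmodel import DEFAULT_BOUND

    report = []
    for r in model.reactions:
        if r.lower_bound not in (0.0, -DEFAULT_BOUND) or r.upper_bound != DEFAULT_BOUND:
            report.append(f"{r.id}: [{r.lower_bound:g}, {r.upper_bound:g}]")
    return report


def _residual(S: np.ndarray, v: np.ndarray) -> float:
    return float(np.max(np.abs(S @ v))) if S.size else 0.0


def _objective_vector(model, rxn_ids, objective) -> np.ndarray:
    c = np.zeros(len(rxn_ids))
    index = {r: j for j, r in enumerate(rxn_ids)}
    obj = model.objective if objective is None else objective
    for rxn_id, coeff in obj.items():
        c[index[rxn_id]] = coeff
    return c


# ---------------------------------------------------------------------------
# flux balance analysis
# ---------------------------------------------------------------------------

def solve_fba(
    model: StoichiometricModel,
    objective: Mapping[str, float] | None = None,
    tolerances: Tolerances = DEFAULT_TOLERANCES,
) -> FluxDistribution:
    """Maximize ``c . v`` subject to ``S v = 0`` and flux bounds.

    Returns a vertex solution with ``objective_value`` set.  Raises
    :class:`Infeasible` (with a report of the non-default bounds) or
    :class:`Unbounded` (naming the objective reactions) as appropriate.
    """
    _require_valid(model)
    S, _, rxn_ids = model.stoichiometric_matrix()
    c = _objective_vector(model, rxn_ids, objective)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    res = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                  method="highs")
    if res.status == 2:
        raise Infeasible(
            "flux polytope is empty under the applied bounds",
            details=_bound_report(model),
        )
    if res.status == 3:
        witnesses = [r for r, w in zip(rxn_ids, c) if w]
        raise Unbounded(f"objective unbounded through reactions {witnesses}")
    if res.status != 0:  # pragma: no cover - solver failure
        raise RuntimeError(f"LP solver failed: {res.message}")
    v = res.x
    return FluxDistribution(
        fluxes=dict(zip(rxn_ids, map(float, v))),
        objective_value=float(c @ v),
        residual=_residual(S, v),
    )


def _min_weighted_abs_flux(
    model: StoichiometricModel,
    weights: np.ndarray,
    tolerances: Tolerances,
) -> tuple[np.ndarray, float, list[str], np.ndarray]:
    """Minimize ``sum_j weights_j |v_j|`` over the flux polytope.

    Reversible reactions are split ``v = v+ - v-``; at a vertex optimum
    with positive weights the two parts are complementary.  Returns
    ``(v, optimum, reaction_ids, S)``.
    """
    S, _, rxn_ids = model.stoichiometric_matrix()
    n = len(rxn_ids)
    lbs = np.array([r.lower_bound for r in model.reactions])
    ubs = np.array([r.upper_bound for r in model.reactions])
    split = [j for j in range(n) if lbs[j] < 0 < ubs[j]]
    n_extra = len(split)
    # columns: v+ for every reaction, then v- for split reactions
    A = np.hstack([S, -S[:, split]]) if n_extra else S
    c = np.concatenate([weights, weights[split]]) if n_extra else weights.copy()
    bounds = []
    for j in range(n):
        if j in split:
            bounds.append((0.0, max(ubs[j], 0.0)))
        else:
            bounds.append((lbs[j], ubs[j]))
    for j in split:
        bounds.append((0.0, -lbs[j]))
    res = linprog(c, A_eq=A, b_eq=np.zeros(A.shape[0]), bounds=bounds,
                  method="highs")
    if res.status == 2:
        raise Infeasible("flux polytope is empty", details=_bound_report(model))
    if res.status != 0:  # pragma: no cover
        raise RuntimeError(f"LP solver failed: {res.message}")
    v = res.x[:n].copy()
    for i, j in enumerate(split):
        v[j] -= res.x[n + i]
    return v, float(res.fun), rxn_ids, S


def reference_fba(
    model: StoichiometricModel,
    state: "PhysiologicalState | None" = None,
    tolerances: Tolerances = DEFAULT_TOLERANCES,
) -> FluxDistribution:
    """FBA for maximal growth with a parsimonious tie-break.

    Applies the state constraints, maximizes growth, then fixes growth at
    its optimum and minimizes the total absolute flux to select a unique,
    physiologically meaningful wild-type flux distribution.  Deterministic
    across runs.
    """
    constrained = apply_state(model, state) if state is not None else model.copy()
    best = solve_fba(constrained, tolerances=tolerances)
    mu = best.objective_value
    growth = constrained.reaction(growth_reaction_id(constrained))
    slack = 1e-9 * max(1.0, abs(mu))
    growth.lower_bound = max(growth.lower_bound, mu - slack)
    growth.upper_bound = min(growth.upper_bound, mu + slack)
    weights = np.ones(len(constrained.reactions))
    v, _, rxn_ids, S = _min_weighted_abs_flux(constrained, weights, tolerances)
    return FluxDistribution(
        fluxes=dict(zip(rxn_ids, map(float, v))),
        objective_value=mu,
        residual=_residual(S, v),
        name=getattr(state, "mode", None),
    )


# ---------------------------------------------------------------------------
# MOMA
# ---------------------------------------------------------------------------

def _feasible_point(model: StoichiometricModel) -> np.ndarray:
    S, _, _ = model.stoichiometric_matrix()
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    res = linprog(np.zeros(S.shape[1]), A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=bounds, method="highs")
    if res.status == 2:
        raise Infeasible("mutant flux polytope is empty",
                         details=_bound_report(model))
    if res.status != 0:  # pragma: no cover
        raise RuntimeError(f"LP solver failed: {res.message}")
    return res.x


def _box_qp_active_set(
    S: np.ndarray,
    w: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    x0: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> np.ndarray:
    """Solve ``min ||x - w||^2 s.t. S x = 0, lb <= x <= ub`` exactly.

    Primal active-set method: on each working set the equality-constrained
    projection is solved through its KKT system (least-squares for the
    equality multipliers, tolerant of redundant rows of S).
    """
    n = len(w)
    x = x0.copy()
    fixed = lb >= ub - 1e-12  # permanently active
    at_lo = fixed | (x <= lb + 1e-9)
    at_hi = ~fixed & (x >= ub - 1e-9)

    for _ in range(max_iter):
        active = at_lo | at_hi
        free = ~active
        xa = np.where(at_lo, lb, np.where(at_hi, ub, 0.0))
        b = -S[:, active] @ xa[active] if active.any() else np.zeros(S.shape[0])
        Sf = S[:, free]
        # stationarity: x_f = w_f - 0.5 * Sf^T y ; feasibility: Sf x_f = b
        rhs = 2.0 * (Sf @ w[free] - b)
        y, *_ = np.linalg.lstsq(Sf @ Sf.T, rhs, rcond=None)
        x_eq = np.where(at_lo, lb, np.where(at_hi, ub, 0.0))
        x_eq[free] = w[free] - 0.5 * (Sf.T @ y)

        d = x_eq - x
        if np.max(np.abs(d)) <= tol:
            # converged on this working set: check bound multipliers
            grad = 2.0 * (x - w) + S.T @ y
            worst, worst_j, drop_side = 0.0, -1, None
            for j in range(n):
                if fixed[j] or not active[j]:
                    continue
                if at_hi[j] and grad[j] > worst + 1e-9:
                    worst, worst_j, drop_side = grad[j], j, "hi"
                elif at_lo[j] and -grad[j] > worst + 1e-9:
                    worst, worst_j, drop_side = -grad[j], j, "lo"
            if worst_j < 0:
                return x
            if drop_side == "hi":
                at_hi[worst_j] = False
            else:
                at_lo[worst_j] = False
            continue

        # line search to the first blocking bound
        alpha, block_j, block_side = 1.0, -1, None
        for j in np.flatnonzero(free):
            if d[j] > tol:
                a = (ub[j] - x[j]) / d[j]
                if a < alpha - 1e-12:
                    alpha, block_j, block_side = a, j, "hi"
            elif d[j] < -tol:
                a = (lb[j] - x[j]) / d[j]
                if a < alpha - 1e-12:
                    alpha, block_j, block_side = a, j, "lo"
        alpha = max(alpha, 0.0)
        x = x + alpha * d
        if block_j >= 0:
            x[block_j] = ub[block_j] if block_side == "hi" else lb[block_j]
            if block_side == "hi":
                at_hi[block_j] = True
            else:
                at_lo[block_j] = True
    return x  # pragma: no cover - iteration cap


def _box_qp_fallback(S, w, lb, ub, x0) -> np.ndarray:  # pragma: no cover
    from scipy.optimize import Bounds, LinearConstraint, minimize

    res = minimize(
        lambda x: float(np.sum((x - w) ** 2)),
        x0,
        jac=lambda x: 2.0 * (x - w),
        bounds=Bounds(lb, ub),
        constraints=[LinearConstraint(S, 0.0, 0.0)],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    return res.x


def solve_moma(
    model: StoichiometricModel,
    reference: FluxDistribution,
    tolerances: Tolerances = DEFAULT_TOLERANCES,
) -> tuple[FluxDistribution, float]:
    """Minimization of metabolic adjustment.

    Finds the mutant flux distribution of minimal Euclidean distance to
    the reference (``min sum_j (v_j - w_j)^2`` subject to steady state and
    the mutant bounds) and returns it together with the metabolic
    adjustment ``MA = sqrt(sum_j (v_j - w_j)^2)``.  The distance runs over
    the union of reactions: model reactions absent from the reference use
    ``w_j = 0``; reference reactions absent from the model contribute
    ``w_j^2`` (their mutant flux is necessarily zero).
    """
    _require_valid(model)
    S, _, rxn_ids = model.stoichiometric_matrix()
    w = np.array([reference.get(r, 0.0) for r in rxn_ids])
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    x0 = _feasible_point(model)
    x = _box_qp_active_set(S, w, lb, ub, x0)
    feasible = (
        _residual(S, x) <= 10 * tolerances.feasibility
        and np.all(x >= lb - 1e-6)
        and np.all(x <= ub + 1e-6)
    )
    if not feasible:  # pragma: no cover - active set is expected to succeed
        x = _box_qp_fallback(S, w, lb, ub, x0)

    extra = sum(
        reference.fluxes[r] ** 2 for r in reference.fluxes if r not in set(rxn_ids)
    )
    ma = math.sqrt(float(np.sum((x - w) ** 2)) + extra)
    growth_id = growth_reaction_id(model) if model.objective else None
    sol = FluxDistribution(
        fluxes=dict(zip(rxn_ids, map(float, x))),
        objective_value=float(dict(zip(rxn_ids, x)).get(growth_id, 0.0))
        if growth_id
        else None,
        residual=_residual(S, x),
    )
    return sol, ma


# ---------------------------------------------------------------------------
# flux variability analysis
# ---------------------------------------------------------------------------

def flux_variability(
    model: StoichiometricModel,
    state: "PhysiologicalState | None" = None,
    fix_growth: bool = False,
    reactions: list[str] | None = None,
    tolerances: Tolerances = DEFAULT_TOLERANCES,
) -> dict[str, FluxRange]:
    """Per-reaction minimum and maximum flux under the given state.

    With ``fix_growth`` the growth reaction is pinned to the state's rate
    (or, when the state leaves growth free, to the FBA optimum) before the
    per-reaction ranges are computed.
    """
    _require_valid(model)
    constrained = apply_state(model, state) if state is not None else model.copy()
    if fix_growth:
        growth = constrained.reaction(growth_reaction_id(constrained))
        if growth.lower_bound != growth.upper_bound:
            mu = solve_fba(constrained, tolerances=tolerances).objective_value
            slack = 1e-9 * max(1.0, abs(mu))
            growth.lower_bound, growth.upper_bound = mu - slack, mu + slack

    S, _, rxn_ids = constrained.stoichiometric_matrix()
    bounds = [(r.lower_bound, r.upper_bound) for r in constrained.reactions]
    b_eq = np.zeros(S.shape[0])
    targets = rxn_ids if reactions is None else list(reactions)
    index = {r: j for j, r in enumerate(rxn_ids)}
    ranges: dict[str, FluxRange] = {}
    for rxn_id in targets:
        j = index[rxn_id]
        c = np.zeros(len(rxn_ids))
        c[j] = 1.0
        extremes = []
        for sign in (1.0, -1.0):
            res = linprog(sign * c, A_eq=S, b_eq=b_eq, bounds=bounds,
                          method="highs")
            if res.status == 2:
                raise Infeasible(
                    "flux polytope is empty under the applied state",
                    details=_bound_report(constrained),
                )
            if res.status != 0:  # pragma: no cover
                raise RuntimeError(f"LP solver failed: {res.message}")
            extremes.append(sign * res.fun)
        lo, hi = extremes
        if lo > hi:  # numerical jitter on a pinned flux
            lo = hi = 0.5 * (lo + hi)
        ranges[rxn_id] = FluxRange(reaction=rxn_id, lo=float(lo), hi=float(hi))
    return ranges


# ---------------------------------------------------------------------------
# minimum metabolite turnover (flux-sum)
# ---------------------------------------------------------------------------

def min_flux_sum(
    model: StoichiometricModel,
    metabolite: str,
    state: "PhysiologicalState | None" = None,
    tolerances: Tolerances = DEFAULT_TOLERANCES,
) -> FluxSumResult:
    """Minimum turnover Phi of an internal metabolite.

    Phi_i = 1/2 sum_k |S_ik v_k| is minimized over steady-state flux
    vectors with the state's exchange fluxes (including growth) fixed at
    their interval midpoints; fluxes are split into nonnegative forward
    and reverse parts so the absolute values are linear.  Minimization
    suppresses futile cycles around the metabolite, so the result is the
    flux that genuinely must pass through it.
    """
    _require_valid(model)
    met = model.metabolite(metabolite)
    if met.is_external:
        raise ValueError(f"metabolite {metabolite!r} is external")

    constrained = apply_state(model, state) if state is not None else model.copy()
    if state is not None:
        for rxn_id, (lo, hi) in state.fixed_rates.items():
            rxn = constrained.reaction(rxn_id)
            mid = 0.5 * (lo + hi)
            rxn.lower_bound = rxn.upper_bound = mid

    S, met_ids, rxn_ids = constrained.stoichiometric_matrix()
    i = met_ids.index(metabolite)
    weights = 0.5 * np.abs(S[i, :])
    v, phi, rxn_ids, S = _min_weighted_abs_flux(constrained, weights, tolerances)
    phi_check = 0.5 * float(np.sum(np.abs(S[i, :] * v)))
    if abs(phi_check - phi) > 1e-6 * max(1.0, abs(phi)):  # pragma: no cover
        raise RuntimeError(
            f"turnover mismatch: LP optimum {phi} vs definition {phi_check}"
        )
    support = FluxDistribution(
        fluxes=dict(zip(rxn_ids, map(float, v))),
        objective_value=phi,
        residual=_residual(S, v),
    )
    return FluxSumResult(metabolite=metabolite, phi_min=float(phi), support=support)
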