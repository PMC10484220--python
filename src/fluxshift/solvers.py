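"""Flux balance analysis (LP) and minimization of metabolic adjustment (QP).

FBA maximizes the model's linear objective c·v subject to steady state
S·v = 0 and the flux bounds lb ≤ v ≤ ub. Because FBA optima are typically
degenerate, :func:`solve_fba` breaks ties by returning the unique
minimum-L2-norm optimum (a secondary quadratic program constrained to the
optimal objective value), so the wild-type reference flux handed to MOMA is
deterministic and reproducible.

MOMA finds the flux vector of a perturbed model closest in Euclidean
distance to a reference (wild-type) flux w:

    minimize  Σ_j (v_j − w_j)²   s.t.  S·v = 0,  lb ≤ v ≤ ub

The objective is strictly convex, so the solution is unique. The distance
sums over all reactions, exchanges included. Reactions present in the
perturbed model but absent from the reference are treated as w_j = 0.

The QP is solved by SQP (scipy's SLSQP) from a feasible interior point,
followed by an exact KKT refinement on the detected active set; the
refinement solves the equality-constrained quadratic subproblem in closed
form and is accepted only when primal feasibility and multiplier signs
check out, which pins solutions to ~1e-10 accuracy on well-scaled models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.optimize import Bounds, linprog, minimize

from .exceptions import ConfigurationError, ContractError
from .metnet import MetabolicModel, stoichiometric_matrix

STATUS_OPTIMAL = "optimal"
STATUS_FEASIBLE = "feasible"  # certified-feasible witness, not an optimum
STATUS_INFEASIBLE = "infeasible"
STATUS_UNBOUNDED = "unbounded"

#: statuses whose flux vectors satisfy all constraints
_SOLVED = (STATUS_OPTIMAL, STATUS_FEASIBLE)


@dataclass(frozen=True)
class SolverTolerances:
    """Numerical tolerances, all in flux units (nominally mmol·gDW⁻¹·h⁻¹)."""

    mass_balance: float = 1e-6
    bound: float = 1e-6
    qp_convergence: float = 1e-8


DEFAULT_TOLERANCES = SolverTolerances()


@dataclass(frozen=True)
class FluxDistribution:
    """One steady-state flux value per reaction plus solver status.

    ``objective_value`` is the attained c·v for FBA and the squared
    Euclidean distance to the reference for MOMA. When status is not a
    solved status the flux map is empty.
    """

    model_id: str
    fluxes: Mapping[str, float]
    status: str
    objective_value: float | None = None
    tolerances: SolverTolerances = field(default=DEFAULT_TOLERANCES)

    def __post_init__(self):
        object.__setattr__(self, "fluxes", dict(self.fluxes))

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]

    def get(self, reaction_id: str, default: float = 0.0) -> float:
        return self.fluxes.get(reaction_id, default)

    @property
    def solved(self) -> bool:
        return self.status in _SOLVED

    def as_vector(self, model: MetabolicModel) -> np.ndarray:
        return np.array([self.fluxes.get(r.id, 0.0) for r in model.reactions])

    def to_tsv(self, path: str | Path) -> None:
        lines = ["reaction_id\tflux"]
        lines += [f"{rid}\t{v:.9g}" for rid, v in self.fluxes.items()]
        Path(path).write_text("\n".join(lines) + "\n")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "model_id": self.model_id,
            "status": self.status,
            "objective_value": self.objective_value,
            "fluxes": {k: self.fluxes[k] for k in sorted(self.fluxes)},
            "tolerances": {
                "mass_balance": self.tolerances.mass_balance,
                "bound": self.tolerances.bound,
                "qp_convergence": self.tolerances.qp_convergence,
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def mass_balance_residual(model: MetabolicModel, dist: FluxDistribution) -> float:
    """max |S·v| over metabolites; ≤ mass-balance tolerance for solved flux
    distributions."""
    S = stoichiometric_matrix(model)
    v = dist.as_vector(model)
    return float(np.max(np.abs(S @ v))) if S.size else 0.0


# ---------------------------------------------------------------------------
# quadratic program: min ½‖v − w‖²  s.t.  A v = b, lb ≤ v ≤ ub
# ---------------------------------------------------------------------------


def _solve_box_eq_qp(
    A: np.ndarray,
    b: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    w: np.ndarray,
    tol: SolverTolerances,
) -> tuple[np.ndarray | None, str]:
    """Strictly convex QP over box and equality constraints.

    Returns (solution, status). Internally rescales the problem to unit
    magnitude so convergence tests are scale-free.
    """
    n = len(w)
    if n == 0:
        return np.zeros(0), STATUS_OPTIMAL

    finite = np.concatenate([x[np.isfinite(x)] for x in (lb, ub, w)] + [np.ones(1)])
    scale = float(np.max(np.abs(finite)))
    A_s, b_s = A, b / scale if len(b) else b
    lb_s, ub_s, w_s = lb / scale, ub / scale, w / scale

    # phase 1: a feasible starting point (also detects infeasibility)
    feas = linprog(
        np.zeros(n),
        A_eq=A_s if A_s.size else None,
        b_eq=b_s if A_s.size else None,
        bounds=np.column_stack([lb_s, ub_s]),
        method="highs",
    )
    if feas.status == 2:
        return None, STATUS_INFEASIBLE
    if feas.status != 0:
        raise RuntimeError(f"feasibility phase failed: {feas.message}")
    x0 = feas.x

    constraints = []
    if A_s.size:
        constraints.append(
            {"type": "eq", "fun": lambda v: A_s @ v - b_s, "jac": lambda v: A_s}
        )
    res = minimize(
        lambda v: 0.5 * float((v - w_s) @ (v - w_s)),
        x0,
        jac=lambda v: v - w_s,
        bounds=Bounds(lb_s, ub_s),
        constraints=constraints,
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 1000},
    )
    x = np.clip(res.x if res.success else x0, lb_s, ub_s)
    x = _kkt_polish(A_s, b_s, lb_s, ub_s, w_s, x)
    return x * scale, STATUS_OPTIMAL


def _kkt_polish(
    A: np.ndarray,
    b: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    w: np.ndarray,
    x: np.ndarray,
    active_tol: float = 1e-6,
    kkt_tol: float = 1e-7,
) -> np.ndarray:
    """Refine an approximate QP solution by solving the equality-constrained
    subproblem on its active set exactly; fall back to ``x`` unless the
    refined point passes primal feasibility and multiplier-sign checks."""
    n = len(x)
    at_lower = x - lb <= active_tol
    at_upper = ub - x <= active_tol
    fixed = at_lower | at_upper
    fixed_vals = np.where(at_lower, lb, ub)

    free = ~fixed
    n_eq = A.shape[0] if A.size else 0
    v = np.empty(n)
    v[fixed] = fixed_vals[fixed]
    if free.any():
        A_free = A[:, free] if n_eq else np.zeros((0, free.sum()))
        c = (b - A[:, fixed] @ v[fixed]) if n_eq else np.zeros(0)
        # v_free = w_free − A_freeᵀ λ with A_free v_free = c
        G = A_free @ A_free.T if n_eq else np.zeros((0, 0))
        rhs = (A_free @ w[free] - c) if n_eq else np.zeros(0)
        lam = np.linalg.lstsq(G, rhs, rcond=None)[0] if n_eq else np.zeros(0)
        v[free] = w[free] - (A_free.T @ lam if n_eq else 0.0)
    else:
        A_free = A[:, free] if n_eq else None
        lam = (
            np.linalg.lstsq(A.T, -(v - w), rcond=None)[0] if n_eq else np.zeros(0)
        )

    # primal feasibility of the refined point
    if np.any(v < lb - kkt_tol) or np.any(v > ub + kkt_tol):
        return x
    if n_eq and np.max(np.abs(A @ v - b)) > kkt_tol:
        return x
    # dual feasibility: multipliers of active bounds must push inward
    g = v - w + (A.T @ lam if n_eq else 0.0)
    strict = lb + active_tol < ub - active_tol  # skip pinned lb == ub vars
    if np.any(g[at_lower & strict] < -kkt_tol):
        return x
    if np.any(g[at_upper & strict] > kkt_tol):
        return x
    return np.clip(v, lb, ub)


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------


def solve_fba(
    model: MetabolicModel,
    tolerances: SolverTolerances = DEFAULT_TOLERANCES,
) -> FluxDistribution:
    """Maximize the model objective subject to S·v = 0 and the bounds.

    Among alternate optima returns the minimum-L2-norm optimum, so repeated
    runs (and downstream MOMA references) are deterministic. Raises
    ConfigurationError when the model declares no (or an all-zero)
    objective; an infeasible or unbounded LP is reported in ``status`` with
    an empty flux map.
    """
    c = np.array([model.objective.get(r.id, 0.0) for r in model.reactions])
    if not model.objective or not np.any(c):
        raise ConfigurationError(
            f"model {model.id!r} has no non-zero objective; FBA needs one"
        )
    S = stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])

    res = linprog(
        -c,
        A_eq=S if S.size else None,
        b_eq=np.zeros(S.shape[0]) if S.size else None,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status == 2:
        return FluxDistribution(model.id, {}, STATUS_INFEASIBLE, None, tolerances)
    if res.status == 3:
        return FluxDistribution(model.id, {}, STATUS_UNBOUNDED, None, tolerances)
    if res.status != 0:
        raise RuntimeError(f"LP solver failed: {res.message}")
    z_star = float(c @ res.x)

    # tie-break: minimum-norm flux on the optimal face {c·v = z*}
    A_aug = np.vstack([S, c]) if S.size else c[None, :]
    b_aug = np.concatenate([np.zeros(S.shape[0]), [z_star]])
    v, status = _solve_box_eq_qp(A_aug, b_aug, lb, ub, np.zeros(len(c)), tolerances)
    if status != STATUS_OPTIMAL:  # numerically degenerate face; keep LP vertex
        v = res.x
    fluxes = {r.id: float(x) for r, x in zip(model.reactions, v)}
    return FluxDistribution(
        model.id, fluxes, STATUS_OPTIMAL, float(c @ v), tolerances
    )


# ---------------------------------------------------------------------------
# MOMA
# ---------------------------------------------------------------------------


def solve_moma(
    perturbed_model: MetabolicModel,
    reference: FluxDistribution,
    tolerances: SolverTolerances = DEFAULT_TOLERANCES,
) -> FluxDistribution:
    """Minimize Σ (v_j − w_j)² over the perturbed model's feasible set.

    ``reference`` must be a solved distribution (the wild-type FBA result
    or a certified-feasible witness); reactions of the perturbed model
    missing from it contribute w_j = 0. ``objective_value`` is the attained
    squared distance.
    """
    if not reference.solved:
        raise ContractError(
            f"MOMA reference must be a solved flux distribution, got "
            f"status {reference.status!r}"
        )
    S = stoichiometric_matrix(perturbed_model)
    lb = np.array([r.lower_bound for r in perturbed_model.reactions])
    ub = np.array([r.upper_bound for r in perturbed_model.reactions])
    w = reference.as_vector(perturbed_model)

    v, status = _solve_box_eq_qp(
        S, np.zeros(S.shape[0]), lb, ub, w, tolerances
    )
    if status != STATUS_OPTIMAL:
        return FluxDistribution(
            perturbed_model.id, {}, STATUS_INFEASIBLE, None, tolerances
        )
    fluxes = {r.id: float(x) for r, x in zip(perturbed_model.reactions, v)}
    distance_sq = float((v - w) @ (v - w))
    return FluxDistribution(
        perturbed_model.id, fluxes, STATUS_OPTIMAL, distance_sq, tolerances
    )
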