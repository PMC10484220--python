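"""Independent numerical oracles used only by the test suite.

The MOMA oracle solves the same quadratic program as the production
solver — minimize ½‖v − w‖² subject to S·v = 0 and box bounds — but by a
completely different algorithm family: ADMM operator splitting (the
box-indicator and the equality-constrained quadratic are handled by
alternating proximal steps), written from scratch with no code shared
with the SQP/KKT main path. Agreement between the two is therefore a
genuine cross-check, not a tautology.
"""

from __future__ import annotations

import numpy as np


def admm_moma(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    w: np.ndarray,
    rho: float = 1.0,
    max_iter: int = 50_000,
    tol: float = 1e-10,
) -> np.ndarray:
    """Projection of w onto {v : S v = 0, lb ≤ v ≤ ub} by ADMM.

    Splitting: f(v) = ½‖v − w‖² + indicator{S v = 0}, g(z) = indicator box,
    coupled by v = z. The v-update is a closed-form KKT solve (factored
    once); the z-update is a clip. Returns the box-feasible iterate z,
    which at convergence also satisfies the steady-state constraint to
    within ``tol``.
    """
    n = len(w)
    m = S.shape[0] if S.size else 0
    if m:
        K = np.block(
            [[(1.0 + rho) * np.eye(n), S.T], [S, np.zeros((m, m))]]
        )
        K_pinv = np.linalg.pinv(K)
    z = np.clip(w, lb, ub)
    u = np.zeros(n)
    for _ in range(max_iter):
        rhs_top = w + rho * (z - u)
        if m:
            v = (K_pinv @ np.concatenate([rhs_top, np.zeros(m)]))[:n]
        else:
            v = rhs_top / (1.0 + rho)
        z_new = np.clip(v + u, lb, ub)
        primal = np.linalg.norm(v - z_new)
        dual = rho * np.linalg.norm(z_new - z)
        u = u + v - z_new
        z = z_new
        if max(primal, dual) < tol:
            break
    return z


def fba_lp_cobra(model) -> tuple[str, float]:
    """FBA via cobrapy/GLPK: an LP formulation fully independent of the
    scipy-based production solver. Returns (status, objective value)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(m.id, compartment=m.compartment or "c")
        for m in model.metabolites
    }
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id)
        cr.lower_bound, cr.upper_bound = r.lower_bound, r.upper_bound
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r, cr in zip(model.reactions, rxns):
        cr.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
    cm.objective = {cm.reactions.get_by_id(k): v for k, v in model.objective.items()}
    sol = cm.optimize()
    return sol.status, sol.objective_value
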