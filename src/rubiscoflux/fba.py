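"""Flux balance analysis and flux variability by linear programming.

FBA maximizes the biomass objective v_obj subject to steady-state mass
balance S·v = 0 and box constraints lb <= v <= ub.  All problems are solved
with SciPy's HiGHS interface under a single fixed configuration, so repeated
runs are deterministic.  Degenerate alternate optima are characterized with
flux variability analysis (FVA) rather than by trusting any particular
optimal vertex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = [
    "FluxSolution",
    "InfeasibleProblemError",
    "fba",
    "flux_variability",
    "minimize_flux_at_objective",
    "ZERO_GROWTH_THRESHOLD",
]

#: Objective values below this count as "no growth" (mmol/gDW/h); LP solvers
#: routinely return tiny nonzeros for blocked models.
ZERO_GROWTH_THRESHOLD = 1e-6

_FEASIBILITY_TOL = 1e-9


class InfeasibleProblemError(RuntimeError):
    """An LP required to be feasible was infeasible or unbounded."""


@dataclass(frozen=True)
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]

    @property
    def grows(self) -> bool:
        return self.optimal and self.objective_value >= ZERO_GROWTH_THRESHOLD


def stoichiometric_matrix(model: MetabolicModel):
    """Sparse S (metabolites x reactions) plus the row/column id orders."""
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rows, cols, data = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            rows.append(met_index[met_id])
            cols.append(j)
            data.append(coeff)
    S = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )
    return S, [m.id for m in model.metabolites], list(model.reaction_ids)


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded"}


def _solve(model: MetabolicModel, c: np.ndarray, sense: int) -> FluxSolution:
    """Optimize ``sense * c @ v`` (sense=+1 maximize) over the flux cone."""
    S, _, rxn_ids = stoichiometric_matrix(model)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    res = linprog(
        -sense * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxSolution(status, float("nan"), {})
    fluxes = {rid: float(v) for rid, v in zip(rxn_ids, res.x)}
    return FluxSolution("optimal", float(sense * -res.fun), fluxes)


def fba(model: MetabolicModel) -> FluxSolution:
    """Maximize the model's objective reaction flux.

    Infeasibility and unboundedness are reported through ``status``; the
    returned fluxes of an optimal solution satisfy |S·v| < 1e-6 and respect
    all bounds (HiGHS default tolerances).
    """
    c = np.zeros(len(model.reactions))
    c[model.reaction_ids.index(model.objective_id)] = 1.0
    return _solve(model, c, sense=+1)


def _with_objective_floor(
    model: MetabolicModel, fraction_of_optimum: float
) -> tuple[MetabolicModel, float]:
    base = fba(model)
    if not base.optimal:
        raise InfeasibleProblemError(
            f"base FBA is {base.status}; cannot constrain the optimum"
        )
    opt = base.objective_value
    obj = model.reaction(model.objective_id)
    floor = fraction_of_optimum * opt
    constrained = model.with_reaction(
        obj.with_bounds(max(obj.lower_bound, floor - _FEASIBILITY_TOL), obj.upper_bound)
    )
    return constrained, opt


def flux_variability(
    model: MetabolicModel,
    reaction_id: str,
    fraction_of_optimum: float = 1.0,
    return_solutions: bool = False,
):
    """Min and max flux of one reaction at >= a fraction of the FBA optimum.

    With ``return_solutions=True`` the two extreme flux vectors are returned
    as well, ``((vmin, vmax), (sol_min, sol_max))``.
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must be in [0, 1]")
    model.reaction(reaction_id)  # raises KeyError on unknown id
    constrained, _ = _with_objective_floor(model, fraction_of_optimum)
    c = np.zeros(len(constrained.reactions))
    c[constrained.reaction_ids.index(reaction_id)] = 1.0
    lo = _solve(constrained, c, sense=-1)
    hi = _solve(constrained, c, sense=+1)
    if not (lo.optimal and hi.optimal):
        raise InfeasibleProblemError(
            f"FVA subproblem for {reaction_id!r} at fraction "
            f"{fraction_of_optimum} was {lo.status}/{hi.status}"
        )
    vmin, vmax = lo.objective_value, hi.objective_value
    if return_solutions:
        return (vmin, vmax), (lo, hi)
    return vmin, vmax


def minimize_flux_at_objective(
    model: MetabolicModel, reaction_id: str, objective_value: float
) -> FluxSolution:
    """Minimize one reaction's flux with the objective pinned to a value."""
    obj = model.reaction(model.objective_id)
    pinned = model.with_reaction(
        obj.with_bounds(objective_value, objective_value)
    )
    c = np.zeros(len(pinned.reactions))
    c[pinned.reaction_ids.index(reaction_id)] = 1.0
    sol = _solve(pinned, c, sense=-1)
    if not sol.optimal:
        raise InfeasibleProblemError(
            f"no feasible flux state at objective = {objective_value}"
        )
    return sol
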