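"""Growth-coupled knockout screening for rubisco-dependent strains.

The screen mirrors the slope-based strategy used to design rubisco-dependent
E. coli: add the two-reaction Calvin-cycle detour (phosphoribulokinase, Prk:
Ru5P -> RuBP; rubisco: RuBP + CO2 -> 2 x 3PG), enumerate small knockout
sets, keep those that cannot grow in silico without the detour but can with
it, and score each survivor by how tightly the minimum rubisco flux is
coupled to biomass production.  A companion routine computes the FBA
prediction of rubisco's share of 3PG production, the quantity that isotopic
labeling estimates in vivo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .fba import (
    ZERO_GROWTH_THRESHOLD,
    InfeasibleProblemError,
    fba,
    flux_variability,
    minimize_flux_at_objective,
)
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "HeterologousSpec",
    "CouplingSlope",
    "KnockoutCandidate",
    "add_heterologous",
    "rubisco_dependence_test",
    "coupling_slope",
    "scan_knockouts",
    "predicted_rubisco_3pg_fraction",
]


@dataclass(frozen=True)
class HeterologousSpec:
    """Ids and metabolite anchors of the Prk + rubisco detour.

    ``ru5p_id``, ``co2_id`` and ``target_metabolite_id`` (the 3PG pool, or
    its proxy in a reduced network) must name metabolites of the host model;
    ``rubp_id`` is created if absent.  Rubisco produces exactly two units of
    the target metabolite per carboxylation.
    """

    prk_id: str = "PRK"
    rubisco_id: str = "RBC"
    ru5p_id: str = "ru5p"
    rubp_id: str = "rubp"
    co2_id: str = "co2"
    target_metabolite_id: str = "3pg"
    #: extra stoichiometry merged into the Prk reaction (e.g. ATP cost);
    #: the reduced toy network carries no energy metabolism and omits it.
    prk_cofactors: tuple[tuple[str, float], ...] = ()


@dataclass(frozen=True)
class CouplingSlope:
    """Fitted line through (biomass, minimum rubisco flux) grid points."""

    slope: float
    intercept: float
    grid: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        biomass = [b for b, _ in self.grid]
        if any(b2 <= b1 for b1, b2 in zip(biomass, biomass[1:])):
            raise ValueError("grid biomass values must be strictly increasing")
        if not np.isfinite(self.slope):
            raise ValueError("coupling slope must be finite")


@dataclass(frozen=True)
class KnockoutCandidate:
    deleted: tuple[str, ...]
    growth_without_het: float
    growth_with_het: float
    slopes: dict[str, CouplingSlope] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.deleted)


def add_heterologous(
    model: MetabolicModel, spec: HeterologousSpec
) -> tuple[MetabolicModel, HeterologousSpec]:
    """Add the Prk and rubisco reactions to a model.

    Idempotent: re-adding an identical spec leaves the model unchanged.
    Raises ``KeyError`` when an anchor metabolite is missing.
    """
    met_ids = {m.id for m in model.metabolites}
    for required in (spec.ru5p_id, spec.co2_id, spec.target_metabolite_id):
        if required not in met_ids:
            raise KeyError(
                f"heterologous spec requires metabolite {required!r}, "
                "absent from the model"
            )
    prk_stoich = {spec.ru5p_id: -1.0, spec.rubp_id: 1.0}
    for met_id, coeff in spec.prk_cofactors:
        prk_stoich[met_id] = prk_stoich.get(met_id, 0.0) + coeff
    rbc_stoich = {
        spec.rubp_id: -1.0,
        spec.co2_id: -1.0,
        spec.target_metabolite_id: 2.0,
    }
    prk = Reaction(spec.prk_id, prk_stoich, 0.0, 1000.0)
    rbc = Reaction(spec.rubisco_id, rbc_stoich, 0.0, 1000.0)
    out = model
    if spec.rubp_id not in met_ids:
        out = out.with_metabolites(
            [Metabolite(spec.rubp_id, "ribulose-1,5-bisphosphate")]
        )
    for rxn in (prk, rbc):
        existing = None
        try:
            existing = out.reaction(rxn.id)
        except KeyError:
            pass
        if existing is not None and existing.stoichiometry != rxn.stoichiometry:
            raise ValueError(
                f"model already contains {rxn.id!r} with different stoichiometry"
            )
        if existing is None:
            out = out.with_reaction(rxn)
    return out, spec


def _without_heterologous(model: MetabolicModel, het: HeterologousSpec) -> MetabolicModel:
    out = model
    for rid in (het.prk_id, het.rubisco_id):
        try:
            rxn = out.reaction(rid)
        except KeyError:
            continue
        out = out.with_reaction(rxn.with_bounds(0.0, 0.0))
    return out


def rubisco_dependence_test(
    model: MetabolicModel,
    ko,
    het: HeterologousSpec,
    source: str | None = None,
    max_uptake: float = 10.0,
) -> tuple[float, float, bool]:
    """Growth without and with the Prk/rubisco detour for one knockout set.

    Returns ``(growth_without, growth_with, dependent)`` where *dependent*
    means the knockout abolishes growth unless the detour is active.
    ``source`` optionally names an exchange to configure as the sole organic
    carbon source before testing.
    """
    from .model import apply_knockouts, set_carbon_source

    base, _ = add_heterologous(model, het)
    if source is not None:
        base = set_carbon_source(base, source, max_uptake)
    ko_model = apply_knockouts(base, ko)
    with_het = fba(ko_model)
    without_het = fba(_without_heterologous(ko_model, het))
    g_without = without_het.objective_value if without_het.optimal else 0.0
    g_with = with_het.objective_value if with_het.optimal else 0.0
    if g_without == 0:
        g_without = 0.0  # normalize the solver's occasional -0.0
    if g_with == 0:
        g_with = 0.0
    dependent = g_without < ZERO_GROWTH_THRESHOLD and g_with >= ZERO_GROWTH_THRESHOLD
    return g_without, g_with, dependent


def coupling_slope(
    model: MetabolicModel,
    het: HeterologousSpec,
    source: str | None = None,
    n_grid: int = 5,
    max_uptake: float = 10.0,
) -> CouplingSlope:
    """Slope of minimum-required rubisco flux against biomass production.

    Biomass is pinned at ``n_grid`` evenly spaced values in (0, mu_max] and
    the rubisco flux is minimized at each; slope and intercept come from an
    ordinary least-squares fit through the grid, which is retained for audit
    so alternative coupling functionals can be recomputed.
    """
    if n_grid < 3:
        raise ValueError("n_grid must be >= 3")
    from .model import set_carbon_source

    m = model
    if source is not None:
        m = set_carbon_source(m, source, max_uptake)
    base = fba(m)
    if not base.optimal or base.objective_value < ZERO_GROWTH_THRESHOLD:
        raise InfeasibleProblemError("model does not grow; no coupling curve")
    mu_max = base.objective_value
    grid = []
    for biomass in np.linspace(mu_max / n_grid, mu_max, n_grid):
        try:
            sol = minimize_flux_at_objective(m, het.rubisco_id, float(biomass))
        except InfeasibleProblemError as exc:
            raise InfeasibleProblemError(
                f"coupling grid infeasible at biomass = {biomass:.6g}"
            ) from exc
        grid.append((float(biomass), sol.objective_value))
    xs = np.array([b for b, _ in grid])
    ys = np.array([v for _, v in grid])
    slope, intercept = np.polyfit(xs, ys, 1)
    return CouplingSlope(float(slope), float(intercept), tuple(grid))


def scan_knockouts(
    model: MetabolicModel,
    het: HeterologousSpec,
    sources,
    candidate_rxns=None,
    max_size: int = 2,
    max_uptake: float = 10.0,
    n_grid: int = 5,
) -> list[KnockoutCandidate]:
    """Exhaustive screen of knockout sets for rubisco-coupled growth.

    Every subset of ``candidate_rxns`` of size 1..``max_size`` is tested on
    every carbon source; a set is retained when at least one source shows
    rubisco dependence (no growth without the detour, growth with it).  For
    each dependent source the coupling slope is computed.  Output is sorted
    by (deletion size, ids) and is complete: every qualifying subset appears.
    """
    if max_size not in (1, 2):
        raise ValueError("max_size must be 1 or 2")
    sources = list(sources)
    base, _ = add_heterologous(model, het)
    if candidate_rxns is None:
        excluded = {het.prk_id, het.rubisco_id, base.objective_id}
        candidate_rxns = [
            r.id
            for r in base.reactions
            if not r.is_exchange and r.id not in excluded
        ]
    candidate_rxns = list(candidate_rxns)
    if not candidate_rxns:
        raise ValueError("empty candidate reaction list")
    bad = {het.prk_id, het.rubisco_id, base.objective_id} & set(candidate_rxns)
    if bad:
        raise ValueError(f"candidate list may not contain {sorted(bad)}")
    if any(base.reaction(rid).is_exchange for rid in candidate_rxns):
        raise ValueError("candidate list may not contain exchange reactions")

    from .model import apply_knockouts, set_carbon_source

    results: list[KnockoutCandidate] = []
    subsets = [
        tuple(sorted(combo))
        for size in range(1, max_size + 1)
        for combo in combinations(sorted(candidate_rxns), size)
    ]
    for deleted in subsets:
        slopes: dict[str, CouplingSlope] = {}
        g_without_rep = g_with_rep = None
        for source in sources:
            g_without, g_with, dependent = rubisco_dependence_test(
                model, deleted, het, source, max_uptake
            )
            if dependent:
                if g_without_rep is None:
                    g_without_rep, g_with_rep = g_without, g_with
                configured = apply_knockouts(
                    set_carbon_source(base, source, max_uptake), deleted
                )
                slopes[source] = coupling_slope(
                    configured, het, source=None, n_grid=n_grid
                )
        if slopes:
            results.append(
                KnockoutCandidate(deleted, g_without_rep, g_with_rep, slopes)
            )
    results.sort(key=lambda c: (c.size, c.deleted))
    return results


def predicted_rubisco_3pg_fraction(
    model: MetabolicModel,
    het: HeterologousSpec,
    at_fraction_of_optimum: float = 1.0,
) -> tuple[float, tuple[float, float]]:
    """FBA-predicted percentage of 3PG production carried by rubisco.

    At the FBA optimum, rubisco's contribution (2 molecules of the target
    metabolite per carboxylation) is divided by the total production flux
    into the target pool, counting only positive contributions.  The range
    re-evaluates the same ratio at the two FVA extremes of the rubisco flux
    with the objective held at ``at_fraction_of_optimum`` of its maximum.
    Returns ``(point_percent, (low_percent, high_percent))``.
    """
    sol = fba(model)
    if not sol.optimal or sol.objective_value < ZERO_GROWTH_THRESHOLD:
        raise InfeasibleProblemError("model does not grow; fraction undefined")

    def fraction(fluxes: dict[str, float]) -> float:
        target = het.target_metabolite_id
        total = 0.0
        rub = 0.0
        for rxn in model.reactions:
            coeff = rxn.stoichiometry.get(target)
            if coeff is None:
                continue
            produced = coeff * fluxes[rxn.id]
            if produced > 0:
                total += produced
                if rxn.id == het.rubisco_id:
                    rub += produced
        if total <= ZERO_GROWTH_THRESHOLD:
            raise ZeroDivisionError(
                "no production flux into the target metabolite"
            )
        return 100.0 * rub / total

    point = fraction(sol.fluxes)
    (_, _), (lo_sol, hi_sol) = flux_variability(
        model, het.rubisco_id, at_fraction_of_optimum, return_solutions=True
    )
    bounds = sorted((fraction(lo_sol.fluxes), fraction(hi_sol.fluxes)))
    return point, (bounds[0], bounds[1])
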