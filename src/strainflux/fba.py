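"""Flux balance analysis over a :class:`MetabolicModel`.

FBA maximizes the biomass objective flux v_obj subject to steady-state
mass balance S·v = 0 and flux bounds l <= v <= u.  The LP is solved with
scipy's HiGHS backend.  A growth condition (one PM-style well) is applied
by closing every nutrient exchange except those it names:

* named nutrient exchange: effective lower bound = max(model lb, -uptake)
* every other exchange:    effective lower bound = max(model lb, 0)

Taking the max against the strain's own bound means the medium can only
restrict availability — it never re-opens an exchange that a regulatory
switch-off pinned to (0, 0).  Secretion (positive exchange flux) keeps
the model's upper bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from strainflux.models import (
    AnalysisConfig,
    GrowthCall,
    GrowthCondition,
    MetabolicModel,
)


class ConditionError(Exception):
    """A growth condition references an exchange id absent from the model."""


@dataclass
class FluxState:
    """One FBA solution: fluxes in mmol/gDCW/h, objective in 1/h."""

    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    @property
    def is_optimal(self) -> bool:
        return self.status == "optimal"


def _condition_bounds(
    model: MetabolicModel, condition: GrowthCondition
) -> list[tuple[float, float]]:
    uptakes = {condition.substrate_exchange_id: condition.substrate_uptake}
    uptakes.update(condition.co_substrates)
    if condition.oxygen_uptake > 0 and model.has_reaction(condition.oxygen_exchange_id):
        uptakes[condition.oxygen_exchange_id] = condition.oxygen_uptake
    if not model.has_reaction(condition.substrate_exchange_id):
        raise ConditionError(
            f"condition {condition.name!r}: exchange "
            f"{condition.substrate_exchange_id!r} not in model {model.id!r}"
        )
    for exch_id in condition.co_substrates:
        if not model.has_reaction(exch_id):
            raise ConditionError(
                f"condition {condition.name!r}: co-substrate exchange "
                f"{exch_id!r} not in model {model.id!r}"
            )
    bounds = []
    for r in model.reactions:
        lb, ub = r.lower_bound, r.upper_bound
        if r.is_exchange:
            lb = max(lb, -uptakes.get(r.id, 0.0))
        bounds.append((lb, ub))
    return bounds


def _solve(
    model: MetabolicModel, bounds: list[tuple[float, float]]
) -> FluxState:
    n = len(model.reactions)
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), n))
    for j, r in enumerate(model.reactions):
        for mid, coef in r.stoichiometry.items():
            S[met_index[mid], j] = coef
    c = np.zeros(n)
    obj_j = model.reaction_ids.index(model.objective_id)
    c[obj_j] = -1.0  # linprog minimizes
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    if res.status == 0:
        fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
        return FluxState(fluxes=fluxes, objective_value=float(-res.fun), status="optimal")
    if res.status == 3:
        return FluxState(fluxes={}, objective_value=float("inf"), status="unbounded")
    return FluxState(fluxes={}, objective_value=0.0, status="infeasible")


def solve_fba(model: MetabolicModel, condition: GrowthCondition) -> FluxState:
    """Maximize the biomass objective under one growth condition.

    Raises :class:`ConditionError` when the condition's substrate or
    co-substrate exchange ids do not resolve in the model.  An infeasible
    LP yields status ``infeasible`` with objective 0.
    """
    return _solve(model, _condition_bounds(model, condition))


def call_growth(state: FluxState, config: AnalysisConfig | None = None) -> GrowthCall:
    """Binary growth call: growth iff optimal and objective > growth_epsilon."""
    config = config or AnalysisConfig()
    if state.is_optimal and state.objective_value > config.growth_epsilon:
        return GrowthCall.GROWTH
    return GrowthCall.NO_GROWTH


def flux_growth_sweep(
    model: MetabolicModel,
    reaction_id: str,
    caps: list[float],
    condition: GrowthCondition,
) -> list[tuple[float, float]]:
    """Growth as a function of a flux cap on one reaction.

    For each cap the reaction's upper bound is set to the cap (and the
    lower bound to min(lb, cap)) and FBA is re-solved.  By LP parametric
    analysis the resulting curve is monotone non-decreasing, concave and
    piecewise linear in the cap.
    """
    if not model.has_reaction(reaction_id):
        raise KeyError(reaction_id)
    if any(c < 0 for c in caps):
        raise ValueError("caps must be non-negative")
    if sorted(caps) != list(caps):
        raise ValueError("caps must be ascending")
    curve = []
    for cap in caps:
        m = model.copy()
        r = m.get_reaction(reaction_id)
        r.upper_bound = cap
        r.lower_bound = min(r.lower_bound, cap)
        state = solve_fba(m, condition)
        curve.append((cap, state.objective_value if state.is_optimal else 0.0))
    return curve


def mass_balance_residual(model: MetabolicModel, state: FluxState) -> float:
    """‖S·v‖∞ of a solved flux state (0 for non-optimal states)."""
    if not state.is_optimal:
        return 0.0
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    residual = np.zeros(len(model.metabolites))
    for r in model.reactions:
        v = state.fluxes[r.id]
        for mid, coef in r.stoichiometry.items():
            residual[met_index[mid]] += coef * v
    return float(np.max(np.abs(residual))) if len(residual) else 0.0
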