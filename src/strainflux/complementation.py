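"""In silico complementation: attributing strain-specific phenotypes to
reaction-level genetic differences.

Given a reference strain, a target strain obtained by applying a
:class:`StrainDelta`, and a panel of growth conditions, the procedure
(1) finds conditions where the two strains' FBA growth calls differ and
(2) for each such differential phenotype, enumerates subsets of the
delta's modification groups in increasing cardinality, reverting each
subset in the target model and re-predicting growth.  A subset is
*responsible* when its reversion makes the target strain's call equal
the reference strain's call (both directions: gain-of-function and
loss-of-function phenotypes).  Only minimal responsible subsets are
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from strainflux.fba import ConditionError, call_growth, solve_fba
from strainflux.models import (
    AnalysisConfig,
    GrowthCall,
    GrowthCondition,
    MetabolicModel,
)
from strainflux.strain_delta import StrainDelta, revert_groups

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DifferentialPhenotype:
    """One condition where the two strains' predicted calls differ."""

    condition: GrowthCondition
    call_target: GrowthCall
    call_reference: GrowthCall

    def __post_init__(self) -> None:
        if self.call_target == self.call_reference:
            raise ValueError(
                f"{self.condition.name}: calls are equal, not a differential phenotype"
            )


@dataclass(frozen=True)
class ResponsibleSet:
    """A minimal set of modification groups whose reversion abolishes a
    target-strain-specific phenotype."""

    condition_name: str
    group_names: frozenset[str]
    reaction_ids: tuple[str, ...]
    kinds: tuple[str, ...]


def _growth_call(
    model: MetabolicModel, condition: GrowthCondition, config: AnalysisConfig
) -> GrowthCall:
    """Growth call with a missing substrate exchange treated as no growth
    (the strain simply cannot take the substrate up)."""
    try:
        return call_growth(solve_fba(model, condition), config)
    except ConditionError:
        logger.info(
            "condition %s: exchange missing from model %s; calling no_growth",
            condition.name,
            model.id,
        )
        return GrowthCall.NO_GROWTH


def differential_conditions(
    model_target: MetabolicModel,
    model_reference: MetabolicModel,
    conditions: list[GrowthCondition],
    config: AnalysisConfig | None = None,
) -> list[DifferentialPhenotype]:
    """Conditions where the two strains' growth calls differ, in input order.

    A substrate exchange missing from one model yields ``no_growth`` for
    that strain (logged); missing from both raises :class:`ConditionError`.
    """
    config = config or AnalysisConfig()
    out = []
    for cond in conditions:
        if not model_target.has_reaction(
            cond.substrate_exchange_id
        ) and not model_reference.has_reaction(cond.substrate_exchange_id):
            raise ConditionError(
                f"condition {cond.name!r}: exchange {cond.substrate_exchange_id!r} "
                f"missing from both models"
            )
        ct = _growth_call(model_target, cond, config)
        cr = _growth_call(model_reference, cond, config)
        if ct != cr:
            out.append(
                DifferentialPhenotype(condition=cond, call_target=ct, call_reference=cr)
            )
    return out


def find_responsible_sets(
    model_target: MetabolicModel,
    model_reference: MetabolicModel,
    delta: StrainDelta,
    diff: DifferentialPhenotype,
    config: AnalysisConfig | None = None,
) -> list[ResponsibleSet]:
    """Minimal modification-group subsets whose reversion flips the
    target strain's call to the reference strain's call.

    Subsets are enumerated in increasing cardinality up to
    ``config.max_revert_subset``; supersets of already-found responsible
    sets are pruned (they cannot be minimal).  Results are sorted by
    (cardinality, lexicographic group names).
    """
    config = config or AnalysisConfig()
    if config.max_revert_subset < 1:
        raise ValueError("max_revert_subset must be >= 1")
    names = sorted(delta.group_names)
    found: list[frozenset[str]] = []
    for k in range(1, min(config.max_revert_subset, len(names)) + 1):
        for combo in combinations(names, k):
            subset = frozenset(combo)
            if any(prev <= subset for prev in found):
                continue
            reverted = revert_groups(model_target, delta, subset)
            if _growth_call(reverted, diff.condition, config) == diff.call_reference:
                found.append(subset)
    results = []
    for subset in found:
        groups = [delta.get_group(n) for n in sorted(subset)]
        results.append(
            ResponsibleSet(
                condition_name=diff.condition.name,
                group_names=subset,
                reaction_ids=tuple(rid for g in groups for rid in g.reaction_ids),
                kinds=tuple(g.kind for g in groups),
            )
        )
    results.sort(key=lambda s: (len(s.group_names), tuple(sorted(s.group_names))))
    return results


_KIND_LABEL = {
    "addition": "Addition",
    "deletion": "Deletion",
    "regulation_off": "Turned off",
}

_CALL_SYMBOL = {GrowthCall.GROWTH: "+", GrowthCall.NO_GROWTH: "-"}


def complementation_report(
    model_target: MetabolicModel,
    model_reference: MetabolicModel,
    delta: StrainDelta,
    conditions: list[GrowthCondition],
    pm_calls: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, int]:
    """One row per differential condition: experimental PM grades (when
    supplied), predicted target/reference calls, the union of reactions
    over minimal responsible sets, and the modification kind(s).

    Returns (table, count of distinct responsible reactions across all
    rows).  ``pm_calls`` is a DataFrame with columns strain, condition,
    call as written by the pm module.
    """
    config = config or AnalysisConfig()
    rows = []
    distinct: set[str] = set()
    for diff in differential_conditions(model_target, model_reference, conditions, config):
        sets = find_responsible_sets(model_target, model_reference, delta, diff, config)
        reaction_ids: list[str] = []
        kinds: list[str] = []
        for s in sets:
            for rid in s.reaction_ids:
                if rid not in reaction_ids:
                    reaction_ids.append(rid)
            for k in s.kinds:
                label = _KIND_LABEL[k]
                if label not in kinds:
                    kinds.append(label)
        distinct.update(reaction_ids)
        pm_t = pm_r = ""
        if pm_calls is not None:
            pm_t = _pm_grade(pm_calls, delta.target_id, diff.condition.name)
            pm_r = _pm_grade(pm_calls, delta.reference_id, diff.condition.name)
        rows.append(
            {
                "condition": diff.condition.name,
                "pm_target": pm_t,
                "pm_reference": pm_r,
                "prediction_target": _CALL_SYMBOL[diff.call_target],
                "prediction_reference": _CALL_SYMBOL[diff.call_reference],
                "responsible_reactions": ", ".join(reaction_ids),
                "modification": ", ".join(kinds),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "condition",
            "pm_target",
            "pm_reference",
            "prediction_target",
            "prediction_reference",
            "responsible_reactions",
            "modification",
        ],
    )
    return table, len(distinct)


_GRADE_SYMBOL = {"minus": "-", "plus": "+", "plus_plus": "++"}


def _pm_grade(pm_calls: pd.DataFrame, strain: str, condition: str) -> str:
    hit = pm_calls[(pm_calls["strain"] == strain) & (pm_calls["condition"] == condition)]
    if hit.empty:
        return ""
    call = str(hit.iloc[0]["call"])
    return _GRADE_SYMBOL.get(call, call)


def write_report(
    table: pd.DataFrame, distinct_count: int, path
) -> None:
    """Write the complementation table as TSV with a trailing summary line."""
    with open(path, "w") as fh:
        table.to_csv(fh, sep="\t", index=False)
        fh.write(f"# distinct_responsible_reactions\t{distinct_count}\n")
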