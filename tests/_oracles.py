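"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own solution paths: the LP oracle
enumerates polytope vertices instead of calling an LP solver, the island
oracle enumerates every window explicitly, and the subset oracle reverts
every one of the 2^n group subsets.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from strainflux.fba import _condition_bounds
from strainflux.models import GrowthCondition, MetabolicModel


def lp_max_by_vertex_enumeration(
    S: np.ndarray, c: np.ndarray, bounds: list[tuple[float, float]]
) -> float | None:
    """Maximize c.v over {S v = 0, l <= v <= u} by enumerating vertices.

    Any bounded feasible LP attains its optimum at a vertex, where at
    least n - rank(S) variables sit at a bound and the basic columns are
    linearly independent.  Returns None when no feasible vertex exists.
    """
    n = S.shape[1]
    r = int(np.linalg.matrix_rank(S)) if S.size else 0
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    best = None
    for basic in combinations(range(n), r):
        SB = S[:, basic]
        if np.linalg.matrix_rank(SB) < r:
            continue
        nonbasic = [j for j in range(n) if j not in basic]
        for choice in product((0, 1), repeat=len(nonbasic)):
            v = np.zeros(n)
            for j, side in zip(nonbasic, choice):
                v[j] = lo[j] if side == 0 else hi[j]
            rhs = -S[:, nonbasic] @ v[nonbasic] if nonbasic else np.zeros(S.shape[0])
            if r:
                xB, *_ = np.linalg.lstsq(SB, rhs, rcond=None)
                if not np.allclose(SB @ xB, rhs, atol=1e-9):
                    continue
                v[list(basic)] = xB
            if np.all(v >= lo - 1e-9) and np.all(v <= hi + 1e-9):
                obj = float(c @ v)
                if best is None or obj > best:
                    best = obj
    return best


def fba_objective_by_vertex_enumeration(
    model: MetabolicModel, condition: GrowthCondition
) -> float | None:
    """Independent FBA objective for a model/condition pair."""
    bounds = _condition_bounds(model, condition)
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for mid, coef in rxn.stoichiometry.items():
            S[met_index[mid], j] = coef
    c = np.zeros(len(model.reactions))
    c[model.reaction_ids.index(model.objective_id)] = 1.0
    return lp_max_by_vertex_enumeration(S, c, bounds)


def islands_by_window_enumeration(
    flags: list[bool], window: int, min_foreign: int
) -> list[tuple[int, int]]:
    """Enumerate every window, collect qualifying ones, merge by interval
    union.  Returns merged (first, last) gene-index ranges, half-open."""
    hits = []
    for i in range(len(flags) - window + 1):
        if sum(flags[i : i + window]) >= min_foreign:
            hits.append((i, i + window))
    merged: list[list[int]] = []
    for start, stop in hits:
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], stop)
        else:
            merged.append([start, stop])
    return [tuple(x) for x in merged]


def responsible_sets_by_exhaustion(
    model_target, model_reference, delta, diff, config
) -> list[frozenset[str]]:
    """All minimal responsible subsets by checking every one of the 2^n
    group subsets, then filtering non-minimal ones."""
    from strainflux.complementation import _growth_call
    from strainflux.strain_delta import revert_groups

    names = delta.group_names
    flipping = []
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            reverted = revert_groups(model_target, delta, combo)
            if _growth_call(reverted, diff.condition, config) == diff.call_reference:
                flipping.append(frozenset(combo))
    return sorted(
        (s for s in flipping if not any(o < s for o in flipping)),
        key=lambda s: (len(s), tuple(sorted(s))),
    )
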