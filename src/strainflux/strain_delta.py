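"""Strain deltas: the reaction-level differences between two strains.

A :class:`StrainDelta` is an ordered set of named modification groups
that transform a reference strain's model into a target strain's model:

* ``addition`` — reactions (with any new metabolites) present only in
  the target strain;
* ``deletion`` — reference reactions whose GPR becomes false under the
  target strain's gene table (pseudogenes count as non-functional);
* ``regulation_off`` — reactions retained in the target model but with
  both flux bounds pinned to 0 by a strain-specific regulatory state.

Groups are the unit of reversion in the in silico complementation test,
so each group stores enough payload (reference reaction/metabolite
definitions, original bounds) to be restored without the reference model
at hand.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from strainflux.models import (
    DEFAULT_BOUND,
    GeneStatus,
    GeneStatusTable,
    Metabolite,
    MetabolicModel,
    ModelParseError,
    Reaction,
    _compartment_of,
    format_equation,
    gpr_gene_ids,
    parse_equation,
)

logger = logging.getLogger(__name__)

ADDITION = "addition"
DELETION = "deletion"
REGULATION_OFF = "regulation_off"
KINDS = (ADDITION, DELETION, REGULATION_OFF)


class GPRSyntaxError(ValueError):
    """Unparsable GPR expression; message carries the token position."""


class DeltaError(Exception):
    """Inconsistent delta construction or application."""


# ---------------------------------------------------------------------------
# GPR boolean evaluation
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.\-]+)")


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens, pos = [], 0
    while pos < len(expression):
        m = _TOKEN.match(expression, pos)
        if m is None:
            raise GPRSyntaxError(
                f"unexpected character {expression[pos]!r} at position {pos}"
            )
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def evaluate_gpr(expression: str, genes: GeneStatusTable) -> bool:
    """Evaluate a GPR boolean string against a gene-status table.

    A gene literal is true iff its status is ``present``; ``absent`` and
    ``pseudogene`` are both false.  Genes missing from the table default
    to present (with a log message) — strain tables typically cover only
    the genes that differ.  The empty expression is true (no genetic
    dependency).  Grammar: ``expr := term ('or' term)*; term := factor
    ('and' factor)*; factor := gene | '(' expr ')'``.
    """
    if not expression.strip():
        return True
    tokens = _tokenize(expression)
    idx = 0

    def peek() -> str | None:
        return tokens[idx][0] if idx < len(tokens) else None

    def advance() -> tuple[str, int]:
        nonlocal idx
        tok = tokens[idx]
        idx += 1
        return tok

    def parse_expr() -> bool:
        value = parse_term()
        while peek() is not None and peek().lower() == "or":
            advance()
            value = parse_term() or value
        return value

    def parse_term() -> bool:
        value = parse_factor()
        while peek() is not None and peek().lower() == "and":
            advance()
            value = parse_factor() and value
        return value

    def parse_factor() -> bool:
        tok = peek()
        if tok is None:
            raise GPRSyntaxError(
                f"unexpected end of expression at position {len(expression)}"
            )
        if tok == "(":
            advance()
            value = parse_expr()
            if peek() != ")":
                _, pos = tokens[idx - 1]
                raise GPRSyntaxError(f"missing ')' near position {pos}")
            advance()
            return value
        if tok == ")" or tok.lower() in ("and", "or"):
            _, pos = advance()
            raise GPRSyntaxError(f"unexpected token {tok!r} at position {pos}")
        gene, _ = advance()
        if gene not in genes:
            logger.debug("gene %s missing from status table; assumed present", gene)
            return True
        return genes[gene] is GeneStatus.PRESENT

    result = parse_expr()
    if idx != len(tokens):
        tok, pos = tokens[idx]
        raise GPRSyntaxError(f"unexpected token {tok!r} at position {pos}")
    return result


# ---------------------------------------------------------------------------
# modification groups & deltas
# ---------------------------------------------------------------------------

@dataclass
class ModificationGroup:
    """A named, atomically-revertible strain modification.

    ``payload_reactions``/``payload_metabolites`` hold full definitions:
    for additions, the target-strain content to insert; for deletions,
    the reference-strain content needed to restore.  ``original_bounds``
    holds the reference (lb, ub) of each regulation_off reaction.
    """

    name: str
    kind: str
    reaction_ids: list[str]
    payload_reactions: list[Reaction] = field(default_factory=list)
    payload_metabolites: list[Metabolite] = field(default_factory=list)
    original_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise DeltaError(f"group {self.name!r}: unknown kind {self.kind!r}")
        if not self.reaction_ids:
            raise DeltaError(f"group {self.name!r}: reaction_ids must be non-empty")
        if self.kind == ADDITION:
            payload_ids = {r.id for r in self.payload_reactions}
            missing = set(self.reaction_ids) - payload_ids
            if missing:
                raise DeltaError(
                    f"addition group {self.name!r}: missing payload for {sorted(missing)}"
                )


@dataclass
class StrainDelta:
    """Ordered modification groups turning the reference model into the
    target model."""

    reference_id: str
    target_id: str
    groups: list[ModificationGroup] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(names) != len(set(names)):
            raise DeltaError("group names must be unique")
        seen: dict[str, str] = {}
        for g in self.groups:
            for rid in g.reaction_ids:
                if rid in seen:
                    raise DeltaError(
                        f"reaction {rid!r} appears in groups {seen[rid]!r} and {g.name!r}"
                    )
                seen[rid] = g.name

    @property
    def group_names(self) -> list[str]:
        return [g.name for g in self.groups]

    def get_group(self, name: str) -> ModificationGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)


# ---------------------------------------------------------------------------
# delta construction
# ---------------------------------------------------------------------------

def build_delta(
    reference: MetabolicModel,
    ref_genes: GeneStatusTable,
    target_genes: GeneStatusTable,
    target_additions: Sequence[ModificationGroup] = (),
    regulations: Sequence[ModificationGroup] = (),
    reference_id: str | None = None,
    target_id: str = "target",
) -> StrainDelta:
    """Derive a strain delta from gene-status differences.

    Deletion groups are generated for every reference reaction whose GPR
    is true under ``ref_genes`` but false under ``target_genes``;
    reactions disabled by the same set of lost genes are grouped into one
    modification (pathway-level gene losses are single events).
    Additions and regulations are passed through after conflict checks.
    """
    ref_rxn_ids = set(reference.reaction_ids)
    for g in target_additions:
        if g.kind != ADDITION:
            raise DeltaError(f"group {g.name!r} passed as addition has kind {g.kind}")
        clash = set(g.reaction_ids) & ref_rxn_ids
        if clash:
            raise DeltaError(
                f"addition group {g.name!r} collides with existing reaction(s) "
                f"{sorted(clash)}"
            )
    by_cause: dict[frozenset[str], list[str]] = {}
    for r in reference.reactions:
        if not r.gpr.strip():
            continue
        if evaluate_gpr(r.gpr, ref_genes) and not evaluate_gpr(r.gpr, target_genes):
            lost = frozenset(
                g
                for g in gpr_gene_ids(r.gpr)
                if ref_genes.get(g, GeneStatus.PRESENT) is GeneStatus.PRESENT
                and target_genes.get(g, GeneStatus.PRESENT) is not GeneStatus.PRESENT
            )
            by_cause.setdefault(lost, []).append(r.id)
    deletion_groups = []
    for cause in sorted(by_cause, key=lambda c: sorted(c)):
        rids = by_cause[cause]
        deletion_groups.append(
            ModificationGroup(
                name="loss_" + "_".join(sorted(cause)) if cause else "loss_unassigned",
                kind=DELETION,
                reaction_ids=rids,
                payload_reactions=[reference.get_reaction(rid).copy() for rid in rids],
                payload_metabolites=_metabolites_for(reference, rids),
            )
        )
    reg_groups = []
    for g in regulations:
        if g.kind != REGULATION_OFF:
            raise DeltaError(f"group {g.name!r} passed as regulation has kind {g.kind}")
        bounds = dict(g.original_bounds)
        for rid in g.reaction_ids:
            if rid not in bounds:
                r = reference.get_reaction(rid)
                bounds[rid] = (r.lower_bound, r.upper_bound)
        reg_groups.append(
            ModificationGroup(
                name=g.name,
                kind=REGULATION_OFF,
                reaction_ids=list(g.reaction_ids),
                original_bounds=bounds,
            )
        )
    return StrainDelta(
        reference_id=reference_id or reference.id,
        target_id=target_id,
        groups=list(target_additions) + deletion_groups + reg_groups,
    )


def _metabolites_for(model: MetabolicModel, reaction_ids: Iterable[str]) -> list[Metabolite]:
    mids: set[str] = set()
    for rid in reaction_ids:
        mids.update(model.get_reaction(rid).stoichiometry)
    return [model.get_metabolite(m) for m in sorted(mids)]


# ---------------------------------------------------------------------------
# delta application / reversion
# ---------------------------------------------------------------------------

def apply_delta(model: MetabolicModel, delta: StrainDelta) -> MetabolicModel:
    """Transform the reference model into the target-strain model.

    Additions are inserted, deletions removed (orphaned metabolites
    dropped), and regulation_off reactions retained with both bounds set
    to 0.  The input model is not modified.
    """
    out = model.copy()
    out.id = delta.target_id
    known_mets = set(out.metabolite_ids)
    for group in delta.groups:
        if group.kind == ADDITION:
            for met in group.payload_metabolites:
                if met.id not in known_mets:
                    out.metabolites.append(met)
                    known_mets.add(met.id)
            for r in group.payload_reactions:
                if out.has_reaction(r.id):
                    raise DeltaError(
                        f"addition group {group.name!r}: reaction {r.id!r} already exists"
                    )
                out.reactions.append(r.copy())
        elif group.kind == DELETION:
            for rid in group.reaction_ids:
                if not out.has_reaction(rid):
                    raise DeltaError(
                        f"deletion group {group.name!r}: reaction {rid!r} not in model"
                    )
                out.reactions = [r for r in out.reactions if r.id != rid]
        else:  # REGULATION_OFF
            for rid in group.reaction_ids:
                if not out.has_reaction(rid):
                    raise DeltaError(
                        f"regulation group {group.name!r}: reaction {rid!r} not in model"
                    )
                r = out.get_reaction(rid)
                r.lower_bound = 0.0
                r.upper_bound = 0.0
    out.drop_orphan_metabolites()
    return out


def revert_groups(
    target_model: MetabolicModel,
    delta: StrainDelta,
    subset: Iterable[str],
    reference: MetabolicModel | None = None,
) -> MetabolicModel:
    """Revert the named groups of an applied delta (in silico
    complementation): remove additions, restore deletions, re-open
    regulation_off bounds to their reference values.

    Restore payloads come from the groups themselves; ``reference`` is a
    fallback payload source for deltas loaded from TSV (which carries
    payloads only for additions).
    """
    subset = set(subset)
    unknown = subset - set(delta.group_names)
    if unknown:
        raise KeyError(f"unknown group name(s): {sorted(unknown)}")
    out = target_model.copy()
    known_mets = set(out.metabolite_ids)
    for group in delta.groups:
        if group.name not in subset:
            continue
        if group.kind == ADDITION:
            for rid in group.reaction_ids:
                out.reactions = [r for r in out.reactions if r.id != rid]
        elif group.kind == DELETION:
            payload_r = group.payload_reactions
            payload_m = group.payload_metabolites
            if not payload_r:
                if reference is None:
                    raise DeltaError(
                        f"deletion group {group.name!r} has no payload and no "
                        f"reference model was supplied"
                    )
                payload_r = [reference.get_reaction(rid) for rid in group.reaction_ids]
                payload_m = _metabolites_for(reference, group.reaction_ids)
            for met in payload_m:
                if met.id not in known_mets:
                    out.metabolites.append(met)
                    known_mets.add(met.id)
            for r in payload_r:
                if not out.has_reaction(r.id):
                    out.reactions.append(r.copy())
        else:  # REGULATION_OFF
            for rid in group.reaction_ids:
                r = out.get_reaction(rid)
                if rid in group.original_bounds:
                    r.lower_bound, r.upper_bound = group.original_bounds[rid]
                elif reference is not None:
                    ref_r = reference.get_reaction(rid)
                    r.lower_bound, r.upper_bound = ref_r.lower_bound, ref_r.upper_bound
                else:
                    raise DeltaError(
                        f"regulation group {group.name!r}: no original bounds for {rid!r}"
                    )
    out.drop_orphan_metabolites()
    return out


# ---------------------------------------------------------------------------
# delta TSV dialect
# ---------------------------------------------------------------------------

_DELTA_HEADER = ["group", "kind", "reaction_id", "equation", "lb", "ub", "gpr"]


def save_delta(delta: StrainDelta, path: str | Path) -> None:
    """Delta TSV: one row per (group, reaction); equation/lb/ub/gpr are
    filled for additions only."""
    lines = [f"# delta\t{delta.reference_id}\t{delta.target_id}"]
    lines.append("\t".join(_DELTA_HEADER))
    for g in delta.groups:
        for rid in g.reaction_ids:
            if g.kind == ADDITION:
                r = next(p for p in g.payload_reactions if p.id == rid)
                lines.append(
                    "\t".join(
                        [g.name, g.kind, rid, format_equation(r),
                         f"{r.lower_bound:g}", f"{r.upper_bound:g}", r.gpr]
                    )
                )
            else:
                lines.append("\t".join([g.name, g.kind, rid, "", "", "", ""]))
    Path(path).write_text("\n".join(lines) + "\n")


def load_delta(
    path: str | Path, reference: MetabolicModel | None = None
) -> StrainDelta:
    """Load a delta TSV; with a reference model, deletion payloads and
    regulation original bounds are resolved immediately."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    reference_id, target_id = "reference", "target"
    if lines and lines[0].startswith("#"):
        head = lines.pop(0).lstrip("#").strip().split("\t")
        if len(head) >= 3 and head[0] == "delta":
            reference_id, target_id = head[1], head[2]
    if lines and lines[0].split("\t")[0] == "group":
        lines.pop(0)
    rows: dict[str, dict] = {}
    order: list[str] = []
    for i, line in enumerate(lines, start=1):
        cols = line.split("\t")
        if len(cols) < 3:
            raise ModelParseError(f"{path}: line {i}: expected >= 3 columns")
        cols += [""] * (7 - len(cols))
        name, kind, rid, equation, lb, ub, gpr = cols[:7]
        if name not in rows:
            rows[name] = {"kind": kind, "rids": [], "payload": []}
            order.append(name)
        if rows[name]["kind"] != kind:
            raise ModelParseError(f"{path}: line {i}: group {name!r} mixes kinds")
        rows[name]["rids"].append(rid)
        if kind == ADDITION:
            stoich, reversible = parse_equation(equation)
            from strainflux.models import Compartment

            is_exchange = len(stoich) == 1 and _compartment_of(
                next(iter(stoich))
            ) is Compartment.EXTRACELLULAR
            rows[name]["payload"].append(
                Reaction(
                    id=rid,
                    stoichiometry=stoich,
                    lower_bound=float(lb) if lb else (-DEFAULT_BOUND if reversible else 0.0),
                    upper_bound=float(ub) if ub else DEFAULT_BOUND,
                    gpr=gpr,
                    is_exchange=is_exchange,
                )
            )
    groups = []
    ref_met_ids = set(reference.metabolite_ids) if reference is not None else set()
    for name in order:
        rec = rows[name]
        kind = rec["kind"]
        payload_m: list[Metabolite] = []
        original_bounds: dict[str, tuple[float, float]] = {}
        payload_r: list[Reaction] = rec["payload"]
        if kind == ADDITION:
            new_mids: set[str] = set()
            for r in payload_r:
                new_mids.update(m for m in r.stoichiometry if m not in ref_met_ids)
            payload_m = [
                Metabolite(id=m, compartment=_compartment_of(m)) for m in sorted(new_mids)
            ]
        elif reference is not None:
            if kind == DELETION:
                payload_r = [reference.get_reaction(rid).copy() for rid in rec["rids"]]
                payload_m = _metabolites_for(reference, rec["rids"])
            else:
                for rid in rec["rids"]:
                    r = reference.get_reaction(rid)
                    original_bounds[rid] = (r.lower_bound, r.upper_bound)
        groups.append(
            ModificationGroup(
                name=name,
                kind=kind,
                reaction_ids=rec["rids"],
                payload_reactions=payload_r,
                payload_metabolites=payload_m,
                original_bounds=original_bounds,
            )
        )
    return StrainDelta(reference_id=reference_id, target_id=target_id, groups=groups)
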