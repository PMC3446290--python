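"""Domain types for constraint-based models and file dialects.

A :class:`MetabolicModel` is a stoichiometric network with flux bounds,
gene-protein-reaction (GPR) boolean rules and a biomass objective.  Two
text dialects are supported: a JSON layout mirroring the de-facto
community constraint-based format (``metabolites`` / ``reactions`` /
``genes`` arrays, so published genome-scale models can be loaded when
available) and a one-reaction-per-row TSV with equation strings such as
``"2 A_c + B_c -> C_c"``.  An SBML Level 3 FBC subset reader is provided
when libsbml is importable.

Flux units are mmol/gDCW/h throughout; the biomass objective flux is the
specific growth rate in 1/h.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: conventional "unbounded" flux sentinel, mmol/gDCW/h
DEFAULT_BOUND = 1000.0


class Compartment(str, Enum):
    """Subcellular compartment of a metabolite."""

    CYTOSOL = "c"
    PERIPLASM = "p"
    EXTRACELLULAR = "e"

    @classmethod
    def coerce(cls, value: "str | Compartment") -> "Compartment":
        if isinstance(value, Compartment):
            return value
        aliases = {
            "c": cls.CYTOSOL,
            "cytosol": cls.CYTOSOL,
            "p": cls.PERIPLASM,
            "periplasm": cls.PERIPLASM,
            "e": cls.EXTRACELLULAR,
            "extracellular": cls.EXTRACELLULAR,
        }
        try:
            return aliases[str(value).strip().lower()]
        except KeyError:
            raise ValueError(f"unknown compartment {value!r}") from None


class GeneStatus(str, Enum):
    """Functional status of a gene in one strain.

    Pseudogenes (disrupted by frameshift, truncation or IS insertion) are
    non-functional for GPR evaluation but kept distinct from physical
    absence in reports.
    """

    PRESENT = "present"
    ABSENT = "absent"
    PSEUDOGENE = "pseudogene"


class GrowthCall(str, Enum):
    """Binary qualitative growth call, the comparison currency between
    FBA predictions and phenotype-microarray grades."""

    GROWTH = "growth"
    NO_GROWTH = "no_growth"


class ModelError(Exception):
    """Base class for model construction/IO errors."""


class ModelParseError(ModelError):
    """Malformed model file; message names the offending line/record."""


class ModelValidationError(ModelError):
    """A model violates its structural invariants."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: Compartment = Compartment.CYTOSOL
    formula: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        object.__setattr__(self, "compartment", Compartment.coerce(self.compartment))
        if not self.name:
            object.__setattr__(self, "name", self.id)


@dataclass
class Reaction:
    """One reaction: stoichiometry (negative coefficient = consumed),
    flux bounds in mmol/gDCW/h, and a GPR boolean string (may be empty,
    meaning no genetic dependency)."""

    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    is_exchange: bool = False
    subsystem: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if not self.name:
            self.name = self.id

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    """A constraint-based metabolic network with a biomass objective."""

    id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective_id: str = ""

    # -- indexed access -------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise KeyError(reaction_id)

    def get_metabolite(self, metabolite_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == metabolite_id:
                return m
        raise KeyError(metabolite_id)

    def has_reaction(self, reaction_id: str) -> bool:
        return any(r.id == reaction_id for r in self.reactions)

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            objective_id=self.objective_id,
        )

    def drop_orphan_metabolites(self) -> None:
        """Remove metabolites referenced by no remaining reaction."""
        used: set[str] = set()
        for r in self.reactions:
            used.update(r.stoichiometry)
        self.metabolites = [m for m in self.metabolites if m.id in used]

    def equal_fields(self, other: "MetabolicModel") -> bool:
        """Field-by-field equality, order-insensitive on the element lists."""
        if self.id != other.id or self.objective_id != other.objective_id:
            return False
        if sorted(self.metabolites, key=lambda m: m.id) != sorted(
            other.metabolites, key=lambda m: m.id
        ):
            return False
        mine = {r.id: r for r in self.reactions}
        theirs = {r.id: r for r in other.reactions}
        return mine == theirs


GeneStatusTable = dict[str, GeneStatus]


@dataclass(frozen=True)
class GrowthCondition:
    """Substrate/uptake specification for one PM-style well.

    ``substrate_uptake`` and ``oxygen_uptake`` are maximal uptake rates in
    mmol/gDCW/h; uptake is realized as a negative exchange flux.
    ``co_substrates`` carries auxiliary carbon/energy sources (for example
    succinate on nitrogen/phosphorus/sulfur plates).
    """

    name: str
    substrate_exchange_id: str
    substrate_uptake: float = 8.0
    oxygen_uptake: float = 18.5
    oxygen_exchange_id: str = "EX_o2(e)"
    co_substrates: Mapping[str, float] = field(default_factory=dict)
    category: str = "carbon"

    def __post_init__(self) -> None:
        if self.substrate_uptake < 0 or self.oxygen_uptake < 0:
            raise ValueError(f"{self.name}: uptake rates must be >= 0")
        if any(v < 0 for v in self.co_substrates.values()):
            raise ValueError(f"{self.name}: co-substrate uptakes must be >= 0")
        object.__setattr__(self, "co_substrates", dict(self.co_substrates))


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds of the whole pipeline.

    growth_epsilon : float
        Objective value (1/h) above which an optimal FBA solution is
        called growth; separates numerical zeros from genuine growth.
    lp_tolerance : float
        Feasibility tolerance for mass-balance and bound checks.
    max_revert_subset : int
        Largest modification-group subset cardinality the
        complementation search enumerates.
    gc_sigma_threshold, codon_p_threshold : float
        A gene is "foreign" when |G+C z-score| exceeds the former AND its
        codon-usage chi-square P falls below the latter.
    window_genes, min_foreign : int
        Sliding-window size (genes) and minimum foreign genes per window
        for an island call.
    """

    growth_epsilon: float = 1e-6
    lp_tolerance: float = 1e-7
    max_revert_subset: int = 3
    gc_sigma_threshold: float = 1.5
    codon_p_threshold: float = 0.05
    window_genes: int = 10
    min_foreign: int = 4
    random_seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "growth_epsilon": self.growth_epsilon,
            "lp_tolerance": self.lp_tolerance,
            "max_revert_subset": self.max_revert_subset,
            "gc_sigma_threshold": self.gc_sigma_threshold,
            "codon_p_threshold": self.codon_p_threshold,
            "window_genes": self.window_genes,
            "min_foreign": self.min_foreign,
        }
        for key, value in positive.items():
            if value <= 0:
                raise ValueError(f"{key} must be strictly positive, got {value}")
        if self.window_genes < self.min_foreign:
            raise ValueError("window_genes must be >= min_foreign")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_model(model: MetabolicModel) -> list[str]:
    """Return a list of invariant violations; empty iff the model is valid."""
    report: list[str] = []
    met_ids = model.metabolite_ids
    seen_mets = set()
    for mid in met_ids:
        if mid in seen_mets:
            report.append(f"duplicate metabolite id {mid!r}")
        seen_mets.add(mid)
    rxn_ids = model.reaction_ids
    seen = set()
    for rid in rxn_ids:
        if rid in seen:
            report.append(f"duplicate reaction id {rid!r}")
        seen.add(rid)
    met_by_id = {m.id: m for m in model.metabolites}
    for r in model.reactions:
        if r.lower_bound > r.upper_bound:
            report.append(
                f"reaction {r.id!r}: lower_bound {r.lower_bound} > "
                f"upper_bound {r.upper_bound}"
            )
        if not r.stoichiometry:
            report.append(f"reaction {r.id!r}: empty stoichiometry")
        dangling = sorted(set(r.stoichiometry) - set(met_by_id))
        if dangling:
            report.append(
                f"reaction {r.id!r}: dangling metabolite reference(s) {dangling}"
            )
        if r.is_exchange:
            if len(r.stoichiometry) != 1:
                report.append(
                    f"exchange reaction {r.id!r} references "
                    f"{len(r.stoichiometry)} metabolites (expected exactly 1)"
                )
            else:
                (mid,) = r.stoichiometry
                met = met_by_id.get(mid)
                if met is not None and met.compartment is not Compartment.EXTRACELLULAR:
                    report.append(
                        f"exchange reaction {r.id!r}: metabolite {mid!r} is not "
                        f"extracellular"
                    )
    if not model.objective_id:
        report.append("objective_id is empty")
    elif model.objective_id not in seen:
        report.append(f"objective_id {model.objective_id!r} is not a reaction id")
    return report


def _require_valid(model: MetabolicModel) -> None:
    report = validate_model(model)
    if report:
        raise ModelValidationError("; ".join(report))


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _model_to_json_dict(model: MetabolicModel) -> dict:
    genes: set[str] = set()
    for r in model.reactions:
        genes.update(gpr_gene_ids(r.gpr))
    return {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment.value,
                "formula": m.formula,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr,
                "subsystem": r.subsystem,
                "is_exchange": r.is_exchange,
                "objective_coefficient": 1.0 if r.id == model.objective_id else 0.0,
            }
            for r in model.reactions
        ],
        "genes": [{"id": g} for g in sorted(genes)],
    }


def _model_from_json_dict(data: dict, source: str = "<json>") -> MetabolicModel:
    try:
        metabolites = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=Compartment.coerce(m.get("compartment", "c")),
                formula=m.get("formula"),
            )
            for m in data.get("metabolites", [])
        ]
        known = {m.id for m in metabolites}
        reactions = []
        objective_id = data.get("objective_id", "")
        for rec in data.get("reactions", []):
            stoich = {k: float(v) for k, v in rec["metabolites"].items()}
            reversible = float(rec.get("lower_bound", 0.0)) < 0
            lb = float(
                rec.get("lower_bound", -DEFAULT_BOUND if reversible else 0.0)
            )
            ub = float(rec.get("upper_bound", DEFAULT_BOUND))
            is_exchange = rec.get("is_exchange")
            if is_exchange is None:
                is_exchange = _infer_exchange(rec["id"], stoich, metabolites)
            reactions.append(
                Reaction(
                    id=rec["id"],
                    name=rec.get("name", ""),
                    stoichiometry=stoich,
                    lower_bound=lb,
                    upper_bound=ub,
                    gpr=rec.get("gene_reaction_rule", rec.get("gpr", "")),
                    is_exchange=bool(is_exchange),
                    subsystem=rec.get("subsystem"),
                )
            )
            if float(rec.get("objective_coefficient", 0.0)) != 0.0:
                objective_id = rec["id"]
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelParseError(f"{source}: malformed model record ({exc})") from exc
    model = MetabolicModel(
        id=data.get("id", "model"),
        metabolites=metabolites,
        reactions=reactions,
        objective_id=objective_id,
    )
    _require_valid(model)
    # silence unused warning; `known` kept for symmetry with TSV path
    del known
    return model


def _infer_exchange(
    rid: str, stoich: Mapping[str, float], metabolites: Iterable[Metabolite]
) -> bool:
    if len(stoich) != 1:
        return False
    (mid,) = stoich
    for m in metabolites:
        if m.id == mid:
            return m.compartment is Compartment.EXTRACELLULAR
    return False


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_TSV_HEADER = ["id", "equation", "lb", "ub", "gpr", "is_exchange"]
_ARROWS = ("<=>", "<->", "-->", "->", "=>")


def _compartment_of(met_id: str) -> Compartment:
    if met_id.endswith("_e") or met_id.endswith("(e)") or met_id.endswith("[e]"):
        return Compartment.EXTRACELLULAR
    if met_id.endswith("_p") or met_id.endswith("(p)") or met_id.endswith("[p]"):
        return Compartment.PERIPLASM
    return Compartment.CYTOSOL


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse ``"2 A_c + B_c -> C_c"`` into a stoichiometry map.

    Returns (stoichiometry, reversible). ``<=>`` marks a reversible
    reaction. Either side may be empty (boundary/exchange reactions).
    """
    arrow = None
    for a in _ARROWS:
        if a in equation:
            arrow = a
            break
    if arrow is None:
        raise ModelParseError(f"equation {equation!r}: no reaction arrow found")
    reversible = arrow in ("<=>", "<->")
    left, right = equation.split(arrow, 1)
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            m = re.match(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$", term)
            if m is None:
                raise ModelParseError(f"equation term {term!r} is malformed")
            coef = float(m.group(1)) if m.group(1) else 1.0
            mid = m.group(2)
            stoich[mid] = stoich.get(mid, 0.0) + sign * coef

    add_side(left, -1.0)
    add_side(right, +1.0)
    if not stoich:
        raise ModelParseError(f"equation {equation!r}: no metabolites")
    return stoich, reversible


def format_equation(reaction: Reaction) -> str:
    def fmt(side: list[tuple[str, float]]) -> str:
        parts = []
        for mid, coef in side:
            coef = abs(coef)
            if math.isclose(coef, 1.0):
                parts.append(mid)
            elif math.isclose(coef, round(coef)):
                parts.append(f"{int(round(coef))} {mid}")
            else:
                parts.append(f"{coef:g} {mid}")
        return " + ".join(parts)

    left = sorted((m, c) for m, c in reaction.stoichiometry.items() if c < 0)
    right = sorted((m, c) for m, c in reaction.stoichiometry.items() if c > 0)
    arrow = "<=>" if reaction.lower_bound < 0 else "->"
    return f"{fmt(left)} {arrow} {fmt(right)}".strip()


def _model_to_tsv(model: MetabolicModel) -> str:
    lines = ["# model\t" + model.id + "\tobjective\t" + model.objective_id]
    lines.append("\t".join(_TSV_HEADER))
    for r in model.reactions:
        lines.append(
            "\t".join(
                [
                    r.id,
                    format_equation(r),
                    f"{r.lower_bound:g}",
                    f"{r.upper_bound:g}",
                    r.gpr,
                    "1" if r.is_exchange else "0",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def _model_from_tsv(text: str, source: str = "<tsv>") -> MetabolicModel:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ModelParseError(f"{source}: empty file")
    model_id, objective_id = "model", ""
    if lines[0].startswith("#"):
        head = lines.pop(0).lstrip("#").strip().split("\t")
        if len(head) >= 4 and head[0] == "model":
            model_id, objective_id = head[1], head[3]
    if lines and lines[0].split("\t")[0] == "id":
        lines.pop(0)
    mets: dict[str, Metabolite] = {}
    reactions: list[Reaction] = []
    for i, line in enumerate(lines, start=1):
        cols = line.split("\t")
        if len(cols) < 4:
            raise ModelParseError(f"{source}: record {i}: expected >= 4 columns")
        rid, equation, lb, ub = cols[0], cols[1], cols[2], cols[3]
        gpr = cols[4] if len(cols) > 4 else ""
        exch = cols[5].strip() in ("1", "true", "True") if len(cols) > 5 else False
        try:
            stoich, reversible = parse_equation(equation)
            lb_f = float(lb) if lb != "" else (-DEFAULT_BOUND if reversible else 0.0)
            ub_f = float(ub) if ub != "" else DEFAULT_BOUND
        except (ValueError, ModelParseError) as exc:
            raise ModelParseError(f"{source}: record {i} ({rid}): {exc}") from exc
        for mid in stoich:
            if mid not in mets:
                mets[mid] = Metabolite(id=mid, compartment=_compartment_of(mid))
        if not exch:
            exch = _infer_exchange(rid, stoich, mets.values())
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb_f,
                upper_bound=ub_f,
                gpr=gpr,
                is_exchange=exch,
            )
        )
    model = MetabolicModel(
        id=model_id,
        metabolites=list(mets.values()),
        reactions=reactions,
        objective_id=objective_id,
    )
    _require_valid(model)
    return model


# ---------------------------------------------------------------------------
# SBML (Level 3 FBC subset), available when libsbml is importable
# ---------------------------------------------------------------------------

def _model_from_sbml(path: Path) -> MetabolicModel:
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover
        raise ModelError(
            "SBML support requires libsbml, which is not installed"
        ) from exc
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() > 0 and doc.getError(0).getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
        raise ModelParseError(f"{path}: {doc.getError(0).getMessage()}")
    sm = doc.getModel()
    if sm is None:
        raise ModelParseError(f"{path}: no model element")
    comp_map = {}
    for i in range(sm.getNumCompartments()):
        c = sm.getCompartment(i)
        try:
            comp_map[c.getId()] = Compartment.coerce(c.getId())
        except ValueError:
            comp_map[c.getId()] = Compartment.CYTOSOL
    mets = [
        Metabolite(
            id=sm.getSpecies(i).getId(),
            name=sm.getSpecies(i).getName() or sm.getSpecies(i).getId(),
            compartment=comp_map.get(sm.getSpecies(i).getCompartment(), Compartment.CYTOSOL),
        )
        for i in range(sm.getNumSpecies())
    ]
    fbc = sm.getPlugin("fbc")
    objective_id = ""
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj.getNumFluxObjectives() > 0:
            objective_id = obj.getFluxObjective(0).getReaction()
    params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }
    reactions = []
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rfbc = sr.getPlugin("fbc")
        lb = -DEFAULT_BOUND if sr.getReversible() else 0.0
        ub = DEFAULT_BOUND
        gpr = ""
        if rfbc is not None:
            if rfbc.isSetLowerFluxBound():
                lb = params.get(rfbc.getLowerFluxBound(), lb)
            if rfbc.isSetUpperFluxBound():
                ub = params.get(rfbc.getUpperFluxBound(), ub)
            gpa = rfbc.getGeneProductAssociation()
            if gpa is not None:
                gpr = _sbml_association_to_gpr(gpa.getAssociation())
        reactions.append(
            Reaction(
                id=sr.getId(),
                name=sr.getName() or sr.getId(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                is_exchange=_infer_exchange(sr.getId(), stoich, mets),
            )
        )
    model = MetabolicModel(
        id=sm.getId() or "model",
        metabolites=mets,
        reactions=reactions,
        objective_id=objective_id,
    )
    _require_valid(model)
    return model


def _sbml_association_to_gpr(assoc) -> str:
    import libsbml

    if assoc is None:
        return ""
    if isinstance(assoc, libsbml.GeneProductRef):
        return assoc.getGeneProduct()
    parts = [
        _sbml_association_to_gpr(assoc.getAssociation(i))
        for i in range(assoc.getNumAssociations())
    ]
    op = " and " if isinstance(assoc, libsbml.FbcAnd) else " or "
    return "(" + op.join(p for p in parts if p) + ")"


# ---------------------------------------------------------------------------
# public IO
# ---------------------------------------------------------------------------

def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    return {".json": "json", ".tsv": "tsv", ".xml": "sbml", ".sbml": "sbml"}.get(
        suffix, "json"
    )


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a model from JSON, TSV or SBML; validates before returning."""
    path = Path(path)
    fmt = format or _sniff_format(path)
    if fmt == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
        return _model_from_json_dict(data, source=str(path))
    if fmt == "tsv":
        return _model_from_tsv(path.read_text(), source=str(path))
    if fmt in ("sbml", "sbml-subset"):
        return _model_from_sbml(path)
    raise ValueError(f"unknown model format {fmt!r}")


def save_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Write a model to JSON or TSV after validating it."""
    path = Path(path)
    _require_valid(model)
    fmt = format or _sniff_format(path)
    if fmt == "json":
        path.write_text(json.dumps(_model_to_json_dict(model), indent=1, ensure_ascii=False))
    elif fmt == "tsv":
        path.write_text(_model_to_tsv(model))
    else:
        raise ValueError(f"unsupported output format {fmt!r}")


# ---------------------------------------------------------------------------
# gene-status & condition tables
# ---------------------------------------------------------------------------

def load_gene_status(path: str | Path) -> GeneStatusTable:
    """Two-column TSV ``gene_id<TAB>status`` -> GeneStatusTable."""
    table: GeneStatusTable = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise ModelParseError(f"{path}: line {i}: expected gene_id<TAB>status")
        if cols[0] == "gene_id":
            continue
        try:
            table[cols[0]] = GeneStatus(cols[1].strip())
        except ValueError:
            raise ModelParseError(
                f"{path}: line {i}: unknown status {cols[1]!r}"
            ) from None
    return table


def save_gene_status(table: GeneStatusTable, path: str | Path) -> None:
    lines = ["gene_id\tstatus"]
    lines += [f"{g}\t{s.value}" for g, s in sorted(table.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def load_conditions(path: str | Path) -> list[GrowthCondition]:
    """Condition TSV: name, substrate exchange id, substrate uptake,
    oxygen uptake, co-substrates (``id=rate;id=rate`` or empty), category."""
    conditions = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if cols[0] == "name":
            continue
        if len(cols) < 6:
            raise ModelParseError(f"{path}: line {i}: expected 6 columns")
        co: dict[str, float] = {}
        if cols[4].strip():
            for item in cols[4].split(";"):
                k, v = item.split("=")
                co[k.strip()] = float(v)
        conditions.append(
            GrowthCondition(
                name=cols[0],
                substrate_exchange_id=cols[1],
                substrate_uptake=float(cols[2]),
                oxygen_uptake=float(cols[3]),
                co_substrates=co,
                category=cols[5].strip(),
            )
        )
    return conditions


def save_conditions(conditions: Iterable[GrowthCondition], path: str | Path) -> None:
    lines = ["name\tsubstrate_exchange_id\tsubstrate_uptake\toxygen_uptake\tco_substrates\tcategory"]
    for c in conditions:
        co = ";".join(f"{k}={v:g}" for k, v in sorted(c.co_substrates.items()))
        lines.append(
            f"{c.name}\t{c.substrate_exchange_id}\t{c.substrate_uptake:g}\t"
            f"{c.oxygen_uptake:g}\t{co}\t{c.category}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def gpr_gene_ids(expression: str) -> set[str]:
    """All gene ids referenced by a GPR boolean expression."""
    tokens = re.findall(r"[A-Za-z0-9_.\-]+", expression)
    return {t for t in tokens if t.lower() not in ("and", "or")}
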