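"""Genome-scale metabolic model containers and readers/writers.

A metabolic model is a set of compartmentalized metabolites, a set of
reactions carrying signed stoichiometry, flux bounds (mmol gDW⁻¹ h⁻¹) and
optional gene–protein–reaction (GPR) boolean rules, plus one designated
biomass pseudo-reaction whose flux is the in silico growth rate.

Two on-disk dialects are supported:

* SBML Level 3 Version 1 with the FBC v2 package — bounds as global
  parameters, GPRs as ``fbc:geneProductAssociation``, the biomass reaction
  as the active FBC objective, reaction kinds as SBO terms.
* A tabular dialect: a directory with ``reactions.tsv`` (columns ``id``,
  ``name``, ``equation``, ``lb``, ``ub``, ``gpr``, ``subsystem``, ``kind``)
  and ``metabolites.tsv`` (``id``, ``name``, ``compartment``), tab-separated
  UTF-8 with a header row.  Equations use ``-->`` for irreversible and
  ``<=>`` for reversible reactions, e.g. ``2 A_c + B_c --> C_c``.

Bounds missing from a file default to (−1000, 1000) for reversible and
(0, 1000) for irreversible reactions, the conventional COBRA proxy for an
unconstrained flux.
"""

from __future__ import annotations

import copy
import math
import os
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

__all__ = [
    "GprParseError",
    "ModelValidationError",
    "ModelIOError",
    "GprExpr",
    "Metabolite",
    "Reaction",
    "ReactionKind",
    "MetabolicModel",
    "ModelCensus",
    "parse_gpr",
    "read_model",
    "write_model",
    "census",
    "DEFAULT_LOWER_BOUND",
    "DEFAULT_UPPER_BOUND",
]

DEFAULT_LOWER_BOUND = -1000.0
DEFAULT_UPPER_BOUND = 1000.0


class GprParseError(ValueError):
    """Malformed GPR text; carries the character position of the problem."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class ModelValidationError(ValueError):
    """A model violates a structural invariant."""


class ModelIOError(OSError):
    """A model file could not be read or written."""


# ---------------------------------------------------------------------------
# GPR boolean trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GprExpr:
    """Boolean gene association: a gene leaf, or an AND/OR over ≥2 children.

    AND encodes enzyme complexes (all subunits required), OR encodes
    isozymes (any one suffices).  Trees serialize to the usual
    ``"g1 and (g2 or g3)"`` text form and round-trip through
    :func:`parse_gpr`.
    """

    kind: str  # "gene" | "and" | "or"
    gene: Optional[str] = None
    children: Tuple["GprExpr", ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "gene":
            if not self.gene:
                raise ValueError("gene leaf requires a non-empty gene id")
        elif self.kind in ("and", "or"):
            if len(self.children) < 2:
                raise ValueError(f"{self.kind!r} node requires >= 2 children")
        else:
            raise ValueError(f"unknown GPR node kind {self.kind!r}")

    @staticmethod
    def gene_(gene_id: str) -> "GprExpr":
        return GprExpr("gene", gene=gene_id)

    @staticmethod
    def and_(*children: "GprExpr") -> "GprExpr":
        return GprExpr("and", children=tuple(children))

    @staticmethod
    def or_(*children: "GprExpr") -> "GprExpr":
        return GprExpr("or", children=tuple(children))

    def genes(self) -> Iterator[str]:
        """Yield every gene id in the tree (leaves, left to right)."""
        if self.kind == "gene":
            yield self.gene  # type: ignore[misc]
        else:
            for child in self.children:
                yield from child.genes()

    def serialize(self) -> str:
        """Render to text; compound children are always parenthesized so
        that ``parse_gpr(serialize(t)) == t`` holds exactly."""
        if self.kind == "gene":
            return self.gene  # type: ignore[return-value]
        parts = [
            c.serialize() if c.kind == "gene" else f"({c.serialize()})"
            for c in self.children
        ]
        return f" {self.kind} ".join(parts)

    def __str__(self) -> str:
        return self.serialize()


_GPR_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize_gpr(text: str) -> List[Tuple[str, int]]:
    tokens: List[Tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _GPR_TOKEN.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(text: str) -> GprExpr:
    """Parse GPR text into a boolean tree.

    ``and`` binds tighter than ``or``; both keywords are case-insensitive;
    parentheses group.  Runs of the same operator flatten into one n-ary
    node, so ``a and b and c`` is a single AND over three genes.

    Raises
    ------
    GprParseError
        On unbalanced parentheses, dangling operators or empty input,
        naming the offending character position.
    """
    tokens = _tokenize_gpr(text)
    if not tokens:
        raise GprParseError("empty GPR expression", 0)
    idx = 0

    def peek() -> Optional[Tuple[str, int]]:
        return tokens[idx] if idx < len(tokens) else None

    def parse_or() -> GprExpr:
        nonlocal idx
        terms = [parse_and()]
        while (tok := peek()) is not None and tok[0].lower() == "or":
            idx += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else GprExpr("or", children=tuple(terms))

    def parse_and() -> GprExpr:
        nonlocal idx
        factors = [parse_factor()]
        while (tok := peek()) is not None and tok[0].lower() == "and":
            idx += 1
            factors.append(parse_factor())
        if len(factors) == 1:
            return factors[0]
        return GprExpr("and", children=tuple(factors))

    def parse_factor() -> GprExpr:
        nonlocal idx
        tok = peek()
        if tok is None:
            raise GprParseError("dangling operator", len(text))
        word, pos = tok
        if word == "(":
            idx += 1
            inner = parse_or()
            closing = peek()
            if closing is None or closing[0] != ")":
                raise GprParseError("unbalanced parenthesis", pos)
            idx += 1
            return inner
        if word == ")":
            raise GprParseError("unexpected ')'", pos)
        if word.lower() in ("and", "or"):
            raise GprParseError(f"dangling operator {word!r}", pos)
        idx += 1
        return GprExpr.gene_(word)

    tree = parse_or()
    if (tok := peek()) is not None:
        raise GprParseError(f"unexpected token {tok[0]!r}", tok[1])
    return tree


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


class ReactionKind(str, Enum):
    ENZYMATIC = "enzymatic"
    SPONTANEOUS = "spontaneous"
    TRANSPORT = "transport"
    EXCHANGE = "exchange"
    BIOMASS = "biomass"


@dataclass
class Metabolite:
    """A compartmentalized chemical species; the row index of S."""

    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    """A stoichiometric conversion; the column index of S.

    ``stoich`` maps metabolite id to a signed coefficient, negative for
    consumption.  Exchange reactions touch exactly one metabolite and use
    the convention "metabolite ↔ ∅" with uptake as negative flux.
    """

    id: str
    stoich: Dict[str, float]
    name: str = ""
    lb: float = DEFAULT_LOWER_BOUND
    ub: float = DEFAULT_UPPER_BOUND
    gpr: Optional[GprExpr] = None
    subsystem: Optional[str] = None
    kind: ReactionKind = ReactionKind.ENZYMATIC

    @property
    def reversible(self) -> bool:
        return self.lb < 0 < self.ub

    def genes(self) -> set:
        return set(self.gpr.genes()) if self.gpr is not None else set()


@dataclass
class MetabolicModel:
    """An ordered GSMM: metabolites, reactions, compartments, biomass id.

    The gene set is derived, always the union of GPR leaves.
    """

    id: str
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    compartments: Dict[str, str] = field(default_factory=dict)
    biomass_id: Optional[str] = None

    @property
    def genes(self) -> set:
        out: set = set()
        for rxn in self.reactions:
            out |= rxn.genes()
        return out

    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}")

    def exchange_ids(self) -> List[str]:
        return [r.id for r in self.reactions if r.kind == ReactionKind.EXCHANGE]

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def validate(self) -> None:
        """Check all structural invariants; raise ModelValidationError."""
        met_ids = self.metabolite_ids()
        met_set = set(met_ids)
        if len(met_set) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = self.reaction_ids()
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        declared = set(self.compartments)
        for met in self.metabolites:
            if not met.id:
                raise ModelValidationError("empty metabolite id")
            if declared and met.compartment not in declared:
                raise ModelValidationError(
                    f"metabolite {met.id!r} uses undeclared compartment "
                    f"{met.compartment!r}"
                )
        n_biomass = 0
        for rxn in self.reactions:
            if rxn.lb > rxn.ub:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} has lb {rxn.lb} > ub {rxn.ub}"
                )
            for met_id in rxn.stoich:
                if met_id not in met_set:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite "
                        f"{met_id!r}"
                    )
            if rxn.kind == ReactionKind.EXCHANGE and len(rxn.stoich) != 1:
                raise ModelValidationError(
                    f"exchange reaction {rxn.id!r} must touch exactly one "
                    f"metabolite, found {len(rxn.stoich)}"
                )
            if rxn.kind != ReactionKind.EXCHANGE and not rxn.stoich:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} has empty stoichiometry"
                )
            if rxn.kind == ReactionKind.BIOMASS:
                n_biomass += 1
        if self.biomass_id is None:
            raise ModelValidationError(f"model {self.id!r} declares no biomass reaction")
        if self.biomass_id not in set(rxn_ids):
            raise ModelValidationError(
                f"biomass reaction {self.biomass_id!r} not present in model"
            )
        if n_biomass != 1:
            raise ModelValidationError(
                f"model must have exactly one biomass-kind reaction, found {n_biomass}"
            )


@dataclass(frozen=True)
class ModelCensus:
    """Structural counts of a model: the standard characteristics table.

    Non-enzymatic reactions are everything without the enzymatic tag —
    spontaneous, transport, exchange and biomass — so
    ``n_enzymatic + n_nonenzymatic == n_reactions`` by construction.
    """

    n_genes: int
    n_metabolites: int
    n_reactions: int
    n_enzymatic: int
    n_nonenzymatic: int
    n_spontaneous: int
    n_transport: int
    n_exchange: int
    n_biomass: int

    def as_dict(self) -> Dict[str, int]:
        return {
            "genes": self.n_genes,
            "metabolites": self.n_metabolites,
            "reactions": self.n_reactions,
            "enzymatic": self.n_enzymatic,
            "nonenzymatic": self.n_nonenzymatic,
            "spontaneous": self.n_spontaneous,
            "transport": self.n_transport,
            "exchange": self.n_exchange,
            "biomass": self.n_biomass,
        }


def census(model: MetabolicModel) -> ModelCensus:
    """Count genes, metabolites and reactions by kind."""
    kinds = [r.kind for r in model.reactions]
    n_enz = sum(k == ReactionKind.ENZYMATIC for k in kinds)
    return ModelCensus(
        n_genes=len(model.genes),
        n_metabolites=len(model.metabolites),
        n_reactions=len(model.reactions),
        n_enzymatic=n_enz,
        n_nonenzymatic=len(kinds) - n_enz,
        n_spontaneous=sum(k == ReactionKind.SPONTANEOUS for k in kinds),
        n_transport=sum(k == ReactionKind.TRANSPORT for k in kinds),
        n_exchange=sum(k == ReactionKind.EXCHANGE for k in kinds),
        n_biomass=sum(k == ReactionKind.BIOMASS for k in kinds),
    )


def infer_kind(rxn: Reaction, biomass_id: Optional[str]) -> ReactionKind:
    """Default kind when a file carries none: exchange = one metabolite,
    biomass = declared id, else enzymatic iff a GPR is present."""
    if biomass_id is not None and rxn.id == biomass_id:
        return ReactionKind.BIOMASS
    if len(rxn.stoich) == 1:
        return ReactionKind.EXCHANGE
    if rxn.gpr is not None:
        return ReactionKind.ENZYMATIC
    return ReactionKind.SPONTANEOUS


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "-->")


def _parse_equation(eq: str, rxn_id: str) -> Tuple[Dict[str, float], bool]:
    """Return (stoich, reversible) from an equation string."""
    arrow = None
    for a in _ARROWS:
        if a in eq:
            arrow = a
            break
    if arrow is None:
        raise ModelIOError(
            f"reaction {rxn_id!r}: equation {eq!r} lacks an arrow (--> or <=>)"
        )
    lhs_text, rhs_text = eq.split(arrow, 1)

    def parse_side(side: str, sign: float, stoich: Dict[str, float]) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ModelIOError(f"reaction {rxn_id!r}: empty term in {eq!r}")
            parts = term.split()
            if len(parts) == 1:
                coeff, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coeff = float(parts[0])
                except ValueError as exc:
                    raise ModelIOError(
                        f"reaction {rxn_id!r}: bad coefficient {parts[0]!r}"
                    ) from exc
                met = parts[1]
            else:
                raise ModelIOError(f"reaction {rxn_id!r}: bad term {term!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    stoich: Dict[str, float] = {}
    parse_side(lhs_text, -1.0, stoich)
    parse_side(rhs_text, +1.0, stoich)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    return stoich, arrow == "<=>"


def _format_equation(rxn: Reaction) -> str:
    def fmt(coeff: float, met: str) -> str:
        return met if coeff == 1.0 else f"{coeff:g} {met}"

    lhs = " + ".join(fmt(-c, m) for m, c in rxn.stoich.items() if c < 0)
    rhs = " + ".join(fmt(c, m) for m, c in rxn.stoich.items() if c > 0)
    arrow = "<=>" if rxn.reversible else "-->"
    return f"{lhs} {arrow} {rhs}".strip()


_RXN_COLUMNS = ["id", "name", "equation", "lb", "ub", "gpr", "subsystem", "kind"]
_MET_COLUMNS = ["id", "name", "compartment"]


def _read_tsv_table(path: Path, required: Sequence[str]) -> List[Dict[str, str]]:
    if not path.exists():
        raise ModelIOError(f"missing file {path}")
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ModelIOError(f"empty table {path}")
    header = lines[0].split("\t")
    missing = [c for c in required if c not in header]
    if missing:
        raise ModelIOError(f"{path}: missing columns {missing}")
    rows = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        cells += [""] * (len(header) - len(cells))
        rows.append(dict(zip(header, cells)))
    return rows


def _read_tsv_model(path: Path) -> MetabolicModel:
    met_rows = _read_tsv_table(path / "metabolites.tsv", _MET_COLUMNS)
    rxn_rows = _read_tsv_table(path / "reactions.tsv", _RXN_COLUMNS[:3])

    metabolites = [
        Metabolite(id=r["id"], name=r.get("name", ""), compartment=r.get("compartment", "c"))
        for r in met_rows
    ]
    compartments = {m.compartment: m.compartment for m in metabolites}

    seen: set = set()
    biomass_id: Optional[str] = None
    reactions: List[Reaction] = []
    deferred_kind: List[Reaction] = []
    for row in rxn_rows:
        rid = row["id"]
        if rid in seen:
            raise ModelIOError(f"duplicate reaction id {rid!r}")
        seen.add(rid)
        stoich, reversible = _parse_equation(row["equation"], rid)
        lb_text, ub_text = row.get("lb", ""), row.get("ub", "")
        lb = float(lb_text) if lb_text else (DEFAULT_LOWER_BOUND if reversible else 0.0)
        ub = float(ub_text) if ub_text else DEFAULT_UPPER_BOUND
        gpr_text = row.get("gpr", "").strip()
        gpr = parse_gpr(gpr_text) if gpr_text else None
        subsystem = row.get("subsystem", "").strip() or None
        rxn = Reaction(
            id=rid,
            name=row.get("name", ""),
            stoich=stoich,
            lb=lb,
            ub=ub,
            gpr=gpr,
            subsystem=subsystem,
        )
        kind_text = row.get("kind", "").strip().lower()
        if kind_text:
            try:
                rxn.kind = ReactionKind(kind_text)
            except ValueError as exc:
                raise ModelIOError(f"reaction {rid!r}: unknown kind {kind_text!r}") from exc
            if rxn.kind == ReactionKind.BIOMASS:
                biomass_id = rid
        else:
            deferred_kind.append(rxn)
        reactions.append(rxn)

    for rxn in deferred_kind:
        rxn.kind = infer_kind(rxn, biomass_id)

    model = MetabolicModel(
        id=path.name or "model",
        metabolites=metabolites,
        reactions=reactions,
        compartments=compartments,
        biomass_id=biomass_id,
    )
    model.validate()
    return model


def _write_tsv_model(model: MetabolicModel, path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "metabolites.tsv", "w", encoding="utf-8") as fh:
        fh.write("\t".join(_MET_COLUMNS) + "\n")
        for met in model.metabolites:
            fh.write(f"{met.id}\t{met.name}\t{met.compartment}\n")
    with open(path / "reactions.tsv", "w", encoding="utf-8") as fh:
        fh.write("\t".join(_RXN_COLUMNS) + "\n")
        for rxn in model.reactions:
            gpr = rxn.gpr.serialize() if rxn.gpr is not None else ""
            fh.write(
                "\t".join(
                    [
                        rxn.id,
                        rxn.name,
                        _format_equation(rxn),
                        f"{rxn.lb:g}",
                        f"{rxn.ub:g}",
                        gpr,
                        rxn.subsystem or "",
                        rxn.kind.value,
                    ]
                )
                + "\n"
            )
    return path


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC v2
# ---------------------------------------------------------------------------

# SBO terms used to round-trip the reaction kind through SBML.
_SBO_BY_KIND = {
    ReactionKind.ENZYMATIC: "SBO:0000176",
    ReactionKind.SPONTANEOUS: "SBO:0000672",
    ReactionKind.TRANSPORT: "SBO:0000185",
    ReactionKind.EXCHANGE: "SBO:0000627",
    ReactionKind.BIOMASS: "SBO:0000629",
}
_KIND_BY_SBO = {v: k for k, v in _SBO_BY_KIND.items()}

_SBML_SAFE = re.compile(r"[^A-Za-z0-9_]")


def _sbml_id(raw: str) -> str:
    """SBML SId-safe encoding; the original id is kept in the name field."""
    sid = _SBML_SAFE.sub("__", raw)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "_" + sid
    return sid


def _gpr_to_association(gpr: GprExpr, plugin, libsbml):
    """Build an fbc Association subtree on ``plugin`` (a GeneProductAssociation
    or a FbcAnd/FbcOr node)."""
    if gpr.kind == "gene":
        ref = plugin.createGeneProductRef()
        ref.setGeneProduct(_sbml_id("G_" + gpr.gene))
        return
    node = plugin.createAnd() if gpr.kind == "and" else plugin.createOr()
    for child in gpr.children:
        _gpr_to_association(child, node, libsbml)


def _association_to_gpr(assoc, libsbml) -> GprExpr:
    type_code = assoc.getTypeCode()
    if type_code == libsbml.SBML_FBC_GENEPRODUCTREF:
        gid = assoc.getGeneProduct()
        model = assoc.getSBMLDocument().getModel()
        gp = model.getPlugin("fbc").getGeneProduct(gid)
        label = gp.getLabel() if gp is not None and gp.isSetLabel() else gid
        return GprExpr.gene_(label)
    children = tuple(
        _association_to_gpr(assoc.getAssociation(i), libsbml)
        for i in range(assoc.getNumAssociations())
    )
    if len(children) == 1:
        return children[0]
    if type_code == libsbml.SBML_FBC_AND:
        return GprExpr("and", children=children)
    return GprExpr("or", children=children)


def _write_sbml_model(model: MetabolicModel, path: Path) -> Path:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sbml_id(model.id))
    sm.setName(model.id)
    fbc = sm.getPlugin("fbc")
    fbc.setStrict(False)

    for code, name in model.compartments.items():
        comp = sm.createCompartment()
        comp.setId(_sbml_id(code))
        comp.setName(name or code)
        comp.setConstant(True)

    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(_sbml_id("M_" + met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(_sbml_id(met.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        # original id, bit-exact, as metaid-free annotation via notes
        sp.appendNotes(
            f'<body xmlns="http://www.w3.org/1999/xhtml"><p>orig_id: {met.id}</p></body>'
        )

    for gene in sorted(model.genes):
        gp = fbc.createGeneProduct()
        gp.setId(_sbml_id("G_" + gene))
        gp.setLabel(gene)

    bound_params: Dict[float, str] = {}

    def bound_id(value: float) -> str:
        if value not in bound_params:
            pid = f"FB_{len(bound_params)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        sr = sm.createReaction()
        sr.setId(_sbml_id("R_" + rxn.id))
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(rxn.reversible)
        sr.setFast(False)
        sr.setSBOTerm(_SBO_BY_KIND[rxn.kind])
        notes = [f"<p>orig_id: {rxn.id}</p>"]
        if rxn.subsystem:
            notes.append(f"<p>subsystem: {rxn.subsystem}</p>")
        sr.appendNotes(
            '<body xmlns="http://www.w3.org/1999/xhtml">' + "".join(notes) + "</body>"
        )
        for met_id, coeff in rxn.stoich.items():
            if coeff < 0:
                ref = sr.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = sr.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies(_sbml_id("M_" + met_id))
            ref.setConstant(True)
        rfbc = sr.getPlugin("fbc")
        rfbc.setLowerFluxBound(bound_id(rxn.lb))
        rfbc.setUpperFluxBound(bound_id(rxn.ub))
        if rxn.gpr is not None:
            gpa = rfbc.createGeneProductAssociation()
            _gpr_to_association(rxn.gpr, gpa, libsbml)

    if model.biomass_id is not None:
        obj = fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_sbml_id("R_" + model.biomass_id))
        fo.setCoefficient(1.0)
        fbc.setActiveObjectiveId("obj")

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise ModelIOError(f"could not write SBML to {path}")
    return path


_NOTES_FIELD = re.compile(r"<p>\s*([a-z_]+):\s*(.*?)\s*</p>", re.S)


def _parse_notes(sbase) -> Dict[str, str]:
    if not sbase.isSetNotes():
        return {}
    text = sbase.getNotesString()
    return {m.group(1): m.group(2) for m in _NOTES_FIELD.finditer(text)}


def _read_sbml_model(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelIOError(f"SBML parse error in {path}: {err.getMessage()}")
    sm = doc.getModel()
    if sm is None:
        raise ModelIOError(f"{path} contains no SBML model")
    fbc = sm.getPlugin("fbc")

    compartments = {}
    for i in range(sm.getNumCompartments()):
        comp = sm.getCompartment(i)
        compartments[comp.getId()] = comp.getName() or comp.getId()

    sid_to_met: Dict[str, str] = {}
    metabolites: List[Metabolite] = []
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        notes = _parse_notes(sp)
        raw = notes.get("orig_id")
        if raw is None:
            raw = sp.getId()
            if raw.startswith("M_"):
                raw = raw[2:]
        sid_to_met[sp.getId()] = raw
        metabolites.append(
            Metabolite(id=raw, name=sp.getName() or raw, compartment=sp.getCompartment())
        )

    biomass_sid: Optional[str] = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getActiveObjective() or fbc.getObjective(0)
        if active is not None and active.getNumFluxObjectives() > 0:
            biomass_sid = active.getFluxObjective(0).getReaction()

    reactions: List[Reaction] = []
    biomass_id: Optional[str] = None
    deferred: List[Reaction] = []
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        notes = _parse_notes(sr)
        raw = notes.get("orig_id")
        if raw is None:
            raw = sr.getId()
            if raw.startswith("R_"):
                raw = raw[2:]
        stoich: Dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            met = sid_to_met.get(ref.getSpecies())
            if met is None:
                raise ModelIOError(
                    f"reaction {raw!r} references unknown species {ref.getSpecies()!r}"
                )
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            met = sid_to_met.get(ref.getSpecies())
            if met is None:
                raise ModelIOError(
                    f"reaction {raw!r} references unknown species {ref.getSpecies()!r}"
                )
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()

        rfbc = sr.getPlugin("fbc")
        lb = DEFAULT_LOWER_BOUND if sr.getReversible() else 0.0
        ub = DEFAULT_UPPER_BOUND
        if rfbc is not None:
            if rfbc.isSetLowerFluxBound():
                par = sm.getParameter(rfbc.getLowerFluxBound())
                if par is not None:
                    lb = par.getValue()
            if rfbc.isSetUpperFluxBound():
                par = sm.getParameter(rfbc.getUpperFluxBound())
                if par is not None:
                    ub = par.getValue()
        gpr: Optional[GprExpr] = None
        if rfbc is not None and rfbc.isSetGeneProductAssociation():
            assoc = rfbc.getGeneProductAssociation().getAssociation()
            if assoc is not None:
                gpr = _association_to_gpr(assoc, libsbml)

        rxn = Reaction(
            id=raw,
            name=sr.getName() or raw,
            stoich=stoich,
            lb=lb,
            ub=ub,
            gpr=gpr,
            subsystem=notes.get("subsystem"),
        )
        sbo = sr.getSBOTermID() if sr.isSetSBOTerm() else ""
        if sr.getId() == biomass_sid:
            rxn.kind = ReactionKind.BIOMASS
            biomass_id = raw
        elif sbo in _KIND_BY_SBO:
            rxn.kind = _KIND_BY_SBO[sbo]
        else:
            deferred.append(rxn)
        reactions.append(rxn)

    for rxn in deferred:
        rxn.kind = infer_kind(rxn, biomass_id)

    model = MetabolicModel(
        id=sm.getName() or sm.getId() or path.stem,
        metabolites=metabolites,
        reactions=reactions,
        compartments=compartments,
        biomass_id=biomass_id,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Public read/write
# ---------------------------------------------------------------------------


def read_model(path: os.PathLike, dialect: str = "auto") -> MetabolicModel:
    """Read a model from ``path``.

    ``dialect`` is ``"sbml_fbc"`` (a single ``.xml`` file), ``"tsv"`` (a
    directory holding ``reactions.tsv`` and ``metabolites.tsv``) or
    ``"auto"`` to infer from the path.  The returned model has been
    validated against all structural invariants.
    """
    p = Path(path)
    if dialect == "auto":
        dialect = "tsv" if p.is_dir() else "sbml_fbc"
    if dialect == "sbml_fbc":
        if not p.exists():
            raise ModelIOError(f"no such file: {p}")
        return _read_sbml_model(p)
    if dialect == "tsv":
        return _read_tsv_model(p)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_model(model: MetabolicModel, path: os.PathLike, dialect: str = "auto") -> Path:
    """Write ``model`` so that :func:`read_model` reproduces it (ids,
    stoichiometry, bounds, GPR logic and kinds) up to field ordering."""
    model.validate()
    p = Path(path)
    if dialect == "auto":
        dialect = "sbml_fbc" if p.suffix.lower() == ".xml" else "tsv"
    if dialect == "sbml_fbc":
        return _write_sbml_model(model, p)
    if dialect == "tsv":
        return _write_tsv_model(model, p)
    raise ValueError(f"unknown dialect {dialect!r}")
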