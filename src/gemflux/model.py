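"""Genome-scale metabolic model data structures and I/O.

The model is the standard constraint-based representation: a set of
metabolites (rows of the stoichiometric matrix S), reactions (columns of
S, each with flux bounds and an optional GPR rule), a linear objective
over reactions, compartment annotations, and pathway ("subsystem")
labels.  Two on-disk dialects are supported: BiGG-style JSON and SBML
Level 3 with the FBC v2 package (bounds as parameters, GPRs as
fbc:geneProductAssociation) — the profile BiGG exports use.
"""
from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np
from scipy import sparse

from .gpr import GprExpression, parse_gpr

DEFAULT_BOUND = 1000.0


class ModelFormatError(ValueError):
    """A file could not be parsed in the requested dialect."""


class ModelValidationError(ValueError):
    """A model violates structural invariants (e.g. unresolved metabolite)."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: Optional[str] = None


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr_text: Optional[str] = None
    subsystem: Optional[str] = None
    name: str = ""
    _gpr_cache: Optional[GprExpression] = field(default=None, repr=False, compare=False)

    @property
    def is_exchange(self) -> bool:
        """Boundary reactions are identified structurally (single metabolite);
        an ``EX_``/``DM_``/``SK_`` prefix is accepted as fallback."""
        if len(self.stoichiometry) == 1:
            return True
        return self.id.startswith(("EX_", "DM_", "SK_"))

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def gpr(self) -> Optional[GprExpression]:
        """GPR rule parsed lazily from ``gpr_text`` (cached)."""
        if self.gpr_text is None or not self.gpr_text.strip():
            return None
        if self._gpr_cache is None:
            self._gpr_cache = parse_gpr(self.gpr_text)
        return self._gpr_cache

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gpr_text=self.gpr_text,
            subsystem=self.subsystem,
            name=self.name,
        )


@dataclass
class FluxDistribution:
    """A single steady-state flux vector with its objective value."""

    fluxes: Dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


@dataclass
class MetabolicModel:
    id: str = "model"
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    objective: Dict[str, float] = field(default_factory=dict)
    compartments: Dict[str, str] = field(default_factory=dict)

    # ---- indexing helpers -------------------------------------------------
    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def metabolite_index(self) -> Dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> Dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def subsystem_index(self) -> Dict[str, List[str]]:
        idx: Dict[str, List[str]] = {}
        for r in self.reactions:
            idx.setdefault(r.subsystem or "other", []).append(r.id)
        return idx

    @property
    def genes(self) -> List[str]:
        seen = set()
        for r in self.reactions:
            if r.gpr is not None:
                seen |= r.gpr.genes()
        return sorted(seen)

    def bounds_arrays(self):
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[Metabolite(m.id, m.name, m.compartment, m.formula) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            objective=dict(self.objective),
            compartments=dict(self.compartments),
        )

    def subnetwork(self, reaction_ids: Iterable[str], model_id: Optional[str] = None) -> "MetabolicModel":
        """Restrict to the given reactions, dropping orphaned metabolites."""
        keep = set(reaction_ids)
        reactions = [r.copy() for r in self.reactions if r.id in keep]
        used = set()
        for r in reactions:
            used |= set(r.stoichiometry)
        metabolites = [
            Metabolite(m.id, m.name, m.compartment, m.formula)
            for m in self.metabolites
            if m.id in used
        ]
        objective = {k: v for k, v in self.objective.items() if k in keep}
        return MetabolicModel(
            id=model_id or f"{self.id}_sub",
            metabolites=metabolites,
            reactions=reactions,
            objective=objective,
            compartments=dict(self.compartments),
        )

    def validate(self) -> None:
        """Raise :class:`ModelValidationError` on broken referential integrity."""
        met_ids = set(self.metabolite_ids)
        if len(met_ids) != len(self.metabolites):
            raise ModelValidationError("duplicate metabolite ids")
        rxn_ids = set(self.reaction_ids)
        if len(rxn_ids) != len(self.reactions):
            raise ModelValidationError("duplicate reaction ids")
        missing = sorted(
            {m for r in self.reactions for m in r.stoichiometry if m not in met_ids}
        )
        if missing:
            raise ModelValidationError(
                f"reactions reference undeclared metabolites: {', '.join(missing)}"
            )
        bad_obj = sorted(k for k in self.objective if k not in rxn_ids)
        if bad_obj:
            raise ModelValidationError(
                f"objective references unknown reactions: {', '.join(bad_obj)}"
            )


# ---- stoichiometric matrix ------------------------------------------------

def stoichiometric_matrix(model: MetabolicModel) -> sparse.csc_matrix:
    """S with S[i, j] = coefficient of metabolite i in reaction j.

    Row order follows ``model.metabolites``, column order ``model.reactions``.
    """
    midx = model.metabolite_index()
    rows, cols, data = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.stoichiometry.items():
            rows.append(midx[met])
            cols.append(j)
            data.append(float(coef))
    return sparse.csc_matrix(
        (data, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )


# ---- structural validation report -----------------------------------------

@dataclass
class Finding:
    level: str  # "error" | "warning"
    code: str
    message: str


def validate_model(model: MetabolicModel) -> List[Finding]:
    """Report structural issues without raising.

    Checks: dangling metabolites (in no reaction), dead-end metabolites
    (only produced or only consumed by non-boundary reactions), bound
    violations (lb > ub), and a missing objective.
    """
    findings: List[Finding] = []
    produced, consumed, used = set(), set(), set()
    for r in model.reactions:
        if r.lower_bound > r.upper_bound:
            findings.append(Finding("error", "bounds", f"bounds: {r.id} (lb > ub)"))
        for met, coef in r.stoichiometry.items():
            used.add(met)
            if coef == 0 or not math.isfinite(coef):
                findings.append(
                    Finding("error", "stoichiometry", f"coefficient of {met} in {r.id}")
                )
            boundary = r.is_exchange or r.reversible
            if coef > 0 or boundary:
                produced.add(met)
            if coef < 0 or boundary:
                consumed.add(met)
    for m in model.metabolites:
        if m.id not in used:
            findings.append(Finding("warning", "dangling", f"dangling: {m.id}"))
        elif m.id not in produced or m.id not in consumed:
            findings.append(Finding("warning", "dead_end", f"dead-end: {m.id}"))
    if not model.objective:
        findings.append(Finding("warning", "objective", "missing objective"))
    declared = set(model.compartments)
    if declared:
        for m in model.metabolites:
            if m.compartment and m.compartment not in declared:
                findings.append(
                    Finding("error", "compartment", f"undeclared compartment: {m.compartment} ({m.id})")
                )
    return findings


# ---- BiGG-style JSON dialect ----------------------------------------------

def _model_to_json_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "version": "1",
        "compartments": dict(model.compartments),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula else {}),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": {k: v for k, v in sorted(r.stoichiometry.items())},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr_text or "",
                "subsystem": r.subsystem or "",
                "objective_coefficient": model.objective.get(r.id, 0.0),
            }
            for r in model.reactions
        ],
        "genes": [{"id": g, "name": g} for g in model.genes],
    }


def _model_from_json_dict(doc: dict) -> MetabolicModel:
    try:
        metabolites = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", ""),
                formula=m.get("formula") or None,
            )
            for m in doc["metabolites"]
        ]
        reactions = []
        objective = {}
        for r in doc["reactions"]:
            lb = float(r.get("lower_bound", 0.0))
            ub = float(r.get("upper_bound", DEFAULT_BOUND))
            reactions.append(
                Reaction(
                    id=r["id"],
                    stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                    lower_bound=lb,
                    upper_bound=ub,
                    gpr_text=r.get("gene_reaction_rule") or None,
                    subsystem=r.get("subsystem") or None,
                    name=r.get("name", ""),
                )
            )
            coef = float(r.get("objective_coefficient", 0.0))
            if coef:
                objective[r["id"]] = coef
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"malformed JSON model: missing field {exc}") from exc
    model = MetabolicModel(
        id=doc.get("id", "model"),
        metabolites=metabolites,
        reactions=reactions,
        objective=objective,
        compartments=dict(doc.get("compartments", {})),
    )
    model.validate()
    return model


# ---- SBML L3 / FBC v2 dialect ---------------------------------------------

_SID_BAD = re.compile(r"[^A-Za-z0-9_]")


def _sid(prefix: str, raw: str) -> str:
    s = _SID_BAD.sub("__", raw)
    if not s or not (s[0].isalpha() or s[0] == "_"):
        s = "_" + s
    return prefix + s


def _unsid(prefix: str, sid: str) -> str:
    s = sid[len(prefix):] if sid.startswith(prefix) else sid
    return s.replace("__", "__")  # ids round-trip through the __ escape


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sid("", model.id) or "model")
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for code, name in (model.compartments or {"c": "default"}).items():
        comp = sbml_model.createCompartment()
        comp.setId(_sid("", code))
        comp.setName(name)
        comp.setConstant(True)

    for m in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(_sid("M_", m.id))
        sp.setName(m.name or m.id)
        sp.setCompartment(_sid("", m.compartment or next(iter(model.compartments or {"c": 0}))))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        if m.formula:
            sp.getPlugin("fbc").setChemicalFormula(m.formula)

    for g in model.genes:
        gp = mplug.createGeneProduct()
        gp.setId(_sid("G_", g))
        gp.setLabel(g)

    # bounds as shared parameters, one per distinct value (BiGG convention)
    bound_params: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    def build_assoc(node, parent):
        from .gpr import And, Gene, Or

        if isinstance(node, Gene):
            ref = parent.createGeneProductRef()
            ref.setGeneProduct(_sid("G_", node.id))
        elif isinstance(node, And):
            op = parent.createAnd()
            for c in node.children:
                build_assoc(c, op)
        elif isinstance(node, Or):
            op = parent.createOr()
            for c in node.children:
                build_assoc(c, op)

    for r in model.reactions:
        rxn = sbml_model.createReaction()
        rxn.setId(_sid("R_", r.id))
        rxn.setName(r.name or r.id)
        rxn.setFast(False)
        rxn.setReversible(r.lower_bound < 0)
        for met, coef in sorted(r.stoichiometry.items()):
            if coef < 0:
                ref = rxn.createReactant()
                ref.setStoichiometry(-coef)
            else:
                ref = rxn.createProduct()
                ref.setStoichiometry(coef)
            ref.setSpecies(_sid("M_", met))
            ref.setConstant(True)
        rplug = rxn.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(float(r.lower_bound)))
        rplug.setUpperFluxBound(bound_param(float(r.upper_bound)))
        if r.gpr is not None:
            gpa = rplug.createGeneProductAssociation()
            build_assoc(r.gpr.root, gpa)
        if r.subsystem:
            rxn.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml"><p>SUBSYSTEM: {r.subsystem}</p></body>'
            )

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    mplug.setActiveObjectiveId("obj")
    for rid, coef in model.objective.items():
        fo = obj.createFluxObjective()
        fo.setReaction(_sid("R_", rid))
        fo.setCoefficient(float(coef))

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"failed to write SBML to {path}")


def _assoc_to_text(assoc) -> str:
    import libsbml

    if isinstance(assoc, libsbml.GeneProductRef):
        return _unsid("G_", assoc.getGeneProduct())
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [_assoc_to_text(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [_assoc_to_text(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
        return "(" + " or ".join(parts) + ")"
    raise ModelFormatError(f"unsupported GPR association node: {assoc}")


_SUBSYS_RE = re.compile(r"SUBSYSTEM:\s*([^<]+)")


def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(f"SBML parse failure: {err.getMessage() if err else 'unknown'}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError("SBML file contains no model")
    mplug = sbml_model.getPlugin("fbc")
    if mplug is None:
        raise ModelFormatError(
            "only SBML Level 3 with the FBC v2 package is supported; "
            "this file lacks the fbc package"
        )

    compartments = {
        _unsid("", c.getId()): c.getName() or c.getId()
        for c in (sbml_model.getCompartment(i) for i in range(sbml_model.getNumCompartments()))
    }
    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = splug.getChemicalFormula() if splug and splug.isSetChemicalFormula() else None
        metabolites.append(
            Metabolite(
                id=_unsid("M_", sp.getId()),
                name=sp.getName(),
                compartment=_unsid("", sp.getCompartment()),
                formula=formula or None,
            )
        )

    def param_value(pid: str, default: float) -> float:
        p = sbml_model.getParameter(pid)
        return p.getValue() if p is not None else default

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            stoich[_unsid("M_", ref.getSpecies())] = stoich.get(_unsid("M_", ref.getSpecies()), 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            stoich[_unsid("M_", ref.getSpecies())] = stoich.get(_unsid("M_", ref.getSpecies()), 0.0) + ref.getStoichiometry()
        rplug = rxn.getPlugin("fbc")
        if rplug is None or not rplug.isSetLowerFluxBound():
            lb = -DEFAULT_BOUND if rxn.getReversible() else 0.0
            ub = DEFAULT_BOUND
        else:
            lb = param_value(rplug.getLowerFluxBound(), -DEFAULT_BOUND)
            ub = param_value(rplug.getUpperFluxBound(), DEFAULT_BOUND)
        gpr_text = None
        if rplug is not None and rplug.isSetGeneProductAssociation():
            assoc = rplug.getGeneProductAssociation().getAssociation()
            if assoc is not None:
                gpr_text = _assoc_to_text(assoc)
                if gpr_text.startswith("(") and gpr_text.endswith(")"):
                    gpr_text = gpr_text[1:-1]
        subsystem = None
        if rxn.isSetNotes():
            m = _SUBSYS_RE.search(rxn.getNotesString())
            if m:
                subsystem = m.group(1).strip()
        reactions.append(
            Reaction(
                id=_unsid("R_", rxn.getId()),
                stoichiometry={k: v for k, v in stoich.items() if v != 0},
                lower_bound=lb,
                upper_bound=ub,
                gpr_text=gpr_text,
                subsystem=subsystem,
                name=rxn.getName(),
            )
        )

    objective: Dict[str, float] = {}
    obj = mplug.getActiveObjective()
    if obj is not None:
        for i in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(i)
            objective[_unsid("R_", fo.getReaction())] = fo.getCoefficient()

    model = MetabolicModel(
        id=_unsid("", sbml_model.getId()) or "model",
        metabolites=metabolites,
        reactions=reactions,
        objective=objective,
        compartments=compartments,
    )
    model.validate()
    return model


# ---- public I/O -----------------------------------------------------------

def read_model(path, format: Optional[str] = None) -> MetabolicModel:
    """Read a metabolic model from BiGG-style JSON or SBML L3/FBC-v2.

    ``format`` is inferred from the file suffix when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("sbml" if path.suffix.lower() in (".xml", ".sbml") else "json")
    if fmt == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"invalid JSON in {path}: {exc}") from exc
        return _model_from_json_dict(doc)
    if fmt == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path, format: Optional[str] = None) -> None:
    """Write a model in the JSON or SBML dialect (inferred from suffix)."""
    path = Path(path)
    fmt = format or ("sbml" if path.suffix.lower() in (".xml", ".sbml") else "json")
    if fmt == "json":
        path.write_text(json.dumps(_model_to_json_dict(model), indent=1, sort_keys=False))
    elif fmt == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def export_reaction_table(model: MetabolicModel, path, sep: str = "\t") -> None:
    """Write a delimited reaction/subsystem table (id, subsystem, lb, ub, gpr)."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "reaction_id": model.reaction_ids,
            "subsystem": [r.subsystem or "other" for r in model.reactions],
            "lower_bound": [r.lower_bound for r in model.reactions],
            "upper_bound": [r.upper_bound for r in model.reactions],
            "gpr": [r.gpr_text or "" for r in model.reactions],
        }
    )
    df.to_csv(path, sep=sep, index=False)
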