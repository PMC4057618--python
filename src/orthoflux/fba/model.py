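"""Genome-scale metabolic model container and I/O.

Two on-disk dialects are supported:

- ``sbml_fbc`` — SBML Level 3 Version 1 with the Flux Balance Constraints
  (fbc v2) package: species, reactions with stoichiometry, flux-bound
  parameters, gene products with gene-product associations, and an active
  maximization objective.
- ``native_json`` — a compact JSON schema used for fixtures::

    {
      "id": "toy",
      "compartments": {"c": "cytosol"},
      "metabolites": [{"id": "A_c", "name": "A", "compartment": "c"}],
      "reactions": [{"id": "R1", "name": "", "stoichiometry": {"A_c": -1.0},
                     "lower_bound": 0.0, "upper_bound": 10.0, "gpr": "g1"}],
      "genes": ["g1"],
      "biomass_reaction_id": "biomass"
    }

Stoichiometric coefficients are signed (negative = consumed). Loading,
saving and re-loading is idempotent on ids, stoichiometry, bounds and GPRs
in either dialect.
"""

from __future__ import annotations

import copy
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import libsbml

from ..records import InvalidInputError
from .gpr import gpr_genes, parse_gpr

PathLike = Union[str, Path]

DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """The model violates a structural invariant; lists all offenders."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"{self.id}: lower_bound {self.lower_bound} > upper_bound "
                f"{self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelValidationError(f"{self.id}: empty stoichiometry")
        parse_gpr(self.gpr)  # raises GPRSyntaxError if malformed


@dataclass
class MetabolicModel:
    id: str
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    genes: set[str]
    biomass_reaction_id: str
    compartments: dict[str, str] = field(default_factory=dict)
    objective: dict[str, float] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.objective:
            self.objective = {self.biomass_reaction_id: 1.0}

    def validate(self) -> None:
        problems = []
        for rxn in self.reactions.values():
            unknown_mets = sorted(
                set(rxn.stoichiometry) - set(self.metabolites)
            )
            if unknown_mets:
                problems.append(
                    f"reaction {rxn.id}: undeclared metabolites {unknown_mets}"
                )
            unknown_genes = sorted(gpr_genes(rxn.gpr) - self.genes)
            if unknown_genes:
                problems.append(
                    f"reaction {rxn.id}: undeclared genes {unknown_genes}"
                )
        declared = set(self.compartments) if self.compartments else None
        if declared is not None:
            for met in self.metabolites.values():
                if met.compartment not in declared:
                    problems.append(
                        f"metabolite {met.id}: unknown compartment "
                        f"{met.compartment!r}"
                    )
        if self.biomass_reaction_id not in self.reactions:
            problems.append(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )
        for rid in self.objective:
            if rid not in self.reactions:
                problems.append(f"objective reaction {rid!r} not in model")
        if problems:
            raise ModelValidationError("; ".join(problems))

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)


@dataclass
class BiomassAugmentation:
    """Extra per-growth metabolite requirements added to the biomass.

    ``coefficient`` mode decrements the metabolite's biomass coefficient by
    the requirement (adding it as a reactant); ``demand`` mode adds a sink
    reaction with the requirement as its lower flux bound.
    """

    requirements: dict[str, float]
    mode: str = "coefficient"  # or "demand"

    def __post_init__(self) -> None:
        if self.mode not in ("coefficient", "demand"):
            raise InvalidInputError(f"unknown augmentation mode {self.mode!r}")
        bad = {m: v for m, v in self.requirements.items() if not v > 0}
        if bad:
            raise InvalidInputError(
                f"non-positive augmentation requirements: {bad}"
            )


# ---------------------------------------------------------------- JSON I/O


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "compartments": dict(sorted(model.compartments.items())),
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr,
            }
            for r in model.reactions.values()
        ],
        "genes": sorted(model.genes),
        "biomass_reaction_id": model.biomass_reaction_id,
        "objective": dict(sorted(model.objective.items())),
        "provenance": list(model.provenance),
    }


def _model_from_dict(data: dict) -> MetabolicModel:
    model = MetabolicModel(
        id=data["id"],
        compartments=dict(data.get("compartments", {})),
        metabolites={
            m["id"]: Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
            )
            for m in data["metabolites"]
        },
        reactions={
            r["id"]: Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                gpr=r.get("gpr", ""),
            )
            for r in data["reactions"]
        },
        genes=set(data.get("genes", [])),
        biomass_reaction_id=data["biomass_reaction_id"],
        objective={
            k: float(v) for k, v in data.get("objective", {}).items()
        },
        provenance=list(data.get("provenance", [])),
    )
    return model


# ---------------------------------------------------------------- SBML I/O

_SID_SAFE = re.compile(r"[^A-Za-z0-9_]")


def _sid(prefix: str, raw: str) -> str:
    safe = _SID_SAFE.sub("_", raw)
    if not safe or not (safe[0].isalpha() or safe[0] == "_"):
        safe = "_" + safe
    return prefix + safe


def _check(value: int, message: str) -> None:
    if value not in (libsbml.LIBSBML_OPERATION_SUCCESS, None):
        if isinstance(value, int) and value < 0:
            raise RuntimeError(f"libsbml error {value}: {message}")


def _write_sbml(model: MetabolicModel, path: PathLike) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_SID_SAFE.sub("_", model.id) or "model")
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = model.compartments or {
        met.compartment: met.compartment for met in model.metabolites.values()
    }
    for cid, cname in sorted(compartments.items()):
        comp = sbml_model.createCompartment()
        comp.setId(_sid("", cid))
        comp.setName(cname)
        comp.setConstant(True)
        comp.setSize(1.0)

    met_sid = {}
    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sid = _sid("M_", met.id)
        met_sid[met.id] = sid
        sp.setId(sid)
        sp.setName(met.name or met.id)
        sp.setCompartment(_sid("", met.compartment))
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)

    gene_sid = {}
    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        sid = _sid("G_", gene)
        gene_sid[gene] = sid
        gp.setId(sid)
        gp.setLabel(gene)

    bound_params = {}

    def bound_param(value: float) -> str:
        key = repr(value)
        if key not in bound_params:
            pid = f"fb_{len(bound_params)}"
            param = sbml_model.createParameter()
            param.setId(pid)
            param.setValue(value)
            param.setConstant(True)
            bound_params[key] = pid
        return bound_params[key]

    rxn_sid = {}
    for rxn in model.reactions.values():
        sr = sbml_model.createReaction()
        sid = _sid("R_", rxn.id)
        rxn_sid[rxn.id] = sid
        sr.setId(sid)
        sr.setName(rxn.name or rxn.id)
        sr.setFast(False)
        sr.setReversible(rxn.lower_bound < 0)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        for met_id, coef in sorted(rxn.stoichiometry.items()):
            if coef < 0:
                ref = sr.createReactant()
                ref.setStoichiometry(-coef)
            else:
                ref = sr.createProduct()
                ref.setStoichiometry(coef)
            ref.setSpecies(met_sid[met_id])
            ref.setConstant(True)
        if rxn.gpr.strip():
            infix = rxn.gpr
            for gene in sorted(gpr_genes(rxn.gpr), key=len, reverse=True):
                infix = re.sub(
                    rf"(?<![\w]){re.escape(gene)}(?![\w])",
                    gene_sid[gene],
                    infix,
                )
            gpa = rplug.createGeneProductAssociation()
            # match gene products by id; never auto-create missing ones
            _check(gpa.setAssociation(infix, True, False), f"GPR of {rxn.id}")

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    for rid, coef in sorted(model.objective.items()):
        fo = objective.createFluxObjective()
        fo.setReaction(rxn_sid[rid])
        fo.setCoefficient(coef)
    mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _read_sbml(path: PathLike) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ModelValidationError(
            f"SBML parse errors in {path}: "
            + doc.getErrorLog().toString()
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelValidationError(f"{path}: no <model> element")
    mplug = sbml_model.getPlugin("fbc")

    compartments = {
        comp.getId(): comp.getName() or comp.getId()
        for comp in sbml_model.getListOfCompartments()
    }
    metabolites = {}
    for sp in sbml_model.getListOfSpecies():
        mid = _strip_prefix(sp.getId(), "M_")
        metabolites[mid] = Metabolite(
            id=mid, name=sp.getName(), compartment=sp.getCompartment()
        )

    gene_label = {}
    genes = set()
    if mplug is not None:
        for gp in mplug.getListOfGeneProducts():
            label = gp.getLabel() or _strip_prefix(gp.getId(), "G_")
            gene_label[gp.getId()] = label
            genes.add(label)

    def param_value(pid: str) -> float:
        param = sbml_model.getParameter(pid)
        if param is None:
            raise ModelValidationError(f"flux bound parameter {pid!r} missing")
        return param.getValue()

    reactions = {}
    for sr in sbml_model.getListOfReactions():
        rid = _strip_prefix(sr.getId(), "R_")
        stoich: dict[str, float] = {}
        for ref in sr.getListOfReactants():
            mid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for ref in sr.getListOfProducts():
            mid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        gpr = ""
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = param_value(rplug.getLowerFluxBound())
            if rplug.isSetUpperFluxBound():
                ub = param_value(rplug.getUpperFluxBound())
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None and gpa.getAssociation() is not None:
                infix = gpa.getAssociation().toInfix()
                for sid, label in sorted(
                    gene_label.items(), key=lambda kv: -len(kv[0])
                ):
                    infix = re.sub(
                        rf"(?<![\w]){re.escape(sid)}(?![\w])", label, infix
                    )
                gpr = infix
        if math.isinf(lb):
            lb = -DEFAULT_BOUND if lb < 0 else DEFAULT_BOUND
        if math.isinf(ub):
            ub = -DEFAULT_BOUND if ub < 0 else DEFAULT_BOUND
        reactions[rid] = Reaction(
            id=rid,
            name=sr.getName(),
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gpr=gpr,
        )

    objective: dict[str, float] = {}
    biomass_id = None
    if mplug is not None and mplug.getActiveObjective() is not None:
        for fo in mplug.getActiveObjective().getListOfFluxObjectives():
            rid = _strip_prefix(fo.getReaction(), "R_")
            objective[rid] = fo.getCoefficient()
        if len(objective) >= 1:
            biomass_id = max(objective, key=lambda r: objective[r])
    if biomass_id is None:
        raise ModelValidationError(
            f"{path}: no active objective designates a biomass reaction; "
            "supply one explicitly via load_model(..., objective=...)"
        )
    return MetabolicModel(
        id=sbml_model.getId() or Path(str(path)).stem,
        compartments=compartments,
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        biomass_reaction_id=biomass_id,
        objective=objective,
    )


# ------------------------------------------------------------- public API


def load_model(
    path: PathLike,
    dialect: Optional[str] = None,
    objective: Optional[str] = None,
) -> MetabolicModel:
    """Load and validate a model from ``sbml_fbc`` or ``native_json``.

    ``dialect`` is inferred from the extension when omitted (.json vs
    .xml/.sbml). ``objective`` overrides / supplies the biomass reaction
    when the file does not designate one.
    """
    path = Path(path)
    if dialect is None:
        dialect = "native_json" if path.suffix == ".json" else "sbml_fbc"
    if dialect == "native_json":
        data = json.loads(path.read_text())
        if objective is not None:
            data["biomass_reaction_id"] = objective
            data.pop("objective", None)
        if "biomass_reaction_id" not in data or not data["biomass_reaction_id"]:
            raise ModelValidationError(
                f"{path}: no biomass_reaction_id; pass objective="
            )
        model = _model_from_dict(data)
    elif dialect == "sbml_fbc":
        model = _read_sbml(path)
        if objective is not None:
            model.biomass_reaction_id = objective
            model.objective = {objective: 1.0}
    else:
        raise InvalidInputError(f"unknown dialect {dialect!r}")
    model.validate()
    return model


def save_model(
    model: MetabolicModel, path: PathLike, dialect: Optional[str] = None
) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "native_json" if path.suffix == ".json" else "sbml_fbc"
    if dialect == "native_json":
        path.write_text(json.dumps(_model_to_dict(model), indent=1) + "\n")
    elif dialect == "sbml_fbc":
        _write_sbml(model, path)
    else:
        raise InvalidInputError(f"unknown dialect {dialect!r}")
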