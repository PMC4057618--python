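"""Knockout simulation and biomass augmentation.

A gene knockout propagates to reactions through the GPR rules: every
reaction whose rule evaluates inactive with the deleted genes gets its flux
bounds forced to [0, 0] — a total loss of function. Reaction-level
knockouts zero the bounds directly. The original model is never modified.

The biomass function can be augmented with small additional requirements
(default 0.0005 per metabolite) either by decrementing the metabolite's
biomass coefficient ("coefficient" mode) or by adding a per-metabolite
demand sink whose lower bound enforces the flux ("demand" mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from ..records import InvalidInputError
from .gpr import evaluate_gpr
from .model import BiomassAugmentation, MetabolicModel, Reaction
from .solve import FluxResult, SolverStatus, minimize_taxicab, solve_fba

DEFAULT_REQUIREMENT = 0.0005
GROWTH_EPSILON = 1e-6  # hr^-1; below this a knockout counts as NO_GROWTH


@dataclass
class KnockoutOutcome:
    target: str
    kind: str  # "gene" | "reaction" | "wild-type"
    biomass_variant: str
    growth_rate: float
    classification: str  # "GROWTH" | "NO_GROWTH" | "FAILED"
    wt_ratio: float
    disabled_reactions: list[str] = field(default_factory=list)
    fluxes: dict[str, float] = field(default_factory=dict)
    message: str = ""


def disabled_reactions_for_genes(
    model: MetabolicModel, deleted_genes: Iterable[str]
) -> list[str]:
    """Reactions whose GPR evaluates inactive under the deletion."""
    deleted = set(deleted_genes)
    out = []
    for rxn in model.reactions.values():
        if rxn.gpr.strip() and not evaluate_gpr(rxn.gpr, deleted):
            out.append(rxn.id)
    return out


def apply_knockout(
    model: MetabolicModel, targets: Sequence[str]
) -> MetabolicModel:
    """Return a copy of the model with the targets knocked out.

    Each target may be a gene id (propagated through GPRs) or a reaction id
    (bounds zeroed directly). Unknown targets raise listing the offenders.
    """
    unknown = [
        t for t in targets if t not in model.genes and t not in model.reactions
    ]
    if unknown:
        raise InvalidInputError(f"unknown knockout targets: {unknown}")
    genes = [t for t in targets if t in model.genes]
    reactions = [t for t in targets if t in model.reactions]
    knocked = model.copy()
    disabled = set(reactions) | set(disabled_reactions_for_genes(model, genes))
    for rid in disabled:
        knocked.reactions[rid].lower_bound = 0.0
        knocked.reactions[rid].upper_bound = 0.0
    knocked.provenance.append(
        f"knockout: genes={sorted(genes)} reactions={sorted(reactions)} "
        f"disabled={sorted(disabled)}"
    )
    return knocked


def augment_biomass(
    model: MetabolicModel, augmentation: BiomassAugmentation
) -> MetabolicModel:
    """Return a copy with extra biomass requirements installed."""
    missing = sorted(set(augmentation.requirements) - set(model.metabolites))
    if missing:
        raise InvalidInputError(
            f"augmentation metabolites not in model: {missing}"
        )
    out = model.copy()
    if augmentation.mode == "coefficient":
        biomass = out.reactions[out.biomass_reaction_id]
        for met, req in sorted(augmentation.requirements.items()):
            biomass.stoichiometry[met] = (
                biomass.stoichiometry.get(met, 0.0) - req
            )
    else:  # demand
        for met, req in sorted(augmentation.requirements.items()):
            rid = f"demand_{met}"
            if rid in out.reactions:
                raise InvalidInputError(f"demand reaction {rid} already exists")
            out.reactions[rid] = Reaction(
                id=rid,
                name=f"augmentation demand for {met}",
                stoichiometry={met: -1.0},
                lower_bound=req,
                upper_bound=1000.0,
            )
    out.provenance.append(
        f"biomass augmentation ({augmentation.mode}): "
        + ", ".join(
            f"{m}={v}" for m, v in sorted(augmentation.requirements.items())
        )
    )
    return out


def classify_growth(result: FluxResult, epsilon: float = GROWTH_EPSILON) -> str:
    if not result.optimal:
        return "NO_GROWTH"
    return "GROWTH" if result.objective_value >= epsilon else "NO_GROWTH"


def _solve_with_taxicab(model: MetabolicModel) -> tuple[FluxResult, dict]:
    result = solve_fba(model)
    fluxes: dict[str, float] = {}
    if result.optimal:
        fluxes = minimize_taxicab(model, result.objective_value)
    return result, fluxes


def simulate_knockout_panel(
    model: MetabolicModel,
    targets: Sequence[str],
    augmentations: Optional[Mapping[str, Optional[BiomassAugmentation]]] = None,
    epsilon: float = GROWTH_EPSILON,
) -> list[KnockoutOutcome]:
    """Run every target under every biomass variant; prepend WT reference rows.

    ``augmentations`` maps variant names to a :class:`BiomassAugmentation`
    or None for the unmodified biomass; by default only the original
    biomass is run. Per-row solver failures are recorded as FAILED rows
    rather than aborting the panel. Reported fluxes are taxicab-minimized.
    """
    if augmentations is None:
        augmentations = {"original": None}
    outcomes: list[KnockoutOutcome] = []
    for variant, aug in augmentations.items():
        variant_model = model if aug is None else augment_biomass(model, aug)
        wt_result, wt_fluxes = _solve_with_taxicab(variant_model)
        wt_rate = wt_result.objective_value if wt_result.optimal else 0.0
        outcomes.append(
            KnockoutOutcome(
                target="",
                kind="wild-type",
                biomass_variant=variant,
                growth_rate=wt_rate,
                classification=classify_growth(wt_result, epsilon),
                wt_ratio=1.0 if wt_rate > 0 else 0.0,
                fluxes=wt_fluxes,
            )
        )
        for target in targets:
            try:
                knocked = apply_knockout(variant_model, [target])
                kind = "gene" if target in model.genes else "reaction"
                result, fluxes = _solve_with_taxicab(knocked)
                rate = result.objective_value if result.optimal else 0.0
                outcomes.append(
                    KnockoutOutcome(
                        target=target,
                        kind=kind,
                        biomass_variant=variant,
                        growth_rate=rate,
                        classification=classify_growth(result, epsilon),
                        wt_ratio=rate / wt_rate if wt_rate > 0 else 0.0,
                        disabled_reactions=sorted(
                            rid
                            for rid, rxn in knocked.reactions.items()
                            if rxn.upper_bound == rxn.lower_bound == 0.0
                            and not (
                                model.reactions.get(rid) is not None
                                and model.reactions[rid].lower_bound == 0.0
                                and model.reactions[rid].upper_bound == 0.0
                            )
                        ),
                        fluxes=fluxes,
                    )
                )
            except Exception as exc:  # noqa: BLE001 — panel must not abort
                outcomes.append(
                    KnockoutOutcome(
                        target=target,
                        kind="gene" if target in model.genes else "reaction",
                        biomass_variant=variant,
                        growth_rate=float("nan"),
                        classification="FAILED",
                        wt_ratio=float("nan"),
                        message=str(exc),
                    )
                )
    return outcomes
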