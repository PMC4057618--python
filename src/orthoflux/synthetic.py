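"""Deterministic synthetic inputs: planted-ortholog proteomes and
hand-solvable toy metabolic models.

The proteome simulator emulates the cross-species search scenario: each
planted pair is an ancestral protein plus a diverged copy whose expected
alignment identity is set by ``target_identity``; substitutions are drawn
from BLOSUM62-conditional frequencies (so diverged pairs still align
positively) and short indels from a geometric length law. Within-species
decoy paralogs are near-identical duplicates of a human protein, producing
the many-to-one best-hit collisions the classifier must resolve. Every
pair carries one planted active site whose fate (preserve / mutate /
delete_column) is recorded in a truth table.

The toy metabolic model generator emits small networks whose wild-type
growth has a closed form, for oracle tests of the LP machinery: parallel
carbon branches with known capacities and yields, an optional
ribose-like branch that the biomass strictly requires (its sole
"isomerase" reaction is essential), and an optional cofactor branch that
only an augmented biomass consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Align import substitution_matrices

from .records import ActiveSite, InvalidInputError, ProteinRecord, Species
from .fba.model import MetabolicModel, Metabolite, Reaction

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ProteomeSimConfig:
    seed: int = 0
    n_pairs: int = 6
    n_paralogs: int = 0
    target_identity: float = 0.6
    site_fate: str = "preserve"  # preserve | mutate | delete_column
    length_range: tuple[int, int] = (80, 160)
    indel_rate: float = 0.01
    paralog_identity: float = 0.95

    def __post_init__(self) -> None:
        if self.site_fate not in ("preserve", "mutate", "delete_column"):
            raise ConfigError(f"unknown site_fate {self.site_fate!r}")
        if not 0 < self.target_identity <= 1:
            raise ConfigError("target_identity must be in (0, 1]")
        if self.target_identity < 0.35:
            raise ConfigError(
                "target_identity < 0.35 cannot guarantee the planted "
                "mutual-best-hit structure over random background"
            )


@dataclass
class SimulatedProteomes:
    human: dict[str, ProteinRecord]
    yeast: dict[str, ProteinRecord]
    #: acc -> list of (position, residue); both species included
    sites: dict[str, list[tuple[int, str]]]
    #: planted pairs: (human_acc, yeast_acc, site_fate, human_site, yeast_site)
    truth: list[tuple[str, str, str, int, int]]


def _conditional_substitution_probs() -> dict[str, tuple[str, np.ndarray]]:
    """P(b | a) over b != a, proportional to exp(BLOSUM62[a,b] / 2)."""
    matrix = substitution_matrices.load("BLOSUM62")
    table = {}
    for a in AA20:
        others = [b for b in AA20 if b != a]
        weights = np.array(
            [np.exp(float(matrix[a, b]) / 2.0) for b in others]
        )
        table[a] = ("".join(others), weights / weights.sum())
    return table

_SUBST = _conditional_substitution_probs()


def _mutate(
    rng: np.random.Generator,
    sequence: str,
    identity: float,
    indel_rate: float,
    protected: Optional[int] = None,  # 0-based position never substituted
    force_substitute: Optional[int] = None,
    delete_position: Optional[int] = None,
) -> tuple[str, dict[int, int]]:
    """Diverge a sequence; return (mutant, old 0-based -> new 0-based map)."""
    p_sub = 1.0 - identity
    out: list[str] = []
    pos_map: dict[int, int] = {}
    for i, residue in enumerate(sequence):
        # geometric-length insertion before this column
        if rng.random() < indel_rate:
            for _ in range(1 + rng.geometric(0.5) - 1):
                out.append(AA20[rng.integers(len(AA20))])
        if i == delete_position or (
            delete_position is None
            and i != protected
            and i != force_substitute
            and rng.random() < indel_rate / 2
        ):
            continue  # deletion
        new_residue = residue
        if i == force_substitute or (
            i != protected and rng.random() < p_sub
        ):
            letters, probs = _SUBST[residue]
            new_residue = letters[rng.choice(len(letters), p=probs)]
        pos_map[i] = len(out)
        out.append(new_residue)
    return "".join(out), pos_map


def simulate_proteomes(cfg: ProteomeSimConfig) -> SimulatedProteomes:
    """Generate paired human/yeast proteomes with planted structure.

    Pure function of the config: identical configs give byte-identical
    sequences. Each planted pair is mutually nearest by alignment score at
    the configured identity; decoy paralogs are closer to their
    within-species source than to any cross-species sequence.
    """
    rng = np.random.default_rng(cfg.seed)
    human: dict[str, ProteinRecord] = {}
    yeast: dict[str, ProteinRecord] = {}
    sites: dict[str, list[tuple[int, str]]] = {}
    truth: list[tuple[str, str, str, int, int]] = []

    for k in range(cfg.n_pairs):
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        ancestor = "".join(AA20[i] for i in rng.integers(len(AA20), size=length))
        site0 = int(rng.integers(10, length - 10))
        h_acc, y_acc = f"HUM{k:03d}", f"YST{k:03d}"

        force = site0 if cfg.site_fate == "mutate" else None
        delete = site0 if cfg.site_fate == "delete_column" else None
        mutant, pos_map = _mutate(
            rng,
            ancestor,
            cfg.target_identity,
            cfg.indel_rate,
            protected=site0 if cfg.site_fate == "preserve" else None,
            force_substitute=force,
            delete_position=delete,
        )
        human[h_acc] = ProteinRecord(
            accession=h_acc,
            species=Species.HUMAN,
            sequence=ancestor,
            active_sites=[ActiveSite(site0 + 1, ancestor[site0])],
        )
        yeast[y_acc] = ProteinRecord(
            accession=y_acc, species=Species.YEAST, sequence=mutant
        )
        sites[h_acc] = [(site0 + 1, ancestor[site0])]
        yeast_site = pos_map.get(site0, -1)
        if yeast_site >= 0 and cfg.site_fate == "preserve":
            sites[y_acc] = [(yeast_site + 1, mutant[yeast_site])]
        truth.append(
            (
                h_acc,
                y_acc,
                cfg.site_fate,
                site0 + 1,
                yeast_site + 1 if yeast_site >= 0 else -1,
            )
        )

    pair_accs = sorted(human)
    for d in range(cfg.n_paralogs):
        source = human[pair_accs[d % len(pair_accs)]]
        dup, _ = _mutate(
            rng, source.sequence, cfg.paralog_identity, cfg.indel_rate
        )
        acc = f"{source.accession}PAR{d:02d}"
        human[acc] = ProteinRecord(
            accession=acc, species=Species.HUMAN, sequence=dup
        )
    return SimulatedProteomes(human=human, yeast=yeast, sites=sites, truth=truth)


def write_sites_tsv(sim: SimulatedProteomes, path) -> None:
    with open(path, "w") as handle:
        handle.write("accession\tsite_position\tsite_residue\tsource\n")
        for acc in sorted(sim.sites):
            for pos, res in sim.sites[acc]:
                handle.write(f"{acc}\t{pos}\t{res}\tsimulated\n")


def write_truth_tsv(sim: SimulatedProteomes, path) -> None:
    with open(path, "w") as handle:
        handle.write(
            "human_acc\tyeast_acc\tsite_fate\thuman_site\tyeast_site\n"
        )
        for row in sim.truth:
            handle.write("\t".join(map(str, row)) + "\n")


# -------------------------------------------------------------- toy models


@dataclass(frozen=True)
class ToyModelConfig:
    seed: int = 0
    n_branches: int = 2
    capacities: tuple[float, ...] = (10.0, 4.0)
    yields_: tuple[float, ...] = (1.0, 1.0)
    include_cofactor_branch: bool = False
    cofactor_gpr: str = "AND"  # two-gene complex; "OR" makes them isozymes
    include_ribose_branch: bool = False
    ribose_capacity: float = 5.0
    ribose_coefficient: float = 0.1

    def __post_init__(self) -> None:
        if len(self.capacities) != self.n_branches or len(self.yields_) != (
            self.n_branches
        ):
            raise ConfigError("capacities/yields must match n_branches")
        if any(c <= 0 for c in self.capacities) or any(
            y <= 0 for y in self.yields_
        ):
            raise ConfigError("degenerate model: non-positive capacity/yield")
        if self.cofactor_gpr not in ("AND", "OR"):
            raise ConfigError("cofactor_gpr must be AND or OR")


def generate_toy_model(cfg: ToyModelConfig) -> tuple[MetabolicModel, float]:
    """Build a toy model and return it with its closed-form WT growth.

    Topology: per branch i, an uptake reaction (bounded by capacity_i) feeds
    A_i, converted to precursor P with yield_i by a one-gene reaction;
    biomass consumes 1 P per unit growth. With the ribose branch, biomass
    additionally consumes ``ribose_coefficient`` R per unit growth, and R is
    made only by the "isomerase" from its own capped uptake. The cofactor
    branch produces COF (mitochondrial compartment) behind a two-gene GPR;
    COF has no consumer until the biomass is augmented with it.

    Closed form: WT growth = min(sum_i capacity_i * yield_i,
    ribose_capacity / ribose_coefficient when the ribose branch is present).
    """
    metabolites = {"P": Metabolite(id="P", name="precursor", compartment="c")}
    reactions: dict[str, Reaction] = {}
    genes: set[str] = set()
    for i in range(cfg.n_branches):
        a_id = f"A{i}"
        metabolites[a_id] = Metabolite(id=a_id, name=f"substrate {i}")
        reactions[f"uptake_{i}"] = Reaction(
            id=f"uptake_{i}",
            stoichiometry={a_id: 1.0},
            lower_bound=0.0,
            upper_bound=cfg.capacities[i],
        )
        gene = f"g_conv{i}"
        genes.add(gene)
        reactions[f"conv_{i}"] = Reaction(
            id=f"conv_{i}",
            stoichiometry={a_id: -1.0, "P": cfg.yields_[i]},
            lower_bound=0.0,
            upper_bound=1000.0,
            gpr=gene,
        )
    biomass_stoich = {"P": -1.0}
    growth = sum(c * y for c, y in zip(cfg.capacities, cfg.yields_))
    if cfg.include_ribose_branch:
        metabolites["AR"] = Metabolite(id="AR", name="ribose precursor")
        metabolites["R"] = Metabolite(id="R", name="ribose-like")
        reactions["ribose_uptake"] = Reaction(
            id="ribose_uptake",
            stoichiometry={"AR": 1.0},
            lower_bound=0.0,
            upper_bound=cfg.ribose_capacity,
        )
        genes.add("g_iso")
        reactions["iso"] = Reaction(
            id="iso",
            name="isomerase (sole ribose route)",
            stoichiometry={"AR": -1.0, "R": 1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            gpr="g_iso",
        )
        biomass_stoich["R"] = -cfg.ribose_coefficient
        growth = min(growth, cfg.ribose_capacity / cfg.ribose_coefficient)
    if cfg.include_cofactor_branch:
        metabolites["PRE"] = Metabolite(id="PRE", name="cofactor precursor")
        metabolites["COF"] = Metabolite(
            id="COF", name="cofactor (heme-like)", compartment="m"
        )
        reactions["cof_uptake"] = Reaction(
            id="cof_uptake",
            stoichiometry={"PRE": 1.0},
            lower_bound=0.0,
            upper_bound=1.0,
        )
        genes.update({"g_cof1", "g_cof2"})
        joiner = " AND " if cfg.cofactor_gpr == "AND" else " OR "
        reactions["cof_synth"] = Reaction(
            id="cof_synth",
            stoichiometry={"PRE": -1.0, "COF": 1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            gpr=joiner.join(["g_cof1", "g_cof2"]),
        )
    reactions["biomass"] = Reaction(
        id="biomass",
        name="biomass pseudo-reaction",
        stoichiometry=biomass_stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
    )
    model = MetabolicModel(
        id=f"toy_seed{cfg.seed}",
        compartments={"c": "cytosol", "m": "mitochondrion"},
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        biomass_reaction_id="biomass",
    )
    model.validate()
    return model, growth


def random_small_model(
    rng: np.random.Generator, max_reactions: int = 8
) -> MetabolicModel:
    """A random bounded model for oracle comparisons.

    All bounds are finite and straddle zero, so v = 0 is always feasible
    (never INFEASIBLE) and the optimum is attained at a vertex of a bounded
    polytope (never UNBOUNDED).
    """
    n_rxn = int(rng.integers(3, max_reactions + 1))
    n_met = int(rng.integers(1, max(2, n_rxn - 1)))
    metabolites = {
        f"m{i}": Metabolite(id=f"m{i}") for i in range(n_met)
    }
    reactions = {}
    for j in range(n_rxn):
        stoich = {}
        for i in range(n_met):
            if rng.random() < 0.6:
                coef = float(rng.integers(-3, 4))
                if coef != 0:
                    stoich[f"m{i}"] = coef
        if not stoich:
            stoich[f"m{int(rng.integers(n_met))}"] = 1.0
        lb = float(rng.choice([-10.0, -5.0, 0.0]))
        ub = float(rng.choice([0.0, 5.0, 10.0]))
        if lb > ub:
            lb, ub = ub, lb
        reactions[f"r{j}"] = Reaction(
            id=f"r{j}", stoichiometry=stoich, lower_bound=lb, upper_bound=ub
        )
    objective_rxn = f"r{int(rng.integers(n_rxn))}"
    model = MetabolicModel(
        id="random_small",
        metabolites=metabolites,
        reactions=reactions,
        genes=set(),
        biomass_reaction_id=objective_rxn,
    )
    model.validate()
    return model
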