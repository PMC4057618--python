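"""Candidate-selection cascade for active-site nsSNV enzymes.

The cascade narrows an initial candidate list (enzymes with a variant at an
annotated catalytic residue) to those suitable for knockout modelling in
yeast, in five fixed stages:

1. ``one_one_one`` — keep enzymes with a 1 enzyme : 1 pathway : 1 reaction
   relationship, so a knockout perturbs exactly one annotated conversion;
2. ``reciprocal_ortholog`` — keep enzymes with a mutual-best-hit yeast
   ortholog;
3. ``active_site_conserved`` — keep pairs whose catalytic residues are
   identical across species at the aligned position;
4. ``unique_ortholog`` — exclude enzymes whose hit profile shows close
   secondary homologs (paralogs could mask the knockout phenotype);
5. ``pathway_match`` — keep pairs annotated to the same pathway acting on
   the same substrate/product compound sets.

Each dropped accession carries exactly one reason: the first stage it
failed. Survivor sets are strictly nested across stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .records import AlignmentHit, InvalidInputError, OrthologPair

STAGES = (
    "one_one_one",
    "reciprocal_ortholog",
    "active_site_conserved",
    "unique_ortholog",
    "pathway_match",
)


@dataclass(frozen=True)
class ReactionChem:
    """Substrate/product compound-ID sets for one catalysed reaction.

    Compound identifiers keep their namespace prefix (``CID:`` for PubChem
    compounds, ``SID:`` for substances without a specific structure).
    """

    substrates: frozenset[str]
    products: frozenset[str]

    def __post_init__(self) -> None:
        for cid in self.substrates | self.products:
            if not (cid.startswith("CID:") or cid.startswith("SID:")):
                raise InvalidInputError(
                    f"compound id {cid!r} lacks CID:/SID: namespace prefix"
                )


@dataclass
class EnzymeAnnotation:
    accession: str
    pathways: frozenset[str]
    reactions: frozenset[ReactionChem]

    @property
    def empty(self) -> bool:
        return not self.pathways and not self.reactions


class PathwayVerdict(str, Enum):
    SAME = "SAME"
    YEAST_ONLY_SAME_CHEMISTRY = "YEAST_ONLY_SAME_CHEMISTRY"
    HUMAN_ONLY = "HUMAN_ONLY"
    MISMATCH = "MISMATCH"


@dataclass
class PathwayComparison:
    verdicts: dict[str, PathwayVerdict]

    @property
    def overall_match(self) -> bool:
        """True iff at least one shared pathway is SAME and none MISMATCH."""
        vals = self.verdicts.values()
        return PathwayVerdict.SAME in vals and PathwayVerdict.MISMATCH not in vals


@dataclass
class FilterReport:
    stages: tuple[str, ...]
    survivors: dict[str, list[str]] = field(default_factory=dict)
    exclusions: dict[str, str] = field(default_factory=dict)  # acc -> reason

    @property
    def counts(self) -> dict[str, int]:
        return {stage: len(self.survivors[stage]) for stage in self.stages}

    def final_survivors(self) -> list[str]:
        return self.survivors[self.stages[-1]] if self.stages else []


def is_one_one_one(annotation: EnzymeAnnotation) -> bool:
    """One pathway, one reaction (one substrate/product set)."""
    if annotation.empty:
        raise InvalidInputError(f"{annotation.accession}: unannotated")
    return len(annotation.pathways) == 1 and len(annotation.reactions) == 1


def intersect_with_orthologs(
    candidates: Iterable[str], pairs: Sequence[OrthologPair]
) -> list[str]:
    """Candidates that have a reciprocal best-match ortholog, sorted."""
    human_accs = {p.human_acc for p in pairs}
    return sorted(set(candidates) & human_accs)


def paralog_screen(
    accession: str,
    hits: Sequence[AlignmentHit],
    min_bit_margin: float = 50.0,
    max_second_ratio: float = 0.9,
) -> bool:
    """True when the query has no close secondary homolog among its hits.

    The ortholog is deemed unique when the second-best hit is absent, or
    trails the best by at least ``min_bit_margin`` bits, or scores below
    ``max_second_ratio`` of the best bit score. The thresholds approximate a
    manual inspection of alignments and are configurable.
    """
    own = sorted(
        (h for h in hits if h.query_id == accession),
        key=lambda h: -h.bit_score,
    )
    if not own:
        raise InvalidInputError(f"{accession}: no hits; screen needs a best hit")
    if len(own) == 1:
        return True
    best, second = own[0].bit_score, own[1].bit_score
    return (second <= best - min_bit_margin) or (
        best > 0 and second / best < max_second_ratio
    )


def pathway_compare(
    human: EnzymeAnnotation, yeast: EnzymeAnnotation
) -> PathwayComparison:
    """Compare pathway membership and reaction chemistry across a pair.

    A pathway annotated in both species is SAME when the substrate/product
    sets of the catalysed reactions are identical, MISMATCH otherwise. A
    yeast-only pathway whose chemistry matches is tolerated (it does not
    break the overall verdict); a yeast-only pathway with differing
    chemistry is a MISMATCH. Human-only pathways are recorded but neutral.
    Chemistry comparison is exact compound-ID set equality — no similarity
    matching.
    """
    if human.empty or yeast.empty:
        raise InvalidInputError("pathway comparison requires both annotations")
    chem_same = human.reactions == yeast.reactions
    verdicts: dict[str, PathwayVerdict] = {}
    for pw in sorted(human.pathways | yeast.pathways):
        in_h, in_y = pw in human.pathways, pw in yeast.pathways
        if in_h and in_y:
            verdicts[pw] = (
                PathwayVerdict.SAME if chem_same else PathwayVerdict.MISMATCH
            )
        elif in_y:
            verdicts[pw] = (
                PathwayVerdict.YEAST_ONLY_SAME_CHEMISTRY
                if chem_same
                else PathwayVerdict.MISMATCH
            )
        else:
            verdicts[pw] = PathwayVerdict.HUMAN_ONLY
    return PathwayComparison(verdicts=verdicts)


def run_filter_cascade(
    candidates: Mapping[str, EnzymeAnnotation],
    pairs: Sequence[OrthologPair],
    conservation_results: Mapping[str, bool],
    hit_tables: Mapping[str, Sequence[AlignmentHit]],
    yeast_annotations: Mapping[str, EnzymeAnnotation],
    min_bit_margin: float = 50.0,
    max_second_ratio: float = 0.9,
    skip_stages: frozenset[str] = frozenset(),
) -> FilterReport:
    """Apply the five-stage cascade and report survivors and dropouts.

    ``conservation_results`` and ``yeast_annotations`` must cover every
    accession that reaches the stage needing them; a missing entry is a hard
    error rather than a silent drop. Stages may be omitted via
    ``skip_stages`` but never reordered. Survivor order is always sorted, so
    input order cannot change the result.
    """
    unknown = skip_stages - set(STAGES)
    if unknown:
        raise InvalidInputError(f"unknown stages {sorted(unknown)}")
    pair_by_human = {p.human_acc: p for p in pairs}
    report = FilterReport(stages=STAGES)
    current = sorted(candidates)

    def advance(stage: str, keep, reason) -> None:
        nonlocal current
        if stage in skip_stages:
            report.survivors[stage] = list(current)
            return
        survivors = []
        for acc in current:
            why = None if keep(acc) else reason(acc)
            if why is None:
                survivors.append(acc)
            else:
                report.exclusions[acc] = f"{stage}: {why}"
        report.survivors[stage] = survivors
        current = survivors

    def keep_111(acc: str) -> bool:
        try:
            return is_one_one_one(candidates[acc])
        except InvalidInputError:
            return False

    def why_111(acc: str) -> str:
        if candidates[acc].empty:
            return "unannotated"
        return "not a 1 enzyme:1 pathway:1 reaction relationship"

    advance("one_one_one", keep_111, why_111)
    advance(
        "reciprocal_ortholog",
        lambda acc: acc in pair_by_human,
        lambda acc: "no reciprocal best-hit ortholog",
    )

    if "active_site_conserved" not in skip_stages:
        missing = [a for a in current if a not in conservation_results]
        if missing:
            raise InvalidInputError(
                f"missing conservation results for {missing}"
            )
    advance(
        "active_site_conserved",
        lambda acc: conservation_results[acc],
        lambda acc: "active site not conserved",
    )

    if "unique_ortholog" not in skip_stages:
        missing = [a for a in current if a not in hit_tables]
        if missing:
            raise InvalidInputError(f"missing hit tables for {missing}")
    advance(
        "unique_ortholog",
        lambda acc: paralog_screen(
            acc, hit_tables[acc], min_bit_margin, max_second_ratio
        ),
        lambda acc: "close paralog/secondary homolog present",
    )

    if "pathway_match" not in skip_stages:
        missing = [
            a
            for a in current
            if pair_by_human[a].yeast_acc not in yeast_annotations
        ]
        if missing:
            raise InvalidInputError(
                f"missing yeast annotations for orthologs of {missing}"
            )
    advance(
        "pathway_match",
        lambda acc: pathway_compare(
            candidates[acc], yeast_annotations[pair_by_human[acc].yeast_acc]
        ).overall_match,
        lambda acc: "pathway or substrate/product mismatch",
    )
    return report
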