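"""Core sequence-level record types shared across the pipeline.

A :class:`ProteinRecord` bundles a protein sequence with its curated
annotations (active-site positions, nonsynonymous variants); an
:class:`AlignmentHit` is one row of a pairwise search result, optionally
carrying the gapped alignment strings needed for coordinate mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: Sentinel for a position that maps into a gap column of the partner sequence.
GAP = None


class Species(str, Enum):
    HUMAN = "human"
    YEAST = "yeast"
    OTHER = "other"


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class ActiveSite:
    """A 1-based annotated catalytic position and its residue letter."""

    position: int
    residue: str


@dataclass(frozen=True)
class Variant:
    """A nonsynonymous variant: 1-based position, reference and variant residue.

    ``variant_residue`` is ``'x'`` for stop/frameshift events, following the
    lowercase convention of curated variant tables.
    """

    position: int
    reference_residue: str
    variant_residue: str


@dataclass
class ProteinRecord:
    accession: str
    species: Species
    sequence: str
    active_sites: list[ActiveSite] = field(default_factory=list)
    variants: list[Variant] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidInputError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise InvalidInputError(
                f"{self.accession}: non-amino-acid letters {sorted(bad)}"
            )
        for site in self.active_sites:
            if not 1 <= site.position <= len(self.sequence):
                raise InvalidInputError(
                    f"{self.accession}: active site {site.position} outside "
                    f"1..{len(self.sequence)}"
                )
            actual = self.sequence[site.position - 1]
            if site.residue.upper() != actual:
                raise InvalidInputError(
                    f"{self.accession}: annotated residue {site.residue!r} at "
                    f"{site.position} but sequence has {actual!r}"
                )

    @property
    def site_positions(self) -> list[int]:
        return [s.position for s in self.active_sites]


@dataclass
class AlignmentHit:
    """One pairwise hit (one row of a tabular search report).

    ``aligned_query``/``aligned_subject`` are equal-length gapped strings
    ('-' = gap) covering the aligned span only; ``query_start`` and
    ``subject_start`` are the 1-based positions of the first aligned residue
    in the respective ungapped sequences.
    """

    query_id: str
    subject_id: str
    e_value: float
    bit_score: float
    percent_identity: float
    aligned_query: Optional[str] = None
    aligned_subject: Optional[str] = None
    query_start: int = 1
    subject_start: int = 1

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise InvalidInputError("e_value must be non-negative")
        if self.aligned_query is not None and self.aligned_subject is not None:
            if len(self.aligned_query) != len(self.aligned_subject):
                raise InvalidInputError(
                    f"{self.query_id}/{self.subject_id}: gapped strings differ "
                    "in length"
                )

    @property
    def has_alignment(self) -> bool:
        return self.aligned_query is not None and self.aligned_subject is not None

    def query_end(self) -> int:
        """1-based last aligned query position."""
        assert self.aligned_query is not None
        return self.query_start + len(self.aligned_query.replace("-", "")) - 1

    def subject_end(self) -> int:
        assert self.aligned_subject is not None
        return self.subject_start + len(self.aligned_subject.replace("-", "")) - 1


@dataclass
class OrthologPair:
    """A mutual-best-hit human/yeast pair with the supporting hit evidence."""

    human_acc: str
    yeast_acc: str
    forward_hit: AlignmentHit
    reverse_hit: AlignmentHit

    def __post_init__(self) -> None:
        if (
            self.forward_hit.query_id != self.human_acc
            or self.forward_hit.subject_id != self.yeast_acc
        ):
            raise InvalidInputError("forward hit does not link human -> yeast")
        if (
            self.reverse_hit.query_id != self.yeast_acc
            or self.reverse_hit.subject_id != self.human_acc
        ):
            raise InvalidInputError("reverse hit does not link yeast -> human")


class HitLabel(str, Enum):
    NO_HIT = "NO_HIT"
    PARALOGOUS = "PARALOGOUS"
    ONE_WAY_BEST = "ONE_WAY_BEST"
    RECIPROCAL = "RECIPROCAL"


@dataclass
class HitClassification:
    """Exhaustive, mutually exclusive per-query labels plus class counts."""

    labels: dict[str, HitLabel]

    @property
    def counts(self) -> dict[HitLabel, int]:
        out = {label: 0 for label in HitLabel}
        for lab in self.labels.values():
            out[lab] += 1
        return out

    def queries_with(self, label: HitLabel) -> list[str]:
        return sorted(q for q, lab in self.labels.items() if lab == label)
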