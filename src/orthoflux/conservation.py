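"""Mapping annotated positions through gapped alignments and judging
active-site conservation.

Positions are 1-based in the ungapped sequences; alignment columns are
0-based. A human active site maps through the pairwise alignment to its
yeast counterpart; it is conserved when the mapped column is gap-free, the
residues are identical, and — when the yeast protein carries its own curated
site annotation — the mapped position agrees with that annotation. The
"conservation block" around a site is the maximal run of gap-free columns
with positive substitution score containing the site: identities render as
the residue letter, positive mismatches as '+', matching alignment-midline
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Align import substitution_matrices

from .records import AlignmentHit, InvalidInputError, OrthologPair

GAP = None


class PositionOutOfRangeError(ValueError):
    """Position outside the aligned span (distinct from mapping into a gap)."""


@dataclass(frozen=True)
class ActiveSiteMapping:
    human_pos: int
    yeast_pos: Optional[int]  # None = maps into a gap
    human_residue: str
    yeast_residue: Optional[str]
    conserved: bool
    column: int  # 0-based alignment column
    note: str = ""


@dataclass(frozen=True)
class ConservationBlock:
    block_string: str
    start: int  # 0-based alignment columns, inclusive
    end: int
    contains_site: bool


def _column_of(hit: AlignmentHit, pos: int, which: str) -> int:
    """0-based alignment column holding 1-based ungapped position ``pos``."""
    if not hit.has_alignment:
        raise InvalidInputError("hit carries no gapped alignment strings")
    gapped = hit.aligned_query if which == "query" else hit.aligned_subject
    start = hit.query_start if which == "query" else hit.subject_start
    if pos < start:
        raise PositionOutOfRangeError(
            f"position {pos} precedes aligned span starting at {start}"
        )
    current = start - 1
    for col, char in enumerate(gapped):
        if char != "-":
            current += 1
            if current == pos:
                return col
    raise PositionOutOfRangeError(
        f"position {pos} beyond aligned span ending at {current}"
    )


def _pos_at(hit: AlignmentHit, col: int, which: str) -> Optional[int]:
    """1-based ungapped position at alignment column ``col`` (None if gap)."""
    gapped = hit.aligned_query if which == "query" else hit.aligned_subject
    start = hit.query_start if which == "query" else hit.subject_start
    if gapped[col] == "-":
        return None
    return start - 1 + sum(1 for c in gapped[: col + 1] if c != "-")


def map_position(
    hit: AlignmentHit, pos: int, direction: str = "query->subject"
) -> Optional[int]:
    """Map a 1-based position to the partner sequence via the alignment.

    Returns the partner position sharing the alignment column, or ``None``
    (GAP) when that column holds a gap in the partner. Positions outside the
    aligned span raise :class:`PositionOutOfRangeError` instead. The mapping
    is strictly increasing over non-gap columns.
    """
    if direction == "query->subject":
        col = _column_of(hit, pos, "query")
        return _pos_at(hit, col, "subject")
    elif direction == "subject->query":
        col = _column_of(hit, pos, "subject")
        return _pos_at(hit, col, "query")
    raise InvalidInputError(f"unknown direction {direction!r}")


def active_site_conserved(
    pair: OrthologPair,
    human_sites: Sequence[int],
    yeast_sites: Sequence[int] = (),
) -> list[ActiveSiteMapping]:
    """Judge conservation of each annotated human active site.

    One mapping per human site. Conservation requires (i) the site maps to a
    residue (not a gap), (ii) identical residue letters, and (iii) when the
    yeast protein has its own site annotation, the mapped position is among
    the annotated yeast sites; a disagreement is flagged in ``note``. When
    the yeast annotation is absent, identity alone decides and the mapping
    is noted "annotation-absent". Sites outside the aligned span are
    recorded as unconserved GAP mappings rather than raising.
    """
    hit = pair.forward_hit
    if not hit.has_alignment:
        raise InvalidInputError("ortholog pair lacks gapped alignment strings")
    out: list[ActiveSiteMapping] = []
    for pos in human_sites:
        try:
            col = _column_of(hit, pos, "query")
        except PositionOutOfRangeError:
            out.append(
                ActiveSiteMapping(
                    human_pos=pos,
                    yeast_pos=GAP,
                    human_residue="?",
                    yeast_residue=None,
                    conserved=False,
                    column=-1,
                    note="outside-aligned-span",
                )
            )
            continue
        human_res = hit.aligned_query[col]
        yeast_pos = _pos_at(hit, col, "subject")
        yeast_res = hit.aligned_subject[col] if yeast_pos is not None else None
        conserved = yeast_pos is not None and human_res == yeast_res
        note = ""
        if not yeast_sites:
            note = "annotation-absent"
        elif yeast_pos is not None and yeast_pos not in yeast_sites:
            conserved = False
            note = (
                f"mapped position {yeast_pos} disagrees with yeast "
                f"annotation {sorted(yeast_sites)}"
            )
        out.append(
            ActiveSiteMapping(
                human_pos=pos,
                yeast_pos=yeast_pos,
                human_residue=human_res,
                yeast_residue=yeast_res,
                conserved=conserved,
                column=col,
                note=note,
            )
        )
    return out


def pair_conserved(mappings: Sequence[ActiveSiteMapping]) -> bool:
    """Overall verdict: every annotated site conserved."""
    return bool(mappings) and all(m.conserved for m in mappings)


def conservation_block(
    hit: AlignmentHit,
    site_column: int,
    matrix_name: str = "BLOSUM62",
) -> ConservationBlock:
    """Extract the maximal conserved block around an alignment column.

    Expansion proceeds left and right from ``site_column`` while columns are
    gap-free and score positively under the substitution matrix; a gap or a
    non-positive score terminates the block. Identical columns render the
    residue letter; positive non-identical columns render '+'. If the site
    column itself scores non-positively the block has length 1 with the same
    rendering rule applied.
    """
    if not hit.has_alignment:
        raise InvalidInputError("hit carries no gapped alignment strings")
    if not 0 <= site_column < len(hit.aligned_query):
        raise InvalidInputError(f"site_column {site_column} outside alignment")
    matrix = substitution_matrices.load(matrix_name)

    def col_score(col: int) -> Optional[float]:
        a, b = hit.aligned_query[col], hit.aligned_subject[col]
        if a == "-" or b == "-":
            return None  # gap terminates
        return float(matrix[a, b])

    def render(col: int) -> str:
        a, b = hit.aligned_query[col], hit.aligned_subject[col]
        return a if a == b else "+"

    start = end = site_column
    site_score = col_score(site_column)
    if site_score is not None and site_score > 0:
        while start > 0:
            s = col_score(start - 1)
            if s is None or s <= 0:
                break
            start -= 1
        while end < len(hit.aligned_query) - 1:
            s = col_score(end + 1)
            if s is None or s <= 0:
                break
            end += 1
    block = "".join(render(c) for c in range(start, end + 1))
    return ConservationBlock(
        block_string=block, start=start, end=end, contains_site=True
    )
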