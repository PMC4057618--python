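"""Reciprocal best-hit (RBH) orthology between two proteomes.

Given pairwise alignment hits in each direction (parsed from a tabular
report or computed with the built-in aligner), every query is classified as
NO_HIT, PARALOGOUS, ONE_WAY_BEST or RECIPROCAL, and mutual best hits are
emitted as ortholog pairs. RBH is the classical operational criterion for
one-to-one orthology: protein *a* in species A and protein *b* in species B
are called orthologs when *b* is a's highest-scoring match and *a* is b's.

The built-in aligner is an optimal dynamic-programming alignment (global or
local) under a substitution matrix with affine gap penalties; it stands in
for an external search tool, so raw scores are converted to bit scores with
fixed Karlin-Altschul-style constants (see :data:`KA_LAMBDA`, :data:`KA_K`).
Exact agreement with any particular BLAST build's statistics is a non-goal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .records import (
    AlignmentHit,
    HitClassification,
    HitLabel,
    InvalidInputError,
    OrthologPair,
    ProteinRecord,
)

#: Gapped Karlin-Altschul constants conventionally quoted for BLOSUM62 with
#: gap open 11 / extend 1. Used only to place raw scores on a bit scale.
KA_LAMBDA = 0.267
KA_K = 0.041

#: Default significance threshold on E-values. The alternative 1e-4 is
#: accepted everywhere a threshold is taken.
DEFAULT_EVALUE = 1e-5


class ScoringError(ValueError):
    """A residue cannot be scored under the chosen substitution matrix."""


class ConfigurationError(ValueError):
    """Inconsistent inputs, e.g. overlapping accession namespaces."""


@dataclass(frozen=True)
class AlignerConfig:
    """Substitution matrix + affine gap penalties (BLAST sign convention:
    a gap of length L costs ``gap_open + L * gap_extend``)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    mode: str = "global"  # or "local"


def _build_aligner(config: AlignerConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(config.matrix_name)
    # PairwiseAligner charges open_gap_score for the first gap column and
    # extend_gap_score for each further one; BLAST charges open + L*extend.
    aligner.open_gap_score = -(config.gap_open + config.gap_extend)
    aligner.extend_gap_score = -config.gap_extend
    aligner.mode = config.mode
    return aligner


def _sanitize(seq: str, alphabet: str) -> str:
    """Replace letters missing from the matrix with X (scored via the X row)."""
    missing = set(seq) - set(alphabet)
    if not missing:
        return seq
    if "X" not in alphabet:
        raise ScoringError(
            f"residues {sorted(missing)} absent from matrix and no X fallback"
        )
    return "".join("X" if c in missing else c for c in seq)


def align_pair(
    a: Union[ProteinRecord, str],
    b: Union[ProteinRecord, str],
    config: AlignerConfig = AlignerConfig(),
) -> AlignmentHit:
    """Optimally align two protein sequences and report a hit row.

    Deterministic: among co-optimal alignments the aligner's first traceback
    is taken, which is a fixed function of the inputs. The bit score is
    ``(lambda * S - ln K) / ln 2`` for raw score ``S``, and the E-value is
    ``m * n * 2**-bits`` for sequence lengths m, n.
    """
    seq_a = a.sequence if isinstance(a, ProteinRecord) else a
    seq_b = b.sequence if isinstance(b, ProteinRecord) else b
    id_a = a.accession if isinstance(a, ProteinRecord) else "query"
    id_b = b.accession if isinstance(b, ProteinRecord) else "subject"
    if not seq_a or not seq_b:
        raise InvalidInputError("cannot align an empty sequence")

    aligner = _build_aligner(config)
    alphabet = str(aligner.substitution_matrix.alphabet)
    seq_a = _sanitize(seq_a.upper(), alphabet)
    seq_b = _sanitize(seq_b.upper(), alphabet)

    alignment = aligner.align(seq_a, seq_b)[0]
    raw_score = alignment.score
    gapped_a, gapped_b = str(alignment[0]), str(alignment[1])

    # Aligned span starts (1-based) from the alignment coordinates; for a
    # global alignment these are 1/1, for local they mark the hit region.
    query_start = int(alignment.coordinates[0][0]) + 1
    subject_start = int(alignment.coordinates[1][0]) + 1

    n_cols = len(gapped_a)
    n_ident = sum(
        1 for x, y in zip(gapped_a, gapped_b) if x == y and x != "-"
    )
    bits = (KA_LAMBDA * raw_score - np.log(KA_K)) / np.log(2.0)
    e_value = float(len(seq_a) * len(seq_b) * 2.0 ** (-bits))
    return AlignmentHit(
        query_id=id_a,
        subject_id=id_b,
        e_value=e_value,
        bit_score=float(bits),
        percent_identity=100.0 * n_ident / n_cols if n_cols else 0.0,
        aligned_query=gapped_a,
        aligned_subject=gapped_b,
        query_start=query_start,
        subject_start=subject_start,
    )


def all_vs_all(
    queries: Mapping[str, ProteinRecord],
    subjects: Mapping[str, ProteinRecord],
    config: AlignerConfig = AlignerConfig(),
) -> list[AlignmentHit]:
    """Align every query against every subject (small inputs only)."""
    return [
        align_pair(q, s, config)
        for q in queries.values()
        for s in subjects.values()
    ]


def _hit_rank_key(hit: AlignmentHit) -> tuple:
    # Best first: highest bit score, then lowest e-value, then smallest
    # subject accession — a total order, so reruns are byte-identical.
    return (-hit.bit_score, hit.e_value, hit.subject_id)


def best_hit_per_query(
    hits: Iterable[AlignmentHit], e_threshold: float = DEFAULT_EVALUE
) -> dict[str, AlignmentHit]:
    """Keep, per query, the single best hit with ``e_value < e_threshold``.

    Queries with no passing hit are absent from the result.
    """
    if e_threshold <= 0:
        raise InvalidInputError("e_threshold must be positive")
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        if hit.e_value >= e_threshold:
            continue
        incumbent = best.get(hit.query_id)
        if incumbent is None or _hit_rank_key(hit) < _hit_rank_key(incumbent):
            best[hit.query_id] = hit
    return best


def reciprocal_best_hits(
    forward: Mapping[str, AlignmentHit],
    reverse: Mapping[str, AlignmentHit],
) -> list[OrthologPair]:
    """Emit (a, b) whenever a's best subject is b and b's best subject is a.

    ``forward`` maps species-A (human) queries to their best species-B hit;
    ``reverse`` the other direction. The accession namespaces must be
    disjoint. Output is sorted by the forward (human) accession; the result
    is a partial matching, so no accession appears twice.
    """
    overlap = set(forward) & set(reverse)
    if overlap:
        raise ConfigurationError(
            f"accession namespaces overlap between species: {sorted(overlap)[:5]}"
        )
    pairs = []
    for query in sorted(forward):
        subject = forward[query].subject_id
        back = reverse.get(subject)
        if back is not None and back.subject_id == query:
            pairs.append(
                OrthologPair(
                    human_acc=query,
                    yeast_acc=subject,
                    forward_hit=forward[query],
                    reverse_hit=back,
                )
            )
    return pairs


def classify_queries(
    queries: Sequence[str],
    forward: Mapping[str, AlignmentHit],
    reverse: Mapping[str, AlignmentHit],
) -> HitClassification:
    """Label every query NO_HIT / PARALOGOUS / ONE_WAY_BEST / RECIPROCAL.

    A many-to-one collision — several queries sharing one best subject — is
    resolved in favour of the highest-scoring query (bit score, then
    e-value, then accession); the losers are labelled PARALOGOUS. The winner
    is RECIPROCAL when the subject's best reverse hit points back at it,
    ONE_WAY_BEST otherwise.
    """
    by_subject: dict[str, list[str]] = {}
    for query in queries:
        hit = forward.get(query)
        if hit is not None:
            by_subject.setdefault(hit.subject_id, []).append(query)

    owners = {
        subject: min(
            group, key=lambda q: _hit_rank_key(forward[q]) + (q,)
        )
        for subject, group in by_subject.items()
    }

    labels: dict[str, HitLabel] = {}
    for query in queries:
        hit = forward.get(query)
        if hit is None:
            labels[query] = HitLabel.NO_HIT
            continue
        subject = hit.subject_id
        if owners[subject] != query:
            labels[query] = HitLabel.PARALOGOUS
            continue
        back = reverse.get(subject)
        if back is not None and back.subject_id == query:
            labels[query] = HitLabel.RECIPROCAL
        else:
            labels[query] = HitLabel.ONE_WAY_BEST
    return HitClassification(labels=labels)
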