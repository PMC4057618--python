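"""Packaged reference tables for the six-candidate human/yeast study.

Four curated tables ship with the package, transcribed exactly as printed
(including original spellings and lowercase variant residue letters):

- ``table1_pairs`` — 113 human/yeast reciprocal best-hit ortholog pairs;
- ``table2_candidates`` — 34 enzymes with an active-site nsSNV and a
  1 enzyme:1 pathway:1 reaction relationship, with substrate/product
  PubChem identifiers;
- ``table3_sites`` — active-site positions and conservation blocks for the
  six final candidate pairs;
- ``table4_pathways`` — pathway-level comparison for the six pairs.

Each file is checksummed at load time so silent packaging corruption is
caught immediately.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import pandas as pd

from .annotation import EnzymeAnnotation, ReactionChem
from .records import AlignmentHit, OrthologPair

FIXTURE_NAMES = (
    "table1_pairs",
    "table2_candidates",
    "table3_sites",
    "table4_pathways",
)

#: sha256 of each packaged TSV; verified on load.
CHECKSUMS: dict[str, str] = {
    "table1_pairs": "50ac64269aabfc31a7ab052e1716edc8441310b605eccbc3cb62b03946f7a65f",
    "table2_candidates": "2d99f6a0b4b3bcf54d7a61cc1edd21355023def12353095d7d1ec6a89c3dd000",
    "table3_sites": "90c6ac18c308daddb4eebc26cd57e8b363226f38c9a5881b73c9fe4eeb2b0021",
    "table4_pathways": "cd4d735d4be78e03332c4b5ac5c496462295f86fc46f595f99e7defbf9b0374e",
}


class PackagingError(RuntimeError):
    """A packaged fixture is missing or corrupted."""


def fixture_path(name: str) -> Path:
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return Path(str(resources.files("orthoflux.data") / f"{name}.tsv"))


def load_paper_fixture(name: str) -> pd.DataFrame:
    """Load a packaged table by name, verifying its checksum."""
    path = fixture_path(name)
    if not path.exists():
        raise PackagingError(f"fixture file missing: {path}")
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != CHECKSUMS[name]:
        raise PackagingError(
            f"fixture {name} checksum mismatch: got {digest}"
        )
    return pd.read_csv(path, sep="\t", dtype=str).apply(
        lambda col: col.str.strip() if col.dtype == object else col
    )


def table1_ortholog_pairs() -> list[OrthologPair]:
    """The 113 curated pairs lifted into :class:`OrthologPair` objects.

    The raw two-way hit evidence is not distributed with the table, so each
    pair carries placeholder hits (the curated table itself is the
    evidence); downstream set operations use only the accessions.
    """
    df = load_paper_fixture("table1_pairs")
    pairs = []
    for row in df.itertuples(index=False):
        fwd = AlignmentHit(
            query_id=row.human_acc,
            subject_id=row.yeast_acc,
            e_value=1e-50,
            bit_score=100.0,
            percent_identity=0.0,
        )
        rev = AlignmentHit(
            query_id=row.yeast_acc,
            subject_id=row.human_acc,
            e_value=1e-50,
            bit_score=100.0,
            percent_identity=0.0,
        )
        pairs.append(
            OrthologPair(
                human_acc=row.human_acc,
                yeast_acc=row.yeast_acc,
                forward_hit=fwd,
                reverse_hit=rev,
            )
        )
    return pairs


def _split_compounds(cell: str) -> frozenset[str]:
    """Split a multi-compound cell on '|' and normalise 'CID: n' -> 'CID:n'."""
    out = set()
    for token in str(cell).split("|"):
        token = token.strip().replace(": ", ":")
        if token:
            out.add(token)
    return frozenset(out)


def table2_annotations() -> dict[str, EnzymeAnnotation]:
    """Candidate annotations: one reaction each, from the printed
    substrate/product identifiers; pathway membership from the pathway
    table when listed there, otherwise a per-enzyme singleton placeholder
    (all 34 are single-pathway by construction of the table)."""
    t2 = load_paper_fixture("table2_candidates")
    t4 = load_paper_fixture("table4_pathways")
    human_pathways: dict[str, set[str]] = {}
    for row in t4.itertuples(index=False):
        # rows marked "Pathway only annotated in yeast" do not belong to the
        # human annotation
        if "only annotated in yeast" not in row.details:
            human_pathways.setdefault(row.human_acc, set()).add(row.pathway)
    annotations = {}
    for row in t2.itertuples(index=False):
        pathways = human_pathways.get(
            row.accession, {f"pathway_of_{row.accession}"}
        )
        reaction = ReactionChem(
            substrates=_split_compounds(row.substrate_id),
            products=_split_compounds(row.product_id),
        )
        annotations[row.accession] = EnzymeAnnotation(
            accession=row.accession,
            pathways=frozenset(pathways),
            reactions=frozenset([reaction]),
        )
    return annotations


def table4_yeast_annotations() -> dict[str, EnzymeAnnotation]:
    """Yeast-side annotations for the six pairs.

    Pathways come from the pathway table (all rows name the yeast protein,
    including the yeast-only ones); the reaction chemistry is shared with
    the human enzyme — the comparison found identical substrates and
    products for every pair.
    """
    t4 = load_paper_fixture("table4_pathways")
    t2_ann = table2_annotations()
    yeast_pathways: dict[str, set[str]] = {}
    human_of: dict[str, str] = {}
    for row in t4.itertuples(index=False):
        yeast_pathways.setdefault(row.yeast_acc, set()).add(row.pathway)
        human_of[row.yeast_acc] = row.human_acc
    return {
        yacc: EnzymeAnnotation(
            accession=yacc,
            pathways=frozenset(pws),
            reactions=t2_ann[human_of[yacc]].reactions,
        )
        for yacc, pws in yeast_pathways.items()
    }


def table3_site_records() -> pd.DataFrame:
    df = load_paper_fixture("table3_sites")
    df["human_site"] = df["human_site"].astype(int)
    df["yeast_site"] = df["yeast_site"].astype(int)
    return df
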