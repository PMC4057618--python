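"""FASTA and tabular hit-table I/O.

FASTA is read and written through Biopython; the accession is the first
whitespace-delimited token of the header line, and output is wrapped at 60
columns. Hit tables use the 12-column tab-separated dialect

    qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore

with an optional extended dialect appending two columns, ``qseq`` and
``sseq``, carrying the gapped alignment strings required for coordinate
mapping.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import AlignmentHit, InvalidInputError, ProteinRecord, Species

PathLike = Union[str, Path]

TABULAR_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


class HitTableParseError(ValueError):
    """Malformed hit-table row; message carries the 1-based line number."""


def read_fasta(
    path: PathLike, species: Species = Species.OTHER
) -> dict[str, ProteinRecord]:
    """Read a protein FASTA into accession-keyed records.

    Duplicate accessions within one file violate the proteome-uniqueness
    invariant and raise :class:`InvalidInputError`.
    """
    records: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id.split()[0]
        if acc in records:
            raise InvalidInputError(f"duplicate accession {acc} in {path}")
        records[acc] = ProteinRecord(
            accession=acc, species=species, sequence=str(rec.seq).upper()
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: PathLike) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description="")
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(seq_records)


def fasta_bytes(records: Iterable[ProteinRecord]) -> bytes:
    """Render records to FASTA bytes (used for determinism checks)."""
    buf = _io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=60)
    writer.write_file(
        SeqRecord(Seq(r.sequence), id=r.accession, description="")
        for r in records
    )
    return buf.getvalue().encode()


def read_hit_table(path: PathLike) -> list[AlignmentHit]:
    """Parse a 12-column (or 14-column extended) tab-separated hit table.

    Lines starting with ``#`` are comments. Malformed rows raise
    :class:`HitTableParseError` naming the offending line.
    """
    hits: list[AlignmentHit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 14):
                raise HitTableParseError(
                    f"{path}:{lineno}: expected 12 or 14 columns, "
                    f"got {len(fields)}"
                )
            try:
                hit = AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    query_start=int(fields[6]),
                    subject_start=int(fields[8]),
                    e_value=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except ValueError as exc:
                raise HitTableParseError(
                    f"{path}:{lineno}: {exc}"
                ) from exc
            if len(fields) == 14:
                hit.aligned_query = fields[12]
                hit.aligned_subject = fields[13]
                if len(fields[12]) != len(fields[13]):
                    raise HitTableParseError(
                        f"{path}:{lineno}: qseq and sseq lengths differ"
                    )
            hits.append(hit)
    return hits


def write_hit_table(
    hits: Iterable[AlignmentHit], path: PathLike, extended: bool = True
) -> None:
    """Write hits in the tabular dialect (extended = append qseq/sseq)."""
    with open(path, "w") as handle:
        for hit in hits:
            aln_len = (
                len(hit.aligned_query) if hit.aligned_query is not None else 0
            )
            n_ident = 0
            n_gapopen = 0
            if hit.has_alignment:
                in_gap = False
                for qc, sc in zip(hit.aligned_query, hit.aligned_subject):
                    if qc == sc and qc != "-":
                        n_ident += 1
                    if qc == "-" or sc == "-":
                        if not in_gap:
                            n_gapopen += 1
                        in_gap = True
                    else:
                        in_gap = False
            mismatch = (
                aln_len
                - n_ident
                - sum(
                    1
                    for qc, sc in zip(
                        hit.aligned_query or "", hit.aligned_subject or ""
                    )
                    if qc == "-" or sc == "-"
                )
            )
            row = [
                hit.query_id,
                hit.subject_id,
                f"{hit.percent_identity:.2f}",
                str(aln_len),
                str(max(mismatch, 0)),
                str(n_gapopen),
                str(hit.query_start),
                str(hit.query_end() if hit.has_alignment else 0),
                str(hit.subject_start),
                str(hit.subject_end() if hit.has_alignment else 0),
                f"{hit.e_value:.3g}",
                f"{hit.bit_score:.1f}",
            ]
            if extended and hit.has_alignment:
                row += [hit.aligned_query, hit.aligned_subject]
            handle.write("\t".join(row) + "\n")
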