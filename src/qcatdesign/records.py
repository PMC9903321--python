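"""Protein sequence records and the file formats that carry them.

Targets are accepted either as FASTA (multi-record, wrapped or
unwrapped) or as plain accession lists (one per line, or comma
separated), mirroring the inputs a quantitation-standard designer
receives in practice. All downstream stages consume
:class:`ProteinRecord`.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Ambiguity letters accepted at parse time but rejected by mass/pI code.
AMBIGUOUS_AA = frozenset("BZXU")
ALLOWED_AA = STANDARD_AA | AMBIGUOUS_AA

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|([^|]+)\|(\S*)")


class SequenceError(ValueError):
    """Malformed sequence input (illegal residue, empty record, duplicate)."""


@dataclass(frozen=True)
class ProteinRecord:
    """A single target or proteome protein.

    The sequence is normalised to uppercase on construction and may
    contain the 20 standard residues plus the ambiguity letters
    B, Z, X and U; anything else raises :class:`SequenceError` naming
    the record and offending position (1-based).
    """

    accession: str
    sequence: str
    name: str = ""
    organism: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise SequenceError(f"record {self.accession!r}: empty sequence")
        for i, ch in enumerate(seq, start=1):
            if ch not in ALLOWED_AA:
                raise SequenceError(
                    f"record {self.accession!r}: illegal residue {ch!r} at position {i}"
                )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_ambiguous_residues(self) -> bool:
        return any(ch in AMBIGUOUS_AA for ch in self.sequence)


def _accession_from_header(header: str) -> tuple[str, str]:
    """Split a FASTA id token into (accession, name).

    UniProt-style ``sp|P01266|THYG_HUMAN`` headers yield the central
    accession; otherwise the token before the first whitespace is used
    verbatim.
    """
    m = _UNIPROT_HEADER.match(header)
    if m:
        return m.group(1), m.group(2)
    return header, ""


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a FASTA file into an ordered list of :class:`ProteinRecord`.

    Raises :class:`SequenceError` on an empty file, a duplicate
    accession, or an illegal residue.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        accession, name = _accession_from_header(entry.id)
        description = entry.description[len(entry.id):].strip()
        rec = ProteinRecord(
            accession=accession,
            sequence=str(entry.seq),
            name=name or description,
        )
        if accession in seen:
            raise SequenceError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        records.append(rec)
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA, preserving accession order."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.name)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def read_accession_list(path: str | Path) -> list[str]:
    """Read accessions, one per line or comma separated.

    Entries are whitespace-trimmed and de-duplicated preserving the
    first occurrence; an effectively empty file raises
    :class:`SequenceError`.
    """
    text = Path(path).read_text()
    out: list[str] = []
    seen: set[str] = set()
    for token in re.split(r"[,\n]", text):
        token = token.strip()
        if token and token not in seen:
            seen.add(token)
            out.append(token)
    if not out:
        raise SequenceError(f"no accessions found in {path}")
    return out


def _looks_like_sequence(text: str) -> bool:
    text = text.strip().upper()
    return len(text) >= 2 and all(ch in ALLOWED_AA for ch in text)


def read_csv_records(path: str | Path) -> list[ProteinRecord] | list[str]:
    """Read a CSV target list: first column accession, optional second
    column sequence.

    A header row is auto-detected (its second field does not look like
    an amino-acid sequence). With sequences present the result is a
    list of :class:`ProteinRecord`; otherwise a de-duplicated accession
    list.
    """
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            cells = [c.strip() for c in row if c.strip()]
            if cells:
                rows.append(cells)
    if not rows:
        raise SequenceError(f"no rows found in {path}")
    header_words = {"accession", "acc", "id", "sequence", "seq", "name"}
    if rows[0][0].lower() in header_words or (
        len(rows[0]) > 1 and not _looks_like_sequence(rows[0][1])
    ):
        rows = rows[1:]  # header row
    if rows and all(len(r) > 1 for r in rows):
        records = []
        seen: set[str] = set()
        for acc, seq, *_ in rows:
            if acc in seen:
                raise SequenceError(f"duplicate accession {acc!r} in {path}")
            seen.add(acc)
            records.append(ProteinRecord(accession=acc, sequence=seq))
        return records
    accessions: list[str] = []
    seen = set()
    for r in rows:
        if r[0] not in seen:
            seen.add(r[0])
            accessions.append(r[0])
    if not accessions:
        raise SequenceError(f"no accessions found in {path}")
    return accessions
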