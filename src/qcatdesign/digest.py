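"""In-silico tryptic limit digestion.

Trypsin cleaves C-terminal to lysine and arginine except when the next
residue is proline (the KP/RP rule). A *limit digest* assumes complete
proteolysis — zero missed cleavages — which is the reference condition
for concatamer standards: every designed peptide must be releasable as
an exact limit fragment from both analyte and standard.

Peptides carry 1-based inclusive coordinates in the parent protein and
the native flanking residues (default three on each side) that become
the digestible linkers of a construct.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from qcatdesign.records import ProteinRecord


class TerminalType(str, enum.Enum):
    PROTEIN_N_TERMINAL = "protein_N_terminal"
    INTERNAL = "internal"
    PROTEIN_C_TERMINAL = "protein_C_terminal"
    WHOLE_PROTEIN = "whole_protein"


@dataclass(frozen=True)
class CleavageRule:
    """Cleave after any residue in ``targets`` unless the next residue
    is in ``blockers``. Ambiguity letters are never cleavage targets,
    so they behave conservatively (no invented cut sites)."""

    targets: frozenset[str] = frozenset("KR")
    blockers: frozenset[str] = frozenset("P")

    def cut_sites(self, sequence: str) -> list[int]:
        """0-based indices i such that a cut falls between sequence[i]
        and sequence[i+1]."""
        return [
            i
            for i in range(len(sequence) - 1)
            if sequence[i] in self.targets and sequence[i + 1] not in self.blockers
        ]

    def cuts_after(self, residue: str, next_residue: str | None) -> bool:
        """Whether a cut occurs after ``residue`` given its successor
        (None means chain terminus: no bond, no cut)."""
        return (
            residue in self.targets
            and next_residue is not None
            and next_residue not in self.blockers
        )


TRYPSIN = CleavageRule()


@dataclass(frozen=True)
class Peptide:
    """A limit-digest product with native context.

    ``start``/``end`` are 1-based inclusive coordinates in the parent;
    ``flank_n``/``flank_c`` are the up-to-k native residues on either
    side (shorter at protein termini).
    """

    sequence: str
    parent_accession: str
    start: int
    end: int
    flank_n: str = ""
    flank_c: str = ""
    terminal_type: TerminalType = TerminalType.INTERNAL

    def __len__(self) -> int:
        return len(self.sequence)


def flanking_sequences(
    parent: ProteinRecord | str, start: int, end: int, k: int = 3
) -> tuple[str, str]:
    """Native flanks of the region [start, end] (1-based inclusive).

    Returns up to ``k`` residues on each side; empty at protein
    termini. Raises ValueError for out-of-range coordinates.
    """
    seq = parent.sequence if isinstance(parent, ProteinRecord) else parent
    if not (1 <= start <= end <= len(seq)):
        raise ValueError(
            f"coordinates {start}..{end} out of range for sequence of length {len(seq)}"
        )
    flank_n = seq[max(0, start - 1 - k) : start - 1]
    flank_c = seq[end : end + k]
    return flank_n, flank_c


def _terminal_type(start: int, end: int, parent_len: int) -> TerminalType:
    if start == 1 and end == parent_len:
        return TerminalType.WHOLE_PROTEIN
    if start == 1:
        return TerminalType.PROTEIN_N_TERMINAL
    if end == parent_len:
        return TerminalType.PROTEIN_C_TERMINAL
    return TerminalType.INTERNAL


def tryptic_limit_digest(
    protein: ProteinRecord,
    flank_k: int = 3,
    rule: CleavageRule = TRYPSIN,
) -> list[Peptide]:
    """Digest ``protein`` to completion under ``rule``.

    The returned peptides are ordered by start position and their
    concatenation reproduces the parent sequence exactly.
    """
    seq = protein.sequence
    if not seq:
        raise ValueError(f"protein {protein.accession!r} has an empty sequence")
    boundaries = [0] + [i + 1 for i in rule.cut_sites(seq)] + [len(seq)]
    peptides: list[Peptide] = []
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        start, end = lo + 1, hi
        flank_n, flank_c = flanking_sequences(seq, start, end, k=flank_k)
        peptides.append(
            Peptide(
                sequence=seq[lo:hi],
                parent_accession=protein.accession,
                start=start,
                end=end,
                flank_n=flank_n,
                flank_c=flank_c,
                terminal_type=_terminal_type(start, end, len(seq)),
            )
        )
    return peptides


def count_linker_fragments(
    flank: str,
    context_before: str | None = None,
    context_after: str | None = None,
    rule: CleavageRule = TRYPSIN,
) -> int:
    """Number of tryptic fragments a flank (linker) region is split
    into when digested in its construct context.

    The flank is embedded between its neighbouring residues and the
    joint string digested; the count is the number of resulting
    fragments that overlap the flank span. 1 means the linker survives
    as a single piece. Release cuts at the linker's boundaries (e.g. a
    native flank ending in K/R cutting against the designed peptide)
    delimit the linker without fragmenting it and so do not raise the
    count. An empty flank returns 0.
    """
    if not flank:
        return 0
    before = context_before or ""
    after = context_after or ""
    joint = before + flank + after
    lo, hi = len(before), len(before) + len(flank)  # flank span [lo, hi)
    boundaries = [0] + [i + 1 for i in rule.cut_sites(joint)] + [len(joint)]
    n = 0
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        if a < hi and b > lo:
            n += 1
    return n


PEPTIDE_TABLE_COLUMNS = (
    "accession",
    "start",
    "end",
    "sequence",
    "flank_n",
    "flank_c",
    "terminal_type",
)


def write_peptide_table(peptides: Iterable[Peptide], path: str | Path) -> None:
    """Emit peptides as tab-separated text."""
    with open(path, "w") as fh:
        fh.write("\t".join(PEPTIDE_TABLE_COLUMNS) + "\n")
        for p in peptides:
            fh.write(
                "\t".join(
                    [
                        p.parent_accession,
                        str(p.start),
                        str(p.end),
                        p.sequence,
                        p.flank_n,
                        p.flank_c,
                        p.terminal_type.value,
                    ]
                )
                + "\n"
            )


def read_peptide_table(path: str | Path) -> list[Peptide]:
    """Read a tab-separated peptide table written by
    :func:`write_peptide_table`."""
    peptides: list[Peptide] = []
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"empty peptide table {path}")
    header = lines[0].split("\t")
    idx = {name: header.index(name) for name in PEPTIDE_TABLE_COLUMNS}
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        peptides.append(
            Peptide(
                sequence=cells[idx["sequence"]],
                parent_accession=cells[idx["accession"]],
                start=int(cells[idx["start"]]),
                end=int(cells[idx["end"]]),
                flank_n=cells[idx["flank_n"]],
                flank_c=cells[idx["flank_c"]],
                terminal_type=TerminalType(cells[idx["terminal_type"]]),
            )
        )
    return peptides
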