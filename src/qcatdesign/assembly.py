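"""Concatamer assembly: Qbricks, Qblocks, QconCATs and Qmenus.

A Qbrick carries the selected surrogate peptides for one protein, each
wrapped in its native flanking residues so that tryptic release from
the construct mimics release from the endogenous protein. The set of
candidate Qbricks for one protein (differing in peptide order) is a
Qblock; the best candidate from every Qblock is concatenated, together
with optional fixed auxiliary elements (purification and normalisation
tags), into one or more QconCAT constructs under a user length budget.
A Qmenu is the resulting set of constructs covering every protein
exactly once.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from qcatdesign.digest import (
    TRYPSIN,
    CleavageRule,
    Peptide,
    count_linker_fragments,
    tryptic_limit_digest,
)
from qcatdesign.records import ProteinRecord
from qcatdesign.scoring import NORMAL, Grade, MetricResult, ScoreCard


@dataclass(frozen=True)
class BrickUnit:
    """One peptide with its construct linkers (native flanks)."""

    flank_n: str
    peptide: Peptide
    flank_c: str

    @property
    def aa_sequence(self) -> str:
        return self.flank_n + self.peptide.sequence + self.flank_c


@dataclass(frozen=True)
class Qbrick:
    parent_accession: str
    units: tuple[BrickUnit, ...]

    @property
    def aa_sequence(self) -> str:
        return "".join(u.aa_sequence for u in self.units)

    @property
    def length(self) -> int:
        return len(self.aa_sequence)


@dataclass
class Qblock:
    """Candidate Qbricks for one protein, with their scorecards."""

    parent_accession: str
    candidates: list[Qbrick]
    scorecards: list[ScoreCard] = field(default_factory=list)

    def best(self) -> Qbrick:
        """Highest-scoring candidate; ties prefer natural peptide order,
        then the first candidate (input order is deterministic)."""
        if not self.candidates:
            raise ValueError(f"Qblock {self.parent_accession!r} has no candidates")
        points = (
            [c.points for c in self.scorecards]
            if len(self.scorecards) == len(self.candidates)
            else [0.0] * len(self.candidates)
        )
        order = sorted(
            range(len(self.candidates)),
            key=lambda i: (-points[i], -natural_order_score(self.candidates[i]), i),
        )
        return self.candidates[order[0]]


@dataclass(frozen=True)
class FixedElement:
    """A named auxiliary sequence placed at a construct terminus."""

    name: str
    sequence: str
    terminus: str = "C"  # "N" or "C"


#: Conventional purification/normalisation tags. These are generic
#: laboratory sequences (not taken from any particular design) and are
#: only included when explicitly requested.
CONVENTIONAL_FIXED_ELEMENTS = (
    FixedElement("GluFib", "EGVNDNEEGFFSAR", terminus="N"),
    FixedElement("cMyc", "EQKLISEEDL", terminus="C"),
    FixedElement("HisTag", "HHHHHH", terminus="C"),
)


@dataclass(frozen=True)
class QconCAT:
    bricks: tuple[Qbrick, ...]
    fixed_elements: tuple[FixedElement, ...] = ()

    def __post_init__(self) -> None:
        accessions = [b.parent_accession for b in self.bricks]
        if len(accessions) != len(set(accessions)):
            raise ValueError("a QconCAT may carry at most one Qbrick per protein")

    @property
    def aa_sequence(self) -> str:
        n_parts = [e.sequence for e in self.fixed_elements if e.terminus == "N"]
        c_parts = [e.sequence for e in self.fixed_elements if e.terminus == "C"]
        return "".join(n_parts) + "".join(b.aa_sequence for b in self.bricks) + "".join(c_parts)

    @property
    def length(self) -> int:
        return len(self.aa_sequence)


@dataclass(frozen=True)
class Qmenu:
    qconcats: tuple[QconCAT, ...]
    score: float = 0.0

    @property
    def proteins(self) -> list[str]:
        return [b.parent_accession for q in self.qconcats for b in q.bricks]


def build_qbricks(
    selected: Sequence[Peptide],
    parent: ProteinRecord,
    k: int = 3,
) -> Qblock:
    """Generate candidate Qbricks for one protein's selected peptides.

    Each unit carries its native ``k``-residue flanks. For one or two
    peptides every ordering is a candidate (1 or 2 candidates); for
    longer selections only the natural and reversed orders are
    generated to keep the candidate set bounded.
    """
    if not selected:
        raise ValueError(f"no peptides selected for {parent.accession!r}")
    for p in selected:
        if p.parent_accession != parent.accession:
            raise ValueError(
                f"peptide {p.sequence!r} belongs to {p.parent_accession!r}, "
                f"not {parent.accession!r}"
            )
        if not (1 <= p.start <= p.end <= len(parent.sequence)):
            raise ValueError(f"peptide {p.sequence!r} coordinates outside parent")
    natural = tuple(sorted(selected, key=lambda p: p.start))
    if len(natural) <= 2:
        orderings = list(itertools.permutations(natural))
    else:
        orderings = [natural, tuple(reversed(natural))]

    def unit(p: Peptide) -> BrickUnit:
        seq = parent.sequence
        flank_n = seq[max(0, p.start - 1 - k) : p.start - 1]
        flank_c = seq[p.end : p.end + k]
        return BrickUnit(flank_n, p, flank_c)

    candidates = [
        Qbrick(parent.accession, tuple(unit(p) for p in ordering))
        for ordering in orderings
    ]
    return Qblock(parent_accession=parent.accession, candidates=candidates)


def natural_order_score(qbrick: Qbrick) -> int:
    """1 if adjacent units appear in ascending native start order
    (the peptide order resembling the original protein), else 0."""
    starts = [u.peptide.start for u in qbrick.units]
    return int(all(a < b for a, b in zip(starts[:-1], starts[1:])))


def score_qbrick(qbrick: Qbrick) -> ScoreCard:
    """Default Qbrick scorecard: the single natural-order metric at
    NORMAL weight. (There are no default construct-level metrics;
    users may attach their own.)"""
    value = natural_order_score(qbrick)
    result = MetricResult(
        "natural_order", value, Grade.PASS if value else Grade.FAIL, NORMAL
    )
    return ScoreCard(
        subject_id=f"qbrick:{qbrick.parent_accession}",
        results=[result],
        subject=qbrick,
    )


def score_qblocks(qblocks: Iterable[Qblock]) -> None:
    """Attach default scorecards to each Qblock's candidates in place."""
    for block in qblocks:
        block.scorecards = [score_qbrick(c) for c in block.candidates]


def _min_partition(sizes: Sequence[int], capacity: int) -> list[list[int]]:
    """Partition item indices into the fewest groups with bounded group
    sum. Exhaustive for <= 8 items, first-fit-decreasing beyond."""
    n = len(sizes)
    if n <= 8:
        best: list[list[int]] | None = None

        def extend(i: int, groups: list[list[int]], sums: list[int]) -> None:
            nonlocal best
            if best is not None and len(groups) >= len(best):
                return
            if i == n:
                best = [g[:] for g in groups]
                return
            for gi in range(len(groups)):
                if sums[gi] + sizes[i] <= capacity:
                    groups[gi].append(i)
                    sums[gi] += sizes[i]
                    extend(i + 1, groups, sums)
                    groups[gi].pop()
                    sums[gi] -= sizes[i]
            groups.append([i])
            sums.append(sizes[i])
            extend(i + 1, groups, sums)
            groups.pop()
            sums.pop()

        extend(0, [], [])
        assert best is not None
        return best
    # first-fit decreasing heuristic
    order = sorted(range(n), key=lambda i: -sizes[i])
    groups: list[list[int]] = []
    sums: list[int] = []
    for i in order:
        for gi in range(len(groups)):
            if sums[gi] + sizes[i] <= capacity:
                groups[gi].append(i)
                sums[gi] += sizes[i]
                break
        else:
            groups.append([i])
            sums.append(sizes[i])
    for g in groups:
        g.sort()
    return groups


def assemble_qconcats(
    qblocks: Sequence[Qblock],
    max_length: int | None = None,
    fixed_elements: Sequence[FixedElement] = (),
) -> Qmenu:
    """Assemble the best Qbrick of every Qblock into the fewest
    QconCATs respecting ``max_length`` (construct length including
    fixed elements).

    With no length limit a single construct carries everything. Within
    a construct, bricks follow the input protein order. A protein whose
    single Qbrick cannot fit even alone raises an error naming it.
    """
    if not qblocks:
        raise ValueError("no Qblocks to assemble")
    bricks = [block.best() for block in qblocks]
    fixed = tuple(fixed_elements)
    fixed_len = sum(len(e.sequence) for e in fixed)
    if max_length is None:
        return Qmenu(qconcats=(QconCAT(tuple(bricks), fixed),))
    capacity = max_length - fixed_len
    for brick in bricks:
        if brick.length > capacity:
            raise ValueError(
                f"Qbrick for protein {brick.parent_accession!r} "
                f"({brick.length} aa + {fixed_len} aa fixed elements) exceeds "
                f"max_length {max_length}"
            )
    groups = _min_partition([b.length for b in bricks], capacity)
    groups.sort(key=lambda g: g[0])  # deterministic construct order
    qconcats = tuple(
        QconCAT(tuple(bricks[i] for i in sorted(g)), fixed) for g in groups
    )
    return Qmenu(qconcats=qconcats)


def expected_fragments(
    qconcat: QconCAT, rule: CleavageRule = TRYPSIN
) -> list[dict]:
    """Tryptic limit fragments of the construct, annotated by origin.

    Each row records the fragment, its construct coordinates, and
    whether it is a designed peptide (exact match to a selected
    peptide), an auxiliary element, or linker-derived material.
    """
    designed = {u.peptide.sequence for b in qconcat.bricks for u in b.units}
    auxiliary = {e.sequence: e.name for e in qconcat.fixed_elements}
    construct = ProteinRecord(accession="construct", sequence=qconcat.aa_sequence)
    rows = []
    for frag in tryptic_limit_digest(construct, rule=rule):
        if frag.sequence in designed:
            origin = "designed"
        elif frag.sequence in auxiliary:
            origin = f"auxiliary:{auxiliary[frag.sequence]}"
        else:
            origin = "linker"
        rows.append(
            {
                "fragment": frag.sequence,
                "start": frag.start,
                "end": frag.end,
                "origin": origin,
            }
        )
    return rows


def linker_fragment_counts(qconcat: QconCAT, rule: CleavageRule = TRYPSIN) -> list[int]:
    """Fragment count of every linker (flank) region evaluated in its
    assembled construct context; the ideal value for each is 1."""
    seq = qconcat.aa_sequence
    counts = []
    pos = sum(len(e.sequence) for e in qconcat.fixed_elements if e.terminus == "N")
    for brick in qconcat.bricks:
        for unit in brick.units:
            for segment, is_flank in (
                (unit.flank_n, True),
                (unit.peptide.sequence, False),
                (unit.flank_c, True),
            ):
                if is_flank and segment:
                    before = seq[max(0, pos - 1) : pos] or None
                    after_idx = pos + len(segment)
                    after = seq[after_idx : after_idx + 1] or None
                    counts.append(
                        count_linker_fragments(segment, before, after, rule=rule)
                    )
                pos += len(segment)
    return counts


def render_construct(qconcat: QconCAT, name: str = "QconCAT") -> str:
    """FASTA text of the construct; the header records the protein
    list, brick order and length."""
    proteins = ",".join(b.parent_accession for b in qconcat.bricks)
    header = f">{name} proteins={proteins} n_bricks={len(qconcat.bricks)} length={qconcat.length}"
    seq = qconcat.aa_sequence
    lines = [header] + [seq[i : i + 60] for i in range(0, len(seq), 60)]
    return "\n".join(lines) + "\n"


def fragment_table_text(qconcat: QconCAT) -> str:
    """Tab-separated expected-fragment table of a construct."""
    rows = expected_fragments(qconcat)
    lines = ["fragment\tstart\tend\torigin"]
    for r in rows:
        lines.append(f"{r['fragment']}\t{r['start']}\t{r['end']}\t{r['origin']}")
    return "\n".join(lines) + "\n"
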