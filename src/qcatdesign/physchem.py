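"""Peptide physicochemical properties: mass, formula, composition, pI.

Masses are for the neutral, unmodified peptide: the sum of residue
formulas plus one water. Residue elemental compositions are the
standard ones; monoisotopic and average masses are derived from the
same formulas using CODATA isotope/atomic masses, so formula and mass
are consistent by construction.

The isoelectric point solves net charge = 0 over the
Henderson–Hasselbalch terms for the free termini and the ionisable
side chains (D, E, C, Y, H, K, R) by bisection on pH in [0, 14],
using the EMBOSS pKa set by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from qcatdesign.records import STANDARD_AA

# Residue (= amino acid minus water) elemental composition, C/H/N/O/S.
RESIDUE_FORMULAS: dict[str, tuple[int, int, int, int, int]] = {
    "G": (2, 3, 1, 1, 0),
    "A": (3, 5, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "V": (5, 9, 1, 1, 0),
    "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1),
    "L": (6, 11, 1, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0),
    "E": (5, 7, 1, 3, 0),
    "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0),
    "F": (9, 9, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
}

_ELEMENTS = ("C", "H", "N", "O", "S")
_MONO = {"C": 12.0, "H": 1.00782503207, "N": 14.0030740048, "O": 15.9949146196, "S": 31.97207100}
_AVG = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}

WATER_MONO = 2 * _MONO["H"] + _MONO["O"]
WATER_AVG = 2 * _AVG["H"] + _AVG["O"]

MONO_RESIDUE_MASS = {
    aa: sum(n * _MONO[el] for n, el in zip(f, _ELEMENTS))
    for aa, f in RESIDUE_FORMULAS.items()
}
AVG_RESIDUE_MASS = {
    aa: sum(n * _AVG[el] for n, el in zip(f, _ELEMENTS))
    for aa, f in RESIDUE_FORMULAS.items()
}

#: EMBOSS pKa values (iep program defaults).
EMBOSS_PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

_BASIC = ("H", "K", "R")
_ACIDIC = ("D", "E", "C", "Y")


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty peptide sequence")
    for i, ch in enumerate(sequence, start=1):
        if ch not in STANDARD_AA:
            raise ValueError(
                f"residue {ch!r} at position {i} is not one of the 20 standard "
                "amino acids; mass and pI are undefined for ambiguity letters"
            )


@dataclass(frozen=True)
class MassReport:
    """Mass, molecular formula and residue composition of a peptide."""

    monoisotopic_mass: float
    average_mass: float
    formula: dict[str, int]
    composition: dict[str, int]

    @property
    def hill_formula(self) -> str:
        """Molecular formula in Hill notation (C, H, then alphabetical)."""
        parts = []
        for el in ("C", "H", "N", "O", "S"):
            n = self.formula.get(el, 0)
            if n:
                parts.append(f"{el}{n if n > 1 else ''}")
        return "".join(parts)


def molecular_formula(sequence: str) -> dict[str, int]:
    _check_sequence(sequence)
    totals = {el: 0 for el in _ELEMENTS}
    for ch in sequence:
        for n, el in zip(RESIDUE_FORMULAS[ch], _ELEMENTS):
            totals[el] += n
    totals["H"] += 2  # one water
    totals["O"] += 1
    return totals


def monoisotopic_mass(sequence: str) -> float:
    """Neutral monoisotopic mass in Da."""
    _check_sequence(sequence)
    return sum(MONO_RESIDUE_MASS[ch] for ch in sequence) + WATER_MONO


def average_mass(sequence: str) -> float:
    """Neutral average mass in Da."""
    _check_sequence(sequence)
    return sum(AVG_RESIDUE_MASS[ch] for ch in sequence) + WATER_AVG


def mass_report(sequence: str) -> MassReport:
    _check_sequence(sequence)
    composition: dict[str, int] = {}
    for ch in sequence:
        composition[ch] = composition.get(ch, 0) + 1
    return MassReport(
        monoisotopic_mass=monoisotopic_mass(sequence),
        average_mass=average_mass(sequence),
        formula=molecular_formula(sequence),
        composition=composition,
    )


def net_charge(sequence: str, ph: float, pka: Mapping[str, float] = EMBOSS_PKA) -> float:
    """Net charge of the peptide at ``ph`` under the given pKa set."""
    _check_sequence(sequence)
    charge = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for aa in _BASIC:
        n = sequence.count(aa)
        if n:
            charge += n / (1.0 + 10 ** (ph - pka[aa]))
    for aa in _ACIDIC:
        n = sequence.count(aa)
        if n:
            charge -= n / (1.0 + 10 ** (pka[aa] - ph))
    return charge


def isoelectric_point(
    sequence: str,
    pka: Mapping[str, float] = EMBOSS_PKA,
    tolerance: float = 1e-4,
) -> float:
    """pH at which the peptide's net charge is zero.

    Bisection on [0, 14]; the free termini guarantee the charge is
    positive at pH 0 and negative at pH 14, so a root always exists.
    Iterates until |charge| < ``tolerance``.
    """
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(sequence, mid, pka)
        if abs(q) < tolerance:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
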