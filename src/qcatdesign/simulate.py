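"""Synthetic proteomes and observation tables with planted structure.

The generator emulates the data the enrichment evaluation consumes: a
limit-digest peptide universe plus per-peptide MS/MS counts across a
set of runs. Detection is per-run Bernoulli: a peptide's per-run
probability is the baseline ``detect_prob`` multiplied by the factor
of every planted property it satisfies (capped at 1), and its MS/MS
count is the number of successful runs. Peptides with zero successes
are omitted from the table and therefore fall into the NotFound class
downstream — the same shape as a search-engine peptide export.

Everything is deterministic under the spec's mandatory seed, so
fixtures can be regenerated at test time instead of shipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from qcatdesign.digest import Peptide, tryptic_limit_digest
from qcatdesign.enrichment import ObservationRecord
from qcatdesign.records import ProteinRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Named peptide properties available to planted effects.
PROPERTY_PREDICATES: dict[str, Callable[[Peptide], bool]] = {
    "methionine_free": lambda p: "M" not in p.sequence,
    "has_methionine": lambda p: "M" in p.sequence,
    "cysteine_free": lambda p: "C" not in p.sequence,
    "midrange_length": lambda p: 7 <= len(p.sequence) <= 25,
    "no_KR_in_linker": lambda p: not any(ch in "KR" for ch in p.flank_n + p.flank_c),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic data set.

    Defaults mirror the evaluation conditions at desk scale: 28 runs,
    300 proteins, residue-wise uniform sequences long enough that most
    proteins clear the 20-limit-peptide filter, and a low baseline
    per-run detection probability so the bulk of the digest universe
    is never observed.
    """

    n_proteins: int = 300
    length_range: tuple[int, int] = (250, 600)
    residue_frequencies: Mapping[str, float] | None = None
    planted_effects: tuple[tuple[str, float], ...] = ()
    detect_prob: float = 0.02
    n_runs: int = 28
    seed: int = 0
    min_qualifying_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.detect_prob <= 1.0:
            raise ValueError("detect_prob must lie in [0, 1]")
        for name, mult in self.planted_effects:
            if name not in PROPERTY_PREDICATES:
                raise ValueError(f"unknown planted property {name!r}")
            if mult <= 0:
                raise ValueError("planted multipliers must be positive")
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError(f"bad length_range {self.length_range}")


def _frequencies(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    if spec.residue_frequencies is None:
        letters = np.array(list(AA20))
        probs = np.full(len(AA20), 1.0 / len(AA20))
    else:
        letters = np.array(list(spec.residue_frequencies))
        probs = np.array(list(spec.residue_frequencies.values()), dtype=float)
        probs = probs / probs.sum()
    return letters, probs


def _random_protein(
    rng: np.random.Generator, letters: np.ndarray, probs: np.ndarray, spec: FixtureSpec, i: int
) -> ProteinRecord:
    length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    seq = "".join(rng.choice(letters, size=length, p=probs))
    return ProteinRecord(accession=f"SYN{i:05d}", sequence=seq, organism="synthetic")


def generate_proteome(
    spec: FixtureSpec, min_peptides: int = 20, max_resample_rounds: int = 50
) -> list[ProteinRecord]:
    """Draw ``spec.n_proteins`` residue-wise random proteins.

    Proteins with fewer than ``min_peptides`` limit peptides are
    resampled (keeping their accession) until at least
    ``spec.min_qualifying_fraction`` of the proteome qualifies; an
    infeasible spec (e.g. very short proteins) raises after bounded
    resampling.
    """
    rng = np.random.default_rng(spec.seed)
    letters, probs = _frequencies(spec)
    proteins = [
        _random_protein(rng, letters, probs, spec, i) for i in range(spec.n_proteins)
    ]
    target = int(np.ceil(spec.min_qualifying_fraction * spec.n_proteins))
    for _ in range(max_resample_rounds):
        short = [
            i
            for i, p in enumerate(proteins)
            if len(tryptic_limit_digest(p)) < min_peptides
        ]
        if spec.n_proteins - len(short) >= target:
            return proteins
        for i in short:
            proteins[i] = _random_protein(rng, letters, probs, spec, i)
    raise ValueError(
        f"could not reach {spec.min_qualifying_fraction:.0%} proteins with "
        f">= {min_peptides} limit peptides under {spec!r}"
    )


def detection_probability(peptide: Peptide, spec: FixtureSpec) -> float:
    """Per-run detection probability of one peptide under the spec."""
    p = spec.detect_prob
    for name, mult in spec.planted_effects:
        if PROPERTY_PREDICATES[name](peptide):
            p *= mult
    return min(p, 1.0)


def generate_observations(
    proteome: Sequence[ProteinRecord], spec: FixtureSpec
) -> list[ObservationRecord]:
    """Simulate MS/MS counts over ``spec.n_runs`` runs.

    One row per (protein, peptide sequence) with at least one
    successful run; duplicated sequences within a protein are observed
    once. Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed + 1)  # independent of proteome stream
    records: list[ObservationRecord] = []
    for protein in proteome:
        seen: set[str] = set()
        peptides = [
            p
            for p in tryptic_limit_digest(protein)
            if not (p.sequence in seen or seen.add(p.sequence))
        ]
        probs = np.array([detection_probability(p, spec) for p in peptides])
        counts = rng.binomial(spec.n_runs, probs)
        for pep, count in zip(peptides, counts):
            if count > 0:
                records.append(
                    ObservationRecord(
                        peptide_sequence=pep.sequence,
                        parent_accession=protein.accession,
                        msms_count=int(count),
                    )
                )
    return records
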