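"""Log-odds enrichment evaluation of peptide-selection metrics.

Observed peptides (search-engine MS/MS counts: the number of runs in
which a peptide was directly identified by fragment spectra) are
partitioned into Low / Medium / High detectability classes at the
33.3% and 66.6% percentiles of the count distribution; limit-digest
peptides never observed form the NotFound class. For every protein
with at least ``min_peptides`` limit peptides, the peptide favored by
a metric of interest is compared, class by class, against a uniformly
random per-protein pick:

    log_odds(class) = ln(n_favored / n_random)

A metric that selects readily detectable peptides shows positive
log-odds in the observed classes and negative in NotFound. A
leave-one-out assessment quantifies each feature's contribution to the
overall ranking the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil, log
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from qcatdesign.digest import Peptide, tryptic_limit_digest
from qcatdesign.records import ProteinRecord

CLASSES = ("High", "Medium", "Low", "NotFound")


@dataclass(frozen=True)
class ObservationRecord:
    """One observed peptide with its MS/MS count."""

    peptide_sequence: str
    parent_accession: str
    msms_count: int

    def __post_init__(self) -> None:
        if self.msms_count < 0:
            raise ValueError("msms_count must be non-negative")


def read_observation_table(path: str | Path) -> list[ObservationRecord]:
    """Read a tab/comma-separated table with columns peptide_sequence,
    parent_accession, msms_count (the shape of a search-engine peptide
    export)."""
    sep = "\t" if Path(path).read_text().splitlines()[0].count("\t") else ","
    frame = pd.read_csv(path, sep=sep)
    required = {"peptide_sequence", "parent_accession", "msms_count"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    return [
        ObservationRecord(r.peptide_sequence, r.parent_accession, int(r.msms_count))
        for r in frame.itertuples()
    ]


def write_observation_table(records: Sequence[ObservationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide_sequence\tparent_accession\tmsms_count\n")
        for r in records:
            fh.write(f"{r.peptide_sequence}\t{r.parent_accession}\t{r.msms_count}\n")


def _nearest_rank(sorted_values: Sequence[int], pct: float) -> int:
    """Nearest-rank percentile of pre-sorted values."""
    n = len(sorted_values)
    k = max(1, ceil(pct / 100.0 * n))
    return sorted_values[min(k, n) - 1]


PeptideKey = tuple[str, str]  # (parent_accession, sequence)


def partition_classes(
    observations: Sequence[ObservationRecord],
    digest_universe: Sequence[Peptide],
    lower_pct: float = 33.3,
    upper_pct: float = 66.6,
) -> dict[PeptideKey, str]:
    """Assign every digest peptide to exactly one observation class.

    Observed peptides are split into Low / Medium / High at the
    nearest-rank percentiles of their MS/MS counts; boundary ties go
    downward (Low includes the first cut value, Medium the second).
    Digest peptides never observed are NotFound. Observations not
    present in the digest universe (e.g. missed-cleavage products) are
    discarded with a warning.
    """
    if not observations:
        raise ValueError("empty observation set")
    universe: set[PeptideKey] = {(p.parent_accession, p.sequence) for p in digest_universe}
    counts: dict[PeptideKey, int] = {}
    dropped = 0
    for obs in observations:
        key = (obs.parent_accession, obs.peptide_sequence)
        if key not in universe:
            dropped += 1
            continue
        counts[key] = max(counts.get(key, 0), obs.msms_count)
    if dropped:
        warnings.warn(
            f"discarded {dropped} observations absent from the limit-digest universe"
        )
    if not counts:
        raise ValueError("no observations overlap the digest universe")
    ordered = sorted(counts.values())
    q1 = _nearest_rank(ordered, lower_pct)
    q2 = _nearest_rank(ordered, upper_pct)
    if q1 == q2:
        warnings.warn(
            f"degenerate percentiles (q1 == q2 == {q1}); observed classes collapse"
        )
    assignment: dict[PeptideKey, str] = {}
    for key in universe:
        c = counts.get(key)
        if c is None:
            assignment[key] = "NotFound"
        elif c <= q1:
            assignment[key] = "Low"
        elif c <= q2:
            assignment[key] = "Medium"
        else:
            assignment[key] = "High"
    return assignment


def qualifying_digests(
    proteome: Sequence[ProteinRecord], min_peptides: int = 20
) -> dict[str, list[Peptide]]:
    """Limit digests of proteins with at least ``min_peptides`` limit
    peptides, keyed by accession."""
    out: dict[str, list[Peptide]] = {}
    for protein in proteome:
        peptides = tryptic_limit_digest(protein)
        if len(peptides) >= min_peptides:
            out[protein.accession] = peptides
    return out


def favored_peptides(
    proteome: Sequence[ProteinRecord] | Mapping[str, list[Peptide]],
    metric: Callable[[Peptide], float],
    direction: str = "highest",
    min_peptides: int = 20,
) -> dict[str, Peptide]:
    """One metric-favored peptide per qualifying protein.

    ``direction`` is "highest" or "lowest"; ties break to the earlier
    start position. Raises if no protein qualifies.
    """
    if direction not in ("highest", "lowest"):
        raise ValueError("direction must be 'highest' or 'lowest'")
    digests = (
        proteome
        if isinstance(proteome, Mapping)
        else qualifying_digests(proteome, min_peptides)
    )
    if not digests:
        raise ValueError(f"no protein has >= {min_peptides} limit peptides")
    sign = -1.0 if direction == "highest" else 1.0
    favored: dict[str, Peptide] = {}
    for accession, peptides in digests.items():
        favored[accession] = min(peptides, key=lambda p: (sign * metric(p), p.start))
    return favored


def class_counts(
    selection: Mapping[str, Peptide], assignment: Mapping[PeptideKey, str]
) -> dict[str, float]:
    counts = dict.fromkeys(CLASSES, 0.0)
    for peptide in selection.values():
        counts[assignment[(peptide.parent_accession, peptide.sequence)]] += 1
    return counts


def random_baseline(
    proteome: Sequence[ProteinRecord] | Mapping[str, list[Peptide]],
    assignment: Mapping[PeptideKey, str],
    min_peptides: int = 20,
    repetitions: int = 1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Per-class counts of one uniformly random limit peptide per
    qualifying protein, averaged over ``repetitions`` draws.

    A seed (or generator) is mandatory so baselines are reproducible.
    """
    if rng is None:
        if seed is None:
            raise ValueError("random_baseline requires an explicit seed")
        rng = np.random.default_rng(seed)
    digests = (
        proteome
        if isinstance(proteome, Mapping)
        else qualifying_digests(proteome, min_peptides)
    )
    if not digests:
        raise ValueError(f"no protein has >= {min_peptides} limit peptides")
    totals = dict.fromkeys(CLASSES, 0.0)
    for _ in range(repetitions):
        for peptides in digests.values():
            p = peptides[rng.integers(len(peptides))]
            totals[assignment[(p.parent_accession, p.sequence)]] += 1
    return {c: totals[c] / repetitions for c in CLASSES}


def log_odds_enrichment(
    favored_counts: Mapping[str, float], random_counts: Mapping[str, float]
) -> pd.DataFrame:
    """Per-class natural-log odds of favored versus random selection.

    When either cell of a class is zero, a +0.5 pseudocount is added to
    both (Haldane–Anscombe), keeping the statistic finite without
    touching well-populated cells.
    """
    if set(favored_counts) != set(random_counts):
        raise ValueError("favored and random counts must cover identical classes")
    rows = []
    for cls in CLASSES:
        nf, nr = favored_counts[cls], random_counts[cls]
        if nf == 0 or nr == 0:
            nf, nr = nf + 0.5, nr + 0.5
        rows.append(
            {
                "class": cls,
                "n_favored": favored_counts[cls],
                "n_random": random_counts[cls],
                "log_odds": log(nf / nr),
            }
        )
    return pd.DataFrame(rows)


def rank_metric(
    features: Sequence[tuple[str, Callable[[Peptide], float], float]],
) -> Callable[[Peptide], float]:
    """Overall-rank metric: POINTS over a weighted Boolean feature set.

    Each feature is (name, predicate returning truthy for PASS,
    weight value); the returned metric is the weighted sum of passes.
    """

    def metric(p: Peptide) -> float:
        return sum(w for _, fn, w in features if fn(p))

    return metric


def leave_one_out_assessment(
    features: Sequence[tuple[str, Callable[[Peptide], float], float]],
    proteome: Sequence[ProteinRecord] | Mapping[str, list[Peptide]],
    assignment: Mapping[PeptideKey, str],
    min_peptides: int = 20,
    repetitions: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Change in per-class log-odds when each feature is left out of
    the overall ranking.

    The random baseline is averaged over ``repetitions`` draws (the
    same seeded draws for every feature, so deltas isolate the feature
    and not baseline noise). Negative deltas in the observed classes
    mean the feature was contributing to detectable-peptide selection.
    """
    if len(features) < 2:
        raise ValueError("leave-one-out needs at least two enabled features")
    if seed is None:
        raise ValueError("leave_one_out_assessment requires an explicit seed")
    digests = (
        proteome
        if isinstance(proteome, Mapping)
        else qualifying_digests(proteome, min_peptides)
    )
    random_counts = random_baseline(
        digests, assignment, min_peptides, repetitions=repetitions, seed=seed
    )

    def enrichment_for(feature_subset) -> pd.DataFrame:
        favored = favored_peptides(digests, rank_metric(feature_subset), "highest", min_peptides)
        return log_odds_enrichment(class_counts(favored, assignment), random_counts)

    full = enrichment_for(features).set_index("class")["log_odds"]
    rows = []
    for i, (name, _, _) in enumerate(features):
        subset = [f for j, f in enumerate(features) if j != i]
        reduced = enrichment_for(subset).set_index("class")["log_odds"]
        for cls in CLASSES:
            rows.append(
                {
                    "feature": name,
                    "class": cls,
                    "log_odds_full": full[cls],
                    "log_odds_without": reduced[cls],
                    "delta": reduced[cls] - full[cls],
                }
            )
    return pd.DataFrame(rows)
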