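"""Weighted Boolean scoring engine for surrogate-peptide selection.

Every candidate subject (peptide, Qbrick, ...) is evaluated against a
set of metrics. Each metric value is graded by a rule as PASS, FAIL,
INFO (recorded but never scored) or ERROR (the metric could not be
computed; the reason is recorded and the metric contributes nothing).
The total is a weighted sum

    POINTS = sum_i ASSESSMENT_i * WEIGHT_i

with ASSESSMENT 1 for PASS and 0 otherwise. Default weight tiers are
two orders of magnitude apart (DISABLED=0, VERY_LOW=1, LOW=1e2,
NORMAL=1e4, HIGH=1e6, VERY_HIGH=1e8) so that a single PASS at a tier
outscores up to 99 passes at any lower tiers — empirical evidence and
expert rules dominate predictions by construction.

The module also houses the built-in scorers (expert elimination chain,
within-submission and proteome-wide repeat searches, local evidence
lookup) and the adapter contract under which external predictors or
databases plug in without ever crashing the pipeline.
"""

from __future__ import annotations

import enum
import hashlib
import json
import math
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping, Sequence

import pandas as pd

from qcatdesign.digest import Peptide, tryptic_limit_digest
from qcatdesign.physchem import monoisotopic_mass
from qcatdesign.records import ProteinRecord


class Grade(str, enum.Enum):
    PASS = "PASS"
    FAIL = "FAIL"
    INFO = "INFO"
    ERROR = "ERROR"


#: Default numeric values of the six weight tiers.
DEFAULT_WEIGHTS: dict[str, float] = {
    "DISABLED": 0,
    "VERY_LOW": 1,
    "LOW": 10**2,
    "NORMAL": 10**4,
    "HIGH": 10**6,
    "VERY_HIGH": 10**8,
}

TIER_NAMES = tuple(DEFAULT_WEIGHTS)


@dataclass(frozen=True)
class WeightCategory:
    """A named weight tier with its (overridable, non-negative) value."""

    name: str
    value: float

    def __post_init__(self) -> None:
        if self.name not in DEFAULT_WEIGHTS:
            raise ValueError(f"unknown weight tier {self.name!r}")
        if self.value < 0:
            raise ValueError(f"weight value must be non-negative, got {self.value}")

    @classmethod
    def default(cls, name: str) -> "WeightCategory":
        return cls(name, DEFAULT_WEIGHTS[name])


DISABLED = WeightCategory.default("DISABLED")
VERY_LOW = WeightCategory.default("VERY_LOW")
LOW = WeightCategory.default("LOW")
NORMAL = WeightCategory.default("NORMAL")
HIGH = WeightCategory.default("HIGH")
VERY_HIGH = WeightCategory.default("VERY_HIGH")


@dataclass(frozen=True)
class RuleSpec:
    """Grading rule for one metric column.

    ``comparator`` is one of ==, !=, <, <=, >, >=, in-set, in-range,
    nonzero, zero. Informational rules always grade INFO.
    """

    metric_name: str
    comparator: str
    threshold: Any = None
    weight: WeightCategory = NORMAL
    informational: bool = False


_COMPARATORS: dict[str, Callable[[Any, Any], bool]] = {
    "==": lambda v, t: v == t,
    "!=": lambda v, t: v != t,
    "<": lambda v, t: v < t,
    "<=": lambda v, t: v <= t,
    ">": lambda v, t: v > t,
    ">=": lambda v, t: v >= t,
    "in-set": lambda v, t: v in t,
    "in-range": lambda v, t: t[0] <= v <= t[1],
    "nonzero": lambda v, t: bool(v),
    "zero": lambda v, t: not bool(v),
}


@dataclass(frozen=True)
class MetricResult:
    """One graded metric value for one subject."""

    metric_name: str
    value: Any
    grade: Grade
    weight: WeightCategory = NORMAL
    detail: str = ""


def _is_missing(value: Any) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def evaluate_rule(value: Any, rule: RuleSpec) -> MetricResult:
    """Grade ``value`` under ``rule``.

    A missing value (None/NaN) and a comparator/type mismatch both
    yield an ERROR grade with the reason recorded — never an exception,
    so one broken metric cannot halt the run.
    """
    if rule.informational:
        return MetricResult(rule.metric_name, value, Grade.INFO, rule.weight)
    if _is_missing(value):
        return MetricResult(
            rule.metric_name, value, Grade.ERROR, rule.weight, detail="missing value"
        )
    comparator = _COMPARATORS.get(rule.comparator)
    if comparator is None:
        return MetricResult(
            rule.metric_name,
            value,
            Grade.ERROR,
            rule.weight,
            detail=f"unknown comparator {rule.comparator!r}",
        )
    try:
        passed = comparator(value, rule.threshold)
    except TypeError as exc:
        return MetricResult(
            rule.metric_name, value, Grade.ERROR, rule.weight, detail=f"type mismatch: {exc}"
        )
    return MetricResult(
        rule.metric_name, value, Grade.PASS if passed else Grade.FAIL, rule.weight
    )


def score_subject(results: Iterable[MetricResult]) -> float:
    """POINTS for one subject: the weighted count of PASS grades.

    INFO and ERROR results contribute nothing.
    """
    return sum(r.weight.value for r in results if r.grade is Grade.PASS)


@dataclass
class ScoreCard:
    """Per-subject row of the scoring matrix."""

    subject_id: str
    results: list[MetricResult] = field(default_factory=list)
    subject: Any = None

    @property
    def points(self) -> float:
        return score_subject(self.results)

    def result(self, metric_name: str) -> MetricResult | None:
        for r in self.results:
            if r.metric_name == metric_name:
                return r
        return None


# ---------------------------------------------------------------------------
# Built-in scorers
# ---------------------------------------------------------------------------

#: Dipeptide motifs prone to deamidation (NG, DG), cleavage artefacts
#: (DP) or missed tryptic cleavage within the peptide (KP, RP).
ELIMINATION_MOTIFS = ("NG", "DG", "DP", "KP", "RP")


def elimination_chain(peptide: Peptide, flank_k: int = 3) -> dict[str, Any]:
    """Expert sequence-hazard screen for one candidate peptide.

    Counts residues whose chemistry splits or shifts MS signal
    (C: alkylation artefacts, M: oxidation, H: charge heterogeneity),
    the hazard dipeptides NG/DG/DP/KP/RP, a glutamine start (pyroGlu
    formation), K/R within either flanking linker (extra tryptic
    sites in the construct), and whether both flanks have their full
    length. ``violations`` totals the broken rules; candidates breaking
    the fewest are preferred.
    """
    seq = peptide.sequence
    counts: dict[str, Any] = {
        "C_count": seq.count("C"),
        "M_count": seq.count("M"),
        "H_count": seq.count("H"),
    }
    for motif in ELIMINATION_MOTIFS:
        # overlapping occurrences (a dipeptide motif can share a residue
        # with the next, e.g. KP in "KKP" counted at one position only,
        # but "KPKP" at two)
        n = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == motif)
        counts[f"{motif}_count"] = n
    counts["Q_start"] = seq.startswith("Q")
    counts["KR_in_linker"] = any(
        ch in "KR" for ch in peptide.flank_n + peptide.flank_c
    )
    counts["complete_linker"] = (
        len(peptide.flank_n) == flank_k and len(peptide.flank_c) == flank_k
    )
    violations = (
        counts["C_count"]
        + counts["M_count"]
        + counts["H_count"]
        + sum(counts[f"{m}_count"] for m in ELIMINATION_MOTIFS)
        + int(counts["Q_start"])
        + int(counts["KR_in_linker"])
        + int(not counts["complete_linker"])
    )
    counts["violations"] = violations
    return counts


def repeat_within_submission(peptides: Sequence[Peptide]) -> dict[Peptide, int]:
    """Occurrence count of each peptide's sequence among the submitted
    candidates; 1 means no duplicate."""
    if not peptides:
        raise ValueError("no peptides submitted")
    tally: dict[str, int] = {}
    for p in peptides:
        tally[p.sequence] = tally.get(p.sequence, 0) + 1
    return {p: tally[p.sequence] for p in peptides}


class ProteomeIndex:
    """Digested proteome indexed for repeat searches.

    Builds the limit-digest peptide universe once and serves
    sequence-identity and monoisotopic-mass (MMI) repeat queries.
    Peptides containing ambiguity letters are indexed by sequence but
    excluded from the mass index (their mass is undefined).
    """

    def __init__(self, proteome: Sequence[ProteinRecord]):
        if not proteome:
            raise ValueError("empty proteome")
        self.sequence_index: dict[str, list[str]] = {}
        masses: list[tuple[float, str, str]] = []
        for protein in proteome:
            for pep in tryptic_limit_digest(protein):
                self.sequence_index.setdefault(pep.sequence, []).append(
                    protein.accession
                )
                try:
                    masses.append(
                        (monoisotopic_mass(pep.sequence), pep.sequence, protein.accession)
                    )
                except ValueError:
                    pass
        masses.sort()
        self._masses = [m for m, _, _ in masses]
        self._mass_entries = masses

    def sequence_repeats(self, sequence: str) -> list[str]:
        return self.sequence_index.get(sequence, [])

    def mass_repeats(self, mass: float, tolerance: float) -> list[tuple[str, str]]:
        lo = bisect_left(self._masses, mass - tolerance)
        hi = bisect_right(self._masses, mass + tolerance)
        return [(seq, acc) for _, seq, acc in self._mass_entries[lo:hi]]


def proteome_repeats(
    peptide: Peptide,
    proteome: Sequence[ProteinRecord] | ProteomeIndex,
    mass_tolerance: float = 0.001,
) -> tuple[int, int, list[str]]:
    """Sequence and MMI repeat counts of ``peptide`` in a proteome.

    Counts are self-inclusive: a peptide present once in the proteome
    scores (1, >=1). Repeat counts of one are favourable — the peptide
    is unique by sequence (and effectively by mass) and so
    unambiguously reports its parent protein. Also returns the
    accessions of sequence-identical duplicates.
    """
    index = proteome if isinstance(proteome, ProteomeIndex) else ProteomeIndex(proteome)
    seq_hits = index.sequence_repeats(peptide.sequence)
    mass_hits = index.mass_repeats(monoisotopic_mass(peptide.sequence), mass_tolerance)
    return len(seq_hits), len(mass_hits), list(seq_hits)


def evidence_lookup(peptide: Peptide, evidence: Iterable[str]) -> bool:
    """Exact-sequence presence in a local list of empirically observed
    peptides (the offline stand-in for spectral-cluster databases)."""
    evidence_set = evidence if isinstance(evidence, (set, frozenset)) else set(evidence)
    if not evidence_set:
        warnings.warn("evidence list is empty; all peptides will score absent")
    return peptide.sequence in evidence_set


def load_evidence_list(path: str | Path) -> frozenset[str]:
    """Load a flat file of observed peptide sequences, one per line."""
    lines = Path(path).read_text().splitlines()
    return frozenset(s.strip().upper() for s in lines if s.strip())


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def _tie_key(card: ScoreCard) -> tuple:
    subject = card.subject
    if isinstance(subject, Peptide):
        return (subject.start, subject.sequence)
    return (0, card.subject_id)


def rank_and_select(
    scorecards: Sequence[ScoreCard], n: int = 2
) -> list[ScoreCard]:
    """Top-``n`` subjects by POINTS.

    Stable descending sort; ties broken by earlier start position then
    lexicographic sequence (subject id for non-peptide subjects). If
    fewer than ``n`` candidates exist all are returned with a warning.
    """
    if not scorecards:
        raise ValueError("no scorecards to rank")
    ranked = sorted(scorecards, key=lambda c: (-c.points, *_tie_key(c)))
    if len(ranked) < n:
        warnings.warn(
            f"requested {n} subjects but only {len(ranked)} candidates available"
        )
        return ranked
    return ranked[:n]


# ---------------------------------------------------------------------------
# External scorer adapters
# ---------------------------------------------------------------------------

AdapterFn = Callable[[Sequence[Peptide]], Mapping[str, Any]]

_ADAPTERS: dict[str, AdapterFn] = {}


class AdapterError(RuntimeError):
    """Unknown adapter name at configuration time."""


def register_adapter(name: str, fn: AdapterFn) -> None:
    """Register an external evidence/prediction source.

    ``fn`` maps a peptide batch to {sequence: value}. Adapters wrap
    remote predictors or databases; offline tests register mocks.
    """
    _ADAPTERS[name] = fn


def registered_adapters() -> tuple[str, ...]:
    return tuple(_ADAPTERS)


def _cache_path(cache_dir: Path, adapter: str, sequence: str) -> Path:
    digest = hashlib.sha256(f"{adapter}\x00{sequence}".encode()).hexdigest()
    return cache_dir / adapter / f"{digest}.json"


def external_scorer_adapter(
    name: str,
    peptides: Sequence[Peptide],
    weight: WeightCategory = NORMAL,
    cache_dir: str | Path | None = None,
    rule: RuleSpec | None = None,
) -> list[MetricResult]:
    """Run a registered adapter over a peptide batch.

    Failures (connection errors, timeouts, bad payloads) are caught and
    recorded as ERROR grades — the pipeline always completes. Results
    are cached on disk keyed by (adapter name, peptide sequence) so a
    peptide encountered before is never re-queried.
    """
    if name not in _ADAPTERS:
        raise AdapterError(
            f"no adapter registered under {name!r}; available: {sorted(_ADAPTERS)}"
        )
    cache_root = Path(cache_dir) if cache_dir is not None else None
    results: dict[str, MetricResult] = {}
    pending: list[Peptide] = []
    for p in peptides:
        if p.sequence in results:
            continue
        if cache_root is not None:
            path = _cache_path(cache_root, name, p.sequence)
            if path.exists():
                payload = json.loads(path.read_text())
                results[p.sequence] = MetricResult(
                    name, payload["value"], Grade(payload["grade"]), weight,
                    payload.get("detail", "cached"),
                )
                continue
        pending.append(p)
    if pending:
        try:
            values = _ADAPTERS[name](pending)
        except Exception as exc:  # adapter failures must not propagate
            for p in pending:
                results[p.sequence] = MetricResult(
                    name, None, Grade.ERROR, weight, detail=f"{type(exc).__name__}: {exc}"
                )
        else:
            for p in pending:
                value = values.get(p.sequence)
                if value is None:
                    results[p.sequence] = MetricResult(
                        name, None, Grade.ERROR, weight, detail="no result returned"
                    )
                elif rule is not None:
                    graded = evaluate_rule(value, rule)
                    results[p.sequence] = MetricResult(
                        name, value, graded.grade, weight, graded.detail
                    )
                else:
                    results[p.sequence] = MetricResult(name, value, Grade.INFO, weight)
        if cache_root is not None:
            for p in pending:
                r = results[p.sequence]
                if r.grade is Grade.ERROR:
                    continue  # errors are transient; do not cache them
                path = _cache_path(cache_root, name, p.sequence)
                path.parent.mkdir(parents=True, exist_ok=True)
                path.write_text(
                    json.dumps({"value": r.value, "grade": r.grade.value, "detail": r.detail})
                )
    return [results[p.sequence] for p in peptides]


# ---------------------------------------------------------------------------
# Metric pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricSpec:
    """A metric column: how to compute the value and how to grade it."""

    name: str
    compute: Callable[[Peptide, "ScoringContext"], Any]
    rule: RuleSpec


@dataclass
class ScoringContext:
    """Shared resources the built-in scorers draw on."""

    proteome: ProteomeIndex | None = None
    evidence: frozenset[str] = frozenset()
    submission: Sequence[Peptide] = ()
    mass_tolerance: float = 0.001
    flank_k: int = 3
    cache_dir: Path | None = None


def _metric_length(p: Peptide, ctx: ScoringContext) -> int:
    return len(p.sequence)


def _metric_mass(p: Peptide, ctx: ScoringContext) -> float | None:
    try:
        return monoisotopic_mass(p.sequence)
    except ValueError:
        return None


def _metric_violations(p: Peptide, ctx: ScoringContext) -> int:
    return elimination_chain(p, flank_k=ctx.flank_k)["violations"]


def _metric_evidence(p: Peptide, ctx: ScoringContext) -> bool:
    return p.sequence in ctx.evidence


def _metric_seq_repeats(p: Peptide, ctx: ScoringContext) -> int | None:
    if ctx.proteome is None:
        return None
    return len(ctx.proteome.sequence_repeats(p.sequence))


def _metric_mmi_repeats(p: Peptide, ctx: ScoringContext) -> int | None:
    if ctx.proteome is None:
        return None
    try:
        mass = monoisotopic_mass(p.sequence)
    except ValueError:
        return None
    return len(ctx.proteome.mass_repeats(mass, ctx.mass_tolerance))


def _metric_submission_repeat(p: Peptide, ctx: ScoringContext) -> int:
    return sum(1 for q in ctx.submission if q.sequence == p.sequence) or 1


def default_metrics(context: ScoringContext) -> list[MetricSpec]:
    """The default metric set and weights.

    Empirical evidence and the expert elimination chain sit at HIGH,
    uniqueness at NORMAL, and the soft length/mass preferences at LOW,
    so that observation and expert rules always dominate. All of this
    is overridable through the config layer.
    """
    metrics = [
        MetricSpec(
            "evidence_present",
            _metric_evidence,
            RuleSpec("evidence_present", "nonzero", weight=HIGH),
        ),
        MetricSpec(
            "elimination_violations",
            _metric_violations,
            RuleSpec("elimination_violations", "zero", weight=HIGH),
        ),
        MetricSpec(
            "submission_repeat",
            _metric_submission_repeat,
            RuleSpec("submission_repeat", "==", 1, weight=NORMAL),
        ),
        MetricSpec(
            "length",
            _metric_length,
            RuleSpec("length", "in-range", (7, 25), weight=LOW),
        ),
        MetricSpec(
            "monoisotopic_mass",
            _metric_mass,
            RuleSpec("monoisotopic_mass", "in-range", (700.0, 3500.0), weight=LOW),
        ),
    ]
    if context.proteome is not None:
        metrics.insert(
            2,
            MetricSpec(
                "proteome_sequence_repeats",
                _metric_seq_repeats,
                RuleSpec("proteome_sequence_repeats", "==", 1, weight=NORMAL),
            ),
        )
        metrics.insert(
            3,
            MetricSpec(
                "proteome_mmi_repeats",
                _metric_mmi_repeats,
                RuleSpec("proteome_mmi_repeats", "==", 1, weight=NORMAL),
            ),
        )
    return metrics


def score_peptides(
    peptides: Sequence[Peptide],
    metrics: Sequence[MetricSpec],
    context: ScoringContext | None = None,
) -> list[ScoreCard]:
    """Evaluate every metric for every peptide and assemble scorecards."""
    ctx = context or ScoringContext()
    if not ctx.submission:
        ctx.submission = peptides
    cards: list[ScoreCard] = []
    for p in peptides:
        subject_id = f"{p.parent_accession}:{p.start}-{p.end}"
        results = []
        for spec in metrics:
            try:
                value = spec.compute(p, ctx)
            except Exception as exc:
                results.append(
                    MetricResult(
                        spec.name, None, Grade.ERROR, spec.rule.weight,
                        detail=f"{type(exc).__name__}: {exc}",
                    )
                )
                continue
            results.append(evaluate_rule(value, spec.rule))
        cards.append(ScoreCard(subject_id=subject_id, results=results, subject=p))
    return cards


def scorecards_to_table(scorecards: Sequence[ScoreCard]) -> pd.DataFrame:
    """Wide score matrix: one row per subject, a (value, grade) column
    pair per metric, plus points and rank (1 = best)."""
    rows = []
    for card in scorecards:
        row: dict[str, Any] = {"subject_id": card.subject_id}
        if isinstance(card.subject, Peptide):
            row["sequence"] = card.subject.sequence
            row["start"] = card.subject.start
        for r in card.results:
            row[f"{r.metric_name}"] = r.value
            row[f"{r.metric_name}_grade"] = r.grade.value
        row["points"] = card.points
        rows.append(row)
    table = pd.DataFrame(rows)
    order = sorted(
        range(len(scorecards)),
        key=lambda i: (-scorecards[i].points, *_tie_key(scorecards[i])),
    )
    ranks = [0] * len(scorecards)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    table["rank"] = ranks
    return table


def compare_subjects(a: ScoreCard, b: ScoreCard) -> float:
    """Pairwise POINTS difference over jointly valid metrics only.

    Metrics where either subject lacks a valid (PASS/FAIL) result are
    skipped for both, so an adapter failure on one side cannot tilt a
    head-to-head comparison. Positive means ``a`` ahead of ``b``.
    """
    b_results = {r.metric_name: r for r in b.results}
    delta = 0.0
    for ra in a.results:
        rb = b_results.get(ra.metric_name)
        if rb is None:
            continue
        if ra.grade in (Grade.ERROR, Grade.INFO) or rb.grade in (Grade.ERROR, Grade.INFO):
            continue
        delta += (ra.grade is Grade.PASS) * ra.weight.value
        delta -= (rb.grade is Grade.PASS) * rb.weight.value
    return delta
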