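"""Structured run configuration.

A single YAML file drives every stage: weight-tier overrides, the
enabled metrics with their rules, digestion and assembly options, and
the enrichment evaluation parameters. Defaults are the package
defaults documented in the scoring module; the length and mass PASS
windows are soft preferences and explicitly marked overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from qcatdesign import scoring
from qcatdesign.assembly import CONVENTIONAL_FIXED_ELEMENTS, FixedElement
from qcatdesign.scoring import (
    DEFAULT_WEIGHTS,
    MetricSpec,
    RuleSpec,
    ScoringContext,
    WeightCategory,
)


@dataclass
class MetricConfig:
    enabled: bool = True
    weight_tier: str = "NORMAL"
    comparator: str | None = None
    threshold: Any = None
    informational: bool = False


@dataclass
class Config:
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    metrics: dict[str, MetricConfig] = field(default_factory=dict)
    flank_k: int = 3
    mass_tolerance: float = 0.001
    select_n: int = 2
    max_length: int | None = None
    fixed_elements: list[FixedElement] = field(default_factory=list)
    lower_pct: float = 33.3
    upper_pct: float = 66.6
    min_peptides: int = 20
    baseline_repetitions: int = 1
    loo_repetitions: int = 10
    cache_dir: str | None = None

    def weight(self, tier: str) -> WeightCategory:
        if tier not in self.weights:
            raise ValueError(f"unknown weight tier {tier!r}")
        return WeightCategory(tier, self.weights[tier])

    def metric_specs(self, context: ScoringContext) -> list[MetricSpec]:
        """Default metric set with config overrides applied.

        Unknown metric names in the config raise at startup rather
        than silently scoring nothing.
        """
        specs = scoring.default_metrics(context)
        known = {s.name for s in specs}
        unknown = set(self.metrics) - known
        if unknown:
            raise ValueError(
                f"unknown metric name(s) in config: {sorted(unknown)}; "
                f"known metrics: {sorted(known)}"
            )
        out: list[MetricSpec] = []
        for spec in specs:
            override = self.metrics.get(spec.name)
            if override is None:
                out.append(spec)
                continue
            if not override.enabled:
                continue
            rule = RuleSpec(
                metric_name=spec.name,
                comparator=override.comparator or spec.rule.comparator,
                threshold=(
                    override.threshold
                    if override.threshold is not None
                    else spec.rule.threshold
                ),
                weight=self.weight(override.weight_tier),
                informational=override.informational,
            )
            out.append(MetricSpec(spec.name, spec.compute, rule))
        return out


def _parse_fixed_elements(raw: Any) -> list[FixedElement]:
    if raw in (None, False):
        return []
    if raw == "conventional":
        return list(CONVENTIONAL_FIXED_ELEMENTS)
    elements = []
    for item in raw:
        elements.append(
            FixedElement(
                name=item["name"],
                sequence=item["sequence"].upper(),
                terminus=item.get("terminus", "C"),
            )
        )
    return elements


def load_config(path: str | Path | None) -> Config:
    """Load a YAML config; a missing path yields pure defaults."""
    cfg = Config()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    weights = raw.get("weights", {})
    for tier, value in weights.items():
        if tier not in DEFAULT_WEIGHTS:
            raise ValueError(f"unknown weight tier {tier!r} in config")
        if value < 0:
            raise ValueError(f"weight tier {tier!r} must be non-negative")
        cfg.weights[tier] = float(value)
    for name, m in raw.get("metrics", {}).items():
        cfg.metrics[name] = MetricConfig(
            enabled=m.get("enabled", True),
            weight_tier=m.get("weight", "NORMAL"),
            comparator=m.get("comparator"),
            threshold=(
                tuple(m["threshold"]) if isinstance(m.get("threshold"), list)
                else m.get("threshold")
            ),
            informational=m.get("informational", False),
        )
    digestion = raw.get("digestion", {})
    cfg.flank_k = int(digestion.get("flank_k", cfg.flank_k))
    scoring_section = raw.get("scoring", {})
    cfg.mass_tolerance = float(scoring_section.get("mass_tolerance", cfg.mass_tolerance))
    cfg.select_n = int(scoring_section.get("select_n", cfg.select_n))
    assembly = raw.get("assembly", {})
    cfg.max_length = assembly.get("max_length", cfg.max_length)
    cfg.fixed_elements = _parse_fixed_elements(assembly.get("fixed_elements"))
    enrichment = raw.get("enrichment", {})
    cfg.lower_pct = float(enrichment.get("lower_pct", cfg.lower_pct))
    cfg.upper_pct = float(enrichment.get("upper_pct", cfg.upper_pct))
    cfg.min_peptides = int(enrichment.get("min_peptides", cfg.min_peptides))
    cfg.baseline_repetitions = int(
        enrichment.get("baseline_repetitions", cfg.baseline_repetitions)
    )
    cfg.loo_repetitions = int(enrichment.get("loo_repetitions", cfg.loo_repetitions))
    cfg.cache_dir = raw.get("cache_dir", cfg.cache_dir)
    return cfg
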