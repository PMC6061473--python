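"""Configurable weighted-evidence engine assigning four pathogenicity tiers.

The engine sums per-criterion points, each criterion binning one evidence
value (conservation indices, an external database frequency, predictor
scores, disease-report flags), and maps the total onto
Neutral/polymorphic → Possibly → Probably → Definitely pathogenic via three
strictly increasing cut points.  The shipped default
(``data/default_rubric.yaml``) is a documented reconstruction in the spirit
of clinically used weighted scoring schemes; every constant lives in the
config file, never in code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import yaml

from .reference_model import DATA_DIR, MitoscreenError
from .sequence_io import TIERS

__all__ = [
    "ConfigurationError",
    "EvidenceBundle",
    "Criterion",
    "RubricConfig",
    "PathogenicityScore",
    "RubricValidationReport",
    "load_rubric",
    "default_rubric",
    "validate_rubric",
    "score_variant",
]


class ConfigurationError(MitoscreenError):
    """The rubric config cannot score the presented evidence."""


@dataclass
class EvidenceBundle:
    """Evidence for one variant.

    ``external_frequency`` (e.g. a GenBank carrier count) and
    ``predictor_scores`` (e.g. PolyPhen-2 / MutPred probabilities) are
    user-supplied annotations carried opaquely — the pipeline never computes
    them.  ``disease_report_flags`` are booleans for independent case
    reports, heteroplasmy, segregation and biochemical evidence.
    """

    nucleotide_ci: Optional[float] = None
    aa_ci: Optional[float] = None
    external_frequency: Optional[float] = None
    predictor_scores: dict[str, float] = field(default_factory=dict)
    disease_report_flags: dict[str, bool] = field(default_factory=dict)
    synonymous: bool = False

    def __post_init__(self) -> None:
        for name in ("nucleotide_ci", "aa_ci"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise MitoscreenError(f"{name}={v} outside [0, 100]")

    def get(self, key: str) -> Any:
        head, _, tail = key.partition(".")
        if head == "predictor_scores":
            return self.predictor_scores.get(tail)
        if head == "disease_report_flags":
            return self.disease_report_flags.get(tail)
        if tail:
            raise ConfigurationError(f"unknown evidence key {key!r}")
        if not hasattr(self, head):
            raise ConfigurationError(f"unknown evidence key {key!r}")
        return getattr(self, head)


@dataclass(frozen=True)
class Criterion:
    name: str
    key: str
    bins: tuple[Mapping[str, Any], ...]
    domain: Any = None  # [lo, hi] numeric domain, "boolean", or "count"


@dataclass(frozen=True)
class RubricConfig:
    criteria: tuple[Criterion, ...]
    tier_thresholds: tuple[float, float, float]

    @property
    def max_total(self) -> float:
        return sum(max(b["points"] for b in c.bins) for c in self.criteria)


@dataclass(frozen=True)
class PathogenicityScore:
    per_criterion: Mapping[str, float]
    total: float
    tier: str


@dataclass
class RubricValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations


def load_rubric(path: str | Path) -> RubricConfig:
    raw = yaml.safe_load(Path(path).read_text())
    criteria = tuple(
        Criterion(
            name=c["name"],
            key=c["key"],
            bins=tuple(c["bins"]),
            domain=c.get("domain"),
        )
        for c in raw["criteria"]
    )
    thresholds = tuple(raw["tier_thresholds"])
    if len(thresholds) != 3:
        raise ConfigurationError("tier_thresholds must have exactly 3 cut points")
    return RubricConfig(criteria, thresholds)


def default_rubric() -> RubricConfig:
    return load_rubric(DATA_DIR / "default_rubric.yaml")


def _bin_matches(b: Mapping[str, Any], value: Any) -> bool:
    if b.get("unknown"):
        return value is None
    if value is None:
        return False
    if "equals" in b:
        return value == b["equals"]
    lo = b.get("min", -math.inf)
    hi = b.get("max", math.inf)
    return lo <= value < hi


def score_variant(evidence: EvidenceBundle, rubric: RubricConfig) -> PathogenicityScore:
    """Deterministic bin lookup per criterion, summed, mapped to a tier.

    Missing optional evidence falls into the bin marked ``unknown: true``;
    a criterion with no matching bin is a configuration error.  Synonymous
    variants are excluded upstream and refuse to score.
    """
    if evidence.synonymous:
        raise MitoscreenError("synonymous variants are excluded from scoring")
    per: dict[str, float] = {}
    for criterion in rubric.criteria:
        value = evidence.get(criterion.key)
        for b in criterion.bins:
            if _bin_matches(b, value):
                per[criterion.name] = float(b["points"])
                break
        else:
            raise ConfigurationError(
                f"criterion {criterion.name!r}: no bin matches value {value!r} "
                "(missing unknown bin?)"
            )
    total = sum(per.values())
    t1, t2, t3 = rubric.tier_thresholds
    if total < t1:
        tier = TIERS[0]
    elif total < t2:
        tier = TIERS[1]
    elif total < t3:
        tier = TIERS[2]
    else:
        tier = TIERS[3]
    return PathogenicityScore(per, total, tier)


def validate_rubric(rubric: RubricConfig) -> RubricValidationReport:
    """Report-only check: disjoint/exhaustive bins per criterion over its
    declared domain, strictly increasing tier thresholds."""
    report = RubricValidationReport()
    t = rubric.tier_thresholds
    if not (t[0] < t[1] < t[2]):
        report.violations.append(
            f"tier_thresholds {t} are not strictly increasing"
        )
    for c in rubric.criteria:
        if not c.bins:
            report.violations.append(f"{c.name}: no bins")
            continue
        if c.domain == "boolean":
            covered = {b.get("equals") for b in c.bins if "equals" in b}
            for want in (True, False):
                if want not in covered:
                    report.violations.append(f"{c.name}: no bin for {want}")
            continue
        ranges = []
        for b in c.bins:
            if b.get("unknown") or "equals" in b:
                continue
            ranges.append((b.get("min", -math.inf), b.get("max", math.inf)))
        ranges.sort()
        for (lo1, hi1), (lo2, hi2) in zip(ranges, ranges[1:]):
            if lo2 < hi1:
                report.violations.append(
                    f"{c.name}: bins [{lo1},{hi1}) and [{lo2},{hi2}) overlap"
                )
            elif lo2 > hi1:
                report.violations.append(
                    f"{c.name}: gap between {hi1} and {lo2}"
                )
        if isinstance(c.domain, (list, tuple)) and len(c.domain) == 2 and ranges:
            lo, hi = c.domain
            if ranges[0][0] > lo:
                report.violations.append(
                    f"{c.name}: domain start {lo} not covered"
                )
            if ranges[-1][1] <= hi:
                report.violations.append(
                    f"{c.name}: domain end {hi} not covered"
                )
        if c.domain == "count" and ranges:
            if ranges[0][0] > 0:
                report.violations.append(f"{c.name}: counts below {ranges[0][0]} uncovered")
            if ranges[-1][1] != math.inf:
                report.violations.append(f"{c.name}: counts above {ranges[-1][1]} uncovered")
    return report
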