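"""Severity ranking of surviving annotated variants and candidate nomination.

Annotations that survived filtering are scored by the ordinal severity of
their consequence category; the strain's genetic map zone, when known, adds
a small bonus that breaks ties between equally severe candidates without
ever overriding a severity-class difference (confirmed causal lesions have
been found outside their mapped zone, so the zone is a guide, not a gate).
Remaining ties prefer the allelic ratio closest to the balanced expectation
2/3, then the leftmost position, which makes the ranking deterministic.

Synonymous and noncoding variants are never candidates; a strain whose
surviving variants are all synonymous/noncoding yields "no candidate".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .callset_io import allelic_ratio
from .effect_annotation import SEVERITY_RANK, EffectAnnotation
from .errors import ValidationError
from .genome_model import MapZone
from .strain_qc import QCReport

ZONE_BONUS = 0.5
BALANCED_RATIO = 2.0 / 3.0

# categories eligible as causal candidates (severity above synonymous)
CANDIDATE_CATEGORIES = frozenset(
    c for c, rank in SEVERITY_RANK.items() if rank >= SEVERITY_RANK["missense"]
)

__all__ = ["RankedCandidate", "CandidateReport", "severity_rank", "rank_candidates", "cohort_summary"]


def severity_rank(category: str) -> int:
    """Ordinal severity of a consequence category (nonsense highest)."""
    try:
        return SEVERITY_RANK[category]
    except KeyError:
        raise ValidationError(f"unknown category {category!r}") from None


@dataclass(frozen=True)
class RankedCandidate:
    annotation: EffectAnnotation
    severity: int
    in_zone: bool
    score: float


@dataclass
class CandidateReport:
    strain_id: str
    ranked: list[RankedCandidate] = field(default_factory=list)
    qc: QCReport | None = None

    @property
    def top_candidate(self) -> EffectAnnotation | None:
        return self.ranked[0].annotation if self.ranked else None


def rank_candidates(
    strain_id: str,
    annotations: list[EffectAnnotation],
    zone: MapZone | None,
    qc: QCReport,
    zone_bonus: float = ZONE_BONUS,
) -> CandidateReport:
    """Score and sort candidate annotations for one QC-passing strain.

    score = severity + zone_bonus·[variant in mapped zone]; the bonus is
    deliberately smaller than one severity step.
    """
    if qc.exclude:
        raise ValidationError(
            f"strain {strain_id} failed QC and cannot be ranked: {'; '.join(qc.reasons)}"
        )
    entries = []
    for ann in annotations:
        if ann.category not in CANDIDATE_CATEGORIES:
            continue
        in_zone = zone is not None and zone.contains(ann.variant.position)
        sev = severity_rank(ann.category)
        score = sev + (zone_bonus if in_zone else 0.0)
        ratio = allelic_ratio(ann.variant) if ann.variant.depth > 0 else float("nan")
        entries.append((score, -abs(ratio - BALANCED_RATIO), -ann.variant.position, ann, sev, in_zone))
    entries.sort(key=lambda e: (e[0], e[1], e[2]), reverse=True)
    ranked = [
        RankedCandidate(annotation=ann, severity=sev, in_zone=in_zone, score=score)
        for score, _, _, ann, sev, in_zone in entries
    ]
    return CandidateReport(strain_id=strain_id, ranked=ranked, qc=qc)


def cohort_summary(reports: list[CandidateReport]) -> pd.DataFrame:
    """Per-strain summary table: top gene, category, amino-acid change, zone.

    Strains without an eligible candidate are reported as "no candidate".
    """
    if not reports:
        raise ValidationError("cohort_summary needs at least one report")
    rows = []
    for rep in reports:
        top = rep.top_candidate
        if top is None:
            rows.append(
                {
                    "strain_id": rep.strain_id,
                    "gene_id": "",
                    "category": "no candidate",
                    "aa_change": "",
                    "chrom": "",
                    "pos": "",
                    "in_zone": "",
                }
            )
        else:
            rows.append(
                {
                    "strain_id": rep.strain_id,
                    "gene_id": top.gene_id or "",
                    "category": top.category,
                    "aa_change": top.aa_change,
                    "chrom": top.variant.chromosome,
                    "pos": top.variant.position + 1,
                    "in_zone": rep.ranked[0].in_zone,
                }
            )
    return pd.DataFrame(
        rows, columns=["strain_id", "gene_id", "category", "aa_change", "chrom", "pos", "in_zone"]
    )
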