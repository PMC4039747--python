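"""The three candidate filters: background subtraction, ratio window, region.

Each filter is a pure predicate over calls, so the filters commute and are
idempotent; composition order never changes the surviving set.

* background subtraction removes every call whose normalized
  (chrom, pos, ref, alt) key appears in the parental strain;
* the allelic-ratio window keeps calls in [0.40, 0.90] — wide enough to
  retain balanced 2-of-3 sites under binomial sampling noise, while
  rejecting homozygous (~1) and single-copy (~1/3) sites;
* the region filter keeps calls inside the duplicated interval, where a
  rescued lethal must lie;
* the coding filter keeps calls touching a CDS or the minimal 2 bp splice
  signals (so splice candidates are not discarded by the location rule).
"""

from __future__ import annotations

from dataclasses import dataclass

from .callset_io import VariantCall
from .errors import ValidationError
from .genome_model import BalancerConfig, GeneModel

__all__ = ["FilterConfig", "subtract_background", "filter_by_ratio", "filter_by_region", "filter_coding"]


@dataclass(frozen=True)
class FilterConfig:
    """Ratio window (inclusive) and region for candidate filtering."""

    ratio_low: float = 0.40
    ratio_high: float = 0.90
    coding_only: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.ratio_low < self.ratio_high <= 1:
            raise ValidationError(
                f"need 0 <= ratio_low < ratio_high <= 1, got "
                f"[{self.ratio_low}, {self.ratio_high}]"
            )


def subtract_background(
    strain_calls: list[VariantCall], parental_calls: list[VariantCall]
) -> list[VariantCall]:
    """Remove strain calls whose identity key occurs in the parental set."""
    background = {c.key for c in parental_calls}
    return [c for c in strain_calls if c.key not in background]


def filter_by_ratio(
    calls: list[VariantCall], config: FilterConfig = FilterConfig()
) -> list[VariantCall]:
    """Keep calls whose allelic ratio lies in the inclusive window.

    Zero-depth calls have no ratio and are dropped.
    """
    kept = []
    for c in calls:
        total = c.ref_count + c.alt_count
        if total == 0:
            continue
        ratio = c.alt_count / total
        if config.ratio_low <= ratio <= config.ratio_high:
            kept.append(c)
    return kept


def filter_by_region(
    calls: list[VariantCall], config: BalancerConfig
) -> list[VariantCall]:
    """Keep calls inside the duplicated interval (half-open)."""
    return [c for c in calls if config.in_duplication(c.chromosome, c.position)]


def _touches_gene(call: VariantCall, gene: GeneModel) -> bool:
    if gene.chromosome != call.chromosome:
        return False
    if call.kind == "SNV":
        return gene.contains_cds(call.position) or call.position in gene.splice_positions()
    if call.kind == "deletion":
        d = len(call.ref) - len(call.alt)
        span = range(call.position + 1, call.position + 1 + d)
        splice = gene.splice_positions()
        return any(gene.contains_cds(p) or p in splice for p in span)
    # insertion: coding when the anchor junction is inside a CDS segment,
    # splice-relevant when either neighbour of the junction is a signal base
    splice = gene.splice_positions()
    return (
        any(s <= call.position < e - 1 for s, e in gene.cds_segments)
        or call.position in splice
        or call.position + 1 in splice
    )


def filter_coding(
    calls: list[VariantCall], gene_models: list[GeneModel]
) -> list[VariantCall]:
    """Keep calls overlapping a CDS segment or a 2 bp splice signal."""
    return [c for c in calls if any(_touches_gene(c, g) for g in gene_models)]
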