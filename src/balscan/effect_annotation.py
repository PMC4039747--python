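"""Coding-consequence classification of small variants.

Each variant is assigned one of seven categories:

    nonsense          SNV creating a stop codon in a CDS
    missense          SNV changing the encoded amino acid
    synonymous        SNV leaving the amino acid unchanged
    splice_signal     SNV/indel hitting the 2 intronic bp at an intron end
    frameshift_indel  indel changing the coding length by a non-multiple of 3
    inframe_indel     indel changing the coding length by a multiple of 3
    noncoding         anything else

Amino-acid changes are reported as "<ref> > <alt>" with '*' for a stop
(e.g. "Q > *").  Minus-strand genes are classified on the coding strand.
Stop-loss and start-loss substitutions fold into missense, keeping the
category set to exactly the seven above.
"""

from __future__ import annotations

from dataclasses import dataclass

from .callset_io import VariantCall
from .errors import ValidationError
from .genome_model import GeneModel, Genome, extract_cds, reverse_complement, translate_cds

CATEGORIES = (
    "nonsense",
    "missense",
    "synonymous",
    "splice_signal",
    "frameshift_indel",
    "inframe_indel",
    "noncoding",
)

# Ordinal severity used both for multi-gene disambiguation here and for
# candidate ranking downstream.  Nonsense and frameshifts are both null-like;
# nonsense is placed on top (the configuration is overridable at ranking).
SEVERITY_RANK = {
    "nonsense": 6,
    "frameshift_indel": 5,
    "splice_signal": 4,
    "inframe_indel": 3,
    "missense": 2,
    "synonymous": 1,
    "noncoding": 0,
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "EffectAnnotation",
    "CATEGORIES",
    "SEVERITY_RANK",
    "classify_effect",
    "annotate_all",
    "aa_change_notation",
]


@dataclass(frozen=True)
class EffectAnnotation:
    variant: VariantCall
    gene_id: str | None
    category: str
    aa_change: str = ""
    codon_index: int | None = None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if (self.category == "noncoding") != (self.gene_id is None):
            raise ValidationError("category is noncoding iff gene_id is None")
        if self.aa_change and self.category not in {"nonsense", "missense", "synonymous"}:
            raise ValidationError("aa_change only applies to coding substitutions")


def aa_change_notation(ref_aa: str, alt_aa: str) -> str:
    """Amino-acid change in '<ref> > <alt>' form ('*' marks a stop)."""
    return f"{ref_aa} > {alt_aa}"


def _classify_snv(call: VariantCall, gene: GeneModel, cds: str) -> EffectAnnotation | None:
    offset = gene.coding_offset(call.position)
    if offset is not None:
        codon_index = offset // 3
        within = offset % 3
        codon = cds[codon_index * 3 : codon_index * 3 + 3]
        alt_base = call.alt if gene.strand == "+" else call.alt.translate(_COMPLEMENT)
        alt_codon = codon[:within] + alt_base + codon[within + 1 :]
        ref_aa = translate_cds(codon)
        alt_aa = translate_cds(alt_codon)
        if alt_aa == ref_aa:
            category = "synonymous"
        elif alt_aa == "*":
            category = "nonsense"
        else:
            # includes stop-loss and start-loss, folded into missense
            category = "missense"
        return EffectAnnotation(
            variant=call,
            gene_id=gene.gene_id,
            category=category,
            aa_change=aa_change_notation(ref_aa, alt_aa),
            codon_index=codon_index,
        )
    if call.position in gene.splice_positions():
        return EffectAnnotation(call, gene.gene_id, "splice_signal")
    return None


def _indel_span(call: VariantCall) -> tuple[int, int]:
    """Genomic interval of bases removed by a deletion (empty for insertions).

    VCF anchors indels on a shared leading base, so a deletion of length d
    removes [position+1, position+1+d).
    """
    if call.kind == "deletion":
        d = len(call.ref) - len(call.alt)
        return (call.position + 1, call.position + 1 + d)
    return (call.position + 1, call.position + 1)


def _classify_indel(call: VariantCall, gene: GeneModel) -> EffectAnnotation | None:
    if call.kind == "insertion":
        inserted = len(call.alt) - len(call.ref)
        # bases are inserted between position and position+1; they become
        # coding when that junction lies strictly inside a CDS segment
        coding_change = (
            inserted
            if any(s <= call.position < e - 1 for s, e in gene.cds_segments)
            else 0
        )
    else:
        del_start, del_end = _indel_span(call)
        coding_change = -sum(
            max(0, min(del_end, e) - max(del_start, s)) for s, e in gene.cds_segments
        )
    if coding_change != 0:
        category = "frameshift_indel" if coding_change % 3 != 0 else "inframe_indel"
        return EffectAnnotation(call, gene.gene_id, category)
    span = range(*_indel_span(call))
    if any(p in gene.splice_positions() for p in span):
        return EffectAnnotation(call, gene.gene_id, "splice_signal")
    return None


def classify_effect(
    call: VariantCall,
    genes: list[GeneModel],
    genome: Genome,
    cds_cache: dict[str, str] | None = None,
) -> EffectAnnotation:
    """Classify one variant against a set of gene models.

    A variant overlapping several genes keeps the most severe classification
    and is flagged ambiguous.  ``cds_cache`` (gene_id -> spliced CDS) avoids
    re-extracting sequence when annotating many variants.
    """
    hits: list[EffectAnnotation] = []
    for gene in genes:
        if gene.chromosome != call.chromosome:
            continue
        # generous overlap window: indel span plus splice margin
        lo, hi = gene.start - len(call.ref) - 2, gene.end + 2
        if not lo <= call.position < hi:
            continue
        if call.kind == "SNV":
            if cds_cache is not None and gene.gene_id in cds_cache:
                cds = cds_cache[gene.gene_id]
            else:
                cds = extract_cds(gene, genome)
                if cds_cache is not None:
                    cds_cache[gene.gene_id] = cds
            ann = _classify_snv(call, gene, cds)
        else:
            ann = _classify_indel(call, gene)
        if ann is not None:
            hits.append(ann)
    if not hits:
        return EffectAnnotation(call, None, "noncoding")
    hits.sort(key=lambda a: SEVERITY_RANK[a.category], reverse=True)
    top = hits[0]
    if len(hits) > 1:
        top = EffectAnnotation(
            variant=top.variant,
            gene_id=top.gene_id,
            category=top.category,
            aa_change=top.aa_change,
            codon_index=top.codon_index,
            ambiguous=True,
        )
    return top


def annotate_all(
    calls: list[VariantCall], genes: list[GeneModel], genome: Genome
) -> list[EffectAnnotation]:
    """One annotation per call, input order preserved."""
    cache: dict[str, str] = {}
    return [classify_effect(c, genes, genome, cds_cache=cache) for c in calls]
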