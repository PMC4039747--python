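"""Brute-force consequence oracle: mutate, re-extract, re-translate, compare.

Independent of the codon-arithmetic classifier: applies the substitution to
the chromosome string, re-extracts the spliced CDS through the gene model
and compares the full translated proteins.
"""

from __future__ import annotations

from balscan.callset_io import VariantCall
from balscan.genome_model import GeneModel, Genome, extract_cds, translate_cds


def oracle_classify_snv(
    call: VariantCall, genes: list[GeneModel], genome: Genome
) -> tuple[str, str | None]:
    """(category, gene_id) for a SNV, by whole-protein comparison."""
    chrom_seq = genome.sequences[call.chromosome]
    assert chrom_seq[call.position] == call.ref
    mutated = Genome(
        {
            call.chromosome: chrom_seq[: call.position]
            + call.alt
            + chrom_seq[call.position + 1 :]
        }
    )
    best: tuple[str, str | None] = ("noncoding", None)
    # severity order for resolving multi-gene overlaps (matches the ranking scheme)
    order = ["noncoding", "synonymous", "missense", "splice_signal", "nonsense"]
    for gene in genes:
        if gene.chromosome != call.chromosome:
            continue
        category = None
        if gene.contains_cds(call.position):
            ref_protein = translate_cds(extract_cds(gene, genome))
            alt_protein = translate_cds(extract_cds(gene, mutated))
            if alt_protein == ref_protein:
                category = "synonymous"
            else:
                changed = next(
                    i for i, (a, b) in enumerate(zip(ref_protein, alt_protein)) if a != b
                )
                category = "nonsense" if alt_protein[changed] == "*" else "missense"
        elif call.position in gene.splice_positions():
            category = "splice_signal"
        if category is not None and order.index(category) > order.index(best[0]):
            best = (category, gene.gene_id)
    return best
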